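"""Parametric 3-D model of the proximal locking screws.

A proximal-humerus locking plate carries seven proximal screws (ids 6..12;
Screw 6 is the inferior-medial *calcar* screw).  Each screw head is fixed at
the plate; the tip can tilt away from the neutral trajectory on a discrete
angle grid in two directions: distal->proximal (dp) and posterior->anterior
(ap).  A screw is modelled as a *capsule*: a line segment from head to tip
swept by the screw radius (1.5 mm for a 3 mm-diameter screw).  Screw length
is chosen so the tip sits a fixed tip-to-joint distance (TJD, 8 mm) short of
the glenohumeral joint surface, modelled as a sphere.  Two screws collide
when the distance between their axis segments drops below the sum of their
radii.

Coordinate convention (right-handed, mm): x = anterior, y = proximal,
z = lateral.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SCREW_IDS",
    "CALCAR_SCREW",
    "ANGLE_COLUMNS",
    "DEFAULT_TJD_MM",
    "DEFAULT_SCREW_RADIUS_MM",
    "GeometryError",
    "HeadSphere",
    "ScrewAnchor",
    "OrientationState",
    "ScrewPose",
    "Configuration",
    "PlateGeometry",
    "tilt_direction",
    "solve_length",
    "segment_distance",
    "detect_collision",
    "realize_configuration",
    "default_geometry",
    "pairwise_collision_tables",
    "collision_flags_batch",
]

SCREW_IDS: tuple[int, ...] = (6, 7, 8, 9, 10, 11, 12)
CALCAR_SCREW = 6

#: dataset / design column order: s6_dp, s6_ap, ..., s12_dp, s12_ap
ANGLE_COLUMNS: tuple[str, ...] = tuple(
    f"s{i}_{ax}" for i in SCREW_IDS for ax in ("dp", "ap")
)

DEFAULT_TJD_MM = 8.0
DEFAULT_SCREW_RADIUS_MM = 1.5

_UNIT_TOL = 1e-9


class GeometryError(ValueError):
    """Raised when a screw trajectory cannot be realized."""


def _vec(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("vector components must be finite")
    return a


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("cannot normalize the zero vector")
    return v / n


@dataclass(frozen=True)
class HeadSphere:
    """Spherical model of the glenohumeral joint surface (centre + radius, mm)."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", _vec(self.center))
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class ScrewAnchor:
    """Fixed head position and orthonormal tilt frame of one screw.

    ``neutral_axis`` is the 0°–0° trajectory; ``u_dp``/``u_ap`` are the unit
    tilt axes along which the tip moves for positive distal->proximal and
    posterior->anterior angles.  The three vectors form an orthonormal frame.
    """

    screw_id: int
    head_point: np.ndarray
    neutral_axis: np.ndarray
    u_dp: np.ndarray
    u_ap: np.ndarray
    radius: float = DEFAULT_SCREW_RADIUS_MM

    def __post_init__(self):
        object.__setattr__(self, "head_point", _vec(self.head_point))
        for name in ("neutral_axis", "u_dp", "u_ap"):
            v = _vec(getattr(self, name))
            if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
                raise ValueError(f"{name} must be unit length")
            object.__setattr__(self, name, v)
        for a, b in (("neutral_axis", "u_dp"), ("neutral_axis", "u_ap"), ("u_dp", "u_ap")):
            if abs(float(getattr(self, a) @ getattr(self, b))) > _UNIT_TOL:
                raise ValueError(f"{a} and {b} must be orthogonal")
        if not self.radius > 0:
            raise ValueError("screw radius must be positive")


@dataclass(frozen=True)
class OrientationState:
    """Tip tilt of one screw in degrees: (dp_deg, ap_deg).

    Negative dp = distal, positive dp = proximal; negative ap = posterior,
    positive ap = anterior.
    """

    dp_deg: float = 0.0
    ap_deg: float = 0.0


@dataclass(frozen=True)
class ScrewPose:
    """A realized screw: head, unit direction, TJD-constrained length, tip."""

    screw_id: int
    head_point: np.ndarray
    direction: np.ndarray
    length: float
    tip: np.ndarray
    radius: float = DEFAULT_SCREW_RADIUS_MM


@dataclass(frozen=True)
class Configuration:
    """The 14-dimensional design point: one OrientationState per screw."""

    states: Mapping[int, OrientationState]

    def __post_init__(self):
        if tuple(sorted(self.states)) != SCREW_IDS:
            raise ValueError(f"configuration must cover screw ids {SCREW_IDS}")
        object.__setattr__(self, "states", dict(self.states))

    @classmethod
    def neutral(cls) -> "Configuration":
        return cls({i: OrientationState(0.0, 0.0) for i in SCREW_IDS})

    @classmethod
    def from_angles(cls, angles: Sequence[float]) -> "Configuration":
        """Build from a flat row in ANGLE_COLUMNS order."""
        a = np.asarray(angles, dtype=float).ravel()
        if a.shape != (14,):
            raise ValueError("expected 14 angles (7 screws x 2 axes)")
        return cls(
            {
                sid: OrientationState(float(a[2 * k]), float(a[2 * k + 1]))
                for k, sid in enumerate(SCREW_IDS)
            }
        )

    def to_angles(self) -> np.ndarray:
        """Flat 14-vector in ANGLE_COLUMNS order."""
        out = np.empty(14)
        for k, sid in enumerate(SCREW_IDS):
            st = self.states[sid]
            out[2 * k] = st.dp_deg
            out[2 * k + 1] = st.ap_deg
        return out


# ---------------------------------------------------------------------------
# core operations


def tilt_direction(anchor: ScrewAnchor, state: OrientationState) -> np.ndarray:
    """Unit direction of a screw tilted by (dp_deg, ap_deg).

    Tangent-offset composition: the tilted axis is
    ``normalize(n + tan(dp)*u_dp + tan(ap)*u_ap)``, which makes single-axis
    tilts exact rotations by the stated angle and is symmetric in the two
    axes.  (0, 0) returns the neutral axis exactly.
    """
    if state.dp_deg == 0.0 and state.ap_deg == 0.0:
        return anchor.neutral_axis.copy()
    v = (
        anchor.neutral_axis
        + math.tan(math.radians(state.dp_deg)) * anchor.u_dp
        + math.tan(math.radians(state.ap_deg)) * anchor.u_ap
    )
    return _unit(v)


def solve_length(
    anchor_or_head, direction: np.ndarray, sphere: HeadSphere, tjd: float = DEFAULT_TJD_MM
) -> float:
    """Screw length putting the tip `tjd` mm short of the joint sphere.

    Solves the ray-sphere quadratic for the *far* intersection t* of the ray
    head + t*direction with the sphere surface and returns t* - tjd.
    """
    head = anchor_or_head.head_point if isinstance(anchor_or_head, ScrewAnchor) else _vec(anchor_or_head)
    d = _unit(_vec(direction))
    if tjd < 0:
        raise ValueError("tjd must be non-negative")
    m = head - sphere.center
    b = float(d @ m)
    c = float(m @ m) - sphere.radius**2
    disc = b * b - c
    if disc < 0:
        raise GeometryError("trajectory misses joint surface")
    t_far = -b + math.sqrt(disc)
    if t_far <= 0:
        raise GeometryError("trajectory misses joint surface")
    length = t_far - tjd
    if length <= 0:
        raise GeometryError("screw head too close to joint")
    return length


def segment_distance(p1, q1, p2, q2) -> float:
    """Exact minimum Euclidean distance between two closed 3-D segments.

    Closed-form closest-point computation with parameter clamping; handles
    parallel and degenerate (point) segments.  Symmetric in its arguments.
    """
    p1, q1, p2, q2 = _vec(p1), _vec(q1), _vec(p2), _vec(q2)
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    eps = 1e-14
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r))
    if a <= eps:
        s = 0.0
        t = min(max(f / e, 0.0), 1.0)
    else:
        c = float(d1 @ r)
        if e <= eps:
            t = 0.0
            s = min(max(-c / a, 0.0), 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            # parallel segments -> pick s = 0, then clamp t and recompute
            s = min(max((b * f - c * e) / denom, 0.0), 1.0) if denom > eps * a * e else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(max(-c / a, 0.0), 1.0)
            elif t > 1.0:
                t = 1.0
                s = min(max((b - c) / a, 0.0), 1.0)
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


def detect_collision(
    poses: Sequence[ScrewPose],
) -> tuple[bool, list[tuple[int, int]]]:
    """Pairwise capsule contact test.

    A pair collides when the distance between the axis segments is strictly
    below the sum of the radii (grazing contact is not a collision).  Returns
    the overall flag and every colliding (id, id) pair, sorted.
    """
    if len(poses) < 2:
        raise ValueError("need at least two poses")
    pairs: list[tuple[int, int]] = []
    ordered = sorted(poses, key=lambda p: p.screw_id)
    for pa, pb in itertools.combinations(ordered, 2):
        d = segment_distance(pa.head_point, pa.tip, pb.head_point, pb.tip)
        if d < pa.radius + pb.radius:
            pairs.append((pa.screw_id, pb.screw_id))
    return (len(pairs) > 0, pairs)


def _realize_one(
    anchor: ScrewAnchor, state: OrientationState, sphere: HeadSphere, tjd: float
) -> ScrewPose:
    d = tilt_direction(anchor, state)
    try:
        length = solve_length(anchor, d, sphere, tjd)
    except GeometryError as err:
        raise GeometryError(f"screw {anchor.screw_id}: {err}") from err
    tip = anchor.head_point + length * d
    return ScrewPose(anchor.screw_id, anchor.head_point, d, length, tip, anchor.radius)


def realize_configuration(
    anchors: Mapping[int, ScrewAnchor],
    sphere: HeadSphere,
    config: Configuration,
    tjd: float = DEFAULT_TJD_MM,
) -> tuple[list[ScrewPose], bool, list[tuple[int, int]]]:
    """Realize all seven screws and test for collisions.

    Composes tilt_direction -> solve_length -> detect_collision; geometry
    errors are tagged with the offending screw id.
    """
    poses = [
        _realize_one(anchors[sid], config.states[sid], sphere, tjd) for sid in SCREW_IDS
    ]
    flag, pairs = detect_collision(poses)
    return poses, flag, pairs


# ---------------------------------------------------------------------------
# default fixture geometry


@dataclass(frozen=True)
class PlateGeometry:
    """Bundle of anchors + joint sphere + TJD for one plate/bone fixture."""

    anchors: Mapping[int, ScrewAnchor]
    sphere: HeadSphere
    tjd: float = DEFAULT_TJD_MM

    def __post_init__(self):
        object.__setattr__(self, "anchors", dict(self.anchors))
        if tuple(sorted(self.anchors)) != SCREW_IDS:
            raise ValueError(f"geometry must define screw ids {SCREW_IDS}")

    def realize(self, config: Configuration):
        return realize_configuration(self.anchors, self.sphere, config, self.tjd)


def _anchor_from_target(
    screw_id: int, head, target, radius=DEFAULT_SCREW_RADIUS_MM
) -> ScrewAnchor:
    """Anchor whose neutral axis points from head to target, with the tilt
    frame built by Gram-Schmidt against global +y (proximal) and +x (anterior)."""
    head = _vec(head)
    n = _unit(_vec(target) - head)
    y_hat = np.array([0.0, 1.0, 0.0])
    x_hat = np.array([1.0, 0.0, 0.0])
    u_dp = _unit(y_hat - (y_hat @ n) * n)
    u_ap = np.cross(n, u_dp)
    if u_ap @ x_hat < 0:  # positive ap tilts the tip anteriorly
        u_ap = -u_ap
    return ScrewAnchor(screw_id, head, n, u_dp, u_ap, radius)


# Synthetic default fixture: seven screw heads on the lateral plate surface,
# neutral axes fanning medially into a 24 mm humeral-head sphere.  The layout
# is documented, collision-free at neutral, and produces collisions when
# adjacent screws converge (e.g. screws 7/8 tilted toward each other by 10°).
# It does not reproduce any proprietary plate.
_FIXTURE_LAYOUT = {
    # screw_id: (head [x, y, z], neutral-axis target [x, y, z]).  The fan is
    # nearly parallel (targets at ~0.78x the head footprint), so the neutral
    # configuration clears by ~4.2 mm while roughly four in five random grid
    # configurations collide — the prevalence regime a tightly clustered
    # seven-screw proximal cluster produces.
    6: ((0.0, -14.0, 28.0), (0.0, -10.92, -8.0)),  # calcar: inferior-medial
    7: ((-4.0, -6.0, 29.0), (-3.12, -4.68, -8.0)),
    8: ((4.0, -6.0, 29.0), (3.12, -4.68, -8.0)),
    9: ((-4.0, 2.0, 29.0), (-3.12, 2.56, -6.0)),
    10: ((4.0, 2.0, 29.0), (3.12, 2.56, -6.0)),
    11: ((-3.0, 9.0, 28.0), (-2.34, 9.02, -3.0)),
    12: ((3.0, 9.0, 28.0), (2.34, 9.02, -3.0)),
}


def default_geometry() -> PlateGeometry:
    """The package's default synthetic plate/bone fixture (see module docs)."""
    sphere = HeadSphere(np.zeros(3), 24.0)
    anchors = {
        sid: _anchor_from_target(sid, head, target)
        for sid, (head, target) in _FIXTURE_LAYOUT.items()
    }
    return PlateGeometry(anchors, sphere, DEFAULT_TJD_MM)


# ---------------------------------------------------------------------------
# vectorized collision labelling on a discrete angle grid
#
# A screw's pose depends only on its own (dp, ap) state, so on an L-level grid
# each screw has L*L possible poses and each screw pair has an (L*L, L*L)
# boolean collision table.  Labelling N configurations then reduces to 21
# table lookups per row.


def pairwise_collision_tables(
    geometry: PlateGeometry, levels_deg: Sequence[float]
) -> dict[tuple[int, int], np.ndarray]:
    """Precompute per-pair collision tables over the grid.

    State index of a screw is dp_index * L + ap_index with levels in the
    given order.
    """
    levels = [float(v) for v in levels_deg]
    L = len(levels)
    poses: dict[int, list[ScrewPose]] = {}
    for sid in SCREW_IDS:
        anchor = geometry.anchors[sid]
        poses[sid] = [
            _realize_one(anchor, OrientationState(dp, ap), geometry.sphere, geometry.tjd)
            for dp in levels
            for ap in levels
        ]
    tables: dict[tuple[int, int], np.ndarray] = {}
    for ia, ib in itertools.combinations(SCREW_IDS, 2):
        tab = np.zeros((L * L, L * L), dtype=bool)
        for i, pa in enumerate(poses[ia]):
            for j, pb in enumerate(poses[ib]):
                d = segment_distance(pa.head_point, pa.tip, pb.head_point, pb.tip)
                tab[i, j] = d < pa.radius + pb.radius
        tables[(ia, ib)] = tab
    return tables


def collision_flags_batch(
    angles: np.ndarray,
    tables: Mapping[tuple[int, int], np.ndarray],
    levels_deg: Sequence[float],
) -> np.ndarray:
    """True-collision flags for an (N, 14) array of on-grid angle rows."""
    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 2 or angles.shape[1] != 14:
        raise ValueError("angles must be an (N, 14) array")
    levels = np.asarray([float(v) for v in levels_deg])
    L = len(levels)
    idx = np.searchsorted(levels, angles)
    if not np.all((idx < L) & np.isclose(levels[np.minimum(idx, L - 1)], angles)):
        raise ValueError("angles contain off-grid values")
    state = idx[:, 0::2] * L + idx[:, 1::2]  # (N, 7)
    col = dict(zip(SCREW_IDS, range(7)))
    flags = np.zeros(angles.shape[0], dtype=bool)
    for (ia, ib), tab in tables.items():
        flags |= tab[state[:, col[ia]], state[:, col[ib]]]
    return flags
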