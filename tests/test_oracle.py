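"""Synthetic strain oracle: density-modulus law, response-surface anchors,
calcar dominance, noise model and dataset generation."""

import math

import numpy as np
import pandas as pd
import pytest

from screwscape.design import TRAINING_GRID, lhs_design
from screwscape.geometry import SCREW_IDS, Configuration, OrientationState
from screwscape.oracle import (
    DATASET_COLUMNS,
    STRAIN_KEYS,
    OracleParams,
    default_params,
    density_to_modulus,
    generate_dataset,
    sample_record,
    strain_response,
    strain_response_batch,
)
from screwscape.oracle import _mixture_quantile, _Z90


def _single_screw_config(sid, dp, ap=0.0):
    states = {i: OrientationState() for i in SCREW_IDS}
    states[sid] = OrientationState(dp, ap)
    return Configuration(states)


class TestDensityToModulus:
    def test_unit_density(self):
        assert density_to_modulus(1.0) == pytest.approx(6850.0)

    def test_zero_density(self):
        assert density_to_modulus(0.0) == 0.0

    def test_power_law_consistency(self):
        # cross-check the power against exp(1.49 * ln rho)
        assert density_to_modulus(0.5) == pytest.approx(
            6850.0 * math.exp(1.49 * math.log(0.5)), rel=1e-12
        )

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            density_to_modulus(-0.1)


class TestStrainResponse:
    def test_neutral_returns_baselines_exactly(self, params):
        rec = strain_response(Configuration.neutral(), False, params)
        for s in SCREW_IDS:
            assert rec.e50[s] == pytest.approx(params.baseline_strain[s], rel=1e-12)
            assert rec.e90[s] == pytest.approx(
                params.gamma[s] * params.baseline_strain[s], rel=1e-12
            )

    def test_calcar_distal_tilt_raises_pooled_strain_36pct(self, params):
        """Only the calcar screw tilted 10 deg distally: the pooled 90th
        percentile rises by ~36% (the surface's calibration anchor)."""
        neutral = strain_response(Configuration.neutral(), False, params)
        tilted = strain_response(_single_screw_config(6, -10.0), False, params)
        ratio = tilted.e90["all"] / neutral.e90["all"]
        assert ratio - 1.0 == pytest.approx(0.3645, abs=1e-6)

    def test_calcar_proximal_tilt_lowers_pooled_strain(self, params):
        neutral = strain_response(Configuration.neutral(), False, params)
        tilted = strain_response(_single_screw_config(6, 10.0), False, params)
        assert tilted.e90["all"] / neutral.e90["all"] - 1.0 == pytest.approx(
            -0.1278, abs=1e-6
        )

    def test_calcar_own_strain_anchors(self, params):
        neutral = strain_response(Configuration.neutral(), False, params)
        distal = strain_response(_single_screw_config(6, -10.0), False, params)
        proximal = strain_response(_single_screw_config(6, 10.0), False, params)
        assert distal.e50[6] / neutral.e50[6] == pytest.approx(1.4506, abs=1e-9)
        assert proximal.e50[6] / neutral.e50[6] == pytest.approx(0.7751, abs=1e-9)

    def test_doubling_baseline_doubles_screw_strain(self, params):
        doubled = OracleParams(
            baseline_strain={**params.baseline_strain, 7: 2 * params.baseline_strain[7]},
            gamma=params.gamma,
            self_coef=params.self_coef,
            cross_coef=params.cross_coef,
            calcar_gain=params.calcar_gain,
            collision_inflation=params.collision_inflation,
            noise_cv=0.0,
            modulus_scale_exponent=params.modulus_scale_exponent,
            rho_app=params.rho_app,
            rho_ref=params.rho_ref,
            seed=params.seed,
        )
        cfg = _single_screw_config(8, 5.0, -5.0)
        r1 = strain_response(cfg, False, params)
        r2 = strain_response(cfg, False, doubled)
        assert r2.e50[7] == pytest.approx(2 * r1.e50[7], rel=1e-12)
        assert r2.e90[7] == pytest.approx(2 * r1.e90[7], rel=1e-12)

    def test_collision_inflates_strain(self, params):
        cfg = Configuration.neutral()
        clean = strain_response(cfg, False, params)
        hit = strain_response(cfg, True, params)
        factor = math.exp(params.collision_inflation)
        for s in SCREW_IDS:
            assert hit.e50[s] / clean.e50[s] == pytest.approx(factor, rel=1e-12)

    def test_calcar_marginal_effect_exceeds_others_by_exactly_gain(self, params):
        """The per-source log-strain shifts of the calcar screw are exactly
        calcar_gain times every other screw's."""
        neutral = np.log(strain_response_batch(np.zeros((1, 14)), [0], params)["e50"])
        shifts = {}
        for k, sid in enumerate(SCREW_IDS):
            effects = []
            for dp, ap in [(-10, 0), (10, 0), (0, -10), (0, 10), (5, 5)]:
                a = np.zeros((1, 14))
                a[0, 2 * k] = dp
                a[0, 2 * k + 1] = ap
                ln = np.log(strain_response_batch(a, [0], params)["e50"])
                effects.append(np.abs(ln - neutral).mean())
            shifts[sid] = np.mean(effects)
        for sid in SCREW_IDS[1:]:
            assert shifts[6] / shifts[sid] == pytest.approx(params.calcar_gain, rel=1e-9)

    def test_stiffer_bone_lowers_strain(self, params):
        stiffer = OracleParams(
            baseline_strain=params.baseline_strain,
            gamma=params.gamma,
            self_coef=params.self_coef,
            cross_coef=params.cross_coef,
            calcar_gain=params.calcar_gain,
            collision_inflation=params.collision_inflation,
            noise_cv=0.0,
            modulus_scale_exponent=params.modulus_scale_exponent,
            rho_app={**params.rho_app, 9: 0.4},
            rho_ref=params.rho_ref,
            seed=params.seed,
        )
        base = strain_response(Configuration.neutral(), False, params)
        hard = strain_response(Configuration.neutral(), False, stiffer)
        assert hard.e50[9] < base.e50[9]
        assert hard.e50[10] == pytest.approx(base.e50[10], rel=1e-12)

    def test_pooled_quantile_matches_scalar_root(self, params):
        """Vectorized mixture quantile agrees with a brute-force bisection."""
        from scipy.optimize import brentq
        from scipy.special import ndtr

        rng = np.random.default_rng(0)
        lnm = rng.normal(7.0, 0.4, size=(5, 7))
        gamma = np.array([params.gamma[s] for s in SCREW_IDS])
        sigma = np.log(gamma) / _Z90
        for p in (0.5, 0.9):
            got = _mixture_quantile(lnm, sigma, p)
            for i in range(5):
                f = lambda x: ndtr((x - lnm[i]) / sigma).mean() - p
                expected = math.exp(brentq(f, lnm[i].min() - 10, lnm[i].max() + 10, xtol=1e-13))
                assert got[i] == pytest.approx(expected, rel=1e-9)


class TestNoise:
    def test_zero_cv_is_noise_free(self, params):
        p0 = default_params(seed=0, noise_cv=0.0)
        cfg = _single_screw_config(7, 5.0)
        clean = strain_response(cfg, False, p0)
        drawn = sample_record(cfg, False, p0, draw_index=5)
        assert drawn.e50 == clean.e50 and drawn.e90 == clean.e90

    def test_same_draw_index_is_bit_identical(self, params):
        cfg = Configuration.neutral()
        a = sample_record(cfg, False, params, draw_index=17)
        b = sample_record(cfg, False, params, draw_index=17)
        assert a.e50 == b.e50 and a.e90 == b.e90

    def test_unit_median_noise(self, params):
        """Median over many draws stays within 1% of the noise-free value."""
        from screwscape.oracle import _noise_factors

        factors = np.array([_noise_factors(params, i) for i in range(10_000)])
        med = np.median(factors, axis=0)
        assert np.all(np.abs(med - 1.0) < 0.01)

    def test_ordering_preserved_per_key(self, params):
        cfg = _single_screw_config(6, -10.0)
        rec = sample_record(cfg, True, params, draw_index=3)
        for k in STRAIN_KEYS:
            assert rec.e90[k] >= rec.e50[k]


class TestGenerateDataset:
    def test_schema(self, small_dataset):
        assert list(small_dataset.columns) == list(DATASET_COLUMNS)
        assert len(small_dataset.columns) == 14 + 1 + 16

    def test_flags_match_exact_geometry(self, geom, params, small_dataset):
        sub = small_dataset.sample(20, random_state=1)
        for _, row in sub.iterrows():
            cfg = Configuration.from_angles(row[: 14].to_numpy())
            _, flag, _ = geom.realize(cfg)
            assert int(flag) == int(row["collision"])

    def test_percentile_ordering_on_every_row(self, small_dataset):
        for k in STRAIN_KEYS:
            c50 = f"e50_s{k}" if k != "all" else "e50_all"
            c90 = f"e90_s{k}" if k != "all" else "e90_all"
            assert (small_dataset[c90] >= small_dataset[c50]).all()
            assert (small_dataset[c50] > 0).all()

    def test_duplicate_configs_without_noise_give_duplicate_rows(self, geom):
        p0 = default_params(seed=0, noise_cv=0.0)
        design = pd.DataFrame(
            np.zeros((2, 14)), columns=[c for c in DATASET_COLUMNS[:14]]
        )
        data = generate_dataset(design, geom, p0)
        assert data.iloc[0].equals(data.iloc[1])

    def test_empty_design_rejected(self, geom, params):
        with pytest.raises(ValueError):
            generate_dataset(pd.DataFrame(np.zeros((0, 14)), columns=list(DATASET_COLUMNS[:14])), geom, params)


class TestParamValidation:
    def test_gamma_must_exceed_one(self, params):
        with pytest.raises(ValueError):
            OracleParams(
                baseline_strain=params.baseline_strain,
                gamma={**params.gamma, 6: 0.9},
                self_coef=params.self_coef,
                cross_coef=params.cross_coef,
            )

    def test_negative_noise_rejected(self, params):
        with pytest.raises(ValueError):
            OracleParams(
                baseline_strain=params.baseline_strain,
                gamma=params.gamma,
                self_coef=params.self_coef,
                cross_coef=params.cross_coef,
                noise_cv=-0.1,
            )
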