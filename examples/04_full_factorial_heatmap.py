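"""Sweep the full 9^7 design space with trained surrogates and rank screws.

Trains the classifier + 16-input regressor, predicts the pooled
90th-percentile strain for every configuration of the reduced factorial
(angles in {-10, 0, +10} deg), and summarizes, per screw and tip state, the
percent strain variation from neutral over the non-colliding predictions.
The calcar screw should emerge as the most influential.
"""

import numpy as np

from screwscape import (
    ANGLE_COLUMNS,
    CLASSIFIER_LAYERS,
    FULLFACT_GRID,
    REGRESSOR16_LAYERS,
    SCREW_IDS,
    TRAINING_GRID,
    HeatmapAccumulator,
    TrainConfig,
    default_geometry,
    default_params,
    forward,
    full_factorial,
    generate_dataset,
    lhs_design,
    predict_label,
    select_best,
    split_dataset,
    strain16_features,
    train_replicates,
)

COLS = list(ANGLE_COLUMNS)
geom = default_geometry()
params = default_params(seed=0)
train = generate_dataset(lhs_design(1341, TRAINING_GRID, seed=1), geom, params)
test = generate_dataset(lhs_design(91, TRAINING_GRID, seed=2), geom, params, start_index=10_000)
tr, va, _ = split_dataset(train, seed=0)
feats = lambda df: strain16_features(df[COLS].to_numpy(), df["collision"].to_numpy())

clf = select_best(train_replicates(
    tr[COLS].to_numpy(), tr["collision"].to_numpy(dtype=float),
    CLASSIFIER_LAYERS, TrainConfig(algorithm="lm", max_epochs=100, val_patience=10),
    test[COLS].to_numpy(), test["collision"].to_numpy(),
    n_replicates=3, base_seed=0, role="classifier",
    X_val=va[COLS].to_numpy(), y_val=va["collision"].to_numpy(dtype=float),
))
reg = select_best(train_replicates(
    feats(tr), tr["e90_all"].to_numpy(),
    REGRESSOR16_LAYERS, TrainConfig(algorithm="bayes", max_epochs=100),
    feats(test), test["e90_all"].to_numpy(),
    n_replicates=3, base_seed=0, role="regressor",
    X_val=feats(va), y_val=va["e90_all"].to_numpy(),
))

acc = HeatmapAccumulator(FULLFACT_GRID)
total = kept = 0
for batch in full_factorial(FULLFACT_GRID, batch_size=500_000):
    flags = predict_label(clf, batch)
    vals = forward(reg, strain16_features(batch, flags))
    acc.update(batch, vals, flags == 0)
    total += len(batch)
    kept += int(np.sum(flags == 0))
print(f"swept {total:,} configurations; {kept:,} predicted collision-free")

print("\nmax |% strain variation from neutral| per screw (e90, all screws):")
for sid in SCREW_IDS:
    cells = [c for c in acc.cells(sid, alpha=0.001) if c.valid]
    worst = max(cells, key=lambda c: abs(c.pct_variation))
    star = " *" if worst.significant else ""
    print(
        f"  screw {sid}: {worst.pct_variation:+6.1f}% at "
        f"(dp={worst.dp_deg:+.0f}, ap={worst.ap_deg:+.0f}){star}"
    )
print(
    "\nThe calcar screw (Screw 6) shows the largest swing: its distal tilt\n"
    "raises pooled peri-screw strain the most, its proximal tilt is safest."
)
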