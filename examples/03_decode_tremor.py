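"""Decode tremor from spectral features with a linear SVR and its null.

Monte-Carlo cross-validated decoding of the tremor metric, compared with
models refit after shuffling the train-set metric (chance level), plus
cross-metric transfer onto slowness.
"""

import numpy as np

from motorstates import (Coupling, SimConfig, compute_epoch_metrics,
                         cross_metric_apply, power_features, shuffled_null,
                         simulate_behavior, simulate_neural, train_decoder)

cfg = SimConfig(duration_s=360.0, seed=3, slow_gain=0.9,
                coupling_map=[Coupling(0, "theta_alpha", "tremor", 2.0),
                              Coupling(0, "beta", "slowness", 3.0)])
session, truth = simulate_behavior(cfg)
rec = simulate_neural(session, truth, cfg)[0]
metrics = compute_epoch_metrics(session)
epochs = [(t, t + 7.0) for t in metrics["t_start"]]
feats = power_features(rec, epochs)
y = metrics["tremor"].to_numpy()

model, result = train_decoder(feats, y, n_folds=50, seed=0, metric="tremor")
null = shuffled_null(feats, y, n_models=30, n_folds=25, seed=0)
p95 = np.percentile(null.r2, 95)

print(f"tremor decoding r2      = {result.r2:.3f}")
print(f"shuffled-null 95th pct  = {p95:.3f}")
print(f"mean theta/alpha weight = {model.weights[:7].mean():+.3f}")

cross = cross_metric_apply(model, feats, metrics["slowness"].to_numpy())
print(f"tremor model -> slowness signed r2 = {cross:+.3f}")
print("\nAn r2 above the null with positive low-frequency weights recovers"
      "\nthe injected theta/alpha coupling; the small (or negative) transfer"
      "\nonto slowness shows the two metrics use distinct spectral features.")
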