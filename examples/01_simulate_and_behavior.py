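"""Simulate a tracking session and extract the four behavioral metrics.

A synthetic subject alternates between tremor, slow and effective motor
states while tracking a smoothly moving target. We recover per-7 s-epoch
tremor amplitude (deg), cursor speed (deg/s), slowness and effective motor
control, and compare the tremor metric against the known latent state.
"""

import numpy as np

from motorstates import SimConfig, compute_epoch_metrics, simulate_behavior

cfg = SimConfig(duration_s=280.0, tremor_gain=1.0, seed=42)
session, truth = simulate_behavior(cfg)
metrics = compute_epoch_metrics(session)

print(metrics[["tremor", "speed", "slowness", "emc"]].describe().round(3))

# epochs overlapping tremor episodes should carry the larger tremor metric
bins = np.arange(len(truth.latent_tremor)) * truth.bin_s
in_tremor = np.array([
    truth.latent_tremor[(bins >= t) & (bins < t + 7)].mean() > 0.2
    for t in metrics["t_start"]])
print(f"\nmean tremor metric | tremor-state epochs:  "
      f"{metrics['tremor'][in_tremor].mean():.3f} deg")
print(f"mean tremor metric | other epochs:         "
      f"{metrics['tremor'][~in_tremor].mean():.3f} deg")
print("\nThe latent tremor state drives a 3-10 Hz cursor oscillation, so the"
      "\nenvelope metric separates the two groups by roughly tremor_gain.")
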