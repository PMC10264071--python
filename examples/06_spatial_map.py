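"""Where along an electrode trajectory is each metric best decoded?

Sites on a 1 mm grid have tremor coupling increasing dorsally and slowness
coupling increasing ventrally. Per-site decoding r2 values are binned into
1 mm voxels and contrasted with a recording-level sign-flip permutation
test; the signed Z-map peaks should separate along the gradient axis.
"""

from motorstates import (Coupling, SimConfig, SiteResult, bin_sites,
                         compute_epoch_metrics, power_features,
                         simulate_behavior, simulate_neural,
                         simulate_site_map, train_decoder,
                         voxelwise_paired_test)

cfg = SimConfig(duration_s=264.0, n_trials=10, slow_gain=0.9, seed=5,
                coupling_map=[Coupling(0, "theta_alpha", "tremor", 2.0),
                              Coupling(0, "beta", "slowness", 3.0)])
session, truth = simulate_behavior(cfg)
metrics = compute_epoch_metrics(session)
epochs = [(t, t + 7.0) for t in metrics["t_start"]]

sites = simulate_site_map(6, {"tremor": 0.8, "slowness": -1.2}, cfg,
                          axis=(0.0, 0.0, 1.0))
results = []
for k, (xyz, site_cfg) in enumerate(sites):
    rec = simulate_neural(session, truth, site_cfg)[0]
    feats = power_features(rec, epochs)
    r2 = {m: train_decoder(feats, metrics[m].to_numpy(),
                           n_folds=25, seed=k)[1].r2
          for m in ("tremor", "slowness")}
    results.append(SiteResult(mni_xyz=xyz, r2_by_metric=r2,
                              recording_id=f"site{k}"))
    print(f"site z={xyz[2]:+5.1f} mm  r2 tremor {r2['tremor']:.2f}  "
          f"slowness {r2['slowness']:.2f}")

maps = bin_sites(results)
test = voxelwise_paired_test(maps["tremor"], maps["slowness"],
                             n_perm=2000, seed=0)
print(f"\ntremor > slowness peak at z = {test.peak_a[0][2]:+.1f} mm "
      f"(Z = {test.peak_a[1]:+.2f})")
print(f"slowness > tremor peak at z = {test.peak_b[0][2]:+.1f} mm "
      f"(Z = {test.peak_b[1]:+.2f})")
print("\nThe tremor-dominant peak sits dorsal (higher z) to the"
      "\nslowness-dominant peak, mirroring the configured gradients.")
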