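"""End-to-end orchestration: simulate -> metrics -> features -> decode ->
weight tests -> spatial map -> population stats.

The pipeline is a library function (:func:`run_pipeline`) over the module
APIs, driven by a :class:`PipelineConfig` (YAML-loadable). All randomness
flows from the config seed; rerunning with the same config yields a
bit-identical JSON report. A thin console entry point
(``motorstates-pipeline``) wraps it for shell use.
"""

from __future__ import annotations

import argparse
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .behavior import compute_epoch_metrics, epoch_grid
from .decoding import shuffled_null, train_decoder
from .lmm import fit_random_intercepts
from .spatial import SiteResult, bin_sites, voxelwise_paired_test
from .spectral import power_features
from .synthetic import Coupling, SimConfig, simulate_behavior, \
    simulate_neural, simulate_site_map
from .weights import contiguity_permutation_test

log = logging.getLogger("motorstates")


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    behavior_csv: str | None = None      # optional measured input
    epoch_len_s: float = 7.0
    fine_bin_s: float = 0.1
    sub_bands: int = 7
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    n_folds: int = 100
    n_null_models: int = 50
    n_perm: int = 10000
    bh_q: float = 0.05
    seed: int = 0
    # synthetic study design
    n_subjects: int = 5
    n_channels: int = 2
    duration_s: float = 168.0
    coupling_slope: float = 2.0
    n_sites: int = 5
    site_gradient: float = 0.3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls(**raw)

    def fast(self) -> "PipelineConfig":
        return replace(self, n_folds=25, n_null_models=15, n_perm=1000)


def _sim_config(cfg: PipelineConfig, seed: int) -> SimConfig:
    couplings = []
    for ch in range(cfg.n_channels):
        couplings.append(Coupling(ch, "theta_alpha", "tremor",
                                  cfg.coupling_slope))
        couplings.append(Coupling(ch, "beta", "slowness", cfg.coupling_slope))
    return SimConfig(duration_s=cfg.duration_s, n_channels=cfg.n_channels,
                     n_trials=max(4, int(cfg.duration_s / 25.0)),
                     coupling_map=couplings, seed=seed)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write CSV/JSON artifacts plus a report."""
    if cfg.behavior_csv is not None and not Path(cfg.behavior_csv).exists():
        raise FileNotFoundError(f"input not found: {cfg.behavior_csv}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    log.info("pipeline seed=%d out=%s", cfg.seed, out)

    report: dict = {"config": asdict(cfg), "version": __version__,
                    "recordings": [], "weight_clusters": {},
                    "spatial": {}, "stats": {}}

    # --- per-subject simulate -> behavior -> features -> decode -----------
    metrics = ("tremor", "slowness", "emc")
    weight_emp = {m: [] for m in metrics}
    weight_null = {m: [] for m in metrics}
    r2_rows = []
    for s in range(cfg.n_subjects):
        sim = _sim_config(cfg, cfg.seed + 1000 * (s + 1))
        session, truth = simulate_behavior(sim)
        recs = simulate_neural(session, truth, sim)
        session.to_csv(out / f"behavior_s{s}.csv")
        truth.to_csv(out / f"truth_s{s}.csv")
        epochs = epoch_grid(session, cfg.epoch_len_s)
        em = compute_epoch_metrics(session, epoch_len=cfg.epoch_len_s)
        em.to_csv(out / f"epochs_s{s}.csv", index=False)
        spans = [epochs[i] for i in em["epoch_index"]]
        for c, rec in enumerate(recs):
            feats = power_features(rec, spans)
            feats.to_hdf5(out / f"features_s{s}_ch{c}.h5")
            for metric in metrics:
                y = em[metric].to_numpy()
                model, res = train_decoder(
                    feats, y, n_folds=cfg.n_folds, seed=cfg.seed + s * 10 + c,
                    C=cfg.svr_c, epsilon=cfg.svr_epsilon, metric=metric)
                null = shuffled_null(feats, y, n_models=cfg.n_null_models,
                                     n_folds=cfg.n_folds,
                                     seed=cfg.seed + s * 10 + c,
                                     C=cfg.svr_c, epsilon=cfg.svr_epsilon)
                weight_emp[metric].append(model.weights)
                weight_null[metric].append(null.weights.mean(axis=0))
                row = {"subject": s, "channel": c, "metric": metric,
                       "r2": res.r2,
                       "null_p95": float(np.percentile(null.r2, 95))}
                r2_rows.append(row)
                report["recordings"].append(row)
                log.info("subject %d ch %d %s r2=%.3f null95=%.3f",
                         s, c, metric, res.r2, row["null_p95"])

    # --- weight cluster tests (empirical vs shuffled, per metric) ---------
    for metric in metrics:
        W_emp = np.asarray(weight_emp[metric])
        W_null = np.asarray(weight_null[metric])
        if W_emp.shape[0] >= 5:
            wt = contiguity_permutation_test(
                W_emp, W_null, n_iter=max(1000, cfg.n_perm), q=cfg.bh_q,
                seed=cfg.seed)
            report["weight_clusters"][metric] = [
                {"start": c.start, "end": c.end, "sign": c.sign}
                for c in wt.clusters]

    # --- spatial survey along one trajectory ------------------------------
    base = _sim_config(cfg, cfg.seed + 77)
    base = replace(base, n_channels=1,
                   coupling_map=[Coupling(0, "theta_alpha", "tremor",
                                          cfg.coupling_slope),
                                 Coupling(0, "beta", "slowness",
                                          cfg.coupling_slope)])
    session, truth = simulate_behavior(base)
    epochs = epoch_grid(session, cfg.epoch_len_s)
    em = compute_epoch_metrics(session, epoch_len=cfg.epoch_len_s)
    spans = [epochs[i] for i in em["epoch_index"]]
    sites = simulate_site_map(
        cfg.n_sites, {"tremor": cfg.site_gradient,
                      "slowness": -cfg.site_gradient}, base)
    site_results = []
    for k, (xyz, site_cfg) in enumerate(sites):
        rec = simulate_neural(session, truth, site_cfg)[0]
        feats = power_features(rec, spans)
        r2s = {}
        for metric in ("tremor", "slowness"):
            _, res = train_decoder(feats, em[metric].to_numpy(),
                                   n_folds=cfg.n_folds,
                                   seed=cfg.seed + 500 + k,
                                   C=cfg.svr_c, epsilon=cfg.svr_epsilon)
            r2s[metric] = res.r2
        site_results.append(SiteResult(mni_xyz=xyz, r2_by_metric=r2s,
                                       recording_id=f"site{k}"))
    maps = bin_sites(site_results)
    sp = voxelwise_paired_test(maps["tremor"], maps["slowness"],
                               n_perm=max(1000, cfg.n_perm), seed=cfg.seed)
    sp.table.to_csv(out / "spatial_map.csv", index=False)
    report["spatial"] = {"peak_tremor": [list(sp.peak_a[0]), sp.peak_a[1]],
                         "peak_slowness": [list(sp.peak_b[0]), sp.peak_b[1]]}

    # --- population stats: tremor vs slowness decoding contrast -----------
    import pandas as pd
    df = pd.DataFrame(r2_rows)
    sub = df[df["metric"].isin(["tremor", "slowness"])]
    res = fit_random_intercepts(
        sub["r2"].to_numpy(),
        np.asarray(sub["metric"], dtype=object),
        sub["subject"].to_numpy())
    report["stats"]["tremor_vs_slowness"] = {
        "beta": res.beta.to_dict(), "z": res.z.to_dict(),
        "p": res.p.to_dict()}

    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
    return report


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(
        description="Run the simulate->decode->map pipeline")
    ap.add_argument("--config", help="YAML pipeline config", default=None)
    ap.add_argument("--out", default=None)
    ap.add_argument("--seed", type=int, default=None)
    ap.add_argument("--fast", action="store_true",
                    help="test-scale folds/permutations")
    args = ap.parse_args(argv)
    cfg = PipelineConfig.from_yaml(args.config) if args.config \
        else PipelineConfig()
    if args.out is not None:
        cfg = replace(cfg, out_dir=args.out)
    if args.seed is not None:
        cfg = replace(cfg, seed=args.seed)
    if args.fast:
        cfg = cfg.fast()
    run_pipeline(cfg)
    return 0


if __name__ == "__main__":
    sys.exit(main())
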