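"""Spatial mapping of decoding performance in MNI millimetre space.

Per-recording decoding r² values are binned into 1 mm³ voxels by site
coordinate, and the question "where is metric A decoded better than metric
B?" is answered with a paired, recording-level sign-flip permutation test:
per populated voxel the difference of mean r² is compared to a null built by
flipping each recording's (A, B) assignment, giving a per-voxel Z and signed
peak locations. Cortical surface-vertex analyses use the same machinery with
vertices in place of voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SiteResult:
    """Decoding performance of one recording at one site."""

    mni_xyz: tuple[float, float, float]
    r2_by_metric: dict[str, float]
    recording_id: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.mni_xyz)):
            raise ValueError("site coordinates must be finite")
        for m, v in self.r2_by_metric.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"r2 for {m} outside [0, 1]")


@dataclass
class VoxelMap:
    """Populated voxels only: voxel index -> contained (recording, value)."""

    voxel_mm: float
    metric: str
    sites: dict[tuple[int, int, int], list[tuple[str, float]]] = \
        field(default_factory=dict)

    @property
    def values(self) -> dict[tuple[int, int, int], float]:
        return {v: float(np.mean([x for _, x in lst]))
                for v, lst in self.sites.items()}

    def to_csv(self, path, z: dict | None = None) -> None:
        rows = []
        for (i, j, k), val in self.values.items():
            row = {"x": i * self.voxel_mm, "y": j * self.voxel_mm,
                   "z": k * self.voxel_mm, "value": val}
            if z is not None:
                row["Z"] = z.get((i, j, k), np.nan)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


def _voxel_index(xyz, voxel_mm: float) -> tuple[int, int, int]:
    return tuple(int(np.floor(c / voxel_mm)) for c in xyz)


def bin_sites(sites: list[SiteResult], voxel_mm: float = 1.0
              ) -> dict[str, VoxelMap]:
    """Assign sites to voxels; voxel value = mean r² of contained sites.

    Returns one VoxelMap per metric present in the site results.
    """
    if not sites:
        raise ValueError("need at least one site")
    metrics = sorted({m for s in sites for m in s.r2_by_metric})
    maps = {m: VoxelMap(voxel_mm=voxel_mm, metric=m) for m in metrics}
    for s in sites:
        vox = _voxel_index(s.mni_xyz, voxel_mm)
        for m, v in s.r2_by_metric.items():
            maps[m].sites.setdefault(vox, []).append((s.recording_id, v))
    return maps


@dataclass
class SpatialTestResult:
    table: pd.DataFrame          # x, y, z, value_a, value_b, diff, Z
    peak_a: tuple[tuple[float, float, float], float]   # (xyz mm, Z) where A > B
    peak_b: tuple[tuple[float, float, float], float]   # (xyz mm, Z) where B > A
    n_perm: int


def voxelwise_paired_test(map_a: VoxelMap, map_b: VoxelMap,
                          n_perm: int = 10000, seed: int = 0
                          ) -> SpatialTestResult:
    """Voxel-wise paired contrast with a recording-level sign-flip null.

    Both maps must be built from the same recordings (shared voxel support).
    Per permutation each recording's (A, B) pair is swapped with probability
    1/2 — flipping the sign of all that recording's site differences — and
    the voxel means are recomputed; Z = (observed − null mean)/null sd.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    if set(map_a.sites) != set(map_b.sites):
        raise ValueError("maps must share voxel support")
    voxels = sorted(map_a.sites)
    if len(voxels) < 10:
        warnings.warn("fewer than 10 populated voxels; low statistical power")
    rec_ids = sorted({r for v in voxels for r, _ in map_a.sites[v]})
    rec_pos = {r: i for i, r in enumerate(rec_ids)}
    # V[v, r] = contribution of recording r's sites to voxel v's mean diff
    V = np.zeros((len(voxels), len(rec_ids)))
    d_obs = np.zeros(len(voxels))
    for vi, vox in enumerate(voxels):
        a_vals = map_a.sites[vox]
        b_vals = {r: val for r, val in map_b.sites[vox]}
        n_in_vox = len(a_vals)
        for r, av in a_vals:
            diff = av - b_vals[r]
            V[vi, rec_pos[r]] += diff / n_in_vox
            d_obs[vi] += diff / n_in_vox
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(rec_ids)))
    null = V @ signs.T                      # (n_vox, n_perm)
    mu = null.mean(axis=1)
    sd = null.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (d_obs - mu) / sd
    z = np.nan_to_num(z)
    vals_a, vals_b = map_a.values, map_b.values
    mm = map_a.voxel_mm
    rows = []
    for vi, vox in enumerate(voxels):
        rows.append({"x": vox[0] * mm, "y": vox[1] * mm, "z": vox[2] * mm,
                     "value_a": vals_a[vox], "value_b": vals_b[vox],
                     "diff": d_obs[vi], "Z": z[vi]})
    table = pd.DataFrame(rows)
    # peaks are located on the paired-difference map: with few recordings
    # per voxel the sign-flip Z saturates near +/-1 (the null is +/-d), so
    # Z carries the sign while d carries the magnitude; each peak is
    # reported with its Z value
    ia, ib = int(np.argmax(d_obs)), int(np.argmin(d_obs))
    xyz = lambda i: (table["x"][i], table["y"][i], table["z"][i])  # noqa: E731
    return SpatialTestResult(table=table,
                             peak_a=(xyz(ia), float(z[ia])),
                             peak_b=(xyz(ib), float(z[ib])),
                             n_perm=n_perm)
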