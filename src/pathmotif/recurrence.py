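"""Selecting the number of recurrent profiles with a silhouette Z-score scan.

Any matrix can be clustered, so the observed mean silhouette at each k is
standardized against a null in which every pathway gene's values are
permuted independently across the on-states — preserving each gene's
marginal distribution exactly while destroying gene–gene correlations. The
optimal cluster count k_opt is the largest k whose smoothed Z-score still
reaches 90% of the maximum; the width of that 90% region, as a fraction of
the k grid, flags pathways without a well-defined profile count; and the
recurrence score r = k_opt / Ng normalizes for pathway size.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._cluster import cosine_distance_matrix, cut_many, silhouette_over_cuts
from .profiles import ScaledPathwayMatrix

log = logging.getLogger(__name__)

DEFAULT_K_GRID = np.arange(3, 101)  #: k_opt selection grid
WIDE_K_GRID = np.arange(3, 203)  #: peak-width survey grid (200 values)
PEAK_WIDTH_CUTOFF = 0.35
SMOOTH_WINDOW = 1
Z_PEAK_FRACTION = 0.9


@dataclass
class SilhouetteScan:
    """Observed / null silhouette curves and the derived statistics."""

    k_grid: np.ndarray
    s_obs: np.ndarray
    s_null: np.ndarray  # (n_rand, len(k_grid))
    z: np.ndarray
    z_smooth: np.ndarray
    k_opt: int
    peak_width: float
    excluded: bool
    recurrence: float
    n_genes: int
    seed: int
    flat_peak: bool = False

    def to_json(self, path: str | Path) -> None:
        d = {
            "k_grid": self.k_grid.tolist(),
            "s_obs": self.s_obs.tolist(),
            "null_mean": np.nanmean(self.s_null, axis=0).tolist(),
            "null_std": np.nanstd(self.s_null, axis=0, ddof=1).tolist(),
            "z": [None if not np.isfinite(v) else v for v in self.z],
            "k_opt": int(self.k_opt),
            "peak_width": self.peak_width,
            "excluded": self.excluded,
            "recurrence": self.recurrence,
            "n_genes": self.n_genes,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(d, indent=1))


def _scan_one_matrix(
    x: np.ndarray, k_grid: np.ndarray, linkage_method: str = "complete"
) -> np.ndarray:
    """Cluster one matrix at every k of the grid; return mean silhouettes."""
    dist = cosine_distance_matrix(x)
    z = linkage(squareform(dist, checks=False), method=linkage_method)
    cuts = cut_many(z, k_grid)
    return silhouette_over_cuts(dist, cuts)


def silhouette_curve(
    p: ScaledPathwayMatrix,
    k_grid: np.ndarray = DEFAULT_K_GRID,
    linkage_method: str = "complete",
) -> np.ndarray:
    """Mean silhouette of the on-state cosine clustering at each k."""
    x = p.on_values.to_numpy(dtype=float)
    k_grid = np.asarray(k_grid)
    if x.shape[0] <= k_grid.max():
        raise ValueError(
            f"{x.shape[0]} on-states cannot support k up to {k_grid.max()}"
        )
    return _scan_one_matrix(x, k_grid, linkage_method)


def shuffle_genes(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute every gene column independently across states.

    Preserves each gene's marginal distribution exactly while destroying
    gene–gene correlations; the randomization behind the null silhouettes.
    """
    return np.column_stack([rng.permutation(x[:, j]) for j in range(x.shape[1])])


def null_silhouette(
    p: ScaledPathwayMatrix,
    k_grid: np.ndarray = DEFAULT_K_GRID,
    n_rand: int = 100,
    seed: int = 0,
    linkage_method: str = "complete",
) -> np.ndarray:
    """Silhouette curves of gene-shuffled null matrices.

    Each randomization permutes every gene column independently across the
    on-states (per-gene marginals exactly preserved) and reruns the whole
    clustering + silhouette procedure, dendrogram included.
    """
    if n_rand < 2:
        raise ValueError("need n_rand >= 2 to form a null std")
    x = p.on_values.to_numpy(dtype=float)
    k_grid = np.asarray(k_grid)
    rng = np.random.default_rng(seed)
    out = np.empty((n_rand, len(k_grid)))
    for r in range(n_rand):
        out[r] = _scan_one_matrix(shuffle_genes(x, rng), k_grid, linkage_method)
    return out


def z_curve(s_obs: np.ndarray, s_null: np.ndarray) -> np.ndarray:
    """Standardize the observed curve against the null: (obs − mean) / std.

    Grid points with zero null spread are undefined (NaN) and logged.
    """
    mean = s_null.mean(axis=0)
    std = s_null.std(axis=0, ddof=1)
    z = np.full_like(s_obs, np.nan, dtype=float)
    ok = std > 0
    z[ok] = (s_obs[ok] - mean[ok]) / std[ok]
    if (~ok).any():
        log.warning("zero null std at %d grid points; Z masked there", (~ok).sum())
    return z


def smooth_z(z: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average with edge truncation, NaN-aware."""
    n = len(z)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = z[lo:hi]
        out[i] = np.nanmean(seg) if np.isfinite(seg).any() else np.nan
    return out


def select_kopt(
    z: np.ndarray,
    k_grid: np.ndarray,
    smooth_window: int = SMOOTH_WINDOW,
    rule: str = "reach",
) -> tuple[int, np.ndarray, bool]:
    """Pick k_opt from the smoothed Z curve.

    ``rule="reach"``: the largest k whose smoothed Z is at least 90% of the
    curve's maximum. ``rule="drop"``: the last k before the smoothed Z
    drops below that level for good; the two coincide whenever the final
    90% crossing is downward. Returns ``(k_opt, z_smooth, flat)`` where
    ``flat`` flags a curve whose 90% region extends to the end of the grid
    (no reliable peak).
    """
    k_grid = np.asarray(k_grid)
    if np.isfinite(z).sum() < 3:
        raise ValueError("need at least 3 defined Z values")
    zs = smooth_z(z, smooth_window)
    cutoff = Z_PEAK_FRACTION * np.nanmax(zs)
    above = np.flatnonzero(zs >= cutoff)
    if rule == "reach":
        idx = above[-1]
    elif rule == "drop":
        # last downward crossing: the final index that is above the cutoff
        # while some later index falls below it; if none fall below, the end.
        below_after = np.isfinite(zs) & (zs < cutoff)
        idx = above[-1]
        for i in above[::-1]:
            if below_after[i + 1 :].any():
                idx = i
                break
    else:
        raise ValueError(f"unknown rule {rule!r}")
    flat = idx == len(k_grid) - 1
    if flat:
        warnings.warn("Z curve has no interior peak; k_opt pinned to the grid edge")
    return int(k_grid[idx]), zs, flat


def peak_width(
    z: np.ndarray, k_grid: np.ndarray, cutoff: float = PEAK_WIDTH_CUTOFF
) -> tuple[float, bool]:
    """Fraction of k values within 90% of the maximum Z; wide peaks excluded.

    Pathways whose width exceeds ``cutoff`` (default 0.35) have no
    well-defined profile count.
    """
    zmax = np.nanmax(z)
    width = float(np.sum(z >= Z_PEAK_FRACTION * zmax) / len(np.asarray(k_grid)))
    return width, width > cutoff


def recurrence_score(k_opt: int, ng: int) -> float:
    """Recurrence score r = k_opt / Ng (reported to one decimal in summaries).

    Lower r means fewer distinct profiles per pathway gene, i.e. stronger
    recurrence of a small set of profiles.
    """
    if ng < 1:
        raise ValueError("pathway must have at least one gene")
    return k_opt / ng


def scan_pathway(
    p: ScaledPathwayMatrix,
    k_grid: np.ndarray = DEFAULT_K_GRID,
    n_rand: int = 100,
    seed: int = 0,
    smooth_window: int = SMOOTH_WINDOW,
    rule: str = "reach",
    linkage_method: str = "complete",
) -> SilhouetteScan:
    """Full scan: observed curve, gene-shuffled null, Z, k_opt, width, r."""
    k_grid = np.asarray(k_grid)
    s_obs = silhouette_curve(p, k_grid, linkage_method)
    s_null = null_silhouette(p, k_grid, n_rand, seed, linkage_method)
    z = z_curve(s_obs, s_null)
    k_opt, zs, flat = select_kopt(z, k_grid, smooth_window, rule)
    width, excluded = peak_width(z, k_grid)
    r = recurrence_score(k_opt, p.values.shape[1])
    return SilhouetteScan(
        k_grid, s_obs, s_null, z, zs, k_opt, width, excluded, r,
        p.values.shape[1], seed, flat,
    )
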