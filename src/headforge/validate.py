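"""Segmentation-agreement metrics and rater-variability statistics.

Dice overlap, modified Hausdorff distance on boundary voxels, a
Kruskal-Wallis rank test (with exact permutation option for tiny n), a
Monte-Carlo Lilliefors normality test, and a variability-study driver
that compares each rater to a STAPLE consensus and tabulates the results
per structure.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .consensus import StapleConfig, staple

__all__ = [
    "dice",
    "boundary_points",
    "mhd",
    "kruskal_wallis",
    "lilliefors",
    "variability_study",
    "SimilarityReport",
]


@dataclass
class SimilarityReport:
    dice: float
    mhd_mm: float
    structure: str
    comparison: tuple[str, str]
    slice_context: str = "volume"


def dice(s1: np.ndarray, s2: np.ndarray) -> float:
    """Dice overlap 2|S1∩S2| / (|S1| + |S2|)."""
    s1 = np.asarray(s1, dtype=bool)
    s2 = np.asarray(s2, dtype=bool)
    if s1.shape != s2.shape:
        raise ValueError("masks must be congruent")
    n1 = int(s1.sum())
    n2 = int(s2.sum())
    if n1 + n2 == 0:
        raise ValueError("undefined Dice: both masks empty")
    inter = int(np.logical_and(s1, s2).sum())
    return 2.0 * inter / (n1 + n2)


def boundary_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Centres (mm) of mask voxels with a face neighbour outside the mask
    or outside the grid.  2-D masks use the in-plane 4-neighbourhood."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    ndim = mask.ndim
    spacing = np.asarray(spacing, dtype=float).reshape(-1)
    if spacing.size == 1:
        spacing = np.repeat(spacing, ndim)
    if spacing.size != ndim:
        raise ValueError("spacing dimensionality mismatch")
    struct = ndimage.generate_binary_structure(ndim, 1)
    # erosion with border_value=0 treats out-of-grid as background
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    boundary = mask & ~interior
    idx = np.argwhere(boundary)
    return idx * spacing[None, :]


def mhd(s1: np.ndarray, s2: np.ndarray, spacing, use_boundary: bool = True) -> float:
    """Modified Hausdorff distance in mm between two masks.

    MHD = max(d(S1,S2), d(S2,S1)) with d(X,Y) the mean over X of the
    nearest-neighbour L2 distance to Y.  By default distances are taken
    between boundary-voxel centres; ``use_boundary=False`` uses all mask
    voxels instead (sensitivity-analysis variant).
    """
    s1 = np.asarray(s1, dtype=bool)
    s2 = np.asarray(s2, dtype=bool)
    if s1.shape != s2.shape:
        raise ValueError("masks must be congruent")
    if not s1.any() or not s2.any():
        raise ValueError("MHD undefined for an empty mask")
    if use_boundary:
        x = boundary_points(s1, spacing)
        y = boundary_points(s2, spacing)
    else:
        ndim = s1.ndim
        sp = np.asarray(spacing, dtype=float).reshape(-1)
        if sp.size == 1:
            sp = np.repeat(sp, ndim)
        x = np.argwhere(s1) * sp[None, :]
        y = np.argwhere(s2) * sp[None, :]
    d_xy = cKDTree(y).query(x)[0].mean()
    d_yx = cKDTree(x).query(y)[0].mean()
    return float(max(d_xy, d_yx))


def _kw_statistic(groups: list[np.ndarray]) -> float:
    """Midrank Kruskal-Wallis H with tie correction."""
    all_vals = np.concatenate(groups)
    n = all_vals.size
    ranks = stats.rankdata(all_vals)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie_corr = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie_corr == 0.0:
        return 0.0
    return h / tie_corr


def kruskal_wallis(groups, exact: bool = False) -> tuple[float, float]:
    """Kruskal-Wallis test across ≥2 groups.

    Returns (H, p).  p comes from the chi-square approximation with
    k−1 degrees of freedom; ``exact=True`` computes the permutation
    p-value by full enumeration (only for total n ≤ 10).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    all_vals = np.concatenate(groups)
    if np.all(all_vals == all_vals[0]):
        return 0.0, 1.0
    h = _kw_statistic(groups)
    k = len(groups)
    if exact:
        n = all_vals.size
        if n > 10:
            raise ValueError("exact permutation limited to n <= 10")
        sizes = [g.size for g in groups]
        count_ge = 0
        total = 0
        idx_all = list(range(n))

        def ordered_splits(remaining, sizes_left):
            if not sizes_left:
                yield []
                return
            m = sizes_left[0]
            for grp in itertools.combinations(remaining, m):
                left = [i for i in remaining if i not in grp]
                for tail in ordered_splits(left, sizes_left[1:]):
                    yield [grp] + tail

        h_obs = h
        for split in ordered_splits(idx_all, sizes):
            gs = [all_vals[list(s)] for s in split]
            total += 1
            if _kw_statistic(gs) >= h_obs - 1e-12:
                count_ge += 1
        return h, count_ge / total
    p = float(stats.chi2.sf(h, k - 1))
    return h, p


def lilliefors(sample, n_mc: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """Lilliefors normality test: KS statistic against a normal with
    estimated mean/SD, p-value from a seeded Monte-Carlo null.

    Returns (statistic, p).
    """
    x = np.asarray(sample, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero-variance sample")

    def ks_stat(rows: np.ndarray) -> np.ndarray:
        rows = np.sort(rows, axis=-1)
        mu = rows.mean(axis=-1, keepdims=True)
        sd = rows.std(ddof=1, axis=-1, keepdims=True)
        z = stats.norm.cdf((rows - mu) / sd)
        i = np.arange(1, n + 1)
        d_plus = np.max(i / n - z, axis=-1)
        d_minus = np.max(z - (i - 1) / n, axis=-1)
        return np.maximum(d_plus, d_minus)

    d_obs = float(ks_stat(x[None, :])[0])
    rng = np.random.default_rng(seed)
    null = ks_stat(rng.standard_normal((n_mc, n)))
    p = (1.0 + np.sum(null >= d_obs)) / (1.0 + n_mc)
    return d_obs, float(p)


def variability_study(
    rater_masks: dict[str, dict[str, np.ndarray]],
    spacing,
    staple_config: StapleConfig | None = None,
    slice_context: str = "volume",
    lilliefors_mc: int = 2000,
    seed: int = 0,
) -> dict:
    """Inter-rater variability study against a STAPLE consensus.

    ``rater_masks`` maps structure name → {rater id → binary mask}.  For
    each structure a STAPLE ground truth is estimated from all raters;
    each rater is then scored with Dice and MHD against it.  Returns a
    dict with a per-comparison table (pandas DataFrame), per-rater
    summaries and Kruskal-Wallis tests across raters on both metrics.
    """
    rows = []
    for structure, masks in rater_masks.items():
        rater_ids = sorted(masks)
        if len(rater_ids) < 2:
            raise ValueError(f"structure {structure!r} needs >= 2 raters")
        result = staple([masks[r] for r in rater_ids], staple_config)
        gt = result.consensus_mask
        for r in rater_ids:
            rows.append({
                "structure": structure,
                "rater": r,
                "dice": dice(masks[r], gt),
                "mhd_mm": mhd(masks[r], gt, spacing),
                "context": slice_context,
            })
    table = pd.DataFrame(rows)
    raters = sorted(table["rater"].unique())
    summary = {
        r: {
            "dice_mean": float(table.loc[table.rater == r, "dice"].mean()),
            "dice_sd": float(table.loc[table.rater == r, "dice"].std(ddof=1)),
            "mhd_mean": float(table.loc[table.rater == r, "mhd_mm"].mean()),
            "mhd_sd": float(table.loc[table.rater == r, "mhd_mm"].std(ddof=1)),
        }
        for r in raters
    }
    dice_groups = [table.loc[table.rater == r, "dice"].to_numpy() for r in raters]
    mhd_groups = [table.loc[table.rater == r, "mhd_mm"].to_numpy() for r in raters]
    h_d, p_d = kruskal_wallis(dice_groups)
    h_m, p_m = kruskal_wallis(mhd_groups)
    normality = {}
    for i, r in enumerate(raters):
        if dice_groups[i].size >= 4 and dice_groups[i].std(ddof=1) > 0:
            normality[r] = {
                "dice_lilliefors_p": lilliefors(dice_groups[i], lilliefors_mc, seed)[1]
            }
    return {
        "table": table,
        "per_rater": summary,
        "kruskal_wallis": {
            "dice": {"H": h_d, "p": p_d},
            "mhd": {"H": h_m, "p": p_m},
        },
        "normality": normality,
        "overall": {
            "dice_mean": float(table["dice"].mean()),
            "dice_sd": float(table["dice"].std(ddof=1)),
            "mhd_mean": float(table["mhd_mm"].mean()),
            "mhd_sd": float(table["mhd_mm"].std(ddof=1)),
        },
    }


def write_report(report: dict, out_dir: str | Path) -> None:
    """Write the variability table as CSV and the summaries as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["table"].to_csv(out / "variability.csv", index=False)
    payload = {k: v for k, v in report.items() if k != "table"}
    (out / "summary.json").write_text(json.dumps(payload, indent=2))
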