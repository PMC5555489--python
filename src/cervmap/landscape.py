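"""Sex-specific recombination landscapes in physical (Mb) coordinates.

Marker Mb positions are estimated from the prior reference genome: within
collinear segments, steps are the absolute base-pair differences between
sequential markers; across rearrangement boundaries, 1 cM of map distance is
taken as 1 Mb.  Crossover probability is then accumulated in 1 Mb windows by
prorating each adjacent-interval recombination fraction over the windows it
overlaps, and the per-window rate is adjusted for chromosome size by dividing
by the chromosome-wide cM/Mb of the same sex.  Acrocentric chromosomes carry
the centromere at bp 0, so "distance from the centromere" is simply the
window midpoint; chromosomes are compared across their centromere histories
(fission forming a new centromere, fission retaining the old one, unchanged)
with penalized-spline fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "estimate_positions",
    "infer_boundaries",
    "group_origin_bp",
    "window_rates",
    "add_adjusted_rates",
    "filter_extreme_windows",
    "smooth_landscape",
    "fit_history_gam",
    "leave_k_out_gam",
    "DEFAULT_HISTORIES",
]

# Centromere histories of the study's linkage groups: fissions that formed a
# new centromere vs. fissions that retained the ancestral one; everything
# else acrocentric is "unchanged" and CEL5 is the metacentric fusion.
DEFAULT_HISTORIES: dict[str, str] = {
    **{g: "new_centromere" for g in ("22", "6", "26", "16", "19", "8")},
    **{g: "retained_centromere" for g in ("3", "17", "28", "29", "31", "33")},
    "5": "metacentric",
}

SMALL_CHROMOSOME_CONTRAST = {
    "new_centromere": ("6", "8", "16", "22", "26"),
    "unchanged": ("2", "7", "10", "24", "27", "32"),
}


def group_origin_bp(first_mapped_bp: dict[str, float] | pd.Series) -> float:
    """Origin for every group: mean first mapped bp over reference chromosomes."""
    vals = pd.Series(first_mapped_bp, dtype=float)
    return float(vals.mean())


def infer_boundaries(prior_chrom: np.ndarray, prior_bp: np.ndarray, max_step_bp: float = 10e6) -> np.ndarray:
    """Heuristic rearrangement boundaries between sequential markers.

    An interval is a boundary when the prior chromosome changes or the
    base-pair step is larger than ``max_step_bp`` (synteny breaks).
    """
    chrom = np.asarray(prior_chrom)
    bp = np.asarray(prior_bp, dtype=float)
    return (chrom[1:] != chrom[:-1]) | (np.abs(np.diff(bp)) > max_step_bp)


def estimate_positions(
    prior_bp: np.ndarray,
    cm: np.ndarray,
    boundaries: np.ndarray | None = None,
    origin_bp: float = 0.0,
) -> np.ndarray:
    """Estimated physical positions along one linkage group.

    Interior steps equal the absolute prior-bp difference of sequential
    markers; at a rearrangement boundary the step is the cM difference at
    1 Mb/cM.  The first marker sits at ``origin_bp``.  Raises on any
    non-positive step (the result must be strictly increasing).
    """
    prior_bp = np.asarray(prior_bp, dtype=float)
    cm = np.asarray(cm, dtype=float)
    if prior_bp.shape != cm.shape:
        raise ValueError("prior_bp and cm must be aligned")
    n = len(prior_bp)
    if boundaries is None:
        boundaries = np.zeros(max(n - 1, 0), dtype=bool)
    steps = np.abs(np.diff(prior_bp))
    cm_steps = np.abs(np.diff(cm)) * 1e6  # 1 cM == 1 Mb at boundaries
    steps = np.where(np.asarray(boundaries, dtype=bool), cm_steps, steps)
    bad = np.flatnonzero(steps <= 0)
    if bad.size:
        raise ValueError(f"non-increasing estimated position at interval {int(bad[0])}")
    return origin_bp + np.concatenate([[0.0], np.cumsum(steps)])


def window_rates(
    intervals: pd.DataFrame,
    window_size: float = 1e6,
    anchor: float | None = None,
) -> pd.DataFrame:
    """Crossover probability per window: prorated sum of interval r.

    ``intervals`` has columns left_bp, right_bp, r (one linkage group, one
    sex); each interval's r is apportioned to overlapping windows in
    proportion to base overlap (r x N_boundary / N_adjSNP at the window
    boundaries).  Windows are half-open [start, start + window) anchored at
    the first SNP (or ``anchor``).  The sum of window probabilities equals
    the sum of interval r exactly.
    """
    iv = intervals.dropna(subset=["r"])
    if iv.empty:
        return pd.DataFrame(columns=["window", "start_bp", "end_bp", "prob"])
    a = float(iv["left_bp"].min() if anchor is None else anchor)
    last = float(iv["right_bp"].max())
    n_win = max(int(math.ceil((last - a) / window_size)), 1)
    prob = np.zeros(n_win)
    for left, right, r in iv[["left_bp", "right_bp", "r"]].itertuples(index=False):
        if right <= left:
            continue
        w0 = int((left - a) // window_size)
        w1 = int(math.ceil((right - a) / window_size))
        for w in range(max(w0, 0), min(w1, n_win)):
            ws, we = a + w * window_size, a + (w + 1) * window_size
            overlap = min(right, we) - max(left, ws)
            if overlap > 0:
                prob[w] += r * overlap / (right - left)
    out = pd.DataFrame({
        "window": np.arange(n_win),
        "start_bp": a + np.arange(n_win) * window_size,
        "end_bp": a + (np.arange(n_win) + 1) * window_size,
        "prob": prob,
    })
    return out


def add_adjusted_rates(windows: pd.DataFrame, window_size: float = 1e6) -> pd.DataFrame:
    """Window rate (cM/Mb) and size-adjusted rate per (group, sex).

    The adjustment divides each window's rate by the chromosome-wide cM/Mb
    of the same sex, so adjusted rates average ~1 within a chromosome.
    """
    out = windows.copy()
    mb = window_size / 1e6
    out["rate_cm_mb"] = 100.0 * out["prob"] / mb
    chrom_rate = {}
    for (g, s), sub in out.groupby(["group", "sex"]):
        span_mb = len(sub) * mb
        chrom_rate[(g, s)] = 100.0 * sub["prob"].sum() / span_mb if span_mb else np.nan
    out["adjusted"] = [
        row.rate_cm_mb / chrom_rate[(row.group, row.sex)] if chrom_rate[(row.group, row.sex)] else np.nan
        for row in out.itertuples()
    ]
    return out


def filter_extreme_windows(windows: pd.DataFrame, percentile: float = 0.01) -> pd.DataFrame:
    """Drop the genome-wide top percentile of size-adjusted window rates.

    Removes ceil(percentile x N) windows ranked by the ``adjusted`` column;
    ties at the cutoff are resolved by removing the later-indexed windows.
    Very high window rates flag map misassembly or underestimated physical
    distance rather than genuine recombination.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    n = len(windows)
    k = int(math.ceil(percentile * n))
    if k == 0 or n == 0:
        return windows.copy()
    ordinal = np.arange(n)
    rank = np.lexsort((ordinal, windows["adjusted"].to_numpy()))
    drop = set(rank[-k:])
    return windows.iloc[[i for i in range(n) if i not in drop]].copy()


def smooth_landscape(windows: pd.DataFrame, span: float = 0.15, column: str = "rate_cm_mb") -> pd.DataFrame:
    """Tricube-weighted local linear (loess) fit per sex over relative position.

    ``windows`` needs columns sex, start_bp, end_bp and the value column;
    the x axis is the window midpoint scaled to [0, 1] per group so groups of
    different physical length are comparable, as the landscape figures plot
    position proportionally.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    out = []
    for sex, sub in windows.groupby("sex"):
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 windows for sex {sex}")
        x = []
        for g, gsub in sub.groupby("group"):
            mid = (gsub["start_bp"] + gsub["end_bp"]) / 2.0
            lo, hi = gsub["start_bp"].min(), gsub["end_bp"].max()
            x.append((mid - lo) / max(hi - lo, 1.0))
        xs = pd.concat(x).to_numpy()
        ys = sub[column].to_numpy(dtype=float)
        sm = lowess(ys, xs, frac=span, return_sorted=True)
        out.append(pd.DataFrame({"sex": sex, "x": sm[:, 0], "fitted": sm[:, 1]}))
    return pd.concat(out, ignore_index=True)


def _gam_fit(x: np.ndarray, y: np.ndarray, basis_dim: int, alpha: float) -> tuple[np.ndarray, np.ndarray, object]:
    bs = BSplines(x[:, None], df=[basis_dim], degree=[3], include_intercept=False)
    model = GLMGam(y, exog=np.ones((len(y), 1)), smoother=bs, alpha=[alpha])
    return bs, model.fit()


def fit_history_gam(
    windows: pd.DataFrame,
    histories: dict[str, str] | None = None,
    sex: str = "female",
    range_mb: tuple[float, float] = (0.0, 40.0),
    basis_dim: int = 10,
    alpha: float = 1.0,
    grid: np.ndarray | None = None,
    exclude_groups: tuple[str, ...] = (),
) -> dict[str, pd.DataFrame]:
    """Penalized-spline fit of size-adjusted rate vs. centromere distance.

    Windows of the requested sex on acrocentric chromosomes (metacentric
    groups are excluded) are grouped by centromere history; for each history
    a cubic regression spline with basis dimension ``basis_dim`` is fitted to
    adjusted rate against the window midpoint (Mb from the centromere at bp
    0) over ``range_mb``.  Returns per history a frame with columns
    x, fit, se.
    """
    histories = dict(DEFAULT_HISTORIES if histories is None else histories)
    sub = windows[windows["sex"] == sex].copy()
    sub["group"] = sub["group"].astype(str)
    sub = sub[~sub["group"].isin(exclude_groups)]
    sub["history"] = sub["group"].map(lambda g: histories.get(g, "unchanged"))
    sub = sub[sub["history"] != "metacentric"]
    sub["dist_mb"] = ((sub["start_bp"] + sub["end_bp"]) / 2.0 - sub.groupby("group")["start_bp"].transform("min")) / 1e6
    lo, hi = range_mb
    sub = sub[(sub["dist_mb"] >= lo) & (sub["dist_mb"] <= hi)].dropna(subset=["adjusted"])
    if sub["history"].nunique() < 2:
        raise ValueError("need at least two history groups in range")
    if grid is None:
        grid = np.linspace(lo, hi, 81)

    out: dict[str, pd.DataFrame] = {}
    for hist, block in sub.groupby("history"):
        if block["group"].nunique() < 2:
            raise ValueError(f"history group '{hist}' has fewer than 2 chromosomes")
        x = block["dist_mb"].to_numpy(dtype=float)
        y = block["adjusted"].to_numpy(dtype=float)
        bs, res = _gam_fit(x, y, basis_dim, alpha)
        gx = np.clip(grid, x.min(), x.max())
        design = np.column_stack([np.ones(len(gx)), bs.transform(gx[:, None])])
        fit = design @ res.params
        cov = np.asarray(res.cov_params())
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", design, cov, design), 0.0))
        out[hist] = pd.DataFrame({"x": grid, "fit": fit, "se": se})
    return out


def leave_k_out_gam(
    windows: pd.DataFrame,
    histories: dict[str, str] | None = None,
    k: int = 1,
    **kwargs,
) -> dict[tuple[str, ...], dict[str, pd.DataFrame]]:
    """Refit the history GAM excluding each chromosome (k=1) or pair (k=2)."""
    import itertools as it

    histories = dict(DEFAULT_HISTORIES if histories is None else histories)
    groups = sorted(set(windows["group"].astype(str)))
    out = {}
    for combo in it.combinations(groups, k):
        try:
            out[combo] = fit_history_gam(windows, histories, exclude_groups=combo, **kwargs)
        except ValueError:
            continue  # exclusion emptied a history group
    return out
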