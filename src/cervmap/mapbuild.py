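"""Recombination-fraction estimation and iterative marker-order refinement.

The estimator is adjacent-interval recombinant counting on phased gametes:
for each adjacent marker pair, r = recombinant gametes / gametes informative
for the interval, where a gamete informs every interval spanned by its
nearest informative flanks and a flank-bounded recombination event
contributes unit mass apportioned over the spanned intervals.  With dense
markers and the phase-cleaning rules applied upstream this agrees closely
with a full multipoint fit while staying transparent and oracle-testable.

Order refinement proceeds in six builds: (1) map on the prior (synteny)
order, (2) drop small "chunks" stranded between large map gaps, (3) assemble
chunks into linkage groups from inter-chunk linkage disequilibrium,
(4) accept local inversions/deletions that shorten the map, (5) place
unmapped markers back by LD plus phase correlation and clean phase errors,
(6) reduce to a skeleton map and exhaustively test small permutations
("flips") by multipoint likelihood.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phasing
from .pedio import MISSING, GenotypeMatrix, SubPedigree

__all__ = [
    "Chunk",
    "LinkageMap",
    "GameteSet",
    "BuildConfig",
    "Placement",
    "map_distance",
    "rec_frac",
    "recfrac_counts",
    "estimate_recfracs",
    "map_positions",
    "segment_chunks",
    "drop_small_chunks",
    "ld_r2",
    "assemble_linkage_groups",
    "local_rearrangement_test",
    "place_unmapped",
    "build_skeleton",
    "flips_test",
    "phase_all",
    "run_build_pipeline",
]

_R_CAP = 0.5 - 1e-9


# ---------------------------------------------------------------------------
# Mapping functions


def map_distance(r, fn: str = "kosambi"):
    """Map distance in cM for recombination fraction(s) r in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any(r[~np.isnan(r)] >= 0.5):
        raise ValueError("map distance undefined for r >= 0.5")
    if fn == "haldane":
        d = -50.0 * np.log1p(-2.0 * r)
    elif fn == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    else:
        raise ValueError(f"unknown mapping function: {fn}")
    return float(d) if d.ndim == 0 else d


def rec_frac(d, fn: str = "kosambi"):
    """Inverse mapping function: cM distance back to recombination fraction."""
    d = np.asarray(d, dtype=float)
    if fn == "haldane":
        r = 0.5 * (1.0 - np.exp(-d / 50.0))
    elif fn == "kosambi":
        r = 0.5 * np.tanh(d / 50.0)
    else:
        raise ValueError(f"unknown mapping function: {fn}")
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# Gamete containers


@dataclass
class GameteSet:
    """Phased origin calls for a set of gametes over a global marker list.

    ``origins`` is gametes x markers, int8 in {+1, -1, 0}; linkage groups are
    views onto this matrix through lists of column indices, so marker moves
    between groups never touch the calls themselves.
    """

    origins: np.ndarray
    ids: list[str]
    sexes: np.ndarray  # "male"/"female" per gamete (the FID's sex)
    markers: list[str]

    def __post_init__(self) -> None:
        self.col = {m: j for j, m in enumerate(self.markers)}

    def sex_mask(self, sex: str | None) -> np.ndarray:
        if sex is None or sex == "pooled":
            return np.ones(len(self.ids), dtype=bool)
        return self.sexes == sex

    def informativeness(self) -> np.ndarray:
        """Phase-known gamete count per marker column."""
        return (self.origins != phasing.UNINFORMATIVE).sum(axis=0)


def phase_all(
    subpeds: list[SubPedigree],
    genotypes: GenotypeMatrix,
    markers: list[str] | None = None,
    par_markers: set[str] | None = None,
) -> GameteSet:
    """Phase every subpedigree at every marker (order-independent calls)."""
    markers = list(markers if markers is not None else genotypes.calls.columns)
    arr = genotypes.calls[markers].to_numpy(dtype=np.int16)
    row_of = {str(i): k for k, i in enumerate(genotypes.calls.index)}
    non_par = None
    if par_markers is not None:
        non_par = np.array([m not in par_markers for m in markers])
    rows, ids, sexes = [], [], []
    for sp in subpeds:
        g, gs, gd, o, m = (arr[row_of[x]] for x in sp.members)
        origins = phasing._phase_core(g, gs, gd, o, m)
        if non_par is not None and sp.fid_sex == "male":
            origins[non_par] = phasing.UNINFORMATIVE
        rows.append(origins)
        ids.append(sp.uid)
        sexes.append(sp.fid_sex)
    origins = np.vstack(rows) if rows else np.zeros((0, len(markers)), dtype=np.int8)
    return GameteSet(origins, ids, np.array(sexes), markers)


# ---------------------------------------------------------------------------
# Recombination fractions


def recfrac_counts(origins: np.ndarray, n_iter: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Recombinant / informative counts per adjacent marker interval.

    A gamete informs every interval spanned by a pair of consecutive
    informative calls (its nearest informative flanks); when the flank
    origins differ, the single recombination event localized between them
    contributes unit mass apportioned over the spanned intervals.  The
    apportionment starts even (1/gap) and is then iterated proportionally to
    the current interval estimates, which re-concentrates event mass onto
    genuinely long intervals instead of smearing sharp map gaps across their
    informative neighbourhood; totals are conserved exactly, so map lengths
    never multi-count crossovers.  Intervals spanned by no informative
    gamete get denominator 0 (reported missing downstream).
    """
    o = np.asarray(origins, dtype=np.int8)
    n_g, n_m = o.shape
    denom = np.zeros(n_m - 1, dtype=np.int64)
    dd = np.zeros(n_m, dtype=np.int64)
    ev_a, ev_b = [], []
    for k in range(n_g):
        row = o[k]
        idx = np.flatnonzero(row != 0)
        if idx.size < 2:
            continue
        vals = row[idx]
        a, b = idx[:-1], idx[1:]
        dd[:] = 0
        np.add.at(dd, a, 1)
        np.add.at(dd, b, -1)
        denom += np.cumsum(dd)[:-1]
        rec = vals[:-1] != vals[1:]
        if rec.any():
            ev_a.append(a[rec])
            ev_b.append(b[rec])
    if not ev_a:
        return np.zeros(n_m - 1), denom
    A = np.concatenate(ev_a)
    B = np.concatenate(ev_b)

    nd = np.zeros(n_m, dtype=float)
    w = 1.0 / (B - A)
    np.add.at(nd, A, w)
    np.add.at(nd, B, -w)
    numer = np.cumsum(nd)[:-1]

    wide = np.flatnonzero(B - A > 1)  # single-interval events never move
    for _ in range(max(n_iter - 1, 0)):
        if wide.size == 0:
            break
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, numer / np.maximum(denom, 1), 0.0)
        base = np.zeros(n_m, dtype=float)
        np.add.at(base, A[B - A == 1], 1.0)
        new = base[:-1].copy()
        for e in wide:
            a, b = A[e], B[e]
            seg = r[a:b]
            tot = seg.sum()
            if tot > 0:
                new[a:b] += seg / tot
            else:
                new[a:b] += 1.0 / (b - a)
        numer = new
    return numer, denom


def estimate_recfracs(
    gametes: GameteSet,
    order: list[int] | None = None,
    sex: str = "pooled",
) -> np.ndarray:
    """Adjacent-interval r for one linkage group; NaN where no gamete informs."""
    cols = np.arange(gametes.origins.shape[1]) if order is None else np.asarray(order)
    sub = gametes.origins[gametes.sex_mask(sex)][:, cols]
    numer, denom = recfrac_counts(sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, numer / np.maximum(denom, 1), np.nan)
    return np.minimum(r, 0.5)


def map_positions(r: np.ndarray, fn: str = "kosambi") -> np.ndarray:
    """Cumulative cM positions from adjacent-interval r (missing r -> 0 cM)."""
    d = np.zeros(len(r) + 1)
    valid = ~np.isnan(r)
    dist = np.zeros(len(r))
    dist[valid] = map_distance(np.minimum(r[valid], _R_CAP), fn)
    d[1:] = np.cumsum(dist)
    return d


def group_length(gametes: GameteSet, order: list[int], fn: str = "kosambi", sex: str = "pooled") -> float:
    return float(map_positions(estimate_recfracs(gametes, order, sex), fn)[-1])


# ---------------------------------------------------------------------------
# Linkage map container


@dataclass
class LinkageMap:
    """Ordered markers with per-sex cM and (optionally) estimated Mb positions."""

    df: pd.DataFrame  # marker, group, order, cm, cm_male, cm_female, mb

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.df["group"]))

    def group_df(self, group: str) -> pd.DataFrame:
        return self.df[self.df["group"] == group]

    def group_length(self, group: str, sex: str = "pooled") -> float:
        col = {"pooled": "cm", "male": "cm_male", "female": "cm_female"}[sex]
        sub = self.group_df(group)[col]
        return float(sub.iloc[-1] - sub.iloc[0]) if len(sub) else 0.0

    def total_length(self, sex: str = "pooled", exclude: tuple[str, ...] = ()) -> float:
        return sum(self.group_length(g, sex) for g in self.groups() if g not in exclude)

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def build_linkage_map(
    gametes: GameteSet,
    orders: dict[str, list[int]],
    fn: str = "kosambi",
) -> LinkageMap:
    """Sex-averaged (pooled-gamete) and sex-specific maps for every group."""
    rows = []
    for gname, order in orders.items():
        cm = map_positions(estimate_recfracs(gametes, order, "pooled"), fn)
        cm_m = map_positions(estimate_recfracs(gametes, order, "male"), fn)
        cm_f = map_positions(estimate_recfracs(gametes, order, "female"), fn)
        for k, j in enumerate(order):
            rows.append((gametes.markers[j], gname, k, cm[k], cm_m[k], cm_f[k], np.nan))
    return LinkageMap(pd.DataFrame(rows, columns=["marker", "group", "order", "cm", "cm_male", "cm_female", "mb"]))


# ---------------------------------------------------------------------------
# Chunks


@dataclass(frozen=True)
class Chunk:
    group: str
    start: int  # order index, inclusive
    end: int  # exclusive
    left_gap: float  # cM to previous marker (inf at the terminal)
    right_gap: float

    @property
    def n(self) -> int:
        return self.end - self.start


def segment_chunks(cm: np.ndarray, gap_threshold_cm: float, group: str = "") -> list[Chunk]:
    """Partition a group at adjacent-marker gaps >= threshold."""
    if gap_threshold_cm <= 0:
        raise ValueError("gap threshold must be positive")
    cm = np.asarray(cm, dtype=float)
    gaps = np.diff(cm)
    cut = np.flatnonzero(gaps >= gap_threshold_cm) + 1
    starts = np.concatenate([[0], cut])
    ends = np.concatenate([cut, [len(cm)]])
    out = []
    for s, e in zip(starts, ends):
        lg = float(gaps[s - 1]) if s > 0 else math.inf
        rg = float(gaps[e - 1]) if e < len(cm) else math.inf
        out.append(Chunk(group, int(s), int(e), lg, rg))
    return out


def drop_small_chunks(chunks: list[Chunk], min_snps: int) -> tuple[list[Chunk], list[tuple[str, int]]]:
    """Remove chunks with < ``min_snps`` markers; dropped (group, order index) recorded."""
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    kept, dropped = [], []
    for c in chunks:
        if c.n < min_snps:
            dropped.extend((c.group, i) for i in range(c.start, c.end))
        else:
            kept.append(c)
    return kept, dropped


# ---------------------------------------------------------------------------
# LD and group assembly


def _pairwise_r2(X: np.ndarray, Y: np.ndarray, min_periods: int = 10) -> np.ndarray:
    """Pairwise-complete squared correlation between genotype-code columns."""
    Xv = (X != MISSING).astype(float)
    Yv = (Y != MISSING).astype(float)
    Xf = np.where(X != MISSING, X, 0).astype(float)
    Yf = np.where(Y != MISSING, Y, 0).astype(float)
    n = Xv.T @ Yv
    sx = Xf.T @ Yv
    sy = Xv.T @ Yf
    sxx = (Xf * Xf).T @ Yv
    syy = Xv.T @ (Yf * Yf)
    sxy = Xf.T @ Yf
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = np.where((vx > 0) & (vy > 0), cov * cov / (vx * vy), np.nan)
    r2[n < min_periods] = np.nan
    return r2


def ld_r2(genotypes: GenotypeMatrix, markers: list[str] | None = None, min_periods: int = 10) -> pd.DataFrame:
    """Composite LD: squared pairwise-complete correlation of genotype codes."""
    ms = list(markers if markers is not None else genotypes.calls.columns)
    X = genotypes.calls[ms].to_numpy(dtype=np.int8)
    return pd.DataFrame(_pairwise_r2(X, X, min_periods), index=ms, columns=ms)


def ld_lookup(genotypes: GenotypeMatrix, min_periods: int = 10):
    """Lazy block-LD accessor: callable(markers_a, markers_b) -> r^2 matrix.

    Avoids materializing a genome-wide marker x marker matrix; the chunk
    assembly and unmapped-placement steps only ever need small blocks.
    """
    calls = genotypes.calls

    def block(a: list[str], b: list[str]) -> np.ndarray:
        X = calls[list(a)].to_numpy(dtype=np.int8)
        Y = calls[list(b)].to_numpy(dtype=np.int8)
        return _pairwise_r2(X, Y, min_periods)

    return block


def assemble_linkage_groups(
    chunks: list[Chunk],
    ld_matrix,
    orders: dict[str, list[str]],
    split_distance_cm: float = 50.0,
    ld_floor: float = 0.02,
    max_markers_per_side: int = 40,
    score_quantile: float = 0.95,
    rng: np.random.Generator | None = None,
    gametes: "GameteSet | None" = None,
    split_recfrac: float = 0.45,
    max_move_fraction: float = 0.5,
) -> tuple[dict[tuple[str, int, int], str], list[dict]]:
    """Assign each chunk to the linkage group with the strongest inter-chunk LD.

    The score per candidate group is an upper quantile (``score_quantile``)
    of the chunk-to-group r^2 distribution — LD decays with distance, so only
    the markers physically near the chunk's true location carry signal and a
    whole-chromosome median would drown it.  The chunk's current (prior)
    group breaks ties and is kept when no group clears ``ld_floor``.  Within
    a group, a boundary between consecutive chunks is declared a fission into
    a new group when inter-chunk LD is below the floor and either the map gap
    reaches ``split_distance_cm`` or (when ``gametes`` are supplied) the
    direct pairwise recombination fraction across the boundary is >=
    ``split_recfrac``, i.e. the chunks segregate independently.
    Returns {(group, start, end): assigned group} plus an audit trail.
    ``ld_matrix`` is either a marker x marker r^2 DataFrame or a callable
    ``(markers_a, markers_b) -> r^2 array`` (see :func:`ld_lookup`).
    """
    rng = rng or np.random.default_rng(0)
    audit: list[dict] = []
    assignment: dict[tuple[str, int, int], str] = {}
    if callable(ld_matrix):
        ld_block = ld_matrix
    else:
        ld_block = lambda a, b: ld_matrix.loc[list(a), list(b)].to_numpy(dtype=float)

    def sample(ms: list[str]) -> list[str]:
        if len(ms) <= max_markers_per_side:
            return ms
        take = rng.choice(len(ms), size=max_markers_per_side, replace=False)
        return [ms[i] for i in sorted(take)]

    chunk_markers = {
        (c.group, c.start, c.end): orders[c.group][c.start : c.end] for c in chunks
    }
    for c in chunks:
        key = (c.group, c.start, c.end)
        if c.n > max_move_fraction * len(orders[c.group]):
            # the bulk of a group is its backbone, not a displacement
            # candidate; a misplaced chunk embedded elsewhere must not drag
            # the backbone toward itself
            assignment[key] = c.group
            continue
        own = set(chunk_markers[key])
        mine = sample(chunk_markers[key])
        best, best_score = c.group, -1.0
        for gname, gmarkers in orders.items():
            others = [m for m in gmarkers if m not in own]
            if not others:
                continue
            block = ld_block(mine, sample(others))
            if not np.isfinite(block).any():
                continue
            score = float(np.nanquantile(block, score_quantile))
            if np.isnan(score):
                continue
            if score > best_score + 1e-12:
                best, best_score = gname, score
        if best_score < ld_floor:
            best = c.group  # no signal anywhere: fall back to the prior group
        assignment[key] = best
        if best != c.group:
            audit.append({"action": "chunk_reassigned", "group": c.group, "start": c.start,
                          "end": c.end, "dest_group": best, "median_r2": best_score})

    # fission detection within each group, on chunks left in place
    by_group: dict[str, list[Chunk]] = {}
    for c in chunks:
        if assignment[(c.group, c.start, c.end)] == c.group:
            by_group.setdefault(c.group, []).append(c)
    def junction_recfrac(left: list[str], right: list[str]) -> float:
        if gametes is None:
            return np.nan
        a = [gametes.col[m] for m in left[-3:]]
        b = [gametes.col[m] for m in right[:3]]
        Oa = gametes.origins[:, a].astype(np.float64)
        Ob = gametes.origins[:, b].astype(np.float64)
        npair = np.abs(Oa).T @ np.abs(Ob)  # doubly informative gametes per pair
        rec = (npair - Oa.T @ Ob) / 2.0  # recombinant gametes per pair
        return float(rec.sum() / npair.sum()) if npair.sum() >= 10 else np.nan

    for gname, cs in by_group.items():
        cs = sorted(cs, key=lambda c: c.start)
        part = 0
        for prev, cur in zip(cs[:-1], cs[1:]):
            gap = cur.left_gap
            a = sample(chunk_markers[(prev.group, prev.start, prev.end)])
            b = sample(chunk_markers[(cur.group, cur.start, cur.end)])
            iblock = ld_block(a, b)
            inter = float(np.nanmedian(iblock)) if np.isfinite(iblock).any() else np.nan
            jr = junction_recfrac(orders[prev.group][prev.start : prev.end],
                                  orders[cur.group][cur.start : cur.end])
            free_recomb = gap >= split_distance_cm or (np.isfinite(jr) and jr >= split_recfrac)
            if free_recomb and (np.isnan(inter) or inter < ld_floor):
                part += 1
                audit.append({"action": "fission", "group": gname, "at_order_index": cur.start,
                              "gap_cm": gap, "junction_r": jr, "median_r2": inter,
                              "new_group": f"{gname}.{part}"})
            if part:
                assignment[(cur.group, cur.start, cur.end)] = f"{gname}.{part}"
    return assignment, audit


# ---------------------------------------------------------------------------
# Local rearrangements (Build 4)


def local_rearrangement_test(
    gametes: GameteSet,
    order: list[int],
    candidate: tuple[str, int, int],
    accept_threshold_cm: float = 1.0,
    fn: str = "kosambi",
) -> tuple[bool, float, list[int]]:
    """Test whether inverting or deleting a span shortens the group map.

    ``candidate`` is (kind, start, end) with kind in {"invert", "delete"} and
    indices into ``order`` (end exclusive).  Accepted iff the total group
    length decreases by >= ``accept_threshold_cm`` (inclusive).  Returns
    (accepted, delta_cm, modified order).
    """
    kind, s, e = candidate
    if not (0 <= s < e <= len(order)):
        raise ValueError("candidate span out of bounds")
    base = group_length(gametes, order, fn)
    if kind == "invert":
        new_order = order[:s] + order[s:e][::-1] + order[e:]
    elif kind == "delete":
        new_order = order[:s] + order[e:]
    else:
        raise ValueError(f"unknown candidate kind: {kind}")
    new_len = group_length(gametes, new_order, fn)
    delta = base - new_len
    return delta >= accept_threshold_cm, delta, new_order


def propose_inversions(
    gametes: GameteSet,
    order: list[int],
    max_len: int = 50,
    min_delta_cm: float = 1.0,
    fn: str = "kosambi",
    min_pairs: int = 8,
    top: int = 100,
) -> list[tuple[float, int, int]]:
    """Candidate inversion spans ranked by predicted map shortening.

    Inverting a contiguous span [s, e) leaves its internal distances intact
    and only swaps the two junction distances, so the expected change is
    d(s-1,s) + d(e-1,e) - d(s-1,e-1) - d(s,e) evaluated on pairwise
    recombination fractions — computable for every span at once from the
    pair count matrices, independent of how precisely chunk boundaries were
    segmented.  Returns up to ``top`` spans with predicted shortening
    >= ``min_delta_cm`` (descending); candidates must still pass the actual
    map-length acceptance test.
    """
    cols = np.asarray(order)
    O = gametes.origins[:, cols].astype(np.float64)
    I = (O != 0).astype(np.float64)
    N = I.T @ I
    P = O.T @ O
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.minimum((N - P) / 2.0 / np.maximum(N, 1), _R_CAP)
    R[N < min_pairs] = np.nan
    D = np.where(np.isnan(R), np.nan, map_distance(np.nan_to_num(R), fn))
    n = len(cols)
    # junction distances averaged over 3-marker blocks on either side: single
    # marker pairs share too few informative gametes to rank spans reliably
    b = 3
    Dp = np.full((n + 2 * b, n + 2 * b), np.nan)
    Dp[b : b + n, b : b + n] = D

    def block_mean(rows_off, cols_off, srow, scol):
        acc = np.zeros(n + 1)
        cnt = np.zeros(n + 1)
        base = np.arange(n + 1)
        for i in rows_off:
            for j in cols_off:
                r_idx = base + srow + i + b
                c_idx = base + scol + j + b
                ok = (r_idx >= 0) & (r_idx < n + 2 * b) & (c_idx >= 0) & (c_idx < n + 2 * b)
                v = np.full(n + 1, np.nan)
                v[ok] = Dp[r_idx[ok], c_idx[ok]]
                good = np.isfinite(v)
                acc[good] += v[good]
                cnt[good] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)

    left = tuple(range(-b, 0))  # markers just before a junction
    right = tuple(range(0, b))  # markers just after
    jAB = block_mean(left, right, 0, 0)  # current junction distance at position q
    out: list[tuple[float, int, int]] = []
    for w in range(2, min(max_len, n - 1) + 1):
        s = np.arange(1, n - w)  # interior spans: both junctions must exist
        e = s + w
        dAB, dCD = jAB[s], jAB[e]
        dAC = block_mean(left, left, 0, w)[s]  # [s-b, s) vs [e-b, e)
        dBD = block_mean(right, right, 0, w)[s]  # [s, s+b) vs [e, e+b)
        delta = dAB + dCD - dAC - dBD
        good = np.flatnonzero(np.nan_to_num(delta, nan=-np.inf) >= min_delta_cm)
        for k in good:
            out.append((float(delta[k]), int(s[k]), int(e[k])))
    out.sort(reverse=True)
    # non-maximum suppression: one noisy junction otherwise floods the list
    # with overlapping spans and starves genuine candidates elsewhere
    kept: list[tuple[float, int, int]] = []
    taken: set[tuple[int, int]] = set()
    for d, s, e in out:
        key_s, key_e = s // (b + 1), e // (b + 1)
        if (key_s, key_e) in taken:
            continue
        taken.add((key_s, key_e))
        kept.append((d, s, e))
        if len(kept) >= top:
            break
    return kept


# ---------------------------------------------------------------------------
# Unmapped-marker placement (Build 5)


@dataclass
class Placement:
    marker: str
    group: str | None
    best_index: int | None  # order index in the group, peak adjusted R^2
    interval: tuple[int, int] | None  # inclusive order-index range with R^2 >= threshold
    best_r2: float
    exact: bool


def place_unmapped(
    marker: str,
    ld_row: pd.Series,
    target_phase: np.ndarray,
    gametes: GameteSet,
    orders: dict[str, list[int]],
    window: int = 120,
    r2_threshold: float = 0.9,
    ld_floor: float = 0.02,
    min_shared: int = 10,
) -> Placement:
    """Place one unmapped marker by LD then phase correlation.

    The most likely group holds the marker with the highest LD to the target;
    a window of ``window`` mapped markers around that position is then scored
    by adjusted R^2 of allelic phase.  The placement is exact when the peak
    is a unique maximizer at or above the threshold; the >=-threshold range
    is reported as the placement interval when it spans several positions.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    best_marker, best_ld = None, -1.0
    mapped = {gametes.markers[j] for order in orders.values() for j in order}
    for m, v in ld_row.items():
        if m == marker or m not in mapped or not np.isfinite(v):
            continue
        if v > best_ld:
            best_marker, best_ld = m, float(v)
    if best_marker is None or best_ld < ld_floor:
        return Placement(marker, None, None, None, np.nan, False)

    jbest = gametes.col[best_marker]
    group = next(g for g, order in orders.items() if jbest in order)
    order = orders[group]
    pos = order.index(jbest)
    lo = max(0, pos - window // 2)
    hi = min(len(order), pos + window // 2)
    cand_cols = order[lo:hi]
    r2 = phasing.phase_correlation(target_phase, gametes.origins[:, cand_cols], min_shared)
    if not np.isfinite(r2).any():
        return Placement(marker, group, None, None, np.nan, False)
    k = int(np.nanargmax(r2))
    unique_peak = np.sum(np.isfinite(r2) & (r2 >= r2[k] - 1e-12)) == 1
    above = np.flatnonzero(r2 >= r2_threshold)
    interval = (lo + int(above[0]), lo + int(above[-1])) if above.size > 1 else None
    exact = bool(r2[k] >= r2_threshold and unique_peak)
    return Placement(marker, group, lo + k, interval, float(r2[k]), exact)


# ---------------------------------------------------------------------------
# Skeleton map and flips test (Build 6)


def build_skeleton(cm: np.ndarray, informativeness: np.ndarray) -> list[int]:
    """One representative per zero-recombination run: the most phase-informative
    marker, ties broken by the lowest order index."""
    cm = np.asarray(cm, dtype=float)
    keep = []
    s = 0
    for e in range(1, len(cm) + 1):
        if e == len(cm) or cm[e] != cm[s]:
            block = np.asarray(informativeness[s:e])
            keep.append(s + int(np.argmax(block)))
            s = e
    return keep


def flips_test(
    gametes: GameteSet,
    order: list[int],
    window: int = 100,
    overlap: int = 50,
    max_k: int = 5,
    lod_threshold: float = 2.0,
) -> list[dict]:
    """Exhaustively test permutations of k=2..max_k adjacent markers.

    Windows of ``window`` markers advance by ``window - overlap``.  Each
    permutation is scored by the change in log10 multipoint likelihood
    (binomial likelihood at the ML recombination fraction per adjacent
    interval, capped at 0.5); permutations beating the incumbent order by
    strictly more than ``lod_threshold`` are flagged.
    """
    if not window > max_k >= 2:
        raise ValueError("need window > max_k >= 2")
    flags: list[dict] = []
    step = max(window - overlap, 1)
    n = len(order)
    starts = list(range(0, max(n - overlap, 1), step)) if n > window else [0]

    for w0 in starts:
        cols = order[w0 : w0 + window]
        w = len(cols)
        if w < 3:
            continue
        O = gametes.origins[:, cols].astype(np.float64)
        I = (O != 0).astype(np.float64)
        P = O.T @ O
        N = I.T @ I
        # log10 likelihood of every marker pair at its ML r.  Each pair is
        # normalized to the window's mean informative count so that orders
        # are compared on a common amount of data: with partially informative
        # gametes the raw likelihood scales with the pair-specific n and
        # would reward adjacency of poorly informative pairs.
        nbar = float(N[np.triu_indices_from(N, 1)].mean())
        with np.errstate(invalid="ignore", divide="ignore"):
            p_hat = np.minimum(np.where(N > 0, (N - P) / 2.0 / np.maximum(N, 1), 0.0), 0.5)
            LL = np.where(p_hat > 0, nbar * p_hat * np.log10(np.maximum(p_hat, 1e-300)), 0.0)
            LL += nbar * (1.0 - p_hat) * np.log10(np.maximum(1.0 - p_hat, 1e-300))
        LL[N == 0] = 0.0

        def pair_ll(a: int, b: int) -> float:
            return float(LL[a, b])

        inc = [pair_ll(i, i + 1) for i in range(w - 1)]
        for k in range(2, max_k + 1):
            for p in range(0, w - k + 1):
                base_ll = sum(inc[max(p - 1, 0) : min(p + k, w - 1)])
                for perm in itertools.permutations(range(k)):
                    if perm == tuple(range(k)):
                        continue
                    block = [p + q for q in perm]
                    ll = 0.0
                    if p > 0:
                        ll += pair_ll(p - 1, block[0])
                    for a, b in zip(block[:-1], block[1:]):
                        ll += pair_ll(a, b)
                    if p + k < w:
                        ll += pair_ll(block[-1], p + k)
                    improvement = ll - base_ll
                    if improvement > lod_threshold:
                        flags.append({
                            "window_start": w0, "position": w0 + p, "k": k,
                            "permutation": perm, "improvement": improvement,
                        })
    return flags


# ---------------------------------------------------------------------------
# The Build 1-6 pipeline


@dataclass
class BuildConfig:
    """Thresholds of the six-build refinement (defaults as used throughout)."""

    chunk_gap_cm: float = 3.0  # Build 2 chunk boundary
    min_chunk_snps: int = 20  # Build 2 chunk size floor
    build4_gap_cm: float = 1.0  # Build 4 re-chunking boundary
    invert_max_snps: int = 50  # Build 4: test inversion of chunks below this
    delete_max_snps: int = 10  # Build 4: test deletion of chunks below this
    accept_threshold_cm: float = 1.0  # Build 4 acceptance (map shortening)
    placement_window: int = 120  # Build 5 phase-correlation window
    placement_r2: float = 0.9  # Build 5 adjusted-R^2 threshold
    dco_max_span_cm: float = 10.0  # Build 5 double-crossover cleaning
    flips_window: int = 100
    flips_overlap: int = 50
    flips_max_k: int = 5
    flips_lod: float = 2.0
    split_distance_cm: float = 50.0  # Build 3 fission call
    ld_floor: float = 0.02
    mapping: str = "kosambi"
    snp_error_threshold: float = 0.01
    subped_error_threshold: int = 50
    seed: int = 0


def _clean_group(gametes: GameteSet, order: list[int], cfg: BuildConfig) -> np.ndarray:
    """Singleton + short-double-crossover cleaning of one group's origin view."""
    sub = gametes.origins[:, order].copy()
    cm = map_positions(_recfracs_of(sub), cfg.mapping)
    for k in range(sub.shape[0]):
        g = phasing.PhasedGamete("", "", "na", sub[k])
        g = phasing.clean_singletons(g)
        g = phasing.remove_short_double_crossovers(g, cm, cfg.dco_max_span_cm)
        sub[k] = g.origins
    return sub


def _recfracs_of(sub: np.ndarray) -> np.ndarray:
    numer, denom = recfrac_counts(sub)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, numer / np.maximum(denom, 1), np.nan)


def run_build_pipeline(
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    config: BuildConfig | None = None,
) -> tuple[LinkageMap, pd.DataFrame]:
    """Run Builds 1-6 end to end; returns the final map and an audit log.

    The prior order comes from the marker metadata (``chrom``/``bp``), the
    stand-in for reference-genome synteny.  Every modification is logged with
    its build stage, rule, and map-length change.
    """
    from .pedio import build_subpedigrees, mendelian_check

    cfg = config or BuildConfig()
    audit: list[dict] = []

    def log(stage: str, action: str, **kw) -> None:
        audit.append({"stage": stage, "action": action, **kw})

    # Build 1: Mendelian cleaning and map on the prior order
    subpeds = build_subpedigrees(pedigree, set(genotypes.calls.index.astype(str)))
    gm, subpeds, mrep = mendelian_check(
        subpeds, genotypes, cfg.snp_error_threshold, cfg.subped_error_threshold
    )
    n_err = mrep.loc[mrep["item"] == "total_incompatibilities", "value"].sum()
    log("build1", "mendelian_check", incompatibilities=float(n_err),
        snps_dropped=int((mrep["reason"] == "mendelian_error_rate").sum()),
        subpeds_dropped=int((mrep["type"] == "subpedigree").sum()))

    meta = gm.markers.sort_values(["chrom", "bp"], kind="stable")
    all_markers = list(meta.index)
    gametes = phase_all(subpeds, gm, all_markers)
    orders: dict[str, list[int]] = {}
    for chrom, sub in meta.groupby("chrom", sort=True):
        orders[str(chrom)] = [gametes.col[m] for m in sub.index]
    log("build1", "prior_order_map", n_groups=len(orders), n_markers=len(all_markers))

    # Build 2: drop small chunks stranded between big gaps
    unplaced: list[int] = []
    for gname in list(orders):
        cm = map_positions(estimate_recfracs(gametes, orders[gname]), cfg.mapping)
        chunks = segment_chunks(cm, cfg.chunk_gap_cm, gname)
        kept, dropped = drop_small_chunks(chunks, cfg.min_chunk_snps)
        if dropped:
            drop_idx = {i for _, i in dropped}
            unplaced.extend(orders[gname][i] for i in sorted(drop_idx))
            orders[gname] = [j for i, j in enumerate(orders[gname]) if i not in drop_idx]
            log("build2", "chunks_dropped", group=gname, n_markers=len(drop_idx),
                n_chunks=len(chunks) - len(kept))
    log("build2", "summary", n_unplaced=len(unplaced))

    # Build 3: assemble chunks into linkage groups by LD (lazy block lookup)
    ld = ld_lookup(gm)
    chunk_lists: list[Chunk] = []
    name_orders = {g: [gametes.markers[j] for j in o] for g, o in orders.items()}
    for gname in list(orders):
        cm = map_positions(estimate_recfracs(gametes, orders[gname]), cfg.mapping)
        chunk_lists.extend(segment_chunks(cm, cfg.chunk_gap_cm, gname))
    assignment, b3audit = assemble_linkage_groups(
        chunk_lists, ld, name_orders, cfg.split_distance_cm, cfg.ld_floor,
        rng=np.random.default_rng(cfg.seed), gametes=gametes,
    )
    for entry in b3audit:
        log("build3", entry.pop("action"), **entry)
    moves = [(c, assignment[(c.group, c.start, c.end)]) for c in chunk_lists
             if assignment[(c.group, c.start, c.end)] != c.group]
    new_orders: dict[str, list[int]] = {g: list(o) for g, o in orders.items()}
    for c, dest in sorted(moves, key=lambda t: -t[0].start):
        span = orders[c.group][c.start : c.end]
        src = new_orders[c.group]
        i = src.index(span[0])
        del src[i : i + len(span)]
        if dest not in new_orders:  # fission: new group
            new_orders[dest] = list(span)
            continue
        # insert next to the highest-LD mapped marker in the destination group
        span_names = [gametes.markers[j] for j in span]
        dest_names = [gametes.markers[j] for j in new_orders[dest]]
        block = ld(span_names, dest_names)
        finite = np.isfinite(block)
        if finite.any():
            at = int(np.argmax(np.where(finite, block, -1.0).max(axis=0))) + 1
        else:
            at = len(dest_names)
        new_orders[dest] = new_orders[dest][:at] + span + new_orders[dest][at:]
    orders = {g: o for g, o in new_orders.items() if o}

    # Build 4: local inversions / deletions that shorten the map
    for gname in list(orders):
        changed = True
        sweeps = 0
        while changed and sweeps < 12:
            changed = False
            sweeps += 1
            # inversion candidates from the pairwise junction scan (robust to
            # imprecise chunk boundaries), each verified by the actual
            # map-length acceptance rule
            for _, s, e in propose_inversions(
                gametes, orders[gname], cfg.invert_max_snps,
                cfg.accept_threshold_cm, cfg.mapping):
                ok, delta, new_order = local_rearrangement_test(
                    gametes, orders[gname], ("invert", s, e),
                    cfg.accept_threshold_cm, cfg.mapping)
                if ok:
                    orders[gname] = new_order
                    log("build4", "inversion_accepted", group=gname, start=s,
                        end=e, delta_cm=delta)
                    changed = True
                    break
            if changed:
                continue
            cm = map_positions(estimate_recfracs(gametes, orders[gname]), cfg.mapping)
            for c in segment_chunks(cm, cfg.build4_gap_cm, gname):
                # deletion is tested for interior chunks only: removing a
                # terminal chunk always discards its flanking gap, so the
                # map-shortening criterion would fire on genuine structure
                if c.n < cfg.delete_max_snps and c.start > 0 and c.end < len(orders[gname]):
                    ok, delta, new_order = local_rearrangement_test(
                        gametes, orders[gname], ("delete", c.start, c.end),
                        cfg.accept_threshold_cm, cfg.mapping)
                    if ok:
                        unplaced.extend(orders[gname][c.start : c.end])
                        orders[gname] = new_order
                        log("build4", "deletion_accepted", group=gname, start=c.start,
                            end=c.end, n_markers=c.end - c.start, delta_cm=delta)
                        changed = True
                        break

    # Build 5: place unmapped markers, then clean phase errors
    if unplaced:
        mapped_names = [gametes.markers[j] for o in orders.values() for j in o]
        for j in unplaced:
            m = gametes.markers[j]
            row = pd.Series(ld([m], mapped_names)[0], index=mapped_names)
            pl = place_unmapped(
                m, row, gametes.origins[:, j], gametes, orders,
                cfg.placement_window, cfg.placement_r2, cfg.ld_floor)
            if pl.group is not None and pl.exact:
                orders[pl.group].insert(pl.best_index + 1, j)
                log("build5", "marker_placed", marker=m, group=pl.group,
                    order_index=pl.best_index + 1, adj_r2=pl.best_r2)
            elif pl.group is not None and pl.interval is not None:
                # phase cannot resolve within a zero-recombination run;
                # break the tie by LD to the candidate flanking markers
                lo_i, hi_i = pl.interval
                cand = orders[pl.group][lo_i : hi_i + 1]
                ld_seg = ld([m], [gametes.markers[q] for q in cand])[0]
                at = lo_i + (int(np.nanargmax(ld_seg)) if np.isfinite(ld_seg).any() else pl.best_index - lo_i)
                orders[pl.group].insert(at + 1, j)
                log("build5", "marker_placed_interval", marker=m, group=pl.group,
                    order_index=at + 1, interval=pl.interval, adj_r2=pl.best_r2)
            else:
                log("build5", "marker_unplaced", marker=m,
                    adj_r2=pl.best_r2 if pl.group else np.nan)

    cleaned = GameteSet(gametes.origins.copy(), gametes.ids, gametes.sexes, gametes.markers)
    for gname, order in orders.items():
        cleaned.origins[:, order] = _clean_group(gametes, order, cfg)
    log("build5", "phase_cleaning", informative_before=int(gametes.informativeness().sum()),
        informative_after=int(cleaned.informativeness().sum()))
    final = build_linkage_map(cleaned, orders, cfg.mapping)

    # Build 6: skeleton map and flips test (flags logged, order retained)
    info = cleaned.informativeness()
    n_flags = 0
    for gname, order in orders.items():
        cm = final.group_df(gname)["cm"].to_numpy()
        skel_pos = build_skeleton(cm, info[np.asarray(order)])
        skel_order = [order[i] for i in skel_pos]
        flags = flips_test(cleaned, skel_order, cfg.flips_window, cfg.flips_overlap,
                           cfg.flips_max_k, cfg.flips_lod)
        n_flags += len(flags)
        log("build6", "skeleton", group=gname, n_skeleton=len(skel_order),
            n_flips_flagged=len(flags))
    log("build6", "summary", total_flips_flagged=n_flags)

    return final, pd.DataFrame(audit)
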