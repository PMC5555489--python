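"""Grandparental-origin phasing of transmitted gametes and crossover calling.

For each subpedigree the allele the FID transmitted to its offspring is
deduced marker-by-marker (resolvable when the mate or the offspring is
homozygous), and its grandparental origin is deduced from the FID's parents
where the FID is heterozygous.  The resulting per-marker origin string
(grandpaternal / grandmaternal / uninformative) is the "chrompic"-style
object everything downstream consumes: crossovers are origin flips between
consecutive informative calls.

Phase-error cleaning follows two rules applied before any map estimation:
singleton origin runs are recoded uninformative, and interior double
crossovers spanning <= 10 cM between flanking markers are recoded
uninformative (crossovers escaping interference are not wanted in a
broad-scale map).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pedio import MISSING, GenotypeMatrix, SubPedigree

GRANDPATERNAL = 1
GRANDMATERNAL = -1
UNINFORMATIVE = 0

_SYMBOLS = {GRANDPATERNAL: "p", GRANDMATERNAL: "m", UNINFORMATIVE: "-"}

__all__ = [
    "GRANDPATERNAL",
    "GRANDMATERNAL",
    "UNINFORMATIVE",
    "PhasedGamete",
    "CrossoverEvent",
    "phase_gamete",
    "clean_singletons",
    "remove_short_double_crossovers",
    "detect_crossovers",
    "phase_correlation",
    "adjusted_r2",
    "write_chrompic",
]


@dataclass
class PhasedGamete:
    """Origin calls along one transmitted gamete on one linkage group."""

    subped_id: str
    group: str
    fid_sex: str
    origins: np.ndarray  # int8: +1 grandpaternal, -1 grandmaternal, 0 uninformative

    def __post_init__(self) -> None:
        self.origins = np.asarray(self.origins, dtype=np.int8)
        bad = set(np.unique(self.origins)) - {GRANDPATERNAL, GRANDMATERNAL, UNINFORMATIVE}
        if bad:
            raise ValueError(f"disallowed origin symbols: {sorted(bad)}")

    @property
    def n_informative(self) -> int:
        return int((self.origins != UNINFORMATIVE).sum())

    def to_string(self) -> str:
        return "".join(_SYMBOLS[v] for v in self.origins)


@dataclass(frozen=True)
class CrossoverEvent:
    """One origin flip, bounded by the nearest informative markers."""

    gamete_id: str
    group: str
    left_index: int
    right_index: int
    span_cm: float


def _runs(origins: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Informative marker indices plus (start, end) slices of same-origin runs
    over the informative subsequence (end exclusive)."""
    idx = np.flatnonzero(origins != UNINFORMATIVE)
    if idx.size == 0:
        return idx, []
    vals = origins[idx]
    breaks = np.flatnonzero(vals[1:] != vals[:-1]) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [vals.size]])
    return idx, list(zip(starts, ends))


def _phase_core(g, gs, gd, o, m) -> np.ndarray:
    """Origin calls from the five members' genotype rows (numpy int16)."""
    het = g == 1
    called = (o != MISSING) & (g != MISSING)

    t = np.full(g.shape, -9, dtype=np.int16)  # transmitted allele, -9 unknown
    mate_hom = (m == 0) | (m == 2)
    cand = o - m // 2
    ok = mate_hom & called & (cand >= 0) & (cand <= 1)
    t[ok] = cand[ok]
    off_hom = called & ((o == 0) | (o == 2))
    t[off_hom] = o[off_hom] // 2

    def can(gp: np.ndarray, x: int) -> np.ndarray:
        return (gp == MISSING) | (gp == 1) | (gp == (0 if x == 0 else 2))

    cons0 = can(gs, 0) & can(gd, 1)  # sire gave 0, dam gave 1
    cons1 = can(gs, 1) & can(gd, 0)
    unique = cons0 ^ cons1

    resolved = het & (t != -9) & unique
    x_from_sire = np.where(cons1, 1, 0)  # allele the sire donated, where unique
    origins = np.zeros(g.shape, dtype=np.int8)
    origins[resolved & (t == x_from_sire)] = GRANDPATERNAL
    origins[resolved & (t != x_from_sire)] = GRANDMATERNAL
    return origins


def phase_gamete(
    subped: SubPedigree,
    genotypes: GenotypeMatrix,
    order: list[str],
    group: str = "",
    par_markers: set[str] | None = None,
) -> PhasedGamete:
    """Deduce the grandparental origin of the FID-transmitted allele per marker.

    At each marker the transmitted allele is resolvable when the mate is
    homozygous (obligate subtraction from the offspring genotype) or the
    offspring is homozygous; ambiguous configurations stay uninformative
    rather than being imputed.  Origin is then assigned where the FID is
    heterozygous and exactly one assignment of its two alleles to its parents
    is consistent with their genotypes.  For a male FID on the X, only
    pseudoautosomal markers (``par_markers``) are phased.
    """
    cols = genotypes.calls.columns
    missing_cols = [m for m in order if m not in cols]
    if missing_cols:
        raise ValueError(f"markers absent from genotype matrix: {missing_cols[:5]}")
    sub = genotypes.calls.loc[list(subped.members), order].to_numpy(dtype=np.int16)
    g, gs, gd, o, m = sub  # fid, fid_sire, fid_dam, offspring, mate
    origins = _phase_core(g, gs, gd, o, m)

    if par_markers is not None and subped.fid_sex == "male":
        non_par = np.array([mk not in par_markers for mk in order])
        origins[non_par] = UNINFORMATIVE
    return PhasedGamete(subped.uid, group, subped.fid_sex, origins)


def clean_singletons(gamete: PhasedGamete) -> PhasedGamete:
    """Recode every informative run of length 1 as uninformative."""
    origins = gamete.origins.copy()
    idx, runs = _runs(origins)
    for s, e in runs:
        if e - s == 1:
            origins[idx[s]] = UNINFORMATIVE
    return replace(gamete, origins=origins)


def remove_short_double_crossovers(
    gamete: PhasedGamete,
    map_cm: np.ndarray,
    max_span_cm: float = 10.0,
) -> PhasedGamete:
    """Recode interior double-crossover runs spanning <= ``max_span_cm``.

    A candidate is an informative run whose neighbouring runs on both sides
    carry the opposite origin; the span is measured between the markers
    immediately flanking the run (inclusive threshold).  Applied iteratively
    until a fixed point, since removals create new adjacencies.
    """
    map_cm = np.asarray(map_cm, dtype=float)
    if np.any(np.diff(map_cm) < 0):
        raise ValueError("map positions must be non-decreasing")
    origins = gamete.origins.copy()
    while True:
        idx, runs = _runs(origins)
        to_clear: list[tuple[int, int]] = []
        for k in range(1, len(runs) - 1):
            s, e = runs[k]
            ps, pe = runs[k - 1]
            ns, ne = runs[k + 1]
            v = origins[idx[s]]
            if origins[idx[ps]] == -v and origins[idx[ns]] == -v:
                left_flank = idx[pe - 1]  # last marker of previous run
                right_flank = idx[ns]  # first marker of next run
                if map_cm[right_flank] - map_cm[left_flank] <= max_span_cm:
                    to_clear.append((s, e))
        if not to_clear:
            break
        for s, e in to_clear:
            origins[idx[s:e]] = UNINFORMATIVE
    return replace(gamete, origins=origins)


def detect_crossovers(gamete: PhasedGamete, map_cm: np.ndarray | None = None) -> list[CrossoverEvent]:
    """One event per origin flip between consecutive informative calls."""
    idx = np.flatnonzero(gamete.origins != UNINFORMATIVE)
    events = []
    if map_cm is None:
        map_cm = np.zeros(len(gamete.origins))
    for a, b in zip(idx[:-1], idx[1:]):
        if gamete.origins[a] != gamete.origins[b]:
            events.append(
                CrossoverEvent(gamete.subped_id, gamete.group, int(a), int(b),
                               float(map_cm[b] - map_cm[a]))
            )
    return events


def adjusted_r2(r2: float, n: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def phase_correlation(
    target_phases: np.ndarray,
    candidate_phases: np.ndarray,
    min_shared: int = 3,
) -> np.ndarray:
    """Adjusted R^2 between a target origin vector and candidate columns.

    Origins are coded +/-1 with uninformative excluded pairwise; positions
    sharing fewer than ``min_shared`` (>= 3) informative gametes with the
    target are NaN, as are positions where either vector is constant over the
    shared gametes (no variation to correlate).  The sign of the correlation
    is irrelevant (phase labelling is arbitrary per gamete set), so the
    squared correlation is used.
    """
    min_shared = max(min_shared, 3)
    t = np.asarray(target_phases, dtype=float)
    C = np.asarray(candidate_phases, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    out = np.full(C.shape[1], np.nan)
    for j in range(C.shape[1]):
        c = C[:, j]
        keep = (t != 0) & (c != 0)
        n = int(keep.sum())
        if n < min_shared:
            continue
        tt, cc = t[keep], c[keep]
        if np.all(tt == tt[0]) or np.all(cc == cc[0]):
            continue
        r = np.corrcoef(tt, cc)[0, 1]
        out[j] = adjusted_r2(r * r, n)
    return out


def write_chrompic(gametes: list[PhasedGamete], path) -> None:
    """Serialize one gamete per line as a chrompic-style p/m/- string."""
    rows = [(g.subped_id, g.group, g.fid_sex, g.to_string()) for g in gametes]
    pd.DataFrame(rows, columns=["gamete", "group", "fid_sex", "origins"]).to_csv(
        path, sep="\t", index=False
    )
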