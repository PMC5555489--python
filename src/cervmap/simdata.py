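"""Synthetic pedigrees, genetic maps, gametes, and genotypes with ground truth.

The generator emulates the study design the mapping pipeline assumes: focal
individuals (FIDs) whose parents are genotyped, each FID-offspring link
completed by a genotyped mate (so every link yields a five-member
subpedigree); per-sex crossover landscapes in which female intensity is
elevated by a constant multiplier in the peri-centromeric fraction of each
(acrocentric) linkage group; genotyping error and missingness; optional
transmission distortion; and injectable marker-order rearrangements that the
map-refinement builds must detect.  Every simulated meiosis is recorded in a
truth ledger (crossover breakpoints and grandparental-origin vectors) for
parameter-recovery tests.

All draws take an explicit seed; no global random state is touched.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pedio import MISSING, GenotypeMatrix

__all__ = [
    "GroupMap",
    "TrueMap",
    "SimTruth",
    "DistortionLocus",
    "Rearrangement",
    "simulate_pedigree",
    "simulate_true_map",
    "simulate_gametes_and_genotypes",
    "inject_rearrangements",
    "write_true_map",
    "write_truth",
    "write_config",
    "read_config",
]

HISTORIES = ("new_centromere", "retained_centromere", "unchanged", "metacentric")


@dataclass
class GroupMap:
    """True map of one linkage group with piecewise-constant sex intensities.

    Female crossover intensity is ``female_rate_peri`` (cM/Mb) on
    ``[0, peri_bp)`` and ``female_rate_rest`` beyond; male intensity is flat.
    The centromere sits at bp 0 for acrocentric groups.
    """

    name: str
    markers: list[str]
    bp: np.ndarray  # strictly increasing, int
    length_bp: int
    male_rate: float  # cM per Mb
    female_rate_peri: float
    female_rate_rest: float
    peri_bp: float
    centromere_bp: float
    history: str
    multiplier: float
    fraction: float

    def cm_at(self, bp: np.ndarray, sex: str) -> np.ndarray:
        bp = np.asarray(bp, dtype=float)
        if sex == "male":
            return self.male_rate * bp / 1e6
        inside = np.minimum(bp, self.peri_bp)
        outside = np.maximum(bp - self.peri_bp, 0.0)
        return (self.female_rate_peri * inside + self.female_rate_rest * outside) / 1e6

    def bp_at_cm(self, cm: np.ndarray, sex: str) -> np.ndarray:
        cm = np.asarray(cm, dtype=float)
        if sex == "male":
            return cm * 1e6 / self.male_rate
        knee = self.female_rate_peri * self.peri_bp / 1e6
        below = cm * 1e6 / self.female_rate_peri
        above = self.peri_bp + (cm - knee) * 1e6 / self.female_rate_rest
        return np.where(cm <= knee, below, above)

    def total_cm(self, sex: str) -> float:
        return float(self.cm_at(np.array([self.length_bp]), sex)[0])

    def marker_cm(self, sex: str) -> np.ndarray:
        return self.cm_at(self.bp, sex)


@dataclass
class TrueMap:
    """Per-group true maps plus the global generating parameters."""

    groups: dict[str, GroupMap]
    female_ratio: float
    pericentromeric_fraction: float

    def group_names(self) -> list[str]:
        return list(self.groups)

    def total_length(self, sex: str) -> float:
        return sum(g.total_cm(sex) for g in self.groups.values())

    def marker_table(self) -> pd.DataFrame:
        rows = []
        for g in self.groups.values():
            cm_m, cm_f = g.marker_cm("male"), g.marker_cm("female")
            for i, m in enumerate(g.markers):
                rows.append((m, g.name, int(g.bp[i]), cm_m[i], cm_f[i], g.history))
        return pd.DataFrame(rows, columns=["marker", "group", "bp", "cm_male", "cm_female", "history"])

    def order(self) -> dict[str, list[str]]:
        return {name: list(g.markers) for name, g in self.groups.items()}


@dataclass(frozen=True)
class DistortionLocus:
    """A locus where a heterozygous parent transmits ``allele`` with probability ``prob``."""

    marker: str
    prob: float
    allele: int = 1
    sex: str | None = None  # restrict to transmitting parents of this sex


@dataclass(frozen=True)
class Rearrangement:
    """Marker-order error to inject into a prior order (not into the truth)."""

    kind: str  # inversion | chunk_displacement | fission
    group: str
    start: int
    length: int
    dest_group: str | None = None
    dest_index: int | None = None
    new_group: str | None = None


@dataclass
class SimTruth:
    """Ledger of everything the simulator actually did."""

    # (parent, child, group) -> crossover breakpoints in bp
    breakpoints: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    # (parent, child, group) -> per-marker origin (+1 grandpaternal, -1 grandmaternal)
    origins: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    rearrangements: list[dict] = field(default_factory=list)
    distortion: list[dict] = field(default_factory=list)

    def crossover_count(self, parent: str, child: str, group: str) -> int:
        return len(self.breakpoints[(parent, child, group)])


def simulate_pedigree(
    n_male_fids: int,
    n_female_fids: int,
    offspring_per_fid: int | tuple[int, int],
    seed: int,
) -> pd.DataFrame:
    """Pedigree in which every FID-offspring link forms a complete subpedigree.

    Each FID gets two founder parents; each offspring gets a dedicated founder
    mate of the opposite sex to the FID.  ``offspring_per_fid`` may be an int
    or an inclusive (low, high) range sampled per FID.
    """
    if n_male_fids < 1 or n_female_fids < 1:
        raise ValueError("FID counts must be >= 1")
    if isinstance(offspring_per_fid, int):
        if offspring_per_fid < 1:
            raise ValueError("offspring_per_fid must be >= 1")
        draw = lambda rng: offspring_per_fid
    else:
        lo, hi = offspring_per_fid
        if lo < 1 or hi < lo:
            raise ValueError("offspring range must satisfy 1 <= low <= high")
        draw = lambda rng: int(rng.integers(lo, hi + 1))

    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str, str]] = []
    off_counter = itertools.count(1)
    mate_counter = itertools.count(1)
    fids = [(f"M{i+1}", "male") for i in range(n_male_fids)] + [
        (f"F{i+1}", "female") for i in range(n_female_fids)
    ]
    for fid, sex in fids:
        gs, gd = f"GS_{fid}", f"GD_{fid}"
        rows.append((gs, "0", "0", "male"))
        rows.append((gd, "0", "0", "female"))
        rows.append((fid, gs, gd, sex))
    for fid, sex in fids:
        for _ in range(draw(rng)):
            mate = f"MT{next(mate_counter)}"
            rows.append((mate, "0", "0", "female" if sex == "male" else "male"))
            off = f"O{next(off_counter)}"
            sire, dam = (fid, mate) if sex == "male" else (mate, fid)
            rows.append((off, sire, dam, rng.choice(["male", "female"])))
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex"])


def simulate_true_map(
    n_groups: int,
    markers_per_group: int,
    chrom_length_mb: float,
    female_ratio: float = 1.21,
    pericentromeric_multiplier: float | dict[str, float] = 4.0,
    pericentromeric_fraction: float = 0.2,
    histories: list[str] | None = None,
    male_rate_cm_per_mb: float = 1.0,
    seed: int = 0,
) -> TrueMap:
    """Generate per-sex true maps with an elevated female peri-centromeric rate.

    Female intensity within the first ``pericentromeric_fraction`` of each
    group is ``multiplier`` times the female intensity elsewhere; a global
    scale is then chosen so that total female map length / total male map
    length equals ``female_ratio`` exactly.  ``pericentromeric_multiplier``
    may be a scalar or a dict keyed by history label (e.g. boosting
    new-centromere groups).
    """
    if not 0.0 < pericentromeric_fraction < 1.0:
        raise ValueError("pericentromeric_fraction must be in (0, 1)")
    if histories is None:
        histories = ["unchanged"] * n_groups
    if len(histories) != n_groups:
        raise ValueError(f"histories has {len(histories)} labels for {n_groups} groups")
    bad = set(histories) - set(HISTORIES)
    if bad:
        raise ValueError(f"unknown history labels: {sorted(bad)}")

    def mult_for(h: str) -> float:
        if isinstance(pericentromeric_multiplier, dict):
            m = pericentromeric_multiplier.get(h, 1.0)
        else:
            m = pericentromeric_multiplier
        if m < 1.0:
            raise ValueError("pericentromeric multiplier must be >= 1")
        return float(m)

    rng = np.random.default_rng(seed)
    L_mb = float(chrom_length_mb)
    L_bp = int(L_mb * 1e6)
    f = pericentromeric_fraction
    mults = [mult_for(h) for h in histories]

    male_len = male_rate_cm_per_mb * L_mb  # per group, identical lengths
    unnorm = [male_rate_cm_per_mb * L_mb * ((1.0 - f) + f * m) for m in mults]
    scale = female_ratio * male_len * n_groups / sum(unnorm)

    groups: dict[str, GroupMap] = {}
    for gi in range(n_groups):
        name = f"G{gi+1}"
        bp = np.sort(rng.choice(np.arange(1, L_bp), size=markers_per_group, replace=False))
        rest = scale * male_rate_cm_per_mb
        groups[name] = GroupMap(
            name=name,
            markers=[f"{name}_{i+1:05d}" for i in range(markers_per_group)],
            bp=bp.astype(np.int64),
            length_bp=L_bp,
            male_rate=male_rate_cm_per_mb,
            female_rate_peri=rest * mults[gi],
            female_rate_rest=rest,
            peri_bp=f * L_bp,
            centromere_bp=0.0 if histories[gi] != "metacentric" else L_bp / 2.0,
            history=histories[gi],
            multiplier=mults[gi],
            fraction=f,
        )
    return TrueMap(groups, female_ratio, f)


def _crossover_positions(rng: np.random.Generator, total_cm: float, interference: str, nu: float) -> np.ndarray:
    """Crossover positions (cM scale) for one meiosis on one group."""
    if interference == "none":
        n = rng.poisson(total_cm / 100.0)
        return np.sort(rng.uniform(0.0, total_cm, size=n))
    if interference == "gamma":
        # chiasmata on the four-strand bundle: gamma renewal, mean 50 cM,
        # shape nu; each event resolves into this gamete with probability 1/2
        mean = 50.0
        burn = 5 * mean
        pos, t = [], -burn
        while t < total_cm:
            t += rng.gamma(nu, mean / nu)
            if 0.0 <= t < total_cm:
                pos.append(t)
        keep = rng.random(len(pos)) < 0.5
        return np.asarray(pos, dtype=float)[keep]
    raise ValueError(f"unknown interference mode: {interference}")


def simulate_gametes_and_genotypes(
    pedigree: pd.DataFrame,
    truemap: TrueMap,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    interference: str = "none",
    interference_nu: float = 5.0,
    distortion_loci: list[DistortionLocus] | None = None,
    founder_freq_range: tuple[float, float] = (0.05, 0.5),
    founder_pool: int | None = None,
    founder_segment_mb: float = 20.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Drop haplotypes through the pedigree and emit genotypes plus truth.

    Founder haplotypes are drawn in linkage equilibrium from per-marker allele
    frequencies uniform on ``founder_freq_range``; with ``founder_pool`` set,
    each founder haplotype is instead a recombinant mosaic of that many base
    haplotypes (segment lengths exponential with mean ``founder_segment_mb``),
    which creates the inter-marker LD the group-assembly and marker-placement
    steps rely on.  Every meiosis places
    crossovers by a Poisson process on the transmitting parent's per-sex cM
    scale (gamma-renewal thinning under ``interference='gamma'``).  Genotype
    error is symmetric reassignment to one of the other two classes;
    missingness is independent per call.  The truth ledger records crossover
    breakpoints and grandparental-origin vectors for every meiosis, untouched
    by error or missingness.
    """
    if not (0.0 <= error_rate < 1.0 and 0.0 <= missing_rate < 1.0):
        raise ValueError("rates must be in [0, 1)")
    distortion_loci = list(distortion_loci or [])
    marker_to_group: dict[str, str] = {}
    for g in truemap.groups.values():
        for m in g.markers:
            marker_to_group[m] = g.name
    for d in distortion_loci:
        if d.marker not in marker_to_group:
            raise ValueError(f"distortion locus {d.marker} not in map")

    rng = np.random.default_rng(seed)
    truth = SimTruth()
    truth.distortion = [
        {"marker": d.marker, "prob": d.prob, "allele": d.allele, "sex": d.sex}
        for d in distortion_loci
    ]
    dist_by_group: dict[str, list[DistortionLocus]] = {}
    for d in distortion_loci:
        dist_by_group.setdefault(marker_to_group[d.marker], []).append(d)

    ped = pedigree.astype({"id": str, "sire": str, "dam": str})
    sexes = dict(zip(ped["id"], ped["sex"]))
    parents = {r.id: (r.sire, r.dam) for r in ped.itertuples()}
    is_founder = {i: (s in ("0", "nan") or d in ("0", "nan")) for i, (s, d) in parents.items()}

    # topological order: founders first, then repeatedly emit resolvable ids
    done: set[str] = set()
    order: list[str] = []
    pending = list(ped["id"])
    while pending:
        nxt = []
        for i in pending:
            if is_founder[i] or (parents[i][0] in done and parents[i][1] in done):
                order.append(i)
                done.add(i)
            else:
                nxt.append(i)
        if len(nxt) == len(pending):
            raise ValueError("pedigree contains a cycle or missing parents")
        pending = nxt

    # haplotypes[group][id] = (hap_from_sire, hap_from_dam)
    haplos: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {g: {} for g in truemap.groups}
    freqs: dict[str, np.ndarray] = {}
    pools: dict[str, np.ndarray] = {}
    for gname, g in truemap.groups.items():
        freqs[gname] = rng.uniform(*founder_freq_range, size=len(g.markers))
        if founder_pool:
            pools[gname] = (rng.random((founder_pool, len(g.markers))) < freqs[gname]).astype(np.int8)

    def founder_hap(gname: str) -> np.ndarray:
        g = truemap.groups[gname]
        p = freqs[gname]
        if not founder_pool:
            return (rng.random(len(p)) < p).astype(np.int8)
        # mosaic of pool haplotypes: exponential segment lengths on the bp scale
        cuts = []
        pos = 0.0
        while pos < g.length_bp:
            pos += rng.exponential(founder_segment_mb * 1e6)
            if pos < g.length_bp:
                cuts.append(pos)
        seg = np.searchsorted(np.asarray(cuts), g.bp, side="right")
        picks = rng.integers(0, founder_pool, size=len(cuts) + 1)
        return pools[gname][picks[seg], np.arange(len(g.markers))].astype(np.int8)

    def meiosis(parent: str, child: str, gname: str) -> np.ndarray:
        g = truemap.groups[gname]
        sex = sexes[parent]
        total = g.total_cm(sex)
        cm_pos = _crossover_positions(rng, total, interference, interference_nu)
        bp_pos = g.bp_at_cm(cm_pos, sex)
        start = int(rng.integers(0, 2))  # 0 = parent's sire-haplotype first
        seg = (start + np.searchsorted(bp_pos, g.bp, side="right")) % 2
        hs, hd = haplos[gname][parent]
        gamete = np.where(seg == 0, hs, hd).astype(np.int8)
        # distortion: single-site override of the transmitted allele
        for d in dist_by_group.get(gname, ()):
            if d.sex is not None and sex != d.sex:
                continue
            j = g.markers.index(d.marker)
            if hs[j] != hd[j]:  # heterozygous transmitting parent
                target = d.allele if rng.random() < d.prob else 1 - d.allele
                gamete[j] = target
        truth.breakpoints[(parent, child, gname)] = bp_pos
        truth.origins[(parent, child, gname)] = np.where(seg == 0, 1, -1).astype(np.int8)
        return gamete

    for ind in order:
        for gname, g in truemap.groups.items():
            if is_founder[ind]:
                haplos[gname][ind] = (founder_hap(gname), founder_hap(gname))
            else:
                sire, dam = parents[ind]
                haplos[gname][ind] = (meiosis(sire, ind, gname), meiosis(dam, ind, gname))

    ids = list(ped["id"])
    blocks, marker_names, meta_rows = [], [], []
    for gname, g in truemap.groups.items():
        mat = np.empty((len(ids), len(g.markers)), dtype=np.int8)
        for k, i in enumerate(ids):
            hs, hd = haplos[gname][i]
            mat[k] = hs + hd
        blocks.append(mat)
        marker_names.extend(g.markers)
        cm_m = g.marker_cm("male")
        for j, m in enumerate(g.markers):
            meta_rows.append((m, gname, int(g.bp[j]), False, False))
    calls = np.concatenate(blocks, axis=1)

    if error_rate > 0:
        err = rng.random(calls.shape) < error_rate
        shift = rng.integers(1, 3, size=calls.shape)  # +1 or +2 mod 3: one of the other classes
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < missing_rate, MISSING, calls).astype(np.int8)

    frame = pd.DataFrame(calls, index=ids, columns=marker_names)
    markers = pd.DataFrame(
        meta_rows, columns=["marker", "chrom", "bp", "x_linked", "pseudoautosomal"]
    ).set_index("marker")
    return GenotypeMatrix(frame, markers), truth


def inject_rearrangements(
    marker_order: dict[str, list[str]],
    spec: list[Rearrangement],
    seed: int = 0,
) -> tuple[dict[str, list[str]], list[dict]]:
    """Apply inversions / chunk displacements / fissions to a marker order.

    Returns the shuffled order and truth-ledger entries recording each span's
    original and new location.  Spans within a group must not overlap.
    """
    rng = np.random.default_rng(seed)
    order = {g: list(ms) for g, ms in marker_order.items()}
    seen: dict[str, list[tuple[int, int]]] = {}
    for r in spec:
        if r.group not in order:
            raise ValueError(f"unknown group {r.group}")
        n = len(marker_order[r.group])
        if r.start < 0 or r.length < 1 or r.start + r.length > n:
            raise ValueError(f"span out of bounds on {r.group}: {r.start}+{r.length}")
        for s, e in seen.get(r.group, ()):
            if r.start < e and s < r.start + r.length:
                raise ValueError(f"overlapping rearrangement spans on {r.group}")
        seen.setdefault(r.group, []).append((r.start, r.start + r.length))

    entries: list[dict] = []
    # apply in reverse start order per group so earlier indices stay valid
    for r in sorted(spec, key=lambda r: -r.start):
        ms = order[r.group]
        span = marker_order[r.group][r.start : r.start + r.length]
        if r.kind == "inversion":
            i = ms.index(span[0])
            ms[i : i + len(span)] = span[::-1]
            entries.append({"kind": "inversion", "group": r.group, "markers": list(span),
                            "start": r.start, "length": r.length})
        elif r.kind == "chunk_displacement":
            dest = r.dest_group or rng.choice([g for g in order if g != r.group])
            i = ms.index(span[0])
            del ms[i : i + len(span)]
            dst = order[dest]
            at = r.dest_index if r.dest_index is not None else int(rng.integers(0, len(dst) + 1))
            order[dest] = dst[:at] + list(span) + dst[at:]
            entries.append({"kind": "chunk_displacement", "group": r.group, "markers": list(span),
                            "start": r.start, "length": r.length,
                            "dest_group": dest, "dest_index": at})
        elif r.kind == "fission":
            new = r.new_group or f"{r.group}b"
            i = ms.index(span[0])
            order[new] = ms[i:]
            order[r.group] = ms[:i]
            entries.append({"kind": "fission", "group": r.group, "new_group": new,
                            "start": r.start, "markers": list(order[new])})
        else:
            raise ValueError(f"unknown rearrangement kind: {r.kind}")
    return order, entries


def simulate_true_gametes(
    truemap: TrueMap,
    n_male: int,
    n_female: int,
    interference: str = "none",
    interference_nu: float = 5.0,
    seed: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Fully informative phased gametes drawn straight from the true map.

    Per group, returns (origins, sexes): origins is (n_male + n_female) x
    markers int8 in {+1, -1} — the chromatid of origin at every marker, with
    crossovers placed by the per-sex intensity — and sexes the transmitting
    parent's sex per row.  Bypasses genotypes entirely: this is the ideal
    noise-free input for landscape and estimator tests.
    """
    rng = np.random.default_rng(seed)
    sexes = np.array(["male"] * n_male + ["female"] * n_female)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for gname, g in truemap.groups.items():
        mat = np.empty((n_male + n_female, len(g.markers)), dtype=np.int8)
        for k, sex in enumerate(sexes):
            total = g.total_cm(sex)
            cm_pos = _crossover_positions(rng, total, interference, interference_nu)
            bp_pos = g.bp_at_cm(cm_pos, sex)
            start = int(rng.integers(0, 2))
            seg = (start + np.searchsorted(bp_pos, g.bp, side="right")) % 2
            mat[k] = np.where(seg == 0, 1, -1)
        out[gname] = (mat, sexes.copy())
    return out


def prior_metadata_from_order(
    order: dict[str, list[str]],
    spacing_bp: float = 250_000.0,
) -> pd.DataFrame:
    """Marker metadata (chrom, bp) encoding a prior order, e.g. after
    rearrangement injection: each group's markers get rank-spaced positions.

    Emulates a reference-synteny prior: the pipeline re-derives marker order
    per group by sorting on (chrom, bp).
    """
    rows = []
    for gname, ms in order.items():
        for i, m in enumerate(ms):
            rows.append((m, gname, int((i + 1) * spacing_bp), False, False))
    return pd.DataFrame(
        rows, columns=["marker", "chrom", "bp", "x_linked", "pseudoautosomal"]
    ).set_index("marker")


# ---------------------------------------------------------------------------
# Writers


def write_true_map(truemap: TrueMap, path: str | Path) -> None:
    truemap.marker_table().to_csv(path, sep="\t", index=False)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    rows = []
    for (parent, child, group), bps in truth.breakpoints.items():
        rows.append((parent, child, group, ";".join(str(int(b)) for b in bps)))
    pd.DataFrame(rows, columns=["parent", "child", "group", "breakpoints_bp"]).to_csv(
        path, sep="\t", index=False
    )


def write_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
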