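"""Pedigree / genotype containers, quality control, and subpedigree construction.

The mapping design phases one transmitted gamete per focal-individual (FID) to
offspring link, using a five-member "subpedigree": the FID, its sire and dam,
one offspring, and the offspring's other parent.  All five must be genotyped.
This module reads the input tables, applies marker/individual QC, builds the
subpedigrees, and removes Mendelian-inconsistent genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1  # genotype code for a missing call

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SubPedigree",
    "qc_filter",
    "build_subpedigrees",
    "mendelian_check",
    "balance_sexes",
    "read_pedigree_tsv",
    "write_pedigree_tsv",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_ped_map",
    "write_ped_map",
]


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype calls with per-marker metadata.

    ``calls`` is an individuals-by-markers integer frame coded {0, 1, 2} as
    copies of the counted (reference) allele, ``MISSING`` (-1) for no-calls.
    ``markers`` is indexed by marker name with columns ``chrom`` (prior
    reference chromosome), ``bp`` (prior reference position), ``x_linked``
    and ``pseudoautosomal`` (booleans).
    """

    calls: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.calls.columns) != list(self.markers.index):
            self.markers = self.markers.loc[list(self.calls.columns)]
        for col, default in (("x_linked", False), ("pseudoautosomal", False)):
            if col not in self.markers.columns:
                self.markers[col] = default
        bad = set(np.unique(self.calls.to_numpy())) - {0, 1, 2, MISSING}
        if bad:
            raise ValueError(f"disallowed genotype codes: {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset(self, individuals=None, markers=None) -> "GenotypeMatrix":
        calls = self.calls
        if individuals is not None:
            calls = calls.loc[list(individuals)]
        if markers is not None:
            calls = calls[list(markers)]
        return GenotypeMatrix(calls.copy(), self.markers.loc[list(calls.columns)].copy())

    def array(self) -> np.ndarray:
        return self.calls.to_numpy(dtype=np.int8)


@dataclass(frozen=True)
class SubPedigree:
    """Five-member phasing unit around one FID-offspring link."""

    fid: str
    fid_sex: str  # sex of the FID: the meiosis under study happens in the FID
    fid_sire: str
    fid_dam: str
    offspring: str
    mate: str

    @property
    def uid(self) -> str:
        return f"{self.fid}|{self.offspring}"

    @property
    def members(self) -> tuple[str, str, str, str, str]:
        return (self.fid, self.fid_sire, self.fid_dam, self.offspring, self.mate)


def _call_rate(frame: pd.DataFrame, axis: int) -> pd.Series:
    return (frame != MISSING).mean(axis=axis)


def _maf(frame: pd.DataFrame) -> pd.Series:
    """Minor allele frequency per marker, from called genotypes only."""
    called = frame.where(frame != MISSING)
    p = called.sum(axis=0) / (2.0 * called.notna().sum(axis=0))
    return np.minimum(p, 1.0 - p)


def qc_filter(
    genotypes: GenotypeMatrix,
    snp_call_threshold: float = 0.99,
    maf_threshold: float = 0.01,
    id_call_threshold: float = 0.99,
    sexes: pd.Series | None = None,
    par_het_threshold: float = 0.05,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply marker and individual QC; returns the filtered matrix and a report.

    Individuals failing ``id_call_threshold`` are removed first; marker call
    rate and MAF are then computed on the retained individuals.  X-linked
    markers whose male heterozygote frequency exceeds ``par_het_threshold``
    are flagged pseudoautosomal; remaining male heterozygous calls at non-PAR
    X markers are set missing (males are hemizygous there, so a heterozygote
    is a genotyping artefact).  The report lists one row per action with
    columns (item, type, reason, value).
    """
    for name, t in (("snp_call_threshold", snp_call_threshold),
                    ("maf_threshold", maf_threshold),
                    ("id_call_threshold", id_call_threshold)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    if genotypes.n_individuals == 0 or genotypes.n_markers == 0:
        raise ValueError("empty genotype matrix")

    report: list[tuple[str, str, str, float]] = []
    calls = genotypes.calls.copy()

    id_rate = _call_rate(calls, axis=1)
    bad_ids = id_rate.index[id_rate < id_call_threshold]
    for i in bad_ids:
        report.append((str(i), "individual", "id_call_rate", float(id_rate[i])))
    calls = calls.drop(index=bad_ids)

    snp_rate = _call_rate(calls, axis=0)
    maf = _maf(calls)
    drop_snps: dict[str, tuple[str, float]] = {}
    for m in calls.columns:
        if snp_rate[m] < snp_call_threshold:
            drop_snps[m] = ("snp_call_rate", float(snp_rate[m]))
        elif not (maf[m] > maf_threshold):  # NaN (monomorphic, all-missing) fails too
            drop_snps[m] = ("maf", float(maf[m]))
    for m, (reason, val) in drop_snps.items():
        report.append((str(m), "marker", reason, val))
    calls = calls.drop(columns=list(drop_snps))

    markers = genotypes.markers.loc[list(calls.columns)].copy()
    if sexes is not None:
        males = [i for i in calls.index if sexes.get(i) == "male"]
        x_markers = markers.index[markers["x_linked"].astype(bool)]
        if males and len(x_markers):
            male_calls = calls.loc[males, x_markers]
            het = (male_calls == 1).sum(axis=0) / (male_calls != MISSING).sum(axis=0).clip(lower=1)
            for m in x_markers:
                if het[m] > par_het_threshold and not markers.at[m, "pseudoautosomal"]:
                    markers.at[m, "pseudoautosomal"] = True
                    report.append((str(m), "marker", "flagged_pseudoautosomal", float(het[m])))
            non_par = [m for m in x_markers if not markers.at[m, "pseudoautosomal"]]
            if non_par:
                block = calls.loc[males, non_par]
                n_masked = int((block == 1).sum().sum())
                calls.loc[males, non_par] = block.where(block != 1, MISSING)
                if n_masked:
                    report.append(("male_X_heterozygotes", "calls", "set_missing", float(n_masked)))

    rep = pd.DataFrame(report, columns=["item", "type", "reason", "value"])
    return GenotypeMatrix(calls, markers), rep


def build_subpedigrees(pedigree: pd.DataFrame, genotyped_ids: set[str]) -> list[SubPedigree]:
    """One SubPedigree per FID-offspring link with all five members genotyped.

    ``pedigree`` has columns id, sire, dam, sex; "0" / NaN denote a missing
    parent.  An FID with k qualifying offspring yields k subpedigrees.
    """
    ped = pedigree.astype({"id": str})
    sire = {r.id: str(r.sire) for r in ped.itertuples() if str(r.sire) not in ("0", "nan", "None", "")}
    dam = {r.id: str(r.dam) for r in ped.itertuples() if str(r.dam) not in ("0", "nan", "None", "")}
    sex = {r.id: r.sex for r in ped.itertuples()}
    geno = {str(i) for i in genotyped_ids}

    out: list[SubPedigree] = []
    for off in ped["id"]:
        parents = [(sire.get(off), "male"), (dam.get(off), "female")]
        for fid, fid_sex in parents:
            if fid is None:
                continue
            mate = dam.get(off) if fid_sex == "male" else sire.get(off)
            fs, fd = sire.get(fid), dam.get(fid)
            members = (fid, fs, fd, off, mate)
            if any(m is None for m in members) or not set(members) <= geno:
                continue
            if len(set(members)) != 5:
                continue
            out.append(SubPedigree(fid, sex.get(fid, fid_sex), fs, fd, off, mate))
    return out


_DUOS = (("fid_sire", "fid"), ("fid_dam", "fid"), ("fid", "offspring"), ("mate", "offspring"))


def mendelian_check(
    subpeds: list[SubPedigree],
    genotypes: GenotypeMatrix,
    snp_error_threshold: float = 0.01,
    subped_error_threshold: int = 50,
) -> tuple[GenotypeMatrix, list[SubPedigree], pd.DataFrame]:
    """Detect parent-offspring genotype incompatibilities and mask them.

    An opposing-homozygote duo conflict (parent 0 / child 2 or vice versa),
    or a trio-impossible configuration (both parents homozygous but the child
    inconsistent with the obligate transmission), sets the implicated calls
    missing on every side.  Per-SNP error rate is incompatibilities divided
    by informative duos; SNPs above ``snp_error_threshold`` are dropped, and
    subpedigrees with more than ``subped_error_threshold`` FID-offspring
    errors are dropped.
    """
    if snp_error_threshold <= 0 or subped_error_threshold <= 0:
        raise ValueError("thresholds must be positive")
    calls = genotypes.calls.copy()
    arr = calls.to_numpy(dtype=np.int16)
    idx = {str(i): k for k, i in enumerate(calls.index)}
    n_markers = calls.shape[1]

    err_count = np.zeros(n_markers, dtype=np.int64)
    duo_count = np.zeros(n_markers, dtype=np.int64)
    mask = np.zeros_like(arr, dtype=bool)
    fid_off_errors: dict[str, int] = {}
    rows = []

    for sp in subpeds:
        r = {name: idx[getattr(sp, name)] for name in ("fid", "fid_sire", "fid_dam", "offspring", "mate")}
        sp_err = 0
        for pa, ch in _DUOS:
            gp, gc = arr[r[pa]], arr[r[ch]]
            informative = (gp != MISSING) & (gc != MISSING)
            conflict = informative & (np.abs(gp - gc) == 2)
            duo_count += informative
            err_count += conflict
            mask[r[pa]] |= conflict
            mask[r[ch]] |= conflict
            if (pa, ch) == ("fid", "offspring"):
                sp_err += int(conflict.sum())
        # trio-impossible: both parents homozygous, child differs from obligate mean
        for p1, p2, ch in (("fid_sire", "fid_dam", "fid"), ("fid", "mate", "offspring")):
            g1, g2, gc = arr[r[p1]], arr[r[p2]], arr[r[ch]]
            informative = (g1 != MISSING) & (g2 != MISSING) & (gc != MISSING)
            hom = (g1 % 2 == 0) & (g2 % 2 == 0)
            conflict = informative & hom & (gc != (g1 + g2) // 2)
            # opposing-homozygote duo conflicts are already counted above
            duo_conf = (np.abs(g1 - gc) == 2) | (np.abs(g2 - gc) == 2)
            conflict &= ~duo_conf
            err_count += conflict
            for who in (p1, p2, ch):
                mask[r[who]] |= conflict
            if ch == "offspring":
                sp_err += int(conflict.sum())
        fid_off_errors[sp.uid] = sp_err

    arr2 = calls.to_numpy(dtype=np.int8)
    arr2[mask] = MISSING
    cleaned = pd.DataFrame(arr2, index=calls.index, columns=calls.columns)

    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(duo_count > 0, err_count / np.maximum(duo_count, 1), 0.0)
    drop = rate > snp_error_threshold
    for j in np.flatnonzero(drop):
        rows.append((str(calls.columns[j]), "marker", "mendelian_error_rate", float(rate[j])))
    cleaned = cleaned.drop(columns=calls.columns[drop])

    retained = []
    for sp in subpeds:
        if fid_off_errors[sp.uid] > subped_error_threshold:
            rows.append((sp.uid, "subpedigree", "fid_offspring_errors", float(fid_off_errors[sp.uid])))
        else:
            retained.append(sp)
    rows.append(("total_incompatibilities", "summary", "count", float(err_count.sum())))
    report = pd.DataFrame(rows, columns=["item", "type", "reason", "value"])
    gm = GenotypeMatrix(cleaned, genotypes.markers.loc[list(cleaned.columns)].copy())
    return gm, retained, report


def balance_sexes(
    subpeds: list[SubPedigree],
    n_per_sex: int,
    n_replicates: int,
    seed: int,
) -> list[list[SubPedigree]]:
    """Resample equal numbers of male- and female-FID pairs, with replacement.

    Guards the sex-difference estimates against the overrepresentation of one
    sex's meioses in the pedigree.
    """
    if n_per_sex <= 0:
        raise ValueError("n_per_sex must be positive")
    males = [s for s in subpeds if s.fid_sex == "male"]
    females = [s for s in subpeds if s.fid_sex == "female"]
    if not males or not females:
        raise ValueError("need at least one subpedigree of each FID sex")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_replicates):
        mi = rng.integers(0, len(males), size=n_per_sex)
        fi = rng.integers(0, len(females), size=n_per_sex)
        reps.append([males[i] for i in mi] + [females[i] for i in fi])
    return reps


# ---------------------------------------------------------------------------
# Readers / writers


def read_pedigree_tsv(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype=str)
    need = {"id", "sire", "dam", "sex"}
    if not need <= set(ped.columns):
        raise ValueError(f"pedigree file must have columns {sorted(need)}")
    return ped


def write_pedigree_tsv(pedigree: pd.DataFrame, path: str | Path) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(calls_path: str | Path, markers_path: str | Path) -> GenotypeMatrix:
    calls = pd.read_csv(calls_path, sep="\t", index_col=0)
    calls.index = calls.index.astype(str)
    markers = pd.read_csv(markers_path, sep="\t", index_col=0)
    markers.index = markers.index.astype(str)
    return GenotypeMatrix(calls.astype(np.int8), markers)


def write_genotypes_tsv(gm: GenotypeMatrix, calls_path: str | Path, markers_path: str | Path) -> None:
    gm.calls.to_csv(calls_path, sep="\t")
    gm.markers.to_csv(markers_path, sep="\t")


def write_ped_map(
    gm: GenotypeMatrix,
    pedigree: pd.DataFrame,
    prefix: str | Path,
) -> None:
    """PLINK-style text .ped/.map (alleles coded 1/2, 0 = missing)."""
    prefix = Path(prefix)
    markers = gm.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for m, row in markers.iterrows():
            fh.write(f"{row['chrom']} {m} 0 {int(row['bp'])}\n")
    ped = pedigree.set_index("id")
    sex_code = {"male": "1", "female": "2"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for ind in gm.calls.index:
            sire = str(ped.at[ind, "sire"]) if ind in ped.index else "0"
            dam = str(ped.at[ind, "dam"]) if ind in ped.index else "0"
            sx = sex_code.get(ped.at[ind, "sex"], "0") if ind in ped.index else "0"
            g = gm.calls.loc[ind].to_numpy()
            alleles = []
            for v in g:
                if v == MISSING:
                    alleles.extend(("0", "0"))
                else:
                    alleles.extend(("2" if v >= 1 else "1", "2" if v == 2 else "1"))
            fh.write(" ".join(["1", str(ind), sire, dam, sx, "0"] + alleles) + "\n")


def read_ped_map(prefix: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read PLINK-style text files written by :func:`write_ped_map`."""
    prefix = Path(prefix)
    mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                     names=["chrom", "marker", "cm", "bp"], dtype={"marker": str})
    markers = mp.set_index("marker")[["chrom", "bp"]]
    rows, meta = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            _, ind, sire, dam, sx, _ = parts[:6]
            alle = np.array(parts[6:], dtype="U1").reshape(-1, 2)
            g = np.where((alle == "0").any(axis=1), MISSING, (alle == "2").sum(axis=1))
            rows.append(pd.Series(g.astype(np.int8), name=ind))
            meta.append((ind, sire, dam, {"1": "male", "2": "female"}.get(sx, "unknown")))
    calls = pd.DataFrame(rows)
    calls.columns = markers.index
    pedigree = pd.DataFrame(meta, columns=["id", "sire", "dam", "sex"])
    return GenotypeMatrix(calls, markers), pedigree
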