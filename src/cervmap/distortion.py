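"""Transmission-ratio distortion scan and peri-centromeric history models.

Where the focal individual (FID) is heterozygous and its mate homozygous,
the allele the FID transmitted to the offspring is identified by subtracting
the mate's obligate contribution from the offspring genotype.  Per locus and
FID sex, an exact binomial test against the Mendelian 0.5 gives a p-value
(transformed to -log10 p); loci are binned in 1 Mb of estimated physical
position and, over the 10 Mb closest to the centromere, linear models with a
chromosome-history x bin interaction ask whether distortion tracks
centromere age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pedio import MISSING, GenotypeMatrix, SubPedigree

__all__ = [
    "transmission_counts",
    "binomial_exact_test",
    "distortion_scan",
    "pericentromeric_models",
]


def transmission_counts(
    subpeds: list[SubPedigree],
    genotypes: GenotypeMatrix,
) -> pd.DataFrame:
    """Transmitted-allele counts per marker per FID sex.

    Only FID-heterozygous x mate-homozygous trios are informative.  Returns a
    frame with columns marker, fid_sex, count_a (the counted allele
    transmitted), count_b.
    """
    arr = genotypes.calls.to_numpy(dtype=np.int16)
    idx = {str(i): k for k, i in enumerate(genotypes.calls.index)}
    n_m = arr.shape[1]
    counts = {("male", 1): np.zeros(n_m, dtype=np.int64),
              ("male", 0): np.zeros(n_m, dtype=np.int64),
              ("female", 1): np.zeros(n_m, dtype=np.int64),
              ("female", 0): np.zeros(n_m, dtype=np.int64)}
    for sp in subpeds:
        g = arr[idx[sp.fid]]
        m = arr[idx[sp.mate]]
        o = arr[idx[sp.offspring]]
        informative = (g == 1) & ((m == 0) | (m == 2)) & (o != MISSING)
        t = o - m // 2  # obligate subtraction
        valid = informative & (t >= 0) & (t <= 1)
        counts[(sp.fid_sex, 1)] += valid & (t == 1)
        counts[(sp.fid_sex, 0)] += valid & (t == 0)
    rows = []
    markers = list(genotypes.calls.columns)
    for sex in ("male", "female"):
        for j, mk in enumerate(markers):
            rows.append((mk, sex, int(counts[(sex, 1)][j]), int(counts[(sex, 0)][j])))
    return pd.DataFrame(rows, columns=["marker", "fid_sex", "count_a", "count_b"])


def binomial_exact_test(count_a: int, count_b: int, method: str = "minlike") -> tuple[float, float]:
    """Two-sided exact binomial p at null 0.5, and -log10 p.

    ``minlike`` (default) sums the probabilities of all outcomes no more
    probable than the observed one; ``double`` doubles the smaller tail,
    capped at 1.
    """
    n = count_a + count_b
    if n < 1:
        raise ValueError("need at least one transmission")
    if method == "minlike":
        p = stats.binomtest(count_a, n, 0.5).pvalue
    elif method == "double":
        cdf = stats.binom.cdf(min(count_a, count_b), n, 0.5)
        p = min(1.0, 2.0 * cdf)
    else:
        raise ValueError(f"unknown method: {method}")
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return float(p), float(-np.log10(p))


def distortion_scan(
    subpeds: list[SubPedigree],
    genotypes: GenotypeMatrix,
    positions_bp: pd.Series | None = None,
    bin_size: float = 1e6,
    min_informative: int = 1,
    method: str = "minlike",
) -> pd.DataFrame:
    """Per-locus exact binomial scan; adds -log10 p and the 1 Mb bin index.

    ``positions_bp`` maps marker to estimated physical position (bin index
    floor(bp / bin_size) measured from the group's first marker when a
    ``group`` can be derived from the genotype metadata).
    """
    recs = transmission_counts(subpeds, genotypes)
    recs = recs[(recs.count_a + recs.count_b) >= max(min_informative, 1)].copy()
    pv, lg = [], []
    for a, b in recs[["count_a", "count_b"]].itertuples(index=False):
        p, l10 = binomial_exact_test(a, b, method)
        pv.append(p)
        lg.append(l10)
    recs["p"] = pv
    recs["neglog10p"] = lg
    meta = genotypes.markers
    recs["group"] = recs["marker"].map(meta["chrom"].astype(str))
    if positions_bp is None:
        positions_bp = meta["bp"].astype(float)
    pos_all = pd.Series({m: positions_bp.get(m, np.nan) for m in meta.index})
    start_by_group = pos_all.groupby(meta["chrom"].astype(str).to_numpy()).min()
    pos = recs["marker"].map(pos_all)
    start = recs["group"].map(start_by_group)
    recs["bin"] = ((pos - start) // bin_size).astype("Int64")
    return recs.reset_index(drop=True)


def pericentromeric_models(
    records: pd.DataFrame,
    histories: dict[str, str],
    range_mb: tuple[float, float] = (0.0, 10.0),
    bin_size_mb: float = 1.0,
) -> dict[str, dict]:
    """Per-sex linear models of -log10 p on history x 1 Mb bin near the centromere.

    Acrocentric chromosomes only (metacentric labels excluded); bins are
    categorical.  Returns, per sex, the coefficient table and the interaction
    F-test from a type-II ANOVA.
    """
    import statsmodels.formula.api as smf

    recs = records.copy()
    recs["group"] = recs["group"].astype(str)
    recs["history"] = recs["group"].map(lambda g: histories.get(g, "unchanged"))
    recs = recs[recs["history"] != "metacentric"].dropna(subset=["bin", "neglog10p"])
    lo, hi = range_mb
    recs = recs[(recs["bin"] * bin_size_mb >= lo) & (recs["bin"] * bin_size_mb < hi)]

    out: dict[str, dict] = {}
    for sex, sub in recs.groupby("fid_sex"):
        if sub["history"].nunique() < 2:
            raise ValueError(f"only one history group in range for sex {sex}")
        cells = sub.groupby(["history", "bin"]).size()
        if (cells < 1).any():
            raise ValueError(f"empty history x bin cell: {cells[cells < 1].index.tolist()}")
        d = sub.assign(bin=sub["bin"].astype(int).astype(str))
        model = smf.ols("neglog10p ~ C(history) * C(bin)", data=d).fit()
        # interaction F-test by model comparison against the additive fit
        reduced = smf.ols("neglog10p ~ C(history) + C(bin)", data=d).fit()
        _, inter_p, _ = model.compare_f_test(reduced)
        inter_p = float(inter_p)
        out[sex] = {
            "coefficients": pd.DataFrame({"estimate": model.params, "se": model.bse,
                                          "p": model.pvalues}),
            "interaction_p": inter_p,
            "n": len(d),
        }
    return out
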