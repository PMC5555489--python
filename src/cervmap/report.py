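"""Per-chromosome summary statistics and length regressions.

Summaries follow the layout of the study's per-linkage-group map table:
locus counts, estimated Mb, and sex-averaged / male / female cM per group,
with autosomal and genome totals, the genome-wide cM/Mb rate, and the
female:male map-length ratio.  Simple regressions relate map length to
physical length across chromosomes (adjusted R^2 reported throughout).  The
printed per-group table from the deer study ships as package data so the
summaries are reproducible offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mapbuild import LinkageMap

__all__ = ["GroupSummary", "load_table2", "summarize_map", "summarize_table", "length_regressions"]

X_GROUP = "34"  # the deer X chromosome's linkage-group label in the packaged table


@dataclass
class GroupSummary:
    """Per-group map lengths plus genome/autosome totals and ratios."""

    per_group: pd.DataFrame  # linkage_group, n_loci, est_length_mb, cm_sexavg, cm_male, cm_female
    x_group: str | None = None

    @property
    def autosomes(self) -> pd.DataFrame:
        if self.x_group is None:
            return self.per_group
        return self.per_group[self.per_group["linkage_group"].astype(str) != str(self.x_group)]

    def totals(self) -> dict[str, float]:
        g, a = self.per_group, self.autosomes
        t = {
            "n_loci": float(g["n_loci"].sum()),
            "mb": float(g["est_length_mb"].sum()),
            "cm_sexavg": float(g["cm_sexavg"].sum()),
            "cm_male": float(g["cm_male"].sum()),
            "cm_female": float(g["cm_female"].sum()),
            "autosomal_n_loci": float(a["n_loci"].sum()),
            "autosomal_mb": float(a["est_length_mb"].sum()),
            "autosomal_cm_sexavg": float(a["cm_sexavg"].sum()),
            "autosomal_cm_male": float(a["cm_male"].sum()),
            "autosomal_cm_female": float(a["cm_female"].sum()),
        }
        t["rate_cm_mb"] = t["autosomal_cm_sexavg"] / t["autosomal_mb"] if t["autosomal_mb"] else np.nan
        t["female_male_ratio"] = (
            t["autosomal_cm_female"] / t["autosomal_cm_male"] if t["autosomal_cm_male"] else np.nan
        )
        return t


def load_table2() -> pd.DataFrame:
    """The packaged per-linkage-group table (34 groups + printed totals rows)."""
    with resources.files("cervmap.data").joinpath("table2.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"linkage_group": str})


def summarize_table(table: pd.DataFrame | None = None, x_group: str | None = X_GROUP) -> GroupSummary:
    """GroupSummary from a printed-style table (totals rows are dropped and
    recomputed from the per-group rows)."""
    t = load_table2() if table is None else table
    per = t[~t["linkage_group"].isin(["All", "All autosomal"])].copy()
    per = per.astype({"n_loci": int, "est_length_mb": float, "cm_sexavg": float,
                      "cm_male": float, "cm_female": float})
    return GroupSummary(per.reset_index(drop=True), x_group)


def summarize_map(linkmap: LinkageMap, x_group: str | None = None) -> GroupSummary:
    """GroupSummary computed from a LinkageMap (Mb from the ``mb`` column where
    present, NaN-safe)."""
    rows = []
    for g in linkmap.groups():
        sub = linkmap.group_df(g)
        mb = np.nan
        if sub["mb"].notna().any():
            mb = float((sub["mb"].max() - sub["mb"].min()) / 1e6)
        rows.append((str(g), len(sub), mb,
                     float(sub["cm"].iloc[-1] - sub["cm"].iloc[0]),
                     float(sub["cm_male"].iloc[-1] - sub["cm_male"].iloc[0]),
                     float(sub["cm_female"].iloc[-1] - sub["cm_female"].iloc[0])))
    per = pd.DataFrame(rows, columns=["linkage_group", "n_loci", "est_length_mb",
                                      "cm_sexavg", "cm_male", "cm_female"])
    return GroupSummary(per, x_group)


def _adj_r2(y: pd.Series, x: pd.Series) -> float:
    fit = sm.OLS(np.asarray(y, dtype=float), sm.add_constant(np.asarray(x, dtype=float))).fit()
    return float(fit.rsquared_adj)


def length_regressions(summary: GroupSummary, include_x: bool = True) -> dict[str, float]:
    """Adjusted R^2 of the cross-chromosome length regressions.

    female~male is always fitted on autosomes (the male X map covers only the
    pseudoautosomal region); male cM ~ Mb likewise excludes the X, while the
    sex-averaged, rate, and female fits use all groups unless
    ``include_x=False``.
    """
    g = summary.per_group if include_x else summary.autosomes
    a = summary.autosomes
    if len(g) < 3 or len(a) < 3:
        raise ValueError("need at least 3 groups per regression")
    rate = g["cm_sexavg"] / g["est_length_mb"]
    return {
        "sexavg_cm_on_mb": _adj_r2(g["cm_sexavg"], g["est_length_mb"]),
        "rate_on_mb": _adj_r2(rate, g["est_length_mb"]),
        "female_on_male_autosomes": _adj_r2(a["cm_female"], a["cm_male"]),
        "male_cm_on_mb": _adj_r2(a["cm_male"], a["est_length_mb"]),
        "female_cm_on_mb": _adj_r2(g["cm_female"], g["est_length_mb"]),
    }
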