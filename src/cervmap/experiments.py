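"""End-to-end validation experiments at the package's study-condition defaults.

Each function simulates data with the generator's study-design settings
(sex-specific landscapes with a 1.21 female:male genome ratio and a 4x female
peri-centromeric multiplier, balanced male/female gamete counts, injectable
order errors), runs the relevant part of the analysis, and returns the
measured quantity.  They are deliberately small enough to run on a laptop in
minutes; the methods note records the problem sizes chosen.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import distortion, landscape, mapbuild, pedio, phasing, report, simdata

__all__ = [
    "table_targets",
    "crossover_detection_oracle",
    "binomial_enumeration_gap",
    "window_mass_error",
    "ratio_recovery",
    "build_error_recovery",
    "gam_history_ordering",
    "male_null_separation",
    "distortion_power",
    "distortion_null_ks",
]


def table_targets() -> dict[str, float]:
    """Printed-table statistics: totals, rates, ratio, and length regressions."""
    s = report.summarize_table()
    t = s.totals()
    r = report.length_regressions(s)
    return {
        "autosomal_cm_sexavg": t["autosomal_cm_sexavg"],
        "n_loci": t["n_loci"],
        "rate_cm_mb": t["rate_cm_mb"],
        "female_male_ratio": t["female_male_ratio"],
        "adjr2_female_on_male": r["female_on_male_autosomes"],
        "adjr2_sexavg_on_mb": r["sexavg_cm_on_mb"],
        "adjr2_rate_on_mb": r["rate_on_mb"],
    }


def crossover_detection_oracle(seed: int, n_meioses: int = 1000) -> dict[str, float]:
    """Detected crossovers vs. the truth ledger on fully informative gametes.

    One 100 cM chromosome; every event must be recovered interval-for-interval
    (observable events are origin changes over the marker span).
    """
    tm = simdata.simulate_true_map(1, 100, 100.0, female_ratio=1.0,
                                   pericentromeric_multiplier=1.0, seed=seed)
    g = tm.groups["G1"]
    rng = np.random.default_rng(seed + 1)
    n_events = n_match = 0
    from .simdata import _crossover_positions

    for k in range(n_meioses):
        cm_pos = _crossover_positions(rng, 100.0, "none", 5.0)
        bp_pos = g.bp_at_cm(cm_pos, "male")
        start = int(rng.integers(0, 2))
        seg = (start + np.searchsorted(bp_pos, g.bp, side="right")) % 2
        origins = np.where(seg == 0, 1, -1).astype(np.int8)
        pg = phasing.PhasedGamete(f"g{k}", "G1", "male", origins)
        detected = [(e.left_index, e.right_index) for e in phasing.detect_crossovers(pg)]
        flips = np.flatnonzero(seg[1:] != seg[:-1])
        expected = [(int(i), int(i) + 1) for i in flips]
        n_events += len(expected)
        n_match += len(expected) if detected == expected else 0
    return {"agreement": n_match / max(n_events, 1), "n_events": n_events}


def binomial_enumeration_gap(max_n: int = 12) -> float:
    """Largest |implementation - enumeration| over every split with n <= max_n."""
    worst = 0.0
    for n in range(1, max_n + 1):
        probs = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
        for a in range(n + 1):
            ref = sum(p for p in probs if p <= probs[a] * (1 + 1e-12))
            p, _ = distortion.binomial_exact_test(a, n - a)
            worst = max(worst, abs(p - ref))
    return worst


def window_mass_error(seed: int, n_intervals: int = 400) -> float:
    """Conservation of recombination mass through the 1 Mb window prorating."""
    rng = np.random.default_rng(seed)
    left = np.cumsum(rng.uniform(0.05, 2.5, n_intervals)) * 1e6
    width = rng.uniform(0.05, 3.0, n_intervals) * 1e6
    iv = pd.DataFrame({"left_bp": left, "right_bp": left + width,
                       "r": rng.uniform(0, 0.05, n_intervals)})
    w = landscape.window_rates(iv)
    return float(abs(w["prob"].sum() - iv["r"].sum()))


def ratio_recovery(seed: int, n_fids_per_sex: int = 242, offspring_per_fid: int = 3,
                   n_groups: int = 8, markers_per_group: int = 1000,
                   chrom_mb: float = 120.0) -> dict[str, float]:
    """Recover the 1.21 female:male genome map-length ratio end to end.

    Simulates genotypes under the study landscape (4x female peri-centromeric
    multiplier over the first 20% of each acrocentric group), phases every
    subpedigree, and estimates sex-specific maps on the true order.
    """
    tm = simdata.simulate_true_map(n_groups, markers_per_group, chrom_mb,
                                   female_ratio=1.21, pericentromeric_multiplier=4.0,
                                   pericentromeric_fraction=0.2, seed=seed)
    ped = simdata.simulate_pedigree(n_fids_per_sex, n_fids_per_sex, offspring_per_fid,
                                    seed=seed + 1)
    gm, _ = simdata.simulate_gametes_and_genotypes(ped, tm, seed=seed + 2)
    subs = pedio.build_subpedigrees(ped, set(gm.calls.index))
    gs = mapbuild.phase_all(subs, gm)
    orders = {g: [gs.col[m] for m in tm.groups[g].markers] for g in tm.groups}
    lm = mapbuild.build_linkage_map(gs, orders)
    return {
        "ratio": lm.total_length("female") / lm.total_length("male"),
        "n_gametes": len(subs),
        "true_ratio": tm.total_length("female") / tm.total_length("male"),
    }


def _one_build_recovery(seed: int) -> tuple[bool, bool]:
    tm = simdata.simulate_true_map(2, 300, 80.0, female_ratio=1.21,
                                   pericentromeric_multiplier=4.0, seed=seed)
    ped = simdata.simulate_pedigree(80, 80, 3, seed=seed + 1)
    gm, _ = simdata.simulate_gametes_and_genotypes(ped, tm, interference="gamma",
                                                   founder_pool=8, seed=seed + 2)
    true_order = tm.order()
    prior, _ = simdata.inject_rearrangements(true_order, [
        simdata.Rearrangement("inversion", "G1", 100, 25),
        simdata.Rearrangement("chunk_displacement", "G1", 200, 30,
                              dest_group="G2", dest_index=150)], seed=seed + 3)
    meta = simdata.prior_metadata_from_order(prior)
    gm2 = pedio.GenotypeMatrix(gm.calls[list(meta.index)], meta)
    lm, _ = mapbuild.run_build_pipeline(gm2, ped, mapbuild.BuildConfig(seed=1))
    fin1 = list(lm.group_df("G1")["marker"])
    chunk_ok = bool(np.mean([m in fin1 for m in true_order["G1"][200:230]]) >= 0.8)
    pos = [fin1.index(m) for m in true_order["G1"][100:125] if m in fin1]
    inv_ok = bool(len(pos) >= 20 and np.mean(np.diff(pos) > 0) >= 0.9)
    return inv_ok, chunk_ok


def build_error_recovery(seed: int, n_replicates: int = 20) -> dict[str, float]:
    """Planted 25-marker inversion and 30-marker displaced chunk per replicate;
    fraction of replicates in which the build pipeline recovers each."""
    inv = chunk = 0
    for rep in range(n_replicates):
        i, c = _one_build_recovery(seed + 37 * rep)
        inv += i
        chunk += c
    return {"inversion_rate": inv / n_replicates, "chunk_rate": chunk / n_replicates,
            "n_replicates": n_replicates}


def _history_windows(seed: int, new_mult: float = 4.0, other_mult: float = 2.0,
                     female_ratio: float = 1.21, n_per_sex: int = 400):
    hist = ["new_centromere"] * 4 + ["retained_centromere"] * 4 + ["unchanged"] * 4
    tm = simdata.simulate_true_map(
        12, 240, 60.0, female_ratio=female_ratio,
        pericentromeric_multiplier={"new_centromere": new_mult,
                                    "retained_centromere": other_mult,
                                    "unchanged": other_mult},
        histories=hist, seed=seed)
    gam = simdata.simulate_true_gametes(tm, n_per_sex, n_per_sex, seed=seed + 1)
    rows = []
    for gname, g in tm.groups.items():
        O, sx = gam[gname]
        for sex in ("male", "female"):
            numer, denom = mapbuild.recfrac_counts(O[sx == sex])
            iv = pd.DataFrame({"left_bp": g.bp[:-1], "right_bp": g.bp[1:],
                               "r": numer / np.maximum(denom, 1)})
            w = landscape.window_rates(iv)
            w["group"], w["sex"] = gname, sex
            rows.append(w)
    wins = landscape.add_adjusted_rates(pd.concat(rows, ignore_index=True))
    wins = landscape.filter_extreme_windows(wins, 0.01)
    return wins, {f"G{i+1}": h for i, h in enumerate(hist)}


def gam_history_ordering(seed: int, n_replicates: int = 20) -> dict[str, float]:
    """Fraction of replicates in which the female history GAM puts the
    new-centromere group above both other groups over 0-5 Mb."""
    ok = 0
    for rep in range(n_replicates):
        wins, hmap = _history_windows(seed + 53 * rep)
        fits = landscape.fit_history_gam(wins, hmap, sex="female")
        near = {h: df[df.x <= 5]["fit"].mean() for h, df in fits.items()}
        ok += (near["new_centromere"] > near["retained_centromere"]
               and near["new_centromere"] > near["unchanged"])
    return {"ordering_rate": ok / n_replicates, "n_replicates": n_replicates}


def male_null_separation(seed: int) -> float:
    """Fraction of grid points where male history curves separate beyond
    2 x (summed SE) — males have no history effect, so this should be small."""
    wins, hmap = _history_windows(seed)
    fits = landscape.fit_history_gam(wins, hmap, sex="male")
    labels = list(fits)
    worst = 0.0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = fits[labels[i]], fits[labels[j]]
            sep = np.abs(a["fit"] - b["fit"]) > 2 * (a["se"] + b["se"])
            worst = max(worst, float(sep.mean()))
    return worst


def distortion_power(seed: int, prob: float = 0.7, min_informative: int = 500) -> dict[str, float]:
    """Exact binomial detection of one planted transmission-distortion locus."""
    tm = simdata.simulate_true_map(1, 30, 40.0, seed=seed)
    locus = tm.groups["G1"].markers[15]
    ped = simdata.simulate_pedigree(5, 1100, 2, seed=seed + 1)
    gm, _ = simdata.simulate_gametes_and_genotypes(
        ped, tm, distortion_loci=[simdata.DistortionLocus(locus, prob, sex="female")],
        seed=seed + 2)
    subs = pedio.build_subpedigrees(ped, set(gm.calls.index))
    rec = distortion.transmission_counts(subs, gm)
    row = rec[(rec.marker == locus) & (rec.fid_sex == "female")].iloc[0]
    n = int(row.count_a + row.count_b)
    p, neglog = distortion.binomial_exact_test(int(row.count_a), int(row.count_b))
    return {"p": p, "neglog10p": neglog, "n_informative": n,
            "proportion": row.count_a / n}


def distortion_null_ks(seed: int) -> dict[str, float]:
    """KS distance between null-scan p-values and the exact discrete null CDF."""
    from scipy import stats

    tm = simdata.simulate_true_map(8, 250, 60.0, seed=seed)
    ped = simdata.simulate_pedigree(40, 100, 3, seed=seed + 1)
    gm, _ = simdata.simulate_gametes_and_genotypes(ped, tm, seed=seed + 2)
    subs = pedio.build_subpedigrees(ped, set(gm.calls.index))
    rec = distortion.distortion_scan(subs, gm, min_informative=10)
    rec = rec[rec.fid_sex == "female"]
    ns = (rec.count_a + rec.count_b).to_numpy()
    pvals = np.sort(rec.p.to_numpy())
    grid = np.unique(pvals)
    exp_cdf = np.zeros(len(grid))
    for n in np.unique(ns):
        k = np.arange(n + 1)
        pk = np.array([stats.binomtest(int(a), int(n), 0.5).pvalue for a in k])
        w = stats.binom.pmf(k, n, 0.5)
        exp_cdf += (ns == n).sum() * np.array([(w[pk <= x + 1e-12]).sum() for x in grid])
    exp_cdf /= len(ns)
    emp_cdf = np.searchsorted(pvals, grid, side="right") / len(pvals)
    return {"ks": float(np.max(np.abs(emp_cdf - exp_cdf))), "n_loci": int(len(pvals))}
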