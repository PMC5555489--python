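"""Per-chromosome summaries and length regressions from the packaged table.

Loads the published per-linkage-group map table shipped with the package
(34 deer linkage groups), recomputes the genome and autosome totals, the
genome-wide recombination rate, the female:male map-length ratio, and the
cross-chromosome length regressions (adjusted R^2).
"""

from cervmap import report

summary = report.summarize_table()
t = summary.totals()
print(f"34 linkage groups, {t['n_loci']:.0f} mapped loci "
      f"({t['autosomal_n_loci']:.0f} autosomal)")
print(f"autosomal map: {t['autosomal_cm_sexavg']:.1f} cM sex-averaged over "
      f"{t['autosomal_mb']:.1f} Mb -> {t['rate_cm_mb']:.2f} cM/Mb")
print(f"female {t['autosomal_cm_female']:.1f} cM vs male "
      f"{t['autosomal_cm_male']:.1f} cM -> ratio {t['female_male_ratio']:.2f}")

r = report.length_regressions(summary)
print("\nadjusted R^2 of the length regressions:")
print(f"  sex-averaged cM ~ Mb (34 groups):   {r['sexavg_cm_on_mb']:.3f}")
print(f"  rate (cM/Mb) ~ Mb (34 groups):      {r['rate_on_mb']:.3f}")
print(f"  female cM ~ male cM (33 autosomes): {r['female_on_male_autosomes']:.3f}")
print(f"  male cM ~ Mb (33 autosomes):        {r['male_cm_on_mb']:.3f}")
print(f"  female cM ~ Mb (34 groups):         {r['female_cm_on_mb']:.3f}")
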