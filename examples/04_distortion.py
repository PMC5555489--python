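"""Transmission-distortion scan with one planted driving locus.

One locus transmits its reference allele with probability 0.7 from
heterozygous mothers instead of the Mendelian 0.5.  The scan counts
transmissions in FID-heterozygous x mate-homozygous trios, tests each locus
with a two-sided exact binomial test, and prints the top hits as -log10 p.
"""

from cervmap import distortion, pedio, simdata

truemap = simdata.simulate_true_map(2, 40, 50.0, seed=11)
driver = truemap.groups["G1"].markers[20]
pedigree = simdata.simulate_pedigree(5, 400, 2, seed=12)
genotypes, _ = simdata.simulate_gametes_and_genotypes(
    pedigree, truemap,
    distortion_loci=[simdata.DistortionLocus(driver, prob=0.7, sex="female")],
    seed=13)

subpeds = pedio.build_subpedigrees(pedigree, set(genotypes.calls.index))
records = distortion.distortion_scan(subpeds, genotypes, min_informative=20)

top = records.nlargest(5, "neglog10p")
print(f"scan over {len(records)} locus x sex records; planted driver: {driver}")
print("\ntop hits:")
for r in top.itertuples():
    flag = "  <- planted" if r.marker == driver else ""
    print(f"  {r.marker} ({r.fid_sex}): {r.count_a}:{r.count_b} transmissions, "
          f"-log10 p = {r.neglog10p:.2f}{flag}")
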