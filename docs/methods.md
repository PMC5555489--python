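# Methods

## Model and assumptions

The package analyses meioses observed through a pedigree. The unit of
observation is one transmitted gamete per focal-individual (FID) → offspring
link, phased within a five-member subpedigree (FID, FID's sire and dam, the
offspring, the offspring's other parent). All five members must be genotyped;
an FID with k such offspring contributes k gametes. Phase is deduced purely
from pedigree logic — no population-scale statistical phasing — so a call is
made only when (i) the FID is heterozygous, (ii) the transmitted allele is
identified (mate homozygous, or offspring homozygous), and (iii) exactly one
assignment of the FID's two alleles to its parents is consistent with their
genotypes. Ambiguity yields "uninformative", never imputation. Under the
default generator settings this leaves roughly a quarter of calls
phase-informative, which is what drives most of the design choices below.

Chromosomes are treated as acrocentric with the centromere at bp 0 (the
metacentric group is excluded from centromere-history analyses). The X is
handled only to the extent that male FID gametes are phased within the
pseudoautosomal region; there is no dosage model beyond "males hemizygous
outside the PAR".

## Recombination-fraction estimator

For each adjacent marker pair, r̂ = recombinant / informative gametes. A
gamete is informative for every interval spanned by a pair of consecutive
phase-informative calls (its nearest informative flanks); a flank origin flip
is one recombination event whose unit mass is apportioned over the spanned
intervals. The apportionment starts even (1/gap) and is iterated three times
proportionally to the current r̂ values. Rationale, in order of failure of
the alternatives:

- counting the full event in *every* spanned interval inflates map totals by
  the mean gap length (≈ 6× at 25% informativeness);
- counting only doubly-informative adjacent pairs is unbiased but so noisy
  (n ≈ 25 per interval at realistic scale) that per-interval distances blow
  up through the convex mapping function;
- fractional apportionment conserves total event mass exactly, so group
  lengths converge to detected events per gamete (Poisson-limited precision),
  and the proportional iteration re-concentrates mass onto genuinely long
  intervals instead of smearing sharp gaps — which chunk segmentation and the
  inversion tests depend on.

Remaining known biases: crossovers outside a gamete's first/last informative
call are invisible (map ends are truncated by about one informative-flank
spacing per end), double crossovers inside one uninformative gap cancel, and
r̂/denominator ratios are slightly inflated near chromosome ends where few
gametes span (Jensen effect). All three shrink with marker density; at the
~0.1 Mb spacing used in the validation experiments, sex-specific totals are
recovered within 2–3%.

Distances use Kosambi by default (Haldane selectable); the function name is
carried in the API, and inverse functions round-trip to < 1e-12 over
r ∈ [0, 0.49].

## Order refinement

Build 1 maps the prior (reference-synteny) order after Mendelian cleaning
(incompatible calls masked on every implicated side; SNPs with error rate
> 0.01 per informative duo dropped; subpedigrees with > 50 FID–offspring
errors dropped). Build 2 segments each group into chunks at ≥ 3 cM gaps and
drops chunks of < 20 SNPs. Build 3 assigns chunks to linkage groups by
inter-chunk LD — composite r², the squared pairwise-complete correlation of
genotype codes — scored as the 0.95 quantile of the chunk-to-group r²
distribution (LD decays with distance, so a whole-chromosome median carries
no signal); a chunk holding more than half its group is treated as backbone
and never reassigned (otherwise a small displaced chunk can drag the backbone
toward itself). Fissions are declared at chunk boundaries with inter-chunk
LD below floor and either a ≥ 50 cM gap or a direct pairwise recombination
fraction ≥ 0.45 across the boundary (independent segregation).

Build 4 accepts local changes that shorten the re-estimated group map by
≥ 1 cM (inclusive). Inversion candidates come from a vectorized junction
scan — inverting [s, e) only swaps the two junction distances, so the
predicted shortening d(s−1,s) + d(e−1,e) − d(s−1,e−1) − d(s,e) is computed
for every span ≤ 50 markers from block-averaged pairwise distances, with
non-maximum suppression so one noisy junction cannot flood the candidate
list; every candidate is verified against the actual map-length rule.
Deletions (< 10 SNP chunks) are tested for interior chunks only: removing a
terminal chunk discards its flanking gap by construction, and the rule would
otherwise eat genuine chromosome ends.

Build 5 places dropped markers back: most-likely group by LD, then adjusted-R²
phase correlation (± half of a 120-SNP window). Origins coded ±1,
uninformative excluded pairwise, adjusted R² = 1 − (1−R²)(n−1)/(n−2);
positions sharing < 10 informative gametes, or with a constant vector over
the shared gametes, are undefined. A unique maximizer ≥ 0.9 places the marker
exactly; when the ≥ 0.9 range spans a zero-recombination run (phase cannot
resolve within it) the marker is inserted at the LD-argmax position inside
the range and logged separately. Phases are then cleaned — singleton origin
runs recoded uninformative, then interior double crossovers whose flanking
markers are ≤ 10 cM apart (inclusive), iterated to a fixed point — and
sex-specific maps estimated (the sex-averaged map from pooled gametes, not
the mean of the sex maps). On error-free simulations the singleton rule's
main cost is terminal singletons (real crossovers near chromosome ends with
one informative call outside), worth a few percent of map length at sparse
informativeness.

Build 6 reduces each group to a skeleton (one most phase-informative marker
per zero-cM run, ties to the lower index) and tests all permutations of 2–5
adjacent markers in 100-SNP windows overlapping by 50. Permutations are
scored by the summed per-pair binomial log₁₀ likelihood at the ML
recombination fraction, with each pair normalized to the window's mean
informative count — without that normalization the likelihood scales with
pair-specific n and rewards adjacency of poorly genotyped pairs. Flags
require an improvement strictly greater than 2; flagged permutations are
logged, not applied.

## Landscape and distortion analyses

Estimated physical positions accumulate |Δ reference bp| between sequential
markers, with 1 cM ≡ 1 Mb across rearrangement boundaries and the group
origin at the mean first mapped bp of the contributing reference chromosomes.
Crossover probability per 1 Mb window is the overlap-prorated sum of interval
r̂ (mass conserved to machine precision); window rates are adjusted by the
chromosome-wide cM/Mb of the same sex (so adjusted rates average ≈ 1 within
a chromosome), and the genome-wide top percentile of adjusted rates is
removed (ceil(p·N) windows, ties resolved against the later index) as likely
misassembly. The same normalization serves both the percentile filter and the
history models, deliberately. Smoothing is tricube local-linear (loess) on
relative chromosome position (span 0.15 pooled, 0.2 per chromosome).

Centromere-history contrasts fit penalized cubic B-spline regressions (basis
dimension 10, fixed smoothing weight α = 1) of adjusted female rate on Mb
from the centromere over 0–40 Mb, one fit per history group, with pointwise
SE bands from the coefficient covariance; leave-one- and leave-two-chromosome
refits are provided. Exact numerical parity with any particular GAM engine is
not a goal — the target is the qualitative group ordering, which the planted
4×-vs-2× multiplier experiments recover in 20/20 replicates.

The distortion scan uses the minimum-likelihood two-sided exact binomial
convention (doubling available by flag) with no multiple-testing correction
at the per-locus stage; inference rests on the per-sex linear models of
−log₁₀ p on history × 1 Mb bin (interaction tested by a full-vs-additive
F-test) over the 10 Mb nearest the centromere. No minimum informative-count
filter is applied by default (configurable).

## Synthetic-data generator

The generator emulates the study design: FID-centred subpedigrees with
dedicated founder mates (so every link is phase-complete), balanced or
configurable male/female FID counts, founder allele frequencies uniform on
[0.05, 0.5], and per-sex crossover landscapes. Female intensity is
piecewise-constant: multiplier m within the peri-centromeric fraction
(default 4× over the first 20%), 1 elsewhere, globally rescaled so the total
female:male map ratio equals the requested value (default 1.21) exactly; the
piecewise-constant shape is a stand-in for the unknown generative biology and
is configurable. Crossovers follow an inhomogeneous Poisson process on the
per-sex cM scale by default; a thinned gamma-renewal mode (shape ν, default 5,
a mammalian-typical interference strength) is used wherever cleaned maps are
compared with truth, since the double-crossover cleaning assumes
interference. Genotyping error is symmetric reassignment to one of the other
two classes; missingness is independent per call. Founders are drawn in
linkage equilibrium by default; a founder-pool mode (mosaics of a small
haplotype pool, exponential segment lengths, default mean 20 Mb) creates the
distance-decaying LD the group-assembly and placement steps require.
Transmission distortion overrides the transmitted allele at the designated
locus in an otherwise faithful haplotype transmission — the per-locus
transmission probability is reproduced exactly while the crossover process is
untouched (the single-site override is invisible to the distortion analyses,
which never phase that locus). Every meiosis is recorded in the truth ledger
(breakpoints in bp, grandparental-origin vectors), untouched by error or
missingness. All draws take explicit seeds; outputs are bit-identical across
runs.

What the generator does not emulate: genotype-intensity artefacts and
batch/cluster-calling error structure, pedigree errors, population structure
and realistic LD decay shapes, X dosage, mutation, or gene conversion.
Passing the validation experiments therefore shows the pipeline's logic and
estimators are correct under the stated stochastic model, not that real-data
QC issues are handled.

## Problem sizes in the validation experiments

Chosen as scaled-down but informative versions of the study design: ratio
recovery uses 8 groups × 1000 markers × 120 Mb and 242 FIDs per sex × 3
offspring (1452 gametes; the study's balanced resamples used 966);
planted-error recovery uses 2 groups × 300 markers × 80 Mb, 480 gametes,
20 replicates; the history GAM uses 12 groups (4 per history) × 240 markers
× 60 Mb, 800 gametes, 20 replicates; the null distortion scan uses 2000 loci.
Marker density matters: the estimator's end-truncation and gap-cancellation
losses shrink roughly linearly with informative-flank spacing, so map-length
recovery is validated at ~0.05–0.12 Mb spacing, close to the real chip's
0.07 Mb.

## Known limitations

- The adjusted-R² rate~Mb regression on the packaged table computes ≈ 0.50;
  see the package tests for the exact value asserted.
- Map ends are truncated by about one informative-flank spacing per gamete;
  totals are 2–3% conservative at chip-like density and more so on sparse
  panels.
- Build 3's automated LD criterion formalizes what was originally a visual
  inspection step; its audit entries are marked accordingly.
- The flips likelihood is a pairwise surrogate for a full multipoint
  likelihood; it is exact for fully informative gametes and conservative
  otherwise.
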