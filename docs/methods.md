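# Methods

This note records the models behind each module, the defaults that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices a maintainer would otherwise have to reverse-
engineer.

## Data model

Genotypes are biallelic SNP dosages per diploid sample (ALT scale
internally; derived scale on demand from a per-site ancestral-state code,
as delivered by outgroup-polarized annotation in real data). Sites with
unknown ancestral state stay in the table and drop out of polarized
statistics only. Interval tracks are 0-based half-open; site positions
are 1-based (VCF). Genetic maps are piecewise-linear and clamped outside
the mapped range, so genetic lengths never extrapolate. Missing genotypes
are excluded per statistic and per site, not per row — with one genome
per population, row-wise deletion would be ruinous.

## Hudson F_ST and the autozygosity correction

The estimator is the ratio-of-sums Hudson form (sum numerators and
denominators over sites, then divide), which is robust at n = 2 and is
not clamped at zero — uncertainty is carried by the weighted block
jackknife (5 cM blocks; Busing-style pseudovalues weighted by block
denominator mass). Sites used: complete data in all used samples,
variable in the union of the two samples.

For a diploid with autozygous genome fraction f, its two alleles at a
site are correlated draws: `Var(p̂) = p(1−p)(1+f)/2` while
`E[p̂(1−p̂)] = p(1−p)(1−f)/2`. The within-population correction term
removes the sampling variance exactly only if its divisor is
`(1−f)/(1+f)`, i.e. the individual contributes `n_eff = 2/(1+f)`
effective observations (the design effect `n/(1+(n−1)ρ)`). A simpler
`n_eff = 2−f` removes only half the bias (residual ≈ f/2 in F_ST units —
at f = 0.2 an error of 0.1, far larger than the jackknife CI), which is
why the design-effect form is used. Frequencies themselves are never
changed; only the n−1 divisors are.

Which f? The correction wants the excess probability that the two
alleles are identical by descent *relative to the population the allele
frequency refers to*. Detected HBD mass in tracts ≥ 2.5 cM measures
recent-kin autozygosity and excludes both the short-tract background any
panmictic genome shows and deep segments whose coalescence is part of
ordinary population variance; empirically (band-model simulations below)
it matches the generative IBD probability closely, while counting all
decoded tracts over-corrects. The reported f (≥ 2.5 cM) is therefore
also the f used for correction.

## Heterozygosity and HBD detection

Heterozygosity is het genotypes per callable base inside the mask,
reported per 10,000 bp, optionally after subtracting HBD tracts from
numerator and denominator.

HBD detection is a two-state HMM over counts of heterozygous sites in
non-overlapping windows of fixed genetic length (0.05 cM — genetic,
not physical, units, because HBD is delimited by recombination and bp
windows distort lengths in recombination deserts). Emissions are Poisson
with mean proportional to callable bases in the window: rate θ_out
outside tracts, ε·θ_out inside (ε = 0.1, covering genotyping error,
back-mutation and recent mutation). Transitions use mean tract length
5 cM and mean gap 50 cM; decoding is by posterior ≥ 0.9; tracts < 2.5 cM
are kept in the raw output but excluded from summaries (classes
[2.5,10) and ≥ 10 cM).

θ_out is initialized from the **top decile** of per-window het rates and
refined by a 3-iteration EM re-weighting (windows weighted by their
posterior probability of being outside). The genome-wide mean would be
badly biased downward in strongly autozygous genomes; the top-decile
start keeps the decoder anchored even at f ≈ 0.9. A genome with no
heterozygous sites at all decodes as one tract per chromosome. A genome
that is *entirely* autozygous with no non-HBD sequence anywhere has no
internal calibration for θ_out and cannot be decoded reliably — at the
package's default test scale (30 chromosomes × 10 Mb) such genomes do
not arise.

## D-statistics, F(A|B), tract assignment

D(ind1, ind2; ind3, outgroup) uses frequency weights on diploid derived
frequencies p ∈ {0, ½, 1}: the ind1–ind3 sharing weight per site is
`p1(1−p2)p3(1−p4)` and the ind2–ind3 weight `(1−p1)p2p3(1−p4)`; D is
their normalized difference, so **positive D means ind3 shares more
derived alleles with ind1**. Z comes from the same weighted block
jackknife; |Z| ≥ 3 is flagged. A random-single-allele mode (seeded) is
available; the frequency mode is the default because it is deterministic
and lower-variance. F(A|B) counts the fraction of conditioning sites
(derived in all/any of B, optionally derived in none of an exclusion
set) where A carries ≥ 1 derived allele. Tract assignment counts, per
introgressed tract, the derived variants of the modern carrier that each
archaic reference genome shares; argmax assigns, ties are "unassigned",
tracts without informative variants "uninformative".

## Branch-shortening dating

Derived *transversions* only (immune to residual cytosine deamination),
counted dosage-aware (summed derived dosage / 2) on the intersection of
callable sites of both genomes, so missingness cannot mimic branch
shortening. Rate mode divides the deficit by μ_tv·L; calibration mode
scales a configured per-lineage calibration time by (1 − C_a/C_m). Both
constants are configuration, never hard-coded. The 2-SD interval treats
the two counts as independent Poisson; this ignores the shared
coalescent variance of the two lineages, which is acceptable at the
multi-Mb scales used here (empirical replicate scatter matches the
nominal SD within ~20% in the recovery benchmarks). Negative point
estimates are reported as 0 with the raw value retained.

## Introgression

**Calling.** Informative sites are donor-diagnostic: the donor panel
carries an allele entirely absent from the background panel. The hidden
state is the number of introgressed haplotypes c ∈ {0,1,2}; each copy
follows an independent two-state chain with stationary introgressed
probability 0.05 and switch probability `1 − exp(−λ·Δ/100)` over Δ cM,
λ = 1,000 (a prior admixture age in generations; optionally re-estimated
by one EM round via expected copy-switch counts). Emissions: each
introgressed copy carries the diagnostic allele with probability
1 − η (η = 0.15), each background copy with probability δ = 0.10. These
are calibrated for *single-genome* panels: with one background diploid,
diagnostic alleles leak into the background population at ~10%
frequency, and an introgressed haplotype misses a "donor" allele
whenever the donor genotype is heterozygous. Segments are maximal runs
with P(c ≥ 1) ≥ 0.8 (or P(c = 2) for homozygous calls), bounded at
midpoints between informative sites, reported at ≥ 0.2 cM.

**Overlap.** Total overlap (cM) between two genomes' segment sets,
against a null that re-places each segment uniformly within its
chromosome's callable genetic span (lengths preserved, within-set
overlap rejected); p = (1 + #{null ≥ obs})/(B + 1).

**Dating.** Above a conservative cutoff c Morgans, single-pulse segment
lengths are memoryless with mean c + 1/t, so t̂ = 1/(mean − c);
bootstrap CI over segments. Two caveats are deliberate: (i) unphased
diploid segments are the union of two haplotypes, and (ii) in small
recipient populations recombination boundaries are healed by drift
(a split-off lineage re-coalesces with its partner with probability
≈ t/2N before the pulse), fattening the tail and biasing t̂ downward by
roughly t/2N. The estimator is therefore benchmarked under its stated
assumption t ≪ 2N; applied to genomes from small populations its dates
are conservative (too recent), which is also why cutoff and map choice
are exposed as configuration rather than fixed.

**TMRCA classification.** For homozygous segments, per-bp divergence d
to the donor genome over the segment's callable length (expected
haplotype mismatch from the two dosages; invariant positions count as
matches through the callable denominator) gives TMRCA = d/(2μ) in years.
A segment is "introgressed" when the upper 95% (Poisson) bound of its
TMRCA is younger than the configured population split time — ILS
segments cannot coalesce more recently than the split, so this
direction of the test is conservative against false introgression
calls. Segments under 50 kb callable are "uninformative".

## Metapopulation fit

Composite likelihood on binned HBD genome-mass proportions
({non-HBD, [2.5,5), [5,10), [10,20), ≥ 20 cM}) rather than tract-level
likelihood: robust to boundary noise, and matched to what the detector
measures. Expectations per grid point come from R simulated diploids
run through **the same detector** as the observed genome — this
ascertainment symmetry is the module's central correctness rule, and it
means detector biases cancel between observed and expected. Proportions
become effective counts at one count per 5 cM of callable genome
(about one per independent linkage block); Laplace smoothing 1e-4 keeps
log-likelihoods finite. N and m are partially confounded, so the
recovery benchmark fixes m at its known value, matching the
conditional form of any group-size claim; the headline output is the
N ≤ 50 indicator at the MLE.

## Synthetic-data generator

Chromosomes are simulated independently (msprime, human-like
r = 1e-8, μ = 1.25e-8 per bp per generation; binary mutation model with
random nucleotide assignment, so 2/3 of sites are transversions;
generation time 29 y for year conversions). Ground truth:

* **HBD tracts** — intervals where the individual's two lineages
  coalesce < 1,000 generations ago (tracts ≥ 2.5 cM essentially always
  coalesce far more recently, so the threshold choice is uncritical);
* **introgressed segments** — per-haplotype ancestry through a census
  recorded just above the admixture pulse (any-copy, both-copy and
  per-haplotype tracks);
* sampling ages, pulse parameters, and cohort allele-frequency F_ST.

Scenario builders encode the study designs: a panmictic control;
sustained island metapopulations (demes of size N, total emigration m
split evenly, founded from an ancestral population — the spec'd
inbred-genome conditions N = 25, d = 10, m = 1e-3 make genomes ~90%
autozygous); two diverged populations whose sampled individuals each
live in a small "band" attached to the population trunk by one-way
lineage escape (band size 10, escape rate 0.065, founded 100 generations
ago — chosen via the closed form f ≈ 1/(1+4Nm) so that reported f_hbd
lands in the 0.2–0.25 range of the most inbred archaic genomes, with
autozygosity concentrated in long, close-kin-like tracts); an archaic
introgression scenario (target + unadmixed sister + donor + deep
outgroup); and four-population trees for D-statistics.

Not emulated: sequencing error, deamination damage, contamination,
genotype-calling uncertainty, mappability structure, non-uniform
recombination maps, and selection. Passing recovery tests therefore
demonstrates statistical correctness of the estimators under clean
genotypes, not robustness to ancient-DNA artifacts — those are assumed
to be handled upstream (the data model consumes masks and polarization
produced by a genotyping pipeline).

## Benchmark problem sizes

The recovery benchmarks (tests and `scripts/acceptance.py`) run at
desk scale, chosen so the full suite completes in well under half an
hour while each property stays clearly resolvable: 30 × 10 Mb genomes
for HBD recovery (inbred-model coalescence is fast to simulate),
10–16 × 10 Mb for F_ST calibration, D-statistics, introgression calling
and dating, 8 × 10 Mb for TMRCA and branch-shortening dating, and
12–15 × 10 Mb with 5–6 simulation replicates per grid point for the
metapopulation fit. The admixture-dating benchmark uses a recipient
population of 10,000 so that t ≪ 2N (the estimator's stated assumption);
the TMRCA benchmark uses a donor of 1,000 so introgressed-segment
TMRCAs sit well below the 14,000-generation split. Replicate counts are
stated with each result; all seeds derive from a single --seed.

## Known limitations

* The HBD detector's f is genetic-length based; on non-uniform real maps
  the bp-based and cM-based fractions differ.
* Admixture-time estimates are downward-biased when the recipient
  population is small (drift healing) and when two admixture pulses are
  conflated; only the single-pulse model is implemented.
* The F_ST correction assumes autozygosity is the only source of excess
  allele correlation; cryptic relatedness *between* the two compared
  genomes is not modeled.
* The introgression HMM's η/δ defaults assume single-genome panels;
  larger panels warrant smaller δ.
* TMRCA classification trusts the configured split time and mutation
  rate; both enter linearly.
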