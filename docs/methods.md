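# Methods

This note records the statistical model behind `halfsib`, the defaults and
why they are what they are, what the synthetic-data generator does and does
not emulate, and the numerical conventions a user should know before
trusting (or extending) the results.

## The half-sib design

All inference is within one paternal half-sib family: daughters share a
sire and have unrelated, ungenotyped dams. At a marker where the sire is
heterozygous ("informative"), a daughter homozygous for either allele
reveals which allele — and therefore, once the sire is phased, which sire
chromosome — she inherited. A heterozygous or missing daughter reveals
nothing at that marker: with the dam unavailable, both origins are equally
consistent. Roughly half the informative-marker calls in a family are
uninformative this way, which drives most of the design decisions below.

## Sire phasing (chain majority)

For each adjacent pair of informative markers, daughters with determined
paternal alleles at both vote on whether the alleles seen together travel
on the same sire chromosome ("same" orientation) or opposite ones. The
majority orientation links the pair; the minority count is the number of
implied recombinants in that interval. A link is refused — a *phase break*,
starting a new arbitrarily-labelled block — when the majority support falls
below `min_informative` (default 5) or the vote ties. With ≥30 daughters
the expected support per link is an order of magnitude above the default,
so whole chromosomes almost always phase as a single block; the threshold
matters only for very small families or marker deserts.

## Daughter state calling (penalized path + abstention)

Each daughter's sequence of paternal-allele calls is decoded against the
phased sire by a minimum-cost dynamic program over states {H1, H2}:
`switch_penalty` (default 2.0) per state change, `mismatch_penalty`
(default 3.0) per determined call contradicting the active haplotype.
Ambiguous calls cost nothing in either state. Ties break toward fewer
switches, then toward H1 (so outputs are deterministic; exact relabeling
symmetry holds on the set of optimal paths, not necessarily the reported
representative).

The penalty ratio encodes the error model. A contradicting call is either
a genotyping error (prior ≈ 1e-3 on chip data) or a double crossover in a
short interval (≈ 2e-2 per informative gap at 3K density, squared for the
pair of switches); the log-odds put the cost of one mismatch a little
below the cost of two switches. The shipped 3:4 ratio keeps the property
that **one isolated miscall is absorbed as an error, never expanded into a
double crossover**, while a run of two or more consistent contradictions
is believed. A substantially smaller mismatch penalty (e.g. 1 against
switch 2) makes the decoder erase every true crossover segment supported
by fewer than four determined calls — on a 3K map that flattens about a
third of real segments and visibly blurs the downstream scan, which is why
the default is not lower. For error-free input (e.g. validation against
simulation truth) the statistically matched setting is
`mismatch_penalty=inf`.

**Abstention.** Inside a run of ambiguous calls whose flanking determined
states disagree, the crossover lies somewhere in the run and no algorithm
can place it: those markers are reported `unknown`, and the breakpoint
interval spans the nearest flanking markers of known state. Runs with
agreeing flanks are interpolated (an undetected even number of crossovers
inside such a run is the only way this errs). Terminal runs extend the
last known state, consistent with reporting no unevidenced crossover.
Consequences: (i) reported states are right ≈ 99.7% of the time on
error-free 3K-density families, and 100% of the time at markers where the
daughter's own genotype determines the state; (ii) breakpoint intervals
are honest uncertainty intervals, which fine-mapping depends on. Whole-
track accuracy counted over *all* informative markers has an information
floor (~1–2% of states are undeterminable near crossovers and at
heterozygous markers) that no decoder can beat; we report abstentions
instead of guesses there.

## The bracket scan

For a bracket (two consecutive informative markers), daughters with the
same known state at both ends get covariate 1 (H1) or 0 (H2); recombinant-
within-bracket, unknown-state and cross-phase-break daughters are
excluded. The model is OLS of mean ovulation rate on intercept, birth-year
indicators, and the covariate; the covariate's two-sided p-value uses the
t distribution with n − rank(design) degrees of freedom (exact under
normal errors; n ≈ 131 makes the normal-vs-t distinction minor but the t
is used throughout). Cohort columns empty in a bracket's subset are
dropped and logged. A constant covariate yields a flagged non-estimable
result with p = 1. The OLS is solved with a least-squares routine directly
(hundreds of thousands of small fits occur in calibration studies);
agreement with statsmodels OLS to 1e-10 is enforced in the test suite.

The plotted profile is raw −log₁₀ p versus bracket midpoint, one panel per
chromosome; a Bonferroni line (α = 0.05 / number of estimable brackets) is
drawn as an annotation only — no correction is applied to the profile.
The *peak* is the estimable bracket with the largest −log₁₀ p; adjacent
brackets with no recombinant between them carry identical covariates and
exactly tied p-values, and the middle bracket of such a tied plateau is
reported. On simulated 131-daughter families with the configured effect
sizes the peak falls within two informative brackets of the true locus in
≈95% of replicates; the residual misses are bracket-to-bracket sampling
noise in a profile whose top is nearly flat over a few megabases — the
same reason single-family linkage peaks should be read as regions, not
points.

## Carrier classification and fine-mapping

The "high" sire haplotype is the one with the larger adjusted mean at the
peak (the sign of the peak beta). Daughters consistent across the peak
bracket are labelled carrier/non-carrier directly. Daughters recombinant
at the peak are flagged and given a provisional label by thresholding
phenotype at the midpoint of the two group means — a deliberately
lower-confidence analogue of the independent-marker haplotyping the
original design used for those animals; these labels are marked
`from_phenotype` and should not drive irreversible conclusions. With the
configured group distributions the threshold mislabels ≈17% of carrier
recombinants (the distributions overlap), which is why fine-mapping from
phenotype-derived labels carries no containment guarantee.

`refine_region` treats each recombinant daughter with exactly one
breakpoint interval inside the candidate region as a one-sided constraint:
a carrier's causative position lies within her high-haplotype segment plus
her breakpoint interval, a non-carrier's outside her high segment. Bounds
are taken at the *outer* edge of each breakpoint interval (conservative:
breakpoint uncertainty stays inside the region). The refined region is the
intersection of all constraints; intersection is commutative and shrinks
monotonically as recombinants are added, and an empty intersection raises
an error naming the daughters whose constraints conflict rather than
silently dropping any. When carrier labels are correct the refined region
provably contains the true locus; this is verified on simulations at every
run of the acceptance suite.

## The synthetic family generator

`SimConfig` defaults are the mapped study's conditions: 131 daughters in
cohorts 33/55/28/15 (2008–2011); 29 autosomes at approximate bovine
assembly lengths (~2.5 Gb) with ~104 jittered-uniform markers each
(~3,000 SNPs, the 3K chip's density); a biallelic QTL on chromosome 10 at
14.2 Mb; carrier phenotype N(2.19, 0.57²), non-carrier N(1.11, 0.22²),
floored at 1.0 (a recorded cycle implies at least one corpus luteum);
genotyping error 1e-3 per call and missingness 1e-2. Meioses follow a
Haldane (no-interference) model: crossover count Poisson with mean equal
to genetic length in Morgans, positions uniform on the genetic map, fair
starting haplotype. Physical-to-genetic conversion is 1 cM/Mb throughout
(configurable); no separate genetic map is modelled.

Deliberate simplifications, and what they mean for the tests:

* The QTL is *not* a genotyped marker (the causative site was not on the
  chip); carrier truth is defined by the paternal state at the QTL
  position. Dams contribute only population-frequency alleles: no
  maternal QTL effect, no polygenic background (the real dams carried
  some polygenic ovulation-rate selection ancestry; here all residual
  variation is in the within-genotype SDs).
* Marker allele frequency defaults to 0.5 everywhere, making ~50% of
  markers informative — the most favorable case; a real chip's frequency
  spectrum would lower informativity and widen unknown runs.
* No crossover interference. Interference would *reduce* close double
  crossovers, i.e. the simulator is harsher than reality for the state
  caller; passing under Haldane is conservative in that respect.
* The phenotype floor makes the realized non-carrier mean
  E[max(1, N(1.11, 0.22))] ≈ 1.154, not 1.11, and the pooled family mean
  ≈ 1.67; estimates recover the realized distribution, so comparisons to
  the configured 1.11 are made at the resolution of a single study's
  group-mean sampling error (3·sd/√n), not the Monte-Carlo error of many
  pooled replicates.

Passing tests on these simulations shows the *inference machinery* is
correct under the stated generative model; it does not validate the model
against real cattle data (chip ascertainment, map error, pedigree
structure, phenotype non-normality are all outside it).

## Population-genetic statistics

Allele frequencies are estimated by counting over called genotypes,
p = count/2n. The standard error is √(p(1−p)/n) with **n = animals, not 2n
chromosomes** — unconventional, but it is the convention that reproduces
the published breed-survey table this module mirrors, and it is what the
tests pin; haplotype-frequency SEs, by contrast, use the binomial form on
2n gametes. Pooled-sequencing frequencies are simple peak-height ratios
h₁/(h₁+h₂). The ≤3-locus EM over diplotype expansions starts uniform,
stops when the largest frequency change drops below `tol` (1e-8), flags
rather than fails on non-convergence, and its log-likelihood is
non-decreasing by construction (EM) and by test. r² is computed from
two-locus haplotype frequencies as D²/(p(1−p)q(1−q)) and is invariant to
allele labelling; monomorphic loci yield a flagged undefined result rather
than 0/0. Published three-locus tables are rounded to three decimals, so
tables built from them are renormalized before use, and r² values derived
from such rounded inputs can differ in the second decimal from values
computed on raw genotypes (the low-frequency cells dominate this
sensitivity).

## Numerical conventions and degenerate inputs

Genotypes are int8 codes 0/1/2 counting an arbitrarily designated
per-marker allele, −1 missing; every computation is symmetric to the
designation. QC removes animals, then markers, below the 95% call-rate
threshold, in that fixed order; the operation is idempotent. Positions are
1-based bp; breakpoint and candidate-region intervals are closed and
bounded by marker positions. p-values are floored at the smallest positive
double before taking −log₁₀. Chromosomes with fewer than two informative
markers are skipped with a log entry; empty phases, all-missing markers,
constant covariates and inconsistent recombinant sets all raise or flag
explicitly rather than propagating NaNs.

## Problem sizes used in the shipped checks

The statistical acceptance checks run at the study's own scale — families
of 131 daughters × ~3,000 markers — with 100 scan replicates for
localization/effect recovery, 30 for fine-map containment, and 2,000 null
fits for type-I calibration; unit tests use a two-chromosome family at the
same marker density. These sizes give the assertions their stated
resolution (e.g. a binomial 99% interval on a 5% rejection rate needs
thousands of fits) while keeping a full run in the low minutes.

## Known limitations

* Maternal genotypes are never used; daughter-heterozygous markers are
  resolved only by flanking context.
* Phase blocks are labelled independently: across a phase break, H1/H2
  identity — and therefore carrier continuity — does not propagate.
* The phenotype-threshold labels for peak recombinants are a stopgap for
  the original design's independent marker system and are flagged as such.
* The EM is deliberately capped at three loci (8 haplotypes); it is not a
  general phasing engine.
* Breed survey tables bundled in `halfsib.published` are rounded published
  values; statistics recomputed from them inherit that rounding.
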