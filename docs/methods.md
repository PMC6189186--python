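# Methods

## The branching model of neurodevelopment

The brain is modelled as the clonal expansion of a single founder cell
through `G = 37` synchronous division rounds, giving `2^37 ≈ 1.37e11` final
cells, half neurons (`neuron_fraction = 0.5`). Every daughter-genome
replication copies each base with a constant mutation probability `λ_m`
(per base per division). A mutation arising during the replication that
produces a generation-`i` daughter — "seeded at generation `i`" — is
inherited by all `2^(G−i)` descendants of that daughter, forming a
spatially contiguous mutant region occupying a brain fraction `f = 2^−i`.
This convention makes the 128-cell regions correspond to `i = 30` and the
2.62×10⁵-cell regions to `i = 19`. All somatic mutations are treated as
heterozygous, so a clone at cell fraction `f` has VAF `f/2`.

The number of replications producing generation-`i` cells is `d(i) = 2^i`,
so seeding events at generation `i` over a target of `L` bases are Poisson
with mean `λ_m·L·d(i)`. Totals follow from the geometric sum
`Σ d(i) = 2^(G+1) − 2`; because `d(i)·f(i) = 1`, every generation
contributes equally to the expected mutant-cell burden, while late
generations dominate region *counts*.

Assumptions deliberately kept simple: symmetric synchronous divisions, no
founder progenitor pool, no migration, no spatial geometry beyond the
lineage-subtree block mapping below. These are acknowledged idealisations;
the package's claims are about this model, not about neuroanatomy.

### Cell death

Cell death is supported through doomed-subtree pruning: each daughter is
independently doomed with probability `q`; a doomed lineage divides for up
to `doomed_depth` further generations (default 6) and then dies entirely.
`q` and the total number of rounds `G′` are solved jointly so survivors
equal `2^G` and the fraction of *ever-produced* cells that die equals
`death_fraction`. Death fractions approaching 1 are reachable only because
doomed subtrees keep dividing before dying; with `doomed_depth = 0` the
reachable ceiling is 50 % (a growing population cannot lose more than half
its daughters each round). In closed form the surviving-daughter count is
`d(i) = (2(1−q))^i` with region fraction `1/d(i)`; at `death_fraction = 0`
this reduces *exactly* to the base model, and a small-`G` explicit tree
simulator validates the closed form in the test-suite. Death barely
perturbs the observable quantities because detection depends on `λ_m·d(i)`
and region sizes through the same `d(i)`.

## Tissue sampling

A dissected tissue block is a uniformly chosen generation-`g` subtree
(default `g = 7`, i.e. 128 blocks of ~1.07e9 cells, the order of a 1 cm³
grey-matter block). A clone seeded at `i ≤ g` either contains the whole
block (probability `2^−i`) or misses it; a clone with `i > g` lies inside
the block with probability `2^−g` at within-block fraction `2^(g−i)`.
Sampling `n_c` cells (default 3,533 = 611,285 cells / 173 samples) draws
binomial mutant-cell counts. Distinct anatomical regions of one individual
are disjoint subtrees sampled without replacement. The block–subtree
mapping is one concrete realisation of "spatially proximal replication";
nothing in the data constrains it further.

## Rejection ABC for the mutation rate

The summary statistic is the detected SRM count in the disease-gene panel
(132,617 bp). Its model marginal is Poisson with a mean linear in `λ_m`:
the detection weight sums, over individuals and generations, hypergeometric
block-coverage (for `i ≤ g`, requiring exactly one sampled block covered)
and single-block presence `R/2^g` times the binomial detection probability
(for `i > g`), where detection requires sampled VAF ≥ 0.5 % and ≥ 10
implied alt reads at 5,374× depth. `simulate_summary` draws from this
marginal; the event-level simulator (`simulate_summary_explicit`) realises
the same law by brute force and the test-suite checks their agreement —
this is what makes 10⁵ prior draws run in seconds without changing the
inference. The prior is log-uniform on [10⁻¹¹, 10⁻⁷] (four orders of
magnitude, literature rates 10⁻¹⁰–10⁻⁹ interior); acceptance is exact
integer match by default (counts are small), with an optional absolute
tolerance. The default design uses all 54 brains / 173 samples; the
inference can be restricted to any design by passing a different
`StudyDesign`.

## Prevalence extrapolation

Each simulated individual uses an independent posterior draw of `λ_m` and
seeds pathogenic events Poisson-wise over `N_path` effective pathogenic
bases. `N_path` cannot ship as a database extract (pathogenic-mutation
catalogues are licensed), so it is calibrated: `count = N_path·λ_m·d(i)`
back-solved at both ends of a published (rate BCI, 128-cell region-count
BCI) pair gives 145.5 and 149.8 — a 2.9 % discrepancy, which doubles as a
model-consistency diagnostic (warning above 25 %). Default `N_path = 148`.
When only a published credible interval is available in place of posterior
draws, `posterior_from_interval` reconstructs draws log-uniformly with
matching equal-tail quantiles; this shape choice is a convention, and the
headline prevalence figures inherit a few-percent systematic uncertainty
from it. Sizes are reported over all cells by default; `neurons_only`
restricts to the neuronal half (the data do not disambiguate which
denominator published prevalence figures used, so both are provided).

## Synthetic cohorts

`synthetic_study` emulates the full study design: 54 brains (20 AD, 20
Lewy-body, 14 control), 173 regions (CB 54, EC 53, FC 32, Med 24, Cin 10),
6 blood-paired individuals, per-sample depth Normal(5374, 745) truncated at
500 and split evenly across strands, two panels (132,617 / 152,519 bp).
Planted classes: developmental clones from the branching simulator
(generations above `g + detectable depth + 3` are truncated — their clones
are orders of magnitude below any detectable VAF); blood-derived
clonal-haematopoiesis MRMs in myeloproliferative control-panel genes,
present in every region at brain VAF = blood VAF / 7.92 with a 2.1×
medulla:EC multiplier (blood VAF level chosen so the mean brain MRM VAF is
~3.67 %); germline heterozygotes at VAF 0.5; and shared background sites.

Sequencing noise has two layers: per-site error rates are Beta-distributed
across sites (mean 2×10⁻⁴, dispersion 0.005 — heavy-tailed, so occasional
hotspot sites reach 10⁻³–10⁻²), and within a site the per-sample error
varies with coefficient of variation 0.3 (a per-observation beta-binomial
with `ρ ≈ cv²·e`). A single fixed large `ρ` at error-rate scale was
rejected as a design: it implies a Beta shape ≪ 1 whose variance cannot be
estimated from ~170 reference samples by moments, making any
moment-calibrated confirmation test miscalibrated by construction. The
two-layer model keeps hotspots (the hard screening problem) while leaving
within-site dispersion estimable. No attempt is made to simulate raw
reads, alignment or capture artefacts, trinucleotide signatures, or
contamination — so passing tests demonstrate the decision logic under this
noise family, not robustness to every failure mode of real libraries.

## The variant screen

Hard filters follow the published thresholds exactly (< 1000× depth, < 10
alt reads, < 4 alt reads on either strand, population MAF > 1 %, repeat
flag). Confirmation uses per-site beta-binomial error models fitted by
method of moments (the pooled alt fraction, floored at `pseudo_error_floor
= 10⁻⁵` so tails are defined at zero-error sites; dispersion from the
excess between-sample variance, clamped at 0). Maximum-likelihood fitting
is the obvious alternative; moments are kept for transparency and speed.

The "significantly different from all other samples" conditions are
implemented as a test against the reference sample with the *highest* alt
fraction (with the cohort-fitted dispersion): requiring the candidate to
beat every reference individually is what rejects hotspot sites, where the
whole cohort sits above the VAF floor. One-sided upper tails are used
throughout (only alt-count excess is of interest). The BH family is the
full set of comparisons run across the study, which bounds the probability
of any false SRM call on an error-only cohort by α = 0.05. Labels: a
candidate site in an individual is **germline** when its median VAF across
regions is in [0.35, 0.65] with every region significant against the
cohort; **SRM** when exactly one region is significant both within the
individual and against the cohort (regions below the 0.5 % floor do not
disqualify); **MRM** when ≥ 2 regions with VAF in [0.5 %, 20 %] are each
significant against other individuals; otherwise rejected. External
discovery callers are not re-implemented: "passes hard filters at ≥ 0.5 %
VAF" is the candidate-generation stage, and the beta-binomial test is the
confirmation layer.

For spike-in evaluation, detection = hard filters + BH-corrected
significance at the planted level; a measured-VAF ≥ 0.5 % cutoff is *not*
applied there, because at a planted VAF exactly at the floor binomial read
sampling puts half of all draws below it, capping sensitivity near 50 % for
any caller — the 0.5–20 % band is a property of the cohort SRM/MRM
classification, not of per-site detection.

## Numerical and testing choices

All randomness flows through `numpy.random.Generator` objects seeded from a
single integer; identical seeds give bit-identical outputs, including the
full pipeline. Problem sizes in the test-suite and acceptance script —
10⁵ ABC prior draws, 10⁴ simulated individuals, 40–60 replicate inferences
for coverage, 100 spike-in sites — were chosen so each stochastic check
has Monte-Carlo error comfortably below its assertion tolerance while the
whole suite stays fast. Stochastic assertions use 3-standard-error bands
against closed-form oracles wherever one exists (geometric sums,
hypergeometric block coverage, Poisson/binomial moments, brute-force
enumeration on tiny trees).

Known limitations: overlapping clones are summed without nesting
corrections (error O(f²) for the rare events involved); the chi-square
rate comparison reproduces ~0.68 for the published 7/132,617 vs 11/152,519
contrast rather than the printed 0.64, whose exact table construction is
not derivable from the text; the real-data VAF concordance between
sequencing platforms (r² ≈ 0.95) concerns wet-lab replication and is out
of scope for synthetic data.
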