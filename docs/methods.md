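# Methods

## The measurement problem

A fluctuation assay grows many parallel cultures from small inocula, plates
each on selective medium (here 5-FOA, which kills cells with functional
*URA3*) and titers a dilution on nonselective medium. Because a mutation
arising early in growth founds a large resistant clone, mutant counts per
culture are heavy-tailed ("jackpots"); the mutant *frequency* is therefore a
poor estimator and the rate must be inferred from the distribution across
cultures. This package implements the Drake median method used throughout
the repeat-instability reporter literature, together with the synthetic
data needed to validate it end to end.

## Luria–Delbrück model

The classical minimal model is assumed throughout: deterministic
exponential growth from `n0` to `nt` cells, mutations arising at rate `mu`
per cell division as a Poisson process proportional to growth, mutant
clones growing at the same rate as the rest of the population (relative
fitness 1), no death, no reverse mutation, no phenotypic lag. The expected
number of mutation events per culture is `m = mu * (nt - n0)` (total
divisions under binary fission; at the default `n0/nt = 5e-6` the
distinction from `mu*nt` is negligible).

`ld_pmf` evaluates the count distribution by the Ma–Sandri–Sarkar
recursion `p_0 = exp(-m)`, `p_k = (m/k) * sum_{j<k} p_j/(k-j+1)`. The
recursion is prefix-stable, so extending the support never changes earlier
entries, and `p_0` is exact by construction.

`sample_mutant_counts` inverts the tabulated CDF, doubling the tabulated
support on demand up to k = 4096. The ~1/k² tail makes unbounded
tabulation quadratically expensive in the deepest draw, so rarer draws
(probability ≈ m/4096) are resolved *exactly* through the compound-Poisson
representation of the same law: the MSS recursion is the Panjer recursion
of a Poisson(m) sum of clone sizes S with P(S ≥ j) = 1/j, so a
tail-conditioned draw is obtained by rejection from that representation.
The hybrid is distributionally identical to full inverse-CDF sampling;
nothing is truncated.

Two forward simulators serve as independent oracles:

* `simulate_culture_forward` — synchronous binary fission: every cell
  divides each generation, new mutants ~ Poisson(mu × nonmutant cells),
  mutant lineages double. Its total event count has exactly the right mean
  and its mutant counts show the jackpot overdispersion, which is what it
  is used to check. Synchronous division quantizes clone sizes to powers
  of two, so its *count distribution* is a coarsened variant of the
  Lea–Coulson law (total-variation distance ≈ 0.1 at m = 2) — a property
  of the model, not a bug.
* `sample_forward_lea_coulson` — event-level continuous-time model:
  deterministic exponential growth, Poisson mutation arrivals proportional
  to growth, each clone growing as a stochastic Yule process (a clone born
  when the population is a fraction u of its final size ends with
  Geometric(u) cells). This is the distributionally faithful oracle: the
  test suite requires total-variation distance < 0.02 between 10⁵ of its
  cultures and 10⁵ sampler draws at m ∈ {0.5, 2, 5}. TV is computed on
  the classes {0, …, 49, ≥50}: on the raw support the 1/k² tail spreads
  10⁵ draws over thousands of near-singleton bins whose
  empirical-vs-empirical distance is noise (≈0.02–0.03 even between two
  samples of the same law), which would swamp the comparison.

Plating is modelled as Binomial(mutants, plated fraction) on the selective
plate and Poisson(nt × dilution) on the titer plate. Default assay
geometry: `nt = 2e8`, `n0 = 1e3`, full selective plating, 1e-6 titer
dilution — chosen so rates in the 1e-8–1e-5 range yield countable plates,
matching stationary 2 ml cultures. Published strain datasets do not
include absolute culture sizes, so these defaults are conventions and are
recorded in output metadata.

## Rate estimation

`solve_drake` finds the unique root μ > 1/N of μ·ln(N·μ) = f by Brent
bisection on the bracket [(1+1e-12)/N, 2·max(f, e/N)] (the objective is
strictly monotone there), to a residual ≤ 1e-10·f; an independent
fixed-point iteration μ ← f/ln(N·μ) agrees to 1e-8 relative over 10⁴
random (f, N) in the test suite.

`estimate_rate` defaults to solving per culture and taking the median of
the per-culture rates ("median values of the mutation rates" is read as
rates first, median second); the classical single solve at the median
frequency is available as a variant for sensitivity analysis. Cultures
with zero selective colonies contribute a rate of 0 (below detection)
rather than being dropped, which would bias the median upward. Even-n
medians average the two central order statistics.

The confidence interval is the distribution-free order-statistic interval
for the median: (x₍ₗ₎, x₍ₙ₊₁₋ₗ₎) with l the largest integer whose binomial
tail BinomCDF(l−1; n, ½) ≤ (1−level)/2. It is conservative by
construction (achieved level 97.85% at n = 10 for a nominal 95%); below
n = 6 the nominal level is unattainable and the full range is returned
with a `below_nominal` flag. The CI algorithm used by legacy statistics
packages for such figures is not documented anywhere authoritative; the
order-statistic interval is this package's convention.

When the median frequency is zero the rate is reported as an upper bound
at the detection-limit frequency f* = 1/(median N × median plated
fraction) — one colony among the cells actually plated — rendered with
"<" as is conventional.

Simulation shows the estimator recovers planted rates within [0.7, 1.8]×
(median over 200 assays of 20 cultures, m ∈ {2, 5, 15}); the upward bias
of tens of percent at small m is a known property of the Drake median
method, not an implementation artifact.

## Reporter-selection model

Three assay types share one selection predicate:

* `control_forward` (random in-frame sequence): resistant iff the *URA3*
  coding sequence itself is hit; tract-length changes are silent.
* `plasmid_frameshift` (tract fused in frame upstream of *URA3*): resistant
  iff the net change `delta_units * unit_bp` is not a multiple of 3 (or a
  coding hit). Hence ±3 units of a dinucleotide are invisible, while any
  ±1 of an 11-mer or 20-mer is selectable.
* `chromosomal_tnr` (trinucleotide tract in the promoter): resistant iff
  expanded by at least 5 units from the 25-repeat reference (total > 29
  repeats); contractions do not disrupt expression and are not recovered.

`simulate_resistant_clones` rejection-samples event classes through this
predicate, so emitted clone proportions are selection-conditional, exactly
as real 5-FOA plates are.

## Fragment sizing and spectra

Observed amplicon length is flank + unit × (reference units + delta) plus
Gaussian sizing noise (default SD 0.3 bp, sub-bp capillary precision).
`call_delta_units` rounds (size − reference length)/unit to the nearest
integer and refuses calls whose residual exceeds 0.45 units — just inside
the half-unit ambiguity boundary. Mononucleotide tracts are refused
outright: 1 bp steps are below capillary resolution, so such assays are
scored only through rate measurements. Flank lengths and calling
tolerances are configuration (primer placement, instrument), not
biological constants.

Deltas are binned into the display classes large deletions (≤ −3), −2, −1,
0, +1, +2, large additions (≥ +3); a resistant clone with delta 0 is
interpreted as a coding hit outside the tract. Percentages are rounded
half-up to integers, matching how such tables are printed and reconciling
with clone totals. Between-strain spectrum comparison runs a Pearson
chi-square on the 2×k count table after pooling classes with any expected
count < 1 into the adjacent class toward the centre of the ordering (the
pooling applied is recorded in the result).

## Nonparametric tests

Mann–Whitney U is exact whenever C(n1+n2, n1) ≤ 2×10⁵: full enumeration of
label assignments conditional on the observed pooled multiset when ties
are present (midranks), the standard exact count distribution otherwise.
Larger problems use the normal approximation with tie and continuity
corrections. Two-sided p doubles the smaller tail, capped at 1. Null
calibration at n = 10 vs 10 gives a rejection rate of ≈0.04–0.05 at
α = 0.05. Kruskal–Wallis uses the tie-corrected H with a chi-square
reference (H defined as 0 with p = 1 when every value is tied, where the
tie correction degenerates); posthoc pairwise tests apply Bonferroni
(×number of pairs, capped at 1). Contingency tables use plain Pearson
chi-square without continuity correction. All strain comparisons are
two-sided by default — sidedness is rarely stated in figure legends, and
two-sided is the conservative choice.

## Epistasis conventions

Fold changes divide point estimates; a detection-limit denominator
("<" baseline) yields a fold flagged as a lower bound, and an upper-bound
numerator is refused. The additive expectation for a double mutant
defaults to the plain *sum* of single-mutant folds — the convention of
this assay literature (4-fold and 38-fold single mutants give a 42-fold
expectation), with the documented quirk that two neutral alleles "expect"
2-fold. The alternative `increments` convention (a + b − 1) is selectable.
Interaction labels use a 10% relative tolerance band around the
expectation: above → synergistic, below → suppressive, inside → additive.
The tolerance is this package's convention; published calls (66 vs 42
synergistic, 14.2 vs 13.4 additive) are reproduced at the default.

## What the synthetic data does and does not show

The generator emulates: Luria–Delbrück dispersion including exact deep
tails, binomial/Poisson plating noise, selection-conditional spectra, and
Gaussian sizing error. It does not emulate differential mutant fitness,
cell death, plating efficiency below 100% as a separate layer (fold it
into the plating fraction), phenotypic lag, culture-to-culture growth
variation, or any mechanistic structure of recombination-driven events.
Passing the recovery and coverage tests therefore demonstrates estimator
correctness under the classical model, not robustness to those biological
departures.

## Problem sizes and determinism

Validation workloads were sized to exercise the asymptotics while staying
cheap: 10⁵ draws per distributional comparison, 200 assays × 20 cultures
per recovery point, 1000 assays for CI coverage, 2000 null simulations for
test calibration, 10⁴ clones per sizing round trip. Every stochastic
component takes a single integer seed (or a numpy Generator) and is
reproducible draw-for-draw; simulation outputs carry their seed and
parameters in a metadata block, and reports are byte-identical for
identical inputs.

## Known limitations

* The Drake median estimator is biased upward at small m; no
  bias-corrected or maximum-likelihood (MSS) estimator is provided.
* Upper-bound rates depend on the assumed detection limit of one colony
  among plated cells.
* Spectrum chi-square p-values are asymptotic; with pooling they remain
  approximate for very sparse tables.
* The per-culture-median and median-frequency estimator variants can
  differ by more than the CI width for skewed titer distributions; both
  are exposed deliberately.
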