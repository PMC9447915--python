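# Methods

## The model

`burdenscope` analyses the *collective* burden of a fixed list of rare
variants in a gene — motivated by Type 1 *CFI* rare variants (genotypes
associated with haploinsufficient complement Factor I levels) in advanced
age-related macular degeneration (AAMD), but written generically.

Two assumptions, carried through every stage:

1. **Mutual exclusivity.** Each individual carries at most one catalogued
   genotype, so the collective carrier count of a cohort is the plain sum of
   per-variant carrier counts, and the collective minor allele frequency
   (MAF) is the sum of per-variant MAFs. At the frequencies involved
   (collective MAF well under 1% in most backgrounds) the probability of a
   joint carrier is negligible, but the assumption is a modelling choice,
   not something the data enforce; the aggregation API records it in output
   metadata.
2. **Heterozygous carriers.** All carriers are modelled as heterozygous.
   Under Hardy–Weinberg the allele frequency *p* and the carrier proportion
   *c* are linked by *c* = 2*p*(1 − *p*), inverted exactly as
   *p* = (1 − √(1 − 2*c*))/2 (`convert_convention`). For rare variants
   *c* ≈ 2*p*. Cohort counts therefore carry an explicit convention flag
   (`carrier_proportion` vs `allele_frequency`) rather than a silent
   assumption, because published summary tables mix the two.

## Enrichment statistics

From case and control cohort counts a 2×2 carrier table
(a, b; c, d) = (case carriers, case non-carriers; control carriers, control
non-carriers) is built. The summary is the sample odds ratio OR = ad/bc with
the Woolf confidence interval

&nbsp;&nbsp;exp( ln OR ± z<sub>(1+γ)/2</sub> · √(1/a + 1/b + 1/c + 1/d) ),

computed with full-precision normal quantiles (z = 1.959964… at 95%). When
any cell is zero, the Haldane–Anscombe correction (+0.5 to every cell) is
applied before OR and CI — only under the default `haldane` policy, and the
result is flagged `correction_applied`.

The p-value comes from the Pearson chi-squared test (1 df, no continuity
correction by default; Yates is a flag), except that a table with *either
carrier cell below five* is routed to the two-sided Fisher exact test in its
probability-mass form (sum of hypergeometric probabilities not exceeding
that of the observed table). This small-count selection rule mirrors common
reporting practice for burden tables with sparse carrier cells. The Pearson
statistic is computed from the closed form N(ad − bc)²/((a+b)(c+d)(a+c)(b+d))
rather than a generic contingency routine so that a degenerate carrier
margin returns (statistic 0, p 1) instead of erroring; without continuity
correction it equals the squared pooled-variance two-proportion z exactly.

For simulation-based bias assessment the package exposes
`gart_log_odds_ratio`, the log OR with 0.5 added to every cell. The raw
sample log OR carries the textbook O(1/count) small-sample bias — about
+0.012 at the recovery-study counts below, which is visible at 2,000
Monte-Carlo replicates — while the Gart estimator removes the leading term;
recovery tests therefore measure log-scale bias with the Gart form.

## Fixed-control-arm power projection

Power projections ask: against a *fixed* reference panel (size n₀,
background collective frequency p₀), how many cases n₁ must be sequenced to
detect enrichment at odds ratio OR with two-sided level α? The alternative
proportion is exact on the odds scale, p₁ = OR·p₀ / (1 − p₀ + OR·p₀), and
power uses the pooled-variance normal approximation to the Pearson
chi-squared two-proportion test:

&nbsp;&nbsp;power(n₁) = Φ( (Δ − z<sub>α/2</sub>·√(p̄q̄(1/n₁ + 1/n₀))) / √(p₁q₁/n₁ + p₀q₀/n₀) ),

with Δ = p₁ − p₀ and p̄ the pooled proportion. Because n₀ is fixed, power
has a finite supremum as n₁ → ∞:

&nbsp;&nbsp;power<sub>∞</sub> = Φ( (Δ − z<sub>α/2</sub>·√(p₁q₁/n₀)) / √(p₀q₀/n₀) ).

Panels whose limit falls below the target can never reach significance at
any case-arm size — the projection reports them as unattainable rather than
printing a meaningless huge n.

Numerical points that matter:

- **The power curve is not globally monotone.** When the limit is small
  (numerator negative), power rises to a modest peak at finite n₁ and then
  *declines* toward the limit from above (e.g. the Finnish panel peaks near
  0.21 around n₁ ≈ 4×10⁴ before falling to its 0.17 asymptote). The solver
  therefore searches the finite grid — exponential bracketing from n₁ = 1,
  a 512-point geometric sweep as a guard against bumps between doubling
  points, then integer bisection on the first crossing — even when the
  limit is below target, and only then declares unattainability.
- **Minimality** holds by construction: the first crossing lies in the
  increasing region, and the solver verifies power(n* − 1) < target.
- **Convergence to the limit is O(n₀/n₁)**: agreement with the closed-form
  limit is ~10⁻⁶ only once n₁ ≳ 10¹⁰–10¹¹ for the sparser panels.
- **Approximation quality.** Against Monte-Carlo power of the actual
  chi-squared/Fisher pipeline, the closed form agrees within Monte-Carlo
  error (3 binomial s.e. at 10,000 replicates) at the mid-frequency design
  points (expected carrier counts ≳ 25 per arm). For very rare events and
  small expected counts the discreteness of the test makes the normal
  approximation optimistic or pessimistic by a percentage point or two
  (e.g. ~0.82 empirical vs 0.80 analytic at the South Asian 80% design
  point); projected sample sizes in that regime should be read as
  first-order guidance, which is also why solved sizes are compared to
  published projections as bounds rather than exact matches.
- Reported n is the exact minimal integer; display rounding (e.g. up to the
  nearest ten) is a presentation option because published tables round
  inconsistently.

## Sequencing-noise filter

Amplicon sequencing calls are screened per site with a four-step rule:
candidate thresholds (alt count > 5 *and* VAF > 0.5%), a high-VAF override
(VAF > 2% is called regardless of noise), a one-sided binomial noise test
(p = P(X ≥ alt | depth, error rate) with X binomial; accept iff p < α), and
a quality-ratio guard ((alt/depth)/(alt-quality/total-quality) must lie
inside configured bounds). The binomial significance level defaults to 0.05
and the quality-ratio bounds to (0.5, 2.0); the source protocol states
neither, so both are explicit, documented parameters. Acceptance is
monotone in alt count at fixed depth and error rate.

## Synthetic cohorts

`simulate_cohort` draws one categorical outcome per individual over
{none} ∪ variants, so mutual exclusivity holds by construction. Case arms
multiply the *collective* carrier odds by the configured OR and rescale the
per-variant frequencies proportionally — enrichment acts on the burden as a
whole, matching the collective-level model; per-variant odds ratios are not
individually configurable. Reproducibility: per-arm generators are spawned
deterministically from the config seed (`SeedSequence.spawn`), so identical
configs give identical cohorts.

`simulate_reads` emits one read-count record per individual: carriers draw
alt counts from Binomial(depth, ½) at their variant site; non-carriers draw
Binomial(depth, error rate) at a single representative background site.
Defaults — depth 1000, error rate 10⁻⁴ — reflect consensus-quality Illumina
amplicon data after quality filtering; at these defaults the probability
that a non-carrier site survives the noise filter is ~10⁻⁸, so one
monitored background site per individual (rather than one per panel
position) does not change the filtered counts. Quality sums are synthesised
proportional to read counts, leaving the quality-ratio guard neutral for
clean data.

What the generator does *not* model: linkage disequilibrium, population
structure or relatedness, coverage heterogeneity across individuals,
homozygous or compound-heterozygous carriers, or genotype likelihoods.
Passing tests therefore demonstrate the statistical machinery under the
analysis's own assumptions; they do not validate those assumptions against
real cohorts.

The Monte-Carlo oracles `empirical_power` and `ci_coverage` draw collective
carrier counts directly from Binomial(n, collective frequency) — exactly
the distribution the categorical construction implies after collapsing to
carrier/non-carrier — for speed; a test pins their agreement with the
per-individual generator.

## Problem sizes used in the checked examples

The reproduction suite uses the published inputs as-is (five cohort rows;
seven reference panels). Monte-Carlo checks use 2,000 replicates for CI
coverage and pipeline OR recovery (collective frequency 0.01, 5,000 per
arm) and 10,000 replicates for empirical power at three published design
points — sizes at which Monte-Carlo error is small enough to resolve the
effects being checked.

## Known limitations

- Reference-panel comparisons inherit gnomAD-style caveats: unpaired
  controls, different sequencing platforms, and per-population coverage
  differences (records missing the filter population are retained with a
  warning rather than dropped).
- The exact-reproduction checks accept one unit in the last printed decimal
  for CI bounds and small p-values, since the display rounding of the
  published values is not bit-reproducible from the printed counts.
- No per-variant association, covariate adjustment, meta-analysis, or
  multiple-testing correction: the collective burden is the unit of
  analysis throughout.
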