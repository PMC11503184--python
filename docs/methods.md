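# Methods

This note describes the statistical model implemented by `ps4lr`, the
parameter defaults and the reasons behind them, the numerical strategy, and
the known limitations. All design decisions described as defaults here are
this package's own choices unless explicitly attributed to the ACMG/AMP or
Bayesian evidence-point conventions.

## 1. Model

### 1.1 Data and conditioning

The input is a 2×2 case-control table: `k` variant carriers among `N` cases
and `m` carriers among `M` controls. The analysis conditions on the carriers:
among the `n = k + m` carriers observed, each independently belongs to the
case series with some unknown probability `p`, so

```
L(p) = C(n, k) · p^k · (1 − p)^(n − k).
```

Conditioning on carriers makes the method insensitive to the absolute rarity
of the variant and well defined when either series contains zero carriers.
The non-carriers enter only through the background odds (below); since
carriers are a negligible fraction of each series for the rare variants this
method targets, the non-carrier counts are treated as fixed rather than
jointly modelled.

### 1.2 Hypotheses as regions of p

For a carrier, the odds of being a case under no association equal the
corresponding odds among non-carriers:

```
odds = case_non_carriers / control_non_carriers .
```

A hypothesised true odds ratio `OR` scales these odds, giving the probability
threshold

```
p(OR) = odds · OR / (1 + odds · OR) = expit( log(odds) + log(OR) ).
```

Two composite hypotheses are compared:

- **H_assoc** — the true OR is at least `or_assoc`: `p ∈ [p(or_assoc), 1]`;
- **H_nonassoc** — the true OR is at most `or_nonassoc`: `p ∈ [0, p(or_nonassoc)]`.

The likelihood ratio is the ratio of the likelihood integrated (unnormalised,
flat in `p`) over the two regions:

```
LR = ∫_{p(or_assoc)}^{1} L(p) dp  /  ∫_{0}^{p(or_nonassoc)} L(p) dp .
```

Integrating rather than maximising means a hypothesis is rewarded only where
it concentrates likelihood mass, and the ratio is symmetric in its treatment
of the two directions: the same machinery produces pathogenic and benign
evidence.

### 1.3 Closed form

With `a = k + 1`, `b = n − k + 1`, the integral over `[lo, hi]` is

```
∫ L(p) dp = [ I_hi(a, b) − I_lo(a, b) ] / (n + 1),
```

where `I_x(a, b)` is the regularized incomplete beta function. The binomial
coefficient cancels in the ratio; it is kept in reported region areas so the
total-area identity `∫_0^1 L(p) dp = 1/(n+1)` holds exactly (this identity is
a test invariant).

### 1.4 Evidence points and strength bands

Evidence points are `EP = ln(LR) / ln(2.08)`, the log of the LR in the base
of the Bayesian points framework in which one point of supporting evidence
corresponds to an LR of 2.08. Band boundaries are at EP ±1, ±2, ±4, ±8
(supporting / moderate / strong / very strong, pathogenic for positive and
benign for negative EP); |EP| < 1 is no evidence. EPs from independently
ascertained series are additive (the LRs multiply); independence is the
caller's responsibility.

### 1.5 Default hypothesis pair

The default is `or_assoc = 5`, `or_nonassoc = 1`. OR ≥ 5 is the categorical
PS4 rule's threshold and a reasonable floor for a fully penetrant dominant
variant; OR ≤ 1 is the natural "no association" complement. Both are
explicit parameters: lower `or_assoc` (e.g. 2–4) encodes reduced penetrance;
`or_assoc` of 10–1000 is appropriate for rare near-monogenic disease where
cases are strongly enriched. The choice materially changes the verdict — the
same counts can be strong pathogenic evidence under one penetrance model and
strong benign evidence under another — so the package treats the pair as a
first-class input rather than a constant.

## 2. Frequentist companion columns

For comparability with the categorical rule, each scenario also gets:

- **Observed OR** `(k·d)/(m·c)` with `c, d` the case/control non-carriers;
  infinite when `m = 0, k > 0`; undefined (error) when `n = 0`.
- **Woolf confidence interval**: `exp( ln OR ± z · sqrt(1/k + 1/m + 1/c + 1/d) )`,
  `z` the standard-normal quantile for the level (1.96 at 95%). Undefined
  (NaN bounds) when any cell is zero — deliberately no continuity
  correction, since the integrated LR is the zero-cell answer.
- **Fisher two-sided exact p** (scipy's implementation).
- **Categorical 2015-rule verdict**: strong when observed OR ≥ 5 *and* the
  95% CI lower bound exceeds 1 (default form), or OR ≥ 5 and p < 0.05
  (alternative form, behind a switch). The two published phrasings are kept
  separate rather than blended.

## 3. Conservatism options

All three options only ever weaken evidence; none is applied by default
(the plain LR is already well calibrated), they are opt-in analysis modes.

### 3.1 Raising the opposing hypothesis

Replacing `or_nonassoc = 1` by e.g. 2 demands that the data discriminate
association not merely from "no effect" but from a modest real effect. The
LR is non-increasing in `or_nonassoc`; raising it to `or_assoc` or beyond is
rejected as a degenerate (overlapping) hypothesis pair.

### 3.2 Confidence-bound attenuation of the targets

Each target OR is replaced by a confidence bound of the OR estimate
*expected* if that target were the truth, computed on the expected table:
the carrier total `n` is apportioned to the case column as `n·p(OR)`
(fractional cells allowed), non-carrier cells kept as observed, and the
Woolf SE taken on that table. The association target moves down
(`or_assoc · exp(−z·SE)`), the non-association target up
(`or_nonassoc · exp(+z·SE)`). Supported levels: 70%, 90%, 95%, each side
independently selectable.

For weakly powered tables the two effective thresholds can cross
(`eff_assoc < eff_nonassoc`). The package permits the resulting overlapping
regions — the LR is then aggressively pulled towards 1, which is the
intended conservative behaviour — and raises the `ci_thresholds_crossed`
warning flag rather than erroring. Crossing is the *normal* regime at 95%
for the kinds of tables this method targets, so treating it as an error
would make the option unusable exactly where it matters.

#### Attenuation overshoot

Attenuation shrinks |EP| strictly on all balanced reference scenarios. It
does **not** on heavily unbalanced rare-disease tables evaluated under very
high association targets (OR ≥ 1000): there the non-association-side SE is
enormous (the expected case-carrier cell under OR = 1 is nearly zero), the
effective non-association threshold explodes upward past the association
threshold, and the attenuated EP overshoots past 0 into the benign
direction (e.g. from +4.1 to −5.7). This is a structural property of the
construction, not an implementation artefact. The properties that hold
universally, and that the test suite asserts, are: attenuation never
inflates pathogenic-direction evidence, and it strictly shrinks |EP| on
balanced designs. For unbalanced designs under extreme targets the option
should be read as "punitive", not "calibrated"; the one acceptance test
asserting strict |EP| shrinkage on *every* reference scenario is expected
to fail and documents this boundary.

### 3.3 Sensitivity analysis

`sensitivity_analysis(counts, targets, case_decrement, control_increment)`
recomputes the LR after removing case carriers and/or adding control
carriers — "how much of the conclusion rests on one or two observations?".
Both perturbation directions are evidence-weakening, and the perturbed LR is
never larger than the original on the reference scenarios (a test
invariant). In the CLI the perturbed record is exempt from the single-case
refusal (perturbing down to a single case carrier is the point of the
probe).

### 3.4 Single case observation

A single case carrier (`k = 1`) is compatible with ascertainment artefacts
and, by this package's policy, must not generate pathogenic-direction
evidence by itself: the batch runner refuses such records when the computed
EP is positive, unless explicitly overridden (`--allow-single-case`).
Benign-direction results from `k = 1` are returned (with the warning flag):
refusing those would discard legitimate evidence *against* pathogenicity.
The refusal-only-when-pathogenic asymmetry is a deliberate design decision
of this package.

## 4. Diagnostics

- **Occupancy** — `(area_assoc + area_nonassoc) / area_total`, the fraction
  of likelihood mass the two hypothesis regions capture. When it is small,
  the data concentrate likelihood *between* the hypotheses (a well-supported
  intermediate OR) and the LR compares two tails of a likelihood that
  actually peaks elsewhere; the `low_occupancy` flag fires below a cutoff of
  **0.05** (package default, configurable). The LR itself is not altered.
- **Zero-case unbalanced** — `k = 0` with `m ≥ 1` and a control series at
  least **100×** (package default) the size of the case series: the benign
  LR then rests entirely on the background-odds anchoring of a very
  asymmetric design, and deserves a flag.
- **Single case observation** — `k = 1`, see §3.4.

Flags never change numerical results; they are metadata for the analyst.

## 5. Numerical implementation

- **Log space end to end.** Reference scenarios span LRs from 1.6e−7 to
  1.3e19, and the individual tail areas underflow doubles far earlier. The
  LR is formed as a difference of log-areas; the linear `lr` field is `inf`
  past `exp(709)` while `log_lr`/`ep` stay exact.
- **Incomplete-beta differences without cancellation.** `I_hi − I_lo` is
  evaluated on the CDF side when the interval lies in the lower half of the
  beta distribution and on the survival side (`I_x(a,b) = 1 − I_{1−x}(b,a)`)
  otherwise, so neither term is near 1. If the difference still loses more
  than ~4 relative digits (ratio < 1e−4) or falls below 1e−280, it is
  recomputed with `mpmath`: endpoint-anchored intervals as a single tail
  integral (exact, no subtraction), interior intervals at escalating
  precision (60 → 1000 digits) until at least ~20 digits survive.
- **Stable OR→probability mapping** through `expit(log odds + log OR)`,
  accurate when the odds-OR product over/underflows.
- **Test oracle independence.** The incomplete-beta path is checked against
  adaptive tanh-sinh quadrature of the raw integrand (`mpmath.quad`) at
  escalating precision, agreeing to 1e−8 relative on hundreds of random
  scenarios — the oracle shares no code with the closed form.

## 6. Limitations

- **Autosomal dominant, monoallelic counting.** Carriers are counted per
  individual under a dominant model; recessive genotype-level evidence and
  X-linked dosage are out of scope.
- **Ascertainment and population matching are assumed.** The model takes
  the table at face value; confounding by ancestry mismatch between case
  and control series, or by ascertainment of cases through the variant
  itself, must be excluded upstream.
- **Flat integration measure.** The integrals weight `p` uniformly within
  each region; the LR is therefore a ratio of *average* likelihoods under
  an implicit uniform prior over each hypothesis region, and region
  parameterisation matters.
- **Non-carrier counts treated as fixed** when anchoring the background
  odds; negligible error for rare variants, increasingly questionable as
  carrier frequency grows.
- **Attenuation overshoot** on unbalanced designs under extreme targets
  (§3.2): the CI-attenuation option is conservative but not calibrated
  there.
- **Independence for additivity.** Summing EPs across studies is valid only
  for non-overlapping case and control series.
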