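# ps4lr

Quantitative case-control (PS4) evidence for germline variant classification,
computed as a likelihood ratio by integrating the binomial likelihood of the
observed carrier counts over competing odds-ratio hypotheses.

## The problem

Under the ACMG/AMP framework, the PS4 criterion awards evidence of
pathogenicity when a variant is significantly more frequent in affected
individuals than in controls. The traditional rule is categorical — observed
odds ratio ≥ 5 with a confidence interval excluding 1 yields "strong"
evidence, anything less yields nothing — which wastes information in small
studies, cannot produce graded or benign-direction evidence, and behaves
erratically for rare variants where the 2×2 table contains zero cells.

`ps4lr` replaces the categorical rule with a likelihood ratio that slots
directly into Bayesian evidence-point frameworks:

- **Graded evidence.** The LR is converted to evidence points
  (EP = log<sub>2.08</sub> LR), so a study can contribute supporting,
  moderate, strong, or very strong evidence — in either direction.
- **No minimum sample size.** Small studies simply yield LRs near 1.
- **Zero cells are fine.** No carriers in controls, or in cases, requires no
  continuity correction.
- **Additivity.** EPs from independently ascertained case-control series sum.

## The model

Let `k` be the variant carriers among the cases and `m` among the controls,
with `n = k + m` carriers in total. Conditional on being a carrier, the
probability `p` of belonging to the case series follows a binomial model:

```
L(p) = C(n, k) · p^k · (1 − p)^(n − k)
```

The background odds of being a case for a carrier under no association are
anchored on the observed non-carriers: `odds = case_non_carriers /
control_non_carriers`. A hypothesised odds ratio `OR` maps to a probability
threshold `p(OR) = odds·OR / (1 + odds·OR)`. Two hypotheses are compared:

- **Association**: the true OR is at least `or_assoc` (default 5), i.e.
  `p ∈ [p(or_assoc), 1]`.
- **No association**: the true OR is at most `or_nonassoc` (default 1), i.e.
  `p ∈ [0, p(or_nonassoc)]`.

The likelihood ratio is the ratio of the likelihood integrated over the two
regions. Both integrals have a closed form in the regularized incomplete beta
function `I_x(k+1, n−k+1)`, and all arithmetic is carried in log space — tail
areas routinely fall far below double-precision range while remaining
perfectly meaningful. Evidence strength bands sit at EP ±1 (supporting),
±2 (moderate), ±4 (strong) and ±8 (very strong).

Alongside the LR, every run reports the conventional frequentist columns
(observed OR, Woolf confidence interval, two-sided Fisher exact p, and the
categorical 2015-rule verdict) plus diagnostics: the fraction of likelihood
mass the two hypothesis regions actually capture ("occupancy"), and flags for
zero-case unbalanced tables and single case observations (for which
pathogenic-direction evidence is refused by default).

Conservatism options attenuate the evidence for weakly powered tables:
raising the opposing hypothesis's OR, replacing the target ORs by confidence
bounds of their expected estimates, and count-perturbation sensitivity
analysis.

## Worked example

Ten carriers among 10 000 breast-cancer cases versus two among 10 000
controls. The observed OR is 5.0, but the 95% CI (1.10–22.84) barely clears
1 — borderline for the categorical rule. The integrated LR gives graded
strong evidence:

```python
>>> from ps4lr import CaseControlCounts, TargetORPair, compute_lr
>>> result = compute_lr(CaseControlCounts(10, 10_000, 2, 10_000))
>>> round(result.lr, 2), round(result.ep, 2), result.strength.value
(33.28, 4.79, 'strong_pathogenic')
```

The same computation from the command line, with the frequentist columns:

```console
$ ps4lr calc -k 10 -N 10000 -m 2 -M 10000 --quiet
[
  {
    "label": "scenario",
    ...
    "frequentist": {
      "or_observed": 5.004004004004004,
      "ci_lower": 1.0961495800950705,
      "ci_upper": 22.84364882931064,
      "ci_level": 0.95,
      "ci_defined": true,
      "fisher_p": 0.0385178321416385,
      "acmg2015_verdict": "strong"
    },
    "lr": {
      "lr": 33.2794324888683,
      "log_lr": 3.5049395631894704,
      "ep": 4.785763539440329,
      "strength": "strong_pathogenic",
      "lr_display": "33.28",
      "ep_display": "4.8"
    },
    ...
  }
]
```

Batch mode takes a tab-separated table and emits one row per scenario:

```console
$ ps4lr batch scenarios.tsv --quiet | cut -f1,13,15,18
label	lr	ep	strength
BRCA2_c.9934A>G	33.279432488868302	4.7857635394403291	strong_pathogenic
rare_panel	586247.90342655708	18.135008561273974	very_strong_pathogenic
```

Reduced penetrance is handled by lowering the association target. Twelve
carriers in 10 000 cases versus six in 10 000 controls, judged against a
target OR of 2 (appropriate for a lower-penetrance gene), yields moderate
evidence:

```python
>>> result = compute_lr(CaseControlCounts(12, 10_000, 6, 10_000), TargetORPair(2, 1))
>>> round(result.lr, 2), round(result.ep, 2), result.strength.value
(5.49, 2.32, 'moderate_pathogenic')
```

Judged against a target OR of 4 instead, the same counts fall below the
supporting band — the choice of penetrance model matters and is explicit.

## Reproduction

Run the test suite (includes an acceptance suite reproducing the published
reference scenarios, plus property-based and oracle tests):

```console
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

One acceptance test is expected to fail: the property bundle asserts, among
properties that hold, that confidence-bound attenuation strictly shrinks
|EP| on *all* reference scenarios; this is false for the three rare-disease
scenarios evaluated under the OR ≥ 1000 hypothesis pair (see
`docs/methods.md`, "Attenuation overshoot"). All other tests pass.

Recompute the headline reference values from scratch:

```console
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The output maps target ids to `{"value": ..., "n": ...}` where `n` is the
carrier total the binomial likelihood is integrated over (e.g. `t1` →
33.28 with n = 12, `t11` → 1.30e19 with n = 25). The computation is
deterministic; `--seed` is accepted for interface uniformity.

## Package layout

| Module | Contents |
| --- | --- |
| `ps4lr.core` | background odds, OR→probability mapping, likelihood areas, LR/EP, strength bands |
| `ps4lr.frequentist` | observed OR, Woolf CI, Fisher exact p, categorical 2015-rule verdict |
| `ps4lr.conservatism` | opposing-hypothesis raising, CI attenuation of targets, sensitivity analysis, single-case rule |
| `ps4lr.diagnostics` | occupancy and warning flags |
| `ps4lr.fixtures` | built-in reference scenarios with printed expectations; random scenario generator |
| `ps4lr.batch` / `ps4lr.cli` | TSV/JSON batch runner, likelihood-curve export, `ps4lr` command line |

See `docs/methods.md` for the full methods note, including numerical choices
and limitations.
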