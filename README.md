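# bae — Bayesian Additional Evidence

Reverse-Bayes tipping-point analysis for effect estimates with high
uncertainty, aimed at researchers working with small samples — rare
diseases, biomarker-defined oncology cohorts, early real-world-evidence
studies — where a single analysis rarely settles a question on its own.

## The method

Given a normally-distributed estimate β̂ with standard error *se* (e.g. a
log hazard ratio from a Cox model), and a normal prior N(μ, s) for the true
effect, conjugacy gives a normal posterior N(μ_p, s_p) with

    1/s_p² = 1/se² + 1/s²          (precisions add)
    μ_p    = s_p² (μ/s² + β̂/se²)   (precision-weighted average)

and a central credible interval μ_p ± z·s_p. The evidence is *credible*
when that interval excludes the null (0 on the log scale, ratio 1 on the
reporting scale).

Bayesian Additional Evidence (BAE) inverts this update. Holding the prior
standard deviation *s* fixed, it solves for the **tipping point** μ\*: the
least extreme prior mean whose posterior credible interval just touches the
null. Because prior and data enter the update symmetrically, μ\* reads as
the estimate a hypothetical replication study (of precision *s*) would have
to observe:

- **Supportive scenario** (initial result non-significant): any replication
  result more extreme than μ\* makes the combined evidence credible. A
  tipping point within the range of plausible effects means the question is
  worth pursuing.
- **Opposing scenario** (initial result significant): any contrary result
  beyond μ\* destroys credibility (or establishes the opposite effect). A
  tipping point far beyond the null means the finding is robust.

No explicit prior is required — the output is compared against
domain-knowledge effect ranges instead. Setting *s* = *se* encodes "a
replication as precise as this analysis"; *s* = *se*/√X approximates a
study X times larger.

## Worked example

A comparative-effectiveness analysis in a small biomarker-defined cohort
estimates a hazard ratio of 0.42 with 95% CI (0.14, 1.23) — not
significant. From Python:

```python
from bae import (EffectEstimate, Scale, Direction, Scenario,
                 tipping_point, to_additive)

obs = to_additive(EffectEstimate(point=0.42, ci_lower=0.14, ci_upper=1.23,
                                 scale=Scale.HAZARD_RATIO))
res = tipping_point(obs, direction=Direction.LESS_THAN_NULL,
                    scenario=Scenario.SUPPORTIVE)
print(round(res.mu_star_reported, 2))   # 0.51
```

or from the shell:

```
bae tip --point 0.42 --ci 0.14 1.23 --scale hazard-ratio \
        --direction less --scenario supportive \
        --reference-prior 0.13 0.06 0.30
```

which prints (abridged):

```
Additive scale: beta = -0.867501, SE = 0.554379
Tipping point (hazard ratio scale): 0.51
posterior_at_tipping: hazard ratio 0.46 (0.22, 1.00) | additive -0.7683 (-1.5366, -0.0000)
Reference priors:
  [1] prior hazard ratio 0.13 (SD 0.4106) -> posterior (-2.2715, -0.9781): credible (negative); beyond the tipping point
```

Reading: a same-precision replication observing HR ≈ 0.51 or lower would
push the pooled 95% credible interval entirely below 1 (the
`posterior_at_tipping` interval touches 1.00 exactly, by construction).
Hazard ratios around 0.5 are not extreme for this comparison, and a
published study of the same question (HR 0.13, CI 0.06–0.30) already sits
beyond the tipping point — combined with the observed data it yields a
credible pooled interval (upper limit HR ≈ 0.38) — so gathering more data
is warranted.

The `examples/` directory holds one short script per capability
(supportive and opposing tipping points, the reference-prior check, the
√X study-size scan, and a Monte-Carlo calibration check).

## Scope

The package consumes (estimate, uncertainty) summaries only: fitting the
upstream survival/regression model is the caller's job. The sampling SD is
used as a plug-in (no prior on σ), priors and likelihoods are normal, and
the Wald interval convention is assumed when converting CIs and p-values to
standard errors. See `docs/methods.md` for assumptions, numerical choices
and limitations.
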