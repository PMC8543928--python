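# Methods

## Model

The package works entirely on the additive (analysis) scale. A reported
effect on a ratio scale — hazard, odds or risk ratio — is log-transformed;
identity-scale effects pass through. On that scale the estimator is taken
to be normal, `β̂ | β ~ N(β, se)`, where `se` is the composite sampling
standard deviation of the estimator (σ/√n in a parametric reading). The
sample size and per-observation σ never appear separately: the plug-in
estimate of the standard error stands in for both, which is the standard
Wald convention and the reason the method accepts any
normally-distributed estimator regardless of the model that produced it.

With a normal prior `β ~ N(μ, s)`, conjugacy gives the posterior
`N(μ_p, s_p)` with `1/s_p² = 1/se² + 1/s²` and
`μ_p = s_p²(μ/s² + β̂/se²)`. Credibility at level `1−α` means the central
posterior interval `μ_p ± z·s_p` strictly excludes 0. Prior and data are
symmetric in the update, which is what licenses reading the "prior" as a
hypothetical replication study.

## The tipping-point inversion

BAE fixes the prior SD `s` and solves for the prior mean μ\* at which the
credible-interval limit nearer the null equals 0. Two user inputs frame
the solve:

- **direction** — which side of the null holds the scientifically
  interesting effects. `less_than_null` (benefit on ratio scales) means
  the *upper* credible limit is the touching one; `greater_than_null`
  mirrors it. This is an analyst's choice; the CLI refuses to guess and
  requires the flag.
- **scenario** — `supportive` requires the observed Wald interval at the
  working level to include the null (a non-significant starting point);
  `opposing` requires it to exclude the null. A mismatch is a precondition
  error with a message pointing at the other scenario.

Because `s_p` does not depend on μ, the touching-limit equation is linear
in μ and has the closed form

    μ* = s² (∓ z/s_p − β̂/se²),

minus sign for `less_than_null`. The production path nevertheless solves
the equation numerically — root finding is the mechanism that extends to
non-conjugate posteriors — and the closed form is kept as an independent
oracle; tests require agreement to 1e−8 across a randomized grid of
configurations covering both directions and scenarios.

## Numerical choices

- **Root solve**: `scipy.optimize.brentq` with `xtol = 1e−12` on the
  touching credible limit as a function of the prior mean. The objective
  is strictly increasing (slope `s_p²/s² > 0`), so the root is unique.
- **Bracketing**: the initial bracket is `±(|β̂| + 20·max(se, s))`,
  doubled geometrically until the objective changes sign. A fixed bracket
  is not safe here: when the prior SD is large relative to the observed
  SE, μ\* scales like `s²·β̂/se²` and can sit orders of magnitude beyond
  any fixed multiple of the inputs. Monotonicity guarantees the expansion
  terminates; a cap of 80 doublings guards against degenerate input.
- **Boundary convention**: a credible limit exactly at 0 is classified
  *not* credible. The tipping point is thereby the first non-credible
  prior mean, and every mean strictly more extreme than μ\* is credible —
  the strict-inequality reading of the method's defining statements.
  Tests verify the classification flips across μ\* under a ±1e−6
  perturbation.
- **Quantiles**: all z-values come from the exact standard-normal inverse
  CDF, never a literal 1.96, so non-0.95 levels work uniformly. P-value
  inversion uses `norm.isf(p/2)` rather than `ppf(1 − p/2)` to keep
  precision for very small p-values.
- **CI precedence**: when an estimate carries both an interval and a
  p-value, the interval wins (it determines the SE without assuming which
  tail the p-value came from) and a warning is logged.
- **Levels**: one `cred_level` (default 0.95) serves both the Bayesian
  credibility level and the significance check of the scenario
  precondition, keeping the frequentist and Bayesian readings aligned.

## Parameters that matter

| parameter | meaning | default |
|---|---|---|
| `prior_s` | SD of the hypothetical replication, additive scale | observed `se` (a same-precision replication) |
| `size_multiplier` | encode a replication X times larger via `se/√X` | — |
| `cred_level` | credibility/significance level | 0.95 |
| `direction` | side of the null of scientific interest | required input |
| `scenario` | supportive (non-significant start) or opposing (significant start) | required input |

The √X scaling assumes the per-observation sampling SD is constant in the
sample size. In models where σ depends on the effect itself (Cox fits
among them) this is only approximate; outputs driven by a
`size_multiplier` are flagged as heuristic in the structured report.

The "plausibility" of effects beyond the tipping point — the quantity
that turns a tipping point into a decision — is a domain-knowledge
judgment. It is accepted as an optional flag and echoed into the
interpretation text; it is never computed.

## Synthetic data

The method consumes only (estimate, SE) summaries, so the simulation
module generates exactly that: draws from `N(true_beta, se)`, each tagged
with the known `se`, from one `numpy` generator seeded per call. This
emulates the sampling distribution of the estimator — the level at which
every property of the method lives — and deliberately not the survival
data underneath: censoring, delayed entry, covariate adjustment and the
σ–β dependence of proportional-hazards fits are upstream of the summary
interface. Passing tests therefore validate the inversion machinery and
its calibration, not the behaviour of any particular survival estimator.

The Monte-Carlo calibration check exploits the defining property of μ\*:
a replication truly centred at the tipping point lands beyond it with
probability exactly ½, so the posterior-credibility rate across simulated
replications must cross 0.5 there. The default check uses 20,000
replicates, putting the binomial standard error near 0.0035 — comfortably
inside the ±0.02 band the test asserts.

## Limitations

- Wald-interval logic throughout: standard errors recovered from
  profile-likelihood, bootstrap or exact small-sample intervals will be
  mis-calibrated. Symmetric intervals on the analysis scale are assumed.
- The plug-in standard error treats σ as known; a fully Bayesian
  treatment would place a prior on it.
- Normal prior and likelihood only; no non-conjugate extensions, no joint
  search over (μ, s), and no decision-theoretic layer.
- One estimate at a time: meta-analytic pooling across many studies is
  out of scope beyond the single reference-prior forward checks.
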