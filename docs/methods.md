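# Methods

## Model and procedure

All computations assume a normally distributed endpoint with known
standard deviation σ (default 1) and a one-sided testing convention.
The planning parameters are the standardized effect Δ = (μ_N − μ_C)/σ
(> 0; reference value 0.2), the one-sided level α (default 0.025) and
the target power 1 − β (default 0.80). Normal quantiles are computed by
`scipy.stats.norm` at full precision (z₀.₉₇₅ = 1.959964, not 1.96);
"about 400"-style figures come from a separate nearest-hundred
presentation helper and never feed back into planning math.

The threshold-crossing design replaces the concurrent control arm with
a fixed benchmark t derived from n_h historical controls:

| rule | t − (historical mean), in σ units |
|---|---|
| naive mean | 0 |
| CI upper | z₍₁₊γ₎⁄₂ / √n_h (γ default 0.95) |
| CI upper + cΔ | z₍₁₊γ₎⁄₂ / √n_h + cΔ, c ≥ 0 |

The trial is sized against the effect that survives the offset,
Δ_eff = Δ − offset, via n = ⌈(z₁₋α + z₁₋β)²/Δ_eff²⌉. The offset uses
the *known* planning σ (the deterministic half-width convention), not
the cohort's observed sd; `compute_threshold(use_observed_sd=True)`
exposes the alternative. When Δ_eff ≤ 0 the design is infeasible and a
typed `InfeasibleDesignError` is raised rather than returning infinity,
so scenario grids can record infeasible cells and continue.

All tests are known-variance z-tests (σ from the design parameters).
Ties at the critical value do not reject; this is a probability-zero
event fixed purely for determinism.

## Exact operating characteristics

Because t is a function of the historical sample mean, the design's
rejection probability must be taken marginally over the historical
sampling distribution. With the historical mean ~ N(μ_C, σ²/n_h), the
concurrent control mean μ_C + drift, and the true treatment mean
μ_C + drift + δσ, the one-sample test rejects with probability

    1 − Φ( (offset + z₁₋α/√n − δ − drift/σ) / √(1/n + 1/n_h) ).

δ = 0 gives the (possibly drifted) type-I error, δ = Δ the power.
Setting n_h = ∞ recovers the nominal α exactly. Two useful corollaries,
both asserted in the test suite: without drift the CI-upper rule keeps
the type-I error at or below α for every (n, n_h), since
z(u + v)/√(u² + v²) ≥ z for u, v > 0; and the naive rule's type-I error
is strictly decreasing in n_h toward α (0.1277 at n_h = 100, n = 197).

## Monte Carlo engine

`estimate_operating_characteristics` draws, per replicate, the
historical mean and the trial mean directly from their exact sampling
distributions N(μ, σ²/m). Since the reference test is a known-variance
z-test, the two sample means are sufficient; this is distributionally
identical to patient-level simulation and lets 10⁵-replicate cells run
in milliseconds. Patient-level generation (full normal vectors with
recomputed summaries) is kept in `simulate_historical_cohort` /
`simulate_single_arm_trial` for data-fixture and export purposes.
Every Monte Carlo record carries the closed-form probability alongside
the estimate and its binomial standard error √(p̂(1 − p̂)/R); agreement
within four standard errors is the engine's standing validation.

Seeding: one root seed per run; each grid cell derives an independent
child stream from `SeedSequence([root, *sha256(descriptors)])`, where
the descriptors are the cell's rule label, γ, n_h, drift, true effect,
historical mean and replicate count. Adding, removing or reordering
cells therefore never perturbs the draws of existing cells, and the
same configuration plus seed reproduces every output byte for byte.

Default replicate counts are 10⁵ for null (type-I) cells and 10⁴ for
power cells, chosen so the binomial standard error is ≈ 0.0005 at
p ≈ 0.025 and ≈ 0.004 at p ≈ 0.8. The default n_h grid
(150–5000) and drift values are package choices; the planned trial
size is deterministic per (rule, n_h) cell, not re-derived from each
simulated historical mean, matching the planning convention above.
The historical control mean defaults to 0: the whole problem is
location invariant, which a dedicated location-shift test asserts.

## Pooling multiple historical sources

Multi-source histories are pooled on the mean scale with
inverse-variance weights w_i = n_i/σ_i² (observed cohort sd when
recorded, planning σ otherwise). The random-effects variant uses the
DerSimonian–Laird moment estimator for the between-source variance
τ² = max(0, (Q − (k − 1))/(Σw − Σw²/Σw)) and re-weights by
1/(σ_i²/n_i + τ²). DL was chosen as the field's default
moment estimator and is deliberately isolated behind
`random_effects_pool` so a REML or Paule–Mandel variant could be
swapped in. The pooled estimate re-enters the threshold rules through
an effective sample size n_eff = σ²/se², floor-rounded (conservative:
a slightly wider CI) with a floor of 1.

## Multistage decision flow

Stage 1 classifies the completed single-arm trial: EFFECTIVE when the
one-sided lower (1 − α) confidence bound mean − z₁₋ασ/√n exceeds the
efficacy threshold (exactly the z-test rejection region; a
point-estimate crossing rule is available as an option), INEFFECTIVE
when the point estimate falls below the futility benchmark, PROMISING
otherwise. The futility benchmark defaults to the historical point
estimate — a sponsor-set quantity, so it is fully overridable, as is a
fixed numeric efficacy threshold. PROMISING results proceed per plan to
a conventional RCT against a freshly simulated concurrent control, to a
second single-arm trial reusing the stage-1 threshold with fresh data
only (stage-1 data are not pooled in), or to nothing (promising is then
terminal). No multiplicity adjustment is applied across stages by
default, so the program-level false-positive rate is bounded by
α₁ + α₂ (asserted by simulation); `split_alpha=True` halves both stage
levels instead.

## What the synthetic-data generator does and does not emulate

Generated cohorts are i.i.d. normal within source with a common known
σ — exactly the sampling model under which the closed forms hold. Real
historical controls additionally carry selection effects, covariate
imbalance, measurement heterogeneity and non-normal outcomes; passing
tests therefore demonstrate the *arithmetic* of the design (threshold
rules, sizes, error rates under the stated model and under mean drift),
not robustness of threshold-crossing trials to confounding or
like-with-unlike comparison, which no simulation under this model can
show. Drift enters only as a location shift of the concurrent control
mean; time trends within a trial are out of scope, as are binary and
survival endpoints, Bayesian borrowing, and covariate adjustment.

## Problem sizes

The shipped test suite and the acceptance script use 10⁴–10⁵ replicates
per Monte Carlo cell and n_h grids of four to six points — sizes at
which every quantity reported is stable to well under one Monte Carlo
standard error of its limit, while the whole suite runs in seconds on a
single CPU.
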