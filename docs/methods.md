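# Methods

This package implements a complete modelling stack for two-alternative
perceptual decisions made from two simultaneous motion sources: a synthetic
behavioural-data generator with the experiment's design structure, a
drift-diffusion model (DDM) core with its first-passage-time likelihood, a
hierarchical Bayesian fitter with DIC model comparison, an extended
two-population attractor (neural-mass) model, dual fixed-step staircases, and
the behavioural statistics around them.  Everything runs from synthetic data;
no downloads are required.

## Experimental structure being emulated

Two rectangular apertures of random-dot motion are tilted at ±θ (20° in one
group, 45° in the other).  Each subject completes 432 trials in 6 blocks of
72: per block, 16 trials of each of four task conditions plus 8 easy control
trials (60% coherence), half leftward / half rightward everywhere.  With
staircase-calibrated coherences c_low < c_high, the conditions are:

- **CON** (congruent, double source): c_low in one aperture, c_high − c_low in
  the other, same direction; net coherence c_high.
- **CON_BSL** (single source): c_high vs 0%; net c_high.
- **INC** (incongruent, double source): c_high vs −(c_high − c_low); net c_low.
- **INC_BSL** (single source): c_low vs 0%; net c_low.

Preprocessing removes responses faster than 250 ms and non-responses, drops
control trials from analysis, and excludes any subject whose task accuracy
over two consecutive blocks falls below 60% (the online early-termination
rule applied retrospectively — the sliding pairs (1,2), (2,3), …, (5,6) are
checked, and the block-pair accuracy is computed over task trials so that the
filter is idempotent).

## DDM core

The basic three-parameter DDM: evidence x(t) evolves as dx = v·dt + dW from
an unbiased start a/2 between absorbing boundaries 0 and a; RT = first
passage + Ter.  The diffusion scale is fixed at σ = 1 (the convention of the
hierarchical DDM toolboxes, so parameter magnitudes are directly comparable
to published posteriors; Ratcliff's s = 0.1 would rescale v and a by 10).
There are no inter-trial variability parameters and no bias (z = a/2).

Closed forms used as oracles throughout the tests: P(upper) = 1/(1+e^{−va})
(depends on the product va only) and mean decision time (a/2v)·tanh(va/2)
(limit a²/4 at v = 0).

**Simulation.**  Euler–Maruyama with dt = 1 ms.  Naive discrete boundary
checking has an O(√dt) first-passage bias (~15 ms at a = 2), which would
exceed Monte-Carlo error at the trial counts we use, so each step also draws
a Brownian-bridge crossing test with probabilities exp(−2(a−x₀)(a−x₁)/dt)
and exp(−2x₀x₁/dt); the remaining bias is O(dt) (RT is recorded at the step
end, ≤ 1 ms).  The per-trial step budget is ter-independent (the full 4-s
window is simulated and crossings later than t_max − Ter count as
non-responses), so a fixed seed yields identical diffusion paths under
different Ter — non-decision time is purely additive by construction.

**Likelihood.**  The Wiener first-passage density is evaluated by the
small-time and large-time series expansions, switching by the standard
fewest-terms criterion at truncation error 1e−7.  The data likelihood is a
mixture: with probability 5% a trial is an outlier, uniform over both
responses and the response window (0, 4 s] (density q/(2·t_max); the support
matches the response window since no support was otherwise specified).
Responses faster than Ter are explained by the outlier component alone.

## Synthetic cohorts

Subject-level parameters are drawn from group-level normals (a truncated
above 0.1, Ter to [0.05, 1]).  The default generative means emulate the
empirically observed pattern: drift reduced in CON relative to CON_BSL
(0.85 vs 1.05), threshold reduced in INC relative to INC_BSL (1.45 vs 1.60),
Ter constant (0.35 s); group SDs 0.30 / 0.20 / 0.05.  With the default
threshold these means put c_high near 83% accuracy and c_low near 74% — the
levels the staircase rules target.  The generative DDM sees only the net
signed evidence of a condition (the combined-coherence framing); the mapping
from coherence to drift is linear with gain 5 s⁻¹ per unit coherence, a
repository convention chosen only to give plausible structure (no such map
is claimed by the underlying study).  Control trials get drift 5 × 0.60 = 3
with the subject's average a and Ter; they exist to exercise the exclusion
filter and are dropped in analysis.

## Hierarchical Bayesian fitting

Four variants let two or all three of (v, a, Ter) vary between the four
conditions: v+a, v+Ter, a+Ter, v+a+Ter; parameters not varying are shared
across conditions within subject.  All parameters vary between subjects.

Priors (the toolbox's exact priors are not public, so these are weakly
informative choices spanning typical 2AFC fits): group means v ~ N(2, 3),
a ~ N(1.5, 1) truncated > 0.1, Ter ~ N(0.3, 0.25) truncated to [0.05, 1];
group SDs half-normal(1).

The sampler is component-wise random-walk Metropolis.  Subject-level
parameters are updated per (kind, condition) block, proposed simultaneously
for all subjects (valid because subjects are conditionally independent given
the group level); group means and SDs are scalar random walks against the
truncated-normal subject likelihood.  Proposal scales adapt every 50
iterations toward ~44% acceptance during burn-in only and are frozen
afterwards, preserving detailed balance.  Chains are deterministic under a
fixed seed.  Non-finite initializations are re-drawn (cap 100) before
failing.

The full protocol is 5 chains × 20,000 samples with 4,000 burn-in;
the package's recovery and model-comparison studies run a scaled budget of
3 chains × 4,000 draws (1,000 adaptive burn-in) on cohorts of 16 subjects ×
48 trials/condition, which converges (max R̂ < 1.1) in about half a minute
per variant on one CPU.  These problem sizes are the package's default study
sizes; the full budget remains available through the function arguments.

Diagnostics and comparison: the classic Gelman–Rubin potential scale
reduction (between/within-chain variance ratio, not the rank-normalized
split variant, to match the statistic the original workflow used) on all
group-level parameters; DIC = mean deviance + p_D with p_D = mean deviance −
deviance at the posterior mean of the subject-level parameters.  The
posterior hypothesis test P(x > y) is computed sample-wise on paired draws
(same chain and iteration) of the two group means; on identical draws this
gives exactly 0, and a `permuted` mode that compares independently shuffled
draws (≈ 0.5 for identical distributions) is provided since the non-overlap
operationalization is not uniquely pinned down.

## Neural-mass model

The reduced two-variable attractor model: NMDA gating variables S_L, S_R with

    dS/dt = −S/τ_s + (1 − S)·γ·H(x),   H(x) = (a_H x − b_H)/(1 − e^{−d_H(a_H x − b_H)})

and total input x_L = J_self·S_L − J_cross·S_R + I_in,L + I_noise,L.  The
two-source extension enters through the deterministic input currents

    I_in,L = J_ext[α·μ(1+c₁) + (1−α)·μ(1+c₂)] + β·I₀
    I_in,R = J_ext[α·μ(1−c₁) + (1−α)·μ(1−c₂)] + β·I₀

with J_ext = 5.2e−4 nA·Hz⁻¹, I₀ = 0.321 nA, μ = 35 Hz.  α ∈ [0, 1] splits
the sensory weight between the dominant (c₁) and weaker (c₂) source; the
weights always sum to μ, so with c₁ = c₂ the currents collapse exactly to
the single-source form for every α.  Equation-level identities (this
collapse and L/R antisymmetry under sign flips) are tested to machine
precision.  β multiplies the non-selective background current and is applied
only in the incongruent double-source condition (β = 1 elsewhere); since
I_in already contains β·I₀, no separate background term is added to x
(no double counting).  Baseline (single-source) conditions run through the
same equation with c₂ = 0 — this is what makes α = 0.5 behaviourally
equivalent to pure evidence summation, and is required for the α > 0.5
constraint to be meaningful.

Constants not fixed by the two-source extension use the published reduced
two-variable model defaults: a_H = 270 Hz/nA, b_H = 108 Hz, d_H = 0.154 s,
γ = 0.641, τ_s = 0.100 s, J_self = 0.2609 nA, J_cross = 0.0497 nA, OU noise
σ = 0.02 nA with τ = 2 ms, discretized as I += −(dt/τ)I + σ√(dt/τ)·N(0,1)
(the original formulation; stationary SD σ/√2).  Decision threshold 15 Hz on
the instantaneous rate H(x), symmetric initial gating S = 0.1, Euler dt =
0.5 ms, 4-s window, fixed 0.3-s non-decision offset (it cancels in every Δ).
Simultaneous threshold crossings in one step go to the larger rate; exact
ties are broken by the trial's random stream.  All constants are
configurable; with these defaults the model's absolute accuracies run higher
than human data at the same coherences, which is immaterial here because the
model is used only for qualitative regime mapping, never fitted to data.

**Regime classification.**  For each (α, β) cell, the four conditions are
simulated (default 5,000 trials each at c_high = 20%, c_low = 15%) and the
cell *qualifies* when acc(CON) < acc(CON_BSL), rt(CON) > rt(CON_BSL),
acc(INC) < acc(INC_BSL), rt(INC) < rt(INC_BSL).  A margin smaller than
1.645 Monte-Carlo standard errors of the difference is flagged
indeterminate; requiring all four margins to clear that one-sided 5% screen
makes a fully null cell (e.g. α = 0.5, β = 1, where the four conditions are
pairwise statistically identical) qualify with probability ~6e−6, while
costing little power at genuinely qualifying cells.

## Staircases

n-down/1-up staircases in log10 coherence: up step 0.1, down step 0.074
(ratio 0.74), start 31.6%, coherence clipped at 100% (run counter reset on
clipping).  A reversal is a level change whose direction differs from the
previous change, recorded at the turning level; the initial monotone descent
is not a reversal (the convention; the source procedure does not specify).
A run stops at 10 reversals and the threshold is the arithmetic mean of the
coherences at the last 9.  The 2-down and 3-down staircases interleave by
strict alternation (chosen for reproducibility; random interleaving is
available by flag), continuing singly after one terminates.

With the 0.74 step ratio the 2-down rule converges to the level where the
observer is ≈74% correct and the 3-down rule to ≈83%, a property of the
rule and step ratio rather than of the observer.  The validation observer is
a logistic psychometric function of log10 coherence with zero lapse
(P = 0.5 + 0.5/(1+e^{−slope·(log c − log c_mid)})), defaults c_mid = 0.12
(the 75% point) and slope 8 per log10 unit — smooth on the scale of the
steps, as the asymptote theory requires.  Asymptotic accuracy is measured by
running 200+ reversals, discarding the first half as transient, averaging
the late reversal levels in log10 coherence (the scale the procedure steps
on), and evaluating the observer's true P(correct) there.  Measured values
are ≈75.2% and ≈83.3% (the convergence targets are asymptotic limits; a
fixed-step procedure with a finite step size equilibrates slightly above the
2-down target).

## Behavioural statistics

Because every factor has two levels, the 2 (sources) × 2 (coherence) mixed
ANOVA with group between reduces exactly to OLS on per-subject contrast
scores with effect-coded group: the intercept tests the within effect
(Type III, unweighted group means), the group coefficient tests the
group × within interaction, and subject means give the between effect; each
F has (1, N−2) degrees of freedom.  Partial η² = SS_effect/(SS_effect +
SS_error).  This closed-form route is verified in tests against the paired-t
reduction and calibrated under the null (type-I error ≈ 5%).  RT summaries
pool correct and error trials (a correct/error split is available by flag).
Paired contrasts are classical paired t-tests; zero-variance differences are
reported as degenerate (t = 0, p = 1 when the difference is identically
zero; ±∞ otherwise) rather than erroring.  Power for the pre-registration
style claim is the exact noncentral-t power of a two-sided paired t-test
(noncentrality d√n, df n−1): at n = 44, d = 0.5, α = 0.05 it evaluates to
0.9000, cross-checked by Monte-Carlo in the tests.

## Known limitations

- The synthetic generator captures the design structure, DDM-consistent
  response distributions and the exclusion rules, but not sequential effects,
  learning/fatigue, lapses beyond the uniform outlier fraction, or any
  aperture-angle effect (none was observed empirically); passing tests
  therefore validate the pipeline's machinery, not claims about real data.
- The hierarchical priors and sampler differ from the original toolbox, so
  posterior scales need not match published figures; only recovery of
  generating parameters and model-ordering behaviour are claimed.
- The neural-mass constants may differ from the (unavailable) supplementary
  values; they are exposed in `NMParams` so they can be aligned later.
- The α = 0.5 sweep column is statistically indistinguishable from equal-
  weight summation by construction; tests treat it as a null, not a proof of
  optimal integration.
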