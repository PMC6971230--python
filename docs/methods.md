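# Methods

## Reward model and posterior update

The unit of observation for the bandit is the clinic-week. Clinic *c*'s
outcome under strategy *i* in week *t* is the pooled discussion fraction
p = Σy / Σn over the clinic's GPs (GP-weeks with n = 0 are excluded — the
fraction is undefined, and the reward model has no mass for empty weeks).
The reward r = p − p_c^baseline subtracts the clinic's own pooled baseline
fraction from the 2-week no-intervention stage, which removes static
clinic-level heterogeneity (patient mix, GP habits) before any modelling.

Rewards are treated as draws from N(μ_i, σ²) with σ = 1 and a conjugate
N(m₀, s₀²) prior per arm. The implementation uses the standard per-arm
conjugate update (precision n_i/σ² + 1/s₀², mean weighted by precisions),
restricted to the rewards actually observed for arm *i*. Posteriors are
always recomputed in batch from the full trial log rather than incrementally:
conjugacy makes the two identical (property-tested to 1e−10), and the batch
form makes ingestion idempotent and order-free, which is how late weekly
submissions are handled — a late record simply joins the history before the
next rebuild; nothing is imputed.

Note that σ = 1 is deliberately conservative relative to the true
clinic-week sampling noise (a binomial fraction over ~66 consultations has
sd ≈ 0.05). It slows posterior concentration but makes the procedure robust
to extra-binomial variation; the prior sd s₀ = 0.3 encodes that mean rewards
beyond ±1 are impossible (the N(0, 0.3) prior puts > 99.9% of its mass on
[−1, 1]).

## Allocation

Parallel Thompson sampling: each week one independent draw-and-argmax per
clinic, so one strategy can run at several clinics simultaneously. Draws are
recorded in the allocation plan for audit. Ties in the argmax (a
probability-zero event unless an arm's posterior is degenerate) are broken
uniformly at random. Every week draws from its own child RNG stream seeded by
(trial seed, week index), so a week's plan can be regenerated from a stored
log without replaying earlier weeks, and identical seeds give bit-identical
trials.

## Staged design

Fixed horizons: 2 baseline weeks, 7 adaptive weeks over all K = 8 arms, 3
confirmation weeks over the top k = 3 arms. Transitions are calendar-driven,
not data-driven; adaptive stopping is out of scope. Top-k selection ranks by
posterior mean alone (deterministic tie-break by strategy id); the t-test
results computed at stage-2 end are attached as evidence for the decision
record but do not enter the ranking, since posterior mean is the only totally
ordered per-arm quantity the design reports. The three stages sum to 12
global weeks; stage-relative week numbering is used in reports.

Confirmation-stage allocation is not dictated by the design logic, so it is
configurable: `restricted_thompson` (default — Thompson sampling over the
surviving k arms, continuous with the adaptive engine) or `balanced`
(rotating round-robin, giving per-arm weekly clinic counts that differ by at
most one, useful for power analysis). Posteriors continue to update during
confirmation; the alternative (freezing beliefs and only accumulating test
data) is noted but not implemented.

## Confirmatory statistics

Per strategy, the "paired" comparison is realised as a one-sample one-sided
t-test on per-GP-week differences: the GP-week discussion fraction minus that
GP's own baseline rate (the GP-level pooled baseline when the GP had relevant
baseline consultations, else the clinic baseline). The baseline is a fixed
pre-computed quantity rather than a contemporaneous paired arm, so this is
the only pairing the data structure supports. All post-baseline observations
of a strategy (adaptive and confirmation stages) enter its test. Differences
are treated as mutually independent across GPs and weeks — no clustering
correction — matching the design's stated assumption; the diagnostics below
exist to check it. Zero-variance difference vectors are flagged degenerate
(p = 0, 1 or 0.5 by the sign of the mean) and never tested further.
Multiplicity is handled by Bonferroni: each of the K tests runs at α/K
(0.05/8 = 0.00625, conventionally printed 0.006).

Strategies with fewer than two observed GP-weeks are reported untestable
(NaN statistics, never significant) rather than dropped, so the final table
always has one row per strategy and trial counts conserve the design total
(13 clinics × 10 intervention weeks = 130).

## Regret and the type-1 monitor

For synthetic runs, per clinic-week regret is max_i δ_i − δ_chosen; the trace
reports weekly sums, the cumulative R_T and the per-week average R_T/T.
Sublinear growth of R_T (decreasing average) is the convergence signature of
Thompson sampling and is exercised at a 50-week horizon in the acceptance
checks.

Because response-adaptive allocation can inflate the type-1 error rate (weak
arms are starved, and the selected arms carry a winner's-curse bias), the
package ships a monitor that replays the entire pipeline on all-null
scenarios and reports the family-wise significant-call rate with a 95%
Clopper–Pearson interval. It is a measurement instrument, not a guarantee:
observed rates modestly above the nominal α are expected and are the reason
the monitor exists.

## Diagnostics

Two declared checks stand in for the design's informal assumption audit;
both are intentionally simple and their thresholds configurable:

- **Stationarity** — per strategy, the least-squares slope of clinic-week
  outcome fraction on week index, flagged when its p-value < 0.05. A linear
  drift of +0.02/week injected by the generator is detected in the majority
  of replicates at a 10-week horizon.
- **Independence** — within each multi-GP clinic, Pearson correlations of the
  GPs' weekly outcome residuals (fraction minus the strategy's overall mean
  fraction), flagged when |r| > 0.5. Not evaluable with single-GP clinics or
  fewer than three shared weeks.

## Synthetic cohort

The generator emulates the structure the analysis assumes: 13 clinics × 2
GPs; per-GP latent baseline rates ~ N(0.18, 0.04²) clipped to [0.01, 0.99]
(the 0.18 centre reflects that under one in five consultations touches on
the behaviour; the 0.04 spread across GPs is a modelling choice, exposed
prominently, not an empirical estimate); relevant consultations per GP-week
~ Poisson(33), calibrated so a 13-week trial yields ≈ 11,200 relevant
conversations in total; discussion counts ~ Binomial(n, clip(gp_rate + δ +
drift·week + clinic effect)). Strategy effects are additive on the
probability scale with clipping — the simplest model consistent with the
additive reward definition; a logistic-scale alternative was considered and
not built. Inappropriate consultations are generated (Poisson with mean set
by the 5% share of total appointments) and carried through I/O but never
enter any outcome.

The `within_clinic_correlation` knob adds a shared clinic-week Gaussian
effect to GP probabilities before clipping, with sd chosen as
sqrt(v·ρ/(1−ρ)) where v is the binomial fraction variance at the baseline
rate, so the induced between-GP correlation of weekly fractions approximates
the requested ρ. Default 0 matches the independence assumption.

What the generator does **not** model: patient covariates, GP learning or
fatigue beyond the linear drift knob, week-to-week volume seasonality,
reporting errors, and clinic-level (as opposed to GP-level) baseline
clustering. Passing tests therefore show that the pipeline is correct and
well-calibrated under its own assumptions, not that those assumptions hold
in any particular real deployment.

## Problem sizes and numerical choices

Monte-Carlo suites use 200 replicates of the 12-week default trial (a single
trial takes ~10 ms), 200 replicates of a 50-week adaptive horizon for regret
decay, and 200 null replicates for the error monitor. The quadrature oracle
for the posterior integrates on 250,001 grid points over [−2.5, 2.5], ample
for 1e−6 agreement. Probabilities are clipped to [0.01, 0.99] so binomial
draws never degenerate; posterior arithmetic is closed-form and needs no
iteration. All randomness flows from explicit integer seeds through
numpy `SeedSequence` children keyed by purpose (cohort, weekly tallies,
weekly allocation), which is what makes replay and file round-trips
byte-stable.
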