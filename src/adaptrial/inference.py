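"""Confirmatory statistics, regret accounting and model diagnostics.

The confirmatory analysis asks, per strategy, whether GP-week discussion
fractions under that strategy exceeded each GP's own no-intervention baseline:
a one-sample, one-sided t-test on the per-GP-week differences, with a
Bonferroni-corrected significance threshold across the strategy family.

Regret accounting (synthetic runs only, where the true effects are known)
measures how much allocation quality the bandit gave up relative to always
playing the best arm; diagnostics probe the two standing assumptions of the
reward model — effect stationarity over time and GP independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    InsufficientDataError,
    UnsupportedOperationError,
    ValidationError,
)
from .trial_core import (
    BASELINE_STRATEGY,
    ClinicProfile,
    Stage,
    TrialLog,
)


@dataclass(frozen=True)
class TestResult:
    """One strategy's row of the final statistics table."""

    strategy_id: str
    mean_difference: float
    standard_error: float
    t_statistic: float
    degrees_freedom: int
    p_value: float
    corrected_threshold: float
    significant: bool
    trial_count: int
    degenerate: bool = False
    testable: bool = True


@dataclass
class RegretTrace:
    """Per-week and cumulative allocation regret against the true best arm."""

    horizon: int
    per_week_regret: list[float]
    cumulative: float
    average: float


@dataclass
class DiagnosticReport:
    """Assumption checks: per-strategy time trends and between-GP correlations."""

    stationarity: dict[str, tuple[float, float]] = field(default_factory=dict)
    stationarity_flags: list[str] = field(default_factory=list)
    stationarity_evaluable: bool = True
    independence_correlations: list[tuple[str, str, str, float, int]] = field(
        default_factory=list
    )
    independence_flags: list[tuple[str, str, str, float]] = field(default_factory=list)
    independence_evaluable: bool = True


def bonferroni_threshold(alpha_family: float, n_tests: int) -> float:
    """Per-test significance threshold controlling the family-wise error rate."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    if not 0.0 < alpha_family < 1.0:
        raise ValidationError("alpha_family must lie in (0, 1)")
    return alpha_family / n_tests


def one_sided_paired_t_test(
    differences: Sequence[float],
    strategy_id: str = "",
    corrected_threshold: float = 0.05,
    trial_count: int = 0,
) -> TestResult:
    """One-sample one-sided t-test of mean(differences) > 0.

    ``differences`` are per-GP-week discussion fractions minus that GP's own
    baseline rate; under H0 the strategy does not beat baseline. Zero-variance
    inputs are flagged degenerate, with p set to 0, 1 or 0.5 by the sign of
    the mean.
    """
    d = np.asarray(list(differences), dtype=float)
    if d.size < 2:
        raise InsufficientDataError(
            f"t-test needs >= 2 differences, got {d.size} (strategy {strategy_id!r})"
        )
    if not np.all(np.isfinite(d)):
        raise ValidationError("non-finite difference values")
    n = int(d.size)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        p = 0.0 if mean > 0 else (1.0 if mean < 0 else 0.5)
        t_stat = math.inf if mean > 0 else (-math.inf if mean < 0 else 0.0)
        return TestResult(
            strategy_id=strategy_id,
            mean_difference=mean,
            standard_error=0.0,
            t_statistic=t_stat,
            degrees_freedom=df,
            p_value=p,
            corrected_threshold=corrected_threshold,
            significant=p < corrected_threshold,
            trial_count=trial_count,
            degenerate=True,
        )
    se = sd / math.sqrt(n)
    t_stat = mean / se
    p = float(stats.t.sf(t_stat, df))
    return TestResult(
        strategy_id=strategy_id,
        mean_difference=mean,
        standard_error=se,
        t_statistic=t_stat,
        degrees_freedom=df,
        p_value=p,
        corrected_threshold=corrected_threshold,
        significant=p < corrected_threshold,
        trial_count=trial_count,
    )


def gp_week_differences(
    log: TrialLog, clinics: Mapping[str, ClinicProfile], strategy_id: str
) -> list[float]:
    """Per-GP-week outcome fractions under the strategy minus the GP's baseline.

    GP-level baselines are used when that GP had relevant baseline
    consultations; the clinic baseline is the fallback. GP-weeks with zero
    relevant consultations are excluded.
    """
    diffs: list[float] = []
    for r in log.records:
        if r.strategy_id != strategy_id or r.stage is Stage.BASELINE:
            continue
        if r.relevant_count == 0:
            continue
        clinic = clinics[r.clinic_id]
        baseline = clinic.gp_baseline_rates.get(r.gp_id, clinic.baseline_rate)
        if baseline is None:
            raise ValidationError(f"clinic {r.clinic_id} baseline unset")
        diffs.append(r.discussed_count / r.relevant_count - baseline)
    return diffs


def final_statistics_table(
    log: TrialLog,
    clinics: Mapping[str, ClinicProfile],
    arms: Sequence[str],
    alpha_family: float = 0.05,
) -> list[TestResult]:
    """One TestResult per strategy, sorted by mean difference descending.

    Trial counts are cumulative clinic-week allocations of the strategy over
    the whole trial. Strategies never allocated (or with fewer than two
    observed GP-weeks) are included with NaN statistics and flagged
    untestable; untestable rows sort to the bottom.
    """
    threshold = bonferroni_threshold(alpha_family, len(arms))
    pulls = log.pull_counts()
    rows: list[TestResult] = []
    for arm in arms:
        diffs = gp_week_differences(log, clinics, arm)
        count = pulls.get(arm, 0)
        if len(diffs) < 2:
            rows.append(
                TestResult(
                    strategy_id=arm,
                    mean_difference=math.nan,
                    standard_error=math.nan,
                    t_statistic=math.nan,
                    degrees_freedom=max(len(diffs) - 1, 0),
                    p_value=math.nan,
                    corrected_threshold=threshold,
                    significant=False,
                    trial_count=count,
                    testable=False,
                )
            )
            continue
        rows.append(
            one_sided_paired_t_test(
                diffs, strategy_id=arm, corrected_threshold=threshold, trial_count=count
            )
        )
    rows.sort(
        key=lambda r: (
            not r.testable,
            -(r.mean_difference if r.testable else -math.inf),
            r.strategy_id,
        )
    )
    return rows


def compute_regret(log: TrialLog, true_effects: Mapping[str, float]) -> RegretTrace:
    """Cumulative regret of the realised allocations against the true best arm.

    Per clinic-week regret is max_i delta_i minus the chosen arm's delta,
    summed over clinics within a week; ``average`` is the cumulative regret
    divided by the number of allocation weeks. Requires ground truth, so this
    is defined for synthetic runs only.
    """
    if not true_effects:
        raise UnsupportedOperationError(
            "regret requires known true effects (synthetic runs only)"
        )
    best = max(true_effects.values())
    weekly: dict[int, float] = {}
    for (clinic_id, week), sid in log.allocations.items():
        if sid == BASELINE_STRATEGY:
            continue
        if sid not in true_effects:
            raise UnsupportedOperationError(
                f"no true effect recorded for strategy {sid!r}"
            )
        weekly[week] = weekly.get(week, 0.0) + (best - true_effects[sid])
    weeks = sorted(weekly)
    per_week = [weekly[w] for w in weeks]
    cumulative = float(sum(per_week))
    horizon = len(weeks)
    return RegretTrace(
        horizon=horizon,
        per_week_regret=per_week,
        cumulative=cumulative,
        average=cumulative / horizon if horizon else 0.0,
    )


def run_diagnostics(
    log: TrialLog,
    slope_alpha: float = 0.05,
    corr_threshold: float = 0.5,
    min_points: int = 3,
) -> DiagnosticReport:
    """Check effect stationarity and between-GP independence on the trial log.

    Stationarity: per strategy, the least-squares slope of the clinic-week
    outcome fraction on week index; a slope with p < ``slope_alpha`` flags the
    strategy. Independence: within each multi-GP clinic, Pearson correlations
    of the two GPs' weekly outcome residuals (fraction minus the strategy's
    overall mean fraction); |r| > ``corr_threshold`` flags the pair.
    """
    report = DiagnosticReport()

    # --- stationarity: outcome fraction vs week, per strategy -------------
    by_strategy: dict[str, list[tuple[int, float]]] = {}
    for o in log.outcomes:
        by_strategy.setdefault(o.strategy_id, []).append((o.week_index, o.outcome_fraction))
    any_evaluated = False
    for sid, pts in sorted(by_strategy.items()):
        weeks = np.array([w for w, _ in pts], dtype=float)
        fracs = np.array([f for _, f in pts], dtype=float)
        if len(pts) < min_points or len(set(weeks.tolist())) < 2:
            continue
        res = stats.linregress(weeks, fracs)
        report.stationarity[sid] = (float(res.slope), float(res.pvalue))
        any_evaluated = True
        if res.pvalue < slope_alpha:
            report.stationarity_flags.append(sid)
    report.stationarity_evaluable = any_evaluated

    # --- independence: residual correlations between GPs within clinic ----
    strat_mean: dict[str, float] = {}
    strat_fracs: dict[str, list[float]] = {}
    gp_series: dict[tuple[str, str], dict[int, tuple[str, float]]] = {}
    for r in log.records:
        if r.stage is Stage.BASELINE or r.relevant_count == 0:
            continue
        frac = r.discussed_count / r.relevant_count
        strat_fracs.setdefault(r.strategy_id, []).append(frac)
        gp_series.setdefault((r.clinic_id, r.gp_id), {})[r.week_index] = (
            r.strategy_id,
            frac,
        )
    strat_mean = {s: float(np.mean(v)) for s, v in strat_fracs.items()}

    clinic_gps: dict[str, list[str]] = {}
    for clinic_id, gp_id in gp_series:
        clinic_gps.setdefault(clinic_id, []).append(gp_id)
    any_pair = False
    for clinic_id, gps in sorted(clinic_gps.items()):
        gps = sorted(gps)
        for i in range(len(gps)):
            for j in range(i + 1, len(gps)):
                s1 = gp_series[(clinic_id, gps[i])]
                s2 = gp_series[(clinic_id, gps[j])]
                common = sorted(set(s1) & set(s2))
                if len(common) < min_points:
                    continue
                r1 = np.array([s1[w][1] - strat_mean[s1[w][0]] for w in common])
                r2 = np.array([s2[w][1] - strat_mean[s2[w][0]] for w in common])
                if r1.std() == 0 or r2.std() == 0:
                    continue
                corr = float(stats.pearsonr(r1, r2).statistic)
                any_pair = True
                report.independence_correlations.append(
                    (clinic_id, gps[i], gps[j], corr, len(common))
                )
                if abs(corr) > corr_threshold:
                    report.independence_flags.append((clinic_id, gps[i], gps[j], corr))
    report.independence_evaluable = any_pair
    return report


@dataclass(frozen=True)
class ErrorMonitorResult:
    """Estimated family-wise significant-call rate under a null scenario."""

    rate: float
    ci_low: float
    ci_high: float
    n_replicates: int
    n_significant: int


def type_one_error_monitor(
    config,
    prior,
    null_spec,
    n_replicates: int,
    seed: int,
) -> ErrorMonitorResult:
    """Estimate the family-wise error rate by replaying the pipeline under the null.

    Runs the full staged trial ``n_replicates`` times on scenarios where every
    true effect is zero and reports the fraction of replicates in which any
    strategy clears the Bonferroni threshold, with a 95% Clopper-Pearson CI.
    """
    from .staged_design import run_trial
    from .synthetic_cohort import ScenarioSpec, TrialStream

    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if any(v != 0.0 for v in null_spec.true_effects.values()):
        raise ValidationError("type-1 monitor requires a null scenario (all effects 0)")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(n_replicates, 2))
    n_sig = 0
    for scen_seed, trial_seed in rep_seeds:
        spec = ScenarioSpec(**{**null_spec.__dict__, "seed": int(scen_seed)})
        stream = TrialStream(spec)
        state = run_trial(
            config, prior, stream.cohort.clinics, spec.arms, stream, int(trial_seed)
        )
        table = final_statistics_table(
            state.log, state.clinics, state.arms, config.alpha_family
        )
        if any(row.significant for row in table):
            n_sig += 1
    lo, hi = proportion_confint(n_sig, n_replicates, alpha=0.05, method="beta")
    return ErrorMonitorResult(
        rate=n_sig / n_replicates,
        ci_low=float(lo),
        ci_high=float(hi),
        n_replicates=n_replicates,
        n_significant=n_sig,
    )
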