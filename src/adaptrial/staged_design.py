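"""Orchestration of the three-stage trial.

Stage 1 collects no-intervention baseline tallies for every clinic; Stage 2
runs parallel Thompson sampling over all K strategies for a fixed number of
weeks; Stage 3 restricts allocation to the top-k strategies (ranked by
posterior mean) for a further fixed window to raise the power of the final
hypothesis tests. Stage transitions happen on the configured horizons, never
on a data-driven stopping rule.

A *tally source* is any callable ``source(week_index, stage, assignments) ->
list[ConsultationTally]`` where ``assignments`` maps clinic_id to the strategy
to run that week (the baseline sentinel during Stage 1). The synthetic cohort
module provides one; a thin file-reading adapter provides another for real
data entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .bandit_engine import (
    AllocationPlan,
    ArmPosterior,
    ArmPrior,
    allocate_week,
    ingest_week,
    recompute_posteriors,
    thompson_draw,
)
from .errors import StageOrderError, ValidationError
from .trial_core import (
    BASELINE_STRATEGY,
    ClinicProfile,
    ConsultationTally,
    Stage,
    TrialLog,
    compute_clinic_baseline,
    compute_gp_baselines,
)

TallySource = Callable[[int, Stage, Mapping[str, str]], Sequence[ConsultationTally]]


@dataclass(frozen=True)
class StageConfig:
    """Fixed horizons and decision parameters of the staged design."""

    n_baseline_weeks: int = 2
    n_adaptive_weeks: int = 7
    n_confirmation_weeks: int = 3
    n_strategies: int = 8
    top_k: int = 3
    alpha_family: float = 0.05
    confirmation_allocation_mode: str = "restricted_thompson"

    def __post_init__(self) -> None:
        if min(self.n_baseline_weeks, self.n_adaptive_weeks, self.n_confirmation_weeks) < 1:
            raise ValidationError("all stage lengths must be >= 1 week")
        if not 1 <= self.top_k <= self.n_strategies:
            raise ValidationError("top_k must satisfy 1 <= top_k <= n_strategies")
        if not 0.0 < self.alpha_family < 1.0:
            raise ValidationError("alpha_family must lie in (0, 1)")
        if self.confirmation_allocation_mode not in ("restricted_thompson", "balanced"):
            raise ValidationError(
                f"unknown confirmation mode {self.confirmation_allocation_mode!r}"
            )

    @property
    def total_weeks(self) -> int:
        return self.n_baseline_weeks + self.n_adaptive_weeks + self.n_confirmation_weeks


@dataclass
class PosteriorSnapshot:
    """One arm's belief at the end of one week (a row of the trajectory table)."""

    week_index: int
    strategy_id: str
    post_mean: float
    post_sd: float
    n_obs: int
    cumulative_pulls: int


@dataclass
class TrialState:
    """Everything the orchestrator carries between weeks."""

    config: StageConfig
    prior: ArmPrior
    clinics: dict[str, ClinicProfile]
    arms: list[str]
    seed: int
    stage: Stage = Stage.BASELINE
    week_index: int = 0
    active_arms: list[str] = field(default_factory=list)
    log: TrialLog = field(default_factory=TrialLog)
    posteriors: dict[str, ArmPosterior] = field(default_factory=dict)
    snapshots: list[PosteriorSnapshot] = field(default_factory=list)
    plans: list[AllocationPlan] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.log.horizon = self.config.total_weeks
        if not self.posteriors:
            self.posteriors = recompute_posteriors(self.log, self.prior, self.arms)


def _week_rng(seed: int, week_index: int) -> np.random.Generator:
    # Child stream per week: reproducible given (seed, week) alone, so a plan
    # can be regenerated from a stored log without replaying earlier draws.
    return np.random.default_rng(np.random.SeedSequence([seed, week_index]))


def _snapshot(state: TrialState) -> None:
    pulls = state.log.pull_counts(up_to_week=state.week_index)
    for arm in state.arms:
        p = state.posteriors[arm]
        state.snapshots.append(
            PosteriorSnapshot(
                week_index=state.week_index,
                strategy_id=arm,
                post_mean=p.post_mean,
                post_sd=p.post_sd,
                n_obs=p.n_obs,
                cumulative_pulls=pulls.get(arm, 0),
            )
        )


def run_baseline(state: TrialState, source: TallySource) -> dict[str, float]:
    """Collect the no-intervention weeks and fix every clinic's baseline rate.

    Returns the clinic_id -> baseline_rate map and advances the trial to the
    adaptive stage. A clinic with zero relevant consultations across the whole
    stage raises a baseline-undefined error naming the clinic.
    """
    if state.stage is not Stage.BASELINE:
        raise StageOrderError(f"run_baseline called in stage {state.stage.value}")
    assignments = {cid: BASELINE_STRATEGY for cid in state.clinics}
    for _ in range(state.config.n_baseline_weeks):
        state.week_index += 1
        week_tallies = list(source(state.week_index, Stage.BASELINE, assignments))
        for clinic_id in state.clinics:
            for t in week_tallies:
                if t.stage is not Stage.BASELINE:
                    raise ValidationError("baseline stage received non-baseline tallies")
        state.log.records.extend(week_tallies)
        for cid in state.clinics:
            state.log.add_allocation(cid, state.week_index, BASELINE_STRATEGY)

    baselines: dict[str, float] = {}
    baseline_records = [r for r in state.log.records if r.stage is Stage.BASELINE]
    for cid, clinic in state.clinics.items():
        own = [r for r in baseline_records if r.clinic_id == cid]
        clinic.baseline_rate = compute_clinic_baseline(own, cid)
        clinic.gp_baseline_rates = compute_gp_baselines(own)
        baselines[cid] = clinic.baseline_rate
    state.stage = Stage.ADAPTIVE
    state.active_arms = list(state.arms)
    return baselines


def _run_allocation_weeks(
    state: TrialState,
    source: TallySource,
    n_weeks: int,
    stage: Stage,
    arms: Sequence[str],
) -> None:
    restricted = {a: None for a in arms}  # preserves order, fast membership
    for _ in range(n_weeks):
        state.week_index += 1
        rng = _week_rng(state.seed, state.week_index)
        if stage is Stage.CONFIRMATION and state.config.confirmation_allocation_mode == "balanced":
            plan = _balanced_plan(state, arms, state.week_index)
        else:
            posts = {a: state.posteriors[a] for a in restricted}
            plan = allocate_week(
                posts,
                list(state.clinics.values()),
                state.week_index,
                rng,
                seed_token=f"seed={state.seed},week={state.week_index}",
            )
        tallies = list(source(state.week_index, stage, plan.assignments))
        state.posteriors = ingest_week(
            state.log, plan, tallies, state.clinics, state.prior, state.arms
        )
        state.plans.append(plan)
        _snapshot(state)


def _balanced_plan(state: TrialState, arms: Sequence[str], week_index: int) -> AllocationPlan:
    # Round-robin over the surviving arms, rotating the offset weekly so the
    # per-arm clinic counts differ by at most one and even out across weeks.
    clinic_ids = sorted(state.clinics)
    k = len(arms)
    assignments = {
        cid: arms[(j + week_index) % k] for j, cid in enumerate(clinic_ids)
    }
    return AllocationPlan(week_index=week_index, assignments=assignments)


def run_adaptive_stage(state: TrialState, source: TallySource) -> TrialState:
    """Stage 2: parallel Thompson sampling over all strategies, week by week."""
    if state.stage is not Stage.ADAPTIVE:
        raise StageOrderError(f"run_adaptive_stage called in stage {state.stage.value}")
    _run_allocation_weeks(
        state, source, state.config.n_adaptive_weeks, Stage.ADAPTIVE, state.active_arms
    )
    return state


def select_top_k(
    posteriors: Mapping[str, ArmPosterior],
    k: int,
    test_results: Sequence | None = None,
) -> list[str]:
    """Rank arms by posterior mean (descending) and return the top k.

    Exact ties are broken deterministically by strategy_id. Hypothesis-test
    results, when supplied, ride along as evidence for the human decision
    record; they do not enter the ranking.
    """
    if k > len(posteriors):
        raise ValidationError(f"k={k} exceeds the number of arms ({len(posteriors)})")
    ranked = sorted(posteriors.values(), key=lambda p: (-p.post_mean, p.strategy_id))
    return [p.strategy_id for p in ranked[:k]]


def run_confirmation_stage(state: TrialState, source: TallySource) -> TrialState:
    """Stage 3: allocate only among the surviving top-k arms.

    Posteriors continue to update throughout; confirmation data also feed the
    final hypothesis tests.
    """
    if state.stage is not Stage.ADAPTIVE:
        raise StageOrderError(
            f"run_confirmation_stage called in stage {state.stage.value}"
        )
    state.active_arms = select_top_k(state.posteriors, state.config.top_k)
    state.stage = Stage.CONFIRMATION
    _run_allocation_weeks(
        state,
        source,
        state.config.n_confirmation_weeks,
        Stage.CONFIRMATION,
        state.active_arms,
    )
    return state


def replay_tallies(
    config: StageConfig,
    prior: ArmPrior,
    tallies: Sequence[ConsultationTally],
    seed: int = 0,
    arms: Sequence[str] | None = None,
) -> TrialState:
    """Reconstruct a TrialState by replaying recorded tallies week by week.

    Clinic rosters, baselines, the allocation map, outcomes, posteriors and
    snapshots are all rebuilt from the tally file alone, so a stored trial can
    be re-analysed (or continued) without any other state.
    """
    rosters: dict[str, set[str]] = {}
    for t in tallies:
        rosters.setdefault(t.clinic_id, set()).add(t.gp_id)
    clinics = {
        cid: ClinicProfile(clinic_id=cid, gp_roster=frozenset(gps))
        for cid, gps in rosters.items()
    }
    baseline_tallies = [t for t in tallies if t.stage is Stage.BASELINE]
    rest = [t for t in tallies if t.stage is not Stage.BASELINE]
    if arms is None:
        arms = sorted({t.strategy_id for t in rest})
    state = TrialState(
        config=config,
        prior=prior,
        clinics=clinics,
        arms=sorted(arms),
        seed=seed,
    )
    state.log.records.extend(baseline_tallies)
    for cid, clinic in clinics.items():
        own = [t for t in baseline_tallies if t.clinic_id == cid]
        if own:
            clinic.baseline_rate = compute_clinic_baseline(own, cid)
            clinic.gp_baseline_rates = compute_gp_baselines(own)
            state.log.add_allocation(
                cid, max(t.week_index for t in own), BASELINE_STRATEGY
            )
    baseline_weeks = {t.week_index for t in baseline_tallies}
    for cid in clinics:
        for w in baseline_weeks:
            state.log.add_allocation(cid, w, BASELINE_STRATEGY)
    state.week_index = max(baseline_weeks, default=0)
    state.stage = Stage.ADAPTIVE
    state.active_arms = list(state.arms)

    by_week: dict[int, list[ConsultationTally]] = {}
    for t in rest:
        by_week.setdefault(t.week_index, []).append(t)
    for week in sorted(by_week):
        week_tallies = by_week[week]
        assignments: dict[str, str] = {}
        for t in week_tallies:
            prev = assignments.setdefault(t.clinic_id, t.strategy_id)
            if prev != t.strategy_id:
                raise ValidationError(
                    f"clinic {t.clinic_id} week {week} mixes strategies "
                    f"{prev!r} and {t.strategy_id!r}"
                )
        plan = AllocationPlan(week_index=week, assignments=assignments)
        state.posteriors = ingest_week(
            state.log, plan, week_tallies, state.clinics, state.prior, state.arms
        )
        state.week_index = max(state.week_index, week)
        state.plans.append(plan)
        _snapshot(state)
        if any(t.stage is Stage.CONFIRMATION for t in week_tallies):
            state.stage = Stage.CONFIRMATION
    return state


def run_trial(
    config: StageConfig,
    prior: ArmPrior,
    clinics: Sequence[ClinicProfile],
    arms: Sequence[str],
    source: TallySource,
    seed: int,
) -> TrialState:
    """Run the full staged trial end to end and return the final state.

    Deterministic: identical (config, prior, clinics, arms, source, seed)
    reproduce identical allocations, posteriors and snapshots.
    """
    state = TrialState(
        config=config,
        prior=prior,
        clinics={c.clinic_id: c for c in clinics},
        arms=sorted(arms),
        seed=seed,
    )
    run_baseline(state, source)
    run_adaptive_stage(state, source)
    run_confirmation_stage(state, source)
    return state
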