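"""Gaussian Thompson sampling: posterior maintenance and weekly allocation.

Each strategy (arm) carries a Gaussian belief over its true mean reward
``mu_i``. Rewards are modelled as ``r = mu_i + eps`` with i.i.d. Gaussian noise
``eps ~ N(0, sigma^2)``; the prior ``N(m0, s0^2)`` is conjugate, so after n
observations of the arm with reward sum S the posterior is

    precision = n / sigma^2 + 1 / s0^2
    mean      = (S / sigma^2 + m0 / s0^2) / precision
    sd        = precision ** -0.5

Defaults m0 = 0, s0 = 0.3 place >99.9% prior mass on rewards in [-1, 1];
the observation noise sd defaults to 1.

Weekly allocation is *parallel* Thompson sampling: one independent draw-and-
argmax per clinic, so a strong arm may run at several clinics at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    AllocationIntegrityError,
    DuplicateWeekError,
    ValidationError,
)
from .trial_core import (
    BASELINE_STRATEGY,
    ClinicProfile,
    ConsultationTally,
    OutcomeRecord,
    TrialLog,
    clinic_week_outcome,
    compute_reward,
)


@dataclass(frozen=True)
class ArmPrior:
    """Shared prior for every arm's mean reward, plus the observation noise sd."""

    prior_mean: float = 0.0
    prior_sd: float = 0.3
    obs_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.prior_sd <= 0 or self.obs_noise_sd <= 0:
            raise ValidationError("prior_sd and obs_noise_sd must be positive")


@dataclass(frozen=True)
class ArmPosterior:
    """Gaussian belief N(post_mean, post_sd^2) about one arm's mean reward."""

    strategy_id: str
    post_mean: float
    post_sd: float
    n_obs: int
    reward_sum: float


def update_posterior(
    prior: ArmPrior,
    rewards_for_arm: Sequence[float],
    strategy_id: str = "",
) -> ArmPosterior:
    """Conjugate normal-normal update restricted to one arm's observed rewards.

    With no rewards the posterior is the prior. The update is a pure function
    of (prior, reward multiset): batch and sequential application agree.
    """
    rewards = np.asarray(list(rewards_for_arm), dtype=float)
    if rewards.size and not np.all(np.isfinite(rewards)):
        raise ValidationError("non-finite reward values")
    n = int(rewards.size)
    s = float(rewards.sum())
    sigma2 = prior.obs_noise_sd**2
    precision = n / sigma2 + 1.0 / prior.prior_sd**2
    var = 1.0 / precision
    mean = var * (s / sigma2 + prior.prior_mean / prior.prior_sd**2)
    return ArmPosterior(
        strategy_id=strategy_id,
        post_mean=mean,
        post_sd=math.sqrt(var),
        n_obs=n,
        reward_sum=s,
    )


def thompson_draw(
    posteriors: Mapping[str, ArmPosterior] | Iterable[ArmPosterior],
    rng: np.random.Generator,
) -> tuple[str, dict[str, float]]:
    """Draw one sample per arm from its posterior and return the argmax arm.

    Returns ``(winner, draws)`` where ``draws`` records each arm's sampled
    mean for audit. Exact ties (possible only with degenerate sd = 0 arms)
    are broken uniformly at random.
    """
    if isinstance(posteriors, Mapping):
        arms = sorted(posteriors)
        posts = [posteriors[a] for a in arms]
    else:
        posts = sorted(posteriors, key=lambda p: p.strategy_id)
        arms = [p.strategy_id for p in posts]
    if not arms:
        raise ValidationError("thompson_draw requires at least one active arm")
    means = np.array([p.post_mean for p in posts])
    sds = np.array([p.post_sd for p in posts])
    samples = means + sds * rng.standard_normal(len(arms))
    best = samples.max()
    tied = np.flatnonzero(samples == best)
    idx = int(tied[0]) if len(tied) == 1 else int(rng.choice(tied))
    return arms[idx], dict(zip(arms, samples.tolist()))


@dataclass
class AllocationPlan:
    """One week's clinic-to-strategy assignment with the draws that produced it."""

    week_index: int
    assignments: dict[str, str]
    sampled_means: dict[str, dict[str, float]] = field(default_factory=dict)
    rng_seed_state: str = ""


def allocate_week(
    posteriors: Mapping[str, ArmPosterior],
    clinics: Sequence[ClinicProfile],
    week_index: int,
    rng: np.random.Generator,
    seed_token: str = "",
) -> AllocationPlan:
    """Parallel Thompson sampling: one independent draw-and-argmax per clinic."""
    if not clinics:
        raise ValidationError("allocate_week requires at least one clinic")
    assignments: dict[str, str] = {}
    sampled: dict[str, dict[str, float]] = {}
    for clinic in sorted(clinics, key=lambda c: c.clinic_id):
        winner, draws = thompson_draw(posteriors, rng)
        assignments[clinic.clinic_id] = winner
        sampled[clinic.clinic_id] = draws
    return AllocationPlan(
        week_index=week_index,
        assignments=assignments,
        sampled_means=sampled,
        rng_seed_state=seed_token,
    )


def recompute_posteriors(
    log: TrialLog, prior: ArmPrior, arms: Iterable[str]
) -> dict[str, ArmPosterior]:
    """Rebuild every arm's posterior from its full reward history in the log.

    Idempotent by construction: late or out-of-order submissions simply join
    the history before the next rebuild, with no imputation.
    """
    return {
        arm: update_posterior(prior, log.rewards_for_arm(arm), strategy_id=arm)
        for arm in arms
    }


def ingest_week(
    log: TrialLog,
    plan: AllocationPlan,
    tallies: Sequence[ConsultationTally],
    clinics: Mapping[str, ClinicProfile],
    prior: ArmPrior,
    arms: Iterable[str],
) -> dict[str, ArmPosterior]:
    """Score one week's tallies against the plan and refresh all posteriors.

    Computes each reporting clinic's pooled outcome and reward, appends them
    to the log, records the allocations, and recomputes every arm's posterior
    from the full history. Clinic-weeks with zero relevant consultations are
    excluded (their fraction is undefined).
    """
    week = plan.week_index
    if week in log.ingested_weeks:
        raise DuplicateWeekError(f"week {week} already ingested")
    by_clinic: dict[str, list[ConsultationTally]] = {}
    for t in tallies:
        if t.week_index != week:
            raise AllocationIntegrityError(
                f"tally for week {t.week_index} submitted against plan week {week}"
            )
        expected = plan.assignments.get(t.clinic_id)
        if expected is None:
            raise AllocationIntegrityError(
                f"clinic {t.clinic_id} has no allocation in week {week}"
            )
        if t.strategy_id != expected:
            raise AllocationIntegrityError(
                f"clinic {t.clinic_id} week {week}: tally reports strategy "
                f"{t.strategy_id!r} but plan assigned {expected!r}"
            )
        by_clinic.setdefault(t.clinic_id, []).append(t)

    for clinic_id, strategy_id in plan.assignments.items():
        log.add_allocation(clinic_id, week, strategy_id)

    for clinic_id, clinic_tallies in by_clinic.items():
        pooled = clinic_week_outcome(clinic_tallies)
        if pooled is None:
            continue
        fraction, _ = pooled
        reward = compute_reward(fraction, clinics[clinic_id].baseline_rate)
        log.outcomes.append(
            OutcomeRecord(
                clinic_id=clinic_id,
                week_index=week,
                strategy_id=plan.assignments[clinic_id],
                outcome_fraction=fraction,
                reward=reward,
            )
        )
    log.records.extend(tallies)
    log.current_week = max(log.current_week, week)
    return recompute_posteriors(log, prior, arms)
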