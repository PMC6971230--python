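"""Domain types and outcome/reward arithmetic.

The unit of data entry is the GP-week tally: one general practitioner's
consultations over one trial week, split into consultations where the target
behaviour (discussing physical activity) was discussed, those where it was
relevant but not discussed, and those deemed inappropriate. A clinic's weekly
outcome is the pooled fraction y/n over its GPs; the reward of a strategy at a
clinic is that fraction minus the clinic's no-intervention baseline fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .errors import (
    BaselineUndefinedError,
    DuplicateWeekError,
    EmptyWeekError,
    ValidationError,
)

#: Reserved strategy_id token marking no-intervention (baseline stage) records.
BASELINE_STRATEGY = "baseline"


class Stage(str, Enum):
    """The three phases of the staged design."""

    BASELINE = "baseline"
    ADAPTIVE = "adaptive"
    CONFIRMATION = "confirmation"


@dataclass(frozen=True)
class ConsultationTally:
    """One GP's consultation counts for one week.

    ``discussed_count`` (y) counts consultations that touched on the target
    behaviour, out of ``relevant_count`` (n) consultations where raising it was
    possible. ``inappropriate_count`` records consultations excluded as
    irrelevant (e.g. profound disability); it is carried through I/O but never
    enters any outcome formula.
    """

    clinic_id: str
    gp_id: str
    week_index: int
    stage: Stage
    strategy_id: str
    discussed_count: int
    relevant_count: int
    inappropriate_count: int = 0

    def __post_init__(self) -> None:
        if self.week_index < 1:
            raise ValidationError(f"week_index must be >= 1, got {self.week_index}")
        for name in ("discussed_count", "relevant_count", "inappropriate_count"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.discussed_count > self.relevant_count:
            raise ValidationError(
                f"discussed_count {self.discussed_count} exceeds relevant_count "
                f"{self.relevant_count} ({self.clinic_id}/{self.gp_id} week {self.week_index})"
            )
        stage = Stage(self.stage)
        object.__setattr__(self, "stage", stage)
        is_baseline_stage = stage is Stage.BASELINE
        is_baseline_arm = self.strategy_id == BASELINE_STRATEGY
        if is_baseline_stage != is_baseline_arm:
            raise ValidationError(
                "stage=baseline iff strategy_id is the baseline sentinel; got "
                f"stage={stage.value!r}, strategy_id={self.strategy_id!r}"
            )


@dataclass
class ClinicProfile:
    """A participating clinic: its GP roster and baseline discussion rate.

    ``baseline_rate`` is the pooled no-intervention fraction over the baseline
    stage (unset until that stage completes). ``gp_baseline_rates`` holds the
    per-GP analogue used for GP-level hypothesis testing; GPs with no relevant
    baseline consultations are absent from the map.
    """

    clinic_id: str
    gp_roster: frozenset[str]
    baseline_rate: float | None = None
    gp_baseline_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gp_roster = frozenset(self.gp_roster)
        if not self.gp_roster:
            raise ValidationError(f"clinic {self.clinic_id} has an empty GP roster")
        if self.baseline_rate is not None and not 0.0 <= self.baseline_rate <= 1.0:
            raise ValidationError(
                f"baseline_rate must lie in [0,1], got {self.baseline_rate}"
            )


@dataclass(frozen=True)
class OutcomeRecord:
    """One clinic-week result: the pooled outcome fraction and its reward."""

    clinic_id: str
    week_index: int
    strategy_id: str
    outcome_fraction: float
    reward: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.outcome_fraction <= 1.0:
            raise ValidationError(f"outcome_fraction out of [0,1]: {self.outcome_fraction}")
        if not -1.0 <= self.reward <= 1.0:
            raise ValidationError(f"reward out of [-1,1]: {self.reward}")


class TrialLog:
    """The full trial history: tallies, outcomes and the allocation map.

    Within a clinic-week all GP tallies share one strategy (clinics are
    allocated as a unit to prevent cross-contamination), so the allocation map
    is keyed by (clinic_id, week_index).
    """

    def __init__(self, horizon: int = 0) -> None:
        self.records: list[ConsultationTally] = []
        self.outcomes: list[OutcomeRecord] = []
        self.allocations: dict[tuple[str, int], str] = {}
        self.current_week: int = 0
        self.horizon: int = horizon

    def add_allocation(self, clinic_id: str, week_index: int, strategy_id: str) -> None:
        key = (clinic_id, week_index)
        if key in self.allocations and self.allocations[key] != strategy_id:
            raise DuplicateWeekError(
                f"clinic {clinic_id} week {week_index} already allocated "
                f"{self.allocations[key]!r}"
            )
        self.allocations[key] = strategy_id

    @property
    def ingested_weeks(self) -> set[int]:
        return {o.week_index for o in self.outcomes}

    def rewards_for_arm(self, strategy_id: str) -> list[float]:
        return [o.reward for o in self.outcomes if o.strategy_id == strategy_id]

    def pull_counts(self, up_to_week: int | None = None) -> dict[str, int]:
        """Cumulative clinic-week allocation counts per strategy."""
        counts: dict[str, int] = {}
        for (_, week), sid in self.allocations.items():
            if sid == BASELINE_STRATEGY:
                continue
            if up_to_week is not None and week > up_to_week:
                continue
            counts[sid] = counts.get(sid, 0) + 1
        return counts

    def records_for_strategy(self, strategy_id: str) -> list[ConsultationTally]:
        return [r for r in self.records if r.strategy_id == strategy_id]


def compute_outcome_fraction(discussed_count: int, relevant_count: int) -> float:
    """Fraction of relevant consultations in which the behaviour was discussed.

    Raises :class:`EmptyWeekError` when ``relevant_count`` is zero: the
    fraction is undefined and the caller must exclude the record rather than
    score it as 0/0.
    """
    if relevant_count == 0:
        raise EmptyWeekError("relevant_count is zero; outcome fraction undefined")
    if relevant_count < 0 or discussed_count < 0 or discussed_count > relevant_count:
        raise ValidationError(
            f"invalid counts: discussed={discussed_count}, relevant={relevant_count}"
        )
    return discussed_count / relevant_count


def compute_clinic_baseline(
    tallies: Iterable[ConsultationTally], clinic_id: str | None = None
) -> float:
    """Pooled no-intervention fraction (sum y / sum n) over the baseline stage.

    Pools every GP and every baseline week, so the estimate is invariant to
    how counts are partitioned across GPs.
    """
    tallies = list(tallies)
    if not tallies:
        raise BaselineUndefinedError("no baseline tallies supplied")
    cid = clinic_id if clinic_id is not None else tallies[0].clinic_id
    total_y = 0
    total_n = 0
    for t in tallies:
        if t.clinic_id != cid:
            raise ValidationError(
                f"tally for clinic {t.clinic_id} passed to baseline of clinic {cid}"
            )
        if t.stage is not Stage.BASELINE:
            raise ValidationError(
                f"non-baseline tally (stage={t.stage.value}) in baseline computation"
            )
        total_y += t.discussed_count
        total_n += t.relevant_count
    if total_n == 0:
        raise BaselineUndefinedError(
            f"clinic {cid}: zero relevant consultations over the baseline stage"
        )
    return total_y / total_n


def compute_gp_baselines(
    tallies: Iterable[ConsultationTally],
) -> dict[str, float]:
    """Per-GP pooled baseline fractions; GPs with zero relevant weeks are omitted."""
    y: dict[str, int] = {}
    n: dict[str, int] = {}
    for t in tallies:
        if t.stage is not Stage.BASELINE:
            raise ValidationError("non-baseline tally in GP baseline computation")
        y[t.gp_id] = y.get(t.gp_id, 0) + t.discussed_count
        n[t.gp_id] = n.get(t.gp_id, 0) + t.relevant_count
    return {gp: y[gp] / n[gp] for gp in n if n[gp] > 0}


def compute_reward(outcome_fraction: float, baseline_rate: float | None) -> float:
    """Reward of a strategy at a clinic: outcome fraction minus the clinic baseline."""
    if baseline_rate is None:
        raise BaselineUndefinedError(
            "clinic baseline is unset; complete the baseline stage first"
        )
    if not 0.0 <= outcome_fraction <= 1.0 or not 0.0 <= baseline_rate <= 1.0:
        raise ValidationError(
            f"fractions must lie in [0,1]: outcome={outcome_fraction}, baseline={baseline_rate}"
        )
    return outcome_fraction - baseline_rate


def clinic_week_outcome(
    tallies: Iterable[ConsultationTally],
) -> tuple[float, int] | None:
    """Pooled (fraction, total n) for one clinic-week, or None if no relevant consults.

    All tallies must share one clinic, week and strategy; that is the caller's
    contract (enforced at ingest time).
    """
    total_y = 0
    total_n = 0
    for t in tallies:
        total_y += t.discussed_count
        total_n += t.relevant_count
    if total_n == 0:
        return None
    return total_y / total_n, total_n


def check_reward_identity(record: OutcomeRecord, baseline_rate: float, tol: float = 1e-12) -> bool:
    """True when reward + baseline equals the outcome fraction to within tol."""
    return math.isclose(
        record.reward + baseline_rate, record.outcome_fraction, abs_tol=tol
    )
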