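"""Synthetic clinic/GP cohort generator.

Emulates the structure of a 13-clinic, 26-GP study of weekly consultation
tallies: each GP has a latent baseline probability of discussing the target
behaviour (centred near 0.18 — under one in five consultations), each week
they see a Poisson number of relevant patients (mean ~33, matching a study
that logged 11,176 conversations over 26 GPs x 13 weeks), and an assigned
strategy shifts the discussion probability additively by its true effect
``delta_i``. Default effects follow the magnitudes a real deployment reported
for its eight strategies: {0.15, 0.09, 0.02, 0.01, -0.01, -0.02, -0.03,
-0.08}.

Two knobs exist purely to *violate* the analysis assumptions on demand:
``drift_per_week`` adds a linear time trend (breaking stationarity) and
``within_clinic_correlation`` adds a shared clinic-week random effect
(breaking GP independence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .trial_core import (
    BASELINE_STRATEGY,
    ClinicProfile,
    ConsultationTally,
    Stage,
)

#: Default true strategy effects, keyed by strategy id, descending in effect.
DEFAULT_TRUE_EFFECTS: dict[str, float] = {
    "7": 0.15,
    "3": 0.09,
    "4": 0.02,
    "5": 0.01,
    "1": -0.01,
    "2": -0.02,
    "6": -0.03,
    "8": -0.08,
}

_PROB_LO, _PROB_HI = 0.01, 0.99


@dataclass
class ScenarioSpec:
    """Ground-truth parameters of a synthetic trial scenario."""

    n_clinics: int = 13
    gps_per_clinic: int = 2
    n_strategies: int = 8
    true_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_EFFECTS)
    )
    baseline_rate_mean: float = 0.18
    baseline_rate_sd: float = 0.04
    consultations_per_gp_week_mean: float = 33.0
    inappropriate_fraction: float = 0.05
    drift_per_week: float = 0.0
    within_clinic_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clinics < 1 or self.gps_per_clinic < 1:
            raise ValidationError("need at least one clinic and one GP per clinic")
        if len(self.true_effects) != self.n_strategies:
            raise ValidationError(
                f"true_effects has {len(self.true_effects)} entries but "
                f"n_strategies={self.n_strategies}"
            )
        if not 0.0 <= self.baseline_rate_mean <= 1.0:
            raise ValidationError("baseline_rate_mean must lie in [0,1]")
        if self.baseline_rate_sd < 0:
            raise ValidationError("baseline_rate_sd must be >= 0")
        if self.consultations_per_gp_week_mean <= 0:
            raise ValidationError("consultations_per_gp_week_mean must be > 0")
        if not 0.0 <= self.inappropriate_fraction < 1.0:
            raise ValidationError("inappropriate_fraction must lie in [0,1)")
        if not 0.0 <= self.within_clinic_correlation < 1.0:
            raise ValidationError("within_clinic_correlation must lie in [0,1)")

    @property
    def arms(self) -> list[str]:
        return sorted(self.true_effects)

    def null_copy(self) -> "ScenarioSpec":
        """Same scenario with every true effect forced to zero."""
        spec = ScenarioSpec(**{**self.__dict__})
        spec.true_effects = {a: 0.0 for a in self.true_effects}
        return spec


@dataclass
class Cohort:
    """The generated population: clinic profiles plus per-GP latent rates."""

    clinics: list[ClinicProfile]
    gp_rates: dict[str, float]

    @property
    def clinic_map(self) -> dict[str, ClinicProfile]:
        return {c.clinic_id: c for c in self.clinics}


def generate_cohort(spec: ScenarioSpec) -> Cohort:
    """Draw the latent per-GP baseline discussion rates.

    Rates are Normal(baseline_rate_mean, baseline_rate_sd) clipped to
    [0.01, 0.99]; deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    clinics: list[ClinicProfile] = []
    gp_rates: dict[str, float] = {}
    for ci in range(1, spec.n_clinics + 1):
        cid = f"C{ci:02d}"
        roster = []
        for gi in range(1, spec.gps_per_clinic + 1):
            gp_id = f"{cid}-G{gi}"
            rate = float(
                np.clip(
                    rng.normal(spec.baseline_rate_mean, spec.baseline_rate_sd),
                    _PROB_LO,
                    _PROB_HI,
                )
            )
            gp_rates[gp_id] = rate
            roster.append(gp_id)
        clinics.append(ClinicProfile(clinic_id=cid, gp_roster=frozenset(roster)))
    return Cohort(clinics=clinics, gp_rates=gp_rates)


def _shared_effect_sd(spec: ScenarioSpec) -> float:
    # Scale the clinic-week random effect so the induced correlation between
    # two GPs' weekly fractions approximates the requested rho: with binomial
    # fraction variance v, rho = s^2/(s^2+v) gives s = sqrt(v * rho/(1-rho)).
    rho = spec.within_clinic_correlation
    if rho == 0.0:
        return 0.0
    p = spec.baseline_rate_mean
    v = p * (1.0 - p) / spec.consultations_per_gp_week_mean
    return math.sqrt(v * rho / (1.0 - rho))


def generate_week(
    spec: ScenarioSpec,
    cohort: Cohort,
    week_index: int,
    stage: Stage,
    assignments: Mapping[str, str],
    rng: np.random.Generator,
) -> list[ConsultationTally]:
    """Simulate one week of GP tallies under the given clinic assignments.

    Per GP: relevant_count ~ Poisson(mean consultations); discussed_count ~
    Binomial(relevant, clip(gp_rate + delta + drift*week + clinic effect));
    inappropriate_count ~ Poisson of the inappropriate share of total
    appointments. The baseline sentinel carries delta = 0.
    """
    shared_sd = _shared_effect_sd(spec)
    inappropriate_mean = (
        spec.consultations_per_gp_week_mean
        * spec.inappropriate_fraction
        / (1.0 - spec.inappropriate_fraction)
    )
    tallies: list[ConsultationTally] = []
    for clinic in cohort.clinics:
        sid = assignments[clinic.clinic_id]
        if sid == BASELINE_STRATEGY:
            delta = 0.0
        else:
            try:
                delta = spec.true_effects[sid]
            except KeyError:
                raise ValidationError(f"unknown strategy id {sid!r}") from None
        clinic_effect = rng.normal(0.0, shared_sd) if shared_sd else 0.0
        for gp_id in sorted(clinic.gp_roster):
            n = int(rng.poisson(spec.consultations_per_gp_week_mean))
            p = float(
                np.clip(
                    cohort.gp_rates[gp_id]
                    + delta
                    + spec.drift_per_week * week_index
                    + clinic_effect,
                    _PROB_LO,
                    _PROB_HI,
                )
            )
            y = int(rng.binomial(n, p)) if n > 0 else 0
            inappropriate = int(rng.poisson(inappropriate_mean))
            tallies.append(
                ConsultationTally(
                    clinic_id=clinic.clinic_id,
                    gp_id=gp_id,
                    week_index=week_index,
                    stage=stage,
                    strategy_id=sid,
                    discussed_count=y,
                    relevant_count=n,
                    inappropriate_count=inappropriate,
                )
            )
    return tallies


class TrialStream:
    """Tally source backed by the generator; plugs into the orchestrator.

    Reproducible: each week draws from a child stream seeded by
    (spec.seed, week), so the stream a given week produces depends only on the
    scenario seed, the week and the assignments — not on call order.
    """

    def __init__(self, spec: ScenarioSpec, cohort: Cohort | None = None) -> None:
        self.spec = spec
        self.cohort = cohort if cohort is not None else generate_cohort(spec)

    def __call__(
        self, week_index: int, stage: Stage, assignments: Mapping[str, str]
    ) -> list[ConsultationTally]:
        rng = np.random.default_rng(
            np.random.SeedSequence([self.spec.seed, 1, week_index])
        )
        return generate_week(self.spec, self.cohort, week_index, stage, assignments, rng)


def generate_full_trial_stream(spec: ScenarioSpec) -> TrialStream:
    """Convenience constructor matching the outcome-source contract."""
    return TrialStream(spec)
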