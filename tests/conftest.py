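"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from adaptrial.bandit_engine import ArmPrior
from adaptrial.staged_design import StageConfig, run_trial
from adaptrial.synthetic_cohort import ScenarioSpec, TrialStream
from adaptrial.trial_core import ConsultationTally, Stage


def grid_posterior_oracle(prior: ArmPrior, rewards, lo=-2.5, hi=2.5, n=250_001):
    """Posterior mean/sd by dense numerical integration of prior x likelihood.

    Independent of the conjugate closed form: evaluates the unnormalised log
    posterior on a grid and integrates with the trapezoid rule.
    """
    mu = np.linspace(lo, hi, n)
    logp = -0.5 * ((mu - prior.prior_mean) / prior.prior_sd) ** 2
    r = np.asarray(rewards, dtype=float)
    if r.size:
        loglik = -0.5 * (((r[:, None] - mu[None, :]) / prior.obs_noise_sd) ** 2).sum(axis=0)
        logp = logp + loglik
    logp -= logp.max()
    w = np.exp(logp)
    z = np.trapezoid(w, mu)
    mean = np.trapezoid(w * mu, mu) / z
    var = np.trapezoid(w * (mu - mean) ** 2, mu) / z
    return mean, np.sqrt(var)


def run_synthetic_trial(trial_seed: int, scenario_seed: int, spec: ScenarioSpec | None = None,
                        config: StageConfig | None = None, prior: ArmPrior | None = None):
    """Run one full staged trial on a synthetic scenario."""
    spec = spec if spec is not None else ScenarioSpec()
    spec = ScenarioSpec(**{**spec.__dict__, "seed": scenario_seed})
    config = config if config is not None else StageConfig()
    prior = prior if prior is not None else ArmPrior()
    stream = TrialStream(spec)
    return run_trial(config, prior, stream.cohort.clinics, spec.arms, stream, trial_seed)


def make_tally(clinic="C01", gp="C01-G1", week=3, stage=Stage.ADAPTIVE,
               strategy="7", discussed=5, relevant=30, inappropriate=1):
    return ConsultationTally(
        clinic_id=clinic, gp_id=gp, week_index=week, stage=stage,
        strategy_id=strategy, discussed_count=discussed,
        relevant_count=relevant, inappropriate_count=inappropriate,
    )


@pytest.fixture(scope="session")
def default_prior() -> ArmPrior:
    return ArmPrior()


@pytest.fixture(scope="session")
def default_config() -> StageConfig:
    return StageConfig()


@pytest.fixture(scope="session")
def default_replicates():
    """200 independent full runs of the default scenario (shared across tests)."""
    rng = np.random.default_rng(20240901)
    seeds = rng.integers(0, 2**31 - 1, size=(200, 2))
    return [run_synthetic_trial(int(ts), int(ss)) for ss, ts in seeds]
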