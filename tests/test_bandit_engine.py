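"""Conjugate posterior updates, Thompson draws and weekly allocation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adaptrial.bandit_engine import (
    AllocationPlan,
    ArmPosterior,
    ArmPrior,
    allocate_week,
    ingest_week,
    thompson_draw,
    update_posterior,
)
from adaptrial.errors import (
    AllocationIntegrityError,
    DuplicateWeekError,
    ValidationError,
)
from adaptrial.staged_design import StageConfig, TrialState, run_adaptive_stage, run_baseline
from adaptrial.synthetic_cohort import ScenarioSpec, TrialStream
from adaptrial.trial_core import ClinicProfile, Stage, TrialLog

from conftest import grid_posterior_oracle, make_tally


@pytest.mark.parametrize(
    "rewards, exp_mean, exp_sd",
    [
        ([], 0.0, 0.3),
        ([0.2], 0.0165138, 0.2873479),
        ([0.15] * 100, 0.135, 0.0948683),
    ],
)
def test_posterior_update_examples(rewards, exp_mean, exp_sd):
    post = update_posterior(ArmPrior(), rewards)
    assert post.post_mean == pytest.approx(exp_mean, abs=1e-5)
    assert post.post_sd == pytest.approx(exp_sd, abs=1e-5)
    assert post.n_obs == len(rewards)


def test_posterior_matches_grid_integration():
    prior = ArmPrior()
    rng = np.random.default_rng(11)
    for _ in range(10):
        rewards = rng.normal(0.05, 0.3, size=rng.integers(1, 30)).tolist()
        post = update_posterior(prior, rewards)
        om, osd = grid_posterior_oracle(prior, rewards)
        assert post.post_mean == pytest.approx(om, abs=1e-6)
        assert post.post_sd == pytest.approx(osd, abs=1e-6)


def test_posterior_rejects_non_finite_rewards():
    with pytest.raises(ValidationError):
        update_posterior(ArmPrior(), [0.1, float("nan")])


@given(
    rewards=st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=20),
    split=st.integers(0, 20),
)
@settings(max_examples=200, deadline=None)
def test_sequential_equals_batch_update(rewards, split):
    """Conjugacy: feeding rewards in two chunks equals one batch update."""
    prior = ArmPrior()
    k = min(split, len(rewards))
    mid = update_posterior(prior, rewards[:k])
    chained = update_posterior(
        ArmPrior(mid.post_mean, mid.post_sd, prior.obs_noise_sd), rewards[k:]
    )
    batch = update_posterior(prior, rewards)
    assert chained.post_mean == pytest.approx(batch.post_mean, abs=1e-10)
    assert chained.post_sd == pytest.approx(batch.post_sd, abs=1e-10)


@given(rewards=st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=50))
@settings(max_examples=200, deadline=None)
def test_posterior_shrinkage_and_sd_contraction(rewards):
    prior = ArmPrior()
    post = update_posterior(prior, rewards)
    sample_mean = float(np.mean(rewards))
    lo, hi = sorted((prior.prior_mean, sample_mean))
    assert lo - 1e-12 <= post.post_mean <= hi + 1e-12
    assert post.post_sd <= prior.prior_sd
    fewer = update_posterior(prior, rewards[:-1])
    if len(rewards) > 1:
        assert post.post_sd < fewer.post_sd


def test_posterior_asymptotics():
    """sd -> 0 and mean -> sample mean as observations accumulate."""
    rng = np.random.default_rng(5)
    rewards = rng.normal(0.12, 1.0, size=10_000)
    post = update_posterior(ArmPrior(), rewards.tolist())
    assert post.post_sd < 0.011
    assert post.post_mean == pytest.approx(float(rewards.mean()), abs=1e-2)


def _post(sid, mean, sd=1e-12):
    return ArmPosterior(sid, mean, sd, 0, 0.0)


def test_thompson_draw_single_and_degenerate_arms():
    rng = np.random.default_rng(0)
    winner, draws = thompson_draw({"A": _post("A", 0.0, 0.3)}, rng)
    assert winner == "A" and set(draws) == {"A"}
    for _ in range(50):
        winner, _ = thompson_draw(
            {"A": _post("A", 0.2), "B": _post("B", 0.1)}, rng
        )
        assert winner == "A"
    with pytest.raises(ValidationError):
        thompson_draw({}, rng)


def test_thompson_draw_symmetric_arms_split_evenly():
    rng = np.random.default_rng(42)
    posts = {"A": _post("A", 0.0, 0.3), "B": _post("B", 0.0, 0.3)}
    wins = sum(thompson_draw(posts, rng)[0] == "A" for _ in range(10_000))
    assert abs(wins / 10_000 - 0.5) < 0.02


def _clinics(n):
    return [
        ClinicProfile(clinic_id=f"C{i:02d}", gp_roster=frozenset({f"C{i:02d}-G1"}))
        for i in range(1, n + 1)
    ]


def test_allocate_week_contracts():
    rng = np.random.default_rng(1)
    clinics = _clinics(13)
    plan = allocate_week({"A": _post("A", 0.1, 0.2)}, clinics, 3, rng)
    assert list(plan.assignments.values()) == ["A"] * 13
    plan = allocate_week(
        {"A": _post("A", 0.3), "B": _post("B", 0.1)}, clinics, 3, rng
    )
    assert set(plan.assignments.values()) == {"A"}
    with pytest.raises(ValidationError):
        allocate_week({"A": _post("A", 0.1)}, [], 3, rng)


def test_allocate_week_identical_posteriors_binomial_split():
    """Two exchangeable arms: clinic counts behave like Binomial(13, 1/2)."""
    posts = {"A": _post("A", 0.0, 0.3), "B": _post("B", 0.0, 0.3)}
    clinics = _clinics(13)
    rng = np.random.default_rng(7)
    counts = [
        sum(s == "A" for s in allocate_week(posts, clinics, w, rng).assignments.values())
        for w in range(400)
    ]
    mean = np.mean(counts)
    # 99% bounds on the mean of 400 draws from Binomial(13, .5): 6.5 +/- 2.58*sd
    se = np.sqrt(13 * 0.25 / 400)
    assert abs(mean - 6.5) < 2.58 * se * 3  # generous guard band, seeded anyway


def _mini_state(n_clinics=1, arms=("A", "B")):
    clinics = {
        c.clinic_id: ClinicProfile(
            clinic_id=c.clinic_id, gp_roster=c.gp_roster, baseline_rate=0.2
        )
        for c in _clinics(n_clinics)
    }
    log = TrialLog()
    return log, clinics, list(arms)


def test_ingest_week_composes_outcome_reward_and_update():
    log, clinics, arms = _mini_state()
    prior = ArmPrior()
    plan = AllocationPlan(week_index=3, assignments={"C01": "A"})
    tallies = [
        make_tally(clinic="C01", gp="C01-G1", week=3, strategy="A", discussed=7, relevant=20)
    ]
    posts = ingest_week(log, plan, tallies, clinics, prior, arms)
    assert log.outcomes[0].outcome_fraction == pytest.approx(0.35)
    assert log.outcomes[0].reward == pytest.approx(0.15)
    ref = update_posterior(prior, [0.15], strategy_id="A")
    assert posts["A"].post_mean == pytest.approx(ref.post_mean, abs=1e-12)
    assert posts["A"].post_sd == pytest.approx(ref.post_sd, abs=1e-12)
    assert posts["B"].post_mean == prior.prior_mean


def test_ingest_week_rejects_duplicates_and_plan_mismatch():
    log, clinics, arms = _mini_state()
    prior = ArmPrior()
    plan = AllocationPlan(week_index=3, assignments={"C01": "A"})
    tallies = [make_tally(clinic="C01", week=3, strategy="A")]
    ingest_week(log, plan, tallies, clinics, prior, arms)
    with pytest.raises(DuplicateWeekError):
        ingest_week(log, plan, tallies, clinics, prior, arms)
    log2, clinics2, _ = _mini_state()
    bad = [make_tally(clinic="C01", week=3, strategy="B")]
    with pytest.raises(AllocationIntegrityError):
        ingest_week(log2, AllocationPlan(3, {"C01": "A"}), bad, clinics2, prior, arms)


def test_ingest_order_free_and_empty_week():
    prior = ArmPrior()
    week3 = [make_tally(clinic="C01", week=3, strategy="A", discussed=7, relevant=20)]
    week4 = [make_tally(clinic="C01", week=4, strategy="B", discussed=4, relevant=20)]
    plans = {
        3: AllocationPlan(3, {"C01": "A"}),
        4: AllocationPlan(4, {"C01": "B"}),
    }
    results = []
    for order in ([3, 4], [4, 3]):
        log, clinics, arms = _mini_state()
        for w in order:
            posts = ingest_week(
                log, plans[w], week3 if w == 3 else week4, clinics, prior, arms
            )
        results.append({a: (p.post_mean, p.post_sd) for a, p in posts.items()})
    assert results[0] == results[1]

    log, clinics, arms = _mini_state()
    posts = ingest_week(log, AllocationPlan(5, {"C01": "A"}), [], clinics, prior, arms)
    assert posts["A"].n_obs == 0 and posts["A"].post_mean == prior.prior_mean


def test_two_arm_allocation_concentrates_on_better_arm():
    """With true effects 0.15 vs 0, the better arm takes >60% of pulls by week
    20 in at least 90% of seeded replicates."""
    spec_base = ScenarioSpec(
        n_strategies=2, true_effects={"A": 0.15, "B": 0.0}
    )
    config = StageConfig(n_strategies=2, n_adaptive_weeks=20, top_k=2)
    rng = np.random.default_rng(77)
    hits = 0
    n_rep = 200
    for ss, ts in rng.integers(0, 2**31 - 1, size=(n_rep, 2)):
        spec = ScenarioSpec(**{**spec_base.__dict__, "seed": int(ss)})
        stream = TrialStream(spec)
        state = TrialState(
            config=config,
            prior=ArmPrior(),
            clinics={c.clinic_id: c for c in stream.cohort.clinics},
            arms=spec.arms,
            seed=int(ts),
        )
        run_baseline(state, stream)
        run_adaptive_stage(state, stream)
        pulls = state.log.pull_counts()
        if pulls.get("A", 0) / sum(pulls.values()) > 0.6:
            hits += 1
    assert hits / n_rep >= 0.90
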