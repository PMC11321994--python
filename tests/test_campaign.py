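"""Acquisition portfolio, batched proposals, the closed loop and its statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from photobo.campaign import (
    AcquisitionConfig,
    CampaignLog,
    DescriptorDesign,
    StopConfig,
    accept_all,
    enrichment_stats,
    explicit_selection,
    propose_from_posterior,
    random_baseline,
    run_closed_loop,
    sample_beta_portfolio,
    top_k_by_score,
    ucb_score,
)
from photobo.errors import SpaceExhaustedError, ValidationError
from photobo.oracles import LandscapeConfig, ReplayTable, make_catalyst_landscape
from photobo.chemspace import descriptor_matrix
from photobo.datasets import synthetic_catalyst_library


class TestUCB:
    def test_direct_arithmetic(self):
        assert ucb_score(0.5, 0.2, 2.0) == pytest.approx(0.9)

    def test_beta_zero_is_pure_exploitation(self):
        assert ucb_score(0.7, 5.0, 0.0) == 0.7

    def test_strictly_increasing_in_beta(self):
        scores = [ucb_score(0.5, 0.3, b) for b in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            ucb_score(0.5, -0.1, 1.0)


class TestBetaPortfolio:
    def test_determinism(self):
        cfg = AcquisitionConfig(portfolio_size=12, beta_scale=1.0, seed=5)
        assert sample_beta_portfolio(cfg) == sample_beta_portfolio(cfg)

    def test_sorted_and_sized(self):
        betas = sample_beta_portfolio(AcquisitionConfig(portfolio_size=12, seed=0))
        assert len(betas) == 12 and betas == sorted(betas)

    def test_law_of_large_numbers(self):
        cfg = AcquisitionConfig(portfolio_size=10_000, beta_scale=2.0, seed=1)
        assert np.mean(sample_beta_portfolio(cfg)) == pytest.approx(2.0, rel=0.05)

    def test_explicit_override(self):
        cfg = AcquisitionConfig(explicit_betas=[0.3, 0.1, 2.0])
        assert sample_beta_portfolio(cfg) == [0.3, 0.1, 2.0]


class TestProposeBatch:
    def test_beta_zero_picks_argmax_mu(self):
        mu = np.array([0.1, 0.9, 0.5])
        sig = np.array([1.0, 0.0, 2.0])
        out = propose_from_posterior(mu, sig, ["a", "b", "c"], set(), [0.0])
        assert out[0][0] == "b"

    def test_dedupe_falls_to_runner_up(self):
        mu = np.array([0.9, 0.5, 0.1])
        sig = np.zeros(3)
        out = propose_from_posterior(mu, sig, ["a", "b", "c"], set(), [0.0, 0.0])
        assert [p[0] for p in out] == ["a", "b"]

    def test_matches_bruteforce_argmax_with_removal(self):
        rng = np.random.default_rng(8)
        ids = [f"c{i}" for i in range(50)]
        mu, sig = rng.normal(size=50), rng.uniform(0, 1, 50)
        observed = set(rng.choice(ids, 10, replace=False))
        betas = list(rng.exponential(1.0, 12))
        got = propose_from_posterior(mu, sig, ids, observed, betas)
        taken = set(observed)
        for cid, beta, score in got:
            pool = [i for i in range(50) if ids[i] not in taken]
            scores = mu[pool] + beta * sig[pool]
            assert ids[pool[int(np.argmax(scores))]] == cid
            assert score == pytest.approx(scores.max())
            taken.add(cid)

    def test_degenerate_posterior_reduces_to_top_k_by_mu(self):
        rng = np.random.default_rng(2)
        mu = rng.normal(size=20)
        ids = [f"c{i}" for i in range(20)]
        out = propose_from_posterior(mu, np.zeros(20), ids, set(), [0.1, 3.0, 7.0, 0.5])
        expect = [ids[i] for i in np.argsort(-mu)[:4]]
        assert [p[0] for p in out] == expect

    def test_exhausted_pool(self):
        with pytest.raises(SpaceExhaustedError):
            propose_from_posterior(np.ones(2), np.ones(2), ["a", "b"], {"a", "b"}, [1.0])


class TestRandomBaseline:
    def test_full_space_is_permutation(self):
        ids = [f"x{i}" for i in range(10)]
        assert sorted(random_baseline(ids, 10, seed=0)) == sorted(ids)

    def test_determinism_and_exclusion(self):
        ids = [f"x{i}" for i in range(30)]
        a = random_baseline(ids, 5, seed=3, exclude=["x0", "x1"])
        assert a == random_baseline(ids, 5, seed=3, exclude=["x0", "x1"])
        assert not {"x0", "x1"} & set(a)

    def test_bounds(self):
        with pytest.raises(ValidationError):
            random_baseline(["a", "b"], 3, seed=0)

    def test_uniformity_chi_square(self):
        ids = [str(i) for i in range(10)]
        counts = np.zeros(10)
        rng_seeds = range(10_000)
        for s in rng_seeds:
            counts[int(random_baseline(ids, 1, seed=s)[0])] += 1
        # each frequency within 3 sigma of uniform
        exp = 1000.0
        sd = np.sqrt(10_000 * 0.1 * 0.9)
        assert np.all(np.abs(counts - exp) <= 3 * sd)


class TestEnrichment:
    def test_hand_counts(self):
        st = enrichment_stats([70.0, 60.0, 80.0], 67.0)
        assert st["n_above"] == 2 and st["max_yield"] == 80.0
        assert st["fraction"] == pytest.approx(2 / 3)
        assert st["best_so_far_trace"] == [70.0, 70.0, 80.0]

    def test_all_below(self):
        assert enrichment_stats([10.0, 20.0], 67.0)["fraction"] == 0.0

    def test_trace_monotone(self):
        st = enrichment_stats(list(np.random.default_rng(0).uniform(0, 100, 50)), 50)
        t = st["best_so_far_trace"]
        assert all(a <= b for a, b in zip(t, t[1:])) and t[-1] == st["max_yield"]


@pytest.fixture(scope="module")
def catalyst_setup():
    lib = synthetic_catalyst_library(0)
    land = make_catalyst_landscape(lib, LandscapeConfig(noise_sd=3.0), seed=1)
    design = DescriptorDesign([m.id for m in lib], descriptor_matrix(lib))
    return lib, land, design


class TestClosedLoop:
    def test_zero_steps_logs_only_seed_batch(self, catalyst_setup):
        _, land, design = catalyst_setup
        log = run_closed_loop(design, land, AcquisitionConfig(seed=0),
                              StopConfig(max_steps=0), init_k=6, seed=0)
        assert len(log.observations) == 6
        assert all(o.arm == "seed" for o in log.observations)

    def test_byte_identical_logs_under_fixed_seeds(self, catalyst_setup):
        _, land, design = catalyst_setup
        kwargs = dict(init_k=6, seed=123)
        acq, stop = AcquisitionConfig(portfolio_size=6, seed=0), StopConfig(max_steps=2)
        a = run_closed_loop(design, land, acq, stop, **kwargs).to_jsonl()
        b = run_closed_loop(design, land, acq, stop, **kwargs).to_jsonl()
        assert a == b

    def test_never_reobserves_and_trace_monotone(self, catalyst_setup):
        _, land, design = catalyst_setup
        log = run_closed_loop(design, land, AcquisitionConfig(portfolio_size=8, seed=1),
                              StopConfig(max_steps=4), init_k=6, seed=7)
        ids = log.observed_ids
        assert len(ids) == len(set(ids))
        trace = log.best_trace()
        assert all(a <= b for a, b in zip(trace, trace[1:]))
        assert trace[-1] == max(o.mean_yield for o in log.observations)

    def test_budget_truncates(self, catalyst_setup):
        _, land, design = catalyst_setup
        log = run_closed_loop(design, land, AcquisitionConfig(portfolio_size=12, seed=0),
                              StopConfig(max_steps=10, budget=20), init_k=6, seed=0)
        assert len(log.observations) == 20

    def test_selection_mask_recorded(self, catalyst_setup):
        _, land, design = catalyst_setup
        log = run_closed_loop(design, land, AcquisitionConfig(portfolio_size=12, seed=0),
                              StopConfig(max_steps=1), init_k=6,
                              selection=top_k_by_score(6), seed=0)
        assert len(log.steps[0].proposals) == 12
        assert len(log.steps[0].selected) == 6
        assert len(log.observations) == 12  # 6 seed + 6 selected

    def test_replay_closure(self, catalyst_setup):
        """BO against a replay table only ever observes measured ids, and an
        exported-then-replayed campaign reproduces its observations."""
        _, land, design = catalyst_setup
        src = run_closed_loop(design, land, AcquisitionConfig(portfolio_size=6, seed=0),
                              StopConfig(max_steps=2), init_k=6, seed=3)
        table = ReplayTable.from_log(src)
        measured = set(table.ids)
        sub_design = DescriptorDesign(
            [i for i in design.ids if i in measured],
            design.X[[design.ids.index(i) for i in design.ids if i in measured]],
        )
        replayed = run_closed_loop(sub_design, table,
                                   AcquisitionConfig(portfolio_size=6, seed=0),
                                   StopConfig(max_steps=2),
                                   init_ids=src.config["init_ids"], seed=3)
        assert set(replayed.observed_ids) <= measured
        by_id = {o.target_id: o.replicate_yields for o in src.observations}
        for o in replayed.observations:
            assert o.replicate_yields == by_id[o.target_id]

    def test_log_roundtrip(self, catalyst_setup):
        _, land, design = catalyst_setup
        log = run_closed_loop(design, land, AcquisitionConfig(portfolio_size=4, seed=0),
                              StopConfig(max_steps=1), init_k=4, seed=0)
        back = CampaignLog.from_jsonl(log.to_jsonl())
        assert back.to_jsonl() == log.to_jsonl()

    def test_explicit_selection_replays_fixed_choices(self, catalyst_setup):
        _, land, design = catalyst_setup
        probe = run_closed_loop(design, land, AcquisitionConfig(portfolio_size=6, seed=0),
                                StopConfig(max_steps=1), init_k=6, seed=5)
        step1 = [p[0] for p in probe.steps[0].proposals][:3]
        log = run_closed_loop(design, land, AcquisitionConfig(portfolio_size=6, seed=0),
                              StopConfig(max_steps=1), init_k=6,
                              selection=explicit_selection([step1]), seed=5)
        assert log.steps[0].selected == step1


def test_bo_beats_random_paired_sign_test(catalyst_setup):
    """On the bundled landscape BO outperforms uniform random sampling at
    equal budgets: higher mean final best-so-far, and a top-decile
    observation fraction that wins a one-sided sign test at p < 0.05."""
    _, land, design = catalyst_setup
    vals = np.array([land.latent[i] for i in land.ids])
    q90 = np.quantile(vals, 0.9)
    n_seeds, budget = 20, 60
    bo_best, rnd_best, frac_wins = [], [], 0
    for s in range(n_seeds):
        log = run_closed_loop(design, land,
                              AcquisitionConfig(portfolio_size=12, seed=0),
                              StopConfig(max_steps=20, budget=budget, patience=None),
                              init_k=6, seed=s)
        assert len(log.observations) == budget
        rnd_ids = random_baseline(design.ids, budget, seed=10_000 + s)
        from photobo.oracles import measure

        rnd_obs = [measure(land, i, seed=s).mean_yield for i in rnd_ids]
        bo_best.append(max(o.mean_yield for o in log.observations))
        rnd_best.append(max(rnd_obs))
        bo_frac = np.mean([land.latent[o.target_id] > q90 for o in log.observations])
        rnd_frac = np.mean([land.latent[i] > q90 for i in rnd_ids])
        frac_wins += bo_frac > rnd_frac
    assert np.mean(bo_best) > np.mean(rnd_best)
    p = sps.binomtest(frac_wins, n_seeds, 0.5, alternative="greater").pvalue
    assert p < 0.05
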