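"""Forward generative model: choice probability, sessions, observers."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm, spearmanr

from metabisect import (
    GroupParams,
    ObserverParams,
    ScheduleSpec,
    choice_probability,
    sample_observers,
    simulate_session,
    simulate_study,
    simulate_trial,
)


class TestChoiceProbability:
    def test_equal_errors_give_half(self):
        for sm in (0.01, 0.5, 10.0):
            assert choice_probability(0.3, 0.3, sm) == 0.5

    def test_small_sigma_approaches_certainty(self):
        # error 1 smaller: probability of choosing interval 1 -> 1
        assert choice_probability(0.1, 0.3, 1e-6) == pytest.approx(1.0)
        assert choice_probability(0.3, 0.1, 1e-6) == pytest.approx(0.0)

    def test_zero_sigma_limit_rule(self):
        assert choice_probability(0.1, 0.3, 0.0) == 1.0
        assert choice_probability(0.3, 0.1, 0.0) == 0.0
        assert choice_probability(0.2, 0.2, 0.0) == 0.5

    def test_matches_quadrature_oracle_on_grid(self):
        # P(chosen 1) is the normal mass below zero; compare against
        # adaptive quadrature of the density over (-inf, 0)
        dd_grid = np.linspace(-1.0, 1.0, 20)
        sm_grid = np.geomspace(0.02, 2.0, 20)
        for dd in dd_grid:
            for sm in sm_grid:
                oracle, err = quad(
                    lambda x: norm.pdf(x, loc=dd, scale=sm), -np.inf, 0.0
                )
                got = choice_probability(abs(dd) + dd, abs(dd), sm)
                assert got == pytest.approx(oracle, abs=1e-8)

    def test_vectorised(self):
        p = choice_probability([0.1, 0.3], [0.3, 0.1], 0.2)
        assert p.shape == (2,) and p[0] > 0.5 > p[1]


class TestSimulateTrial:
    def test_degenerate_noise_pins_estimates(self):
        obs = ObserverParams(phi=0.6, sigma_i1=0.0, sigma_i2=0.0, sigma_meta=0.5)
        rec = simulate_trial(obs, "V", 1.5, rng=np.random.default_rng(0))
        assert rec.estimate1 == rec.estimate2 == pytest.approx(0.6)

    def test_zero_meta_noise_always_picks_smaller_error(self):
        obs = ObserverParams(phi=0.75, sigma_meta=0.0)
        ds = simulate_session(obs, "V", 1.5, ScheduleSpec(200, 100), seed=4)
        f = ds.frame
        err1 = np.abs(f.estimate1 - 0.75)
        err2 = np.abs(f.estimate2 - 0.75)
        assert np.array_equal(
            f.meta_choice.to_numpy(), np.where(err1 <= err2, 1, 2)
        )

    def test_choice_rate_matches_analytic_probability(self):
        obs = ObserverParams(phi=0.75, sigma_i1=0.15, sigma_i2=0.15, sigma_meta=0.3)
        n = 100_000
        ds = simulate_session(obs, "V", 1.5, ScheduleSpec(n, 0), seed=13)
        f = ds.frame
        d1 = np.abs(f.estimate1 - 0.75)
        d2 = np.abs(f.estimate2 - 0.75)
        p = choice_probability(d1.to_numpy(), d2.to_numpy(), 0.3)
        expected = p.mean()
        observed = (f.meta_choice == 1).mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se


class TestSimulateSession:
    def test_seed_determinism(self):
        obs = ObserverParams()
        a = simulate_session(obs, "A", 1.5, seed=77)
        b = simulate_session(obs, "A", 1.5, seed=77)
        assert a.frame.equals(b.frame)

    def test_zero_trials_empty(self):
        ds = simulate_session(
            ObserverParams(), "V", 1.5, ScheduleSpec(n_trials=0, block_size=0)
        )
        assert len(ds) == 0

    def test_estimates_respect_physical_bounds(self):
        obs = ObserverParams(phi=0.2, sigma_i1=0.5, sigma_i2=0.5)
        ds = simulate_session(obs, "V", 1.5, ScheduleSpec(400, 0), seed=2)
        f = ds.frame
        assert f.estimate1.between(0, 1.5).all()
        assert f.estimate2.between(0, 1.5).all()
        ds.validate()

    def test_sample_mean_near_phi_clt(self):
        obs = ObserverParams(phi=0.75, sigma_i1=0.15)
        ds = simulate_session(obs, "V", 1.5, seed=31)
        m = ds.frame.estimate1.mean()
        assert abs(m - 0.75) < 4 * 0.15 / np.sqrt(500)

    def test_unbiased_observer_relative_bisection_half(self):
        obs = ObserverParams(phi=0.75)
        ds = simulate_session(obs, "V", 1.5, seed=8)
        rel = ds.frame.estimate1.mean() / 1.5
        assert rel == pytest.approx(0.5, abs=0.02)

    def test_drift_decays_toward_static_midpoint(self):
        obs = ObserverParams(phi=0.75, sigma_i1=0.02, drift=(0.3, 20.0))
        ds = simulate_session(obs, "V", 1.5, ScheduleSpec(500, 0), seed=14)
        e = ds.frame.estimate1.to_numpy()
        assert e[:25].mean() > e[-100:].mean() + 0.05

    def test_study_covers_all_subject_condition_cells(self):
        obs = sample_observers(GroupParams(), 2, seed=1)
        ds = simulate_study(obs, ("V", "A"), 1.5, ScheduleSpec(20, 0), seed=2)
        cells = ds.frame.groupby(["subject_id", "condition"]).size()
        assert len(cells) == 4 and (cells == 20).all()


class TestSampleObservers:
    def test_rho_one_perfect_rank_correlation(self):
        group = GroupParams(rho=1.0, sigma_spread=0.3)
        obs = sample_observers(group, 40, seed=3)
        v = np.array([[o.sigma_i1[c] for c in ("V", "A", "AV")] for o in obs])
        r = np.corrcoef(np.log(v.T))
        assert np.allclose(r, 1.0, atol=1e-9)

    def test_rho_zero_near_independence(self):
        group = GroupParams(rho=0.0, sigma_spread=0.3)
        obs = sample_observers(group, 2000, seed=4)
        v = np.array([[o.sigma_meta[c] for c in ("V", "A")] for o in obs])
        r = np.corrcoef(v.T)[0, 1]
        assert abs(r) < 0.05

    def test_requested_rho_recovered_empirically(self):
        group = GroupParams(rho=0.6, sigma_spread=0.2)
        obs = sample_observers(group, 2000, seed=5)
        v = np.array([[o.sigma_i2[c] for c in ("V", "A", "AV")] for o in obs])
        r = np.corrcoef(v.T)
        off = r[np.triu_indices(3, 1)]
        assert np.all(np.abs(off - 0.6) < 0.05)

    def test_positivity_and_validation(self):
        group = GroupParams(phi_sd=0.2, sigma_spread=1.0)
        for o in sample_observers(group, 50, seed=6):
            assert all(v > 0 for v in o.phi.values())
            assert all(v > 0 for v in o.sigma_meta.values())

    def test_parameter_bounds_enforced(self):
        with pytest.raises(ValueError):
            ObserverParams(rho=1.5)
        with pytest.raises(ValueError):
            ObserverParams(sigma_i1=-0.1)
        with pytest.raises(ValueError):
            GroupParams(rho=-0.2)


def test_mci_monotonic_short_grid():
    """Mean MCI ranks inversely with metacognitive noise (coarse grid)."""
    grid = (0.05, 0.4)
    means = []
    for sm in grid:
        vals = []
        for rep in range(40):
            obs = ObserverParams(sigma_meta=sm)
            ds = simulate_session(
                obs, "V", 1.5, ScheduleSpec(200, 0), seed=500 + rep
            )
            from metabisect import mci_from_dataset

            vals.append(mci_from_dataset(ds).mci)
        means.append(np.mean(vals))
    rho, _ = spearmanr(grid, means)
    assert rho == pytest.approx(-1.0)
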