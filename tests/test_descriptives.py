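"""Re-sorting, MCI, and trial-series statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from metabisect import (
    ObserverParams,
    ScheduleSpec,
    SessionDataset,
    TrialRecord,
    binned_series,
    coefficient_of_variation,
    compute_mci,
    estimate_histogram,
    mci_from_dataset,
    simulate_session,
    sort_ideal,
    sort_subjective,
    trial_autocorrelation,
)
from metabisect.descriptives import DegenerateVarianceError


def dataset_from_pairs(pairs, choices=None, dur=1.5):
    choices = choices or [1] * len(pairs)
    recs = [
        TrialRecord("S01", "V", dur, i + 1, e1, e2, ch)
        for i, ((e1, e2), ch) in enumerate(zip(pairs, choices))
    ]
    return SessionDataset.from_records(recs)


class TestSorting:
    @pytest.mark.parametrize(
        "choice,best,worst", [(1, 0.70, 0.90), (2, 0.90, 0.70)]
    )
    def test_subjective_routes_by_choice(self, choice, best, worst):
        ds = dataset_from_pairs([(0.70, 0.90)], [choice])
        s = sort_subjective(ds)
        assert (s.best[0], s.worst[0]) == (best, worst)

    def test_ideal_picks_closer_to_midpoint(self):
        ds = dataset_from_pairs([(0.70, 0.90)])
        s = sort_ideal(ds, true_mid=0.75)
        assert (s.best[0], s.worst[0]) == (0.70, 0.90)

    def test_ideal_tie_break_interval_1(self):
        ds = dataset_from_pairs([(0.74, 0.76)])
        s = sort_ideal(ds, true_mid=0.75)
        assert s.best[0] == 0.74

    def test_empty_slice_raises(self):
        ds = SessionDataset.from_records([])
        with pytest.raises(ValueError):
            sort_subjective(ds)

    @given(st.integers(0, 2**32 - 1))
    def test_multiset_preserved_under_both_sortings(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        pairs = rng.uniform(0, 1.5, size=(n, 2))
        choices = list(rng.integers(1, 3, size=n))
        ds = dataset_from_pairs([tuple(p) for p in pairs], choices)
        all_est = np.sort(pairs.ravel())
        for sorter in (sort_subjective, lambda d: sort_ideal(d, 0.75)):
            s = sorter(ds)
            combined = np.sort(np.concatenate([s.best, s.worst]))
            assert np.allclose(combined, all_est)

    def test_ideal_best_minimises_mse_exhaustively(self, rng):
        # over all 2^n per-pair selections, the ideal sorting attains the
        # minimum mean squared deviation from the target midpoint
        n, mid = 10, 0.75
        pairs = rng.uniform(0, 1.5, size=(n, 2))
        ds = dataset_from_pairs([tuple(p) for p in pairs])
        s = sort_ideal(ds, true_mid=mid)
        best_mse = np.mean((s.best - mid) ** 2)
        brute = min(
            np.mean(
                [(pairs[i, k] - mid) ** 2 for i, k in enumerate(sel)]
            )
            for sel in itertools.product([0, 1], repeat=n)
        )
        assert best_mse == pytest.approx(brute, abs=1e-15)

    def test_ideal_worst_further_from_midpoint_every_trial(self, small_session):
        s = sort_ideal(small_session)
        assert np.all(
            np.abs(s.best - s.true_mid) <= np.abs(s.worst - s.true_mid)
        )


class TestMci:
    def test_identical_sortings_give_exactly_one(self, small_session):
        s = sort_ideal(small_session)
        res = compute_mci(s, s)
        assert res.mci == 1.0

    def test_no_self_knowledge_reduces_to_ideal_ratio(self):
        # equal subjective best/worst variances => denominator is 1
        rng = np.random.default_rng(3)
        pairs = rng.uniform(0, 1.5, size=(50, 2))
        ds = dataset_from_pairs([tuple(p) for p in pairs])
        subj = sort_subjective(ds)
        ideal = sort_ideal(ds, 0.75)
        res = compute_mci(subj, ideal)
        expected = (res.v_ideal_best / res.v_ideal_worst) / (
            res.v_subj_best / res.v_subj_worst
        )
        assert res.mci == pytest.approx(expected)

    def test_ideal_chooser_end_to_end_is_one(self):
        obs = ObserverParams(phi=0.75, sigma_meta=0.0)
        ds = simulate_session(obs, "V", 1.5, seed=9)
        assert mci_from_dataset(ds).mci == 1.0

    def test_degenerate_variance_raises(self):
        # 0.5 is exactly representable, so the best-set variance is exactly 0
        ds = dataset_from_pairs([(0.5, 0.5), (0.5, 0.5), (0.5, 1.0)], [1, 1, 1])
        subj = sort_subjective(ds)
        ideal = sort_ideal(ds, 0.75)
        with pytest.raises(DegenerateVarianceError):
            compute_mci(subj, ideal)

    def test_affine_invariance(self, rng):
        pairs = rng.uniform(0, 1.5, size=(80, 2))
        choices = list(rng.integers(1, 3, size=80))
        ds = dataset_from_pairs([tuple(p) for p in pairs], choices)
        base = compute_mci(sort_subjective(ds), sort_ideal(ds, 0.75)).mci
        # rescale all estimates and the midpoint jointly
        a, b = 2.0, 0.3
        ds2 = dataset_from_pairs(
            [tuple(a * p + b) for p in pairs], choices, dur=a * 1.5 + 2 * b
        )
        scaled = compute_mci(
            sort_subjective(ds2), sort_ideal(ds2, a * 0.75 + b)
        ).mci
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_mean_mci_decreases_with_meta_noise(self):
        # 2-point check; the full grid is exercised in the acceptance suite
        means = []
        for sm in (0.05, 0.8):
            vals = []
            for rep in range(30):
                obs = ObserverParams(sigma_meta=sm)
                ds = simulate_session(
                    obs, "V", 1.5, ScheduleSpec(300, 100), seed=1000 + rep
                )
                vals.append(mci_from_dataset(ds).mci)
            means.append(np.mean(vals))
        assert means[0] > means[1]


class TestSeriesStats:
    def test_cv_definition(self):
        x = [1.0, 3.0]  # mean 2, sd sqrt(2)
        assert coefficient_of_variation(x) == pytest.approx(np.sqrt(2) / 2)
        assert coefficient_of_variation([2.0, 2.0, 2.0]) == 0.0
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])

    def test_cv_constant_across_durations_weber(self):
        # Weber scaling: sigma proportional to duration => equal CVs
        cvs = []
        for dur, sig in ((1.5, 0.15), (3.0, 0.30)):
            obs = ObserverParams(phi=dur / 2, sigma_i1=sig)
            ds = simulate_session(obs, "V", dur, ScheduleSpec(500, 100), seed=21)
            cvs.append(coefficient_of_variation(ds.frame["estimate1"]))
        assert cvs[0] == pytest.approx(cvs[1], rel=0.15)

    def test_binned_constant_series(self):
        bs = binned_series(np.full(100, 0.7), bin_size=50)
        assert len(bs.means) == 2
        assert np.all(bs.ci_low == bs.means) and np.all(bs.ci_high == bs.means)
        assert not bs.partial_last_bin

    def test_bin_centers_500_by_50(self):
        bs = binned_series(np.arange(500.0), bin_size=50)
        assert len(bs.means) == 10
        assert np.allclose(bs.centers, np.arange(25.5, 500, 50))

    def test_bin_means_match_bruteforce(self, rng):
        x = rng.normal(size=237)
        bs = binned_series(x, bin_size=50)
        brute = [x[i : i + 50].mean() for i in range(0, 237, 50)]
        assert np.allclose(bs.means, brute)
        assert bs.partial_last_bin

    def test_bin_size_larger_than_n_single_bin(self):
        bs = binned_series(np.arange(10.0), bin_size=50)
        assert len(bs.means) == 1

    def test_histogram_conventions(self, rng):
        edges, counts = estimate_histogram(np.full(7, 1.5), upper=1.5)
        assert counts[-1] == 7 and counts.sum() == 7
        edges, counts = estimate_histogram([], upper=1.5)
        assert counts.sum() == 0 and len(counts) == 150
        x = rng.uniform(0, 1.5, 400)
        edges, counts = estimate_histogram(x, upper=1.5)
        # independent digitize-and-tally
        idx = np.minimum(np.digitize(x, edges) - 1, 149)
        tally = np.bincount(idx, minlength=150)
        assert np.array_equal(counts, tally)

    def test_autocorrelation_limits(self, rng):
        assert trial_autocorrelation([1.0, 2.0, 3.0], 0)[0] == 1.0
        alt = np.tile([1.0, -1.0], 100)
        assert trial_autocorrelation(alt, 1)[1] == pytest.approx(-1.0)
        white = rng.normal(size=2000)
        ac = trial_autocorrelation(white, 5)
        assert np.all(np.abs(ac[1:]) < 3 / np.sqrt(2000))
        with pytest.raises(ValueError):
            trial_autocorrelation(np.ones(10), 2)
        with pytest.raises(ValueError):
            trial_autocorrelation([1.0, 2.0], 5)
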