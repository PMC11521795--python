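"""Generator contracts: determinism, Poisson moments, Hawkes stationarity."""

import numpy as np
import pytest
from scipy import stats

from strinet.behavior import CORRECT_LABELS, DEFAULT_TAXONOMY, extract_event_windows
from strinet.synthetic import (
    ClusterSpec,
    SimConfig,
    branching_matrix,
    check_stability,
    child_rng,
    gen_behavior_session,
    gen_event_modulated_train,
    gen_homogeneous_poisson,
    gen_hawkes_session,
    gen_unit_feature_table,
    simulate_hawkes,
)


class TestBehaviorGeneration:
    def test_seed_reproducibility(self):
        cfg = SimConfig(seed=1)
        s1, m1 = gen_behavior_session(cfg, stage=2)
        s2, m2 = gen_behavior_session(cfg, stage=2)
        assert s1.zone_timeline == s2.zone_timeline
        assert m1.trial_labels == m2.trial_labels

    def test_stage4_with_correct_prob_one_is_all_correct(self, monkeypatch):
        import strinet.synthetic as syn

        monkeypatch.setitem(syn.STAGE_CORRECT_PROB, 4, 1.0)
        cfg = SimConfig(seed=2)
        _, manifest = gen_behavior_session(cfg, stage=4)
        assert manifest.trial_labels
        assert all(lab in CORRECT_LABELS for lab in manifest.trial_labels)

    def test_classified_labels_match_manifest(self, stage1_session):
        session, manifest = stage1_session
        assert [tr.label for tr in session.traversals] == manifest.trial_labels

    def test_uniform_menu_path_counts_within_binomial_bound(self):
        """Across many stage-1 trials each eligible path stays within 3 sigma
        of its expected draw count (binomial CI oracle, conditional on the
        starting feeder being visited about half the time each)."""
        cfg = SimConfig(seed=3, session_duration=12000.0)
        _, manifest = gen_behavior_session(cfg, stage=1)
        n = len(manifest.trial_labels)
        assert n > 300
        # incorrect paths: per starting feeder, 5 eligible with equal menu
        # weight sharing probability (1 - 0.5); expected per path = n/2 * 0.1
        counts = {lab: manifest.trial_labels.count(lab) for lab in DEFAULT_TAXONOMY}
        for lab in DEFAULT_TAXONOMY:
            if lab in CORRECT_LABELS:
                p = 0.5  # given the starting feeder
            else:
                p = 0.1
            exp = n / 2 * p
            sd = np.sqrt(n / 2 * p * (1 - p))
            assert abs(counts[lab] - exp) < 3.5 * sd, lab

    def test_invalid_probabilities_rejected(self):
        menu = {lab: (5.0, 0.5) for lab in DEFAULT_TAXONOMY}
        with pytest.raises(Exception):
            SimConfig(seed=0, path_menu=menu)

    def test_trials_separated_by_gap(self, stage1_session):
        session, _ = stage1_session
        trs = session.traversals
        for a, b in zip(trs, trs[1:]):
            assert b.start - a.end >= 0.5


class TestHomogeneousPoisson:
    def test_zero_rate_empty(self, rng):
        assert gen_homogeneous_poisson(0.0, [(0, 100)], rng).size == 0

    def test_negative_rate_errors(self, rng):
        with pytest.raises(ValueError):
            gen_homogeneous_poisson(-1.0, [(0, 1)], rng)

    def test_support_restricted_to_intervals(self, rng):
        sp = gen_homogeneous_poisson(10.0, [(0, 1), (2, 3)], rng)
        assert np.all((sp < 1) | (sp >= 2))
        assert np.all(np.diff(sp) >= 0)

    def test_mean_count_matches_poisson_moment(self):
        """Mean of 500 replicate counts at 5 Hz x 1000 s within 3 SE of 5000."""
        counts = [
            gen_homogeneous_poisson(5.0, [(0, 1000)], child_rng(11, k)).size
            for k in range(500)
        ]
        se = np.sqrt(5000 / 500)
        assert abs(np.mean(counts) - 5000) < 3 * se

    def test_counts_fit_poisson_distribution(self):
        """Chi-squared goodness of fit of 500 replicate counts at alpha=0.01."""
        lam = 20.0
        counts = np.array([
            gen_homogeneous_poisson(lam, [(0, 1.0)], child_rng(12, k)).size
            for k in range(500)
        ])
        lo, hi = int(stats.poisson.ppf(0.01, lam)), int(stats.poisson.ppf(0.99, lam))
        edges = np.arange(lo, hi + 1)
        obs = np.array([np.sum(counts == v) for v in edges], dtype=float)
        obs = np.concatenate(([np.sum(counts < lo)], obs, [np.sum(counts > hi)]))
        probs = np.concatenate(
            ([stats.poisson.cdf(lo - 1, lam)], stats.poisson.pmf(edges, lam),
             [stats.poisson.sf(hi, lam)])
        )
        res = stats.chisquare(obs, 500 * probs / probs.sum())
        assert res.pvalue > 0.01


class TestEventModulatedPoisson:
    def test_unit_gains_reduce_to_homogeneous_rate(self, stage1_session, stage1_windows):
        session, _ = stage1_session
        sp = gen_event_modulated_train(4.0, np.ones(30), session, child_rng(13, 0),
                                       windows=stage1_windows)
        rate = sp.size / session.duration
        se = np.sqrt(4.0 / session.duration)
        assert abs(rate - 4.0) < 4 * se

    def test_gain_zero_bin_is_silent(self, stage1_session, stage1_windows):
        session, _ = stage1_session
        gains = np.ones(30)
        gains[7] = 0.0  # second bin of event B
        sp = gen_event_modulated_train(20.0, gains, session, child_rng(13, 1),
                                       windows=stage1_windows)
        for w in stage1_windows:
            if w.event == "B":
                b0, b1 = w.bins[2]  # 30-bin layout: B occupies bins 5..9
        gains_bins = [w.bins[2] for w in stage1_windows if w.event == "B"]
        n = sum(
            np.searchsorted(sp, b1) - np.searchsorted(sp, b0) for b0, b1 in gains_bins
        )
        assert n == 0

    def test_modulated_bin_rate_matches_gain(self, stage1_session, stage1_windows):
        """Gain 4 on one 100 ms bin of event A at 2 Hz baseline: empirical
        rate in that bin is ~8 Hz within 3 SE across passages."""
        session, _ = stage1_session
        gains = {"A": np.array([1.0, 1.0, 4.0, 1.0, 1.0])}
        sp = gen_event_modulated_train(2.0, gains, session, child_rng(13, 2),
                                       windows=stage1_windows)
        a_bins = [w.bins[2] for w in stage1_windows if w.event == "A"]
        n = sum(np.searchsorted(sp, b1) - np.searchsorted(sp, b0) for b0, b1 in a_bins)
        dur = 0.1 * len(a_bins)
        rate = n / dur
        se = np.sqrt(8.0 / dur)
        assert abs(rate - 8.0) < 3 * se


class TestHawkesSimulation:
    def test_zero_kernel_reduces_to_poisson_rate(self, rng):
        mu = np.array([3.0, 1.0])
        a = np.zeros((2, 2, 6))
        trains = simulate_hawkes(mu, a, (0.0, 1000.0), rng)
        for n, m in enumerate(mu):
            se = np.sqrt(m / 1000.0)
            assert abs(trains[n].size / 1000.0 - m) < 4 * se

    def test_long_run_rate_matches_branching_closed_form(self):
        """(I - A)^-1 mu with A the L1 branching matrix, within 3 MC SE."""
        mu = np.array([1.0, 2.0])
        a = np.zeros((2, 2, 6))
        a[0, 0, :] = 0.3 / 0.06  # self mass 0.3
        a[0, 1, 1] = 0.4 / 0.01  # cross mass 0.4 on one plateau
        A = branching_matrix(a)
        target = np.linalg.solve(np.eye(2) - A.T, mu)
        T = 3000.0
        trains = simulate_hawkes(mu, a, (0.0, T), np.random.default_rng(5))
        for n in range(2):
            rate = trains[n].size / T
            se = np.sqrt(target[n] / T) * 3  # conservative Poisson-scale SE
            assert abs(rate - target[n]) < 3 * se

    def test_unstable_spec_rejected_with_condition_name(self):
        a = np.zeros((1, 1, 6))
        a[0, 0, :] = 2.0 / 0.06
        with pytest.raises(ValueError, match="boom"):
            check_stability(a, "boom")

    def test_session_trains_are_deterministic_and_in_trials(self, stage1_session):
        session, _ = stage1_session
        mu = np.array([2.0, 2.0])
        a = np.zeros((2, 2, 6))
        a[0, 1, 0] = 20.0
        spec = {lab: (mu, a) for lab in DEFAULT_TAXONOMY}
        t1 = gen_hawkes_session(spec, session, 42)
        t2 = gen_hawkes_session(spec, session, 42)
        for x, y in zip(t1, t2):
            assert np.array_equal(x, y)
        spans = [(tr.start, tr.end) for tr in session.traversals]
        for train in t1:
            assert np.all(np.diff(train) > 0)
            inside = np.zeros(train.size, dtype=bool)
            for s, e in spans:
                inside |= (train >= s) & (train < e)
            assert inside.all()

    def test_negative_kernels_require_rectify(self, rng):
        a = np.zeros((1, 1, 6))
        a[0, 0, 0] = -5.0
        with pytest.raises(ValueError):
            simulate_hawkes(np.array([1.0]), a, (0, 10), rng)
        trains = simulate_hawkes(np.array([1.0]), a, (0, 10), rng, rectify=True)
        assert trains[0].size >= 0


class TestUnitFeatureTable:
    SPEC = {
        "MSN": ClusterSpec(mean=(0.2, 550.0, 320.0), sd=(0.5, 60.0, 40.0)),
        "FSI": ClusterSpec(mean=(2.5, 250.0, 150.0), sd=(0.5, 60.0, 40.0)),
    }

    def test_single_cluster_table(self, rng):
        df, labels = gen_unit_feature_table(self.SPEC, n_msn=5, n_fsi=0, rng=rng)
        assert len(df) == 5 and set(labels) == {"MSN"}

    def test_negative_counts_error(self, rng):
        with pytest.raises(ValueError):
            gen_unit_feature_table(self.SPEC, n_msn=-1, n_fsi=2, rng=rng)

    def test_seed_reproducibility(self):
        df1, _ = gen_unit_feature_table(self.SPEC, 10, 5, np.random.default_rng(3))
        df2, _ = gen_unit_feature_table(self.SPEC, 10, 5, np.random.default_rng(3))
        assert df1.equals(df2)

    def test_fsi_cluster_is_fast_and_narrow(self, rng):
        df, labels = gen_unit_feature_table(self.SPEC, 50, 50, rng)
        lab = np.array(labels)
        assert df.loc[lab == "FSI", "log_rate"].mean() > df.loc[lab == "MSN", "log_rate"].mean()
        assert df.loc[lab == "FSI", "pv_us"].mean() < df.loc[lab == "MSN", "pv_us"].mean()
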