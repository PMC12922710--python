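"""Staircase dynamics, curation, binning, and Weibull threshold fits."""

import numpy as np
import pandas as pd
import pytest

from conedrift import psychophysics as psy
from conedrift.errors import BinningError, DegenerateInputError, FitError


class TestStaircase:
    def test_initial_descent_factor(self):
        state = psy.StaircaseState()
        assert state.next_size == 48.0
        state = psy.staircase_next(state, True)
        assert state.next_size == pytest.approx(48.0 / 1.75)  # 27.43 arcsec

    def test_first_error_enters_main_phase(self):
        state = psy.StaircaseState()
        state = psy.staircase_next(state, True)
        state = psy.staircase_next(state, False)
        assert state.phase == "main"

    def test_two_down_step(self):
        state = psy.StaircaseState(current_size=20.0, phase="main")
        state = psy.staircase_next(state, True)
        assert state.current_size == 20.0  # one correct: no step yet
        state = psy.staircase_next(state, True)
        assert state.current_size == pytest.approx(20.0 * 0.82)  # 16.4

    def test_one_up_step(self):
        state = psy.StaircaseState(current_size=20.0, phase="main")
        state = psy.staircase_next(state, False)
        assert state.current_size == pytest.approx(30.0)  # x1.5

    def test_every_sixth_trial_is_motivational(self):
        state = psy.StaircaseState(current_size=10.0, phase="main")
        sizes, flags = [], []
        for i in range(12):
            sizes.append(state.next_size)
            flags.append(state.next_is_motivational)
            state = psy.staircase_next(state, True)
        assert flags[5] and flags[11]
        assert sizes[5] == 48.0 and sizes[11] == 48.0
        # motivational responses never advance the two-down counter: with
        # all-correct responses, down-steps happen every 2 staircase trials
        log = pd.DataFrame(state.history, columns=["size", "correct", "mot"])
        staircase_sizes = log.loc[~log.mot, "size"].to_numpy()
        ratio = staircase_sizes[2] / staircase_sizes[0]
        assert ratio == pytest.approx(0.82)

    def test_convergence_near_alpha(self):
        # with multiplicative steps 0.82 down / 1.5 up the two-down/one-up
        # rule balances where p^2 log 0.82 + (1-p^2) log 1.5 = 0, i.e. at
        # ~82% correct, ~1.14 alpha for a beta = 3 Weibull; the late-trial
        # sizes concentrate there, within 25% of alpha
        alpha, beta, lam = 30.0, 3.0, 0.01
        meds = []
        for rep in range(100):
            rng = np.random.default_rng(900 + rep)
            log = psy.run_staircase(
                46, lambda s, i: psy.simulate_observer(s, alpha, beta, lam, rng)[0])
            tail = log.loc[~log.motivational, "size"].to_numpy()[-10:]
            meds.append(np.median(tail))
        assert abs(np.median(meds) / alpha - 1) < 0.25
        assert np.mean(np.abs(np.array(meds) / alpha - 1) < 0.25) > 0.6


class TestWeibull:
    def test_asymptotes(self):
        assert psy.weibull(1e-9, 30, 3, lam=0.01) == pytest.approx(0.25)
        assert psy.weibull(1e9, 30, 3, lam=0.01) == pytest.approx(0.99)

    def test_threshold_criterion_identity(self):
        for alpha, beta, lam in [(30, 3, 0.0), (20, 2.2, 0.05), (45, 5, 0.01)]:
            thr = psy.weibull_threshold(alpha, beta, lam=lam)
            assert psy.weibull(thr, alpha, beta, lam=lam) == pytest.approx(
                0.625, abs=1e-9)

    def test_criterion_halfway_between_guess_and_perfect(self):
        # 0.625 = gamma + (1 - gamma) / 2 for gamma = 0.25
        assert psy.CRITERION == psy.GUESS_RATE + (1 - psy.GUESS_RATE) / 2

    def test_monotone_nondecreasing(self):
        x = np.linspace(0.1, 100, 500)
        y = psy.weibull(x, 30, 3, lam=0.02)
        assert np.all(np.diff(y) >= 0)


class TestSimulatedObserver:
    def test_empirical_rate_matches_curve(self):
        rng = np.random.default_rng(55)
        alpha, beta, lam, size = 30.0, 3.0, 0.01, 26.0
        p = psy.weibull(size, alpha, beta, lam=lam)
        n = 10_000
        hits = sum(psy.simulate_observer(size, alpha, beta, lam, rng)[0]
                   for _ in range(n))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_incorrect_reports_are_foils(self):
        rng = np.random.default_rng(56)
        reports = {psy.simulate_observer(1e-6, 30, 3, 0.0, rng)[1]
                   for _ in range(200)}
        assert reports <= {0, 1, 2, 3}
        assert {1, 2, 3} <= reports

    def test_nonpositive_size_raises(self):
        with pytest.raises(DegenerateInputError):
            psy.simulate_observer(0.0, 30, 3, 0.0, np.random.default_rng(0))


class TestCuration:
    @staticmethod
    def _trials(n, flags):
        df = pd.DataFrame({"size": np.full(n, 20.0),
                           "correct": np.ones(n, bool)})
        for k, v in flags.items():
            df[k] = v
        return df

    def test_no_flags_keeps_all(self):
        kept, excl = psy.curate(self._trials(10, {}))
        assert len(kept) == 10 and len(excl) == 0

    def test_single_blink_removed_with_reason(self):
        blink = np.zeros(10, bool)
        blink[4] = True
        kept, excl = psy.curate(self._trials(10, {"blink": blink,
                                                  "microsaccade": False}))
        assert len(kept) == 9
        assert excl.index.tolist() == [4]
        assert excl.reason.iloc[0] == "blink"

    def test_all_removed_raises(self):
        with pytest.raises(DegenerateInputError):
            psy.curate(self._trials(5, {"blink": True}))


class TestBinning:
    def test_uniform_sizes_partition(self):
        rng = np.random.default_rng(61)
        sizes = rng.uniform(10, 48, 200)
        correct = rng.random(200) < 0.7
        bins = psy.bin_trials(sizes, correct)
        assert len(bins.center) >= 7
        assert bins.n.sum() == 200          # every trial in exactly one bin
        assert bins.width == 5.0            # smallest allowed width works
        assert not bins.fallback

    def test_matches_bruteforce_interval_assignment(self):
        rng = np.random.default_rng(62)
        sizes = 48 * 0.82 ** rng.integers(0, 10, 150)
        correct = rng.random(150) < 0.6
        bins = psy.bin_trials(sizes, correct)
        # oracle: assign each trial to its interval by direct comparison
        lo = bins.edges[0]
        centers, ns, ks = [], [], []
        for i in range(len(bins.edges) - 1):
            sel = (sizes >= bins.edges[i]) & (sizes < bins.edges[i + 1])
            if sel.any():
                centers.append(sizes[sel].mean())
                ns.append(sel.sum())
                ks.append(correct[sel].sum())
        order = np.argsort(centers)
        assert np.allclose(bins.center, np.array(centers)[order])
        assert np.array_equal(bins.n, np.array(ns)[order])
        assert np.array_equal(bins.k, np.array(ks)[order])
        assert bins.n.sum() == 150

    def test_degenerate_single_size_raises(self):
        with pytest.raises(BinningError):
            psy.bin_trials(np.full(50, 20.0), np.ones(50, bool))


class TestFit:
    @staticmethod
    def _simulated_log(rng, alpha=30.0, beta=3.0, lam=0.01, runs=5):
        logs = [psy.run_staircase(
            23, lambda s, i: psy.simulate_observer(s, alpha, beta, lam, rng)[0])
            for _ in range(runs)]
        return pd.concat(logs, ignore_index=True)

    def test_threshold_invariant_to_trial_order(self):
        rng = np.random.default_rng(71)
        log = self._simulated_log(rng)
        bins1 = psy.bin_trials(log["size"], log["correct"])
        perm = log.sample(frac=1, random_state=1)
        bins2 = psy.bin_trials(perm["size"], perm["correct"])
        f1 = psy.fit_psychometric(bins1)
        f2 = psy.fit_psychometric(bins2)
        assert f1.threshold == pytest.approx(f2.threshold, rel=1e-9)

    def test_monotone_recovery_in_alpha(self):
        # better true acuity (lower alpha) -> lower estimated threshold
        med = []
        for alpha in (20.0, 30.0, 40.0):
            thrs = []
            for rep in range(10):
                rng = np.random.default_rng(1000 + rep)
                log = self._simulated_log(rng, alpha=alpha)
                bins = psy.bin_trials(log["size"], log["correct"])
                thrs.append(psy.fit_psychometric(bins).threshold)
            med.append(np.median(thrs))
        assert med[0] < med[1] < med[2]

    def test_all_correct_raises(self):
        bins = psy.Bins(edges=np.array([0, 50]), center=np.array([10., 20., 30.]),
                        n=np.array([5, 5, 5]), k=np.array([5, 5, 5]), width=5.0)
        with pytest.raises(FitError):
            psy.fit_psychometric(bins)

    def test_chance_performance_raises(self):
        bins = psy.Bins(edges=np.array([0, 50]), center=np.array([10., 20., 30.]),
                        n=np.array([20, 20, 20]), k=np.array([5, 4, 5]), width=5.0)
        with pytest.raises(FitError):
            psy.fit_psychometric(bins)

    def test_bootstrap_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(72)
        log = self._simulated_log(rng)
        bins = psy.bin_trials(log["size"], log["correct"])
        fit = psy.fit_psychometric(bins, n_boot=200, rng=rng,
                                   sizes=log["size"], correct=log["correct"])
        assert fit.ci is not None
        assert fit.ci[0] < fit.threshold < fit.ci[1]
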