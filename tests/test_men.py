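import numpy as np
import pytest

from motionbmi import (
    FilterConfig,
    MagnitudePair,
    MEnParams,
    calibrate_tolerances,
    filter_windows,
    motion_entropy,
    template_match_counts,
    vector_magnitudes,
)

from _oracles import naive_match_counts, naive_motion_entropy, naive_sampen
from conftest import make_window, random_window

MODES = ["literal_average", "joint"]
NORMS = ["sampen_consistent", "strict_literal"]


def magnitude_window(acc_mag, gyro_mag):
    """Window whose per-sample magnitudes equal the given series exactly."""
    acc = np.asarray(acc_mag, dtype=float)
    gyro = np.asarray(gyro_mag, dtype=float)
    data = np.zeros((6, len(acc)))
    data[0] = acc  # magnitude of (x, 0, 0) is |x|
    data[3] = gyro
    return make_window(data)


class TestVectorMagnitudes:
    def test_pythagorean_triple(self):
        data = np.array([[3.0], [4.0], [0.0], [0.0], [0.0], [0.0]])
        m = vector_magnitudes(make_window(data))
        assert m.acc_mag[0] == 5.0
        assert m.gyro_mag[0] == 0.0

    def test_zero_sample(self):
        m = vector_magnitudes(make_window(np.zeros((6, 4))))
        assert np.all(m.acc_mag == 0) and np.all(m.gyro_mag == 0)

    def test_matches_elementwise_loop(self, rng):
        win = random_window(rng, w=25)
        m = vector_magnitudes(win)
        for i in range(25):
            acc = sum(win.data[c, i] ** 2 for c in range(3)) ** 0.5
            gyro = sum(win.data[c, i] ** 2 for c in range(3, 6)) ** 0.5
            assert abs(m.acc_mag[i] - acc) < 1e-12
            assert abs(m.gyro_mag[i] - gyro) < 1e-12


class TestTemplateMatchCounts:
    def test_constant_series_all_match(self):
        m = MagnitudePair(np.full(10, 2.0), np.full(10, 3.0))
        b0, b1 = template_match_counts(m, 2, 0.5, 0.5)
        assert b0 == 1.0 and b1 == 1.0

    def test_zero_tolerance_all_distinct_no_matches(self):
        x = np.arange(10, dtype=float)
        m = MagnitudePair(x, x)
        b0, b1 = template_match_counts(m, 2, 0.0, 0.0)
        assert b0 == 0.0 and b1 == 0.0

    @pytest.mark.parametrize("mode", MODES)
    @pytest.mark.parametrize("norm", NORMS)
    def test_toy_window_matches_triple_loop(self, mode, norm):
        acc = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 9.0])
        m = MagnitudePair(acc, acc.copy())
        got = template_match_counts(m, 2, 0.5, 0.5, mode, norm)
        want = naive_match_counts(acc, acc, 2, 0.5, 0.5, mode, norm)
        assert got == pytest.approx(want, abs=1e-12)

    def test_rejects_oversized_template(self):
        m = MagnitudePair(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError, match="template"):
            template_match_counts(m, 4, 1.0, 1.0)

    def test_monotone_in_tolerance(self, rng):
        for _ in range(20):
            x = rng.normal(size=20)
            m = MagnitudePair(np.abs(x), np.abs(rng.normal(size=20)))
            probs = [
                template_match_counts(m, 2, r, 0.3)[0] for r in (0.05, 0.2, 0.8)
            ]
            assert probs == sorted(probs)
            probs_g = [
                template_match_counts(m, 2, 0.3, r)[0] for r in (0.05, 0.2, 0.8)
            ]
            assert probs_g == sorted(probs_g)


class TestMotionEntropy:
    def test_constant_window_has_zero_entropy(self):
        win = make_window(np.ones((6, 20)))
        res = motion_entropy(win, MEnParams(xi=2, r_acc=0.1, r_gyro=0.1))
        assert res.value == 0.0

    def test_no_matches_yields_inf_sentinel(self):
        win = magnitude_window(np.arange(10.0), np.arange(10.0))
        res = motion_entropy(win, MEnParams(xi=2, r_acc=0.0, r_gyro=0.0))
        assert np.isinf(res.value)
        assert res.degenerate

    @pytest.mark.parametrize("mode", MODES)
    @pytest.mark.parametrize("norm", NORMS)
    def test_oracle_equivalence_random_windows(self, rng, mode, norm):
        for _ in range(25):
            w = int(rng.integers(12, 40))
            win = random_window(rng, w=w)
            m = vector_magnitudes(win)
            r_acc = 0.2 * m.acc_mag.std() + 0.05
            r_gyro = 0.2 * m.gyro_mag.std() + 0.05
            got = motion_entropy(
                win,
                MEnParams(
                    xi=2, r_acc=r_acc, r_gyro=r_gyro,
                    match_mode=mode, normalization=norm,
                ),
            ).value
            want = naive_motion_entropy(
                m.acc_mag, m.gyro_mag, 2, r_acc, r_gyro, mode, norm
            )
            if np.isinf(want):
                assert np.isinf(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("mode", MODES)
    def test_reduces_to_sampen_when_channels_coincide(self, rng, mode):
        for _ in range(10):
            x = np.abs(rng.normal(1.0, 0.5, size=30))
            win = magnitude_window(x, x)
            r = 0.25 * x.std()
            got = motion_entropy(
                win, MEnParams(xi=2, r_acc=r, r_gyro=r, match_mode=mode)
            ).value
            want = naive_sampen(x, 2, r)
            if np.isinf(want):
                assert np.isinf(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)

    def test_sampen_consistent_entropy_is_nonnegative(self, rng):
        for _ in range(30):
            win = random_window(rng, w=int(rng.integers(15, 45)))
            m = vector_magnitudes(win)
            res = motion_entropy(
                win,
                MEnParams(
                    xi=2,
                    r_acc=0.3 * m.acc_mag.std(),
                    r_gyro=0.3 * m.gyro_mag.std(),
                ),
            )
            assert res.b_xi_plus_1 <= res.b_xi + 1e-15
            if not res.degenerate:
                assert res.value >= 0.0


class TestCalibration:
    def test_zero_variance_warns(self):
        wins = [make_window(np.ones((6, 10)))]
        with pytest.warns(RuntimeWarning, match="zero"):
            r_acc, r_gyro = calibrate_tolerances(wins, 0.05)
        assert r_acc == 0.0 and r_gyro == 0.0

    def test_single_window_scales_std(self):
        # acc magnitude alternates 0/4 -> std 2.0; psi 0.05 -> r_acc 0.1
        acc = np.tile([0.0, 4.0], 10)
        win = magnitude_window(acc, acc)
        r_acc, _ = calibrate_tolerances([win], 0.05)
        assert r_acc == pytest.approx(0.1)

    def test_matches_two_pass_recomputation(self, rng):
        wins = [random_window(rng, w=30) for _ in range(100)]
        r_acc, r_gyro = calibrate_tolerances(wins, 0.05)
        accs, gyros = [], []
        for w in wins:
            m = vector_magnitudes(w)
            accs.append(np.std(m.acc_mag))
            gyros.append(np.std(m.gyro_mag))
        assert r_acc == pytest.approx(0.05 * np.mean(accs), abs=1e-12)
        assert r_gyro == pytest.approx(0.05 * np.mean(gyros), abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            calibrate_tolerances([], 0.05)


class TestFiltering:
    def make_pool(self, rng, n=200, w=30):
        return [random_window(rng, w=w, index=i + 1) for i in range(n)]

    def test_theta_zero_is_identity(self, rng):
        wins = self.make_pool(rng, n=50)
        kept, results = filter_windows(
            wins, FilterConfig(threshold_percentile=0.0, psi=1.0)
        )
        assert kept == wins
        assert len(results) == 50

    @pytest.mark.parametrize("theta", [0.05, 0.1, 0.25])
    def test_retention_law(self, rng, theta):
        from motionbmi import compute_men

        cfg = FilterConfig(threshold_percentile=theta, psi=1.0)
        pool = self.make_pool(rng, n=300, w=60)
        tol = calibrate_tolerances(pool, cfg.psi)
        men = compute_men(pool, cfg, tolerances=tol)
        # build a tie-free finite pool by deduplicating on MEn value
        seen, wins = set(), []
        for win, res in zip(pool, men):
            if np.isfinite(res.value) and res.value not in seen:
                seen.add(res.value)
                wins.append(win)
        n = len(wins)
        assert n >= 150
        kept, results = filter_windows(wins, cfg, tolerances=tol)
        k = int(np.floor(theta * n))
        assert abs(len(kept) - (n - 2 * k)) <= 1

    def test_keeps_central_mass(self, rng):
        wins = self.make_pool(rng, n=100)
        cfg = FilterConfig(threshold_percentile=0.2, psi=1.0)
        kept, results = filter_windows(wins, cfg)
        values = np.array([r.value for r in results])
        kept_idx = [wins.index(w) for w in kept]
        kept_vals = values[kept_idx]
        dropped_vals = np.delete(values, kept_idx)
        lo, hi = kept_vals.min(), kept_vals.max()
        assert np.all((dropped_vals < lo) | (dropped_vals > hi))

    def test_order_preserved(self, rng):
        wins = self.make_pool(rng, n=80)
        kept, _ = filter_windows(wins, FilterConfig(threshold_percentile=0.1, psi=1.0))
        positions = [wins.index(w) for w in kept]
        assert positions == sorted(positions)

    def test_identical_values_tie_break_is_stable(self):
        wins = [make_window(np.ones((6, 12)), index=i + 1) for i in range(50)]
        cfg = FilterConfig(threshold_percentile=0.1, psi=1.0)
        # constant windows -> MEn 0 everywhere (all templates match)
        kept, results = filter_windows(wins, cfg, tolerances=(0.5, 0.5))
        assert len(kept) in (40, 50)

    def test_infinite_men_always_removed(self, rng):
        wins = self.make_pool(rng, n=60)
        cfg = FilterConfig(threshold_percentile=0.05)
        kept, results = filter_windows(wins, cfg, tolerances=(1e-9, 1e-9))
        # zero-ish tolerance: no matches anywhere -> all degenerate -> all removed
        assert all(np.isinf(r.value) for r in results)
        assert kept == []

    def test_filtering_is_label_blind(self, rng):
        wins = self.make_pool(rng, n=100)
        cfg = FilterConfig(threshold_percentile=0.15, psi=1.0)
        kept_a, _ = filter_windows(wins, cfg)
        relabeled = [
            make_window(w.data, index=w.window_index, bmi=float(i))
            for i, w in enumerate(wins)
        ]
        kept_b, _ = filter_windows(relabeled, cfg)
        assert [w.window_index for w in kept_a] == [
            w.window_index for w in kept_b
        ]

    def test_low_noise_windows_survive_preferentially(self):
        rng = np.random.default_rng(7)
        t = np.arange(30) / 30.0
        clean, noisy = [], []
        for i in range(40):
            base = np.tile(np.sin(2 * np.pi * 3 * t + rng.uniform(0, 6)), (6, 1))
            clean.append(make_window(base + rng.normal(0, 0.01, base.shape), index=i + 1))
            noisy.append(
                make_window(base + rng.normal(0, 1.0, base.shape), index=100 + i)
            )
        pool = clean + noisy
        cfg = FilterConfig(threshold_percentile=0.25, tail_mode="upper_tail")
        kept, results = filter_windows(pool, cfg)
        men = np.array([r.value for r in results])
        assert np.median(men[:40]) < np.median(men[40:])
        kept_clean = sum(1 for w in kept if w.window_index <= 40)
        kept_noisy = len(kept) - kept_clean
        assert kept_clean > kept_noisy

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(threshold_percentile=0.5, tail_mode="both_tails")
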