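"""Population binning and distance correlation with shuffle correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lamstate as ls
from lamstate.timescale import bin_ladder, bin_trace


def naive_dcor(x, y):
    """Independent O(n^2) double-centering oracle, element by element."""
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    n = x.shape[1]

    def centered(m):
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d[i, j] = np.linalg.norm(m[:, i] - m[:, j])
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                out[i, j] = d[i, j] - d[i].mean() - d[:, j].mean() + d.mean()
        return out

    a, b = centered(x), centered(y)
    dcov2 = (a * b).mean()
    dvx = (a * a).mean()
    dvy = (b * b).mean()
    if dvx * dvy <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0) / np.sqrt(dvx * dvy)))


class TestBinning:
    def test_two_spikes_two_bins(self):
        u = ls.Unit(unit_id="u", spike_times=np.array([0.05, 0.15]))
        m = ls.bin_population([u], duration_s=0.2, bin_s=0.1)
        assert np.allclose(m, [[10.0, 10.0]])

    def test_empty_unit_zero_row(self):
        u = ls.Unit(unit_id="u", spike_times=np.array([]))
        assert not ls.bin_population([u], 1.0, 0.1).any()

    def test_count_conservation(self, rng):
        spikes = np.sort(rng.uniform(0, 9.99, 500))
        u = ls.Unit(unit_id="u", spike_times=spikes)
        m = ls.bin_population([u], 10.0, 0.25)
        assert m.sum() * 0.25 == len(spikes)

    def test_trailing_partial_bin_dropped(self):
        u = ls.Unit(unit_id="u", spike_times=np.array([0.95]))
        m = ls.bin_population([u], duration_s=0.95, bin_s=0.3)
        assert m.shape[1] == 3  # 0.9 s covered; spike at 0.95 dropped
        assert m.sum() == 0

    def test_duration_shorter_than_bin_errors(self):
        u = ls.Unit(unit_id="u", spike_times=np.array([]))
        with pytest.raises(ValueError):
            ls.bin_population([u], 0.05, 0.1)

    def test_bin_trace_averages_within_bins(self):
        tr = ls.BehaviorTrace(np.arange(10) / 10.0, np.arange(10, dtype=float), 10.0)
        v = bin_trace(tr, 1.0, 0.5)
        assert np.allclose(v, [2.0, 7.0])


class TestDistanceCorrelation:
    def test_self_dependence_is_one(self, rng):
        x = rng.normal(size=50)
        assert ls.distance_correlation(x, x) == pytest.approx(1.0)

    def test_constant_input_is_zero(self, rng):
        assert ls.distance_correlation(np.full(30, 2.0), rng.normal(size=30)) == 0.0

    def test_six_point_bivariate_matches_oracle(self, rng):
        x = rng.normal(size=(2, 6))
        y = rng.normal(size=6)
        assert ls.distance_correlation(x, y) == pytest.approx(
            naive_dcor(x, y), abs=1e-12
        )

    def test_oracle_equality_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            k = int(rng.integers(1, 4))
            x = rng.normal(size=(k, n))
            y = rng.normal(size=n)
            assert ls.distance_correlation(x, y) == pytest.approx(
                naive_dcor(x, y), abs=1e-10
            )

    def test_perfect_linear_dependence_is_one(self, rng):
        x = rng.normal(size=40)
        assert ls.distance_correlation(x, 3.0 * x - 7.0) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=25)
    @given(
        st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
        st.floats(-5, 5),
        st.floats(-5, 5).filter(lambda c: abs(c) > 1e-3),
        st.floats(-5, 5),
        st.integers(0, 10_000),
    )
    def test_affine_invariance(self, a, b, c, d, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = rng.normal(size=25) + 0.5 * x
        d0 = ls.distance_correlation(x, y)
        d1 = ls.distance_correlation(a * x + b, c * y + d)
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_mismatched_samples_error(self):
        with pytest.raises(ValueError):
            ls.distance_correlation(np.zeros(10), np.zeros(11))


class TestSweep:
    def _null_case(self, seed=0, duration=210.0):
        rng = np.random.default_rng(seed)
        units = [
            ls.Unit(
                unit_id=f"u{k}",
                spike_times=np.sort(rng.uniform(0, duration, int(8 * duration))),
            )
            for k in range(12)
        ]
        speed = ls.BehaviorTrace(
            np.arange(int(duration * 100)) / 100.0,
            np.abs(rng.normal(0, 2, int(duration * 100))),
            100.0,
        )
        return units, speed, duration

    def test_null_coupling_corrected_near_zero(self):
        units, speed, duration = self._null_case()
        sweep = ls.dcor_sweep(
            units, speed, duration, bin_ladder(0.1, 1.6), n_shuffles=30, seed=5
        )
        assert np.all(np.abs(sweep.dcor_corrected) < 0.05)

    def test_raw_values_bounded(self):
        units, speed, duration = self._null_case(seed=1)
        sweep = ls.dcor_sweep(
            units, speed, duration, bin_ladder(0.2, 3.2), n_shuffles=10, seed=2
        )
        ok = np.isfinite(sweep.dcor_raw)
        assert np.all((sweep.dcor_raw[ok] >= 0) & (sweep.dcor_raw[ok] <= 1))
        assert np.all(
            (sweep.p_value[ok] >= 0) & (sweep.p_value[ok] <= 1)
        )

    def test_p_value_granularity(self):
        units, speed, duration = self._null_case(seed=2, duration=60.0)
        sweep = ls.dcor_sweep(
            units, speed, duration, np.array([0.4]), n_shuffles=10, seed=0
        )
        assert (sweep.p_value[0] * 10) == pytest.approx(round(sweep.p_value[0] * 10))

    def test_fixed_seed_reproducible(self):
        units, speed, duration = self._null_case(seed=3, duration=80.0)
        a = ls.dcor_sweep(units, speed, duration, bin_ladder(0.2, 1.6), 10, seed=9)
        b = ls.dcor_sweep(units, speed, duration, bin_ladder(0.2, 1.6), 10, seed=9)
        assert np.array_equal(a.dcor_raw, b.dcor_raw)
        assert np.array_equal(a.shuffle_mean, b.shuffle_mean)
        assert np.array_equal(a.p_value, b.p_value)

    def test_too_few_bins_marked_undefined(self):
        units, speed, duration = self._null_case(seed=4, duration=60.0)
        sweep = ls.dcor_sweep(
            units, speed, duration, np.array([0.4, 40.0]), n_shuffles=5, seed=0
        )
        assert np.isfinite(sweep.dcor_raw[0])
        assert np.isnan(sweep.dcor_raw[1])

    def test_coupled_population_detected(self):
        units, speed = ls.generate_coupled_population(
            n_units=20, duration_s=120.0, tau_s=0.4, seed=0
        )
        sweep = ls.dcor_sweep(
            units, speed, 120.0, np.array([0.4]), n_shuffles=20, seed=1
        )
        assert sweep.dcor_corrected[0] > 0.2
        assert sweep.p_value[0] == 0.0

    def test_p_value_valid_under_null(self):
        """P(p <= alpha) stays near alpha for independent speed/firing."""
        rng = np.random.default_rng(11)
        alpha, n_shuffles, n_rep = 0.1, 20, 100
        hits = 0
        for _ in range(n_rep):
            units = [
                ls.Unit(
                    unit_id="u",
                    spike_times=np.sort(rng.uniform(0, 40.0, 300)),
                )
            ]
            speed = ls.BehaviorTrace(
                np.arange(800) / 20.0, np.abs(rng.normal(0, 2, 800)), 20.0
            )
            sweep = ls.dcor_sweep(
                units, speed, 40.0, np.array([0.5]), n_shuffles,
                seed=rng.integers(1 << 31),
            )
            hits += sweep.p_value[0] <= alpha
        frac = hits / n_rep
        mc_se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert frac <= alpha + 1.0 / n_shuffles + 2 * mc_se

    def test_ladder_doubles_to_ceiling(self):
        ladder = bin_ladder(0.05, 40.0)
        assert ladder[0] == 0.05
        assert np.allclose(np.diff(np.log2(ladder)), 1.0)
        assert ladder[-1] <= 40.0 < ladder[-1] * 2
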