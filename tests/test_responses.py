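"""Per-trial firing rates, evoked-response significance, and latency."""

import numpy as np
import pytest

import lamstate as ls
from lamstate.responses import (
    ConditionKey,
    psth,
    response_latency,
    significant_evoked,
    trial_rates,
)


def _unit(spikes):
    return ls.Unit(unit_id="u", spike_times=np.asarray(spikes, float))


def _trials(onsets, stim="WN", laser="off", state="sitting"):
    t = ls.make_trial_table(onsets, [stim] * len(onsets), [laser] * len(onsets))
    t["state"] = state
    return t


class TestTrialRates:
    def test_direct_count_in_half_open_window(self):
        u = _unit([1.05, 1.25])
        rates = trial_rates(u, _trials([1.0]), window=(0.0, 0.1))
        assert rates[0] == pytest.approx(10.0)  # 1 spike / 0.1 s

    def test_no_spikes_zero_rate(self):
        assert trial_rates(_unit([]), _trials([1.0]), (0.0, 0.1))[0] == 0.0

    def test_boundary_spike_counted_once(self):
        u = _unit([1.1])  # exactly at window end
        assert trial_rates(u, _trials([1.0]), (0.0, 0.1))[0] == 0.0
        assert trial_rates(u, _trials([1.0]), (0.1, 0.2))[0] == pytest.approx(10.0)

    def test_homogeneous_poisson_rate_recovered(self, rng):
        rate, n = 20.0, 200
        onsets = 1.0 + np.arange(n) * 1.6
        spikes = np.sort(rng.uniform(0, onsets[-1] + 2, int(rate * (onsets[-1] + 2))))
        est = trial_rates(_unit(spikes), _trials(onsets), (0.0, 0.6)).mean()
        se = np.sqrt(rate / (n * 0.6))
        assert abs(est - rate) < 3 * se

    def test_window_additivity(self, rng):
        spikes = np.sort(rng.uniform(0, 30, 300))
        tr = _trials(1.0 + np.arange(15) * 1.6)
        whole = trial_rates(_unit(spikes), tr, (0.0, 0.1))
        first = trial_rates(_unit(spikes), tr, (0.0, 0.05))
        second = trial_rates(_unit(spikes), tr, (0.05, 0.1))
        assert np.allclose(whole, (first + second) / 2)

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError, match="running"):
            trial_rates(
                _unit([1.0]), _trials([1.0]), (0, 0.1),
                key=ConditionKey("running", "off", "WN"),
            )


class TestSignificance:
    def _session_trials(self, n=30):
        onsets = 1.0 + np.arange(2 * n) * 1.6
        stim = ["WN", "blank"] * n
        t = ls.make_trial_table(onsets, stim, ["off"] * (2 * n))
        t["state"] = "sitting"
        return t

    def test_full_separation_is_significant_increase(self):
        tr = self._session_trials()
        wn_onsets = tr.loc[tr.stim == "WN", "onset_s"].to_numpy()
        spikes = np.sort(np.concatenate([wn_onsets + d for d in (0.01, 0.04, 0.07)]))
        sig, p = significant_evoked(_unit(spikes), tr)
        assert sig and p < 0.01

    def test_identical_rates_not_significant(self, rng):
        tr = self._session_trials()
        spikes = np.sort(rng.uniform(0, 100, 800))
        sig, p = significant_evoked(_unit(spikes), tr)
        assert not sig
        assert p > 0.01

    def test_suppressed_unit_excluded_by_increase_rule(self):
        tr = self._session_trials()
        blanks = tr.loc[tr.stim == "blank", "onset_s"].to_numpy()
        spikes = np.sort(np.concatenate([blanks + d for d in (0.01, 0.05, 0.09)]))
        sig, p = significant_evoked(_unit(spikes), tr)
        assert p < 0.01 and not sig

    def test_insufficient_trials_errors(self):
        tr = _trials([1.0], stim="WN")
        with pytest.raises(ValueError, match="trials"):
            significant_evoked(_unit([1.0]), tr)


class TestLatency:
    def test_step_response_latency_at_step(self):
        onsets = 1.0 + np.arange(50) * 1.6
        # dense spikes from exactly 20 ms post-onset
        spikes = np.sort(
            np.concatenate([on + np.arange(0.020, 0.1, 0.002) for on in onsets])
        )
        lat = response_latency(_unit(spikes), _trials(onsets))
        assert lat == pytest.approx(0.020, abs=0.008)  # within ~1.5 bins

    def test_linear_ramp_half_max_at_midpoint(self):
        # deterministic PSTH ramping linearly over 0-100 ms: bin b holds b
        # spikes, so the smoothed rate stays linear and half-max sits at 50 ms
        onsets = 1.0 + np.arange(20) * 1.6
        spikes = []
        for b in range(20):
            t_in_bin = 1e-4 + b * 0.005
            spikes.extend(onsets[:b] + t_in_bin)
        lat = response_latency(_unit(np.sort(spikes)), _trials(onsets))
        assert lat == pytest.approx(0.050, abs=0.01)

    def test_zero_peak_flagged_nan(self):
        lat = response_latency(_unit([]), _trials([1.0, 2.6]))
        assert np.isnan(lat)

    def test_shift_equivariance_within_one_bin(self):
        onsets = 1.0 + np.arange(40) * 1.6
        rng = np.random.default_rng(3)
        base = np.sort(
            np.concatenate([on + 0.02 + rng.exponential(0.01, 8) for on in onsets])
        )
        l0 = response_latency(_unit(base), _trials(onsets))
        l1 = response_latency(_unit(base + 0.015), _trials(onsets))
        assert l1 - l0 == pytest.approx(0.015, abs=0.005)

    def test_latency_difference_recovered_between_groups(self):
        """Units generated at 15 vs 25 ms latency differ by 10 +- 5 ms."""
        means = {}
        for lat_ms in (15.0, 25.0):
            session, _, _ = _labeled(
                n_units=50, n_trials_per_combo=30, seed=4,
                latency_range_ms=(lat_ms, lat_ms),
                include_lfp=False, include_pupil=False,
            )
            vals = []
            for u in session.units:
                est = response_latency(
                    u, session.trials, ConditionKey("sitting", "off", "WN")
                )
                if np.isfinite(est):
                    vals.append(est * 1000)
            means[lat_ms] = np.mean(vals)
        assert means[25.0] - means[15.0] == pytest.approx(10.0, abs=5.0)


def _labeled(**kw):
    from conftest import make_labeled_session

    return make_labeled_session(**kw)


def test_psth_counts_match_window_counts(small_session):
    """5 ms binned PSTH integrates to the direct window count."""
    session, _, _ = small_session
    u = session.units[0]
    wn = session.trials[session.trials.stim == "WN"]
    centers, rate = psth(u, wn, window=(0.0, 0.1))
    direct = trial_rates(u, wn, (0.0, 0.1)).mean()
    assert rate.mean() == pytest.approx(direct, rel=1e-9)


def test_offset_window_follows_stimulus_duration(small_session):
    from lamstate.responses import offset_window

    session, _, _ = small_session
    assert offset_window(session.meta.stim_dur_s) == (0.6, 0.7)
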