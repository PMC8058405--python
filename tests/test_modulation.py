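"""Modulation indices, effect decomposition, additivity, subsampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lamstate as ls
from lamstate.modulation import effects, sound_mi


class TestSoundMi:
    def test_equal_rates_give_zero(self):
        assert sound_mi(10.0, 10.0) == 0.0

    def test_boundary_values(self):
        assert sound_mi(10.0, 0.0) == 1.0
        assert sound_mi(0.0, 10.0) == -1.0

    def test_direct_arithmetic(self):
        assert sound_mi(10.0, 5.0) == pytest.approx(1.0 / 3.0)

    def test_zero_zero_undefined(self):
        assert np.isnan(sound_mi(0.0, 0.0))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sound_mi(-1.0, 2.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0, 1e4), st.floats(0, 1e4))
    def test_always_bounded(self, e, s):
        if e + s == 0:
            return
        assert -1.0 <= sound_mi(e, s) <= 1.0


class TestEffects:
    def test_running_effect_difference(self):
        run, vip, pred, obs = effects(0.5, 0.2, 0.4, 0.1)
        assert run == pytest.approx(-0.3)
        assert vip == pytest.approx(-0.1)
        assert pred == pytest.approx(-0.4)
        assert obs == pytest.approx(-0.4)

    def test_all_equal_mis_give_zero_effects(self):
        assert effects(0.3, 0.3, 0.3, 0.3) == (0.0, 0.0, 0.0, 0.0)

    def test_nan_propagates(self):
        run, vip, pred, obs = effects(0.3, np.nan, 0.2, 0.1)
        assert np.isnan(run) and np.isnan(pred)
        assert vip == pytest.approx(-0.1)


class TestAdditivityTest:
    def test_identity_population(self):
        x = np.linspace(-1, 1, 20)
        df = pd.DataFrame(
            {
                "predicted_combined": x,
                "observed_combined": x,
                "running_effect": x / 2,
                "vip_effect": x / 2,
            }
        )
        res = ls.additivity_test(df)
        assert res.rho == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0)

    def test_too_few_units_errors(self):
        df = pd.DataFrame({"predicted_combined": [0.1], "observed_combined": [0.2],
                           "running_effect": [0.1], "vip_effect": [0.0]})
        with pytest.raises(ValueError, match=">=3"):
            ls.additivity_test(df)

    def test_interaction_compresses_slope(self):
        """Sub-additive interaction yields slope below the additive run."""
        from conftest import make_labeled_session

        slopes = {}
        for gamma in (0.0, -0.5):
            session, truth, _ = make_labeled_session(
                n_units=100, n_trials_per_combo=100, seed=0,
                interaction=gamma, include_lfp=False, include_pupil=False,
            )
            mod = ls.compute_modulation(session)
            tu = truth.units.set_index("unit_id")
            keep = mod[~mod["unit_id"].isin(tu.index[tu["clipped"]])]
            slopes[gamma] = ls.additivity_test(keep).slope
        assert slopes[-0.5] < 1.0
        assert slopes[-0.5] < slopes[0.0]


def test_raw_rate_additivity_spont_tighter_than_evoked(rich_session):
    """Additivity on raw rates holds, with spontaneous changes better
    predicted than evoked changes (longer measurement window)."""
    session, _, _ = rich_session
    res = ls.rate_additivity_test(session)
    assert res["spont"].rho >= res["evoked"].rho
    assert res["evoked"].rho > 0.5


class TestConditionMi:
    def test_sit_off_mi_in_unit_interval_for_responsive_units(self, rich_session):
        session, _, _ = rich_session
        mod = ls.compute_modulation(session)
        sig = mod[mod.sig_increase]
        assert sig["mi_sit_off"].dropna().between(0, 1).all()
        for col in ("mi_run_off", "mi_sit_on", "mi_run_on"):
            assert sig[col].dropna().between(-1, 1).all()

    def test_effect_ranges(self, rich_session):
        session, _, _ = rich_session
        mod = ls.compute_modulation(session)
        assert mod["running_effect"].dropna().between(-2, 2).all()
        assert mod["vip_effect"].dropna().between(-2, 2).all()
        assert mod["predicted_combined"].dropna().between(-4, 4).all()

    def test_nonresponsive_units_excluded(self, rich_session):
        session, _, _ = rich_session
        mod = ls.compute_modulation(session)
        assert mod.loc[~mod.sig_increase, "mi_sit_off"].isna().all()

    def test_forced_sign_of_running_effect(self):
        """Evoked drop + spontaneous rise under running forces MI decrease."""
        from conftest import make_labeled_session

        session, truth, _ = make_labeled_session(
            n_units=40, n_trials_per_combo=100, seed=5,
            run_spont_delta_hz=(3.0, 0.0), run_evoked_delta_hz=(-8.0, 0.0),
            include_lfp=False, include_pupil=False,
        )
        mod = ls.compute_modulation(session)
        tu = truth.units.set_index("unit_id")
        keep = mod[mod.sig_increase & ~mod["unit_id"].isin(tu.index[tu["clipped"]])]
        d = (keep["mi_run_off"] - keep["mi_sit_off"]).dropna()
        assert len(d) >= 10
        assert (d < 0).mean() > 0.9


class TestMatchedSubsample:
    def test_determinism_under_fixed_seed(self, rich_session):
        session, _, _ = rich_session
        mod = ls.compute_modulation(session)
        a = ls.matched_subsample_mi(session, mod, n_repeats=10, seed=42)
        b = ls.matched_subsample_mi(session, mod, n_repeats=10, seed=42)
        assert np.array_equal(a.sitting_means, b.sitting_means)
        assert np.array_equal(a.p_values, b.p_values)

    def test_subsample_brackets_full_data_sitting_mi(self, rich_session):
        session, _, _ = rich_session
        mod = ls.compute_modulation(session)
        res = ls.matched_subsample_mi(session, mod, n_repeats=50, seed=1)
        full = mod.loc[mod.sig_increase, "mi_sit_off"].dropna().mean()
        lo, hi = res.range
        assert lo - 0.05 <= full <= hi + 0.05

    def test_matched_counts_draw_without_replacement(self, rich_session):
        session, _, _ = rich_session
        mod = ls.compute_modulation(session)
        res = ls.matched_subsample_mi(session, mod, n_repeats=5, seed=3)
        n_run = (
            (session.trials.state == "running") & (session.trials.laser == "off")
        ).sum()
        assert res.n_running_wn + res.n_running_blank == n_run


class TestLaserEffectNorm:
    def test_no_laser_change_gives_zero(self):
        from conftest import make_labeled_session

        session, _, _ = make_labeled_session(
            n_units=10, n_trials_per_combo=60, seed=9,
            laser_spont_delta_hz=(0.0, 0.0), laser_evoked_delta_hz=(0.0, 0.0),
            include_lfp=False, include_pupil=False,
        )
        mod = ls.compute_modulation(session)
        ev = mod["laser_effect_evoked_norm"].dropna()
        assert len(ev) >= 5
        assert np.abs(ev).mean() < 0.15  # zero up to sampling noise

    def test_normalization_arithmetic(self):
        # laser-on evoked 20 Hz, laser-off 10 Hz, peak 40 Hz -> +0.25
        assert (20.0 - 10.0) / 40.0 == pytest.approx(0.25)

    def test_scale_invariance(self, rng):
        """Scaling every spike-count proportionally leaves the effect unchanged."""
        onsets = 1.0 + np.arange(120) * 1.6
        stim = (["WN", "blank"] * 60)[:120]
        laser = (["off", "off", "on", "on"] * 30)[:120]
        trials = ls.make_trial_table(onsets, stim, laser)
        trials["state"] = "sitting"

        def spikes(scale):
            out = []
            for on, s, l in zip(onsets, stim, laser):
                rate = (30 if s == "WN" else 6) * (1.5 if l == "on" else 1.0)
                n = rng.poisson(rate * scale * 0.6)
                out.append(on + np.sort(rng.uniform(0, 0.6, n)))
            return np.sort(np.concatenate(out))

        rng0 = np.random.default_rng(0)
        base = spikes(1.0)
        u1 = ls.Unit(unit_id="a", spike_times=base)
        # triple the rate by superposing three jittered copies
        u3 = ls.Unit(
            unit_id="b",
            spike_times=np.sort(np.concatenate([base, base + 1e-4, base + 2e-4])),
        )
        e1, s1 = ls.laser_effect_norm(u1, trials)
        e3, s3 = ls.laser_effect_norm(u3, trials)
        assert e3 == pytest.approx(e1, abs=0.02)
        assert s3 == pytest.approx(s1, abs=0.02)
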