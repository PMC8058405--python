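"""Per-unit, per-condition firing-rate metrics.

Onset responses are the mean firing rate 0-100 ms after sound onset and
offset responses the mean rate 600-700 ms after onset (the first 100 ms
after sound offset for the 600 ms stimulus). Spontaneous rate is measured
on the interleaved silent blanks, whose durations and presentation
intervals match the sound trials, over the stimulus-equivalent window.

A unit counts as sound-responsive when a two-sided Wilcoxon rank-sum test
between per-trial onset rates on WN trials and the matched window on blank
trials (sitting, laser-off) gives p < 0.01 with a firing-rate *increase*;
only such units enter the modulation-index analyses.

Response latency is read from the trial-averaged PSTH (5 ms bins, 15 ms
centered moving average) as the first post-onset time at which the smoothed
rate reaches half of its peak, measured from a 0 Hz baseline, with linear
interpolation between bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session import Session, Unit

__all__ = [
    "ConditionKey",
    "condition_trials",
    "psth",
    "response_latency",
    "response_table",
    "significant_evoked",
    "trial_rates",
]

ONSET_WINDOW = (0.0, 0.1)
PSTH_BIN_S = 0.005
PSTH_SMOOTH_BINS = 3  # 15 ms centered moving average
SIG_ALPHA = 0.01


@dataclass(frozen=True)
class ConditionKey:
    """A (state, laser, stim) trial-selection key; 'either' ignores that axis."""

    state: str = "either"  # running / sitting / either
    laser: str = "either"  # on / off / either
    stim: str = "WN"  # WN / blank

    def __post_init__(self) -> None:
        if self.state not in ("running", "sitting", "either"):
            raise ValueError(f"bad state {self.state!r}")
        if self.laser not in ("on", "off", "either"):
            raise ValueError(f"bad laser {self.laser!r}")
        if self.stim not in ("WN", "blank"):
            raise ValueError(f"bad stim {self.stim!r}")


def condition_trials(trials: pd.DataFrame, key: ConditionKey) -> pd.DataFrame:
    """Select the trials matching a condition key."""
    mask = trials["stim"] == key.stim
    if key.laser != "either":
        mask &= trials["laser"] == key.laser
    if key.state != "either":
        mask &= trials["state"] == key.state
    return trials[mask]


def trial_rates(
    unit: Unit,
    trials: pd.DataFrame,
    window: tuple[float, float] = ONSET_WINDOW,
    key: ConditionKey | None = None,
) -> np.ndarray:
    """Per-trial firing rate (Hz) in ``[onset + t0, onset + t1)``.

    Counts spikes by binary search on the sorted spike-time array; the rate
    is count / (t1 - t0).
    """
    sel = trials if key is None else condition_trials(trials, key)
    if len(sel) == 0:
        raise ValueError(f"empty trial selection for {key}")
    t0, t1 = window
    onsets = sel["onset_s"].to_numpy(float)
    lo = np.searchsorted(unit.spike_times, onsets + t0, side="left")
    hi = np.searchsorted(unit.spike_times, onsets + t1, side="left")
    return (hi - lo) / (t1 - t0)


def offset_window(stim_dur_s: float = 0.6) -> tuple[float, float]:
    """The 100 ms window following sound offset, relative to onset."""
    return (stim_dur_s, stim_dur_s + 0.1)


def significant_evoked(
    unit: Unit,
    trials: pd.DataFrame,
    alpha: float = SIG_ALPHA,
    window: tuple[float, float] = ONSET_WINDOW,
) -> tuple[bool, float]:
    """Increase-only sound responsiveness on sitting laser-off trials.

    Two-sided rank-sum between per-trial onset rates on WN trials and the
    matched window on blank trials; exact null distribution when both
    samples have <= 25 trials, normal approximation otherwise.
    """
    wn = condition_trials(trials, ConditionKey("sitting", "off", "WN"))
    blank = condition_trials(trials, ConditionKey("sitting", "off", "blank"))
    if len(wn) < 2 or len(blank) < 2:
        raise ValueError(
            f"need >=2 sitting laser-off WN and blank trials "
            f"(have {len(wn)} WN, {len(blank)} blank)"
        )
    r_wn = trial_rates(unit, wn, window)
    r_blank = trial_rates(unit, blank, window)
    method = "exact" if (len(r_wn) <= 25 and len(r_blank) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(r_wn, r_blank, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return bool(p < alpha and r_wn.mean() > r_blank.mean()), p


def psth(
    unit: Unit,
    trials: pd.DataFrame,
    window: tuple[float, float] = (0.0, 0.7),
    bin_s: float = PSTH_BIN_S,
    smooth_bins: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged PSTH (bin centers s, rate Hz) in 5 ms bins.

    ``smooth_bins`` applies a centered moving average (shrinking at the
    edges); 3 bins gives the 15 ms smoothing used for latency estimation.
    """
    if len(trials) == 0:
        raise ValueError("no trials for PSTH")
    t0, t1 = window
    n_bins = int(round((t1 - t0) / bin_s))
    edges = t0 + np.arange(n_bins + 1) * bin_s
    counts = np.zeros(n_bins)
    for on in trials["onset_s"].to_numpy(float):
        rel = unit.spike_times - on
        rel = rel[(rel >= t0) & (rel < edges[-1])]
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (len(trials) * bin_s)
    if smooth_bins > 1:
        rate = (
            pd.Series(rate)
            .rolling(smooth_bins, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    centers = edges[:-1] + bin_s / 2.0
    return centers, rate


def response_latency(
    unit: Unit,
    trials: pd.DataFrame,
    key: ConditionKey | None = None,
    window: tuple[float, float] = (0.0, 0.7),
    min_trials: int = 2,
) -> float:
    """Half-maximum latency (s) of the smoothed evoked PSTH; NaN if no peak.

    Latency is the first time >= 0 at which the 15 ms-smoothed PSTH crosses
    half of its post-onset peak (baseline 0 Hz), linearly interpolated
    between bins.
    """
    sel = trials if key is None else condition_trials(trials, key)
    if len(sel) < min_trials:
        raise ValueError(f"need >= {min_trials} trials for latency, have {len(sel)}")
    centers, rate = psth(unit, sel, window=window, smooth_bins=PSTH_SMOOTH_BINS)
    peak = rate.max()
    if peak <= 0:
        return float("nan")
    half = peak / 2.0
    above = np.nonzero(rate >= half)[0]
    if above.size == 0:
        return float("nan")
    i = above[0]
    if i == 0 or rate[i] == rate[i - 1]:
        return float(centers[i])
    frac = (half - rate[i - 1]) / (rate[i] - rate[i - 1])
    return float(centers[i - 1] + frac * (centers[i] - centers[i - 1]))


def response_table(
    session: Session,
    conditions: list[ConditionKey] | None = None,
    min_trials: int = 2,
) -> pd.DataFrame:
    """Per-unit x per-condition response summary.

    Columns: unit_id, state, laser, spont_hz (blank trials, full stimulus
    window), spont_onset_hz (blank trials, onset-matched window), onset_hz,
    offset_hz, n_wn, n_blank, plus session-wide sig_increase / p_sig from
    sitting laser-off trials. Conditions with too few trials get NaN rates.
    """
    trials = session.trials
    stim_dur = session.meta.stim_dur_s
    off_win = offset_window(stim_dur)
    if conditions is None:
        conditions = [
            ConditionKey(state, laser, "WN")
            for state in ("sitting", "running")
            for laser in ("off", "on")
        ]
    rows = []
    for u in session.units:
        try:
            sig, p_sig = significant_evoked(u, trials)
        except ValueError:
            sig, p_sig = False, float("nan")
        for key in conditions:
            wn = condition_trials(trials, key)
            blank = condition_trials(
                trials, ConditionKey(key.state, key.laser, "blank")
            )
            if len(wn) >= min_trials and len(blank) >= min_trials:
                onset_hz = float(np.mean(trial_rates(u, wn, ONSET_WINDOW)))
                offset_hz = float(np.mean(trial_rates(u, wn, off_win)))
                spont_hz = float(np.mean(trial_rates(u, blank, (0.0, stim_dur))))
                spont_onset_hz = float(np.mean(trial_rates(u, blank, ONSET_WINDOW)))
            else:
                onset_hz = offset_hz = spont_hz = spont_onset_hz = float("nan")
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "state": key.state,
                    "laser": key.laser,
                    "onset_hz": onset_hz,
                    "offset_hz": offset_hz,
                    "spont_hz": spont_hz,
                    "spont_onset_hz": spont_onset_hz,
                    "n_wn": len(wn),
                    "n_blank": len(blank),
                    "sig_increase": sig,
                    "p_sig": p_sig,
                }
            )
    return pd.DataFrame(rows)
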