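"""Behavioral-state processing: running-trace smoothing and trial labeling.

The running trace is smoothed with a 200 ms centered moving median (robust
to single-sample optical-mouse artifacts). A trial is labeled *running*
when its mean smoothed speed over the 600 ms stimulus window exceeds 5% of
the session's maximum smoothed speed, otherwise *sitting*; a session enters
running analyses only if it has at least 7 running trials. Both the maximum
and the per-trial means are taken on the same smoothed trace so the
threshold and the means share one signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import BehaviorTrace

__all__ = ["StateLabeling", "arousal_gate", "label_trials", "smooth_running"]

#: running threshold as a fraction of session maximum smoothed speed
SPEED_THRESHOLD_FRACTION = 0.05
#: minimum number of running trials for a session to enter running analyses
MIN_RUNNING_TRIALS = 7
#: high-arousal pupil threshold as a fraction of session maximum
PUPIL_FRACTION = 0.60


@dataclass
class StateLabeling:
    """Per-trial running/sitting labels plus session-level inclusion."""

    mean_speed: np.ndarray  # cm/s per trial
    state: np.ndarray  # "running" / "sitting" per trial
    max_speed: float
    n_running: int
    included: bool


def smooth_running(trace: BehaviorTrace, window_s: float = 0.2) -> BehaviorTrace:
    """Centered moving-median smoothing with an odd-forced window.

    Edge samples use shrinking (truncated) windows; output length equals
    input length. A constant trace is returned unchanged and isolated
    single-sample artifacts are removed for windows of 3+ samples.
    """
    if len(trace.v) == 0:
        raise ValueError("cannot smooth an empty trace")
    w = int(round(window_s * trace.rate_hz))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    smoothed = (
        pd.Series(trace.v).rolling(w, center=True, min_periods=1).median().to_numpy()
    )
    return BehaviorTrace(t=trace.t.copy(), v=smoothed, rate_hz=trace.rate_hz)


def label_trials(
    trials: pd.DataFrame,
    speed: BehaviorTrace,
    threshold_fraction: float = SPEED_THRESHOLD_FRACTION,
    min_running_trials: int = MIN_RUNNING_TRIALS,
) -> StateLabeling:
    """Label each trial running/sitting from the smoothed speed trace.

    ``speed`` must already be smoothed (see :func:`smooth_running`) and must
    cover every trial window. Running means *strictly above*
    ``threshold_fraction`` of the session maximum smoothed speed.
    """
    t = speed.t
    v = speed.v
    max_speed = float(np.max(v))
    onsets = trials["onset_s"].to_numpy(float)
    durs = trials["duration_s"].to_numpy(float)

    mean_speed = np.empty(len(trials))
    for i, (on, du) in enumerate(zip(onsets, durs)):
        if on < t[0] - 0.5 / speed.rate_hz or on + du > t[-1] + 0.5 / speed.rate_hz:
            raise ValueError(
                f"trial {i} window [{on:g}, {on + du:g}) outside speed trace support"
            )
        mask = (t >= on) & (t < on + du)
        if not mask.any():
            raise ValueError(f"trial {i}: no speed samples in window")
        mean_speed[i] = v[mask].mean()

    running = mean_speed > threshold_fraction * max_speed
    state = np.where(running, "running", "sitting")
    n_running = int(running.sum())
    return StateLabeling(
        mean_speed=mean_speed,
        state=state,
        max_speed=max_speed,
        n_running=n_running,
        included=n_running >= min_running_trials,
    )


def apply_labels(trials: pd.DataFrame, labeling: StateLabeling) -> pd.DataFrame:
    """Return a copy of the trial table with mean_speed/state filled in."""
    out = trials.copy()
    out["mean_speed"] = labeling.mean_speed
    out["state"] = pd.array(labeling.state, dtype="str")
    return out


def arousal_gate(
    pupil: BehaviorTrace | None, fraction: float = PUPIL_FRACTION
) -> np.ndarray:
    """Per-sample high-arousal mask: pupil strictly above ``fraction`` of max.

    Raises if the session has no pupil trace, so a missing trace can never
    silently pass as low arousal.
    """
    if pupil is None:
        raise ValueError("no pupil trace recorded for this session")
    return pupil.v > fraction * float(np.max(pupil.v))
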