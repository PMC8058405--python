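"""Spike-waveform features and narrow-/regular-spiking classification.

Extracellular waveforms are measured on the peak-amplitude channel. Width
is the trough-to-subsequent-peak time (the extracellular convention for the
"peak to trough distance"); the end-slope is the least-squares slope over a
fixed terminal epoch of the mean waveform (default the final 0.2 ms), and
the peak-trough ratio is |peak| / |trough|.

Classification follows a fixed width threshold at 0.5 ms: narrow-spiking
(NS, putative fast-spiking interneurons) requires width < 0.5 ms AND a
negative end-slope; width >= 0.5 ms is regular-spiking (RS, putative
excitatory). A sub-threshold width with non-negative end-slope satisfies
neither rule and is left unclassified rather than silently forced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import UNCLASSIFIED

__all__ = [
    "WIDTH_THRESHOLD_MS",
    "WaveformFeatures",
    "classify_unit",
    "waveform_features",
]

WIDTH_THRESHOLD_MS = 0.5
END_WINDOW_MS = 0.2


@dataclass(frozen=True)
class WaveformFeatures:
    width_ms: float  # trough-to-peak time
    end_slope: float  # uV/ms over the terminal epoch
    peak_trough_ratio: float  # |peak| / |trough|


def waveform_features(
    wf: np.ndarray, rate_hz: float, end_window_ms: float = END_WINDOW_MS
) -> WaveformFeatures:
    """Measure width, end-slope and peak/trough ratio of one waveform.

    ``wf`` is the peak-channel mean waveform in uV. The trough is the global
    minimum; the peak is the maximum strictly after it. Raises on monotone
    waveforms with no trough/peak pair.
    """
    wf = np.asarray(wf, dtype=float)
    if wf.ndim != 1 or wf.size < 3:
        raise ValueError("waveform must be a 1-D array of >=3 samples")
    trough = int(np.argmin(wf))
    if trough >= wf.size - 1:
        raise ValueError("no trough/peak pair: trough at waveform end")
    peak = trough + 1 + int(np.argmax(wf[trough + 1 :]))
    width_ms = (peak - trough) / rate_hz * 1000.0
    if width_ms <= 0:
        raise ValueError("no trough/peak pair: nonpositive width")

    n_end = max(int(round(end_window_ms * rate_hz / 1000.0)), 2)
    tail = wf[-n_end:]
    t_ms = np.arange(n_end) / rate_hz * 1000.0
    slope = float(np.polyfit(t_ms, tail, 1)[0])

    trough_amp = abs(float(wf[trough]))
    ratio = abs(float(wf[peak])) / trough_amp if trough_amp > 0 else np.inf
    return WaveformFeatures(width_ms=width_ms, end_slope=slope, peak_trough_ratio=ratio)


def classify_unit(
    features: WaveformFeatures, width_threshold_ms: float = WIDTH_THRESHOLD_MS
) -> str:
    """Classify a unit NS / RS / unclassified from its waveform features."""
    if features.width_ms >= width_threshold_ms:
        return "RS"
    if features.end_slope < 0:
        return "NS"
    return UNCLASSIFIED
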