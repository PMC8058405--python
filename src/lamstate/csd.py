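"""Current-source-density analysis and laminar depth assignment.

The LFP is zero-phase band-pass filtered (1-300 Hz, removing spike energy)
and the CSD is the discrete second spatial derivative across equally spaced
probe channels::

    csd[j] = (trace[j-1] + trace[j+1] - 2 * trace[j]) / spacing_um**2

Sound-evoked auditory cortex shows a robust short-latency current sink at
the layer-3/4 boundary; that sink is anchored at a depth of 400 um and each
unit's depth follows from the signed channel offset between its
max-amplitude waveform channel and the sink channel (25 um per channel,
deeper channel = larger index). Layers are then looked up in a fixed
boundary table (L1 0-128, L2/3 129-380, L4 381-525, L5 526-805,
L6 806-1200 um). Sessions whose evoked CSD yields no unambiguous sink are
excluded from laminar analyses but retained everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .session import LFPBlock, UNASSIGNED, Unit

__all__ = [
    "LAYER_BOUNDS_UM",
    "SINK_DEPTH_UM",
    "CSDProfile",
    "assign_depths",
    "compute_csd",
    "layer_of_depth",
    "locate_sink",
]

#: layer boundary table, um (inclusive upper bounds)
LAYER_BOUNDS_UM: dict[str, tuple[float, float]] = {
    "L1": (0.0, 128.0),
    "L2/3": (129.0, 380.0),
    "L4": (381.0, 525.0),
    "L5": (526.0, 805.0),
    "L6": (806.0, 1200.0),
}

#: anchored depth of the short-latency L3/4-boundary sink
SINK_DEPTH_UM = 400.0

_UPPER_EDGES = np.array([128.0, 380.0, 525.0, 805.0, 1200.0])
_LAYER_NAMES = ("L1", "L2/3", "L4", "L5", "L6")


def layer_of_depth(depth_um: float) -> str:
    """Map a cortical depth (um) to its layer label; out of range -> unassigned."""
    if depth_um < 0 or depth_um > 1200:
        return UNASSIGNED
    return _LAYER_NAMES[int(np.searchsorted(_UPPER_EDGES, depth_um, side="left"))]


@dataclass
class CSDProfile:
    """CSD over interior channels; row j corresponds to LFP channel j+1."""

    csd: np.ndarray  # (channels - 2) x samples, uV/um^2
    spacing_um: float
    rate_hz: float
    sink_channel: int | None = None  # interior-channel index
    sink_latency_s: float | None = None

    @property
    def sink_channel_global(self) -> int | None:
        """Sink channel on the full LFP channel axis."""
        return None if self.sink_channel is None else self.sink_channel + 1


def compute_csd(
    lfp: LFPBlock, band: tuple[float, float] | None = (1.0, 300.0)
) -> CSDProfile:
    """Band-filter the LFP and take the second spatial difference.

    ``band=None`` bypasses filtering (used by closed-form tests and when the
    block was already filtered at acquisition). Filtering is zero-phase
    (forward-backward) so the sink latency is not displaced.
    """
    x = lfp.data
    if x.shape[0] < 3:
        raise ValueError("CSD requires >=3 channels")
    if band is not None:
        lo, hi = band
        nyq = lfp.rate_hz / 2.0
        if not (0 < lo < hi < nyq):
            raise ValueError(f"band {band} outside (0, Nyquist={nyq:g}) Hz")
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=lfp.rate_hz, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=1)
    csd = (x[:-2] + x[2:] - 2.0 * x[1:-1]) / lfp.spacing_um**2
    return CSDProfile(csd=csd, spacing_um=lfp.spacing_um, rate_hz=lfp.rate_hz)


def locate_sink(
    profile: CSDProfile,
    trials: pd.DataFrame,
    window_s: tuple[float, float] = (0.0, 0.05),
    baseline_s: float = 0.05,
    k_sd: float = 3.0,
) -> CSDProfile:
    """Locate the short-latency evoked sink on WN laser-off trials.

    Averages the CSD across WN laser-off trials aligned to sound onset, then
    takes the most negative value within ``window_s`` post-onset. The sink
    counts as detected only if its magnitude exceeds ``k_sd`` standard
    deviations of the pre-stimulus trial-averaged CSD (depth-of-modulation
    criterion); otherwise the profile is returned with ``sink_channel=None``
    and the session is flagged for exclusion from laminar analyses.
    """
    sel = trials[(trials["stim"] == "WN") & (trials["laser"] == "off")]
    if len(sel) == 0:
        raise ValueError("no WN laser-off trials available for sink localization")

    rate = profile.rate_hz
    pre = int(round(baseline_s * rate))
    post = int(round(window_s[1] * rate))
    start = int(round(window_s[0] * rate))
    n_samples = profile.csd.shape[1]

    epochs = []
    for on in sel["onset_s"].to_numpy(float):
        i0 = int(round(on * rate))
        if i0 - pre < 0 or i0 + post > n_samples:
            continue
        epochs.append(profile.csd[:, i0 - pre : i0 + post])
    if not epochs:
        raise ValueError("no WN laser-off trial epochs fall inside the LFP block")
    avg = np.mean(epochs, axis=0)  # channels x (pre + post)

    baseline = avg[:, :pre]
    sd = float(baseline.std())
    evoked = avg[:, pre + start :]
    flat_idx = int(np.argmin(evoked))
    ch, samp = np.unravel_index(flat_idx, evoked.shape)
    depth_of_mod = abs(float(evoked[ch, samp]))
    if sd == 0.0 and depth_of_mod == 0.0:
        return replace(profile, sink_channel=None, sink_latency_s=None)
    if sd > 0.0 and depth_of_mod <= k_sd * sd:
        return replace(profile, sink_channel=None, sink_latency_s=None)
    latency = window_s[0] + samp / rate
    return replace(profile, sink_channel=int(ch), sink_latency_s=float(latency))


def assign_depths(
    units: list[Unit],
    sink_channel_global: int | None,
    spacing_um: float = 25.0,
    sink_depth_um: float = SINK_DEPTH_UM,
) -> list[Unit]:
    """Assign each unit a depth and layer from its peak channel.

    ``depth = sink_depth + (peak_channel - sink_channel) * spacing`` with
    channel indices on the full LFP axis (channel 0 most superficial). With
    an undetected sink (``None``) every unit is returned unassigned. Units
    landing outside 0-1200 um are left unassigned.
    """
    out = []
    for u in units:
        new = replace(u)
        if sink_channel_global is None or u.peak_channel is None:
            new.depth_um = None
            new.layer = UNASSIGNED
        else:
            depth = sink_depth_um + (u.peak_channel - sink_channel_global) * spacing_um
            layer = layer_of_depth(depth)
            if layer == UNASSIGNED:
                new.depth_um = None
                new.layer = UNASSIGNED
            else:
                new.depth_um = float(depth)
                new.layer = layer
        out.append(new)
    return out
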