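"""Calibrated synthetic sessions with recoverable ground truth.

Every analysis stage in this package is exercised against sessions whose
true state/laser effects, laminar depths and waveform classes are known.
The generator emulates the recorded experiment:

* a randomly interleaved schedule of 600 ms white-noise bursts and silent
  blanks at 1 s inter-stimulus interval, each with or without an 800 ms
  laser pulse (onset 50 ms before the sound, offset 150 ms after), at
  least 30 repeats per (stim, laser) combination;
* bout-structured running (two-state Markov chain with 200 ms
  raised-cosine speed ramps) calibrated so roughly 13% of trials are
  running trials at ~7 cm/s, with a co-varying pupil trace;
* per-unit inhomogeneous-Poisson spiking whose rate is a baseline plus
  *additive* condition deltas: evoked onset/offset increments on
  white-noise trials (latency-shifted 100 ms windows), running deltas on
  running trials, laser deltas inside the laser window. An optional
  multiplicative running x laser interaction term breaks additivity for
  the interaction-detection tests;
* a stimulus-evoked LFP dipole whose current sink sits at the channel
  nearest the 400 um layer-3/4 boundary, over pink noise.

Population calibration targets (means across units): spontaneous rate
4.87 Hz sitting / 6.50 Hz running; onset-window rate 15.81 Hz sitting /
13.97 Hz running. Because the analysis windows are fixed at 0-100 ms and
600-700 ms while the injected increments are latency-shifted, the mean
increments are scaled up by the expected window-overlap factor
(1 - latency/100 ms; 0.8 at the 20 ms mean latency) so the *measured*
window means hit the targets. Across-unit delta spreads (4 Hz spontaneous,
10 Hz evoked) reproduce the broad single-cell diversity of the effect
decomposition rather than the narrow SEMs of the population means.

One seed governs all draws through named ``SeedSequence`` child streams
(schedule, behavior, units, waveforms, spikes, lfp, pupil), so identical
parameters give byte-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior
from .csd import layer_of_depth
from .session import (
    AcquisitionMeta,
    BehaviorTrace,
    LFPBlock,
    Session,
    Unit,
    make_trial_table,
)

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "generate_coupled_population",
    "generate_lfp",
    "generate_session",
    "generate_waveform",
]

_STREAMS = ("schedule", "behavior", "units", "waveforms", "spikes", "lfp", "pupil")


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class GeneratorParams:
    """Study-condition parameters of the synthetic session generator."""

    n_units: int = 100
    seed: int = 0
    n_trials_per_combo: int = 30  # >= 30 repeats of each (stim, laser) combo

    # cell classes and depths
    p_ns: float = 0.2
    depth_weights: dict[str, float] = field(
        default_factory=lambda: {"L2/3": 0.15, "L4": 0.20, "L5": 0.50, "L6": 0.15}
    )

    # per-unit rate draws (Hz); gamma baselines, normal deltas
    spont_mean_hz: float = 4.87
    spont_shape: float = 2.5
    onset_gain_mean_hz: float = (15.81 - 4.87) / 0.8  # window-overlap corrected
    offset_gain_mean_hz: float = (12.85 - 4.87) / 0.8
    gain_shape: float = 3.0
    # (mean, sd). The sds give the broad single-cell diversity of state and
    # laser effects (MI effects spanning roughly +-1); the means are
    # moment-matched so the *rectified* (clip-at-zero) population means hit
    # the calibration targets: 6.50 Hz running spontaneous, 13.97 Hz running
    # onset, and an MI-neutral laser effect (+1.0 Hz spontaneous with the
    # evoked-window increase that leaves the population-mean MI unchanged).
    run_spont_delta_hz: tuple[float, float] = (1.4201, 4.0)
    run_evoked_delta_hz: tuple[float, float] = (-4.9517, 10.0)
    laser_spont_delta_hz: tuple[float, float] = (0.7097, 4.0)
    laser_evoked_delta_hz: tuple[float, float] = (2.8105, 10.0)
    latency_range_ms: tuple[float, float] = (10.0, 30.0)

    #: multiplicative running x laser interaction; 0 = purely additive.
    #: Negative values compress the combined effect (sub-additivity).
    interaction: float = 0.0

    # running bouts: two-state Markov chain at the trace rate
    trace_rate_hz: float = 100.0
    bout_start_per_s: float = 0.04  # mean 25 s between bouts
    bout_stop_per_s: float = 1.0 / 3.0  # mean 3 s bouts -> ~13% of trials running
    ramp_s: float = 0.2
    speed_mu_cmps: float = 6.96
    speed_jitter_cmps: float = 1.5
    sit_noise_cmps: float = 0.02

    # LFP dipole + noise
    lfp_channels: int = 32
    lfp_rate_hz: float = 1000.0
    lfp_spacing_um: float = 25.0
    lfp_sink_channel: int = 10  # channel anchored at 400 um
    lfp_amp_uv: float = 60.0
    lfp_noise_uv: float = 15.0
    lfp_sink_latency_s: float = 0.015
    include_lfp: bool = True
    include_pupil: bool = True


@dataclass
class GroundTruth:
    """Generator truth aligned one-to-one with the emitted session."""

    units: pd.DataFrame  # per-unit true parameters
    trial_state: np.ndarray  # "running"/"sitting" per trial
    sink_channel_global: int
    channel0_depth_um: float
    params: GeneratorParams


# ---------------------------------------------------------------------------
# waveforms


def generate_waveform(
    cell_class: str,
    seed: int | np.random.Generator,
    n_channels: int = 32,
    center_channel: int = 0,
    rate_hz: float = 30000.0,
    spacing_um: float = 25.0,
) -> tuple[np.ndarray, float]:
    """Synthesize a per-channel mean waveform; returns (waveforms, width_ms).

    The peak-channel template is a negative trough Gaussian followed by a
    positive peak Gaussian whose separation is the drawn trough-to-peak
    width: < 0.5 ms for NS (0.25-0.45), >= 0.5 ms for RS (0.55-0.85). The
    decaying positive tail makes the end-slope strictly negative. Amplitude
    peaks on ``center_channel`` and decays exponentially with distance.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if cell_class == "NS":
        width_ms = float(rng.uniform(0.25, 0.45))
    elif cell_class == "RS":
        width_ms = float(rng.uniform(0.55, 0.85))
    else:
        raise ValueError(f"unknown cell class {cell_class!r}")
    n = int(round(0.003 * rate_hz))  # 3 ms of samples
    t_ms = np.arange(n) / rate_hz * 1000.0
    t0 = 0.8
    amp = float(rng.uniform(60.0, 140.0))
    template = -amp * np.exp(-((t_ms - t0) ** 2) / (2 * 0.06**2)) + 0.4 * amp * np.exp(
        -((t_ms - t0 - width_ms) ** 2) / (2 * 0.25**2)
    )
    decay = np.exp(
        -np.abs(np.arange(n_channels) - center_channel) * spacing_um / 50.0
    )
    return decay[:, None] * template[None, :], width_ms


# ---------------------------------------------------------------------------
# behavior


def _running_trace(
    params: GeneratorParams, duration_s: float, rng: np.random.Generator
) -> tuple[BehaviorTrace, np.ndarray]:
    """Bout-structured speed trace; returns (trace, binary run state per sample)."""
    rate = params.trace_rate_hz
    n = int(round(duration_s * rate))
    p01 = params.bout_start_per_s / rate
    p10 = params.bout_stop_per_s / rate
    u = rng.random(n)
    state = np.zeros(n, dtype=bool)
    cur = False
    for i in range(n):
        if cur:
            cur = u[i] >= p10
        else:
            cur = u[i] < p01
        state[i] = cur
    # 200 ms raised-cosine ramps at bout edges
    k = int(round(params.ramp_s * rate))
    kernel = 0.5 * (1 - np.cos(2 * np.pi * np.arange(1, k + 1) / (k + 1)))
    kernel /= kernel.sum()
    envelope = np.convolve(state.astype(float), kernel, mode="same")
    # within-bout speed fluctuation (AR(1) with ~1 s correlation time)
    rho = np.exp(-1.0 / rate)
    eps = rng.normal(0, params.speed_jitter_cmps * np.sqrt(1 - rho**2), n)
    jitter = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = rho * acc + eps[i]
        jitter[i] = acc
    speed = envelope * np.maximum(params.speed_mu_cmps + jitter, 1.0)
    speed += np.abs(rng.normal(0, params.sit_noise_cmps, n))
    t = np.arange(n) / rate
    return BehaviorTrace(t=t, v=speed, rate_hz=rate), state


def _pupil_trace(
    run_env: np.ndarray, rate: float, rng: np.random.Generator
) -> BehaviorTrace:
    """Pupil fraction-of-max trace co-varying with running (high arousal)."""
    n = len(run_env)
    k = int(round(0.5 * rate))
    kernel = np.ones(k) / k
    slow_env = np.convolve(run_env, kernel, mode="same")
    v = 0.5 + 0.4 * slow_env + rng.normal(0, 0.015, n)
    v = np.clip(v, 0.0, 1.0)
    t = np.arange(n) / rate
    return BehaviorTrace(t=t, v=v, rate_hz=rate)


# ---------------------------------------------------------------------------
# LFP


def generate_lfp(
    trials: pd.DataFrame,
    duration_s: float,
    sink_channel: int = 10,
    n_channels: int = 32,
    spacing_um: float = 25.0,
    rate_hz: float = 1000.0,
    amp_uv: float = 60.0,
    noise_uv: float = 15.0,
    sink_latency_s: float = 0.015,
    seed: int | np.random.Generator = 0,
) -> LFPBlock:
    """Stimulus-locked laminar dipole plus pink noise.

    Each WN onset adds a 30 ms half-sine positive LFP deflection with a
    compactly supported raised-cosine spatial profile centered on
    ``sink_channel``; its second spatial difference is a current sink at
    that channel flanked by superficial/deep sources, and (compact support)
    the CSD sums to zero across channels at every sample. Sink latency is
    ``sink_latency_s`` (< 50 ms) after sound onset.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    n = int(round(duration_s * rate_hz))
    w = 4  # spatial half-width, channels
    if not (w <= sink_channel < n_channels - w):
        raise ValueError("sink channel too close to the probe edge")
    ch = np.arange(n_channels)
    prof = np.where(
        np.abs(ch - sink_channel) < w,
        0.5 * (1 + np.cos(np.pi * (ch - sink_channel) / w)),
        0.0,
    )
    dur_kernel = 0.03
    nk = int(round(dur_kernel * rate_hz))
    kernel = np.sin(np.pi * np.arange(nk) / nk)

    drive = np.zeros(n)
    wn_onsets = trials.loc[trials["stim"] == "WN", "onset_s"].to_numpy(float)
    for on in wn_onsets:
        i0 = int(round((on + sink_latency_s) * rate_hz))
        i1 = min(i0 + nk, n)
        if i0 < n:
            drive[i0:i1] += kernel[: i1 - i0]
    data = amp_uv * prof[:, None] * drive[None, :]
    if noise_uv > 0:
        data += _pink_noise((n_channels, n), rate_hz, rng) * noise_uv
    return LFPBlock(data=data, spacing_um=spacing_um, rate_hz=rate_hz)


def _pink_noise(
    shape: tuple[int, int], rate_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance 1/f noise along the last axis."""
    n_ch, n = shape
    white = rng.normal(size=(n_ch, n))
    f = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    scale = np.where(f > 0, 1.0 / np.sqrt(np.maximum(f, f[1] if len(f) > 1 else 1.0)), 0.0)
    x = np.fft.irfft(np.fft.rfft(white, axis=1) * scale[None, :], n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


# ---------------------------------------------------------------------------
# session assembly


def _draw_units(params: GeneratorParams, rng: np.random.Generator) -> pd.DataFrame:
    layers = list(params.depth_weights)
    weights = np.array([params.depth_weights[k] for k in layers], float)
    weights /= weights.sum()
    probe_top = 400.0 - params.lfp_sink_channel * params.lfp_spacing_um
    probe_bot = probe_top + (params.lfp_channels - 1) * params.lfp_spacing_um
    from .csd import LAYER_BOUNDS_UM

    rows = []
    for i in range(params.n_units):
        layer = layers[rng.choice(len(layers), p=weights)]
        lo, hi = LAYER_BOUNDS_UM[layer]
        lo, hi = max(lo, probe_top), min(hi, probe_bot)
        depth = float(rng.uniform(lo, hi))
        cls = "NS" if rng.random() < params.p_ns else "RS"
        rows.append(
            {
                "unit_id": f"u{i:03d}",
                "depth_um": depth,
                "layer": layer_of_depth(depth),
                "cell_class": cls,
                "base_spont_hz": float(
                    rng.gamma(params.spont_shape, params.spont_mean_hz / params.spont_shape)
                ),
                "onset_gain_hz": float(
                    rng.gamma(
                        params.gain_shape, params.onset_gain_mean_hz / params.gain_shape
                    )
                ),
                "offset_gain_hz": float(
                    rng.gamma(
                        params.gain_shape,
                        params.offset_gain_mean_hz / params.gain_shape,
                    )
                ),
                "run_spont_delta_hz": float(rng.normal(*params.run_spont_delta_hz)),
                "run_evoked_delta_hz": float(rng.normal(*params.run_evoked_delta_hz)),
                "laser_spont_delta_hz": float(rng.normal(*params.laser_spont_delta_hz)),
                "laser_evoked_delta_hz": float(
                    rng.normal(*params.laser_evoked_delta_hz)
                ),
                "latency_ms": float(rng.uniform(*params.latency_range_ms)),
            }
        )
    return pd.DataFrame(rows)


def _unit_spikes(
    row: pd.Series,
    onsets: np.ndarray,
    is_wn: np.ndarray,
    is_laser: np.ndarray,
    is_run: np.ndarray,
    interaction: float,
    duration_s: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Piecewise-constant inhomogeneous-Poisson spikes for one unit.

    The 1.6 s trial cycle [onset-0.2, onset+1.4) tiles the session; within
    a cycle the rate changes at the laser edges (-50/+750 ms), the
    latency-shifted onset window and the latency-shifted offset window.
    Returns (sorted spike times, whether any segment rate was clipped at 0).
    """
    lat = row.latency_ms / 1000.0
    bounds = np.array([-0.2, -0.05, lat, lat + 0.1, 0.6 + lat, 0.7 + lat, 0.75, 1.4])
    durs = np.diff(bounds)  # (7,)
    n_trials = len(onsets)

    in_laser = np.array([False, True, True, True, True, True, False])
    evoked = np.array([0.0, 0.0, row.onset_gain_hz, 0.0, row.offset_gain_hz, 0.0, 0.0])
    is_evoked_seg = evoked > 0

    run = is_run.astype(float)[:, None]  # (n_trials, 1)
    laser = (is_laser.astype(float)[:, None]) * in_laser[None, :]
    wn = is_wn.astype(float)[:, None]
    both = (is_run & is_laser).astype(float)[:, None]
    gain_scale = 1.0 + interaction * both  # multiplicative interaction term

    spont_delta = (
        run * row.run_spont_delta_hz + laser * row.laser_spont_delta_hz
    ) * gain_scale
    evoked_delta = (
        run * row.run_evoked_delta_hz + laser * row.laser_evoked_delta_hz
    ) * gain_scale
    rates = (
        row.base_spont_hz
        + spont_delta
        + wn * is_evoked_seg[None, :] * (evoked[None, :] + evoked_delta)
    )
    clipped = bool(np.any(rates < 0))
    rates = np.maximum(rates, 0.0)

    starts = onsets[:, None] + bounds[None, :-1]
    counts = rng.poisson(rates * durs[None, :])
    flat_counts = counts.ravel()
    seg_starts = np.repeat(starts.ravel(), flat_counts)
    seg_durs = np.repeat(np.broadcast_to(durs, counts.shape).ravel(), flat_counts)
    spikes = seg_starts + rng.random(flat_counts.sum()) * seg_durs

    # pre-schedule and post-schedule baseline at the sitting spontaneous rate
    head = onsets[0] - 0.2
    tail0 = onsets[-1] + 1.4
    for a, b in ((0.0, head), (tail0, duration_s)):
        if b > a:
            k = rng.poisson(max(row.base_spont_hz, 0.0) * (b - a))
            spikes = np.concatenate([spikes, a + rng.random(k) * (b - a)])
    spikes = np.sort(spikes)
    return spikes[(spikes >= 0) & (spikes <= duration_s)], clipped


def generate_session(
    params: GeneratorParams | None = None,
) -> tuple[Session, GroundTruth]:
    """Generate one synthetic session and its aligned ground truth."""
    params = params or GeneratorParams()
    rngs = _child_rngs(params.seed)
    meta = AcquisitionMeta()

    # --- trial schedule: 4 combos randomly interleaved
    combos = [
        (stim, laser) for stim in ("WN", "blank") for laser in ("off", "on")
    ] * params.n_trials_per_combo
    order = rngs["schedule"].permutation(len(combos))
    combos = [combos[i] for i in order]
    cycle = meta.stim_dur_s + meta.isi_s
    onsets = 1.0 + np.arange(len(combos)) * cycle
    trials = make_trial_table(
        onsets,
        [c[0] for c in combos],
        [c[1] for c in combos],
        meta.stim_dur_s,
    )
    duration_s = float(onsets[-1] + 1.4 + 0.6)

    # --- behavior; trial-state truth uses the same deterministic labeling
    # rule as the analysis (median smoothing + 5%-of-max threshold), so
    # recovery tests are not confounded by ramp-straddling trials.
    running, run_state = _running_trace(params, duration_s, rngs["behavior"])
    labeling = behavior.label_trials(trials, behavior.smooth_running(running))
    is_run = labeling.state == "running"

    pupil = (
        _pupil_trace(run_state.astype(float), params.trace_rate_hz, rngs["pupil"])
        if params.include_pupil
        else None
    )

    # --- units
    truth_units = _draw_units(params, rngs["units"])
    probe_top = 400.0 - params.lfp_sink_channel * params.lfp_spacing_um
    is_wn = (trials["stim"] == "WN").to_numpy()
    is_laser = (trials["laser"] == "on").to_numpy()
    onsets_arr = trials["onset_s"].to_numpy(float)

    units: list[Unit] = []
    clipped_flags = []
    widths = []
    for row in truth_units.itertuples(index=False):
        center = int(round((row.depth_um - probe_top) / params.lfp_spacing_um))
        center = int(np.clip(center, 0, params.lfp_channels - 1))
        wf, width_ms = generate_waveform(
            row.cell_class,
            rngs["waveforms"],
            n_channels=params.lfp_channels,
            center_channel=center,
            spacing_um=params.lfp_spacing_um,
        )
        spikes, clipped = _unit_spikes(
            row,
            onsets_arr,
            is_wn,
            is_laser,
            is_run,
            params.interaction,
            duration_s,
            rngs["spikes"],
        )
        units.append(
            Unit(
                unit_id=row.unit_id,
                spike_times=spikes,
                waveforms=wf,
                peak_channel=center,
            )
        )
        clipped_flags.append(clipped)
        widths.append(width_ms)
    truth_units = truth_units.assign(clipped=clipped_flags, width_ms=widths)

    # --- LFP
    lfp = None
    if params.include_lfp:
        lfp = generate_lfp(
            trials,
            duration_s,
            sink_channel=params.lfp_sink_channel,
            n_channels=params.lfp_channels,
            spacing_um=params.lfp_spacing_um,
            rate_hz=params.lfp_rate_hz,
            amp_uv=params.lfp_amp_uv,
            noise_uv=params.lfp_noise_uv,
            sink_latency_s=params.lfp_sink_latency_s,
            seed=rngs["lfp"],
        )

    session = Session(
        session_id=f"synthetic-{params.seed}",
        units=units,
        trials=trials,
        running=running,
        duration_s=duration_s,
        pupil=pupil,
        lfp=lfp,
        meta=meta,
    )
    truth = GroundTruth(
        units=truth_units,
        trial_state=labeling.state.copy(),
        sink_channel_global=params.lfp_sink_channel,
        channel0_depth_um=probe_top,
        params=params,
    )
    return session, truth


# ---------------------------------------------------------------------------
# latent-timescale coupling (population/speed distance-correlation tests)


def generate_coupled_population(
    n_units: int = 30,
    duration_s: float = 240.0,
    tau_s: float = 0.4,
    gain: float = 0.8,
    base_rate_hz: float = 10.0,
    seed: int = 0,
    rate_hz: float = 100.0,
) -> tuple[list[Unit], BehaviorTrace]:
    """Population whose rates track a latent speed component with timescale tau.

    Speed is the rectified sum of a slow drift (tau ~ 8 s), a latent
    Ornstein-Uhlenbeck process z with correlation time ``tau_s``, and fast
    per-sample noise; unit rates are ``base * (1 + gain * z)`` (clipped at
    0). Only the z component is shared between speed and firing, so the
    shuffle-corrected distance correlation across a bin-size ladder peaks
    near ``tau_s``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    dt = 1.0 / rate_hz

    def _ou(tau: float) -> np.ndarray:
        rho = np.exp(-dt / tau)
        eps = rng.normal(0, np.sqrt(1 - rho**2), n)
        out = np.empty(n)
        acc = rng.normal()
        for i in range(n):
            acc = rho * acc + eps[i]
            out[i] = acc
        return out

    z = _ou(tau_s)
    slow = _ou(8.0)
    fast = rng.normal(0, 1.0, n)
    speed = np.maximum(3.0 + 2.0 * (0.6 * slow + 1.0 * z + 0.8 * fast), 0.0)
    trace = BehaviorTrace(t=np.arange(n) * dt, v=speed, rate_hz=rate_hz)

    bases = rng.uniform(0.5, 1.5, n_units) * base_rate_hz
    units = []
    for k in range(n_units):
        lam = np.maximum(bases[k] * (1.0 + gain * z), 0.0) * dt
        counts = rng.poisson(lam)
        idx = np.repeat(np.arange(n), counts)
        spikes = np.sort((idx + rng.random(idx.size)) * dt)
        units.append(Unit(unit_id=f"c{k:03d}", spike_times=spikes))
    return units, trace
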