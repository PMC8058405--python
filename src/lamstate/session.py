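"""Session data model and on-disk format.

A *session* is one head-fixed recording: sorted units (spike times +
per-channel mean waveforms), a trial table (white-noise bursts and silent
blanks, each with or without an optogenetic laser pulse), a running-speed
trace, and optionally a pupil trace and a multichannel LFP block from a
laminar probe (channels ordered superficial to deep, 25 um site spacing).

Conventions used throughout the package:

* all event times are in seconds (float64); spike and trial times share one
  clock starting at 0 at the start of the recording;
* channel indices are 0-based with channel 0 the most superficial site;
* trial windows are half-open ``[onset, onset + duration)`` so a spike on a
  boundary is counted exactly once.

The native on-disk layout is a directory of delimited text tables plus one
HDF5 file for the LFP::

    trials.tsv    onset_s  stim  laser  duration_s  [mean_speed  state]
    units.tsv     unit_id  peak_channel  [depth_um  layer  cell_class]
    spikes.tsv    unit_id  spike_time_s
    waveforms.tsv unit_id  channel  sample  uv        (long format)
    running.tsv   t_s  value          pupil.tsv  t_s  value
    lfp.h5        dataset "lfp" (channels x samples), attrs spacing_um,
                  rate_hz, band_low_hz, band_high_hz
    meta.json     acquisition metadata + session_id + duration_s

A reader for phy/Kilosort-style output (``spike_times.npy``,
``spike_clusters.npy``, ``templates.npy``) is provided as a convenience;
the tabular layout above is the contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionMeta",
    "BehaviorTrace",
    "LFPBlock",
    "Session",
    "SessionLoadError",
    "SessionValidationError",
    "Unit",
    "make_trial_table",
    "read_phy",
    "read_session",
    "validate_session",
    "write_session",
]

LAYERS = ("L1", "L2/3", "L4", "L5", "L6")
UNASSIGNED = "unassigned"
UNCLASSIFIED = "unclassified"

TRIAL_COLUMNS = ("onset_s", "stim", "laser", "duration_s", "mean_speed", "state")

#: float format used for every delimited-text write; round-trips float64 exactly.
_FLOAT_FMT = "%.17g"


class SessionLoadError(IOError):
    """A mandatory session component is missing or unreadable."""


class SessionValidationError(ValueError):
    """A session violates a data-model invariant."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Stimulus-schedule constants of the experiment.

    600 ms white-noise bursts at 1 s inter-stimulus interval, randomly
    interleaved with matched silent blanks; 800 ms laser pulses starting
    50 ms before sound onset and ending 150 ms after sound offset; at least
    30 repeats of each (stim, laser) combination.
    """

    stim_dur_s: float = 0.6
    isi_s: float = 1.0
    laser_pre_s: float = 0.05
    laser_post_s: float = 0.15
    laser_dur_s: float = 0.8
    min_reps_per_combo: int = 30

    def __post_init__(self) -> None:
        expected = self.stim_dur_s + self.laser_pre_s + self.laser_post_s
        if abs(self.laser_dur_s - expected) > 1e-9:
            raise SessionValidationError(
                f"laser_dur_s must equal stim_dur_s + laser_pre_s + laser_post_s "
                f"({expected:g}), got {self.laser_dur_s:g}"
            )


@dataclass
class BehaviorTrace:
    """A uniformly sampled behavioral signal (running speed or pupil size)."""

    t: np.ndarray
    v: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BehaviorTrace):
            return NotImplemented
        return (
            self.rate_hz == other.rate_hz
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.v, other.v)
        )


@dataclass
class LFPBlock:
    """Multichannel LFP, channels ordered superficial (row 0) to deep."""

    data: np.ndarray  # channels x samples, uV
    spacing_um: float = 25.0
    rate_hz: float = 1000.0
    filtered_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LFPBlock):
            return NotImplemented
        return (
            self.spacing_um == other.spacing_um
            and self.rate_hz == other.rate_hz
            and self.filtered_band == other.filtered_band
            and np.array_equal(self.data, other.data)
        )


@dataclass
class Unit:
    """One sorted neuron."""

    unit_id: str
    spike_times: np.ndarray
    waveforms: np.ndarray | None = None  # channels x samples, uV
    peak_channel: int | None = None
    waveform_rate_hz: float = 30000.0
    depth_um: float | None = None
    layer: str = UNASSIGNED
    cell_class: str = UNCLASSIFIED

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.waveforms is not None:
            self.waveforms = np.asarray(self.waveforms, dtype=float)
            if self.peak_channel is None:
                self.peak_channel = int(
                    np.argmax(np.ptp(self.waveforms, axis=1))
                )

    @property
    def peak_waveform(self) -> np.ndarray:
        if self.waveforms is None:
            raise ValueError(f"unit {self.unit_id} has no stored waveforms")
        return self.waveforms[self.peak_channel]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Unit):
            return NotImplemented
        same_wf = (
            (self.waveforms is None and other.waveforms is None)
            or (
                self.waveforms is not None
                and other.waveforms is not None
                and np.array_equal(self.waveforms, other.waveforms)
            )
        )
        return (
            self.unit_id == other.unit_id
            and np.array_equal(self.spike_times, other.spike_times)
            and same_wf
            and self.peak_channel == other.peak_channel
            and self.depth_um == other.depth_um
            and self.layer == other.layer
            and self.cell_class == other.cell_class
        )


@dataclass
class Session:
    """Container binding every component of one recording."""

    session_id: str
    units: list[Unit]
    trials: pd.DataFrame
    running: BehaviorTrace
    duration_s: float
    pupil: BehaviorTrace | None = None
    lfp: LFPBlock | None = None
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def unit(self, unit_id: str) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        same_pupil = (self.pupil is None) == (other.pupil is None) and (
            self.pupil is None or self.pupil == other.pupil
        )
        same_lfp = (self.lfp is None) == (other.lfp is None) and (
            self.lfp is None or self.lfp == other.lfp
        )
        return (
            self.session_id == other.session_id
            and self.units == other.units
            and self.trials.reset_index(drop=True).equals(
                other.trials.reset_index(drop=True)
            )
            and self.running == other.running
            and self.duration_s == other.duration_s
            and same_pupil
            and same_lfp
            and self.meta == other.meta
        )


def make_trial_table(
    onsets_s: Sequence[float],
    stim: Sequence[str],
    laser: Sequence[str],
    duration_s: float = 0.6,
) -> pd.DataFrame:
    """Build a trial table with unfilled behavioral-state columns."""
    n = len(onsets_s)
    if not (len(stim) == len(laser) == n):
        raise ValueError("onsets, stim and laser must have equal length")
    return pd.DataFrame(
        {
            "onset_s": np.asarray(onsets_s, dtype=float),
            "stim": pd.array(stim, dtype="str"),
            "laser": pd.array(laser, dtype="str"),
            "duration_s": float(duration_s),
            "mean_speed": np.nan,
            "state": pd.array(["unfilled"] * n, dtype="str"),
        }
    )


# ---------------------------------------------------------------------------
# validation


def validate_session(session: Session) -> list[str]:
    """Check every data-model invariant; return human-readable violations.

    An empty list means the session is safe for every downstream operation.
    """
    out: list[str] = []
    dur = session.duration_s

    ids = [u.unit_id for u in session.units]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        out.append(f"duplicate unit ids: {dupes}")

    for u in session.units:
        st = u.spike_times
        if st.size and (np.any(np.diff(st) < 0)):
            out.append(f"unit {u.unit_id}: spike times not nondecreasing")
        if st.size and (st[0] < 0 or st[-1] > dur):
            out.append(
                f"unit {u.unit_id}: spike times outside [0, {dur:g}] s"
            )
        if u.depth_um is not None and not (0 <= u.depth_um <= 1200):
            out.append(
                f"unit {u.unit_id}: depth {u.depth_um:g} um outside [0, 1200]"
            )
        if u.layer not in LAYERS + (UNASSIGNED,):
            out.append(f"unit {u.unit_id}: unknown layer {u.layer!r}")
        if u.cell_class not in ("NS", "RS", UNCLASSIFIED):
            out.append(f"unit {u.unit_id}: unknown cell class {u.cell_class!r}")
        if u.waveforms is not None and u.peak_channel is not None:
            amp = np.ptp(u.waveforms, axis=1)
            if int(np.argmax(amp)) != u.peak_channel:
                out.append(
                    f"unit {u.unit_id}: peak_channel {u.peak_channel} is not the "
                    f"max-amplitude channel {int(np.argmax(amp))}"
                )

    tr = session.trials
    missing = [c for c in ("onset_s", "stim", "laser", "duration_s") if c not in tr]
    if missing:
        out.append(f"trial table missing columns: {missing}")
        return out
    on = tr["onset_s"].to_numpy(float)
    if on.size:
        if on.min() < 0 or (on + tr["duration_s"].to_numpy(float)).max() > dur:
            out.append("trial windows outside [0, duration]")
        spacing = np.diff(np.sort(on))
        if spacing.size and spacing.min() < tr["duration_s"].max() - 1e-9:
            out.append("inter-trial onset spacing smaller than stimulus duration")
    bad_stim = set(tr["stim"]) - {"WN", "blank"}
    if bad_stim:
        out.append(f"unknown stim values: {sorted(bad_stim)}")
    bad_laser = set(tr["laser"]) - {"on", "off"}
    if bad_laser:
        out.append(f"unknown laser values: {sorted(bad_laser)}")

    for name, trace in (("running", session.running), ("pupil", session.pupil)):
        if trace is None:
            continue
        if len(trace.t) != len(trace.v):
            out.append(f"{name} trace: t and v lengths differ")
        elif len(trace.t) > 1:
            dt = np.diff(trace.t)
            if np.any(np.abs(dt - 1.0 / trace.rate_hz) > 1.0 / trace.rate_hz):
                out.append(f"{name} trace: sampling not uniform at rate_hz")

    if session.lfp is not None:
        if session.lfp.spacing_um <= 0:
            out.append("LFP spacing_um must be positive")
        if session.lfp.n_channels < 3:
            out.append("CSD requires >=3 channels")

    return out


# ---------------------------------------------------------------------------
# writing


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_session(session: Session, path: str | Path) -> None:
    """Serialize a session to ``path`` in the native directory layout.

    Deterministic: the same session always produces byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    _write_tsv(session.trials, path / "trials.tsv")

    units_rows = []
    spike_frames = []
    wf_frames = []
    for u in session.units:
        units_rows.append(
            {
                "unit_id": u.unit_id,
                "peak_channel": -1 if u.peak_channel is None else u.peak_channel,
                "waveform_rate_hz": u.waveform_rate_hz,
                "depth_um": np.nan if u.depth_um is None else u.depth_um,
                "layer": u.layer,
                "cell_class": u.cell_class,
            }
        )
        if u.spike_times.size:
            spike_frames.append(
                pd.DataFrame(
                    {"unit_id": u.unit_id, "spike_time_s": u.spike_times}
                )
            )
        if u.waveforms is not None:
            ch, samp = np.nonzero(np.ones_like(u.waveforms, dtype=bool))
            wf_frames.append(
                pd.DataFrame(
                    {
                        "unit_id": u.unit_id,
                        "channel": ch,
                        "sample": samp,
                        "uv": u.waveforms.ravel(),
                    }
                )
            )
    _write_tsv(pd.DataFrame(units_rows, columns=[
        "unit_id", "peak_channel", "waveform_rate_hz", "depth_um", "layer",
        "cell_class",
    ]), path / "units.tsv")
    _write_tsv(
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["unit_id", "spike_time_s"]),
        path / "spikes.tsv",
    )
    if wf_frames:
        _write_tsv(pd.concat(wf_frames, ignore_index=True), path / "waveforms.tsv")

    for name, trace in (("running", session.running), ("pupil", session.pupil)):
        if trace is not None:
            _write_tsv(
                pd.DataFrame({"t_s": trace.t, "value": trace.v}),
                path / f"{name}.tsv",
            )

    if session.lfp is not None:
        with h5py.File(path / "lfp.h5", "w", track_order=False) as f:
            d = f.create_dataset("lfp", data=session.lfp.data, track_times=False)
            d.attrs["spacing_um"] = session.lfp.spacing_um
            d.attrs["rate_hz"] = session.lfp.rate_hz
            if session.lfp.filtered_band is not None:
                d.attrs["band_low_hz"] = session.lfp.filtered_band[0]
                d.attrs["band_high_hz"] = session.lfp.filtered_band[1]

    meta = {
        "session_id": session.session_id,
        "duration_s": session.duration_s,
        "running_rate_hz": session.running.rate_hz,
        "pupil_rate_hz": None if session.pupil is None else session.pupil.rate_hz,
        "stim_dur_s": session.meta.stim_dur_s,
        "isi_s": session.meta.isi_s,
        "laser_pre_s": session.meta.laser_pre_s,
        "laser_post_s": session.meta.laser_post_s,
        "laser_dur_s": session.meta.laser_dur_s,
        "min_reps_per_combo": session.meta.min_reps_per_combo,
    }
    (path / "meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# reading


def _require(path: Path, component: str) -> Path:
    if not path.exists():
        raise SessionLoadError(f"missing session component {component!r}: {path}")
    return path


def read_session(path: str | Path, validate: bool = True) -> Session:
    """Load a session directory written by :func:`write_session`."""
    path = Path(path)
    meta_raw = json.loads(_require(path / "meta.json", "meta").read_text())
    meta = AcquisitionMeta(
        stim_dur_s=meta_raw["stim_dur_s"],
        isi_s=meta_raw["isi_s"],
        laser_pre_s=meta_raw["laser_pre_s"],
        laser_post_s=meta_raw["laser_post_s"],
        laser_dur_s=meta_raw["laser_dur_s"],
        min_reps_per_combo=meta_raw["min_reps_per_combo"],
    )

    trials = pd.read_csv(
        _require(path / "trials.tsv", "trials"),
        sep="\t",
        dtype={"stim": "str", "laser": "str", "state": "str"},
        float_precision="round_trip",
    )
    for col in ("onset_s", "duration_s"):
        trials[col] = trials[col].astype(float)
    if "mean_speed" not in trials:
        trials["mean_speed"] = np.nan
    trials["mean_speed"] = trials["mean_speed"].astype(float)
    if "state" not in trials:
        trials["state"] = pd.array(["unfilled"] * len(trials), dtype="str")

    units_df = pd.read_csv(_require(path / "units.tsv", "units"), sep="\t",
                           float_precision="round_trip")
    spikes = pd.read_csv(_require(path / "spikes.tsv", "spikes"), sep="\t",
                         float_precision="round_trip")
    spikes_by_unit = (
        {k: g["spike_time_s"].to_numpy(float) for k, g in spikes.groupby("unit_id")}
        if len(spikes)
        else {}
    )
    wf_path = path / "waveforms.tsv"
    wf_by_unit: dict[str, np.ndarray] = {}
    if wf_path.exists():
        wf = pd.read_csv(wf_path, sep="\t", float_precision="round_trip")
        for uid, g in wf.groupby("unit_id"):
            n_ch = int(g["channel"].max()) + 1
            n_s = int(g["sample"].max()) + 1
            arr = np.zeros((n_ch, n_s))
            arr[g["channel"].to_numpy(), g["sample"].to_numpy()] = g["uv"].to_numpy()
            wf_by_unit[str(uid)] = arr

    units = []
    for row in units_df.itertuples(index=False):
        uid = str(row.unit_id)
        depth = None if pd.isna(row.depth_um) else float(row.depth_um)
        units.append(
            Unit(
                unit_id=uid,
                spike_times=spikes_by_unit.get(uid, np.array([])),
                waveforms=wf_by_unit.get(uid),
                peak_channel=None if row.peak_channel < 0 else int(row.peak_channel),
                waveform_rate_hz=float(row.waveform_rate_hz),
                depth_um=depth,
                layer=str(row.layer),
                cell_class=str(row.cell_class),
            )
        )

    def _read_trace(name: str, rate: float | None) -> BehaviorTrace | None:
        p = path / f"{name}.tsv"
        if not p.exists() or rate is None:
            return None
        df = pd.read_csv(p, sep="\t", float_precision="round_trip")
        return BehaviorTrace(df["t_s"].to_numpy(), df["value"].to_numpy(), rate)

    running = _read_trace("running", meta_raw["running_rate_hz"])
    if running is None:
        raise SessionLoadError(f"missing session component 'running': {path}")
    pupil = _read_trace("pupil", meta_raw.get("pupil_rate_hz"))

    lfp = None
    lfp_path = path / "lfp.h5"
    if lfp_path.exists():
        with h5py.File(lfp_path, "r") as f:
            d = f["lfp"]
            band = None
            if "band_low_hz" in d.attrs:
                band = (float(d.attrs["band_low_hz"]), float(d.attrs["band_high_hz"]))
            lfp = LFPBlock(
                data=d[()],
                spacing_um=float(d.attrs["spacing_um"]),
                rate_hz=float(d.attrs["rate_hz"]),
                filtered_band=band,
            )

    session = Session(
        session_id=meta_raw["session_id"],
        units=units,
        trials=trials,
        running=running,
        duration_s=float(meta_raw["duration_s"]),
        pupil=pupil,
        lfp=lfp,
        meta=meta,
    )
    if validate:
        violations = validate_session(session)
        if violations:
            raise SessionValidationError("; ".join(violations))
    return session


def read_phy(
    path: str | Path,
    sample_rate_hz: float,
    duration_s: float | None = None,
) -> list[Unit]:
    """Read units from a phy/Kilosort-style directory.

    Expects ``spike_times.npy`` (samples), ``spike_clusters.npy`` and
    optionally ``templates.npy`` (cluster x samples x channels). Convenience
    only; the tabular layout is the native contract.
    """
    path = Path(path)
    times = np.load(_require(path / "spike_times.npy", "spike_times")).ravel()
    clusters = np.load(_require(path / "spike_clusters.npy", "spike_clusters")).ravel()
    templates = None
    if (path / "templates.npy").exists():
        templates = np.load(path / "templates.npy")
    units = []
    for cid in np.unique(clusters):
        st = np.sort(times[clusters == cid]) / sample_rate_hz
        if duration_s is not None:
            st = st[st <= duration_s]
        wf = None
        if templates is not None and cid < len(templates):
            wf = np.asarray(templates[cid]).T  # to channels x samples
        units.append(Unit(unit_id=str(int(cid)), spike_times=st, waveforms=wf))
    return units
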