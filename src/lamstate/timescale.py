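"""Distance correlation between population firing and running speed.

The sample distance correlation (double-centering definition) measures
arbitrary — including non-linear — dependence between the population rate
vector (n_units x n_bins) and the binned running speed. It is zero only
under independence and can relate variables of different dimension, which
lets a whole simultaneously recorded population be compared against a
scalar speed trace.

Firing is binned in 100 ms bins by default; to probe the timescale of
state modulation the bin size is swept over a doubling ladder from 50 ms
(default ceiling 40 s). Because slow signals make any statistic of finite
recordings nonzero, each raw value is corrected by subtracting the mean
distance correlation over random permutations of the binned speed, and a
permutation p-value is reported as the fraction of shuffles at or above
the raw value (50 shuffles by default). A circular-shift null is available
as an option for strongly autocorrelated traces; the full permutation is
the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .session import BehaviorTrace, Unit

__all__ = [
    "DcorSweep",
    "bin_ladder",
    "bin_population",
    "bin_trace",
    "dcor_sweep",
    "distance_correlation",
]

N_SHUFFLES = 50


def bin_ladder(
    start_s: float = 0.05, ceiling_s: float = 40.0
) -> np.ndarray:
    """Doubling bin-size ladder: 0.05, 0.1, 0.2, ... up to the ceiling."""
    sizes = [start_s]
    while sizes[-1] * 2 <= ceiling_s * (1 + 1e-9):
        sizes.append(sizes[-1] * 2)
    return np.array(sizes)


def bin_population(
    units: list[Unit], duration_s: float, bin_s: float
) -> np.ndarray:
    """n_units x n_bins matrix of firing rates (Hz); trailing partial bin dropped."""
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    n_bins = int(np.floor(duration_s / bin_s + 1e-9))
    if n_bins < 1:
        raise ValueError(f"duration {duration_s:g} s shorter than bin {bin_s:g} s")
    edges = np.arange(n_bins + 1) * bin_s
    out = np.zeros((len(units), n_bins))
    for i, u in enumerate(units):
        out[i] = np.histogram(u.spike_times, bins=edges)[0] / bin_s
    return out


def bin_trace(trace: BehaviorTrace, duration_s: float, bin_s: float) -> np.ndarray:
    """Bin-averaged trace values at the same bin grid as :func:`bin_population`."""
    n_bins = int(np.floor(duration_s / bin_s + 1e-9))
    idx = np.floor(trace.t / bin_s + 1e-12).astype(int)
    ok = (idx >= 0) & (idx < n_bins)
    sums = np.bincount(idx[ok], weights=trace.v[ok], minlength=n_bins)
    counts = np.bincount(idx[ok], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def _centered_distance_matrix(x: np.ndarray) -> np.ndarray:
    """Double-centered Euclidean distance matrix of the sample columns.

    ``x`` is (n_vars, n_samples) or (n_samples,).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = cdist(x.T, x.T)
    row = d.mean(axis=1, keepdims=True)
    col = d.mean(axis=0, keepdims=True)
    return d - row - col + d.mean()


def _dcor_from_centered(a: np.ndarray, b: np.ndarray) -> float:
    dcov2 = (a * b).mean()
    dvarx2 = (a * a).mean()
    dvary2 = (b * b).mean()
    denom2 = dvarx2 * dvary2
    if denom2 <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(denom2)))


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation in [0, 1] between ``x`` and ``y``.

    ``x`` may be (n_vars, n_samples) or (n_samples,); ``y`` likewise. The
    biased (simple-mean) dCov estimator of the classical definition is
    used. Constant input on either side gives 0 by convention.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("x and y must share the sample (bin) axis")
    if x.shape[1] < 4:
        raise ValueError("need >=4 samples for a distance correlation")
    return _dcor_from_centered(
        _centered_distance_matrix(x), _centered_distance_matrix(y)
    )


@dataclass
class DcorSweep:
    """Raw, shuffle-corrected distance correlation across bin sizes."""

    bin_sizes_s: np.ndarray
    dcor_raw: np.ndarray
    shuffle_mean: np.ndarray
    dcor_corrected: np.ndarray
    p_value: np.ndarray
    n_bins: np.ndarray
    n_shuffles: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_s": self.bin_sizes_s,
                "n_bins": self.n_bins,
                "dcor_raw": self.dcor_raw,
                "shuffle_mean": self.shuffle_mean,
                "dcor_corrected": self.dcor_corrected,
                "p": self.p_value,
            }
        )

    @property
    def peak_bin_s(self) -> float:
        """Bin size with the largest corrected distance correlation."""
        ok = np.isfinite(self.dcor_corrected)
        if not ok.any():
            return float("nan")
        idx = np.nonzero(ok)[0]
        return float(self.bin_sizes_s[idx[np.argmax(self.dcor_corrected[idx])]])


def dcor_sweep(
    units: list[Unit],
    speed: BehaviorTrace,
    duration_s: float,
    bin_sizes_s: np.ndarray | None = None,
    n_shuffles: int = N_SHUFFLES,
    seed: int | np.random.Generator = 0,
    shuffle: str = "permute",
) -> DcorSweep:
    """Shuffle-corrected distance-correlation sweep over bin sizes.

    For each bin size the population rate matrix and the bin-averaged speed
    are compared; the shuffle null permutes the binned speed vector
    (``shuffle="shift"`` instead applies random circular shifts, a stricter
    null under autocorrelation). ``p = #{shuffled >= raw} / n_shuffles``.
    Ladder steps with fewer than 4 bins are marked undefined (NaN).

    Shuffles reuse the centered distance matrices: permuting the speed
    sample order conjugates its centered matrix by the same permutation, so
    each shuffle costs one matrix gather and one mean product.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if bin_sizes_s is None:
        bin_sizes_s = bin_ladder()
    bin_sizes_s = np.asarray(bin_sizes_s, dtype=float)

    raw = np.full(len(bin_sizes_s), np.nan)
    sh_mean = np.full(len(bin_sizes_s), np.nan)
    pval = np.full(len(bin_sizes_s), np.nan)
    nbins = np.zeros(len(bin_sizes_s), dtype=int)

    for i, bs in enumerate(bin_sizes_s):
        n_bins = int(np.floor(duration_s / bs + 1e-9))
        nbins[i] = n_bins
        if n_bins < 4:
            continue
        rates = bin_population(units, duration_s, bs)
        v = bin_trace(speed, duration_s, bs)
        a = _centered_distance_matrix(rates)
        b = _centered_distance_matrix(v)
        raw[i] = _dcor_from_centered(a, b)
        shuffled = np.empty(n_shuffles)
        for s in range(n_shuffles):
            if shuffle == "permute":
                perm = rng.permutation(n_bins)
            elif shuffle == "shift":
                perm = np.roll(np.arange(n_bins), rng.integers(1, n_bins))
            else:
                raise ValueError(f"unknown shuffle mode {shuffle!r}")
            shuffled[s] = _dcor_from_centered(a, b[np.ix_(perm, perm)])
        sh_mean[i] = shuffled.mean()
        pval[i] = float(np.sum(shuffled >= raw[i])) / n_shuffles

    return DcorSweep(
        bin_sizes_s=bin_sizes_s,
        dcor_raw=raw,
        shuffle_mean=sh_mean,
        dcor_corrected=raw - sh_mean,
        p_value=pval,
        n_bins=nbins,
        n_shuffles=n_shuffles,
    )
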