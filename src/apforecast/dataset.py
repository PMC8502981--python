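"""Forecasting-ready datasets from raw voltage time series.

A :class:`SampledSeries` -- a strictly increasing, possibly nonuniform
sequence of (time, voltage[, stimulus]) samples -- is the currency passed
between simulation, preprocessing, training, and evaluation.  This module
provides unit-interval rescaling, voltage-adaptive undersampling, beat
onset detection, stimulus-channel reconstruction, spline artifact removal,
and beat-aligned train/test splitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy.interpolate import CubicSpline

__all__ = [
    "SampledSeries",
    "AffineMap",
    "ResampleConfig",
    "DatasetSplit",
    "rescale_unit_interval",
    "resample",
    "detect_beat_onsets",
    "reconstruct_stimulus_channel",
    "remove_artifacts_spline",
    "split_train_test",
]


@dataclass
class SampledSeries:
    """Nonuniformly sampled voltage trace with an optional stimulus channel.

    Parameters
    ----------
    times
        Sample times in ms, strictly increasing.
    voltage
        Voltage at each sample (dimensionless after rescaling).
    stimulus
        Optional stimulus-current channel aligned with ``times``; absent
        for univariate (autonomously beating) data.
    meta
        Free-form provenance (model name, parameters, dt, seed).
    """

    times: np.ndarray
    voltage: np.ndarray
    stimulus: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.stimulus is not None:
            self.stimulus = np.asarray(self.stimulus, dtype=float)
        if self.times.ndim != 1 or self.voltage.shape != self.times.shape:
            raise ValueError("times and voltage must be 1-D and equal length")
        if self.stimulus is not None and self.stimulus.shape != self.times.shape:
            raise ValueError("stimulus must match times in length")
        if len(self.times) and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        arrays = [self.times, self.voltage]
        if self.stimulus is not None:
            arrays.append(self.stimulus)
        for a in arrays:
            if not np.all(np.isfinite(a)):
                raise ValueError("series contains non-finite values")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def is_multivariate(self) -> bool:
        return self.stimulus is not None

    def take(self, indices: np.ndarray) -> "SampledSeries":
        """Subset by sample index, preserving channel alignment."""
        stim = None if self.stimulus is None else self.stimulus[indices]
        return SampledSeries(self.times[indices], self.voltage[indices], stim,
                             dict(self.meta))

    def window(self, t0: float, t1: float) -> "SampledSeries":
        """Samples with t0 <= t < t1."""
        idx = np.nonzero((self.times >= t0) & (self.times < t1))[0]
        return self.take(idx)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_ms": self.times, "voltage": self.voltage}
        if self.stimulus is not None:
            cols["stimulus"] = self.stimulus
        return pd.DataFrame(cols)

    def save_csv(self, path: str | Path) -> None:
        """Write as delimited text with a ``#``-prefixed JSON metadata line."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(self.meta) + "\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def load_csv(cls, path: str | Path) -> "SampledSeries":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first[1:].strip()) if first.startswith("#") else {}
            if not first.startswith("#"):
                fh.seek(0)
            frame = pd.read_csv(fh)
        stim = frame["stimulus"].to_numpy() if "stimulus" in frame else None
        return cls(frame["time_ms"].to_numpy(), frame["voltage"].to_numpy(),
                   stim, meta)

    def save_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_ms", data=self.times)
            fh.create_dataset("voltage", data=self.voltage)
            if self.stimulus is not None:
                fh.create_dataset("stimulus", data=self.stimulus)
            fh.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "SampledSeries":
        import h5py

        with h5py.File(path, "r") as fh:
            stim = fh["stimulus"][:] if "stimulus" in fh else None
            return cls(fh["time_ms"][:], fh["voltage"][:], stim,
                       json.loads(fh.attrs.get("meta", "{}")))


@dataclass(frozen=True)
class AffineMap:
    """Voltage rescaling v' = scale * v + offset, kept for inversion."""

    scale: float
    offset: float

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(v) + self.offset

    def inverse(self, v: np.ndarray) -> np.ndarray:
        return (np.asarray(v) - self.offset) / self.scale


@dataclass(frozen=True)
class ResampleConfig:
    """Voltage-adaptive undersampling thresholds.

    ``dv_threshold`` keeps a point once the voltage has moved at least that
    far from the last kept point; ``dt_max`` forces a point whenever the gap
    since the last kept point exceeds it, guaranteeing coverage of plateau
    and rest phases.  Both are hyperparameters of the forecasting pipeline.
    """

    dv_threshold: float = 0.02
    dt_max: float = 20.0

    def __post_init__(self) -> None:
        if self.dv_threshold < 0:
            raise ValueError("dv_threshold must be >= 0")
        if self.dt_max <= 0:
            raise ValueError("dt_max must be > 0")


@dataclass
class DatasetSplit:
    """Contiguous warmup / train / test partition at beat boundaries."""

    pre_train: SampledSeries
    train: SampledSeries
    test: SampledSeries
    beat_onsets: np.ndarray
    n_warmup_beats: int = 0
    n_train_beats: int = 0

    @property
    def full(self) -> SampledSeries:
        """Concatenation of the three segments (the original series)."""
        times = np.concatenate(
            [self.pre_train.times, self.train.times, self.test.times])
        volt = np.concatenate(
            [self.pre_train.voltage, self.train.voltage, self.test.voltage])
        stim = None
        if self.pre_train.stimulus is not None:
            stim = np.concatenate(
                [self.pre_train.stimulus, self.train.stimulus,
                 self.test.stimulus])
        return SampledSeries(times, volt, stim, dict(self.pre_train.meta))

    @property
    def n_test_beats(self) -> int:
        return len(self.beat_onsets) - self.n_warmup_beats - self.n_train_beats


def rescale_unit_interval(
    series: SampledSeries, *, assume_scaled: bool = False
) -> tuple[SampledSeries, AffineMap]:
    """Linearly rescale voltage to span [0, 1].

    Returns the rescaled series and the affine map applied so predictions
    can be mapped back to physical units.  ``assume_scaled`` passes the
    series through with an identity map, for models whose upstroke is
    already normalized to one.
    """
    if assume_scaled:
        return series, AffineMap(1.0, 0.0)
    v = series.voltage
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 0:
        raise ValueError("cannot rescale a constant-voltage series")
    amap = AffineMap(1.0 / (hi - lo), -lo / (hi - lo))
    out = SampledSeries(series.times.copy(), amap(v),
                        None if series.stimulus is None
                        else series.stimulus.copy(),
                        dict(series.meta))
    return out, amap


@njit(cache=True)
def _resample_mask(times, voltage, dv_threshold, dt_max):  # pragma: no cover
    n = times.shape[0]
    keep = np.zeros(n, dtype=np.bool_)
    keep[0] = True
    t_last = times[0]
    v_last = voltage[0]
    for i in range(1, n):
        if abs(voltage[i] - v_last) >= dv_threshold or times[i] - t_last > dt_max:
            keep[i] = True
            t_last = times[i]
            v_last = voltage[i]
    return keep


def resample(series: SampledSeries, config: ResampleConfig) -> SampledSeries:
    """Undersample a series, keeping points where voltage moves or time lags.

    The first point is always kept.  A later point is kept iff its voltage
    differs from the *last kept* point by at least ``dv_threshold``, or the
    time since the last kept point exceeds ``dt_max``.  No interpolation is
    introduced: every output sample is an input sample.  With
    ``dv_threshold = 0`` every point qualifies and the series is unchanged.
    """
    if len(series) == 0:
        raise ValueError("cannot resample an empty series")
    keep = _resample_mask(series.times, series.voltage,
                          float(config.dv_threshold), float(config.dt_max))
    return series.take(np.nonzero(keep)[0])


def detect_beat_onsets(
    series: SampledSeries,
    upstroke_threshold: float = 0.15,
    lockout_ms: float = 50.0,
) -> np.ndarray:
    """Times of upward threshold crossings, one per action potential.

    The crossing time is linearly interpolated between the bracketing
    samples.  A refractory lockout suppresses re-triggering on noisy or
    notched upstrokes.  Returns an empty array when no crossing exists.
    """
    v = series.voltage
    t = series.times
    above = v > upstroke_threshold
    idx = np.nonzero(~above[:-1] & above[1:])[0]
    onsets = []
    last = -np.inf
    for i in idx:
        frac = (upstroke_threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= lockout_ms:
            onsets.append(tc)
            last = tc
    return np.asarray(onsets, dtype=float)


def reconstruct_stimulus_channel(
    onsets: np.ndarray,
    grid: np.ndarray,
    pulse_duration: float = 2.0,
    pulse_amplitude: float = 0.2,
) -> np.ndarray:
    """Stamp square stimulus pulses onto a (possibly nonuniform) time grid.

    Each onset contributes ``pulse_amplitude`` at every grid point inside
    ``[onset, onset + pulse_duration)``.  Used when stimulus timing is only
    known through detected beat onsets, e.g. for experimental recordings.
    """
    onsets = np.sort(np.asarray(onsets, dtype=float))
    grid = np.asarray(grid, dtype=float)
    if len(onsets) > 1 and np.any(np.diff(onsets) < pulse_duration):
        raise ValueError("overlapping stimulus pulses")
    out = np.zeros_like(grid)
    for onset in onsets:
        inside = (grid >= onset) & (grid < onset + pulse_duration)
        if not inside.any():
            warnings.warn(
                f"stimulus pulse at t={onset:g} ms contains no grid point",
                stacklevel=2)
        out[inside] = pulse_amplitude
    return out


def remove_artifacts_spline(
    series: SampledSeries, artifact_windows: list[tuple[float, float]]
) -> SampledSeries:
    """Replace voltage inside artifact windows by cubic-spline interpolation.

    The spline is anchored on all samples outside the windows; samples
    inside each window are re-evaluated from it.  Windows must lie strictly
    inside the series span and not overlap.
    """
    if not artifact_windows:
        return series
    wins = sorted((float(a), float(b)) for a, b in artifact_windows)
    for (a0, b0), (a1, _) in zip(wins, wins[1:]):
        if a1 < b0:
            raise ValueError("artifact windows overlap")
    t = series.times
    for a, b in wins:
        if a <= t[0] or b >= t[-1]:
            raise ValueError("artifact window covers the series boundary")
    inside = np.zeros(len(t), dtype=bool)
    for a, b in wins:
        inside |= (t >= a) & (t <= b)
    spline = CubicSpline(t[~inside], series.voltage[~inside])
    voltage = series.voltage.copy()
    voltage[inside] = spline(t[inside])
    return SampledSeries(t.copy(), voltage,
                         None if series.stimulus is None
                         else series.stimulus.copy(),
                         dict(series.meta))


def split_train_test(
    series: SampledSeries,
    onsets: np.ndarray,
    n_warmup_beats: int,
    n_train_beats: int,
) -> DatasetSplit:
    """Partition a series into warmup / train / test at beat onsets.

    The warmup (washout) beats develop forecaster state but contribute no
    training rows; everything after the training beats is the closed-loop
    test horizon.  Requires at least one beat left for testing.
    """
    onsets = np.asarray(onsets, dtype=float)
    n_beats = len(onsets)
    if n_beats < n_warmup_beats + n_train_beats + 1:
        raise ValueError(
            f"need > {n_warmup_beats + n_train_beats} beats, have {n_beats}")
    t_train = onsets[n_warmup_beats]
    t_test = onsets[n_warmup_beats + n_train_beats]
    t = series.times
    i_train = int(np.searchsorted(t, t_train))
    i_test = int(np.searchsorted(t, t_test))
    return DatasetSplit(
        pre_train=series.take(np.arange(0, i_train)),
        train=series.take(np.arange(i_train, i_test)),
        test=series.take(np.arange(i_test, len(t))),
        beat_onsets=onsets,
        n_warmup_beats=n_warmup_beats,
        n_train_beats=n_train_beats,
    )
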