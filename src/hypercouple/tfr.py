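"""Single-trial time-frequency decomposition with adaptive Hanning tapers.

Power at (trial, channel, f, t) is the squared magnitude of a windowed DFT
coefficient: a Hanning taper of length ``cycles / f`` seconds (rounded to the
nearest odd sample count, ties upward) is centered on t and normalized by its
coherent gain (taper sum), so narrow-band power is amplitude-calibrated across
frequencies despite the adaptive window length; points whose full window would
extend past the epoch edges are masked rather than extrapolated.

Also provides relative-baseline correction, band/window averaging, and ERP
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DataError,
    DegenerateBaselineError,
    DomainError,
    SelectionError,
)
from .synth import EpochSet


@dataclass(frozen=True)
class BandSpec:
    """Named frequency band with its analysis time window (seconds)."""

    name: str
    f_lo: float
    f_hi: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise DomainError("band requires f_lo < f_hi")
        if not self.window[0] < self.window[1]:
            raise DomainError("band window must be an increasing interval")


#: canonical band definitions (window = feedback-locked analysis window)
BANDS = {
    "delta": BandSpec("delta", 1.0, 4.0, (0.0, 4.0)),
    "theta": BandSpec("theta", 4.0, 7.0, (0.0, 4.0)),
    "alpha": BandSpec("alpha", 8.0, 14.0, (0.0, 4.0)),
    "low_beta": BandSpec("low_beta", 15.0, 20.0, (0.0, 4.0)),
    "high_beta": BandSpec("high_beta", 20.0, 25.0, (0.0, 4.0)),
}


@dataclass
class TFRSet:
    """Single-trial power with axis metadata.

    ``power`` is (trials, channels, freqs, times); masked (edge) points hold
    NaN and are flagged True in ``mask`` (freqs x times). ``baseline_mode`` is
    'raw' (non-negative power) or 'relchange' ((P - B)/B).
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: tuple[str, ...]
    baseline_mode: str = "raw"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise DataError("freqs must be strictly increasing")
        if np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if self.mask is None:
            self.mask = np.zeros((len(self.freqs), len(self.times)), dtype=bool)

    def axes_equal(self, other: "TFRSet") -> bool:
        return (
            np.array_equal(self.freqs, other.freqs)
            and np.array_equal(self.times, other.times)
            and self.channel_labels == other.channel_labels
        )


@dataclass
class ERP:
    """Trial-averaged time-locked waveform (channels x times), baseline-corrected."""

    amplitude: np.ndarray
    times: np.ndarray
    channel_labels: tuple[str, ...]
    baseline: tuple[float, float]


def taper_length(freq: float, cycles: float, sfreq: float) -> int:
    """Adaptive window length in samples: cycles/f seconds, nearest odd, ties +1."""
    n = cycles / freq * sfreq
    lo = int(np.floor(n))
    odd = lo if lo % 2 == 1 else lo + 1  # odd candidates around n
    cand = np.array([odd - 2, odd, odd + 2])
    cand = cand[cand > 0]
    dist = np.abs(cand - n)
    best = cand[dist <= dist.min() + 1e-12]
    return int(best.max())  # ties broken upward


def compute_tfr(
    epochs: EpochSet,
    freqs: np.ndarray,
    times: np.ndarray,
    cycles: float = 3.0,
    dtype: type = np.float32,
) -> TFRSet:
    """Sliding Hanning-taper power for every trial, channel, frequency, time.

    The taper is normalized by its sum; time points whose window exceeds the
    epoch are masked (NaN), not extrapolated. Arithmetic is double precision;
    ``dtype`` sets the storage precision of the power array (float32 default
    to bound memory on full grids).
    """
    freqs = np.asarray(freqs, dtype=float)
    times = np.asarray(times, dtype=float)
    data = np.asarray(epochs.data, dtype=np.float64)
    n_trials, n_ch, n_samples = data.shape
    duration = n_samples / epochs.sfreq
    if np.any(freqs < 1.0 / duration):
        raise DomainError("requested frequency below 1/epoch-duration")
    power = np.full((n_trials, n_ch, len(freqs), len(times)), np.nan, dtype=dtype)
    mask = np.ones((len(freqs), len(times)), dtype=bool)
    centers = np.round((times - epochs.tmin) * epochs.sfreq).astype(int)
    for fi, f in enumerate(freqs):
        n_tap = taper_length(f, cycles, epochs.sfreq)
        half = n_tap // 2
        taper = np.hanning(n_tap)
        taper = taper / taper.sum()  # coherent gain: unit sinusoid -> 1/4 power
        phase = np.exp(-2j * np.pi * f * (np.arange(n_tap) - half) / epochs.sfreq)
        kernel = (taper * phase).conj()
        for ti, c in enumerate(centers):
            if c - half < 0 or c + half >= n_samples:
                continue  # stays masked
            seg = data[:, :, c - half: c + half + 1]
            coef = seg @ kernel
            power[:, :, fi, ti] = (coef.real ** 2 + coef.imag ** 2).astype(dtype)
            mask[fi, ti] = False
    return TFRSet(
        power=power,
        freqs=freqs,
        times=times,
        channel_labels=tuple(epochs.channel_labels),
        baseline_mode="raw",
        mask=mask,
    )


def baseline_relative_change(
    tfr: TFRSet, baseline: tuple[float, float], per_trial: bool = True
) -> TFRSet:
    """Relative change from baseline: (P - B)/B.

    B is the mean power over the baseline time window, per channel and
    frequency — per trial by default (required for single-trial coupling and
    regression), or per trial-average (``per_trial=False``) for grand-average
    contrast maps.
    """
    if tfr.baseline_mode != "raw":
        raise DataError("baseline correction expects raw power")
    in_base = (tfr.times >= baseline[0]) & (tfr.times <= baseline[1])
    if not in_base.any():
        raise SelectionError("baseline window contains no time points")
    if tfr.mask[:, in_base].any():
        raise SelectionError("baseline window must be fully unmasked at all frequencies")
    base = tfr.power[:, :, :, in_base].mean(axis=3, keepdims=True)
    if not per_trial:
        base = np.nanmean(base, axis=0, keepdims=True)
        base = np.broadcast_to(base, (tfr.power.shape[0],) + base.shape[1:])
    if np.any(base == 0):
        raise DegenerateBaselineError("zero baseline power; relative change undefined")
    out = (tfr.power - base) / base
    return replace(tfr, power=out.astype(tfr.power.dtype), baseline_mode="relchange",
                   mask=tfr.mask.copy())


def average_band(
    tfr: TFRSet,
    band: BandSpec,
    channels: list[str] | None = None,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-trial unweighted mean over channels x band frequencies x window times.

    Masked points are excluded from the mean. ``window`` defaults to the
    band's own analysis window.
    """
    if window is None:
        window = band.window
    if channels is None:
        ch_idx = np.arange(len(tfr.channel_labels))
    else:
        missing = [c for c in channels if c not in tfr.channel_labels]
        if missing:
            raise SelectionError(f"unknown channels: {missing}")
        ch_idx = np.array([tfr.channel_labels.index(c) for c in channels])
    f_sel = (tfr.freqs >= band.f_lo) & (tfr.freqs <= band.f_hi)
    t_sel = (tfr.times >= window[0]) & (tfr.times <= window[1])
    if not f_sel.any() or not t_sel.any() or ch_idx.size == 0:
        raise SelectionError("empty channel/frequency/time selection")
    block = tfr.power[np.ix_(np.arange(tfr.power.shape[0]), ch_idx,
                             np.flatnonzero(f_sel), np.flatnonzero(t_sel))]
    sub_mask = tfr.mask[np.ix_(np.flatnonzero(f_sel), np.flatnonzero(t_sel))]
    if sub_mask.all():
        raise SelectionError("selection contains only masked points")
    with np.errstate(invalid="ignore"):
        return np.nanmean(block, axis=(1, 2, 3))


def compute_erp(epochs: EpochSet, baseline: tuple[float, float] = (-0.1, 0.0)) -> ERP:
    """Trial-average waveform with per-channel baseline-mean subtraction."""
    if epochs.n_trials == 0:
        raise DataError("cannot compute an ERP from zero trials")
    times = epochs.times
    in_base = (times >= baseline[0]) & (times <= baseline[1])
    if not in_base.any():
        raise SelectionError("ERP baseline window outside the epoch")
    mean = np.asarray(epochs.data, dtype=np.float64).mean(axis=0)
    mean -= mean[:, in_base].mean(axis=1, keepdims=True)
    return ERP(amplitude=mean, times=times,
               channel_labels=tuple(epochs.channel_labels), baseline=baseline)
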