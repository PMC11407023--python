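"""Synthetic dyad generator.

Produces behavioral trial tables and paired feedback-locked EEG epochs with the
statistical structure the downstream analysis assumes:

* a two-player time-estimation task (short/medium/long auditory cues, 10 trials
  per cue per block) in which cooperation succeeds when the two button presses
  fall within ``success_threshold`` of each other, with Weber-scaled timing
  noise and a simple convergent feedback-learning rule;
* paired EEG epochs (trials x channels x samples) built from spatially
  correlated 1/f background noise plus a feedback-locked frontal-midline theta
  burst whose trial-wise amplitudes in the two players follow a Gaussian copula
  with a configurable Spearman correlation, set by the outcome of the NEXT
  trial (positive coupling preceding failure, negative preceding success), and
  a post-feedback beta increase on successful trials.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigError, FormatError

CONDITIONS = ("short", "medium", "long")

#: auditory cue frequencies, condition metadata only (Hz)
TONE_FREQS_HZ = {"short": 2500.0, "medium": 1000.0, "long": 200.0}

MONTAGE_RESOURCE = "standard_1020_32.txt"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorLayout:
    """Electrode labels with unit-sphere 3D positions."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class ThetaBurstSpec:
    """Feedback-locked frontal-midline theta burst parameters.

    ``amplitude_median`` is the median of the lognormal single-trial burst
    amplitude (arbitrary microvolt-scale units); ``amplitude_sigma`` the
    lognormal shape; ``fail_gain`` the mean amplitude ratio of failed-feedback
    to successful-feedback trials (>1: negative feedback drives more theta).
    """

    freq: float = 6.0
    window: tuple[float, float] = (0.0, 0.4)
    amplitude_median: float = 15.0
    amplitude_sigma: float = 0.4
    fail_gain: float = 1.5
    topography: np.ndarray | None = None  # per-channel weights; None = fronto-central default


@dataclass
class NoiseSpec:
    """1/f background noise: PSD ~ f**-exponent, per-channel std = amplitude.

    ``spatial_kernel_width`` is the width (unit-sphere distance) of the
    Gaussian mixing kernel that introduces realistic inter-channel covariance.
    """

    exponent: float = 1.0
    amplitude: float = 10.0
    spatial_kernel_width: float = 0.5


@dataclass
class BetaBoostSpec:
    """Post-feedback beta increase on successful trials (strategy maintenance)."""

    freq: float = 20.0
    window: tuple[float, float] = (0.2, 1.0)
    amplitude: float = 5.0


@dataclass
class SimConfig:
    """Full study-generator configuration (defaults = study conditions)."""

    n_pairs: int = 1
    n_trials: int = 300
    n_blocks: int = 10
    interval_means: tuple[float, float, float] = (1.0, 2.0, 3.0)
    weber_fraction: float = 0.12
    initial_spread: float = 0.15
    learning_rate: float = 0.3
    success_threshold: float = 0.250
    sfreq: float = 500.0
    epoch_window: tuple[float, float] = (-4.0, 4.8)
    n_channels: int = 32
    theta_burst: ThetaBurstSpec = field(default_factory=ThetaBurstSpec)
    coupling_rho_fail: float = 0.5
    coupling_rho_success: float = -0.5
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    beta_boost: BetaBoostSpec = field(default_factory=BetaBoostSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if self.n_trials % 3 != 0:
            raise ConfigError("n_trials must be divisible by 3 (equal condition counts)")
        if self.n_trials % self.n_blocks != 0 or (self.n_trials // self.n_blocks) % 3 != 0:
            raise ConfigError("each block must hold an equal number of each condition")
        means = tuple(self.interval_means)
        if any(m <= 0 for m in means):
            raise ConfigError("interval means must be positive")
        if not (means[0] < means[1] < means[2]):
            raise ConfigError("interval_means must be strictly increasing")
        if self.weber_fraction < 0:
            raise ConfigError("weber_fraction must be >= 0")
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ConfigError("learning_rate must be in [0, 1]")
        if self.success_threshold <= 0:
            raise ConfigError("success_threshold must be positive")
        for rho in (self.coupling_rho_fail, self.coupling_rho_success):
            if abs(rho) > 1:
                raise ConfigError("|coupling rho| must be <= 1")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ConfigError("epoch_window must be an increasing interval")
        w = self.theta_burst.window
        if w[0] < self.epoch_window[0] or w[1] > self.epoch_window[1]:
            raise ConfigError("theta burst window must lie inside the epoch window")

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_window[1] - self.epoch_window[0]) * self.sfreq))


@dataclass
class EpochSet:
    """One player's epoched EEG: trials x channels x samples, feedback-locked.

    Time 0 is the onset of the feedback text. The trial axis is aligned 1:1
    with the rows of the generating TrialTable (``trial_indices`` records the
    trial_index of each epoch when only a subset was generated).
    """

    player_id: int
    data: np.ndarray  # (n_trials, n_channels, n_samples) float32
    sfreq: float
    tmin: float
    channel_labels: tuple[str, ...]
    trial_indices: np.ndarray | None = None

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def make_montage() -> SensorLayout:
    """Load the packaged 32-channel 10-20 layout (unit-sphere positions)."""
    text = resources.files("hypercouple.data").joinpath(MONTAGE_RESOURCE).read_text()
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"montage line must be 'label x y z': {line!r}")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate channel label in montage fixture")
    for required in ("Fz", "FC2", "Cz"):
        if required not in labels:
            raise FormatError(f"montage fixture is missing {required}")
    pos = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise FormatError("zero-length position vector in montage fixture")
    return SensorLayout(labels=tuple(labels), positions=pos / norms)


def _scalp_gaussian(layout: SensorLayout, anchors: tuple[str, str],
                    width: float) -> np.ndarray:
    if not all(a in layout.labels for a in anchors):
        # reduced montages (e.g. few-channel test layouts): uniform weighting
        return np.ones(len(layout.labels))
    center = sum(layout.positions[layout.index(a)] for a in anchors)
    center /= np.linalg.norm(center)
    d = np.linalg.norm(layout.positions - center, axis=1)
    return np.exp(-(d ** 2) / (2 * width ** 2))


def frontocentral_topography(layout: SensorLayout, width: float = 0.4) -> np.ndarray:
    """Gaussian scalp weighting centered between Fz and Cz (FCz site)."""
    return _scalp_gaussian(layout, ("Fz", "Cz"), width)


def _centroposterior_topography(layout: SensorLayout, width: float = 0.4) -> np.ndarray:
    return _scalp_gaussian(layout, ("Cz", "Pz"), width)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

_MIN_RT = 0.05  # physiological floor, seconds


def simulate_behavior(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate the cooperation task for all pairs.

    Each player holds an internal mean mu_c per condition; responses are drawn
    Normal(mu_c, weber_fraction * mu_c). After failed feedback the slower
    player decreases and the faster player increases mu_c by
    learning_rate * |delta| (the simplest convergent dynamic).

    Returns a TrialTable with columns pair_id, trial_index, block, condition,
    rt1, rt2, delta, abs_delta, outcome.
    """
    if seed is None:
        seed = config.seed
    per_block = config.n_trials // config.n_blocks // 3
    children = np.random.SeedSequence(seed).spawn(config.n_pairs)
    frames = []
    means = np.asarray(config.interval_means, dtype=float)
    for pair, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        mu = np.empty((2, 3))
        for p in range(2):
            mu[p] = np.maximum(
                means * (1.0 + config.initial_spread * rng.standard_normal(3)), _MIN_RT
            )
        rows = []
        trial = 0
        for block in range(config.n_blocks):
            order = np.repeat(np.arange(3), per_block)
            rng.shuffle(order)
            for c in order:
                sd = config.weber_fraction * mu[:, c]
                rt = np.maximum(mu[:, c] + sd * rng.standard_normal(2), _MIN_RT)
                delta = rt[0] - rt[1]
                success = abs(delta) <= config.success_threshold
                rows.append(
                    (pair, trial, block, CONDITIONS[c], rt[0], rt[1], delta,
                     abs(delta), "success" if success else "fail")
                )
                if not success and config.learning_rate > 0:
                    step = config.learning_rate * abs(delta)
                    slower = 0 if rt[0] > rt[1] else 1
                    mu[slower, c] = max(mu[slower, c] - step, _MIN_RT)
                    mu[1 - slower, c] = mu[1 - slower, c] + step
                trial += 1
        frames.append(
            pd.DataFrame(
                rows,
                columns=["pair_id", "trial_index", "block", "condition",
                         "rt1", "rt2", "delta", "abs_delta", "outcome"],
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula Pearson parameter reproducing Spearman rho_s.

    Exact for bivariate normal ranks: r = 2 sin(pi * rho_s / 6).
    """
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                sfreq: float, exponent: float, amplitude: float) -> np.ndarray:
    """1/f**exponent noise along the last axis, per-series std = amplitude."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    scale = np.empty_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    scale[0] = scale[1]  # keep DC finite; removed by std-normalization anyway
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return amplitude * x / sd


def _spatial_mixer(layout_pos: np.ndarray, width: float) -> np.ndarray:
    """Variance-preserving Gaussian mixing matrix over channel positions."""
    d = np.linalg.norm(layout_pos[:, None, :] - layout_pos[None, :, :], axis=-1)
    k = np.exp(-(d ** 2) / (2 * width ** 2))
    return k / np.sqrt((k ** 2).sum(axis=1, keepdims=True))


def _burst_waveforms(times: np.ndarray, freq: float, window: tuple[float, float],
                     phases: np.ndarray) -> tuple[slice, np.ndarray]:
    """Hanning-windowed sinusoid per trial inside ``window``; returns (slice, trials x L)."""
    i0 = int(np.searchsorted(times, window[0], side="left"))
    i1 = int(np.searchsorted(times, window[1], side="right"))
    seg = times[i0:i1]
    taper = np.hanning(len(seg))
    wave = taper * np.sin(2 * np.pi * freq * (seg - seg[0]) + phases[:, None])
    return slice(i0, i1), wave


def _next_outcome_labels(trials: pd.DataFrame) -> np.ndarray:
    """Outcome of trial i+1 per row; last trial labeled 'none'."""
    out = trials.sort_values("trial_index")["outcome"].to_numpy()
    nxt = np.empty(len(out), dtype=object)
    nxt[:-1] = out[1:]
    nxt[-1] = "none"
    order = np.argsort(trials["trial_index"].to_numpy())
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return nxt[inv]


def draw_coupled_amplitudes(rng: np.random.Generator, rho_s: np.ndarray,
                            median: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial lognormal amplitude pairs from a Gaussian copula.

    ``rho_s`` is the target Spearman correlation per trial, ``median`` the
    lognormal median per trial (shared by the two players).
    """
    r = 2.0 * np.sin(np.pi * np.asarray(rho_s, dtype=float) / 6.0)
    u1 = rng.standard_normal(len(r))
    u2 = rng.standard_normal(len(r))
    z1 = u1
    z2 = r * u1 + np.sqrt(np.maximum(1.0 - r ** 2, 0.0)) * u2
    a1 = median * np.exp(sigma * z1)
    a2 = median * np.exp(sigma * z2)
    return a1, a2


def simulate_dyad_eeg(
    trials: pd.DataFrame,
    config: SimConfig,
    seed: int | None = None,
    trial_indices: np.ndarray | None = None,
) -> tuple[EpochSet, EpochSet]:
    """Generate paired feedback-locked epochs for one pair's trial table.

    Each epoch = spatially smoothed 1/f noise + fronto-central theta burst
    (copula-coupled amplitudes, coupling sign set by the NEXT trial's outcome)
    + beta boost on successful trials. ``trial_indices`` restricts generation
    to a subset of trials (epochs stay aligned with that subset, in the given
    order); epochs for a subset are bit-identical to the corresponding epochs
    of a full run with the same seed.
    """
    if seed is None:
        seed = config.seed
    if trials["pair_id"].nunique() != 1:
        raise AlignmentError("simulate_dyad_eeg expects the trial table of a single pair")
    trials = trials.sort_values("trial_index").reset_index(drop=True)
    expected = np.arange(len(trials))
    if not np.array_equal(trials["trial_index"].to_numpy(), expected):
        raise AlignmentError("trial_index must be 0..n-1 chronological for the pair")

    layout = make_montage()
    if config.n_channels > len(layout.labels):
        raise ConfigError("n_channels exceeds the packaged montage size")
    labels = layout.labels[: config.n_channels]
    pos = layout.positions[: config.n_channels]
    sub = SensorLayout(labels=labels, positions=pos)

    n_all = len(trials)
    n_samples = config.n_samples
    times = config.epoch_window[0] + np.arange(n_samples) / config.sfreq

    # trial-level random structure is drawn for ALL trials so that subsets are
    # reproducible slices of the full simulation
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    next_out = _next_outcome_labels(trials)
    rho = np.where(
        next_out == "fail", config.coupling_rho_fail,
        np.where(next_out == "success", config.coupling_rho_success, 0.0),
    ).astype(float)
    tb = config.theta_burst
    median = np.where(
        trials["outcome"].to_numpy() == "fail",
        tb.amplitude_median * tb.fail_gain,
        tb.amplitude_median,
    ).astype(float)
    a1, a2 = draw_coupled_amplitudes(rng, rho, median, tb.amplitude_sigma)
    theta_phases = rng.uniform(0, 2 * np.pi, size=(2, n_all))
    beta_phases = rng.uniform(0, 2 * np.pi, size=(2, n_all))
    noise_seeds = rng.integers(0, 2 ** 31, size=(2, n_all))

    if trial_indices is None:
        sel = np.arange(n_all)
    else:
        sel = np.asarray(trial_indices, dtype=int)
        if sel.size and (sel.min() < 0 or sel.max() >= n_all):
            raise AlignmentError("trial_indices out of range for this pair")

    topo = tb.topography
    if topo is None:
        topo = frontocentral_topography(sub)
    topo = np.asarray(topo, dtype=float)
    if topo.shape != (config.n_channels,):
        raise ConfigError("theta topography must have one weight per channel")
    beta_topo = _centroposterior_topography(sub)
    mixer = _spatial_mixer(pos, config.noise.spatial_kernel_width)

    success_mask = trials["outcome"].to_numpy() == "success"
    amps = (a1, a2)
    epochs = []
    for p in range(2):
        data = np.empty((len(sel), config.n_channels, n_samples), dtype=np.float32)
        for row, i in enumerate(sel):
            nrng = np.random.default_rng(int(noise_seeds[p, i]))
            noise = _pink_noise(
                nrng, (config.n_channels,), n_samples, config.sfreq,
                config.noise.exponent, config.noise.amplitude,
            )
            x = mixer @ noise
            sl, wave = _burst_waveforms(times, tb.freq, tb.window,
                                        theta_phases[p, i][None])
            x[:, sl] += amps[p][i] * topo[:, None] * wave[0]
            if success_mask[i] and config.beta_boost.amplitude > 0:
                bw = (max(config.beta_boost.window[0], times[0]),
                      min(config.beta_boost.window[1], times[-1]))
                if bw[0] < bw[1]:
                    sl_b, wave_b = _burst_waveforms(times, config.beta_boost.freq, bw,
                                                    beta_phases[p, i][None])
                    x[:, sl_b] += config.beta_boost.amplitude * beta_topo[:, None] * wave_b[0]
            data[row] = x.astype(np.float32)
        epochs.append(
            EpochSet(
                player_id=p + 1,
                data=data,
                sfreq=config.sfreq,
                tmin=config.epoch_window[0],
                channel_labels=labels,
                trial_indices=sel.copy(),
            )
        )
    return epochs[0], epochs[1]


def simulate_study(config: SimConfig, seed: int | None = None,
                   ) -> tuple[pd.DataFrame, list[tuple[EpochSet, EpochSet]]]:
    """Convenience: behavior + paired epochs for every pair.

    EEG seeds are derived per pair from ``seed`` so the whole study is
    deterministic.
    """
    if seed is None:
        seed = config.seed
    table = simulate_behavior(config, seed)
    eeg_seeds = np.random.SeedSequence((seed, 1)).generate_state(config.n_pairs) % (2 ** 31)
    dyads = []
    for pair in range(config.n_pairs):
        sub = table[table["pair_id"] == pair]
        dyads.append(simulate_dyad_eeg(sub, config, int(eeg_seeds[pair])))
    return table, dyads
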