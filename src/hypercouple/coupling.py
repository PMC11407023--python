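"""Inter-player power coupling.

For a pair of participants, the coupling at each (channel, frequency, time)
point is the Spearman rank correlation ACROSS TRIALS between the two players'
single-trial power at that point, converted to Fisher Z (atanh) so maps from
pairs with unequal trial counts are comparable. One map is produced per pair
per forecast condition.

Rank correlation across trials is not invariant to per-trial normalization, so
whether raw or baseline-corrected power enters is an explicit analysis choice;
raw single-trial power is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import AlignmentError, ConstantInputError, DataError, DomainError
from .tfr import TFRSet

#: clip |rho| here before atanh so Z stays finite
RHO_CLIP = 1.0 - 1e-7

#: pairs contributing fewer trials than this to a condition are excluded
MIN_TRIALS = 10


@dataclass
class CouplingMap:
    """Per-pair inter-player coupling: Fisher-Z and Spearman rho maps.

    ``z`` and ``rho`` are (channels, freqs, times); undefined points
    (masked TFR points, constant-power points) hold NaN.
    """

    z: np.ndarray
    rho: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: tuple[str, ...]
    pair_id: int | str = 0
    condition: str = ""
    n_trials: int = 0


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks. Raises if either input is constant (the
    correlation is undefined; such points are masked downstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AlignmentError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise DataError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ConstantInputError("correlation undefined for constant input")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    return float(np.clip(rho, -1.0, 1.0))


def fisher_z(rho: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing Fisher transform, atanh(rho), with |rho| clipped
    to 1 - 1e-7 so perfectly (anti)correlated inputs stay finite."""
    arr = np.asarray(rho, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.abs(arr[~np.isnan(arr)]) > 1.0 + 1e-9):
            raise DomainError("|rho| > 1")
    out = np.arctanh(np.clip(arr, -RHO_CLIP, RHO_CLIP))
    out = np.where(np.isnan(arr), np.nan, out)
    if np.isscalar(rho) or np.ndim(rho) == 0:
        return float(out)
    return out


def _rank_along_trials(x: np.ndarray) -> np.ndarray:
    """Mid-ranks along axis 0 of a (trials, ...) array."""
    return sps.rankdata(x, axis=0)


def interplayer_coupling(
    tfr1: TFRSet,
    tfr2: TFRSet,
    trial_ids: np.ndarray | None = None,
    pair_id: int | str = 0,
    condition: str = "",
) -> CouplingMap:
    """Spearman/Fisher-Z coupling map across trials, per (ch, f, t) point.

    The two TFRs must share axes and be computed on the same set of trials
    (identical trial order). ``trial_ids`` selects the rows (positions along
    the trial axis) entering the correlation.
    """
    if not tfr1.axes_equal(tfr2):
        raise AlignmentError("TFR axes differ between players")
    if tfr1.power.shape[0] != tfr2.power.shape[0]:
        raise AlignmentError("players have different trial counts")
    if trial_ids is None:
        trial_ids = np.arange(tfr1.power.shape[0])
    trial_ids = np.asarray(trial_ids, dtype=int)
    if trial_ids.size and (trial_ids.min() < 0 or trial_ids.max() >= tfr1.power.shape[0]):
        raise AlignmentError("trial_ids out of range")
    n = len(trial_ids)
    if n < 3:
        raise DataError("need at least 3 trials for a coupling map")

    p1 = np.asarray(tfr1.power[trial_ids], dtype=float)
    p2 = np.asarray(tfr2.power[trial_ids], dtype=float)
    nan_cols = np.isnan(p1).any(axis=0) | np.isnan(p2).any(axis=0)
    # rankdata cannot digest NaN columns; fill them, then re-mask
    p1 = np.where(nan_cols[None], 0.0, p1)
    p2 = np.where(nan_cols[None], 0.0, p2)
    r1 = _rank_along_trials(p1)
    r2 = _rank_along_trials(p2)
    r1 -= r1.mean(axis=0)
    r2 -= r2.mean(axis=0)
    num = (r1 * r2).sum(axis=0)
    den = np.sqrt((r1 ** 2).sum(axis=0) * (r2 ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.clip(num / den, -1.0, 1.0)
    rho[den == 0] = np.nan  # constant power across trials: undefined
    rho[nan_cols] = np.nan
    rho[:, tfr1.mask] = np.nan
    z = np.arctanh(np.clip(rho, -RHO_CLIP, RHO_CLIP))
    return CouplingMap(
        z=z,
        rho=rho,
        freqs=tfr1.freqs.copy(),
        times=tfr1.times.copy(),
        channel_labels=tfr1.channel_labels,
        pair_id=pair_id,
        condition=condition,
        n_trials=n,
    )
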