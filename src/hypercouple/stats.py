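"""Cluster-based permutation inference for paired channel x time maps.

Implements the nonparametric family-wise-error-controlled contrast used for
both individual power contrasts (units = participants) and pair-level coupling
contrasts (units = pairs): per-point dependent-samples t statistics are
thresholded, supra-threshold points are clustered over sensor adjacency and
consecutive time bins (positive and negative tails separately), and each
cluster's summed t is compared to a Monte-Carlo null distribution of the
maximum |cluster sum| under within-unit condition swaps (sign flips of the
paired differences).

Sensor adjacency comes from Delaunay triangulation of the 2-D
azimuthal-equidistant projection of the electrode positions, with implausibly
long edges pruned. Clusters whose spatial footprint covers fewer than two
channels are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.spatial import Delaunay, QhullError

from .errors import DataError, SelectionError
from .synth import SensorLayout
from .tfr import BandSpec, TFRSet
from .coupling import CouplingMap

EDGE_PRUNE_FACTOR = 1.5  # drop triangulation edges longer than this x median
MIN_CLUSTER_CHANNELS = 2


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Adjacency:
    """Symmetric, irreflexive channel neighbor relation."""

    labels: tuple[str, ...]
    matrix: np.ndarray  # (n, n) bool

    def neighbors(self, label: str) -> tuple[str, ...]:
        i = self.labels.index(label)
        return tuple(self.labels[j] for j in np.flatnonzero(self.matrix[i]))

    def neighbor_lists(self) -> list[np.ndarray]:
        return [np.flatnonzero(row) for row in self.matrix]


def _azimuthal_projection(positions: np.ndarray) -> np.ndarray:
    """Project unit-sphere positions to 2-D, preserving distance from vertex."""
    p = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    polar = np.arccos(np.clip(p[:, 2], -1.0, 1.0))
    azimuth = np.arctan2(p[:, 1], p[:, 0])
    return np.column_stack([polar * np.cos(azimuth), polar * np.sin(azimuth)])


def build_neighbors(layout: SensorLayout) -> Adjacency:
    """Channel adjacency via Delaunay triangulation of projected positions.

    Edges longer than 1.5x the median edge length are pruned. Degenerate
    geometries (collinear, too few points) fall back to symmetrized
    4-nearest-neighbors with a warning.
    """
    n = len(layout.labels)
    matrix = np.zeros((n, n), dtype=bool)
    if n <= 1:
        return Adjacency(labels=tuple(layout.labels), matrix=matrix)
    pts = _azimuthal_projection(np.asarray(layout.positions, dtype=float))
    try:
        if n < 4:
            raise QhullError("too few points for triangulation")
        tri = Delaunay(pts)
        edges = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    i, j = sorted((simplex[a], simplex[b]))
                    edges.add((i, j))
        lengths = {e: np.linalg.norm(pts[e[0]] - pts[e[1]]) for e in edges}
        cutoff = EDGE_PRUNE_FACTOR * float(np.median(list(lengths.values())))
        for (i, j), d in lengths.items():
            if d <= cutoff:
                matrix[i, j] = matrix[j, i] = True
    except QhullError:
        warnings.warn(
            "degenerate sensor geometry; falling back to 4-nearest-neighbor adjacency",
            stacklevel=2,
        )
        k = min(4, n - 1)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        for i in range(n):
            for j in np.argsort(d[i])[:k]:
                matrix[i, j] = matrix[j, i] = True
    np.fill_diagonal(matrix, False)
    return Adjacency(labels=tuple(layout.labels), matrix=matrix)


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

@dataclass
class StatMap:
    """Per-point dependent-samples t values over channels x times."""

    t: np.ndarray  # (ch, times)
    df: int
    n_units: int
    degenerate: np.ndarray  # (ch, times) bool: zero-variance points


def dependent_t_map(a: np.ndarray, b: np.ndarray) -> StatMap:
    """Paired t statistic per (channel, time) point: t = mean(d)/(sd(d)/sqrt(n)).

    Zero-variance points get t = sign(mean) * inf and are flagged. Points with
    NaN in any unit propagate NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise DataError("expected matching (units, channels, times) arrays")
    n = a.shape[0]
    if n < 3:
        raise DataError("need at least 3 paired units")
    d = a - b
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (sd / np.sqrt(n))
    degenerate = (sd == 0) & np.isfinite(m)
    t[degenerate & (m > 0)] = np.inf
    t[degenerate & (m < 0)] = -np.inf
    t[degenerate & (m == 0)] = 0.0
    return StatMap(t=t, df=n - 1, n_units=n, degenerate=degenerate)


def point_threshold(df: int, alpha: float = 0.05) -> float:
    """Two-sided Student-t point threshold at significance level alpha."""
    return float(sps.t.ppf(1.0 - alpha / 2.0, df))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    """A connected supra-threshold region of the channel x time map."""

    mask: np.ndarray  # (ch, times) bool
    stat: float  # sum of t values (maxsum statistic)
    sign: int
    p: float | None = None

    def channel_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask.any(axis=1))

    def time_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask.any(axis=0))


@dataclass
class ClusterResult:
    """Observed clusters with Monte-Carlo p-values and the null summary."""

    clusters: list[Cluster]
    n_perm: int
    seed: int
    threshold: float
    df: int
    n_units: int
    null_max: np.ndarray = field(default_factory=lambda: np.empty(0))
    exact: bool = False
    channel_labels: tuple[str, ...] | None = None
    times: np.ndarray | None = None
    band: str | None = None
    window: tuple[float, float] | None = None

    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def to_dict(self) -> dict:
        out = {
            "n_perm": int(self.n_perm),
            "seed": int(self.seed),
            "threshold": round(float(self.threshold), 10),
            "df": int(self.df),
            "n_units": int(self.n_units),
            "exact": bool(self.exact),
            "band": self.band,
            "window": list(self.window) if self.window is not None else None,
            "clusters": [],
        }
        for c in sorted(self.clusters, key=lambda c: -abs(c.stat)):
            entry = {
                "maxsum": round(float(c.stat), 10),
                "sign": int(c.sign),
                "p": round(float(c.p), 10) if c.p is not None else None,
                "n_points": int(c.mask.sum()),
            }
            if self.channel_labels is not None:
                entry["channels"] = [self.channel_labels[i] for i in c.channel_indices()]
            if self.times is not None:
                ts = c.time_indices()
                entry["time_start"] = round(float(self.times[ts[0]]), 10)
                entry["time_end"] = round(float(self.times[ts[-1]]), 10)
            out["clusters"].append(entry)
        return out


def _cluster_components(supra: np.ndarray, neighbor_lists: list[np.ndarray]):
    """Yield index arrays (flattened ch*t) of connected supra-threshold points.

    Connectivity: same channel & adjacent time bins, or same time bin &
    neighboring channels.
    """
    n_ch, n_t = supra.shape
    visited = np.zeros_like(supra, dtype=bool)
    coords = np.argwhere(supra)
    for c0, t0 in coords:
        if visited[c0, t0]:
            continue
        stack = [(c0, t0)]
        visited[c0, t0] = True
        members = []
        while stack:
            c, t = stack.pop()
            members.append((c, t))
            if t > 0 and supra[c, t - 1] and not visited[c, t - 1]:
                visited[c, t - 1] = True
                stack.append((c, t - 1))
            if t < n_t - 1 and supra[c, t + 1] and not visited[c, t + 1]:
                visited[c, t + 1] = True
                stack.append((c, t + 1))
            for nb in neighbor_lists[c]:
                if supra[nb, t] and not visited[nb, t]:
                    visited[nb, t] = True
                    stack.append((nb, t))
        yield members


def find_clusters(stat: StatMap | np.ndarray, threshold: float,
                  adj: Adjacency) -> list[Cluster]:
    """Supra-threshold clusters for both tails, maxsum statistic per cluster.

    Clusters whose spatial footprint spans fewer than two channels are
    discarded. Returns clusters sorted by descending |maxsum|.
    """
    if threshold <= 0:
        raise DataError("cluster-forming threshold must be positive")
    tmap = stat.t if isinstance(stat, StatMap) else np.asarray(stat, dtype=float)
    nb = adj.neighbor_lists()
    clusters: list[Cluster] = []
    for sign in (1, -1):
        with np.errstate(invalid="ignore"):
            supra = (sign * tmap) > threshold
        for members in _cluster_components(supra, nb):
            chans = {c for c, _ in members}
            if len(chans) < MIN_CLUSTER_CHANNELS:
                continue
            mask = np.zeros_like(supra)
            rows, cols = zip(*members)
            mask[rows, cols] = True
            clusters.append(Cluster(mask=mask, stat=float(tmap[mask].sum()), sign=sign))
    clusters.sort(key=lambda c: -abs(c.stat))
    return clusters


def _max_cluster_stat(tmap: np.ndarray, threshold: float,
                      neighbor_lists: list[np.ndarray]) -> float:
    """Maximum |cluster sum| over both tails (0 if no qualifying cluster)."""
    best = 0.0
    for sign in (1, -1):
        with np.errstate(invalid="ignore"):
            supra = (sign * tmap) > threshold
        if supra.sum() < 2:
            continue
        for members in _cluster_components(supra, neighbor_lists):
            chans = {c for c, _ in members}
            if len(chans) < MIN_CLUSTER_CHANNELS:
                continue
            s = abs(sum(tmap[c, t] for c, t in members))
            if s > best:
                best = s
    return best


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _sign_matrix(n_units: int, n_perm: int, seed: int) -> tuple[np.ndarray, bool]:
    """Random (or exhaustive, when feasible) within-unit condition-swap signs."""
    if 2 ** n_units <= n_perm:
        idx = np.arange(2 ** n_units)
        bits = (idx[:, None] >> np.arange(n_units)[None, :]) & 1
        return (2 * bits - 1).astype(float), True
    rng = np.random.default_rng(seed)
    return rng.choice([-1.0, 1.0], size=(n_perm, n_units)), False


def _null_t_maps(d_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t maps for every sign-flip permutation, vectorized.

    Uses the identity sum((s_i d_i)^2) = sum(d_i^2) for s_i = +-1, so only the
    permuted means need recomputing.
    """
    n = d_flat.shape[0]
    m = signs @ d_flat / n
    ss = (d_flat ** 2).sum(axis=0)
    var = (ss[None, :] - n * m ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / np.sqrt(var / n)
    zero = var == 0
    with np.errstate(invalid="ignore"):
        t[zero] = np.sign(m[zero]) * np.inf
    t[zero & (m == 0)] = 0.0
    return t


def cluster_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    adj: Adjacency,
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float | None = None,
) -> ClusterResult:
    """Paired cluster-based permutation test on (units, channels, times) data.

    The null distribution is the maximum |cluster sum| under within-unit
    random condition swaps (sign flips of the paired differences); each
    observed cluster gets p = (#{null >= observed} + 1) / (n_perm + 1). When
    2**n_units <= n_perm the sign-flip space is enumerated exactly.
    """
    if n_perm < 100:
        raise DataError("n_perm must be >= 100")
    stat = dependent_t_map(a, b)
    n = stat.n_units
    if n < 5:
        warnings.warn(f"only {n} paired units; permutation space is tiny", stacklevel=2)
    if threshold is None:
        threshold = point_threshold(stat.df)

    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    shape = d.shape[1:]
    # points undefined in any unit are excluded from observed and null maps
    invalid = ~np.isfinite(d).all(axis=0)
    tmap_obs = stat.t.copy()
    tmap_obs[invalid] = np.nan
    clusters = find_clusters(tmap_obs, threshold, adj)

    d_flat = d.reshape(n, -1).copy()
    d_flat[:, invalid.ravel()] = np.nan
    signs, exact = _sign_matrix(n, n_perm, seed)
    nb = adj.neighbor_lists()
    null_t = _null_t_maps(np.nan_to_num(d_flat, nan=0.0), signs)
    null_t[:, invalid.ravel()] = np.nan
    null_max = np.array([
        _max_cluster_stat(row.reshape(shape), threshold, nb) for row in null_t
    ])
    n_eff = signs.shape[0]
    for c in clusters:
        c.p = float((np.sum(null_max >= abs(c.stat)) + 1) / (n_eff + 1))
    return ClusterResult(
        clusters=clusters,
        n_perm=n_eff,
        seed=seed,
        threshold=float(threshold),
        df=stat.df,
        n_units=n,
        null_max=null_max,
        exact=exact,
    )


# ---------------------------------------------------------------------------
# band/window contrast
# ---------------------------------------------------------------------------

def _unit_map(obj: TFRSet | CouplingMap) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple]:
    """(ch, f, t) array + axes from a per-unit TFRSet (trial-averaged) or CouplingMap."""
    if isinstance(obj, TFRSet):
        with np.errstate(invalid="ignore"):
            arr = np.nanmean(np.asarray(obj.power, dtype=float), axis=0)
        return arr, obj.freqs, obj.times, obj.channel_labels
    if isinstance(obj, CouplingMap):
        return np.asarray(obj.z, dtype=float), obj.freqs, obj.times, obj.channel_labels
    raise DataError(f"cannot extract a unit map from {type(obj).__name__}")


def band_window_contrast(
    data_a: list,
    data_b: list,
    band: BandSpec,
    adj: Adjacency,
    window: tuple[float, float] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float | None = None,
) -> ClusterResult:
    """Band-average per-unit maps, restrict to the analysis window, then run
    the paired cluster permutation test on the channel x time maps.

    ``data_a``/``data_b`` are per-unit TFRSets or CouplingMaps, pairwise
    aligned (same unit order in both conditions).
    """
    if len(data_a) != len(data_b) or not data_a:
        raise DataError("conditions must provide the same nonzero number of units")
    if window is None:
        window = band.window
    ref_f = ref_t = ref_ch = None
    stacked = {0: [], 1: []}
    for cond, maps in enumerate((data_a, data_b)):
        for obj in maps:
            arr, freqs, times, chs = _unit_map(obj)
            if ref_f is None:
                ref_f, ref_t, ref_ch = freqs, times, chs
                f_sel = (freqs >= band.f_lo) & (freqs <= band.f_hi)
                t_sel = (times >= window[0]) & (times <= window[1])
                if not f_sel.any():
                    raise SelectionError(f"no frequencies inside band {band.name}")
                if not t_sel.any():
                    raise SelectionError("analysis window outside the time axis")
            elif not (np.array_equal(freqs, ref_f) and np.array_equal(times, ref_t)
                      and chs == ref_ch):
                raise DataError("per-unit maps are not axis-aligned")
            with np.errstate(invalid="ignore"):
                banded = np.nanmean(arr[:, f_sel, :], axis=1)
            stacked[cond].append(banded[:, t_sel])
    a = np.stack(stacked[0])
    b = np.stack(stacked[1])
    # drop time bins undefined everywhere (edge-masked under the reduced grid)
    keep = np.isfinite(a).any(axis=(0, 1)) & np.isfinite(b).any(axis=(0, 1))
    if not keep.any():
        raise SelectionError("analysis window contains only masked points")
    a, b = a[:, :, keep], b[:, :, keep]
    times_used = ref_t[t_sel][keep]
    result = cluster_permutation_test(a, b, adj, n_perm=n_perm, seed=seed,
                                      threshold=threshold)
    result.channel_labels = tuple(ref_ch)
    result.times = times_used
    result.band = band.name
    result.window = (float(window[0]), float(window[1]))
    return result
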