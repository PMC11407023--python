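"""End-to-end orchestration: simulate -> TFR -> sort -> couple -> cluster
stats -> regressions -> report, with a single seeded configuration.

All stages consume/produce the documented file formats and every JSON output
records the seeds used, so runs are exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import io as hio
from .coupling import MIN_TRIALS, interplayer_coupling
from .errors import ConfigError, DataError
from .stats import band_window_contrast, build_neighbors, ClusterResult
from .synth import SimConfig, ThetaBurstSpec, NoiseSpec, BetaBoostSpec, \
    make_montage, simulate_behavior, simulate_dyad_eeg
from .tfr import BANDS, TFRSet, baseline_relative_change, compute_tfr

logger = logging.getLogger("hypercouple")

#: named analysis windows (seconds, feedback-locked)
WINDOWS = {
    "theta_predefined": (0.0, 0.4),
    "theta_predefined_late": (0.6, 1.05),
    "alpha_predefined_methods": (0.4, 1.65),
    "alpha_predefined_results": (0.3, 1.75),
    "exploratory_0_2": (0.0, 2.0),
    "full_0_4": (0.0, 4.0),
}

#: central / centro-parietal sensors used for the trial-by-trial theta readout
CENTRAL_CHANNELS = ("Cz", "C3", "C4", "CP1", "CPz", "CP2")

#: fronto-central sensors for coupling time-course summaries
FRONTOCENTRAL_CHANNELS = ("Fz", "FC1", "FC2")


@dataclass
class TFRGrid:
    """Time-frequency analysis grid (full study grid: 2-50 Hz / -1..4.8 s)."""

    f_lo: float = 2.0
    f_hi: float = 50.0
    f_step: float = 1.0
    t_lo: float = -1.0
    t_hi: float = 4.8
    t_step: float = 0.05
    cycles: float = 3.0
    baseline: tuple[float, float] = (-0.6, -0.1)

    def freqs(self) -> np.ndarray:
        return np.round(np.arange(self.f_lo, self.f_hi + 1e-9, self.f_step), 10)

    def times(self) -> np.ndarray:
        return np.round(np.arange(self.t_lo, self.t_hi + 1e-9, self.t_step), 10)


@dataclass
class RunConfig:
    """Everything needed for a full reproducible run."""

    sim: SimConfig = field(default_factory=SimConfig)
    grid: TFRGrid = field(default_factory=TFRGrid)
    bands: tuple[str, ...] = ("theta",)
    coupling_window: str = "theta_predefined"
    individual_window: str = "full_0_4"
    coupling_input: str = "raw"  # 'raw' or 'relchange'
    n_perm: int = 1000
    seed: int = 0
    min_trials: int = MIN_TRIALS
    trials_per_condition: int | None = None  # cap per forecast condition
    run_global: bool = False
    save_maps: bool = False
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for b in self.bands:
            if b not in BANDS:
                raise ConfigError(f"unknown band {b!r}; known: {sorted(BANDS)}")
        for w in (self.coupling_window, self.individual_window):
            if w not in WINDOWS:
                raise ConfigError(f"unknown window {w!r}; known: {sorted(WINDOWS)}")
        if self.coupling_input not in ("raw", "relchange"):
            raise ConfigError("coupling_input must be 'raw' or 'relchange'")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be >= 100")

    # -- config (de)serialization -------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub: dict):
            known = {f.name: f for f in fields(klass)}
            unknown = set(sub) - set(known)
            if unknown:
                raise ConfigError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            kwargs = {}
            nested = {"sim": SimConfig, "grid": TFRGrid, "theta_burst": ThetaBurstSpec,
                      "noise": NoiseSpec, "beta_boost": BetaBoostSpec}
            for k, v in sub.items():
                if k in nested and isinstance(v, dict):
                    kwargs[k] = build(nested[k], v)
                elif isinstance(v, list):
                    kwargs[k] = tuple(v)
                else:
                    kwargs[k] = v
            return klass(**kwargs)

        return build(cls, d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as f:
            d = yaml.safe_load(f) or {}
        if not isinstance(d, dict):
            raise ConfigError("run config must be a YAML mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["theta_burst"]["topography"] = None  # arrays not serialized
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def test_profile(n_pairs: int = 6, seed: int = 0, **overrides) -> RunConfig:
    """Reduced-size profile: short epochs, theta-only grid, fewer permutations.

    Used by the test suite and worked examples to keep runs fast; the full
    study grid remains available through the default RunConfig.
    """
    sim = SimConfig(n_pairs=n_pairs, epoch_window=(-1.3, 1.5), seed=seed)
    grid = TFRGrid(f_lo=4.0, f_hi=7.0, f_step=1.0,
                   t_lo=-0.8, t_hi=1.0, t_step=0.1)
    base = dict(sim=sim, grid=grid, n_perm=200, seed=seed,
                trials_per_condition=60)
    base.update(overrides)
    return RunConfig(**base)


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _eeg_seeds(seed: int, n_pairs: int) -> np.ndarray:
    return np.random.SeedSequence((seed, 1)).generate_state(n_pairs) % (2 ** 31)


def _clip_window(window: tuple[float, float], times: np.ndarray) -> tuple[float, float]:
    lo, hi = max(window[0], float(times[0])), min(window[1], float(times[-1]))
    if lo >= hi:
        raise DataError("analysis window lies outside the TFR time axis")
    return (lo, hi)


def _pair_tfrs(cfg: RunConfig, pair_trials: pd.DataFrame, eeg_seed: int,
               trial_indices: np.ndarray) -> tuple[TFRSet, TFRSet]:
    """Raw (or baseline-corrected) single-trial TFRs for both players."""
    ep1, ep2 = simulate_dyad_eeg(pair_trials, cfg.sim, int(eeg_seed),
                                 trial_indices=trial_indices)
    out = []
    for ep in (ep1, ep2):
        t = compute_tfr(ep, cfg.grid.freqs(), cfg.grid.times(), cfg.grid.cycles)
        if cfg.coupling_input == "relchange":
            t = baseline_relative_change(t, cfg.grid.baseline)
        out.append(t)
    return out[0], out[1]


def _mean_map(tfr: TFRSet, rows: np.ndarray) -> TFRSet:
    """Trial-average of selected rows, kept as a singleton-trial TFRSet."""
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(tfr.power[rows], axis=0, keepdims=True)
    return replace(tfr, power=mean, mask=tfr.mask.copy())


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def run_coupling_forecast(
    cfg: RunConfig,
    scope: str = "local",
    trials: pd.DataFrame | None = None,
) -> dict:
    """Inter-player coupling contrast: forecast-fail vs forecast-success.

    Returns a dict with the per-band ClusterResults, per-pair coupling maps,
    mean Z per condition, Z time courses, and dropped-pair accounting.
    """
    if scope not in ("local", "global"):
        raise ConfigError("scope must be 'local' or 'global'")
    if trials is None:
        trials = simulate_behavior(cfg.sim, cfg.seed)
    layout = make_montage()
    adj = build_neighbors(layout)
    seeds = _eeg_seeds(cfg.seed, cfg.sim.n_pairs)
    sorter = bhv.sort_local_forecast if scope == "local" else bhv.sort_global_forecast

    maps_fail, maps_success, used_pairs, dropped = [], [], [], []
    theta_trial_rows = []  # per-trial theta power for the trial-by-trial regression
    theta_band = BANDS["theta"]
    for pair_id, grp in trials.groupby("pair_id"):
        sorted_sets = sorter(grp)
        fail_ids = sorted_sets["forecast_fail"]
        success_ids = sorted_sets["forecast_success"]
        if cfg.trials_per_condition is not None:
            fail_ids = fail_ids[: cfg.trials_per_condition]
            success_ids = success_ids[: cfg.trials_per_condition]
        if min(len(fail_ids), len(success_ids)) < cfg.min_trials:
            logger.warning("pair %s dropped: %d/%d trials below minimum %d",
                           pair_id, len(fail_ids), len(success_ids), cfg.min_trials)
            dropped.append(int(pair_id))
            continue
        union = np.array(sorted(set(fail_ids) | set(success_ids)))
        tfr1, tfr2 = _pair_tfrs(cfg, grp, seeds[int(pair_id)], union)
        pos = {t: i for i, t in enumerate(union)}
        rows_fail = np.array([pos[t] for t in fail_ids])
        rows_success = np.array([pos[t] for t in success_ids])
        maps_fail.append(interplayer_coupling(
            tfr1, tfr2, rows_fail, pair_id=int(pair_id), condition="forecast_fail"))
        maps_success.append(interplayer_coupling(
            tfr1, tfr2, rows_success, pair_id=int(pair_id), condition="forecast_success"))
        used_pairs.append(int(pair_id))

        window = _clip_window(WINDOWS["theta_predefined"], tfr1.times)
        abs_delta = grp.sort_values("trial_index")["abs_delta"].to_numpy()
        central = [c for c in CENTRAL_CHANNELS if c in tfr1.channel_labels]
        p1 = _band_power_per_trial(tfr1, theta_band, central, window)
        p2 = _band_power_per_trial(tfr2, theta_band, central, window)
        for i, t in enumerate(union):
            theta_trial_rows.append((int(pair_id), int(t), float(p1[i]), float(p2[i]),
                                     float(abs_delta[t])))

    if len(used_pairs) < 5:
        raise DataError(f"only {len(used_pairs)} usable pairs; need >= 5")

    results = {}
    for band_name in cfg.bands:
        band = BANDS[band_name]
        window = WINDOWS[cfg.coupling_window] if band_name == "theta" \
            else WINDOWS["exploratory_0_2"]
        window = _clip_window(window, maps_fail[0].times)
        res = band_window_contrast(maps_fail, maps_success, band, adj,
                                   window=window, n_perm=cfg.n_perm, seed=cfg.seed)
        results[band_name] = res

    theta_res = results.get("theta") or next(iter(results.values()))
    summary = _coupling_summary(cfg, scope, theta_res, maps_fail, maps_success,
                                used_pairs, dropped)
    return {
        "summary": summary,
        "results": results,
        "maps_fail": maps_fail,
        "maps_success": maps_success,
        "theta_trials": pd.DataFrame(
            theta_trial_rows,
            columns=["pair_id", "trial_index", "theta1", "theta2", "abs_delta"]),
    }


def _band_power_per_trial(tfr: TFRSet, band, channels, window) -> np.ndarray:
    from .tfr import average_band
    return average_band(tfr, band, channels=channels or None, window=window)


def _coupling_summary(cfg, scope, res: ClusterResult, maps_fail, maps_success,
                      used, dropped) -> dict:
    """Cluster extents, mean Z per condition, and Fz/FC2 Z time courses."""
    band = BANDS[res.band] if res.band in BANDS else BANDS["theta"]
    f_sel = (maps_fail[0].freqs >= band.f_lo) & (maps_fail[0].freqs <= band.f_hi)

    def banded(maps):
        with np.errstate(invalid="ignore"):
            return np.stack([np.nanmean(m.z[:, f_sel, :], axis=1) for m in maps])

    zf, zs = banded(maps_fail), banded(maps_success)  # (pairs, ch, times)
    times = maps_fail[0].times
    t_sel = (times >= res.window[0]) & (times <= res.window[1])
    if res.clusters:
        best = res.clusters[0]
        ch_idx = best.channel_indices()
        tw = np.flatnonzero(t_sel)[best.time_indices()]
        sel = np.ix_(ch_idx, tw)
    else:
        sel = np.ix_(np.arange(zf.shape[1]), np.flatnonzero(t_sel))
    with np.errstate(invalid="ignore"):
        mean_z_fail = float(np.nanmean(zf[:, sel[0], sel[1]]))
        mean_z_success = float(np.nanmean(zs[:, sel[0], sel[1]]))
    fc = [i for i, c in enumerate(maps_fail[0].channel_labels)
          if c in FRONTOCENTRAL_CHANNELS]
    with np.errstate(invalid="ignore"):
        tc_fail = np.nanmean(zf[:, fc, :], axis=(0, 1))
        tc_success = np.nanmean(zs[:, fc, :], axis=(0, 1))
    return {
        "scope": scope,
        "n_input_pairs": int(cfg.sim.n_pairs),
        "n_used": len(used),
        "n_dropped": len(dropped),
        "dropped_pairs": sorted(dropped),
        "n_trials_per_pair": {
            "forecast_fail": [int(m.n_trials) for m in maps_fail],
            "forecast_success": [int(m.n_trials) for m in maps_success],
        },
        "mean_z_forecast_fail": round(mean_z_fail, 10),
        "mean_z_forecast_success": round(mean_z_success, 10),
        "z_timecourse": {
            "channels": [maps_fail[0].channel_labels[i] for i in fc],
            "times": [round(float(t), 10) for t in times],
            "forecast_fail": _roundlist(tc_fail),
            "forecast_success": _roundlist(tc_success),
        },
    }


def _roundlist(arr) -> list:
    return [None if not np.isfinite(v) else round(float(v), 10) for v in arr]


def run_individual_contrast(
    cfg: RunConfig,
    trials: pd.DataFrame | None = None,
) -> dict:
    """Per-participant success-vs-fail power contrast (relative change),
    cluster-tested per band across participants."""
    if trials is None:
        trials = simulate_behavior(cfg.sim, cfg.seed)
    layout = make_montage()
    adj = build_neighbors(layout)
    seeds = _eeg_seeds(cfg.seed, cfg.sim.n_pairs)

    maps_success, maps_fail, used, dropped = [], [], [], []
    for pair_id, grp in trials.groupby("pair_id"):
        grp = grp.sort_values("trial_index").reset_index(drop=True)
        s_ids = np.flatnonzero(grp["outcome"].to_numpy() == "success")
        f_ids = np.flatnonzero(grp["outcome"].to_numpy() == "fail")
        if cfg.trials_per_condition is not None:
            s_ids = s_ids[: cfg.trials_per_condition]
            f_ids = f_ids[: cfg.trials_per_condition]
        if min(len(s_ids), len(f_ids)) < cfg.min_trials:
            logger.warning("pair %s participants dropped: missing condition trials",
                           pair_id)
            dropped.extend([(int(pair_id), 1), (int(pair_id), 2)])
            continue
        union = np.array(sorted(set(s_ids) | set(f_ids)))
        ep1, ep2 = simulate_dyad_eeg(grp, cfg.sim, int(seeds[int(pair_id)]),
                                     trial_indices=union)
        pos = {t: i for i, t in enumerate(union)}
        rows_s = np.array([pos[t] for t in s_ids])
        rows_f = np.array([pos[t] for t in f_ids])
        for ep, player in ((ep1, 1), (ep2, 2)):
            t = compute_tfr(ep, cfg.grid.freqs(), cfg.grid.times(), cfg.grid.cycles)
            t = baseline_relative_change(t, cfg.grid.baseline)
            maps_success.append(_mean_map(t, rows_s))
            maps_fail.append(_mean_map(t, rows_f))
            used.append((int(pair_id), player))

    if len(used) < 5:
        raise DataError(f"only {len(used)} usable participants; need >= 5")
    results = {}
    for band_name in cfg.bands:
        band = BANDS[band_name]
        window = _clip_window(WINDOWS[cfg.individual_window], maps_fail[0].times)
        results[band_name] = band_window_contrast(
            maps_fail, maps_success, band, adj, window=window,
            n_perm=cfg.n_perm, seed=cfg.seed)
    summary = {
        "n_input_participants": int(2 * cfg.sim.n_pairs),
        "n_used": len(used),
        "n_dropped": len(dropped),
        "contrast": "fail_minus_success",
    }
    return {"summary": summary, "results": results}


def run_behavior(cfg: RunConfig, trials: pd.DataFrame,
                 theta_trials: pd.DataFrame | None = None) -> dict:
    """Behavioral analyses: adherence check, paired-adjustment interaction
    regression, adjuster split, and (optionally) the trial-by-trial theta
    interaction regression."""
    out: dict = {}
    out["adherence"] = bhv.adherence_check(trials).to_dict()

    ys, x1s, x2s = [], [], []
    for _, grp in trials.groupby("pair_id"):
        grp = grp.sort_values("trial_index").reset_index(drop=True)
        a1 = bhv.compute_behavioral_adjustment(grp, 1).to_numpy()
        a2 = bhv.compute_behavioral_adjustment(grp, 2).to_numpy()
        ys.append(grp["abs_delta"].to_numpy())
        x1s.append(a1)
        x2s.append(a2)
    res = bhv.fit_ols_interaction(np.concatenate(ys), np.concatenate(x1s),
                                  np.concatenate(x2s))
    res.terms = ["intercept", "adjustment_p1", "adjustment_p2",
                 "adjustment_p1:adjustment_p2"]
    out["adjustment_interaction"] = res.to_dict()

    labels = bhv.classify_adjusters(trials)
    out["adjusters"] = {
        "n_adjusters": sum(v == "adjuster" for v in labels.values()),
        "n_non_adjusters": sum(v == "non_adjuster" for v in labels.values()),
    }

    if theta_trials is not None and len(theta_trials) > 10:
        t1 = theta_trials["theta1"].to_numpy()
        t2 = theta_trials["theta2"].to_numpy()
        res = bhv.fit_ols_interaction(
            theta_trials["abs_delta"].to_numpy(), t1, t2,
            extra=np.abs(t1 - t2), extra_name="abs_theta_diff")
        res.terms = ["intercept", "theta_p1", "theta_p2", "theta_p1:theta_p2",
                     "abs_theta_diff"]
        out["theta_interaction"] = res.to_dict()
    return out


# ---------------------------------------------------------------------------
# report and run-all
# ---------------------------------------------------------------------------

def run_report(cfg: RunConfig, results_dir: str | Path, plots: bool = True) -> Path:
    """Collect the JSON artifacts of a run into a single markdown report
    (with Z-by-time line plots per forecast condition when available)."""
    results_dir = Path(results_dir)
    report = results_dir / "report.md"
    lines = ["# hypercouple run report", ""]
    artifacts = sorted(p.name for p in results_dir.glob("*.json"))
    if not artifacts:
        lines += ["no analyses found", ""]
        report.write_text("\n".join(lines), encoding="utf-8")
        return report
    prov = results_dir / "provenance.json"
    if prov.exists():
        p = hio.read_json(prov)
        lines += [f"- config hash: `{p.get('config_hash')}`",
                  f"- seed: {p.get('seed')}", ""]
    for name in artifacts:
        if name == "provenance.json":
            continue
        obj = hio.read_json(results_dir / name)
        lines += [f"## {name}", "", "```json",
                  json.dumps(obj, sort_keys=True, indent=2), "```", ""]
        if plots and "summary" in obj and "z_timecourse" in obj.get("summary", {}):
            png = results_dir / (name.replace(".json", "_z_timecourse.png"))
            _plot_timecourse(obj["summary"]["z_timecourse"], png)
            lines += [f"![Z time course]({png.name})", ""]
    report.write_text("\n".join(lines), encoding="utf-8")
    return report


def _plot_timecourse(tc: dict, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 3.2))
    t = np.array(tc["times"], dtype=float)
    for key, color in (("forecast_fail", "tab:red"), ("forecast_success", "tab:blue")):
        z = np.array([np.nan if v is None else v for v in tc[key]], dtype=float)
        ax.plot(t, z, label=key.replace("_", " "), color=color)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("time from feedback text onset (s)")
    ax.set_ylabel(f"mean Fisher Z ({'/'.join(tc['channels'])})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_all(cfg: RunConfig, out_dir: str | Path | None = None,
            plots: bool = True) -> Path:
    """Full pipeline run; writes all artifacts under ``out_dir``."""
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run-all start: %d pairs, seed %d", cfg.sim.n_pairs, cfg.seed)

    trials = simulate_behavior(cfg.sim, cfg.seed)
    hio.write_trials(out / "trials.csv", trials)

    coup = run_coupling_forecast(cfg, "local", trials=trials)
    _write_cluster_json(out / "coupling_local.json", cfg, coup)
    if cfg.run_global:
        coup_g = run_coupling_forecast(cfg, "global", trials=trials)
        _write_cluster_json(out / "coupling_global.json", cfg, coup_g)
    if cfg.save_maps:
        maps_dir = out / "coupling_maps"
        maps_dir.mkdir(exist_ok=True)
        for m in coup["maps_fail"] + coup["maps_success"]:
            hio.write_coupling(maps_dir / f"pair{m.pair_id}_{m.condition}.h5", m)

    indiv = run_individual_contrast(cfg, trials=trials)
    _write_cluster_json(out / "individual_contrast.json", cfg, indiv)

    behav = run_behavior(cfg, trials, theta_trials=coup.get("theta_trials"))
    hio.write_json(out / "behavior.json", {"seed": cfg.seed, **behav})

    hio.write_json(out / "provenance.json", {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    })
    return run_report(cfg, out, plots=plots)


def _write_cluster_json(path: Path, cfg: RunConfig, run: dict) -> None:
    obj = {
        "seed": cfg.seed,
        "summary": run["summary"],
        "bands": {name: res.to_dict() for name, res in run["results"].items()},
    }
    hio.write_json(path, obj)
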