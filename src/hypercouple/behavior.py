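"""Behavioral analyses of the cooperation task.

Outcome classification (the 250 ms synchrony rule), forecasting trial sorts
(local = next consecutive trial, global = next trial of the same cue
condition), per-player behavioral adjustment relative to the nearest preceding
same-condition trial, speed-up/slow-down splits, the adjuster/non-adjuster
median split, and the ordinary-least-squares interaction regressions that link
paired adjustment (or paired theta power) to the continuous cooperative
outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, SingularDesignError


@dataclass
class SortedTrials:
    """Disjoint per-condition trial-index sets for one pair."""

    sets: dict[str, list[int]]

    def __getitem__(self, key: str) -> list[int]:
        return self.sets[key]


@dataclass
class RegressionResult:
    """OLS fit summary: per-term coefficients and the overall F test."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n: int
    contrasts: dict[str, dict] | None = None

    def to_dict(self) -> dict:
        out = {
            "terms": list(self.terms),
            "beta": [round(float(v), 10) for v in self.beta],
            "se": [round(float(v), 10) for v in self.se],
            "t": [round(float(v), 10) for v in self.tvalues],
            "p": [round(float(v), 12) for v in self.pvalues],
            "F": round(float(self.fvalue), 10),
            "F_p": round(float(self.f_pvalue), 12),
            "df": [int(self.df_model), int(self.df_resid)],
            "n": int(self.n),
        }
        if self.contrasts is not None:
            out["contrasts"] = self.contrasts
        return out


def classify_outcome(rt1: float, rt2: float, threshold: float = 0.250) -> str:
    """'success' iff the button presses fall within ``threshold`` seconds
    (inclusive boundary), else 'fail'."""
    if rt1 <= 0 or rt2 <= 0:
        raise DataError("response times must be positive")
    if threshold <= 0:
        raise DataError("threshold must be positive")
    return "success" if abs(rt1 - rt2) <= threshold else "fail"


def _single_pair(trials: pd.DataFrame) -> pd.DataFrame:
    if trials["pair_id"].nunique() != 1:
        raise DataError("this sort operates on one pair at a time")
    return trials.sort_values("trial_index").reset_index(drop=True)


def sort_local_forecast(trials: pd.DataFrame) -> SortedTrials:
    """Classify each failed trial by the outcome of the next consecutive trial.

    The final trial of a pair has no successor and is excluded.
    """
    t = _single_pair(trials)
    outcomes = t["outcome"].to_numpy()
    idx = t["trial_index"].to_numpy()
    fail = outcomes == "fail"
    sets: dict[str, list[int]] = {"forecast_fail": [], "forecast_success": []}
    for i in np.flatnonzero(fail[:-1]):
        key = "forecast_fail" if outcomes[i + 1] == "fail" else "forecast_success"
        sets[key].append(int(idx[i]))
    return SortedTrials(sets=sets)


def sort_global_forecast(trials: pd.DataFrame) -> SortedTrials:
    """Classify each failed trial by the outcome of the NEXT trial sharing its
    cue condition; failed trials with no later same-condition trial are
    excluded."""
    t = _single_pair(trials)
    outcomes = t["outcome"].to_numpy()
    conds = t["condition"].to_numpy()
    idx = t["trial_index"].to_numpy()
    sets: dict[str, list[int]] = {"forecast_fail": [], "forecast_success": []}
    for i in np.flatnonzero(outcomes == "fail"):
        later = np.flatnonzero(conds[i + 1:] == conds[i])
        if later.size == 0:
            continue
        nxt = i + 1 + later[0]
        key = "forecast_fail" if outcomes[nxt] == "fail" else "forecast_success"
        sets[key].append(int(idx[i]))
    return SortedTrials(sets=sets)


def compute_behavioral_adjustment(trials: pd.DataFrame, player: int) -> pd.Series:
    """Per-trial behavioral adjustment for one player, in seconds.

    adjustment(i) = RT of the nearest PRECEDING same-condition trial minus RT
    of trial i (positive = speeding up across repeats of the condition). The
    first occurrence of each condition is undefined (NaN).
    """
    if player not in (1, 2):
        raise DataError("player must be 1 or 2")
    t = _single_pair(trials)
    rts = t[f"rt{player}"].to_numpy()
    conds = t["condition"].to_numpy()
    adj = np.full(len(t), np.nan)
    last_rt: dict[str, float] = {}
    for i, (c, r) in enumerate(zip(conds, rts)):
        if c in last_rt:
            adj[i] = last_rt[c] - r
        last_rt[c] = r
    return pd.Series(adj, index=t["trial_index"].to_numpy(), name=f"adjustment{player}")


def classify_speed_direction(trials: pd.DataFrame, player: int) -> SortedTrials:
    """Split FAILED trials by the adjustment the given player must make next:
    'speedup' if that player pressed second (larger RT), 'slowdown' if first.

    Successful trials are never classified; an exact RT tie on a failed trial
    is impossible (|delta| > threshold > 0)."""
    if player not in (1, 2):
        raise DataError("player must be 1 or 2")
    t = _single_pair(trials)
    own = t[f"rt{player}"].to_numpy()
    other = t["rt2" if player == 1 else "rt1"].to_numpy()
    fail = t["outcome"].to_numpy() == "fail"
    assert not np.any(fail & (own == other)), "tied RTs cannot fail the threshold rule"
    idx = t["trial_index"].to_numpy()
    return SortedTrials(sets={
        "speedup": [int(i) for i in idx[fail & (own > other)]],
        "slowdown": [int(i) for i in idx[fail & (own < other)]],
    })


def classify_adjusters(trials: pd.DataFrame) -> dict[tuple[int, int], str]:
    """Median split of per-player RT standard deviations over the whole task.

    Players strictly above the median SD are 'adjuster'; values at or below
    the median (including exact ties) are 'non_adjuster'.
    """
    sds = {}
    for pair_id, grp in trials.groupby("pair_id"):
        for player in (1, 2):
            sds[(pair_id, player)] = float(grp[f"rt{player}"].std(ddof=1))
    if len(sds) < 2:
        raise DataError("need at least 2 players for a median split")
    values = np.array(list(sds.values()))
    med = float(np.median(values))
    if np.all(values == values[0]):
        warnings.warn("all RT standard deviations identical; no adjusters", stacklevel=2)
    return {k: ("adjuster" if v > med else "non_adjuster") for k, v in sds.items()}


def fit_ols_interaction(
    y: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    extra: np.ndarray | None = None,
    extra_name: str = "extra",
) -> RegressionResult:
    """OLS fit of y ~ 1 + x1 + x2 + x1*x2 (+ extra covariate).

    The overall F tests the full model against intercept-only. Rows with any
    non-finite value are dropped.
    """
    y = np.asarray(y, dtype=float)
    cols = [np.asarray(x1, dtype=float), np.asarray(x2, dtype=float)]
    names = ["x1", "x2", "x1:x2"]
    cols.append(cols[0] * cols[1])
    if extra is not None:
        cols.append(np.asarray(extra, dtype=float))
        names.append(extra_name)
    if any(c.shape != y.shape for c in cols):
        raise DataError("predictors must align with the outcome vector")
    X = np.column_stack(cols)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]
    if len(y) <= X.shape[1] + 1:
        raise DataError("more parameters than observations")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        terms=["intercept"] + names,
        beta=fit.params,
        se=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        fvalue=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n=len(y),
    )


def adherence_check(trials: pd.DataFrame) -> RegressionResult:
    """Fixed-effects least-squares check that RTs track the cue condition.

    Long-format RTs (both players) are regressed on condition indicators plus
    pair indicators; reports the three pairwise condition contrasts
    (short vs medium, medium vs long, short vs long).
    """
    if trials["condition"].nunique() < 2:
        raise DataError("need at least 2 conditions")
    long = pd.concat(
        [
            trials[["pair_id", "condition"]].assign(rt=trials["rt1"]),
            trials[["pair_id", "condition"]].assign(rt=trials["rt2"]),
        ],
        ignore_index=True,
    )
    cond = pd.get_dummies(long["condition"], dtype=float)
    for c in ("short", "medium", "long"):
        if c not in cond:
            cond[c] = 0.0
    pair = pd.get_dummies(long["pair_id"], prefix="pair", dtype=float, drop_first=True)
    # treatment coding with 'short' as reference
    X = pd.concat([cond[["medium", "long"]], pair], axis=1)
    design = sm.add_constant(X.to_numpy(), has_constant="add")
    fit = sm.OLS(long["rt"].to_numpy(), design).fit()
    b_medium, b_long = fit.params[1], fit.params[2]

    def _contrast(vec: np.ndarray) -> dict:
        tt = fit.t_test(vec)
        return {
            "estimate": round(float(tt.effect.ravel()[0]), 10),
            "se": round(float(tt.sd.ravel()[0]), 10),
            "t": round(float(tt.tvalue.ravel()[0]), 10),
            "p": round(float(tt.pvalue.ravel()[0]), 12),
        }

    k = design.shape[1]
    v_sm = np.zeros(k); v_sm[1] = -1.0          # short - medium = -b_medium
    v_ml = np.zeros(k); v_ml[1] = 1.0; v_ml[2] = -1.0  # medium - long
    v_sl = np.zeros(k); v_sl[2] = -1.0          # short - long
    contrasts = {
        "short_vs_medium": _contrast(v_sm),
        "medium_vs_long": _contrast(v_ml),
        "short_vs_long": _contrast(v_sl),
    }
    return RegressionResult(
        terms=["intercept", "medium", "long"] + list(X.columns[2:]),
        beta=fit.params,
        se=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        fvalue=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n=len(long),
        contrasts=contrasts,
    )
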