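"""Analyses of the learned affordance representation and training curves.

The central statistic is the preference index of a unit over n stimulus
categories,

    PI = (n - sum_i r_i / r_pref) / (n - 1),

where r_i is the unit's mean activity for category i and r_pref the mean
activity for its preferred category.  PI is 0 for a unit responding
equally to all categories and 1 for a unit responding to exactly one.
Units are classed as highly selective (PI > 0.75), moderately selective
(0.25 <= PI <= 0.75) or non-selective (PI < 0.25).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .training import TrialRecord

FEATURES = ("shape", "phi_s", "theta_s", "o_x", "o_y", "o_z",
            "s_x", "s_y", "s_z")


def preference_index(mean_activity: Sequence[float]) -> float:
    """PI over category means; requires n >= 2 and a positive peak."""
    r = np.asarray(mean_activity, dtype=float)
    n = r.size
    if n < 2:
        raise ValueError("need at least two categories")
    r_pref = r.max()
    if r_pref <= 0:
        raise ValueError("undefined PI: non-positive preferred response")
    return float((n - r.sum() / r_pref) / (n - 1))


def classify_selectivity(pi: float) -> str:
    """'high' above 0.75, 'non' below 0.25, 'moderate' in the closed band."""
    if not 0.0 <= pi <= 1.0 + 1e-12:
        raise ValueError("PI must lie in [0, 1]")
    if pi > 0.75:
        return "high"
    if pi < 0.25:
        return "non"
    return "moderate"


def _pi_per_unit(activity: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized PI for every unit (columns of *activity*) over *labels*.

    Units whose preferred-category mean is non-positive get NaN (excluded).
    """
    cats = np.unique(labels)
    n = len(cats)
    if n < 2:
        return np.full(activity.shape[1], np.nan)
    means = np.stack([activity[labels == c].mean(axis=0) for c in cats])
    r_pref = means.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = (n - means.sum(axis=0) / r_pref) / (n - 1)
    pi[r_pref <= 0] = np.nan
    return pi


def _trial_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        obj = r.object
        rows.append({
            "trial": r.trial, "stage": r.stage, "shape": obj["shape"],
            "novel": r.novel, "success": r.success,
            "phi_s": np.arctan2(obj["position"][2], obj["position"][0]),
            "theta_s": np.arccos(np.clip(
                obj["position"][1] / np.linalg.norm(obj["position"]), -1, 1)),
            "o_x": obj["orientation"][0], "o_y": obj["orientation"][1],
            "o_z": obj["orientation"][2],
            "s_x": obj["size"][0], "s_y": obj["size"][1], "s_z": obj["size"][2],
        })
    return pd.DataFrame(rows)


def _bin_feature(values: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equal-width bins over the sampled range (continuous features -> categories)."""
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.zeros(len(values), dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.digitize(values, edges[1:-1]), 0, n_bins - 1)


@dataclass
class SelectivityReport:
    """Per-block selectivity summary of the affordance map."""

    block: int
    pi: np.ndarray               # per-unit PI (NaN = excluded)
    max_pi: float
    mean_pi: float
    min_pi: float
    counts: Dict[str, int]       # high / moderate / non / excluded

    @property
    def n_units(self) -> int:
        return int(self.pi.size)


def _summarize_block(block: int, pi: np.ndarray) -> SelectivityReport:
    valid = pi[np.isfinite(pi)]
    counts = {"high": 0, "moderate": 0, "non": 0,
              "excluded": int(np.sum(~np.isfinite(pi)))}
    for v in valid:
        counts[classify_selectivity(min(max(v, 0.0), 1.0))] += 1
    return SelectivityReport(
        block=block, pi=pi,
        max_pi=float(valid.max()) if valid.size else np.nan,
        mean_pi=float(valid.mean()) if valid.size else np.nan,
        min_pi=float(valid.min()) if valid.size else np.nan,
        counts=counts)


def selectivity_timecourse(records: Sequence[TrialRecord],
                           block: int = 500) -> List[SelectivityReport]:
    """Shape PI of every map unit in consecutive trial blocks."""
    acts = np.stack([r.aip for r in records]).astype(float)
    shapes = np.array([r.object["shape"] for r in records])
    reports = []
    for b, start in enumerate(range(0, len(records), block)):
        sl = slice(start, min(start + block, len(records)))
        if len(np.unique(shapes[sl])) < 2:
            continue  # block missing almost every category: PI undefined
        pi = _pi_per_unit(acts[sl], shapes[sl])
        reports.append(_summarize_block(b, pi))
    return reports


def feature_pi_panel(records: Sequence[TrialRecord],
                     n_bins: int = 5) -> pd.DataFrame:
    """PI of every unit for shape, direction, orientation and size features.

    Continuous features are discretized into equal-width bins over their
    sampled range.  Returns a (units x features) frame.
    """
    acts = np.stack([r.aip for r in records]).astype(float)
    df = _trial_frame(records)
    out = {}
    for feat in FEATURES:
        if feat == "shape":
            labels = df["shape"].to_numpy()
        else:
            labels = _bin_feature(df[feat].to_numpy(), n_bins)
        out[feat] = _pi_per_unit(acts, labels)
    return pd.DataFrame(out)


def linear_feature_fit(records: Sequence[TrialRecord]) -> dict:
    """Per-unit ordinary least squares on z-scored object features.

    Shape enters as dummy variables; continuous features are z-scored over
    the log.  Returns coefficients (units x features), R^2 per unit and the
    design column names.  Requires at least 10x more trials than features.
    """
    acts = np.stack([r.aip for r in records]).astype(float)
    df = _trial_frame(records)
    cont = [f for f in FEATURES if f != "shape"]
    X_cont = df[cont].to_numpy()
    mu, sd = X_cont.mean(0), X_cont.std(0)
    sd[sd == 0] = 1.0
    X_cont = (X_cont - mu) / sd
    shape_d = pd.get_dummies(df["shape"], prefix="shape", drop_first=True)
    X = np.column_stack([X_cont, shape_d.to_numpy(dtype=float)])
    names = cont + list(shape_d.columns)
    # drop collinear columns via rank-revealing QR
    q, r_, piv = _qr_pivot(X)
    keep = piv[: np.linalg.matrix_rank(X)]
    dropped = [names[i] for i in range(len(names)) if i not in keep]
    Xk = X[:, sorted(keep)]
    if acts.shape[0] < 10 * (Xk.shape[1] + 1):
        raise ValueError("need >= 10x more trials than features")
    A = np.column_stack([np.ones(len(Xk)), Xk])
    coef, *_ = np.linalg.lstsq(A, acts, rcond=None)
    fitted = A @ coef
    ss_res = ((acts - fitted) ** 2).sum(0)
    ss_tot = ((acts - acts.mean(0)) ** 2).sum(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    kept_names = [names[i] for i in sorted(keep)]
    return {"coefficients": coef[1:].T, "intercept": coef[0],
            "r_squared": r2, "features": kept_names, "dropped": dropped}


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr
    q, r_, piv = qr(X, pivoting=True, mode="economic")
    return q, r_, piv


def success_rate_curve(records: Sequence[TrialRecord], window: int = 500,
                       ) -> pd.DataFrame:
    """Blocked success fraction, separately for familiar and novel trials."""
    df = _trial_frame(records)
    df["block"] = np.arange(len(df)) // window
    grouped = (df.groupby(["block", "novel"])["success"]
               .agg(["mean", "count"]).reset_index())
    return grouped.rename(columns={"mean": "success_rate", "count": "n_trials"})
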