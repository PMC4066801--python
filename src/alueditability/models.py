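"""Editability models: exponential distance decay, residual neighbor-count
regression, stratified fits, variance decomposition and group summaries.

The central model is E(d) = A * exp(-d / L) + B with E the per-element
editability in percent and d the gap to the nearest reversely oriented
repeat in bp.  The neighbor-count model is an ordinary least-squares fit of
the distance-model residuals on the same- and reverse-strand neighbor
counts, reproducing the sequential two-stage structure of the combined
linear model E = A*exp(-d/L) + beta_ss*Nss + beta_rs*Nrs + intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """Non-convergence or an ill-posed design."""


@dataclass(frozen=True)
class ExpFitParams:
    amplitude: float        # percent
    decay_bp: float         # bp
    baseline: float         # percent
    r2_binned: float
    variance_explained_per_element: float

    def as_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "decay_bp": self.decay_bp,
            "baseline": self.baseline,
            "r2_binned": self.r2_binned,
            "variance_explained_per_element": self.variance_explained_per_element,
        }


@dataclass(frozen=True)
class NeighborModelParams:
    beta_ss: float            # percent per same-strand element
    beta_rs: float            # percent per reverse-strand element
    intercept_combined: float  # exponential baseline + OLS intercept

    def as_dict(self) -> dict:
        return {
            "beta_ss": self.beta_ss,
            "beta_rs": self.beta_rs,
            "intercept_combined": self.intercept_combined,
        }


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean_editability: float
    mean_residual: float | None


def predict_exponential(params: ExpFitParams, d) -> float | np.ndarray:
    """A * exp(-d/L) + B for d >= 0."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    out = params.amplitude * np.exp(-d / params.decay_bp) + params.baseline
    return float(out) if out.ndim == 0 else out


def residual_editability(e, d, params: ExpFitParams):
    """Observed minus distance-predicted editability (may be negative)."""
    return np.asarray(e, dtype=float) - predict_exponential(params, d)


def variance_explained(e: Sequence[float], e_hat: Sequence[float],
                       clip: bool = False) -> float:
    """1 - SS_res / SS_tot of predictions against per-element values."""
    e = np.asarray(e, dtype=float)
    e_hat = np.asarray(e_hat, dtype=float)
    if e.shape != e_hat.shape or e.size < 2:
        raise ValueError("need equal-length arrays with n >= 2")
    ss_tot = float(np.sum((e - e.mean()) ** 2))
    if ss_tot == 0:
        raise FitError("zero total variance")
    raw = 1.0 - float(np.sum((e - e_hat) ** 2)) / ss_tot
    return float(np.clip(raw, 0.0, 1.0)) if clip else raw


def _exp_resid(theta, d, e, w):
    a, log_l, b = theta
    return w * (a * np.exp(-d / np.exp(log_l)) + b - e)


def fit_exponential(d: Sequence[float], e: Sequence[float],
                    mode: str = "binned", bin_width: int = 100,
                    max_d: int = 4000) -> ExpFitParams:
    """Least-squares fit of E = A*exp(-d/L) + B.

    In ``binned`` mode (the figure-style default) the curve is fitted to
    mean editability within ``bin_width``-bp distance bins; records with
    d > max_d are excluded from the curve fit.  In ``per_element`` mode raw
    pairs up to max_d are fitted.  The per-element variance explained is
    always computed on the full raw data (including d > max_d) with the
    fitted curve.

    Trust-region NLS with multi-start over decay initials {200, 1000, 3000}
    bp; bounds A >= 0, L in [10, 1e6], B >= 0.
    """
    d = np.asarray(d, dtype=float)
    e = np.asarray(e, dtype=float)
    keep = np.isfinite(d) & np.isfinite(e)
    d, e = d[keep], e[keep]
    if len(np.unique(d)) < 3:
        raise FitError("need at least 3 distinct distances")
    if mode not in ("binned", "per_element"):
        raise ValueError(f"unknown fit mode {mode!r}")

    in_range = d <= max_d
    if mode == "binned":
        bins = np.arange(0, max_d + bin_width, bin_width)
        which = np.minimum(np.digitize(d[in_range], bins) - 1, len(bins) - 2)
        sums = np.bincount(which, weights=e[in_range], minlength=len(bins) - 1)
        cnts = np.bincount(which, minlength=len(bins) - 1)
        nz = cnts > 0
        x_fit = (bins[:-1] + 0.5 * bin_width)[nz]
        y_fit = sums[nz] / cnts[nz]
        # bin means have variance ~ 1/n: inverse-variance weights
        w_fit = np.sqrt(cnts[nz])
    else:
        x_fit, y_fit = d[in_range], e[in_range]
        w_fit = np.ones_like(y_fit)
    if len(np.unique(x_fit)) < 3:
        raise FitError("need at least 3 distinct distances within max_d")

    a0 = max(float(y_fit.max() - y_fit.min()), 1e-6)
    b0 = max(float(y_fit.min()), 0.0)
    best = None
    for l0 in (200.0, 1000.0, 3000.0):
        try:
            res = least_squares(
                _exp_resid, x0=[a0, np.log(l0), b0], args=(x_fit, y_fit, w_fit),
                bounds=([0.0, np.log(10.0), 0.0], [np.inf, np.log(1e6), np.inf]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=10_000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise FitError("exponential fit failed to converge from all starts")

    a, log_l, b = best.x
    params0 = ExpFitParams(float(a), float(np.exp(log_l)), float(b), 0.0, 0.0)
    yhat_fit = predict_exponential(params0, x_fit)
    sst = float(np.sum((y_fit - y_fit.mean()) ** 2))
    r2_b = 1.0 - float(np.sum((y_fit - yhat_fit) ** 2)) / sst if sst > 0 else 0.0
    try:
        ve = variance_explained(e, predict_exponential(params0, d), clip=False)
    except FitError:  # flat data: nothing to explain
        ve = 0.0
    return ExpFitParams(float(a), float(np.exp(log_l)), float(b),
                        float(r2_b), float(ve))


def stratified_exponential_fit(merged: pd.DataFrame, stratum: str,
                               mode: str = "binned", bin_width: int = 100,
                               max_d: int = 4000) -> ExpFitParams:
    """fit_exponential on records of one expressed-strand class.

    ``merged`` needs columns d, editability_pct, expressed_strand_class.
    """
    if stratum not in ("polyA", "polyU"):
        raise ValueError(f"unknown stratum {stratum!r}")
    sub = merged[merged["expressed_strand_class"] == stratum]
    if sub.empty:
        raise FitError(f"empty stratum {stratum}")
    return fit_exponential(sub["d"], sub["editability_pct"],
                           mode=mode, bin_width=bin_width, max_d=max_d)


def fit_neighbor_regression(residuals, nss, nrs,
                            exp_baseline: float = 0.0) -> NeighborModelParams:
    """OLS of distance-model residuals on neighbor counts (with intercept).

    intercept_combined is the exponential baseline plus the OLS intercept,
    i.e. the constant of the combined linear model.
    """
    r = np.asarray(residuals, dtype=float)
    x1 = np.asarray(nss, dtype=float)
    x2 = np.asarray(nrs, dtype=float)
    if not (len(r) == len(x1) == len(x2)):
        raise ValueError("residuals, nss, nrs must have equal length")
    keep = np.isfinite(r) & np.isfinite(x1) & np.isfinite(x2)
    r, x1, x2 = r[keep], x1[keep], x2[keep]
    X = np.column_stack([np.ones_like(x1), x1, x2])
    if np.linalg.matrix_rank(X) < 3:
        raise FitError("rank-deficient design (nss/nrs collinear or constant)")
    coef, *_ = np.linalg.lstsq(X, r, rcond=None)
    return NeighborModelParams(float(coef[1]), float(coef[2]),
                               float(exp_baseline + coef[0]))


def neighbor_effect(params: NeighborModelParams,
                    delta_nss: float, delta_nrs: float) -> float:
    """Predicted editability change (percent) for count changes, all else fixed."""
    return params.beta_ss * delta_nss + params.beta_rs * delta_nrs


_LENGTH_BINS = np.array([0, 100, 150, 200, 250, 275, 300, 325, 400, 10_000])
_IDENTITY_BINS = np.arange(0, 101, 10)

GROUPINGS = ("family", "subfamily_match", "segment_relation",
             "length_bin", "identity_bin", "neighbor_length_bin")


def _grouping_labels(merged: pd.DataFrame, grouping: str) -> pd.Series:
    if grouping == "family":
        lab = merged.get("family")
    elif grouping == "subfamily_match":
        fam = merged.get("same_family")
        sub = merged.get("same_subfamily")
        if fam is None or sub is None:
            lab = None
        else:
            lab = np.select(
                [sub.astype("boolean").fillna(False),
                 fam.astype("boolean").fillna(False)],
                ["same_subfamily", "same_family_only"], default="different_family",
            )
            lab = pd.Series(lab, index=merged.index)
    elif grouping == "segment_relation":
        lab = merged.get("segment_relation")
    elif grouping == "length_bin":
        length = merged["end"] - merged["start"] if "end" in merged else None
        lab = None if length is None else pd.cut(length, _LENGTH_BINS).astype(str)
    elif grouping == "identity_bin":
        col = merged.get("pair_identity_pct")
        lab = None if col is None else pd.cut(
            col, _IDENTITY_BINS, include_lowest=True).astype(str)
    elif grouping == "neighbor_length_bin":
        col = merged.get("neighbor_length")
        lab = None if col is None else pd.cut(col, _LENGTH_BINS).astype(str)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if lab is None:
        raise ValueError(f"columns for grouping {grouping!r} missing from table")
    return pd.Series(lab, index=merged.index).fillna("unknown").replace("nan", "unknown")


def summarize_by(merged: pd.DataFrame, grouping: str,
                 distance_correct: bool = False,
                 exp_params: ExpFitParams | None = None) -> list[GroupSummary]:
    """Per-group count and mean editability; optionally the mean residual
    from the global exponential fit (distance-corrected comparison).

    ``merged`` is the joined editability+features table.
    """
    labels = _grouping_labels(merged, grouping)
    resid = None
    if distance_correct:
        if exp_params is None:
            exp_params = fit_exponential(merged["d"], merged["editability_pct"])
        ok = merged["d"].notna()
        resid = pd.Series(np.nan, index=merged.index)
        resid[ok] = residual_editability(
            merged.loc[ok, "editability_pct"], merged.loc[ok, "d"], exp_params)
    out = []
    for name, idx in merged.groupby(labels).groups.items():
        sub = merged.loc[idx]
        mean_res = None
        if resid is not None:
            vals = resid.loc[idx].dropna()
            mean_res = float(vals.mean()) if len(vals) else None
        out.append(GroupSummary(str(name), int(len(sub)),
                                float(sub["editability_pct"].mean()), mean_res))
    out.sort(key=lambda s: s.group)
    return out


def summaries_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.group, s.n, s.mean_editability, s.mean_residual) for s in summaries],
        columns=["group", "n", "mean_editability", "mean_residual"],
    )
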