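"""Relative inequality indices: performance ratios and best-vs-worst odds.

Two complementary relative measures:

* the **performance ratio** — highest over lowest modelled district
  prevalence; 1 means spatial homogeneity, larger values a wider gap;
* the **best-vs-worst odds ratio** — the coefficient of the best-performing
  region (by *observed* sample coverage) in an unadjusted logistic regression
  of the outcome on region indicators with the worst region as reference.
  An interval overlapping zero means no significant effect of place alone.

The logistic fit uses iteratively reweighted least squares (Newton-Raphson)
run to a gradient norm below 1e-8; the same routine doubles as the
plain-logistic oracle elsewhere in the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

if TYPE_CHECKING:  # pragma: no cover
    from .estimates import DistrictEstimateSet

logger = logging.getLogger(__name__)

_Z975 = 1.959963984540054


class SeparationError(RuntimeError):
    """Perfect separation: some region has all-0 or all-1 outcomes."""


@dataclass
class IrlsResult:
    coef: np.ndarray
    cov: np.ndarray  # inverse observed Fisher information
    n_iter: int
    converged: bool

    def wald_ci(self, k: int) -> tuple[float, float]:
        se = float(np.sqrt(self.cov[k, k]))
        return (float(self.coef[k]) - _Z975 * se, float(self.coef[k]) + _Z975 * se)


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> IrlsResult:
    """Maximum-likelihood logistic regression by Newton-Raphson (IRLS).

    Iterates until the score (gradient) norm falls below ``tol``.  Raises
    :class:`SeparationError` when the fit diverges, which for this model
    happens exactly under (quasi-)separation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            w = mu * (1.0 - mu)
            cov = np.linalg.inv(X.T @ (X * w[:, None]))
            return IrlsResult(coef=beta, cov=cov, n_iter=it, converged=True)
        w = mu * (1.0 - mu)
        if np.any(w < 1e-12) and np.abs(eta).max() > 30.0:
            raise SeparationError(
                "logistic fit diverging (fitted probabilities at 0/1); the data "
                "are separated — consider exact or penalized methods (not provided)"
            )
        H = X.T @ (X * w[:, None])
        try:
            beta = beta + np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
    raise SeparationError(f"IRLS did not converge in {max_iter} iterations")


def performance_ratio(
    estimates: "DistrictEstimateSet",
) -> tuple[float, tuple[float, float] | None]:
    """Best-to-worst ratio of district point estimates, with a draw interval.

    The point ratio divides the largest posterior-mean prevalence by the
    smallest.  When prevalence draws are available the 95% interval of the
    draw-wise max/min ratio is returned alongside (the ratio of interval
    endpoints would not be a valid interval).
    """
    means = estimates.table["mean"].to_numpy(dtype=float)
    if len(means) == 0:
        raise ValueError("no districts in estimate set")
    if np.any(means <= 0.0):
        bad = estimates.table.index[means <= 0.0].tolist()
        raise ValueError(
            f"performance ratio undefined: zero prevalence estimate in {bad}; "
            "inspect these districts"
        )
    ratio = float(means.max() / means.min())
    interval = None
    draws = estimates.draws
    if draws is not None and draws.shape[0] > 1:
        per_draw = draws.max(axis=1) / draws.min(axis=1)
        interval = (
            float(np.quantile(per_draw, 0.025)),
            float(np.quantile(per_draw, 0.975)),
        )
    return ratio, interval


@dataclass
class RegionCoverage:
    coverage: pd.Series  # observed sample proportion per region
    n_by_region: pd.Series
    best: str
    worst: str


def _region_of(data: pd.DataFrame, region_map: Mapping[str, str] | None) -> pd.Series:
    if region_map is None:
        return data["district_id"].astype(str)
    region = data["district_id"].map(region_map)
    if region.isna().any():
        missing = sorted(set(data.loc[region.isna(), "district_id"]))
        raise KeyError(f"districts without a region mapping: {missing}")
    return region.astype(str)


def observed_region_coverage(
    data: pd.DataFrame,
    region_map: Mapping[str, str] | None,
    outcome: str,
) -> RegionCoverage:
    """Observed coverage (sample proportion) per region, with best and worst.

    Coverage is the proportion of women in the sample receiving the service;
    9 of 10 positive means 90% coverage.  Ties break on the lexicographically
    smallest region id.
    """
    rows = data.loc[data[outcome].notna()].copy()
    if len(rows) == 0:
        raise ValueError(f"no usable observations for outcome {outcome!r}")
    rows["_region"] = _region_of(rows, region_map)
    grp = rows.groupby("_region")[outcome]
    coverage = grp.mean().astype(float).sort_index()
    n = grp.size().sort_index()
    if (n == 0).any():
        raise ValueError("empty region encountered")
    best = coverage.index[np.lexsort((coverage.index, -coverage.to_numpy()))][0]
    worst = coverage.index[np.lexsort((coverage.index, coverage.to_numpy()))][0]
    return RegionCoverage(coverage=coverage, n_by_region=n, best=str(best), worst=str(worst))


@dataclass
class OrResult:
    log_or: float
    ci: tuple[float, float]
    coef: pd.Series  # all region coefficients (worst = reference)


def best_vs_worst_or(
    data: pd.DataFrame,
    best_region: str,
    worst_region: str,
    region_map: Mapping[str, str] | None = None,
    outcome: str = "sba",
) -> OrResult:
    """Unadjusted log odds ratio of the best- vs worst-performing region.

    Fits outcome ~ region indicators over all regions with the worst region
    as reference and reports the best region's coefficient with its Wald 95%
    interval.  Raises :class:`SeparationError` when any region's outcomes are
    all 0 or all 1.
    """
    rows = data.loc[data[outcome].notna()].copy()
    rows["_region"] = _region_of(rows, region_map)
    y = rows[outcome].astype(int).to_numpy()
    if len(rows) == 0 or y.min() == y.max():
        raise ValueError(
            f"outcome {outcome!r} needs both classes present in the pooled data"
        )
    regions = sorted(rows["_region"].unique())
    for r in (best_region, worst_region):
        if r not in regions:
            raise ValueError(f"region {r!r} has no observations")
    per_region = rows.groupby("_region")[outcome].agg(["mean", "size"])
    degenerate = per_region.index[(per_region["mean"] == 0) | (per_region["mean"] == 1)]
    if len(degenerate) > 0:
        raise SeparationError(
            f"regions {list(degenerate)} have all-0 or all-1 outcomes; the "
            "unpenalized logistic OR is undefined — consider exact or "
            "penalized alternatives"
        )
    others = [r for r in regions if r != worst_region]
    X = np.column_stack(
        [np.ones(len(rows))]
        + [(rows["_region"] == r).to_numpy(dtype=float) for r in others]
    )
    res = logistic_irls(X, y)
    names = ["intercept"] + others
    k = names.index(best_region)
    return OrResult(
        log_or=float(res.coef[k]),
        ci=res.wald_ci(k),
        coef=pd.Series(res.coef, index=names),
    )


def inequality_report(
    estimates: "DistrictEstimateSet",
    data: pd.DataFrame,
    region_map: Mapping[str, str] | None = None,
    label: str = "",
) -> dict:
    """Full relative-inequality report for one outcome and survey."""
    ratio, interval = performance_ratio(estimates)
    cov = observed_region_coverage(data, region_map, estimates.outcome)
    if cov.best == cov.worst:
        log_or, ci = 0.0, (0.0, 0.0)
        logger.warning("single region: best==worst, odds ratio trivially 0")
    else:
        orr = best_vs_worst_or(
            data, cov.best, cov.worst, region_map, estimates.outcome
        )
        log_or, ci = orr.log_or, orr.ci
    return {
        "outcome": estimates.outcome,
        "label": label or estimates.label,
        "ratio": ratio,
        "ratio_ci": list(interval) if interval else None,
        "best_region": cov.best,
        "worst_region": cov.worst,
        "log_or": log_or,
        "or_ci": list(ci),
        "n_by_region": cov.n_by_region.to_dict(),
    }


def write_inequality_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
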