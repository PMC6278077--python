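"""District-level prevalence estimates and absolute change between surveys.

District prevalence for one posterior draw is the average predicted
probability over the district's observed women (the empirical covariate
distribution, matching the survey notion of coverage as the proportion of
sampled women receiving the service).  Summaries are taken across draws.
Districts without observations are extrapolated from the spatial-effect
posterior at a reference covariate profile and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.special import expit

from .recode import build_design

if TYPE_CHECKING:  # pragma: no cover
    from .bym import PosteriorFit


@dataclass
class DistrictEstimateSet:
    """Posterior prevalence summaries per district for one outcome/survey."""

    outcome: str
    label: str
    district_ids: tuple[str, ...]
    table: pd.DataFrame  # index district_id: mean, median, sd, q025, q975, n_obs, extrapolated
    draws: np.ndarray  # (n_draws, n_districts) prevalence draws

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.insert(0, "outcome", self.outcome)
        out.insert(1, "year", self.label)
        out.to_csv(path, index_label="district_id")


@dataclass
class ChangeTable:
    """Last-minus-first change in district prevalence (proportion scale)."""

    outcome: str
    first_label: str
    last_label: str
    table: pd.DataFrame  # index district_id: change, uncertain

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="district_id")


def district_prevalence(
    fit: "PosteriorFit",
    data: pd.DataFrame,
    label: str = "",
    chunk: int = 200,
) -> DistrictEstimateSet:
    """Draw-wise district prevalence from a fitted model and its survey table.

    For each retained draw, a district's prevalence is the mean of
    inverse-logit(x'beta + b_j) over its observed women (rows with the
    outcome missing are excluded, as in the fit).  Unobserved districts get
    the prevalence of the sample-mean covariate profile under their own
    spatial effect, flagged ``extrapolated``.
    """
    beta = fit.flat("beta")
    b = fit.flat("b")
    if beta.shape[0] == 0:
        raise ValueError("fit contains no draws")
    rows = data.loc[data[fit.outcome].notna()]
    X, _ = build_design(rows, fit.coding)
    idx = {d: i for i, d in enumerate(fit.district_ids)}
    dix = rows["district_id"].map(idx).astype(int).to_numpy()
    J = len(fit.district_ids)
    M = beta.shape[0]
    n = len(rows)
    counts = np.bincount(dix, minlength=J)
    observed = counts > 0
    # sparse district-averaging operator: (J, n), rows of unobserved districts zero
    import scipy.sparse as sp

    weights = 1.0 / counts[dix]
    G = sp.csr_matrix((weights, (dix, np.arange(n))), shape=(J, n))
    x_ref = X.mean(axis=0)

    draws = np.empty((M, J))
    for start in range(0, M, chunk):
        B = beta[start : start + chunk]  # (m, p)
        bb = b[start : start + chunk]  # (m, J)
        eta = X @ B.T + bb.T[dix, :]  # (n, m)
        block = np.asarray((G @ expit(eta)).T)  # (m, J)
        if (~observed).any():
            eta_ref = B @ x_ref  # (m,)
            block[:, ~observed] = expit(eta_ref[:, None] + bb[:, ~observed])
        draws[start : start + len(B)] = block

    table = pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "median": np.quantile(draws, 0.5, axis=0),
            "sd": draws.std(axis=0, ddof=1) if M > 1 else np.zeros(J),
            "q025": np.quantile(draws, 0.025, axis=0),
            "q975": np.quantile(draws, 0.975, axis=0),
            "n_obs": counts,
            "extrapolated": ~observed,
        },
        index=pd.Index(fit.district_ids, name="district_id"),
    )
    return DistrictEstimateSet(
        outcome=fit.outcome,
        label=label,
        district_ids=fit.district_ids,
        table=table,
        draws=draws,
    )


def absolute_change(first: DistrictEstimateSet, last: DistrictEstimateSet) -> ChangeTable:
    """Per-district change in prevalence between two surveys (last - first).

    A draw-free ``uncertain`` flag marks districts whose two 95% credible
    intervals overlap, i.e. where the sign of the change is not clearly
    resolved.
    """
    if first.outcome != last.outcome:
        raise ValueError(
            f"outcome mismatch: {first.outcome!r} vs {last.outcome!r}"
        )
    a, bset = set(first.district_ids), set(last.district_ids)
    if a != bset:
        diff = sorted(a.symmetric_difference(bset))
        raise ValueError(f"district sets differ; symmetric difference: {diff}")
    f = first.table
    l = last.table.loc[f.index]
    change = l["mean"] - f["mean"]
    uncertain = (f["q025"] <= l["q975"]) & (l["q025"] <= f["q975"])
    table = pd.DataFrame({"change": change, "uncertain": uncertain})
    return ChangeTable(
        outcome=first.outcome,
        first_label=first.label,
        last_label=last.label,
        table=table,
    )


def plot_district_estimates(est: DistrictEstimateSet, graph=None, ax=None):
    """Minimal choropleth/interval helper for quick inspection."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if graph is not None and graph.polygons is not None:
        from matplotlib import cm, colors

        norm = colors.Normalize(vmin=0.0, vmax=1.0)
        for d in est.district_ids:
            poly = graph.polygons[d]
            xs, ys = poly.exterior.xy
            ax.fill(xs, ys, color=cm.viridis(norm(est.table.loc[d, "mean"])))
        ax.set_aspect("equal")
        ax.set_title(f"{est.outcome} {est.label}".strip())
    else:
        t = est.table.sort_values("mean")
        y = np.arange(len(t))
        ax.errorbar(
            t["mean"], y,
            xerr=[t["mean"] - t["q025"], t["q975"] - t["mean"]],
            fmt="o", ms=3, lw=1,
        )
        ax.set_yticks(y, t.index)
        ax.set_xlabel(f"{est.outcome} prevalence")
    return ax
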