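"""Out-of-sample validation: 75/25 holdout with MAE, MSE, and pseudo-R².

A quarter of the individual records is removed (stratified by district so
every district contributes held-out data where possible), the model is
refitted on the remainder, and the district-level posterior-mean prevalence
predictions are compared with the held-out observed proportions.  MAE, MSE,
and pseudo-R² summarize precision, bias, and variance explained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .bym import IcarStructure, McmcSettings, ModelSpec

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    mae: float
    mse: float
    pseudo_r2: float | None
    n_train: int
    n_test: int
    split_seed: int
    level: str = "district"
    pseudo_r2_variant: str = "r2"
    pseudo_r2_reason: str | None = None
    brier: float | None = None  # individual-level secondary metric

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "mse": self.mse,
            "pseudo_r2": self.pseudo_r2,
            "pseudo_r2_variant": self.pseudo_r2_variant,
            "pseudo_r2_reason": self.pseudo_r2_reason,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "split_seed": self.split_seed,
            "level": self.level,
            "brier": self.brier,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def holdout_split(
    data: pd.DataFrame,
    fraction: float = 0.25,
    seed: int = 0,
    unit: str = "individual",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test split stratified by district.

    Test counts are allocated by the largest-remainder rule so the overall
    test share equals ``round(n * fraction)`` exactly while each district's
    split stays as close to ``fraction`` as rounding allows.  Districts with
    a single record go entirely to train (logged).  With ``unit="cluster"``
    whole clusters are held out instead of individual women.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    if unit == "cluster":
        key = data["cluster_id"]
    elif unit == "individual":
        key = pd.Series(np.arange(len(data)), index=data.index)
    else:
        raise ValueError(f"unknown split unit {unit!r}")
    units = pd.DataFrame(
        {"key": key, "district": data["district_id"].to_numpy()}, index=data.index
    ).drop_duplicates("key")
    n_units = len(units)
    target = int(np.floor(n_units * fraction + 0.5))
    per_district = units.groupby("district", sort=True).size()
    eligible = per_district[per_district > 1]
    for d in per_district.index[per_district == 1]:
        logger.info("district %s has a single record; kept in train", d)
    quota = eligible * fraction
    base = np.floor(quota).astype(int)
    remainder = quota - base
    n_extra = min(target - int(base.sum()), int((eligible - base).gt(0).sum()))
    alloc = base.copy()
    if n_extra > 0:
        order = sorted(
            eligible.index, key=lambda d: (-remainder[d], d)
        )
        for d in order:
            if n_extra == 0:
                break
            if alloc[d] < eligible[d]:
                alloc[d] += 1
                n_extra -= 1
    test_keys: list = []
    for d, k in alloc.items():
        if k == 0:
            continue
        pool = units.loc[units["district"] == d, "key"].to_numpy()
        test_keys.extend(rng.choice(pool, size=int(k), replace=False))
    test_mask = key.isin(set(test_keys))
    return data.loc[~test_mask], data.loc[test_mask]


def validation_stats(
    observed,
    predicted,
    n_train: int = 0,
    n_test: int = 0,
    split_seed: int = 0,
    pseudo_r2_variant: str = "r2",
    brier: float | None = None,
) -> ValidationReport:
    """MAE, MSE, and pseudo-R² of district predictions against held-out data.

    ``observed`` are held-out per-district proportions, ``predicted`` the
    matching posterior-mean prevalence from the train-only fit (aligned on
    index when pandas Series are given).  pseudo-R² defaults to the
    coefficient of determination 1 - SS_res/SS_tot; ``"pearson2"`` selects
    the squared Pearson correlation instead.  Zero variance in the observed
    values makes pseudo-R² undefined; it is reported missing with a reason.
    """
    if isinstance(observed, pd.Series) and isinstance(predicted, pd.Series):
        predicted = predicted.loc[observed.index]
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must align")
    if obs.size < 2:
        raise ValueError("need held-out data from at least 2 districts")
    err = obs - pred
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    reason = None
    if ss_tot == 0.0:
        r2 = None
        reason = "observed proportions have zero variance"
    elif pseudo_r2_variant == "r2":
        r2 = float(1.0 - np.sum(err**2) / ss_tot)
    elif pseudo_r2_variant == "pearson2":
        if np.std(pred) == 0.0:
            r2 = None
            reason = "predictions have zero variance"
        else:
            r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    else:
        raise ValueError(f"unknown pseudo_r2 variant {pseudo_r2_variant!r}")
    return ValidationReport(
        mae=mae,
        mse=mse,
        pseudo_r2=r2,
        n_train=n_train,
        n_test=n_test,
        split_seed=split_seed,
        pseudo_r2_variant=pseudo_r2_variant,
        pseudo_r2_reason=reason,
        brier=brier,
    )


def validate_model(
    spec: "ModelSpec",
    data: pd.DataFrame,
    structure: "IcarStructure",
    mcmc: "McmcSettings",
    fraction: float = 0.25,
    seed: int = 0,
    unit: str = "individual",
    pseudo_r2_variant: str = "r2",
) -> ValidationReport:
    """End-to-end holdout validation of one outcome's model."""
    from .bym import fit as fit_model
    from .estimates import district_prevalence
    from .recode import build_design
    from scipy.special import expit

    train, test = holdout_split(data, fraction=fraction, seed=seed, unit=unit)
    fitted = fit_model(spec, train, structure, mcmc)
    est = district_prevalence(fitted, train)
    test_rows = test.loc[test[spec.outcome].notna()]
    obs = test_rows.groupby("district_id")[spec.outcome].mean().astype(float)
    pred = est.table["mean"].loc[obs.index]
    # individual-level Brier score on held-out women (secondary metric)
    X, _ = build_design(test_rows, fitted.coding)
    idx = {d: i for i, d in enumerate(fitted.district_ids)}
    dix = test_rows["district_id"].map(idx).astype(int).to_numpy()
    beta_mean = fitted.flat("beta").mean(axis=0)
    b_mean = fitted.flat("b").mean(axis=0)
    p_ind = expit(X @ beta_mean + b_mean[dix])
    brier = float(np.mean((test_rows[spec.outcome].astype(float).to_numpy() - p_ind) ** 2))
    return validation_stats(
        obs,
        pred,
        n_train=len(train),
        n_test=len(test),
        split_seed=seed,
        pseudo_r2_variant=pseudo_r2_variant,
        brier=brier,
    )
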