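"""Eligibility restriction, binary outcome definitions, and covariate coding.

The analysis concerns each woman's most recent birth in the five years before
the survey.  Three binary service indicators are derived per record:

* ``sba``   — skilled birth attendance: delivery attended by a doctor, nurse,
  or auxiliary midwife.
* ``anc4``  — four or more antenatal care visits.
* ``pnc48`` — maternal postnatal check-up by a health professional within
  48 hours of delivery (inclusive).  Facility deliveries are assumed to have
  received professional postnatal care when both postnatal fields are absent,
  unless the data say otherwise.

Missing inputs exclude a record from that outcome's model only (listwise per
outcome); the three models are fitted independently.
"""

from __future__ import annotations

import logging
from typing import Any

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SKILLED_PROVIDERS = frozenset({"doctor", "nurse", "aux_midwife"})
ATTENDANT_VOCAB = SKILLED_PROVIDERS | {
    "trad_attendant",
    "relative",
    "none",
    "other",
    "missing",
}
EDUCATION_LEVELS = ("none", "primary", "secondary+")
OUTCOMES = ("sba", "anc4", "pnc48")

#: Columns every raw survey table must provide (after column mapping).
RAW_COLUMNS = (
    "woman_id",
    "cluster_id",
    "years_since_birth",
    "is_most_recent_birth",
    "attendant_code",
    "anc_visits",
    "pnc_hours",
    "pnc_provider",
    "facility_delivery",
    "urban",
    "education",
    "wealth_quintile",
    "maternal_age",
    "parity",
)


def _is_missing(value: Any) -> bool:
    if value is None or value is pd.NA:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and value in ("", "missing"):
        return True
    return False


def derive_sba(attendant_code: Any) -> int | None:
    """1 iff the birth attendant was a doctor, nurse, or auxiliary midwife.

    Missing codes return ``None`` (record excluded from the SBA model).
    """
    if _is_missing(attendant_code):
        return None
    if attendant_code not in ATTENDANT_VOCAB:
        raise ValueError(f"unknown attendant code {attendant_code!r}")
    return int(attendant_code in SKILLED_PROVIDERS)


def derive_anc4(anc_visits: Any) -> int | None:
    """1 iff the woman reported four or more antenatal care visits."""
    if _is_missing(anc_visits):
        return None
    visits = float(anc_visits)
    if visits < 0:
        raise ValueError(f"anc_visits must be non-negative, got {visits}")
    return int(visits >= 4)


def derive_pnc48(pnc_hours: Any, pnc_provider: Any, facility_delivery: Any) -> int | None:
    """1 iff a professional postnatal check-up occurred within 48 h (inclusive).

    The facility assumption — postnatal care counted as professional for
    facility deliveries — applies only when *both* postnatal fields are
    missing; any recorded data override it (e.g. a recorded 72 h check-up
    yields 0 even for a facility birth).  Returns ``None`` only when the
    postnatal fields and the facility flag are all missing.
    """
    hours_missing = _is_missing(pnc_hours)
    provider_missing = _is_missing(pnc_provider)
    if not provider_missing and pnc_provider not in ATTENDANT_VOCAB:
        raise ValueError(f"unknown pnc provider {pnc_provider!r}")
    if not hours_missing:
        if float(pnc_hours) > 48.0:
            return 0
        return int(not provider_missing and pnc_provider in SKILLED_PROVIDERS)
    if provider_missing:
        if _is_missing(facility_delivery):
            return None
        return int(bool(facility_delivery))
    # provider recorded but timing unknown: cannot establish the 48 h window
    return 0


def filter_eligible(records: pd.DataFrame) -> pd.DataFrame:
    """Keep most-recent births within the previous five years, order preserved."""
    mask = records["is_most_recent_birth"].astype(bool) & (
        records["years_since_birth"].astype(float) <= 5.0
    )
    return records.loc[mask]


def recode_survey(records: pd.DataFrame) -> pd.DataFrame:
    """Append derived ``sba``/``anc4``/``pnc48`` columns (nullable Int8)."""
    out = records.copy()
    out["sba"] = pd.array(
        [derive_sba(v) for v in records["attendant_code"]], dtype="Int8"
    )
    out["anc4"] = pd.array(
        [derive_anc4(v) for v in records["anc_visits"]], dtype="Int8"
    )
    out["pnc48"] = pd.array(
        [
            derive_pnc48(h, p, f)
            for h, p, f in zip(
                records["pnc_hours"],
                records["pnc_provider"],
                records["facility_delivery"],
            )
        ],
        dtype="Int8",
    )
    return out


def apply_column_mapping(records: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Rename arbitrary source columns onto the raw schema (source -> schema)."""
    renamed = records.rename(columns=mapping)
    missing = [c for c in RAW_COLUMNS if c not in renamed.columns]
    if missing:
        raise KeyError(f"survey table missing required columns: {missing}")
    return renamed


def build_design(
    records: pd.DataFrame, coding: str = "ordinal"
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix for the coverage model.

    Two codings of education and wealth are supported:

    * ``"ordinal"`` (default): education as 0/1/2 levels and wealth as
      quintile steps 0..4, giving the compact six-parameter form
      (intercept, urban, education, wealth, age, parity).
    * ``"categorical"``: indicator sets with *no education* and quintile 1 as
      reference categories.

    Maternal age and parity are centered and scaled by the sample mean/sd.
    """
    urban = records["urban"].astype(bool).to_numpy(dtype=float)
    edu = records["education"].map({k: i for i, k in enumerate(EDUCATION_LEVELS)})
    if edu.isna().any():
        bad = sorted(set(records["education"]) - set(EDUCATION_LEVELS))
        raise ValueError(f"unknown education levels: {bad}")
    edu = edu.to_numpy(dtype=float)
    wealth = records["wealth_quintile"].to_numpy(dtype=float)
    if np.any((wealth < 1) | (wealth > 5)):
        raise ValueError("wealth_quintile must lie in 1..5")
    age = _standardize(records["maternal_age"].to_numpy(dtype=float))
    parity = _standardize(records["parity"].to_numpy(dtype=float))
    n = len(records)
    ones = np.ones(n)
    if coding == "ordinal":
        cols = [ones, urban, edu, wealth - 1.0, age, parity]
        names = ["intercept", "urban", "education", "wealth", "age_std", "parity_std"]
    elif coding == "categorical":
        cols = [ones, urban, (edu == 1).astype(float), (edu == 2).astype(float)]
        names = ["intercept", "urban", "edu_primary", "edu_secondary+"]
        for q in (2, 3, 4, 5):
            cols.append((wealth == q).astype(float))
            names.append(f"wealth_q{q}")
        cols += [age, parity]
        names += ["age_std", "parity_std"]
    else:
        raise ValueError(f"unknown covariate coding {coding!r}")
    logger.debug("design coding=%s columns=%s", coding, names)
    return np.column_stack(cols), names


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd
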