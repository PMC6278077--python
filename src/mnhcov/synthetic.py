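"""DHS-like synthetic surveys generated from known model parameters.

The generator emulates the structure of geolocated cluster surveys: districts
on a contiguity graph, clusters nested in districts with confidentiality
displacement of reported coordinates (up to 2 km urban / 5 km rural), and
women nested in clusters.  Binary service outcomes are drawn from the same
BYM-2 logistic model the package fits, so parameter recovery, inequality
indices, and out-of-sample validation can all be tested against known truth.

Raw survey fields (attendant code, visit counts, postnatal timing) are
back-filled so the recode step recovers the simulated binaries exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import Point

from .bym import IcarStructure, draw_scaled_icar, icar_precision
from .geography import ClusterLocation, DistrictGraph
from .recode import EDUCATION_LEVELS, build_design

#: Fixed effects used throughout the package's simulation studies
#: (ordinal coding: intercept, urban, education, wealth, age, parity).
DEFAULT_BETA = np.array([-0.5, 0.6, 0.4, 0.2, 0.1, -0.1])


@dataclass
class CovariateConfig:
    """Simple marginal laws for the simulated covariates.

    Age is uniform over the reproductive range 15-49; parity is a
    zero-truncated Poisson (every sampled woman has had a birth); wealth
    quintiles are uniform with an optional tilt toward higher quintiles in
    urban clusters; education is categorical over none/primary/secondary+.
    """

    age_min: float = 15.0
    age_max: float = 49.0
    parity_rate: float = 2.5
    education_probs: tuple[float, float, float] = (0.25, 0.5, 0.25)
    wealth_urban_tilt: float = 0.0
    coding: str = "ordinal"


@dataclass
class TruthRecord:
    """Ground truth behind one simulated survey."""

    beta: np.ndarray
    sigma_b: float
    phi: float
    seed: int
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    district_ids: tuple[str, ...] = ()
    beta_names: list[str] = field(default_factory=list)
    coding: str = "ordinal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be non-negative")
        self.beta = np.asarray(self.beta, dtype=float)

    @property
    def b(self) -> np.ndarray:
        """Realized combined district effect sigma_b (sqrt(1-phi) v + sqrt(phi) u)."""
        if self.u is None or self.v is None:
            raise ValueError("spatial effects not realized yet")
        return self.sigma_b * (
            np.sqrt(1.0 - self.phi) * self.v + np.sqrt(self.phi) * self.u
        )

    def to_json(self, path: str | Path) -> None:
        obj = {
            "beta": self.beta.tolist(),
            "sigma_b": self.sigma_b,
            "phi": self.phi,
            "seed": self.seed,
            "u": None if self.u is None else self.u.tolist(),
            "v": None if self.v is None else self.v.tolist(),
            "district_ids": list(self.district_ids),
            "beta_names": self.beta_names,
            "coding": self.coding,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        obj = json.loads(Path(path).read_text())
        return cls(
            beta=np.array(obj["beta"]),
            sigma_b=obj["sigma_b"],
            phi=obj["phi"],
            seed=obj["seed"],
            u=None if obj["u"] is None else np.array(obj["u"]),
            v=None if obj["v"] is None else np.array(obj["v"]),
            district_ids=tuple(obj["district_ids"]),
            beta_names=list(obj["beta_names"]),
            coding=obj["coding"],
        )


def realize_truth(
    graph: DistrictGraph,
    beta: Sequence[float] = DEFAULT_BETA,
    sigma_b: float = 0.8,
    phi: float = 0.6,
    seed: int = 0,
    structure: IcarStructure | None = None,
) -> TruthRecord:
    """Draw the district random effects for a truth record.

    ``u`` comes from the scaled ICAR (sum-to-zero within each component,
    islands at 0), ``v`` iid standard normal.
    """
    structure = structure or icar_precision(graph)
    rng = np.random.default_rng(seed)
    u = draw_scaled_icar(structure, rng)
    v = rng.standard_normal(graph.n)
    return TruthRecord(
        beta=np.asarray(beta, dtype=float),
        sigma_b=sigma_b,
        phi=phi,
        seed=seed,
        u=u,
        v=v,
        district_ids=graph.district_ids,
    )


def _uniform_in_polygon(poly, rng: np.random.Generator) -> tuple[float, float]:
    minx, miny, maxx, maxy = poly.bounds
    while True:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if poly.covers(Point(x, y)):
            return x, y


def generate_clusters(
    graph: DistrictGraph,
    clusters_per_district: int,
    urban_fraction: float = 0.3,
    seed: int = 0,
    urban_displacement_m: float = 2000.0,
    rural_displacement_m: float = 5000.0,
) -> list[ClusterLocation]:
    """Sample cluster locations with confidentiality displacement.

    True points are uniform within each district polygon; reported coordinates
    are displaced a uniform distance (up to 2 km urban / 5 km rural) in a
    uniform direction.  ``assigned_district`` holds the *generating* district;
    re-linking on the displaced coordinates may legitimately disagree near
    borders, which is exactly the error the buffer protocol flags.
    """
    if graph.polygons is None:
        raise ValueError("graph must carry polygons to place clusters")
    if clusters_per_district < 1:
        raise ValueError("clusters_per_district must be at least 1")
    rng = np.random.default_rng(seed)
    out: list[ClusterLocation] = []
    for d in graph.district_ids:
        poly = graph.polygons[d]
        for k in range(clusters_per_district):
            x, y = _uniform_in_polygon(poly, rng)
            urban = bool(rng.uniform() < urban_fraction)
            radius = urban_displacement_m if urban else rural_displacement_m
            dist = radius * rng.uniform()
            theta = rng.uniform(0.0, 2.0 * np.pi)
            out.append(
                ClusterLocation(
                    cluster_id=f"{d}_c{k:03d}",
                    x=x + dist * np.cos(theta),
                    y=y + dist * np.sin(theta),
                    urban=urban,
                    assigned_district=d,
                    ambiguous=False,
                    true_x=x,
                    true_y=y,
                )
            )
    return out


def _truncated_poisson(rate: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson(rate) conditioned on >= 1, by resampling the zeros."""
    draws = rng.poisson(rate, size=size)
    while True:
        zeros = draws == 0
        if not zeros.any():
            return draws
        draws[zeros] = rng.poisson(rate, size=int(zeros.sum()))


def generate_survey(
    graph: DistrictGraph,
    clusters: Sequence[ClusterLocation],
    women_per_cluster: int,
    truth: TruthRecord,
    covariates: CovariateConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate a raw per-woman survey table from the logistic truth.

    Outcomes for the three services are independent Bernoulli draws from the
    same linear predictor x'beta + b_district (they share the truth's fixed
    and spatial effects but not their noise).  Raw fields are back-filled so
    the recode step reproduces the simulated binaries exactly: SBA=1 maps to
    a nurse attendant, ANC4=1 to 4 visits (else 2), PNC48=1 to a nurse
    check-up at 24 h (else 72 h), and the facility flag mirrors PNC48.
    """
    cov = covariates or CovariateConfig()
    if women_per_cluster < 1:
        raise ValueError("women_per_cluster must be at least 1")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if truth.u is None or truth.v is None:
        truth = realize_truth(
            graph, truth.beta, truth.sigma_b, truth.phi, seed=truth.seed
        )
    n = len(clusters) * women_per_cluster
    cluster_ids = np.repeat([c.cluster_id for c in clusters], women_per_cluster)
    urban = np.repeat([c.urban for c in clusters], women_per_cluster)
    district = np.repeat([c.assigned_district for c in clusters], women_per_cluster)
    cx = np.repeat([c.x for c in clusters], women_per_cluster)
    cy = np.repeat([c.y for c in clusters], women_per_cluster)

    age = rng.uniform(cov.age_min, cov.age_max, size=n)
    parity = _truncated_poisson(cov.parity_rate, n, rng)
    edu = rng.choice(EDUCATION_LEVELS, size=n, p=np.asarray(cov.education_probs))
    # optional urban tilt: shift urban women's quintile distribution upward
    base_q = rng.integers(1, 6, size=n)
    if cov.wealth_urban_tilt > 0:
        bump = rng.uniform(size=n) < cov.wealth_urban_tilt
        base_q = np.where(urban & bump, np.minimum(base_q + 1, 5), base_q)
    df = pd.DataFrame(
        {
            "woman_id": [f"w{i:06d}" for i in range(n)],
            "cluster_id": cluster_ids,
            "district_id": district,
            "x": cx,
            "y": cy,
            "years_since_birth": rng.uniform(0.0, 5.0, size=n),
            "is_most_recent_birth": True,
            "urban": urban,
            "education": edu,
            "wealth_quintile": base_q,
            "maternal_age": age,
            "parity": parity,
        }
    )
    X, names = build_design(df, cov.coding)
    if X.shape[1] != len(truth.beta):
        raise ValueError(
            f"truth.beta has length {len(truth.beta)} but the {cov.coding} "
            f"design has {X.shape[1]} columns"
        )
    truth.beta_names = names
    truth.coding = cov.coding
    jdx = np.array([graph.index(d) for d in district])
    eta = X @ truth.beta + truth.b[jdx]
    prob = expit(eta)
    sba = rng.binomial(1, prob)
    anc4 = rng.binomial(1, prob)
    pnc48 = rng.binomial(1, prob)

    df["attendant_code"] = np.where(sba == 1, "nurse", "trad_attendant")
    df["anc_visits"] = np.where(anc4 == 1, 4, 2)
    df["pnc_hours"] = np.where(pnc48 == 1, 24.0, 72.0)
    df["pnc_provider"] = "nurse"
    df["facility_delivery"] = pnc48 == 1
    # keep the simulated binaries alongside for truth-based checks
    df["true_sba"] = sba
    df["true_anc4"] = anc4
    df["true_pnc48"] = pnc48
    return df, truth
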