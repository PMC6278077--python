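"""Bayesian hierarchical logistic model with BYM-2 district random effects.

Model
-----
For woman *i* in district *j*,

    logit(p_ij) = x_ij' beta + b_j
    b_j = sigma_b * ( sqrt(1 - phi) * v_j + sqrt(phi) * u_j )

where ``v`` is an iid standard-normal (unstructured) effect, ``u`` follows the
variance-scaled intrinsic CAR (ICAR) prior on the district contiguity graph
with a hard sum-to-zero constraint per connected component, ``sigma_b >= 0``
is the marginal standard deviation of the combined effect and ``phi`` in
[0, 1] is the structured share of its variance (the BYM-2 parametrization).
Islands (components of size one) have ``u = 0`` and rely on ``v`` alone.

Priors (weakly informative, configurable): beta_k ~ N(0, 1000),
sigma_b ~ half-normal(1), phi ~ uniform(0, 1).

Inference is an adaptive Metropolis-within-Gibbs sampler: a joint random-walk
update of beta preconditioned by the IRLS covariance of the plain logistic
fit, graph-colored single-site updates of u (districts of one color are
conditionally independent given the rest), simultaneous independent updates
of v, and scalar random-walk updates of log sigma_b and logit phi.  The
sum-to-zero constraint on u is re-imposed by recentering within each
component at every iteration.  Adaptation runs during warmup only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import arviz as az
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .geography import DistrictGraph
from .recode import build_design

logger = logging.getLogger(__name__)

_Z975 = 1.959963984540054


class SeparationError(RuntimeError):
    """The outcome is perfectly separated or has a single response class."""


@dataclass
class ModelSpec:
    """Outcome, covariate coding, and prior settings for one model."""

    outcome: str
    coding: str = "ordinal"
    sd_beta: float = float(np.sqrt(1000.0))  # N(0, 1000) fixed-effect prior
    sigma_b_scale: float = 1.0  # half-normal scale for sigma_b
    # phi prior is uniform(0, 1)

    def __post_init__(self) -> None:
        if self.sd_beta <= 0 or self.sigma_b_scale <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class McmcSettings:
    chains: int = 4
    iters: int = 2500
    warmup: int = 1000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.warmup < self.iters:
            raise ValueError("warmup must lie in [0, iters)")


@dataclass
class IcarStructure:
    """Scaled ICAR precision for a district graph.

    ``Q = D - W`` with D the diagonal degree matrix and W the 0/1 adjacency.
    ``scaling`` holds, per node, the factor *s* of its component such that the
    generalized variance of the s-scaled ICAR has geometric-mean marginal
    variance 1 (islands carry 0).  ``components`` are index arrays into the
    node order; ``islands`` lists degree-isolated district ids.
    """

    district_ids: tuple[str, ...]
    Q: sp.csr_matrix
    W: sp.csr_matrix
    degrees: np.ndarray
    scaling: np.ndarray
    components: tuple[np.ndarray, ...]
    islands: tuple[str, ...]
    # eigen-decompositions of non-island component blocks, for simulation:
    # list of (indices, nonzero eigenvalues, matching eigenvectors)
    comp_eig: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=list, repr=False
    )

    @property
    def n(self) -> int:
        return len(self.district_ids)


def icar_precision(graph: DistrictGraph) -> IcarStructure:
    """Build Q = D - W and the per-component BYM-2 variance scaling."""
    if graph.n == 0:
        raise ValueError("empty district graph")
    W = graph.adjacency_matrix()
    degrees = np.asarray(W.sum(axis=1)).ravel()
    Q = sp.diags(degrees) - W
    idx = {d: i for i, d in enumerate(graph.district_ids)}
    components = tuple(
        np.array(sorted(idx[d] for d in comp), dtype=int) for comp in graph.components
    )
    scaling = np.zeros(graph.n)
    islands: list[str] = []
    comp_eig = []
    Qd = None
    for comp in components:
        if len(comp) == 1:
            islands.append(graph.district_ids[comp[0]])
            continue
        if Qd is None:
            Qd = Q.toarray()
        Qc = Qd[np.ix_(comp, comp)]
        vals, vecs = np.linalg.eigh(Qc)
        # one zero eigenvalue per connected component
        nonzero = vals > vals.max() * 1e-10
        vnz, enz = vals[nonzero], vecs[:, nonzero]
        marg_var = np.einsum("ik,k,ik->i", enz, 1.0 / vnz, enz)
        s = float(np.exp(np.mean(np.log(marg_var))))
        scaling[comp] = s
        comp_eig.append((comp, vnz, enz))
    return IcarStructure(
        district_ids=graph.district_ids,
        Q=sp.csr_matrix(Q),
        W=W,
        degrees=degrees,
        scaling=scaling,
        components=components,
        islands=tuple(islands),
        comp_eig=comp_eig,
    )


def draw_scaled_icar(structure: IcarStructure, rng: np.random.Generator) -> np.ndarray:
    """One realization of the scaled ICAR effect (sum-to-zero per component).

    Drawn in the spectral basis of each component block: coordinates on the
    non-null eigenvectors are independent N(0, 1/(s * lambda_k)).  Islands
    receive exactly 0.
    """
    u = np.zeros(structure.n)
    for comp, vals, vecs in structure.comp_eig:
        s = structure.scaling[comp[0]]
        z = rng.standard_normal(len(vals))
        u[comp] = vecs @ (z / np.sqrt(s * vals))
    return u


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Sum of Bernoulli log-likelihoods, stable for |eta| up to ~700."""
    return float(np.sum(_loglik_obs(y, eta)))


def _loglik_obs(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # y*eta - log(1+exp(eta)) == -log(1+exp(-eta)) for y=1, -log(1+exp(eta)) for y=0
    sign = np.where(y == 1, -1.0, 1.0)
    return -np.logaddexp(0.0, sign * eta)


def log_likelihood(
    beta: np.ndarray,
    b: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    district_index: np.ndarray,
) -> float:
    """Bernoulli log-likelihood of the model at (beta, b)."""
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    eta = X @ np.asarray(beta, dtype=float) + np.asarray(b, dtype=float)[district_index]
    return bernoulli_loglik(y, eta)


@dataclass
class PosteriorFit:
    """Retained MCMC draws plus summaries, diagnostics, and DIC.

    ``draws`` maps parameter block names (``beta``, ``u``, ``v``, ``b``,
    ``sigma_b``, ``phi``) to chain-major arrays of shape (chains, draws, ...).
    """

    outcome: str
    district_ids: tuple[str, ...]
    beta_names: list[str]
    draws: dict[str, np.ndarray]
    summaries: pd.DataFrame
    diagnostics: pd.DataFrame
    dic: float
    dic_pd: float
    seed: int
    warnings: list[str] = field(default_factory=list)
    coding: str = "ordinal"

    def flat(self, name: str) -> np.ndarray:
        """Draws of one block with chains stacked: (chains*draws, ...)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def n_draws(self) -> int:
        return self.draws["beta"].shape[0] * self.draws["beta"].shape[1]

    # -- serialization ----------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Write draws as one CSV per block plus a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        names = {
            "beta": self.beta_names,
            "u": list(self.district_ids),
            "v": list(self.district_ids),
            "b": list(self.district_ids),
            "sigma_b": ["sigma_b"],
            "phi": ["phi"],
        }
        chains, ndraw = self.draws["beta"].shape[:2]
        for block, arr in self.draws.items():
            flat = arr.reshape(chains * ndraw, -1)
            pd.DataFrame(flat, columns=names[block]).to_csv(
                outdir / f"draws_{block}.csv", index=False
            )
        self.summaries.to_csv(outdir / "summaries.csv")
        self.diagnostics.to_csv(outdir / "diagnostics.csv")
        manifest = {
            "outcome": self.outcome,
            "district_ids": list(self.district_ids),
            "beta_names": self.beta_names,
            "chains": chains,
            "draws_per_chain": ndraw,
            "dic": self.dic,
            "dic_pd": self.dic_pd,
            "seed": self.seed,
            "warnings": self.warnings,
            "coding": self.coding,
        }
        (outdir / "fit.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    @classmethod
    def load(cls, outdir: str | Path) -> "PosteriorFit":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "fit.json").read_text())
        chains = manifest["chains"]
        ndraw = manifest["draws_per_chain"]
        draws = {}
        for block in ("beta", "u", "v", "b", "sigma_b", "phi"):
            flat = pd.read_csv(outdir / f"draws_{block}.csv").to_numpy()
            if block in ("sigma_b", "phi"):
                draws[block] = flat.reshape(chains, ndraw)
            else:
                draws[block] = flat.reshape(chains, ndraw, -1)
        return cls(
            outcome=manifest["outcome"],
            district_ids=tuple(manifest["district_ids"]),
            beta_names=manifest["beta_names"],
            draws=draws,
            summaries=pd.read_csv(outdir / "summaries.csv", index_col=0),
            diagnostics=pd.read_csv(outdir / "diagnostics.csv", index_col=0),
            dic=manifest["dic"],
            dic_pd=manifest["dic_pd"],
            seed=manifest["seed"],
            warnings=list(manifest["warnings"]),
            coding=manifest["coding"],
        )


def _prepare_outcome(
    spec: ModelSpec, data: pd.DataFrame, structure: IcarStructure
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    if spec.outcome not in data.columns:
        raise KeyError(f"data has no outcome column {spec.outcome!r}")
    rows = data.loc[data[spec.outcome].notna()]
    if len(rows) == 0:
        raise SeparationError(f"outcome {spec.outcome!r}: no usable observations")
    y = rows[spec.outcome].astype(int).to_numpy()
    if y.min() == y.max():
        raise SeparationError(
            f"outcome {spec.outcome!r} has a single response class "
            f"(all {int(y[0])}); the model is not identified"
        )
    X, names = build_design(rows, spec.coding)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient; check covariate coding")
    idx = {d: i for i, d in enumerate(structure.district_ids)}
    try:
        dix = rows["district_id"].map(idx).astype(int).to_numpy()
    except (ValueError, TypeError):
        unknown = sorted(set(rows["district_id"]) - set(idx))
        raise KeyError(f"records reference districts absent from the graph: {unknown}")
    return y, names, X, dix


def fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    structure: IcarStructure,
    mcmc: McmcSettings | None = None,
) -> PosteriorFit:
    """Sample the posterior of the BYM-2 logistic model.

    ``data`` is an analysis-ready table (one row per woman) holding the
    covariate columns, ``district_id``, and the binary outcome named by
    ``spec.outcome`` (rows with a missing outcome are dropped for this model
    only).  Returns retained post-warmup draws with split-Rhat/ESS
    diagnostics and DIC; a warning is attached when any fixed-effect Rhat
    exceeds 1.05.
    """
    mcmc = mcmc or McmcSettings()
    y, names, X, dix = _prepare_outcome(spec, data, structure)

    # IRLS initialization / preconditioner from the plain logistic fit
    from .inequality import logistic_irls

    p = X.shape[1]
    try:
        irls = logistic_irls(X, y)
        beta0, chol = irls.coef, np.linalg.cholesky(
            irls.cov + 1e-10 * np.eye(p)
        )
    except Exception:  # fall back to a unit preconditioner
        beta0, chol = np.zeros(p), np.eye(p) / np.sqrt(len(y))

    keep = (mcmc.iters - mcmc.warmup) // mcmc.thin
    chain_seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    blocks = {
        "beta": np.empty((mcmc.chains, keep, p)),
        "u": np.empty((mcmc.chains, keep, structure.n)),
        "v": np.empty((mcmc.chains, keep, structure.n)),
        "b": np.empty((mcmc.chains, keep, structure.n)),
        "sigma_b": np.empty((mcmc.chains, keep)),
        "phi": np.empty((mcmc.chains, keep)),
    }
    for c, ss in enumerate(chain_seeds):
        out = _run_chain(
            spec, y, X, dix, structure, mcmc, np.random.default_rng(ss), beta0, chol
        )
        for k, arr in out.items():
            blocks[k][c] = arr

    summaries, diagnostics = _summarize(blocks, names, structure.district_ids)
    warnings = []
    rhat_beta = diagnostics.loc[
        [f"beta[{n}]" for n in names], "rhat"
    ].to_numpy()
    if np.any(rhat_beta > 1.05):
        bad = [n for n, r in zip(names, rhat_beta) if r > 1.05]
        warnings.append(
            f"split-Rhat > 1.05 for fixed effects {bad}; chains may not have mixed"
        )
        logger.warning(warnings[-1])
    fit_obj = PosteriorFit(
        outcome=spec.outcome,
        district_ids=structure.district_ids,
        beta_names=names,
        draws=blocks,
        summaries=summaries,
        diagnostics=diagnostics,
        dic=np.nan,
        dic_pd=np.nan,
        seed=mcmc.seed,
        warnings=warnings,
        coding=spec.coding,
    )
    fit_obj.dic, fit_obj.dic_pd = dic_from_draws(
        fit_obj.flat("beta"), fit_obj.flat("b"), X, y, dix
    )
    return fit_obj


def _run_chain(
    spec: ModelSpec,
    y: np.ndarray,
    X: np.ndarray,
    dix: np.ndarray,
    structure: IcarStructure,
    mcmc: McmcSettings,
    rng: np.random.Generator,
    beta0: np.ndarray,
    chol: np.ndarray,
) -> dict[str, np.ndarray]:
    n, p = X.shape
    J = structure.n
    keep = (mcmc.iters - mcmc.warmup) // mcmc.thin

    # graph coloring so that u sites of one color are conditionally independent
    g = nx.Graph()
    g.add_nodes_from(range(J))
    W = structure.W.tocoo()
    g.add_edges_from(zip(W.row.tolist(), W.col.tolist()))
    coloring = nx.greedy_color(g, strategy="largest_first")
    island_idx = {structure.district_ids.index(d) for d in structure.islands}
    colors: list[np.ndarray] = []
    for color in sorted(set(coloring.values())):
        nodes = np.array(
            sorted(j for j, c in coloring.items() if c == color and j not in island_idx),
            dtype=int,
        )
        if len(nodes) > 0:
            colors.append(nodes)
    # observations grouped by district for fast local likelihood deltas
    order = np.argsort(dix, kind="stable")
    dix_sorted = dix[order]
    bounds = np.searchsorted(dix_sorted, np.arange(J + 1))
    obs_of = [order[bounds[j] : bounds[j + 1]] for j in range(J)]
    color_obs = [np.concatenate([obs_of[j] for j in nodes]) for nodes in colors]
    color_pos = [
        np.repeat(np.arange(len(nodes)), [len(obs_of[j]) for j in nodes])
        for nodes in colors
    ]
    nonisland = np.array([j for j in range(J) if j not in island_idx], dtype=int)
    comps = [c for c in structure.components if len(c) > 1]
    # free dimension of u on the per-component sum-to-zero subspace
    d_u = sum(len(c) - 1 for c in comps)
    has_intercept = np.allclose(X[:, 0], 1.0)

    sgn = np.where(y == 1, -1.0, 1.0)
    s_node = structure.scaling
    deg = structure.degrees
    Wcsr = structure.W

    # state
    beta = beta0.copy()
    u = np.zeros(J)
    v = np.zeros(J)
    sigma = 0.5
    phi = 0.5
    ls, lp = np.log(sigma), 0.0

    def b_of(u_, v_, sigma_, phi_):
        return sigma_ * (np.sqrt(1.0 - phi_) * v_ + np.sqrt(phi_) * u_)

    b = b_of(u, v, sigma, phi)
    base = X @ beta
    eta = base + b[dix]
    ll_obs = -np.logaddexp(0.0, sgn * eta)
    sd2 = spec.sd_beta**2
    s0_2 = spec.sigma_b_scale**2

    # adaptive scales (log), frozen after warmup
    lstep_beta = np.log(2.4 / np.sqrt(p))
    lstep_u = np.full(J, np.log(0.5))
    lstep_v = np.full(J, np.log(0.5))
    lstep_s = np.log(0.5)
    lstep_p = np.log(0.8)
    lstep_t = np.log(0.25)  # intercept/v translation
    lstep_r = np.log(0.4)  # sigma/(u,v) rescale
    lstep_q = np.log(0.8)  # phi/(u,v) rebalance

    out = {
        "beta": np.empty((keep, p)),
        "u": np.empty((keep, J)),
        "v": np.empty((keep, J)),
        "b": np.empty((keep, J)),
        "sigma_b": np.empty(keep),
        "phi": np.empty(keep),
    }
    k = 0
    for t in range(mcmc.iters):
        # two full kernel sweeps per recorded iteration sharpen mixing
        for _ in range(2):
            adapting = t < mcmc.warmup
            gamma = 1.0 / (t + 10.0) ** 0.6

            # ---- beta: joint preconditioned random walk (several sweeps) ------
            for _ in range(3):
                dbeta = np.exp(lstep_beta) * (chol @ rng.standard_normal(p))
                beta_p = beta + dbeta
                eta_p = eta + X @ dbeta
                ll_p = -np.logaddexp(0.0, sgn * eta_p)
                dprior = -0.5 * (beta_p @ beta_p - beta @ beta) / sd2
                logr = ll_p.sum() - ll_obs.sum() + dprior
                acc = np.log(rng.uniform()) < logr
                if acc:
                    beta, eta, ll_obs = beta_p, eta_p, ll_p
                    base = base + X @ dbeta
                if adapting:
                    lstep_beta += gamma * (float(acc) - 0.234)

            # ---- u: colored single-site Metropolis ----------------------------
            if len(nonisland) > 0:
                for nodes, oidx, opos in zip(colors, color_obs, color_pos):
                    du = np.exp(lstep_u[nodes]) * rng.standard_normal(len(nodes))
                    u_new = u[nodes] + du
                    Wu = Wcsr @ u
                    dpri = s_node[nodes] * (
                        -0.5 * deg[nodes] * (u_new**2 - u[nodes] ** 2)
                        + (u_new - u[nodes]) * Wu[nodes]
                    )
                    b_new = sigma * (np.sqrt(1.0 - phi) * v[nodes] + np.sqrt(phi) * u_new)
                    eta_new = base[oidx] + b_new[opos]
                    ll_new = -np.logaddexp(0.0, sgn[oidx] * eta_new)
                    dll = np.bincount(opos, ll_new - ll_obs[oidx], minlength=len(nodes))
                    acc_m = np.log(rng.uniform(size=len(nodes))) < dpri + dll
                    if acc_m.any():
                        u[nodes[acc_m]] = u_new[acc_m]
                        b[nodes[acc_m]] = b_new[acc_m]
                        upd = acc_m[opos]
                        ll_obs[oidx[upd]] = ll_new[upd]
                        eta[oidx[upd]] = eta_new[upd]
                    if adapting:
                        lstep_u[nodes] += gamma * (acc_m.astype(float) - 0.44)
                # hard sum-to-zero per component, then refresh caches
                for comp in comps:
                    u[comp] -= u[comp].mean()
                b = b_of(u, v, sigma, phi)
                eta = base + b[dix]
                ll_obs = -np.logaddexp(0.0, sgn * eta)

            # ---- v: simultaneous independent Metropolis -----------------------
            dv = np.exp(lstep_v) * rng.standard_normal(J)
            v_new = v + dv
            b_new = b_of(u, v_new, sigma, phi)
            eta_new = base + b_new[dix]
            ll_new = -np.logaddexp(0.0, sgn * eta_new)
            dll = np.bincount(dix, ll_new - ll_obs, minlength=J)
            dpri = -0.5 * (v_new**2 - v**2)
            acc_m = np.log(rng.uniform(size=J)) < dll + dpri
            if acc_m.any():
                v[acc_m] = v_new[acc_m]
                b[acc_m] = b_new[acc_m]
                upd = acc_m[dix]
                eta[upd] = eta_new[upd]
                ll_obs[upd] = ll_new[upd]
            if adapting:
                lstep_v += gamma * (acc_m.astype(float) - 0.44)

            # ---- sigma_b: random walk on the log scale ------------------------
            ls_p = ls + np.exp(lstep_s) * rng.standard_normal()
            sigma_p = np.exp(ls_p)
            b_new = b_of(u, v, sigma_p, phi)
            eta_new = base + b_new[dix]
            ll_new = -np.logaddexp(0.0, sgn * eta_new)
            # half-normal prior plus log-scale Jacobian
            dpri = -(sigma_p**2 - sigma**2) / (2.0 * s0_2) + (ls_p - ls)
            acc = np.log(rng.uniform()) < ll_new.sum() - ll_obs.sum() + dpri
            if acc:
                ls, sigma, b, eta, ll_obs = ls_p, sigma_p, b_new, eta_new, ll_new
            if adapting:
                lstep_s += gamma * (float(acc) - 0.44)

            # ---- phi: random walk on the logit scale --------------------------
            lp_p = lp + np.exp(lstep_p) * rng.standard_normal()
            phi_p = 1.0 / (1.0 + np.exp(-lp_p))
            b_new = b_of(u, v, sigma, phi_p)
            eta_new = base + b_new[dix]
            ll_new = -np.logaddexp(0.0, sgn * eta_new)
            # uniform prior on phi -> logit-scale Jacobian log(phi (1-phi))
            dpri = np.log(phi_p * (1.0 - phi_p)) - np.log(phi * (1.0 - phi))
            acc = np.log(rng.uniform()) < ll_new.sum() - ll_obs.sum() + dpri
            if acc:
                lp, phi, b, eta, ll_obs = lp_p, phi_p, b_new, eta_new, ll_new
            if adapting:
                lstep_p += gamma * (float(acc) - 0.44)

            # ---- likelihood-invariant interweaving moves -----------------------
            # These leave eta (hence the likelihood) fixed and move along the
            # directions where the centered and non-centered parametrizations
            # disagree; only prior ratios and map Jacobians enter the MH ratio.

            # (a) translate the intercept against a constant shift of v
            sv = sigma * np.sqrt(1.0 - phi)
            if has_intercept and sv > 1e-10:
                eps = np.exp(lstep_t) * rng.standard_normal()
                b0_new = beta[0] + eps
                v_new = v - eps / sv
                dlp = (
                    -0.5 * (b0_new**2 - beta[0] ** 2) / sd2
                    - 0.5 * (v_new @ v_new - v @ v)
                )
                acc = np.log(rng.uniform()) < dlp
                if acc:
                    beta = beta.copy()
                    beta[0] = b0_new
                    v = v_new
                    base = base + eps
                    b = b - eps
                if adapting:
                    lstep_t += gamma * (float(acc) - 0.44)

            # (b) rescale sigma_b against (u, v); b is untouched
            eps = np.exp(lstep_r) * rng.standard_normal()
            c = np.exp(-eps)
            sigma_new = sigma * np.exp(eps)
            quad_u = float((s_node * u) @ (structure.Q @ u))
            dlp = (
                -(sigma_new**2 - sigma**2) / (2.0 * s0_2)
                + eps  # log-scale Jacobian of the sigma prior
                - 0.5 * quad_u * (c * c - 1.0)
                - 0.5 * float(v @ v) * (c * c - 1.0)
                - eps * (d_u + J)  # Jacobian of (u, v) -> c (u, v)
            )
            acc = np.log(rng.uniform()) < dlp
            if acc:
                sigma, ls = sigma_new, ls + eps
                u = u * c
                v = v * c
            if adapting:
                lstep_r += gamma * (float(acc) - 0.44)

            # (c) rebalance phi against (u, v); b is untouched
            eps = np.exp(lstep_q) * rng.standard_normal()
            lp_new = lp + eps
            phi_new = 1.0 / (1.0 + np.exp(-lp_new))
            if 0.0 < phi_new < 1.0 and 0.0 < phi < 1.0:
                cu = np.sqrt(phi / phi_new)
                cv = np.sqrt((1.0 - phi) / (1.0 - phi_new))
                quad_u = float((s_node * u) @ (structure.Q @ u))
                dlp = (
                    np.log(phi_new * (1.0 - phi_new)) - np.log(phi * (1.0 - phi))
                    - 0.5 * quad_u * (cu * cu - 1.0)
                    - 0.5 * float(v @ v) * (cv * cv - 1.0)
                    + d_u * np.log(cu)
                    + J * np.log(cv)
                )
                acc = np.log(rng.uniform()) < dlp
                if acc:
                    phi, lp = phi_new, lp_new
                    u = u * cu
                    v = v * cv
                if adapting:
                    lstep_q += gamma * (float(acc) - 0.44)

        if t >= mcmc.warmup and (t - mcmc.warmup) % mcmc.thin == 0 and k < keep:
            out["beta"][k] = beta
            out["u"][k] = u
            out["v"][k] = v
            out["b"][k] = b
            out["sigma_b"][k] = sigma
            out["phi"][k] = phi
            k += 1
    return out


def _summarize(
    blocks: dict[str, np.ndarray],
    beta_names: list[str],
    district_ids: tuple[str, ...],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-scalar posterior summaries plus split-Rhat / ESS diagnostics."""
    scalars: dict[str, np.ndarray] = {}
    for i, nm in enumerate(beta_names):
        scalars[f"beta[{nm}]"] = blocks["beta"][:, :, i]
    for i, d in enumerate(district_ids):
        scalars[f"u[{d}]"] = blocks["u"][:, :, i]
        scalars[f"v[{d}]"] = blocks["v"][:, :, i]
        scalars[f"b[{d}]"] = blocks["b"][:, :, i]
    scalars["sigma_b"] = blocks["sigma_b"]
    scalars["phi"] = blocks["phi"]

    rows = {}
    for name, arr in scalars.items():
        flat = arr.reshape(-1)
        rows[name] = {
            "mean": flat.mean(),
            "sd": flat.std(ddof=1) if flat.size > 1 else 0.0,
            "q025": np.quantile(flat, 0.025),
            "median": np.quantile(flat, 0.5),
            "q975": np.quantile(flat, 0.975),
        }
    summaries = pd.DataFrame.from_dict(rows, orient="index")

    idata = az.from_dict(posterior={k: v for k, v in scalars.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    diagnostics = pd.DataFrame(
        {
            "rhat": {k: float(rhat[k].values) for k in scalars},
            "ess": {k: float(ess[k].values) for k in scalars},
        }
    ).loc[list(scalars)]
    return summaries, diagnostics


def dic_from_draws(
    beta_draws: np.ndarray,
    b_draws: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    district_index: np.ndarray,
    chunk: int = 256,
) -> tuple[float, float]:
    """Deviance Information Criterion from posterior draws.

    D(theta) = -2 log p(y | theta); pD = mean_m D(theta_m) - D(theta_bar)
    with theta_bar the posterior mean (plug-in) of (beta, b);
    DIC = mean deviance + pD.
    """
    beta_draws = np.atleast_2d(np.asarray(beta_draws, dtype=float))
    b_draws = np.atleast_2d(np.asarray(b_draws, dtype=float))
    if beta_draws.shape[0] < 1:
        raise ValueError("need at least one posterior draw")
    y = np.asarray(y)
    dev = np.empty(beta_draws.shape[0])
    for start in range(0, beta_draws.shape[0], chunk):
        B = beta_draws[start : start + chunk]
        bb = b_draws[start : start + chunk]
        eta = X @ B.T + bb.T[district_index, :]
        sign = np.where(y == 1, -1.0, 1.0)[:, None]
        dev[start : start + len(B)] = 2.0 * np.logaddexp(0.0, sign * eta).sum(axis=0)
    mean_dev = float(dev.mean())
    dev_at_mean = -2.0 * log_likelihood(
        beta_draws.mean(axis=0), b_draws.mean(axis=0), X, y, district_index
    )
    pd_ = mean_dev - dev_at_mean
    return mean_dev + pd_, pd_


def compute_dic(fit: PosteriorFit, data: pd.DataFrame) -> tuple[float, float]:
    """Recompute (DIC, pD) for a fit against its analysis table."""
    rows = data.loc[data[fit.outcome].notna()]
    y = rows[fit.outcome].astype(int).to_numpy()
    X, _ = build_design(rows, fit.coding)
    idx = {d: i for i, d in enumerate(fit.district_ids)}
    dix = rows["district_id"].map(idx).astype(int).to_numpy()
    return dic_from_draws(fit.flat("beta"), fit.flat("b"), X, y, dix)
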