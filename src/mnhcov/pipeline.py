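"""End-to-end pipeline: recode -> link -> fit -> estimates -> inequality -> validation.

``run_pipeline`` sequences the whole analysis for one survey and writes a
manifest recording seeds, package versions, DIC per outcome, and every
artifact path.  The run is idempotent given fixed seeds.  On a stage failure
the stage's partially written artifacts are renamed with a ``.partial``
suffix and the error is re-raised with the stage name.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bym import McmcSettings, ModelSpec, fit, icar_precision
from .config import RunConfig
from .estimates import district_prevalence
from .geography import (
    ClusterLocation,
    link_clusters,
    read_adjacency,
    read_geojson,
)
from .inequality import inequality_report, write_inequality_report
from .recode import apply_column_mapping, filter_eligible, recode_survey
from .validation import validate_model

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seed(master: int, stage_index: int) -> int:
    # deterministic per-stage seeds below 2**31, recorded in the manifest
    return int((master * 1_000_003 + stage_index * 7919) % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by ``config``; returns the manifest."""
    outdir = Path(config.paths.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": {},
        "versions": {
            "mnhcov": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": json.loads(config.model_dump_json()),
        "artifacts": {},
        "dic": {},
        "warnings": {},
    }
    written: list[Path] = []

    def _fail(stage: str, exc: Exception):
        for p in written:
            if p.exists() and not p.name.endswith(".partial"):
                p.rename(p.with_name(p.name + ".partial"))
        raise PipelineError(stage, exc) from exc

    # -- recode ----------------------------------------------------------
    stage = "recode"
    try:
        df = pd.read_csv(config.paths.survey)
        if config.columns:
            df = apply_column_mapping(df, config.columns)
        df = filter_eligible(df)
        df = recode_survey(df)
        analysis_path = outdir / "analysis.csv"
        written = [analysis_path]
        df.to_csv(analysis_path, index=False)
        manifest["artifacts"]["analysis"] = str(analysis_path)
    except Exception as exc:
        _fail(stage, exc)

    # -- link ------------------------------------------------------------
    stage = "link"
    written = []
    try:
        if config.paths.boundaries is not None:
            graph = read_geojson(config.paths.boundaries)
            cl = (
                df[["cluster_id", "x", "y", "urban"]]
                .drop_duplicates("cluster_id")
                .itertuples(index=False)
            )
            clusters = [
                ClusterLocation(cluster_id=str(c.cluster_id), x=c.x, y=c.y, urban=bool(c.urban))
                for c in cl
            ]
            linked = link_clusters(
                clusters,
                graph,
                urban_buffer_m=config.linkage.urban_buffer_m,
                rural_buffer_m=config.linkage.rural_buffer_m,
            )
            assign = {c.cluster_id: c.assigned_district for c in linked}
            flag = {c.cluster_id: c.ambiguous for c in linked}
            df["district_id"] = df["cluster_id"].astype(str).map(assign)
            df["ambiguous"] = df["cluster_id"].astype(str).map(flag)
            n_drop = int(df["district_id"].isna().sum())
            if n_drop:
                logger.warning("%d records in unassigned clusters dropped", n_drop)
                df = df.loc[df["district_id"].notna()]
            if config.linkage.drop_ambiguous:
                df = df.loc[~df["ambiguous"]]
        else:
            graph = read_adjacency(config.paths.adjacency)
            if "district_id" not in df.columns:
                raise ValueError(
                    "adjacency-only run requires a district_id column in the survey"
                )
        linked_path = outdir / "linked.csv"
        written = [linked_path]
        df.to_csv(linked_path, index=False)
        manifest["artifacts"]["linked"] = str(linked_path)
    except Exception as exc:
        _fail(stage, exc)

    structure = icar_precision(graph)
    region_map = None
    if config.region_column is not None:
        region_map = (
            df.drop_duplicates("district_id")
            .set_index("district_id")[config.region_column]
            .astype(str)
            .to_dict()
        )

    # -- per-outcome stages ------------------------------------------------
    fits = {}
    for k, outcome in enumerate(config.outcomes):
        mcmc = McmcSettings(
            chains=config.mcmc.chains,
            iters=config.mcmc.iters,
            warmup=config.mcmc.warmup,
            thin=config.mcmc.thin,
            seed=_stage_seed(config.seed, 10 + k),
        )
        manifest["stage_seeds"][f"fit_{outcome}"] = mcmc.seed
        spec = ModelSpec(
            outcome=outcome,
            coding=config.coding,
            sd_beta=config.priors.sd_beta,
            sigma_b_scale=config.priors.sigma_b_scale,
        )
        stage = f"fit:{outcome}"
        try:
            fitted = fit(spec, df, structure, mcmc)
            fit_dir = outdir / f"fit_{outcome}"
            written = [fit_dir]
            fitted.save(fit_dir)
            fits[outcome] = fitted
            manifest["artifacts"][f"fit_{outcome}"] = str(fit_dir)
            manifest["dic"][outcome] = fitted.dic
            manifest["warnings"][outcome] = fitted.warnings
        except Exception as exc:
            _fail(stage, exc)

        stage = f"estimates:{outcome}"
        try:
            est = district_prevalence(fitted, df)
            est_path = outdir / f"estimates_{outcome}.csv"
            written = [est_path]
            est.to_csv(est_path)
            manifest["artifacts"][f"estimates_{outcome}"] = str(est_path)
        except Exception as exc:
            _fail(stage, exc)

        stage = f"inequality:{outcome}"
        try:
            report = inequality_report(est, df, region_map)
            ineq_path = outdir / f"inequality_{outcome}.json"
            written = [ineq_path]
            write_inequality_report(report, ineq_path)
            manifest["artifacts"][f"inequality_{outcome}"] = str(ineq_path)
        except Exception as exc:
            _fail(stage, exc)

        stage = f"validate:{outcome}"
        try:
            split_seed = _stage_seed(config.seed, 100 + k)
            manifest["stage_seeds"][f"validate_{outcome}"] = split_seed
            vmcmc = McmcSettings(
                chains=config.mcmc.chains,
                iters=config.mcmc.iters,
                warmup=config.mcmc.warmup,
                thin=config.mcmc.thin,
                seed=_stage_seed(config.seed, 200 + k),
            )
            report = validate_model(
                spec,
                df,
                structure,
                vmcmc,
                fraction=config.split.fraction,
                seed=split_seed,
                unit=config.split.unit,
                pseudo_r2_variant=config.metrics.pseudo_r2,
            )
            val_path = outdir / f"validation_{outcome}.json"
            written = [val_path]
            report.to_json(val_path)
            manifest["artifacts"][f"validation_{outcome}"] = str(val_path)
        except Exception as exc:
            _fail(stage, exc)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["artifacts"]["manifest"] = str(manifest_path)
    return manifest
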