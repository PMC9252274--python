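"""End-to-end orchestration: simulate -> connectome -> metrics -> stats -> nbs.

Each stage writes its outputs under the run directory and the run ends
with a provenance manifest (config hash, seed, package version, row
counts). Rerunning with the same config and seed reproduces every numeric
output; ``resume=True`` skips stages whose outputs already exist.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import macroarea_assign
from .config import PipelineConfig, config_hash
from .fc import compute_fc, sparsity_grid
from .inference import adjusted_sex_contrast, classify_amyloid, demographics_table
from .io import (
    read_fc_matrix,
    read_participants,
    read_timeseries,
    write_fc_matrix,
    write_json,
    write_participants,
    write_timeseries,
)
from .metrics import METRIC_NAMES, compute_metric_tables, zscore_metrics
from .nbs import macroarea_summary, nbs_permutation
from .synthetic import generate_cohort, generate_cohort_timeseries
from .fc import ROITimeSeries

logger = logging.getLogger(__name__)

STAGES = ("simulate", "connectome", "metrics", "stats", "nbs")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, resume: bool = False
) -> Path:
    """Run all stages on a synthetic cohort; returns the run directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    grid = sparsity_grid(config.sparsity_min, config.sparsity_max, config.sparsity_step)

    sessions_dir = out / "sessions"
    fc_dir = out / "fc"
    participants_path = out / "participants.csv"

    # -- simulate ---------------------------------------------------------
    if resume and participants_path.exists() and sessions_dir.exists():
        logger.info("resume: reusing simulated cohort")
        sessions = read_participants(participants_path)
    else:
        try:
            cohort = generate_cohort(config.sim)
            ts_by_session = generate_cohort_timeseries(cohort, config.sim)
            sessions_dir.mkdir(exist_ok=True)
            for sid, arr in ts_by_session.items():
                write_timeseries(
                    ROITimeSeries(arr, cohort.region_labels, sid),
                    sessions_dir / f"{sid}.tsv",
                )
            write_participants(cohort.sessions, participants_path)
            write_json(cohort.ground_truth, out / "ground_truth.json")
            sessions = cohort.sessions
        except Exception as err:
            raise StageError("simulate", err) from err
    counts["sessions"] = len(sessions)

    # -- connectome -------------------------------------------------------
    try:
        fc_dir.mkdir(exist_ok=True)
        fc_by_session = {}
        labels = None
        for ts_path in sorted(sessions_dir.glob("*.tsv")):
            sid = ts_path.stem
            fc_path = fc_dir / f"{sid}.csv"
            if resume and fc_path.exists():
                fcm = read_fc_matrix(fc_path, session_id=sid)
            else:
                ts = read_timeseries(ts_path, atlas_labels=labels, session_id=sid)
                fcm = compute_fc(ts)
                write_fc_matrix(fcm, fc_path)
            labels = labels or fcm.region_labels
            fc_by_session[sid] = fcm
    except Exception as err:
        raise StageError("connectome", err) from err
    counts["fc_matrices"] = len(fc_by_session)

    # -- metrics ----------------------------------------------------------
    try:
        nodal, glob = compute_metric_tables(
            fc_by_session,
            grid=grid,
            integration=config.integration,
            aggregate=config.global_aggregate,
            negative_weights=config.negative_weights,
            edge_length=config.edge_length,
            clustering_denominator=config.clustering_denominator,
            clustering_normalize=config.clustering_normalize,
        )
        nodal.to_csv(out / "metrics_nodal.csv", index=False)
        glob_z = zscore_metrics(glob)
        glob.to_csv(out / "metrics_global.csv")
        glob_z.to_csv(out / "metrics_global_z.csv")
    except Exception as err:
        raise StageError("metrics", err) from err
    counts["metric_rows"] = len(nodal)

    # -- stats ------------------------------------------------------------
    try:
        sess = sessions.set_index("session_id").loc[glob_z.index].reset_index()
        contrasts = []
        for metric in METRIC_NAMES:
            res, adj = adjusted_sex_contrast(
                glob_z[metric].to_numpy(),
                sess[["sex", *config.covariates]],
                sess["subject_id"],
                n_comparisons=config.bonferroni_global,
                metric=metric,
                region="global",
                nuisance=config.covariates,
            )
            contrasts.append(dataclasses.asdict(res) | {"lme_method": adj.method})
        pd.DataFrame(contrasts).to_csv(out / "sex_contrasts_global.csv", index=False)

        demo = demographics_table(
            sessions.drop_duplicates("subject_id"), sessions
        )
        demo.to_csv(out / "demographics.csv", index=False)
        status = classify_amyloid(
            sessions, threshold=config.amyloid_threshold,
            window_days=config.amyloid_window_days,
        )
        counts["amyloid_positive"] = int((status == "positive").sum())
        counts["amyloid_negative"] = int((status == "negative").sum())
        counts["amyloid_unknown"] = int((status == "unknown").sum())
    except Exception as err:
        raise StageError("stats", err) from err

    # -- nbs --------------------------------------------------------------
    try:
        sids = list(fc_by_session)
        sess_idx = sessions.set_index("session_id").loc[sids]
        result = nbs_permutation(
            [fc_by_session[s] for s in sids],
            sess_idx[["sex", *config.covariates]].reset_index(drop=True),
            sess_idx["subject_id"].to_numpy(),
            sess_idx["sex"].to_numpy(),
            n_perm=config.nbs_n_perm,
            threshold=config.nbs_threshold,
            direction=config.nbs_direction,
            statistic=config.nbs_statistic,
            seed=config.seed,
        )
        summary = {
            "n_permutations": result.n_permutations,
            "primary_threshold": result.primary_threshold,
            "direction": result.direction,
            "components": [
                {"extent": c.extent, "fwe_p": c.fwe_p, "n_nodes": len(c.nodes)}
                for c in result.components
            ],
        }
        write_json(summary, out / "nbs_summary.json")
        if result.components and len(result.region_labels) == 94:
            areas = macroarea_assign(result.region_labels)
            macroarea_summary(
                result.components[0], areas, result.region_labels
            ).to_csv(out / "nbs_macroarea_counts.csv")
        edge_rows = [
            {"region_i": result.region_labels[i], "region_j": result.region_labels[j],
             "component": k, "fwe_p": c.fwe_p}
            for k, c in enumerate(result.components)
            for i, j in c.edges
        ]
        pd.DataFrame(edge_rows).to_csv(out / "nbs_edges.csv", index=False)
    except Exception as err:
        raise StageError("nbs", err) from err
    counts["nbs_components"] = len(result.components)

    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "fctopo_version": __version__,
        "numpy_version": np.__version__,
        "stage_counts": counts,
    }
    write_json(manifest, out / "manifest.json")
    return out
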