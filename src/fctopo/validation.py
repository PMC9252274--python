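"""Simulation studies that characterize the pipeline's error rates.

These routines run the full chain — synthetic cohort, FC estimation,
sparsity-swept metrics, mixed-model adjustment, contrasts or NBS — many
times over independent cohorts, and report rejection or recovery rates.
They back the package's calibration claims: type-I error of the global
metric contrast under a null cohort, FWE control of the network-based
statistic, and power/sign recovery under an implanted female connectivity
deficit.

Problem sizes default to compact cohorts (small atlases, short runs) so a
several-hundred-replicate study completes on one CPU in minutes; the
statistical structure (repeated sessions, subject-level covariance
perturbations, Table-1-like covariates) matches the full-size generator.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .config import BaseCovParams, SimConfig
from .fc import ROITimeSeries, compute_fc
from .inference import adjusted_sex_contrast
from .metrics import integrated_global_metrics
from .nbs import nbs_permutation
from .synthetic import generate_cohort, generate_cohort_timeseries

#: compact null-cohort conditions for the type-I studies
NULL_METRIC_CONFIG = SimConfig(
    n_men=30, n_women=40, n_regions=10, n_timepoints=48,
    sex_effect_scale=1.0, reversal_regions=(),
)
#: 24 regions (276 edges) rather than a smaller toy: the component-extent
#: statistic is integer-valued, and on sparser graphs the null max-extent
#: tail is so coarse that the largest attainable rejection level sits well
#: below the nominal 0.05 — the study would then measure discreteness, not
#: calibration
NULL_NBS_CONFIG = SimConfig(
    n_men=20, n_women=20, n_regions=24, n_timepoints=60,
    sex_effect_scale=1.0, reversal_regions=(),
)
#: implanted-deficit conditions for the recovery studies
DEFICIT_METRIC_CONFIG = SimConfig(
    n_men=40, n_women=40, n_regions=16, n_timepoints=120,
    sex_effect_scale=0.8, reversal_regions=(),
)
#: the implanted block sits inside one baseline community (n_blocks=2 over
#: 24 regions -> community size 12) so its edges share the same baseline
#: correlation; a block straddling communities would legitimately split
#: into several supra-threshold clusters
DEFICIT_BLOCK = tuple(range(10))
DEFICIT_NBS_CONFIG = SimConfig(
    n_men=40, n_women=40, n_regions=24, n_timepoints=120,
    sex_effect_scale=0.8, reversal_regions=(), deficit_regions=DEFICIT_BLOCK,
    base_cov=BaseCovParams(n_blocks=2, r_within=0.35, r_between=0.12),
)

_COVARIATE_COLS = ["sex", "age", "education", "handedness", "apoe4"]


def _session_global_metrics(config: SimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate one cohort and return (sessions x 3 metrics, session table)."""
    cohort = generate_cohort(config)
    ts = generate_cohort_timeseries(cohort, config)
    sids = list(ts)
    G = np.array(
        [
            integrated_global_metrics(
                compute_fc(ROITimeSeries(ts[s], cohort.region_labels, s))
            )
            for s in sids
        ]
    )
    sess = cohort.sessions.set_index("session_id").loc[sids].reset_index()
    return G, sess


def _metric_contrasts(config: SimConfig, seed: int):
    """Adjusted sex contrasts (Bonferroni m=3) for one simulated cohort."""
    cfg = replace(config, seed=seed)
    G, sess = _session_global_metrics(cfg)
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(3):
            col = (G[:, k] - G[:, k].mean()) / G[:, k].std(ddof=1)
            res, _ = adjusted_sex_contrast(
                col, sess[_COVARIATE_COLS], sess["subject_id"], n_comparisons=3
            )
            results.append(res)
    return results


def null_metric_typeI_study(
    n_reps: int = 500, seed: int = 0, config: SimConfig = NULL_METRIC_CONFIG
) -> dict:
    """Family-wise type-I error of the global-metric sex contrast.

    Each replicate simulates a null cohort (no implanted sex effect, with
    subject random effects), runs metrics + LME adjustment + subject-level
    pooled t per metric, and rejects if any Bonferroni-corrected p < 0.05.
    """
    rejections = 0
    for r in range(n_reps):
        results = _metric_contrasts(config, seed=seed + r)
        if min(res.p_bonferroni for res in results) < 0.05:
            rejections += 1
    return {
        "rate": rejections / n_reps,
        "rejections": rejections,
        "n_reps": n_reps,
        "n_subjects": config.n_men + config.n_women,
    }


def metric_effect_recovery_study(
    n_reps: int = 25, seed: int = 0, config: SimConfig = DEFICIT_METRIC_CONFIG
) -> dict:
    """Power and sign recovery under an implanted female FC deficit.

    Counts replicates where all three global metrics are significantly
    lower in women (negative t, Bonferroni-corrected p < 0.05).
    """
    hits = 0
    for r in range(n_reps):
        results = _metric_contrasts(config, seed=seed + r)
        if all(res.t < 0 and res.p_bonferroni < 0.05 for res in results):
            hits += 1
    return {"rate": hits / n_reps, "hits": hits, "n_reps": n_reps}


def _nbs_once(config: SimConfig, seed: int, n_perm: int):
    cfg = replace(config, seed=seed)
    cohort = generate_cohort(cfg)
    ts = generate_cohort_timeseries(cohort, cfg)
    sids = list(ts)
    fcs = [
        compute_fc(ROITimeSeries(ts[s], cohort.region_labels, s)) for s in sids
    ]
    sess = cohort.sessions.set_index("session_id").loc[sids].reset_index()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return nbs_permutation(
            fcs,
            sess[_COVARIATE_COLS],
            sess["subject_id"].to_numpy(),
            sess["sex"].to_numpy(),
            n_perm=n_perm,
            threshold=0.005,
            direction="women_lt_men",
            seed=seed + 1,
        )


def nbs_null_calibration_study(
    n_reps: int = 200,
    n_perm: int = 500,
    seed: int = 0,
    config: SimConfig = NULL_NBS_CONFIG,
) -> dict:
    """P(FWE p < 0.05) of the NBS on null cohorts (should be near 0.05)."""
    rejections = 0
    for r in range(n_reps):
        res = _nbs_once(config, seed=seed + 17 * r, n_perm=n_perm)
        if res.components and res.components[0].fwe_p < 0.05:
            rejections += 1
    return {
        "rate": rejections / n_reps,
        "rejections": rejections,
        "n_reps": n_reps,
        "n_perm": n_perm,
    }


def nbs_block_localization_study(
    n_reps: int = 10,
    n_perm: int = 500,
    seed: int = 0,
    config: SimConfig = DEFICIT_NBS_CONFIG,
    block: tuple[int, ...] = DEFICIT_BLOCK,
) -> dict:
    """Recovery of a deficit confined to a node block.

    A replicate counts as localized when the top component is significant
    (FWE p < 0.05) and covers at least 80% of the implanted block's nodes.
    """
    hits = 0
    coverages = []
    for r in range(n_reps):
        res = _nbs_once(config, seed=seed + 31 * r, n_perm=n_perm)
        if not res.components:
            coverages.append(0.0)
            continue
        top = res.components[0]
        cover = len(set(top.nodes) & set(block)) / len(block)
        coverages.append(cover)
        if top.fwe_p < 0.05 and cover >= 0.8:
            hits += 1
    return {
        "rate": hits / n_reps,
        "hits": hits,
        "n_reps": n_reps,
        "mean_block_coverage": float(np.mean(coverages)),
    }
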