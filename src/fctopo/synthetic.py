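"""Synthetic resting-state cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
sex groups with group-specific between-region covariance, one to three
fMRI sessions per subject (subject covariates constant across sessions),
Table-1-like covariate distributions, amyloid-PET SUVR values straddling
the 1.11 positivity cutoff with a fraction of sessions lacking a PET scan
within the one-year window, and cognition scores affinely linked to a
global network metric with per-sex slopes.

Region time series are zero-mean multivariate Gaussian with optional
per-region AR(1) temporal autocorrelation — the simplest model carrying
the correlation structure that FC estimation assumes. No voxelwise signal,
scanner noise, or motion is simulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CognitionLink, ConfigError, SimConfig
from . import atlas

_EPOCH = np.datetime64("2012-01-01")


@dataclass
class Cohort:
    """Subjects and sessions tables plus the implanted ground truth.

    ``subjects``: one row per subject (subject_id, sex, age, education,
    handedness, apoe4). ``sessions``: one row per fMRI session
    (session_id, subject_id, sex + covariates copied from the subject,
    mri_date, suvr, pet_date, score columns added by
    :func:`generate_cognition`).
    """

    subjects: pd.DataFrame
    sessions: pd.DataFrame
    region_labels: list[str]
    ground_truth: dict = field(default_factory=dict)

    def validate(self) -> None:
        known = set(self.subjects["subject_id"])
        orphans = set(self.sessions["subject_id"]) - known
        if orphans:
            raise ValueError(f"sessions reference unknown subjects: {sorted(orphans)}")
        cov_cols = ["sex", "age", "education", "handedness", "apoe4"]
        merged = self.sessions.merge(
            self.subjects, on="subject_id", suffixes=("", "_subj")
        )
        for col in cov_cols:
            if not (merged[col] == merged[f"{col}_subj"]).all():
                raise ValueError(f"covariate {col} varies within subject")


def _ensure_positive_definite(mat: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    """Diagonal-load a symmetric matrix until PD, then rescale to unit diagonal."""
    out = (mat + mat.T) / 2
    for _ in range(50):
        w = np.linalg.eigvalsh(out)
        if w.min() > min_eig:
            break
        warnings.warn(
            f"covariance not positive definite (min eig {w.min():.2e}); "
            "applying diagonal loading",
            stacklevel=3,
        )
        out = out + (min_eig - w.min() + 1e-6) * np.eye(out.shape[0])
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
    return out


def build_group_covariance(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Construct (men, women) between-region correlation matrices.

    The men's matrix has a block-community structure (``base_cov``); the
    women's off-diagonal entries are ``sex_effect_scale`` times the men's,
    except rows/columns in ``reversal_regions`` where the factor is
    inverted, and — when ``deficit_regions`` is set — the scaling is
    confined to edges with both endpoints inside that set. Both outputs
    are symmetric positive definite with unit diagonal.
    """
    config.validate()
    n = config.n_regions
    bc = config.base_cov
    block = np.repeat(np.arange(bc.n_blocks), int(np.ceil(n / bc.n_blocks)))[:n]
    same = block[:, None] == block[None, :]
    men = np.where(same, bc.r_within, bc.r_between).astype(float)
    np.fill_diagonal(men, 1.0)
    men = _ensure_positive_definite(men)

    scale = np.full((n, n), config.sex_effect_scale)
    if config.deficit_regions is not None:
        mask = np.zeros(n, dtype=bool)
        mask[list(config.deficit_regions)] = True
        inside = np.outer(mask, mask)
        scale = np.where(inside, scale, 1.0)
    reversal = config.reversal_regions
    if reversal is None and n == 94:
        reversal = atlas.default_reversal_indices(atlas.region_labels(94))
    if reversal:
        rmask = np.zeros(n, dtype=bool)
        rmask[list(reversal)] = True
        touches = rmask[:, None] | rmask[None, :]
        scale = np.where(touches, 1.0 / scale, scale)
    women = men * scale
    np.fill_diagonal(women, 1.0)
    women = np.clip(women, -0.999, 0.999)
    np.fill_diagonal(women, 1.0)
    women = _ensure_positive_definite(women)
    return men, women


def generate_session_timeseries(
    cov: np.ndarray, config: SimConfig, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw a T x N multivariate Gaussian series with stationary covariance ``cov``.

    With ``ar1_coef`` = phi > 0 each region follows x_t = phi x_{t-1} +
    sqrt(1 - phi^2) e_t with correlated innovations, so the stationary
    cross-sectional covariance equals ``cov`` and each region has lag-1
    autocorrelation phi.
    """
    T, n = config.n_timepoints, cov.shape[0]
    if T < 3:
        raise ConfigError("need at least 3 timepoints")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance is not positive definite") from err
    innov = rng.standard_normal((T, n)) @ chol.T
    phi = config.ar1_coef
    if phi == 0:
        return innov
    out = np.empty_like(innov)
    out[0] = innov[0]
    scale = np.sqrt(1 - phi**2)
    for t in range(1, T):
        out[t] = phi * out[t - 1] + scale * innov[t]
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, upper: float, size: int
) -> np.ndarray:
    """Resample draws above ``upper`` (keeps the generator inside eligibility)."""
    vals = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = vals > upper
        if not bad.any():
            break
        vals[bad] = rng.normal(mean, sd, bad.sum())
    return np.minimum(vals, upper)


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate the subjects/sessions tables (no time series yet).

    Deterministic given ``config.seed``; repeated sessions share subject
    covariates; session ADAS-Cog wiggles slightly around the subject mean
    but stays within the eligibility cutoff.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    cp, sp = config.covariate_params, config.suvr_params

    rows = []
    for sex, n_subj, prefix in (("M", config.n_men, "M"), ("F", config.n_women, "F")):
        is_f = sex == "F"
        age = _truncated_normal(
            rng,
            cp.age_mean_women if is_f else cp.age_mean_men,
            cp.age_sd_women if is_f else cp.age_sd_men,
            cp.age_max,
            n_subj,
        )
        edu = np.round(
            rng.normal(
                cp.edu_mean_women if is_f else cp.edu_mean_men,
                cp.edu_sd_women if is_f else cp.edu_sd_men,
                n_subj,
            )
        ).clip(8, 24)
        adas = _truncated_normal(
            rng,
            cp.adas_mean_women if is_f else cp.adas_mean_men,
            cp.adas_sd_women if is_f else cp.adas_sd_men,
            cp.adas_max - 0.5,
            n_subj,
        ).clip(0, None)
        hand = rng.random(n_subj) < (
            cp.left_handed_prob_women if is_f else cp.left_handed_prob_men
        )
        apoe = rng.random(n_subj) < (
            cp.apoe4_prob_women if is_f else cp.apoe4_prob_men
        )
        for i in range(n_subj):
            rows.append(
                {
                    "subject_id": f"{prefix}{i + 1:03d}",
                    "sex": sex,
                    "age": round(float(age[i]), 1),
                    "education": int(edu[i]),
                    "handedness": "L" if hand[i] else "R",
                    "apoe4": int(apoe[i]),
                    "_adas_mean": float(adas[i]),
                }
            )
    subjects = pd.DataFrame(rows)

    n_levels = np.array(sorted(config.sessions_per_subject))
    probs = np.array([config.sessions_per_subject[k] for k in n_levels], dtype=float)
    n_sessions = rng.choice(n_levels, size=len(subjects), p=probs)

    # latent per-subject amyloid state drives SUVR across that subject's sessions
    p_pos = np.where(
        subjects["apoe4"].to_numpy() == 1, sp.p_positive_carrier, sp.p_positive_noncarrier
    )
    amyloid_latent = rng.random(len(subjects)) < p_pos
    suvr_mean = np.where(
        amyloid_latent,
        rng.normal(sp.positive_mean, sp.positive_sd, len(subjects)),
        rng.normal(sp.negative_mean, sp.negative_sd, len(subjects)),
    ).clip(0.7, None)

    sess_rows = []
    for i, subj in subjects.iterrows():
        base_day = int(rng.integers(0, 365))
        for k in range(int(n_sessions[i])):
            mri_date = _EPOCH + np.timedelta64(base_day + 182 * k, "D")
            no_pet = rng.random() < sp.unknown_frac
            if no_pet:
                # half missing outright, half outside the one-year window
                if rng.random() < 0.5:
                    pet_date, suvr = pd.NaT, np.nan
                else:
                    off = int(rng.integers(380, 900)) * (1 if rng.random() < 0.5 else -1)
                    pet_date = mri_date + np.timedelta64(off, "D")
                    suvr = float(suvr_mean[i] + rng.normal(0, 0.02))
            else:
                off = int(rng.integers(-300, 301))
                pet_date = mri_date + np.timedelta64(off, "D")
                suvr = float(suvr_mean[i] + rng.normal(0, 0.02))
            sess_rows.append(
                {
                    "session_id": f"{subj.subject_id}_s{k + 1}",
                    "subject_id": subj.subject_id,
                    "sex": subj.sex,
                    "age": subj.age,
                    "education": subj.education,
                    "handedness": subj.handedness,
                    "apoe4": subj.apoe4,
                    "mri_date": pd.Timestamp(mri_date),
                    "pet_date": pd.Timestamp(pet_date) if pet_date is not pd.NaT else pd.NaT,
                    "suvr": np.nan if suvr is np.nan else suvr,
                    "adas_cog": round(
                        float(np.clip(subj._adas_mean + rng.normal(0, 0.4), 0, cp.adas_max)), 1
                    ),
                }
            )
    sessions = pd.DataFrame(sess_rows)
    subjects = subjects.drop(columns=["_adas_mean"])

    labels = atlas.region_labels(config.n_regions)
    truth = {
        "sex_effect_scale": config.sex_effect_scale,
        "reversal_regions": list(config.reversal_regions or []),
        "deficit_regions": list(config.deficit_regions or []),
        "seed": config.seed,
        "subject_cov_sd": config.subject_cov_sd,
        "cognition_links": [vars(l).copy() for l in config.cognition_links],
    }
    cohort = Cohort(subjects=subjects, sessions=sessions, region_labels=labels,
                    ground_truth=truth)
    cohort.validate()
    return cohort


def _pd_project(mat: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Nearest-ish correlation matrix: clip eigenvalues, renormalize diagonal."""
    w, v = np.linalg.eigh((mat + mat.T) / 2)
    out = (v * np.maximum(w, floor)) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def subject_covariance(
    group_cov: np.ndarray, subject_cov_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Perturb the group covariance into a subject-specific one.

    A symmetric Gaussian perturbation (SD ``subject_cov_sd``, correlation
    units) on the off-diagonals, projected back to a valid correlation
    matrix. All sessions of the subject share this matrix — the subject
    random effect that makes repeated sessions more alike than sessions
    from different subjects.
    """
    if subject_cov_sd == 0:
        return group_cov
    n = group_cov.shape[0]
    noise = rng.normal(0, subject_cov_sd, (n, n))
    noise = np.triu(noise, k=1)
    noise = noise + noise.T
    pert = np.clip(group_cov + noise, -0.999, 0.999)
    np.fill_diagonal(pert, 1.0)
    return _pd_project(pert)


def generate_cohort_timeseries(
    cohort: Cohort, config: SimConfig
) -> dict[str, np.ndarray]:
    """One T x N series per session, from the sex-specific covariance.

    Each subject's sessions share a subject-specific covariance (group
    covariance plus a random perturbation of SD ``subject_cov_sd``).
    Per-subject seeds derive deterministically from ``config.seed`` via a
    spawned SeedSequence, so subjects can be regenerated in isolation.
    """
    cov_men, cov_women = build_group_covariance(config)
    base = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    children = base.spawn(len(cohort.subjects))
    cov_by_subject: dict[str, np.ndarray] = {}
    rng_by_subject: dict[str, np.random.Generator] = {}
    for child, (_, subj) in zip(children, cohort.subjects.iterrows()):
        rng = np.random.default_rng(child)
        group_cov = cov_women if subj.sex == "F" else cov_men
        cov_by_subject[subj.subject_id] = subject_covariance(
            group_cov, config.subject_cov_sd, rng
        )
        rng_by_subject[subj.subject_id] = rng
    out: dict[str, np.ndarray] = {}
    for _, row in cohort.sessions.iterrows():
        out[row.session_id] = generate_session_timeseries(
            cov_by_subject[row.subject_id], config, rng_by_subject[row.subject_id]
        )
    return out


def generate_cognition(
    cohort: Cohort,
    metric_values: pd.Series,
    link: CognitionLink | None = None,
    seed: int | None = None,
) -> Cohort:
    """Attach a cognition score column affinely linked to a per-session metric.

    ``metric_values`` must provide one value per session (indexed by
    session_id). Missing sessions raise. Returns the same cohort with the
    score column added to ``sessions``.
    """
    link = link or CognitionLink()
    sess = cohort.sessions
    missing = [s for s in sess["session_id"] if s not in metric_values.index]
    if missing:
        raise ValueError(f"metric values missing for sessions: {missing[:5]}")
    m = metric_values.loc[sess["session_id"]].to_numpy(dtype=float)
    is_f = (sess["sex"] == "F").to_numpy()
    slope = np.where(is_f, link.slope_women, link.slope_men)
    intercept = np.where(is_f, link.intercept_women, link.intercept_men)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cohort.ground_truth.get("seed", 0) if seed is None else seed,
                               spawn_key=(2,))
    )
    noise = rng.normal(0, link.noise_sd, len(sess)) if link.noise_sd > 0 else 0.0
    cohort.sessions = sess.assign(**{link.score: intercept + slope * m + noise})
    return cohort
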