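"""Group-level inference on network metrics.

The sex contrast follows a two-step scheme: a random-intercept linear
mixed model (metric ~ sex + age + handedness + education + APOE4 +
(1|subject), REML) absorbs nuisance covariates and the repeated-session
correlation; the "adjusted" metric removes the centered nuisance fixed
effects and the predicted subject intercept while keeping the sex effect
and residual; a pooled two-sample t with Bonferroni correction is then
applied to the adjusted values. Demographics tests, SUVR-based amyloid
classification, eligibility filtering, two-way ANOVA, and per-group
brain-cognition regressions round out the stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

NUISANCE_COVARIATES = ("age", "education", "handedness", "apoe4")


def encode_covariates(df: pd.DataFrame, covariates=NUISANCE_COVARIATES) -> pd.DataFrame:
    """Numeric covariate coding: handedness R=0/L=1, APOE4 carrier 0/1, sex M=0/F=1."""
    out = pd.DataFrame(index=df.index)
    if "sex" in df:
        out["sex"] = df["sex"].map({"M": 0, "F": 1, 0: 0, 1: 1}).astype(float)
    for cov in covariates:
        col = df[cov]
        if cov == "handedness":
            out[cov] = col.map({"R": 0, "L": 1, 0: 0, 1: 1}).astype(float)
        else:
            out[cov] = pd.to_numeric(col).astype(float)
    return out


@dataclass
class AdjustedValues:
    """Per-session adjusted metric values plus the fit they came from."""

    adjusted: pd.Series
    method: str  # "reml", "ml", or "ols"
    fixed_effects: pd.Series
    random_intercepts: pd.Series
    var_subject: float
    var_residual: float
    n_dropped: int = 0


def fit_lme_adjust(
    values: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    subject_ids: pd.Series | np.ndarray,
    nuisance=NUISANCE_COVARIATES,
    remove_subject_effect: bool = True,
) -> AdjustedValues:
    """Random-intercept LME adjustment of one metric column.

    Nuisance covariates are centered at their sample means so removing
    their contributions leaves the grand level intact. On a singular or
    non-convergent REML fit the model falls back to ML, then to a
    fixed-effects-only OLS (subject intercepts zero) with a warning.
    Sessions with missing covariates are dropped and counted.

    ``remove_subject_effect`` also subtracts the predicted (BLUP) subject
    intercept. Note that a naive session-level t-test on BLUP-removed
    values is anticonservative — the shrinkage deflates the within-group
    spread while the sampling noise of the sex contrast remains — so for
    inference prefer ``remove_subject_effect=False`` together with
    :func:`sex_ttest` at ``level='subject'``, which is calibrated under a
    clustered null.
    """
    y = pd.Series(np.asarray(values, dtype=float)).reset_index(drop=True)
    enc = encode_covariates(covariates.reset_index(drop=True), nuisance)
    subj = pd.Series(np.asarray(subject_ids)).reset_index(drop=True)

    mask = enc.notna().all(axis=1) & y.notna() & subj.notna()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("fit_lme_adjust: dropped %d sessions with missing data", n_dropped)
    y, enc, subj = y[mask], enc[mask], subj[mask]
    if subj.nunique() < 4 or enc["sex"].nunique() < 2:
        raise ValueError("need >= 2 subjects per sex to fit the mixed model")

    X_nuis = enc[list(nuisance)] - enc[list(nuisance)].mean()
    exog = pd.concat(
        [pd.Series(1.0, index=y.index, name="const"), enc["sex"], X_nuis], axis=1
    )

    method = "reml"
    params = None
    re_by_subj: dict = {}
    var_u, var_e = 0.0, float(np.var(y, ddof=1))
    # without repeated sessions the subject variance is unidentifiable
    # (any split of the residual fits equally well); use the OLS path
    if subj.value_counts().max() == 1:
        ols = sm.OLS(y, exog).fit()
        adjusted = pd.Series(
            y.to_numpy() - X_nuis.to_numpy() @ ols.params[list(nuisance)].to_numpy(),
            index=y.index, name="adjusted",
        )
        return AdjustedValues(
            adjusted=adjusted, method="ols", fixed_effects=ols.params,
            random_intercepts=pd.Series(dtype=float), var_subject=0.0,
            var_residual=float(ols.scale), n_dropped=n_dropped,
        )

    attempts = [("reml", "lbfgs"), ("reml", "powell"), ("ml", "lbfgs"), ("ml", "powell")]
    for attempt, optimizer in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, exog, groups=subj)
                res = model.fit(reml=(attempt == "reml"), method=optimizer)
            if not np.isfinite(res.params).all() or not res.converged:
                raise ValueError("mixed model did not converge cleanly")
            params = res.fe_params
            re_by_subj = {k: float(v.iloc[0]) for k, v in res.random_effects.items()}
            var_u = float(res.cov_re.iloc[0, 0])
            var_e = float(res.scale)
            method = attempt
            break
        except Exception:  # singular fit, non-convergence
            continue
    if params is None:
        warnings.warn(
            "mixed model failed to converge; falling back to fixed-effects OLS",
            stacklevel=2,
        )
        ols = sm.OLS(y, exog).fit()
        params = ols.params
        re_by_subj = {}
        var_u, var_e = 0.0, float(ols.scale)
        method = "ols"

    nuis_contrib = X_nuis.to_numpy() @ params[list(nuisance)].to_numpy()
    u = subj.map(lambda s: re_by_subj.get(s, 0.0)).to_numpy()
    if not remove_subject_effect:
        u = np.zeros_like(u)
    adjusted = pd.Series(y.to_numpy() - nuis_contrib - u, index=y.index, name="adjusted")
    return AdjustedValues(
        adjusted=adjusted,
        method=method,
        fixed_effects=params,
        random_intercepts=pd.Series(re_by_subj, dtype=float),
        var_subject=var_u,
        var_residual=var_e,
        n_dropped=n_dropped,
    )


@dataclass
class ContrastResult:
    """Two-sample sex contrast on adjusted values."""

    t: float
    p: float
    p_bonferroni: float
    mean_men: float
    mean_women: float
    sd_men: float
    sd_women: float
    n_men: int
    n_women: int
    metric: str = ""
    region: str = ""


def sex_ttest(
    adjusted: pd.Series | np.ndarray,
    sex_labels: pd.Series | np.ndarray,
    n_comparisons: int = 1,
    metric: str = "",
    region: str = "",
    subject_ids: pd.Series | np.ndarray | None = None,
    level: str = "session",
) -> ContrastResult:
    """Two-sided pooled-variance t-test of women vs men on adjusted values.

    Negative t means women lower. Bonferroni: corrected p = min(1, p * m)
    (m = 94 within each regional metric family, m = 3 for the globals).

    ``level='subject'`` (requires ``subject_ids``) first averages each
    subject's sessions; with nuisance-only adjusted values this is the
    calibrated test under repeated sessions.
    """
    vals = np.asarray(adjusted, dtype=float)
    sex = np.asarray(sex_labels)
    if level == "subject":
        if subject_ids is None:
            raise ValueError("level='subject' requires subject_ids")
        df = pd.DataFrame({"v": vals, "sex": sex, "subj": np.asarray(subject_ids)})
        coll = df.groupby("subj").agg(v=("v", "mean"), sex=("sex", "first"))
        vals, sex = coll["v"].to_numpy(), coll["sex"].to_numpy()
    elif level != "session":
        raise ValueError(f"unknown level: {level}")
    men = vals[(sex == "M") | (sex == 0)]
    women = vals[(sex == "F") | (sex == 1)]
    if len(men) < 2 or len(women) < 2:
        raise ValueError("need at least 2 sessions per sex")
    t, p = stats.ttest_ind(women, men, equal_var=True)
    return ContrastResult(
        t=float(t),
        p=float(p),
        p_bonferroni=min(1.0, float(p) * n_comparisons),
        mean_men=float(men.mean()),
        mean_women=float(women.mean()),
        sd_men=float(men.std(ddof=1)),
        sd_women=float(women.std(ddof=1)),
        n_men=len(men),
        n_women=len(women),
        metric=metric,
        region=region,
    )


def adjusted_sex_contrast(
    values: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    subject_ids: pd.Series | np.ndarray,
    n_comparisons: int = 1,
    metric: str = "",
    region: str = "",
    nuisance=NUISANCE_COVARIATES,
) -> tuple[ContrastResult, AdjustedValues]:
    """The pipeline's sex contrast: LME nuisance adjustment, subject-level t.

    Adjusts for the nuisance fixed effects (subject random intercept
    modeled but retained in the values), collapses each subject's sessions
    to their mean, and applies the pooled two-sample t. This keeps the
    family-wise error of the contrast near nominal under repeated sessions.
    """
    adj = fit_lme_adjust(
        values, covariates, subject_ids, nuisance=nuisance,
        remove_subject_effect=False,
    )
    sex = np.asarray(covariates["sex"])[adj.adjusted.index]
    subj = np.asarray(subject_ids)[adj.adjusted.index]
    res = sex_ttest(
        adj.adjusted, sex, n_comparisons=n_comparisons, metric=metric,
        region=region, subject_ids=subj, level="subject",
    )
    return res, adj


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    tab = np.asarray(counts, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (tab < 0).any():
        raise ValueError("counts must be nonnegative")
    if tab.sum() == 0:
        raise ValueError("table total must be positive")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(stat), float(p)


def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t from summary statistics."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(t), float(p)


def classify_amyloid(
    sessions: pd.DataFrame,
    threshold: float = 1.11,
    window_days: int = 365,
) -> pd.Series:
    """Per-session amyloid status from composite SUVR.

    ``unknown`` if there is no PET scan within ``window_days`` of the MRI
    date (or no SUVR at all); otherwise ``positive`` iff SUVR is strictly
    above the threshold (SUVR exactly at 1.11 is negative), else
    ``negative``. Negative SUVR values are a data error.
    """
    suvr = pd.to_numeric(sessions["suvr"], errors="coerce")
    if (suvr.dropna() < 0).any():
        bad = sessions.loc[suvr < 0, "session_id"].tolist() if "session_id" in sessions else []
        raise ValueError(f"negative SUVR values: {bad or 'present'}")
    mri = pd.to_datetime(sessions["mri_date"])
    pet = pd.to_datetime(sessions["pet_date"])
    gap = (pet - mri).abs().dt.days
    known = suvr.notna() & pet.notna() & (gap <= window_days)
    status = pd.Series("unknown", index=sessions.index, name="amyloid_status")
    status[known & (suvr > threshold)] = "positive"
    status[known & (suvr <= threshold)] = "negative"
    return status


def attach_nearest_pet(
    sessions: pd.DataFrame, pet_scans: pd.DataFrame
) -> pd.DataFrame:
    """Attach the PET scan nearest in time to each session's MRI date.

    ``pet_scans`` needs columns subject_id, pet_date, suvr. All scans are
    considered; window filtering happens in :func:`classify_amyloid`.
    """
    pet = pet_scans.assign(pet_date=pd.to_datetime(pet_scans["pet_date"]))
    out = sessions.copy()
    out["pet_date"] = pd.NaT
    out["suvr"] = np.nan
    mri = pd.to_datetime(out["mri_date"])
    for idx, row in out.iterrows():
        cand = pet[pet["subject_id"] == row["subject_id"]]
        if cand.empty:
            continue
        gaps = (cand["pet_date"] - mri.loc[idx]).abs()
        best = gaps.idxmin()
        out.loc[idx, "pet_date"] = cand.loc[best, "pet_date"]
        out.loc[idx, "suvr"] = cand.loc[best, "suvr"]
    return out


def filter_eligibility(
    sessions: pd.DataFrame, age_cutoff: float = 80.0, adas_cutoff: float = 10.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain sessions with age <= 80 and ADAS-Cog <= 10 (strict > excludes).

    Returns the retained subset and a per-reason exclusion count.
    """
    age = pd.to_numeric(sessions["age"])
    adas = pd.to_numeric(sessions["adas_cog"])
    too_old = age > age_cutoff
    too_impaired = adas > adas_cutoff
    log = {
        "age_gt_cutoff": int(too_old.sum()),
        "adas_gt_cutoff": int(too_impaired.sum()),
        "excluded_total": int((too_old | too_impaired).sum()),
        "retained": int((~(too_old | too_impaired)).sum()),
    }
    logger.info("eligibility filter: %s", log)
    return sessions[~(too_old | too_impaired)].copy(), log


def two_way_anova(
    y: pd.Series | np.ndarray,
    factor_a: pd.Series | np.ndarray,
    factor_b: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Two-way ANOVA with interaction, Type II sums of squares.

    Suited to the unbalanced sex-by-APOE4 / sex-by-amyloid designs. Returns
    the statsmodels ANOVA table (rows: factor_a, factor_b, interaction,
    residual).
    """
    df = pd.DataFrame(
        {"y": np.asarray(y, dtype=float), "a": np.asarray(factor_a), "b": np.asarray(factor_b)}
    ).dropna()
    for name in ("a", "b"):
        levels = df[name].unique()
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels, got {levels}")
    fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    table.index = ["factor_a", "factor_b", "interaction", "residual"]
    return table


@dataclass
class GroupRegression:
    slope: float
    intercept: float
    stderr: float
    r: float
    p: float
    n: int


@dataclass
class SlopeComparison:
    """Per-group OLS fits and the Welch-style slope-difference test."""

    groups: dict[str, GroupRegression] = field(default_factory=dict)
    t_diff: float = np.nan
    p_diff: float = np.nan
    df: float = np.nan


def groupwise_regression_slope_test(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
) -> SlopeComparison:
    """Per-group simple regression of score on metric, plus slope difference.

    t = (b1 - b2) / sqrt(SE1^2 + SE2^2) with Welch-Satterthwaite degrees of
    freedom from the per-group residual dfs (n_g - 2), two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    grp = np.asarray(groups)
    result = SlopeComparison()
    names = pd.unique(grp)
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(names)}")
    for name in names:
        m = grp == name
        if m.sum() < 3:
            raise ValueError(f"group {name!r} has fewer than 3 points")
        if np.var(x[m]) == 0:
            raise ValueError(f"zero variance in x within group {name!r}")
        fit = stats.linregress(x[m], y[m])
        result.groups[str(name)] = GroupRegression(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            stderr=float(fit.stderr),
            r=float(fit.rvalue),
            p=float(fit.pvalue),
            n=int(m.sum()),
        )
    g1, g2 = (result.groups[str(n)] for n in names)
    se2 = g1.stderr**2 + g2.stderr**2
    t = (g1.slope - g2.slope) / np.sqrt(se2)
    df = se2**2 / (g1.stderr**4 / (g1.n - 2) + g2.stderr**4 / (g2.n - 2))
    result.t_diff = float(t)
    result.df = float(df)
    result.p_diff = float(2 * stats.t.sf(abs(t), df))
    return result


def demographics_table(subjects: pd.DataFrame, sessions: pd.DataFrame) -> pd.DataFrame:
    """Sex-comparison table over demographics (chi-square and pooled t rows)."""
    rows = []
    men_s = sessions[sessions["sex"] == "M"]
    women_s = sessions[sessions["sex"] == "F"]
    for col in ("age", "education", "adas_cog"):
        if col not in sessions:
            continue
        m, w = men_s[col].astype(float), women_s[col].astype(float)
        _, p = ttest_from_summary(
            m.mean(), m.std(ddof=1), len(m), w.mean(), w.std(ddof=1), len(w)
        )
        rows.append(
            {"variable": col, "men": f"{m.mean():.1f} ± {m.std(ddof=1):.1f}",
             "women": f"{w.mean():.1f} ± {w.std(ddof=1):.1f}", "p": p, "test": "pooled t"}
        )
    men_subj = subjects[subjects["sex"] == "M"]
    women_subj = subjects[subjects["sex"] == "F"]
    for col, pos in (("apoe4", 1), ("handedness", "L")):
        tab = [
            [int((men_subj[col] == pos).sum()), int((men_subj[col] != pos).sum())],
            [int((women_subj[col] == pos).sum()), int((women_subj[col] != pos).sum())],
        ]
        _, p = chi_square_2x2(tab)
        rows.append(
            {"variable": col, "men": f"{tab[0][0]}/{tab[0][1]}",
             "women": f"{tab[1][0]}/{tab[1][1]}", "p": p, "test": "chi-square"}
        )
    return pd.DataFrame(rows)
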