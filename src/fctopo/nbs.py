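"""Network-based statistic (NBS) for edge-wise sex differences.

Edge-wise Fisher-z connectivity is adjusted for the same nuisance
covariates and subject random intercept as the network metrics, then a
one-sided two-sample t is computed per edge in the requested direction.
Edges with raw p below the primary threshold (0.005 by default) form a
graph whose connected components are the candidate clusters; family-wise
error is controlled by permuting sex labels at the SUBJECT level (all
sessions of a subject move together — repeated sessions make session-level
labels non-exchangeable) and comparing each observed component's extent
against the permutation distribution of the maximal extent.

Because one mixed-model fit per edge is prohibitive at 4,371 edges, the
default adjustment is a single vectorized OLS projection (the design
matrix is shared by every edge, so one pseudoinverse adjusts all edges at
once; sex is retained). Repeated sessions are then handled by the test's
structure rather than by subtracting estimated subject intercepts: each
subject's sessions are averaged into one adjusted value per edge before
the t-test. Subtracting per-subject BLUPs instead would encode the
observed labels into the values (shrinkage pulls each subject toward its
own group mean), which makes observed statistics systematically exceed
label-permuted ones and destroys FWE control — so that variant is
deliberately not offered here. Nuisance adjustment is computed once on
the observed labels; permutations re-test the adjusted values (a
Freedman-Lane-style shortcut; ``exact=True`` recomputes the adjustment
inside every permutation). An exact per-edge mixed-model path
(``method='lme'``) is available for small problems and used to validate
the vectorized scheme.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .fc import FCMatrix
from .inference import NUISANCE_COVARIATES, encode_covariates, fit_lme_adjust

logger = logging.getLogger(__name__)


@dataclass
class EdgeStats:
    """Edge-wise one-sided t statistics and raw p-values on adjusted FC."""

    t: np.ndarray
    p: np.ndarray
    direction: str
    region_labels: list[str]
    n_degenerate: int = 0


@dataclass
class Component:
    """One supra-threshold connected component."""

    nodes: tuple[int, ...]
    edges: list[tuple[int, int]]
    extent: int
    intensity: float = 0.0
    fwe_p: float = np.nan


@dataclass
class NBSResult:
    components: list[Component]
    n_permutations: int
    primary_threshold: float
    direction: str
    statistic: str
    seed: int | None
    null_max: np.ndarray = field(default_factory=lambda: np.array([]))
    region_labels: list[str] = field(default_factory=list)


def _edge_matrix(fc_stack: list[FCMatrix]) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    n = fc_stack[0].n_regions
    labels = fc_stack[0].region_labels
    iu, ju = np.triu_indices(n, k=1)
    Y = np.stack([fcm.z[iu, ju] for fcm in fc_stack])
    return Y, iu, ju, labels


def nuisance_adjust(
    Y: np.ndarray,
    covariates: pd.DataFrame,
    nuisance=NUISANCE_COVARIATES,
) -> np.ndarray:
    """Vectorized nuisance adjustment of S x E edge values.

    Fits y_e = b0 + b_sex sex + B_nuis X_nuis + eps by OLS with one shared
    pseudoinverse for all edges and removes the centered nuisance
    contribution; the sex term and residual (including any subject-level
    structure) stay in the values.
    """
    enc = encode_covariates(covariates.reset_index(drop=True), nuisance)
    X_nuis = (enc[list(nuisance)] - enc[list(nuisance)].mean()).to_numpy()
    X = np.column_stack([np.ones(len(enc)), enc["sex"].to_numpy(), X_nuis])
    B = np.linalg.pinv(X) @ Y  # p x E
    return Y - X_nuis @ B[2:]


def subject_collapse(
    Y: np.ndarray, subject_ids: np.ndarray, is_female: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Average session rows into one row per subject.

    Returns the collapsed matrix and the per-subject female indicator.
    The collapse absorbs within-subject correlation so the subsequent
    two-sample t across subjects is calibrated.
    """
    subj_codes, subj_idx = np.unique(subject_ids, return_inverse=True)
    counts = np.bincount(subj_idx).astype(float)
    G = np.zeros((len(subj_codes), len(subj_idx)))
    G[subj_idx, np.arange(len(subj_idx))] = 1.0
    collapsed = (G @ Y) / counts[:, None]
    subj_is_f = np.zeros(len(subj_codes), dtype=bool)
    for k in range(len(subj_codes)):
        subj_is_f[k] = is_female[subj_idx == k].any()
    return collapsed, subj_is_f


def _one_sided_t(
    adj: np.ndarray, is_f: np.ndarray, direction: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled one-sided t per column (rows = subjects).

    Positive t favors the tested direction."""
    men, women = adj[~is_f], adj[is_f]
    n1, n2 = len(men), len(women)
    m1, m2 = men.mean(axis=0), women.mean(axis=0)
    v1 = men.var(axis=0, ddof=1)
    v2 = women.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    degenerate = se <= 0
    se = np.where(degenerate, 1.0, se)
    diff = (m1 - m2) if direction == "women_lt_men" else (m2 - m1)
    t = diff / se
    p = stats.t.sf(t, n1 + n2 - 2)
    p[degenerate] = 1.0
    t[degenerate] = 0.0
    return t, p, int(degenerate.sum())


def edgewise_stats(
    fc_stack: list[FCMatrix],
    covariates: pd.DataFrame,
    subject_ids,
    sex_labels,
    direction: str = "women_lt_men",
    method: str = "ols",
    nuisance=NUISANCE_COVARIATES,
) -> EdgeStats:
    """Adjusted one-sided edge-wise sex contrasts across all N(N-1)/2 edges.

    ``method='ols'`` (default) uses the vectorized shared-design nuisance
    adjustment; ``method='lme'`` loops an exact per-edge mixed model for
    the nuisance fit. Either way, sessions are collapsed to subject means
    before the t-test so repeated sessions do not inflate the statistics.
    Degenerate edges (zero pooled variance) get p = 1 with a logged count.
    """
    if direction not in ("women_lt_men", "women_gt_men"):
        raise ValueError(f"unknown direction: {direction}")
    Y, iu, ju, labels = _edge_matrix(fc_stack)
    subj = np.asarray(subject_ids)
    sex = np.asarray(sex_labels)
    is_f = (sex == "F") | (sex == 1)
    if is_f.sum() < 2 or (~is_f).sum() < 2:
        raise ValueError("need >= 2 sessions per sex")

    if method == "ols":
        adj = nuisance_adjust(Y, covariates, nuisance)
    elif method == "lme":
        cols = []
        for e in range(Y.shape[1]):
            cols.append(
                fit_lme_adjust(
                    Y[:, e], covariates, subj, nuisance,
                    remove_subject_effect=False,
                ).adjusted.to_numpy()
            )
        adj = np.column_stack(cols)
    else:
        raise ValueError(f"unknown method: {method}")

    adj_subj, subj_is_f = subject_collapse(adj, subj, is_f)
    t, p, n_degen = _one_sided_t(adj_subj, subj_is_f, direction)
    if n_degen:
        logger.info("edgewise_stats: %d degenerate edges set to p=1", n_degen)
    n = fc_stack[0].n_regions
    T = np.zeros((n, n))
    P = np.ones((n, n))
    T[iu, ju] = t
    T += T.T
    P[iu, ju] = p
    P[ju, iu] = p
    np.fill_diagonal(P, 1.0)
    return EdgeStats(t=T, p=P, direction=direction, region_labels=labels,
                     n_degenerate=n_degen)


def supra_components(edge_stats: EdgeStats, threshold: float = 0.005) -> list[Component]:
    """Connected components of the graph of edges with raw p < threshold.

    Sorted by extent (edge count) descending; the intensity field carries
    the sum of supra-threshold t values in the component.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    n = edge_stats.p.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = edge_stats.p[iu, ju] < threshold
    g = nx.Graph()
    g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        edges = sorted(tuple(sorted(e)) for e in sub.edges())
        intensity = float(sum(edge_stats.t[i, j] for i, j in edges))
        comps.append(
            Component(
                nodes=tuple(sorted(nodes)),
                edges=edges,
                extent=sub.number_of_edges(),
                intensity=intensity,
            )
        )
    comps.sort(key=lambda c: c.extent, reverse=True)
    return comps


def _component_stat(comps: list[Component], statistic: str) -> float:
    if not comps:
        return 0.0
    if statistic == "extent":
        return float(max(c.extent for c in comps))
    return float(max(c.intensity for c in comps))


def _max_null_stat(
    p_vals: np.ndarray, t_vals: np.ndarray, iu, ju, n, threshold, statistic
) -> float:
    mask = p_vals < threshold
    if not mask.any():
        return 0.0
    g = nx.Graph()
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    g.add_edges_from(edges)
    best = 0.0
    tvals = dict(zip(edges, t_vals[mask]))
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        if statistic == "extent":
            best = max(best, float(sub.number_of_edges()))
        else:
            best = max(
                best, float(sum(tvals[tuple(sorted(e)) if tuple(sorted(e)) in tvals else e]
                                for e in sub.edges()))
            )
    return best


def _subject_permutations(
    subj_codes: np.ndarray, n_men: int, n_perm: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Subject-level sex reassignments: boolean is_female per subject."""
    n_subj = len(subj_codes)
    total = math.comb(n_subj, n_men)
    if total <= n_perm:
        warnings.warn(
            f"only {total} distinct subject-label permutations; enumerating all",
            stacklevel=3,
        )
        out = []
        for men_set in itertools.combinations(range(n_subj), n_men):
            is_f = np.ones(n_subj, dtype=bool)
            is_f[list(men_set)] = False
            out.append(is_f)
        return out
    out = []
    for _ in range(n_perm):
        perm = rng.permutation(n_subj)
        is_f = np.ones(n_subj, dtype=bool)
        is_f[perm[:n_men]] = False
        out.append(is_f)
    return out


def nbs_permutation(
    fc_stack: list[FCMatrix],
    covariates: pd.DataFrame,
    subject_ids,
    sex_labels,
    n_perm: int = 10_000,
    threshold: float = 0.005,
    direction: str = "women_lt_men",
    statistic: str = "extent",
    seed: int | None = 0,
    adjustment: str = "reduced",
    nuisance=NUISANCE_COVARIATES,
) -> NBSResult:
    """Subject-level permutation FWE inference over supra-threshold components.

    The null distribution is the maximal component statistic under random
    reassignment of sex labels to subjects (sessions follow their subject).
    FWE p = (1 + #{null max >= observed}) / (1 + n_perm), never zero and
    monotone non-increasing in the observed statistic. Deterministic for a
    fixed seed. If fewer distinct permutations exist than requested, all
    are enumerated (with a warning).

    ``adjustment`` controls how nuisance covariates are removed:

    * ``"reduced"`` (default): Freedman-Lane-style residualization on the
      reduced model (nuisance only, no sex term), computed once. The
      adjustment is then label-independent, so subject relabeling is a
      true symmetry of the adjusted data and the permutation test is
      essentially exact.
    * ``"full"``: the sex term stays in the adjustment fit, re-estimated
      with the permuted labels inside every permutation. Because the
      cohort's covariates genuinely differ by sex (education, APOE), the
      observed labeling is the most collinear with the nuisance columns
      and carries the most adjustment noise, which makes this variant
      mildly anticonservative; it is kept for comparison only.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    Y, iu, ju, labels = _edge_matrix(fc_stack)
    n = fc_stack[0].n_regions
    subj = np.asarray(subject_ids)
    sex = np.asarray(sex_labels)
    is_f_obs = (sex == "F") | (sex == 1)

    if adjustment not in ("reduced", "full"):
        raise ValueError(f"unknown adjustment: {adjustment}")
    enc = encode_covariates(covariates.reset_index(drop=True), nuisance)
    X_nuis = (enc[list(nuisance)] - enc[list(nuisance)].mean()).to_numpy() \
        if nuisance else np.empty((len(enc), 0))
    ones = np.ones((len(enc), 1))

    def _adjust_full(is_f_vec: np.ndarray) -> np.ndarray:
        X = np.column_stack([ones, is_f_vec.astype(float), X_nuis])
        B = np.linalg.lstsq(X, Y, rcond=None)[0]
        return Y - X_nuis @ B[2:]

    def _adjust_reduced() -> np.ndarray:
        X = np.column_stack([ones, X_nuis])
        B = np.linalg.lstsq(X, Y, rcond=None)[0]
        return Y - X_nuis @ B[1:]

    subj_codes, subj_idx = np.unique(subj, return_inverse=True)
    counts = np.bincount(subj_idx).astype(float)
    Gnorm = np.zeros((len(subj_codes), len(subj_idx)))
    Gnorm[subj_idx, np.arange(len(subj_idx))] = 1.0
    Gnorm /= counts[:, None]

    adj = _adjust_reduced() if adjustment == "reduced" else _adjust_full(is_f_obs)
    adj_subj = Gnorm @ adj
    subj_is_f = np.zeros(len(subj_codes), dtype=bool)
    for k in range(len(subj_codes)):
        subj_is_f[k] = is_f_obs[subj_idx == k].any()
    t_obs, p_obs, _ = _one_sided_t(adj_subj, subj_is_f, direction)
    obs_stats = EdgeStats(
        t=_square(t_obs, iu, ju, n, fill=0.0),
        p=_square(p_obs, iu, ju, n, fill=1.0),
        direction=direction,
        region_labels=labels,
    )
    components = supra_components(obs_stats, threshold)
    n_men_subj = int((~subj_is_f).sum())

    rng = np.random.default_rng(seed)
    perms = _subject_permutations(subj_codes, n_men_subj, n_perm, rng)
    null_max = np.empty(len(perms))
    for b, perm_is_f_subj in enumerate(perms):
        if adjustment == "full":
            adj_b = Gnorm @ _adjust_full(perm_is_f_subj[subj_idx])
        else:
            adj_b = adj_subj
        t_b, p_b, _ = _one_sided_t(adj_b, perm_is_f_subj, direction)
        null_max[b] = _max_null_stat(p_b, t_b, iu, ju, n, threshold, statistic)

    for comp in components:
        obs = comp.extent if statistic == "extent" else comp.intensity
        comp.fwe_p = float((1 + (null_max >= obs).sum()) / (1 + len(perms)))
    return NBSResult(
        components=components,
        n_permutations=len(perms),
        primary_threshold=threshold,
        direction=direction,
        statistic=statistic,
        seed=seed,
        null_max=null_max,
        region_labels=labels,
    )


def _square(vals: np.ndarray, iu, ju, n: int, fill: float) -> np.ndarray:
    out = np.full((n, n), fill)
    out[iu, ju] = vals
    out[ju, iu] = vals
    np.fill_diagonal(out, fill)
    return out


def macroarea_summary(
    component: Component,
    macroareas: pd.Series,
    region_labels: list[str],
    area_order: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Count component edges within/between macroareas (symmetric 6x6 table).

    The sum of the diagonal plus the upper triangle equals the component
    extent.
    """
    from .atlas import MACROAREAS

    order = list(area_order or MACROAREAS)
    counts = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for i, j in component.edges:
        a = macroareas[region_labels[i]]
        b = macroareas[region_labels[j]]
        if a not in order or b not in order:
            raise KeyError(f"macroarea {a!r} or {b!r} not in area order")
        counts.loc[a, b] += 1
        if a != b:
            counts.loc[b, a] += 1
    return counts
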