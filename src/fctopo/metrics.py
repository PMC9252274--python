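"""Weighted network metrics: strength, efficiency, clustering.

For each thresholded graph the three nodal metrics are

* strength  k_i = sum_j w_ij,
* efficiency  E_i = sum_{j != i} d_ij^{-1} / (n - 1) with d_ij the weighted
  shortest-path length under edge length 1/w (unreachable pairs contribute 0),
* clustering  C_i = 2 t_i / (deg_i (deg_i - 1)) with
  t_i = 1/2 sum_{j,h} (w'_ij w'_jh w'_hi)^{1/3}, w' = w / max(w), and deg_i
  the count of suprathreshold neighbors; C_i = 0 for deg_i < 2.

Global values aggregate nodal values over nodes (mean by default; the sum
variant of global strength is available via ``aggregate='sum'``). Each
metric is computed on every graph of the sparsity sweep, averaged over the
sweep, then z-scored across sessions before inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fc import FCMatrix, ThresholdedGraph, sparsity_grid

METRIC_NAMES = ("strength", "efficiency", "clustering")


def _weights(g) -> np.ndarray:
    return g.weights if hasattr(g, "weights") else np.asarray(g, dtype=float)


def nodal_strength(g: ThresholdedGraph | np.ndarray) -> np.ndarray:
    """Sum of edge weights incident to each node."""
    return _weights(g).sum(axis=1)


def nodal_efficiency(
    g: ThresholdedGraph | np.ndarray, edge_length: str = "inverse"
) -> np.ndarray:
    """Mean inverse weighted shortest-path length from each node to all others.

    Edge lengths are 1/w (``edge_length='neglog'`` uses -log(w), which
    requires weights in (0, 1]). Disconnected pairs have d = inf and
    contribute zero.
    """
    w = _weights(g)
    n = w.shape[0]
    if n < 2:
        return np.zeros(n)
    if edge_length == "inverse":
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1), np.inf)
    elif edge_length == "neglog":
        if (w > 1).any():
            raise ValueError("neglog edge length requires weights <= 1")
        lengths = np.where(w > 0, -np.log(np.where(w > 0, w, 1)), np.inf)
    else:
        raise ValueError(f"unknown edge_length: {edge_length}")
    # vectorized Floyd-Warshall (min-plus); fastest for the sizes used here
    d = lengths
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_clustering(
    g: ThresholdedGraph | np.ndarray, denominator: str = "degree", normalize: str = "max"
) -> np.ndarray:
    """Weighted clustering coefficient (geometric-mean triangle form).

    ``normalize='max'`` rescales weights by the graph maximum before the
    cube-root triangle products; ``denominator`` chooses between the binary
    degree (default, keeps C in [0, 1]) and nodal strength.
    """
    w = _weights(g)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wn = w / wmax if normalize == "max" else w.copy()
    if normalize not in ("max", "none"):
        raise ValueError(f"unknown normalize: {normalize}")
    cbrt = np.cbrt(wn)
    t = np.diag(cbrt @ cbrt @ cbrt) / 2.0
    if denominator == "degree":
        k = (w > 0).sum(axis=1).astype(float)
    elif denominator == "strength":
        k = w.sum(axis=1)
    else:
        raise ValueError(f"unknown denominator: {denominator}")
    denom = k * (k - 1)
    out = np.zeros(n)
    ok = denom > 0
    out[ok] = 2.0 * t[ok] / denom[ok]
    if denominator == "degree":
        out[(w > 0).sum(axis=1) < 2] = 0.0
    return out


def global_metric(nodal: np.ndarray, aggregate: str = "mean") -> float:
    """Aggregate nodal values into the global metric (mean over nodes)."""
    if aggregate == "mean":
        return float(np.mean(nodal))
    if aggregate == "sum":
        return float(np.sum(nodal))
    raise ValueError(f"unknown aggregate: {aggregate}")


def nodal_metric_stack(
    fc: FCMatrix,
    grid: np.ndarray | None = None,
    negative_weights: str = "exclude",
    edge_length: str = "inverse",
    clustering_denominator: str = "degree",
    clustering_normalize: str = "max",
) -> np.ndarray:
    """All three nodal metrics at every sparsity level, as a (L, 3, N) array.

    Axis 1 follows ``METRIC_NAMES`` (strength, efficiency, clustering).
    """
    if grid is None:
        grid = sparsity_grid()
    n = fc.n_regions
    out = np.empty((len(grid), 3, n))
    # proportional-threshold edge sets are nested across the sweep, so sort
    # once and grow one weight matrix instead of re-thresholding per level
    w = fc.z.copy()
    if negative_weights == "exclude":
        w[w < 0] = 0.0
    elif negative_weights == "absolute":
        w = np.abs(w)
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    n_avail = int((vals > 0).sum())
    running = np.zeros((n, n))
    prev = 0
    m_possible = n * (n - 1) // 2
    for li, s in enumerate(grid):
        n_keep = min(int(np.floor(s * m_possible + 0.5)), n_avail)
        new = order[prev:n_keep]
        running[iu[new], ju[new]] = vals[new]
        running[ju[new], iu[new]] = vals[new]
        prev = max(prev, n_keep)
        out[li, 0] = nodal_strength(running)
        out[li, 1] = nodal_efficiency(running, edge_length=edge_length)
        out[li, 2] = nodal_clustering(
            running, denominator=clustering_denominator, normalize=clustering_normalize
        )
    return out


def integrated_nodal_metrics(
    fc: FCMatrix, grid: np.ndarray | None = None, integration: str = "mean", **kwargs
) -> np.ndarray:
    """Sparsity-integrated nodal metrics, shape (3, N)."""
    if grid is None:
        grid = sparsity_grid()
    stack = nodal_metric_stack(fc, grid=grid, **kwargs)
    if integration == "mean":
        return stack.mean(axis=0)
    if integration == "trapezoid":
        return np.trapezoid(stack, grid, axis=0) / (grid[-1] - grid[0])
    raise ValueError(f"unknown integration method: {integration}")


def integrated_global_metrics(
    fc: FCMatrix,
    grid: np.ndarray | None = None,
    integration: str = "mean",
    aggregate: str = "mean",
    **kwargs,
) -> np.ndarray:
    """Sparsity-integrated global metrics (strength, efficiency, clustering)."""
    nodal = integrated_nodal_metrics(fc, grid=grid, integration=integration, **kwargs)
    if aggregate == "mean":
        return nodal.mean(axis=1)
    if aggregate == "sum":
        return nodal.sum(axis=1)
    raise ValueError(f"unknown aggregate: {aggregate}")


def session_metrics(
    fc: FCMatrix, grid: np.ndarray | None = None, **kwargs
) -> pd.DataFrame:
    """All three nodal metrics at every sparsity level for one session.

    Long format: columns (session_id, sparsity, metric, region, value).
    """
    if grid is None:
        grid = sparsity_grid()
    stack = nodal_metric_stack(fc, grid=grid, **kwargs)
    L, _, n = stack.shape
    labels = fc.region_labels
    df = pd.DataFrame(
        {
            "session_id": fc.session_id,
            "sparsity": np.repeat(grid, 3 * n),
            "metric": np.tile(np.repeat(METRIC_NAMES, n), L),
            "region": np.tile(labels, 3 * L),
            "value": stack.reshape(-1),
        }
    )
    return df


def integrate_over_sparsity(
    per_level: pd.Series | np.ndarray,
    grid: np.ndarray | None = None,
    method: str = "mean",
) -> float:
    """Collapse a per-sparsity curve to one number (mean over the grid).

    ``method='trapezoid'`` returns the trapezoid AUC divided by the grid
    range; for an even grid the two differ only in endpoint weighting.
    A Series must be indexed by exactly the grid levels.
    """
    if grid is None:
        grid = sparsity_grid()
    if isinstance(per_level, pd.Series):
        missing = [s for s in grid if s not in per_level.index]
        if missing:
            raise ValueError(f"missing sparsity levels: {missing}")
        vals = per_level.loc[list(grid)].to_numpy(dtype=float)
    else:
        vals = np.asarray(per_level, dtype=float)
        if vals.shape[0] != grid.shape[0]:
            raise ValueError(
                f"expected {grid.shape[0]} levels, got {vals.shape[0]}"
            )
    if method == "mean":
        return float(vals.mean())
    if method == "trapezoid":
        return float(np.trapezoid(vals, grid) / (grid[-1] - grid[0]))
    raise ValueError(f"unknown integration method: {method}")


def integrate_metric_table(
    long_df: pd.DataFrame, grid: np.ndarray | None = None, method: str = "mean"
) -> pd.DataFrame:
    """Sparsity-integrate a long metric table to one value per (session, metric, region)."""
    if grid is None:
        grid = sparsity_grid()
    expected = set(np.round(grid, 6))

    def _agg(group: pd.DataFrame) -> float:
        present = set(np.round(group["sparsity"].to_numpy(), 6))
        missing = sorted(expected - present)
        if missing:
            raise ValueError(f"missing sparsity levels: {missing}")
        ordered = group.sort_values("sparsity")["value"].to_numpy()
        return integrate_over_sparsity(ordered, grid=grid, method=method)

    out = (
        long_df.groupby(["session_id", "metric", "region"], sort=False)
        .apply(_agg, include_groups=False)
        .rename("value")
        .reset_index()
    )
    return out


def global_from_nodal(nodal_df: pd.DataFrame, aggregate: str = "mean") -> pd.DataFrame:
    """Global metric per (session, metric) as the aggregate of nodal values."""
    agg = "mean" if aggregate == "mean" else "sum"
    return (
        nodal_df.groupby(["session_id", "metric"], sort=False)["value"]
        .agg(agg)
        .reset_index()
    )


def zscore_metrics(wide: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize each metric column across all sessions pooled.

    Uses the n-1 denominator. Ranking within a column is unchanged; a
    zero-variance column is an error.
    """
    if len(wide) < 2:
        raise ValueError("need at least 2 sessions to z-score")
    out = wide.copy()
    num = out.select_dtypes(include=[np.number]).columns
    for col in num:
        sd = out[col].std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance; cannot z-score")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


def compute_metric_tables(
    fc_by_session: dict[str, FCMatrix],
    grid: np.ndarray | None = None,
    integration: str = "mean",
    aggregate: str = "mean",
    **metric_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full metric stage for a stack of sessions.

    Returns ``(nodal, global)``: sparsity-integrated nodal values in long
    format and a wide per-session global table with columns
    ``strength, efficiency, clustering``.
    """
    if grid is None:
        grid = sparsity_grid()
    nodal_frames = []
    glob_rows = {}
    for sid, fcm in fc_by_session.items():
        integ = integrated_nodal_metrics(
            fcm, grid=grid, integration=integration, **metric_kwargs
        )
        n = fcm.n_regions
        nodal_frames.append(
            pd.DataFrame(
                {
                    "session_id": sid,
                    "metric": np.repeat(METRIC_NAMES, n),
                    "region": np.tile(fcm.region_labels, 3),
                    "value": integ.reshape(-1),
                }
            )
        )
        glob_rows[sid] = integ.mean(axis=1) if aggregate == "mean" else integ.sum(axis=1)
    nodal = pd.concat(nodal_frames, ignore_index=True)
    wide = pd.DataFrame.from_dict(glob_rows, orient="index", columns=list(METRIC_NAMES))
    wide.index.name = "session_id"
    return nodal, wide
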