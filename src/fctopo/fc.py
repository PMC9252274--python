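"""Functional connectivity matrices and proportional sparsity thresholding.

FC between two regions is the Fisher r-to-z transform of the Pearson
correlation of their time series. Graphs stay weighted at every sparsity
level: thresholding selects which edges survive, never binarizes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_R_CLIP = 1 - 1e-7


@dataclass
class ROITimeSeries:
    """T x N regional time-series table for one fMRI session."""

    values: np.ndarray
    region_labels: list[str]
    session_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a T x N table")
        T, n = self.values.shape
        if T < 3:
            raise ValueError(f"need at least 3 timepoints, got {T}")
        if len(self.region_labels) != n:
            raise ValueError("region_labels length does not match column count")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains non-finite values")


@dataclass
class FCMatrix:
    """N x N symmetric Fisher-z connectivity matrix with zero diagonal."""

    z: np.ndarray
    region_labels: list[str]
    session_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(self.z, self.z.T, atol=0, rtol=0):
            raise ValueError("FC matrix must be exactly symmetric")
        if np.any(np.diag(self.z) != 0):
            raise ValueError("FC matrix diagonal must be zero")
        if not np.isfinite(self.z).all():
            raise ValueError("FC matrix contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class ThresholdedGraph:
    """Weighted undirected graph retained at one sparsity level."""

    weights: np.ndarray
    sparsity: float
    n_edges_kept: int
    region_labels: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def compute_fc(ts: ROITimeSeries) -> FCMatrix:
    """Pearson correlation between all region pairs, Fisher r-to-z transformed.

    Correlations are clipped to |r| <= 1 - 1e-7 before atanh so duplicated
    series cannot produce infinities. A constant region is an error (its
    correlation is undefined) and is reported by label.
    """
    x = ts.values
    sd = x.std(axis=0)
    scale = np.abs(x).max(axis=0) + 1.0
    dead = np.flatnonzero(sd <= 1e-12 * scale)
    if dead.size:
        names = [ts.region_labels[i] for i in dead]
        raise ValueError(f"constant (zero-variance) regions: {names}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return FCMatrix(z=z, region_labels=list(ts.region_labels), session_id=ts.session_id)


def sparsity_grid(
    start: float = 0.05, stop: float = 0.50, step: float = 0.01
) -> np.ndarray:
    """The sparsity sweep: 0.05, 0.06, ..., 0.50 (46 levels by default).

    Computed with integer arithmetic so the grid is free of floating-point
    drift and the endpoints are exact.
    """
    k = int(round(step * 100))
    lo, hi = int(round(start * 100)), int(round(stop * 100))
    return np.array([i / 100 for i in range(lo, hi + 1, k)])


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def apply_sparsity(
    fc: FCMatrix, s: float, negative_weights: str = "exclude"
) -> ThresholdedGraph:
    """Keep the top ``round(s * N(N-1)/2)`` positive edges at original weight.

    Negative Fisher-z edges are excluded before ranking by default
    (``negative_weights='absolute'`` ranks and keeps magnitudes instead).
    Ties are broken by (i, j) index so edge sets are deterministic and
    nested across the sweep. If fewer positive edges exist than requested,
    all of them are kept and a warning is emitted.
    """
    if not 0 < s <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {s}")
    n = fc.n_regions
    w = fc.z.copy()
    if negative_weights == "exclude":
        w[w < 0] = 0.0
    elif negative_weights == "absolute":
        w = np.abs(w)
    elif negative_weights != "keep":
        raise ValueError(f"unknown negative_weights policy: {negative_weights}")

    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    pos = vals > 0
    n_target = _round_half_away(s * n * (n - 1) / 2)
    n_avail = int(pos.sum())
    if n_avail < n_target:
        warnings.warn(
            f"only {n_avail} positive edges available for target {n_target}; keeping all",
            stacklevel=2,
        )
    n_keep = min(n_target, n_avail)
    # primary key: descending weight; ties: ascending (i, j)
    order = np.lexsort((ju, iu, -vals))
    keep = order[:n_keep]
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = vals[keep]
    out = out + out.T
    return ThresholdedGraph(
        weights=out, sparsity=s, n_edges_kept=n_keep,
        region_labels=list(fc.region_labels),
    )
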