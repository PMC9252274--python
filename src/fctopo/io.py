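"""Plain-text readers/writers for time series, participants, and matrices.

Everything is delimited text: session time series are TSV with a header of
region labels, FC matrices are CSV with label header row and index column,
and the participants/sessions table is CSV. The pipeline starts at ROI
time series, so no imaging formats are handled.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .fc import FCMatrix, ROITimeSeries


def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    df = pd.DataFrame(ts.values, columns=ts.region_labels)
    # default float formatting is the shortest round-trip repr (lossless)
    df.to_csv(path, sep="\t", index=False)


def read_timeseries(
    path: str | Path,
    atlas_labels: list[str] | None = None,
    session_id: str | None = None,
) -> ROITimeSeries:
    """Read a T x N delimited time-series file (header = region labels).

    If ``atlas_labels`` is given, the columns are checked against it;
    a permuted column order is fixed by reordering (with a warning), a
    label mismatch is an error. Ragged or non-numeric rows raise.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path.name}: malformed delimited file ({err})") from err
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as err:
        raise ValueError(f"{path.name}: non-numeric cell ({err})") from err
    labels = list(df.columns)
    if atlas_labels is not None:
        if set(labels) != set(atlas_labels):
            extra = sorted(set(labels) - set(atlas_labels))
            missing = sorted(set(atlas_labels) - set(labels))
            raise ValueError(
                f"{path.name}: region labels do not match atlas "
                f"(extra={extra[:5]}, missing={missing[:5]})"
            )
        if labels != list(atlas_labels):
            warnings.warn(
                f"{path.name}: columns reordered to atlas order", stacklevel=2
            )
            df = df[list(atlas_labels)]
            values = df.to_numpy(dtype=float)
            labels = list(atlas_labels)
    return ROITimeSeries(
        values=values,
        region_labels=labels,
        session_id=session_id or path.stem,
    )


def write_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    pd.DataFrame(fc.z, index=fc.region_labels, columns=fc.region_labels).to_csv(path)


def read_fc_matrix(path: str | Path, session_id: str | None = None) -> FCMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    z = df.to_numpy(dtype=float)
    z = (z + z.T) / 2  # symmetrize away text round-trip noise
    np.fill_diagonal(z, 0.0)
    return FCMatrix(
        z=z, region_labels=list(df.columns), session_id=session_id or Path(path).stem
    )


def write_participants(sessions: pd.DataFrame, path: str | Path) -> None:
    sessions.to_csv(path, index=False)


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["mri_date", "pet_date"])
    required = {"subject_id", "session_id", "sex", "age", "education",
                "handedness", "apoe4"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"participants table lacks columns: {sorted(missing)}")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
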