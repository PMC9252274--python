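"""Region labels and macroarea grouping for the 94-region cerebral atlas.

The bundled mapping assigns each of the 94 cortical/subcortical regions
(47 bilateral pairs) to one of six anatomical macroareas: prefrontal,
other frontal, occipital, temporal, parietal, and central structures.
It approximates standard lobar anatomy and is shipped as an editable CSV —
treat it as configuration, not as a canonical atlas definition.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

MACROAREAS = (
    "prefrontal",
    "other_frontal",
    "occipital",
    "temporal",
    "parietal",
    "central_structures",
)

#: Regions where the implanted sex effect runs in the opposite direction
#: (bilateral thalamus, right caudate, left putamen).
DEFAULT_REVERSAL_LABELS = ("Thalamus_L", "Thalamus_R", "Caudate_R", "Putamen_L")


def load_macroarea_table(path: str | None = None) -> pd.DataFrame:
    """Return the region -> macroarea mapping as a two-column DataFrame."""
    if path is None:
        ref = resources.files("fctopo.data").joinpath("aal94_macroareas.csv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    missing = {"region_label", "macroarea"} - set(table.columns)
    if missing:
        raise ValueError(f"mapping table lacks columns: {sorted(missing)}")
    return table


def region_labels(n_regions: int = 94) -> list[str]:
    """Atlas region labels; synthetic ``ROI_k`` names for non-94 toy sizes."""
    if n_regions == 94:
        return load_macroarea_table()["region_label"].tolist()
    return [f"ROI_{i:03d}" for i in range(n_regions)]


def macroarea_assign(
    labels: Sequence[str], mapping: Mapping[str, str] | pd.DataFrame | None = None
) -> pd.Series:
    """Assign a macroarea to every region label.

    Raises ``KeyError`` listing any unmapped region; the result is a Series
    indexed by region label in the input order.
    """
    if mapping is None:
        mapping = load_macroarea_table()
    if isinstance(mapping, pd.DataFrame):
        mapping = dict(zip(mapping["region_label"], mapping["macroarea"]))
    unmapped = [lab for lab in labels if lab not in mapping]
    if unmapped:
        raise KeyError(f"regions missing from macroarea mapping: {unmapped}")
    return pd.Series([mapping[lab] for lab in labels], index=list(labels), name="macroarea")


def default_reversal_indices(labels: Sequence[str]) -> tuple[int, ...]:
    """Indices of the default reversal regions present in ``labels``."""
    return tuple(i for i, lab in enumerate(labels) if lab in DEFAULT_REVERSAL_LABELS)
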