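"""Barell matrix cells and TBI typing for ICD-9-CM diagnosis codes.

The Barell injury diagnosis matrix cross-classifies ICD-9-CM injury codes by
body region and nature of injury; its first three rows define traumatic brain
injury as Type 1 (intracranial injury or moderate/prolonged loss of
consciousness), Type 2 (no intracranial injury, LOC under one hour or of
unspecified duration) and Type 3 (no intracranial injury, no LOC). Lookup is
at full code precision: a code that requires a fifth digit but arrives with
four is unmappable, mirroring the missingness mechanism of real discharge
data.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .assets import barell_cell_map, tbi_type_map
from .records import split_codes

TBI_TYPES = ("type1", "type2", "type3")


@dataclass(frozen=True)
class BarellCell:
    body_region: str | None
    nature: str | None
    mappable: bool


def map_barell(dx_code: str) -> BarellCell:
    """Barell matrix cell of a diagnosis code (unmappable if the code is not
    an injury code or lacks a required fifth digit)."""
    if not dx_code:
        raise ValueError("empty diagnosis code")
    cell = barell_cell_map().get(str(dx_code))
    if cell is None:
        return BarellCell(None, None, False)
    return BarellCell(cell[0], cell[1], True)


def classify_tbi(dx_code: str) -> str:
    """TBI type of a diagnosis code: ``type1``/``type2``/``type3``/``not_tbi``."""
    if not dx_code:
        raise ValueError("empty diagnosis code")
    return tbi_type_map().get(str(dx_code), "not_tbi")


def annotate_tbi(records: pd.DataFrame) -> pd.DataFrame:
    """Annotate visits with Barell/TBI columns.

    ``tbi_primary`` and ``tbi_type`` come from the FIRST-listed (primary)
    diagnosis; ``tbi_any`` flags a TBI code in any position (the broader
    "implicated in the death" sense). ``barell_region``/``barell_nature``/
    ``barell_mappable`` describe the primary diagnosis cell.
    """
    tmap = tbi_type_map()
    bmap = barell_cell_map()
    tbi_type, tbi_primary, tbi_any = [], [], []
    region, nature, mappable = [], [], []
    for cell in records["dx_codes"].fillna(""):
        codes = split_codes(cell)
        if not codes:
            tbi_type.append("none")
            tbi_primary.append(0)
            tbi_any.append(0)
            region.append(None)
            nature.append(None)
            mappable.append(False)
            continue
        first = codes[0]
        t = tmap.get(first, "not_tbi")
        tbi_type.append(t if t in TBI_TYPES else "none")
        tbi_primary.append(int(t in TBI_TYPES))
        tbi_any.append(int(any(tmap.get(c, "not_tbi") in TBI_TYPES for c in codes)))
        b = bmap.get(first)
        region.append(None if b is None else b[0])
        nature.append(None if b is None else b[1])
        mappable.append(b is not None)
    out = records.copy()
    out["tbi_type"] = tbi_type
    out["tbi_primary"] = np.asarray(tbi_primary, dtype=np.int8)
    out["tbi_any"] = np.asarray(tbi_any, dtype=np.int8)
    out["barell_region"] = region
    out["barell_nature"] = nature
    out["barell_mappable"] = mappable
    return out


class BarellAnnotator(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapping :func:`annotate_tbi`."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return annotate_tbi(X)
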