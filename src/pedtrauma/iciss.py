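"""ICD-derived Injury Severity Score (ICISS).

The survival risk ratio (SRR) of a diagnosis code is the fraction of its
occurrences that fall on surviving patients; a patient's ICISS is the product
of the SRRs of their listed diagnoses (up to ten), interpreted as a survival
probability. Severe injury is a survival probability strictly below 0.94,
i.e. an estimated death probability of 6% or more.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .records import split_codes

logger = logging.getLogger(__name__)

SEVERITY_THRESHOLD = 0.94
MAX_CODES = 10


@dataclass
class SRRTable:
    """Diagnosis-code -> survival-risk-ratio map with occurrence counts."""

    entries: dict = field(default_factory=dict)  # code -> (srr, n_total, n_survived)
    min_count: int = 10

    def srr(self, code: str):
        e = self.entries.get(code)
        return None if e is None else e[0]

    def __len__(self):
        return len(self.entries)

    def __contains__(self, code):
        return code in self.entries

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, n, s, r) for c, (r, n, s) in sorted(self.entries.items())]
        return pd.DataFrame(rows, columns=["code", "n_total", "n_survived", "srr"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, min_count: int = 0) -> "SRRTable":
        df = pd.read_csv(path, dtype={"code": str}, float_precision="round_trip")
        entries = {
            r.code: (float(r.srr), int(r.n_total), int(r.n_survived))
            for r in df.itertuples()
        }
        return cls(entries=entries, min_count=min_count)


def estimate_srrs(records: pd.DataFrame, min_count: int = 10) -> SRRTable:
    """Estimate SRRs from visit records (unweighted occurrence counts).

    Every listed occurrence of a code counts once; codes seen fewer than
    ``min_count`` times are omitted from the table (their ICISS contribution
    is then flagged as missing rather than estimated from a handful of
    visits).
    """
    if len(records) == 0:
        logger.warning("estimate_srrs called on empty input; returning empty table")
        return SRRTable(entries={}, min_count=min_count)
    dx = records["dx_codes"].fillna("").astype(str)
    survived = 1 - records["died"].to_numpy().astype(int)
    totals: dict[str, int] = {}
    surv: dict[str, int] = {}
    for cell, s in zip(dx, survived):
        for code in cell.split("|") if cell else []:
            totals[code] = totals.get(code, 0) + 1
            surv[code] = surv.get(code, 0) + s
    entries = {
        c: (surv[c] / n, n, surv[c])
        for c, n in totals.items() if n >= min_count
    }
    return SRRTable(entries=entries, min_count=min_count)


@dataclass
class ICISSResult:
    survival_probability: float | None
    n_codes_used: int
    severe: bool | None
    complete: bool


def flag_severe(probability: float) -> bool:
    """Severe injury indicator: survival probability strictly below 0.94."""
    return probability < SEVERITY_THRESHOLD


def compute_iciss(dx_codes, srr_table: SRRTable,
                  threshold: float = SEVERITY_THRESHOLD) -> ICISSResult:
    """ICISS of one visit: product of SRRs over the first ten listed codes.

    Codes among the first ten without an SRR entry are skipped and the result
    is flagged ``complete=False``. An empty code list yields an undefined
    (None) probability.
    """
    codes = list(dx_codes)[:MAX_CODES]
    if not codes:
        logger.warning("compute_iciss: empty diagnosis list; probability undefined")
        return ICISSResult(None, 0, None, False)
    prob, used = 1.0, 0
    for code in codes:
        s = srr_table.srr(code)
        if s is not None:
            prob *= s
            used += 1
    if used == 0:
        return ICISSResult(None, 0, None, False)
    return ICISSResult(prob, used, prob < threshold, used == len(codes))


class ICISSScorer(BaseEstimator, TransformerMixin):
    """Estimate SRRs on fit, score visits on transform.

    Parameters
    ----------
    min_count : minimum occurrences for a code to receive an SRR entry.
    threshold : severity cut point on the survival probability (default 0.94).
    srr_table : optional externally supplied :class:`SRRTable`; when given,
        ``fit`` uses it verbatim instead of estimating from the data.

    Attributes
    ----------
    srr_table_ : the fitted (or adopted) SRR table.
    """

    def __init__(self, min_count: int = 10, threshold: float = SEVERITY_THRESHOLD,
                 srr_table: SRRTable | None = None):
        self.min_count = min_count
        self.threshold = threshold
        self.srr_table = srr_table

    def fit(self, X: pd.DataFrame, y=None):
        if self.srr_table is not None:
            self.srr_table_ = self.srr_table
        else:
            self.srr_table_ = estimate_srrs(X, min_count=self.min_count)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "srr_table_"):
            raise RuntimeError("ICISSScorer must be fitted before transform")
        out = X.copy()
        res = [
            compute_iciss(split_codes(cell), self.srr_table_, self.threshold)
            for cell in out["dx_codes"].fillna("")
        ]
        out["iciss"] = [r.survival_probability for r in res]
        out["severe"] = [np.nan if r.severe is None else int(r.severe) for r in res]
        out["iciss_n_codes"] = [r.n_codes_used for r in res]
        out["iciss_complete"] = [r.complete for r in res]
        return out
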