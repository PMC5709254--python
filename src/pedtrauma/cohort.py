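"""Cohort definition: E-code mechanism classification and inclusion rules.

The analysis cohort is every ED visit whose external-cause codes identify a
pedestrian or bicyclist (pedalcyclist) struck by or colliding with a motorized
vehicle — including pedestrians struck by bicyclists — and excluding
bicyclists injured by other bicyclists or themselves (E826.1-.4, .8-.9) and
motor-vehicle occupants injured in a collision with a pedestrian (E814.0-.4).
"""
from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .assets import ecode_category_map, ecode_group_map
from .records import split_codes

logger = logging.getLogger(__name__)

AGE_GROUPS = ("0-4", "5-9", "10-14", "15-19")
_ECODE_RE = re.compile(r"^E\d{3,4}$")

QUALIFYING = {"pedestrian", "bicyclist"}
EXCLUDING = {"excluded_occupant", "excluded_cyclist_only"}


def classify_ecode(code: str) -> str:
    """Mechanism category of a single well-formed E-code.

    Returns one of ``pedestrian``, ``bicyclist``, ``excluded_occupant``,
    ``excluded_cyclist_only`` or ``other``; classification is total over
    well-formed codes (anything outside the lookup asset is ``other``).
    """
    if not isinstance(code, str) or not _ECODE_RE.match(code):
        raise ValueError(f"malformed E-code: {code!r}")
    return ecode_category_map().get(code, "other")


def assign_age_group(age) -> str:
    """Pediatric age bin (0-4, 5-9, 10-14, 15-19 years), bounds inclusive."""
    age = int(age)
    if not 0 <= age <= 19:
        raise ValueError(f"age {age} outside the pediatric range 0-19")
    return AGE_GROUPS[age // 5]


def _age_group_series(age: pd.Series) -> pd.Series:
    if ((age < 0) | (age > 19)).any():
        raise ValueError("age outside the pediatric range 0-19")
    return pd.Series(np.asarray(AGE_GROUPS, dtype=object)[age.to_numpy() // 5],
                     index=age.index)


def extract_cohort(records: pd.DataFrame, return_summary: bool = False):
    """Apply the inclusion/exclusion rules and annotate mechanism.

    A visit enters the cohort iff at least one of its E-codes classifies as
    pedestrian or bicyclist AND none classifies as an exclusion. The mechanism
    comes from the first qualifying E-code in listed order (a visit listing a
    pedestrian code before a bicyclist code is a pedestrian). Adds
    ``mechanism``, ``matched_ecode`` and ``age_group`` columns; idempotent on
    its own output.

    With ``return_summary=True`` also returns a dict of bookkeeping counts,
    including sensitivity counts with/without the non-traffic (E820-E825)
    code block.
    """
    cat = ecode_category_map()
    grp = ecode_group_map()

    mechanisms, matched, included, nontraffic_only = [], [], [], []
    excluded_by_rule = 0
    for cell in records["ecodes"].fillna(""):
        codes = split_codes(cell)
        cats = [cat.get(c, "other") for c in codes]
        if any(c in EXCLUDING for c in cats):
            included.append(False)
            mechanisms.append(None)
            matched.append(None)
            nontraffic_only.append(False)
            excluded_by_rule += 1
            continue
        mech, hit = None, None
        for code, c in zip(codes, cats):
            if c in QUALIFYING:
                mech, hit = c, code
                break
        included.append(mech is not None)
        mechanisms.append(mech)
        matched.append(hit)
        if mech is not None:
            traffic_hit = any(
                cat.get(c) in QUALIFYING and grp.get(c) != "nontraffic"
                for c in codes)
            nontraffic_only.append(not traffic_hit)
        else:
            nontraffic_only.append(False)

    inc = np.asarray(included)
    cohort = records.loc[inc].copy()
    cohort["mechanism"] = np.asarray(mechanisms, dtype=object)[inc]
    cohort["matched_ecode"] = np.asarray(matched, dtype=object)[inc]
    cohort["age_group"] = _age_group_series(cohort["age"])

    summary = {
        "n_input": len(records),
        "n_included": int(inc.sum()),
        "n_excluded": int(len(records) - inc.sum()),
        "n_excluded_by_exclusion_code": excluded_by_rule,
        "n_included_nontraffic_only": int(np.asarray(nontraffic_only)[inc].sum()),
        "n_included_traffic": int(inc.sum() - np.asarray(nontraffic_only)[inc].sum()),
    }
    logger.info("cohort extraction: %s", summary)
    if return_summary:
        return cohort, summary
    return cohort


class EcodeCohortExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapping :func:`extract_cohort` for pipelines."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return extract_cohort(X)
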