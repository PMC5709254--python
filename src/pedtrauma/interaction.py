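"""Additive interaction between pedestrian status and TBI on fatality risk.

The interaction contrast (IC) measures departure from risk additivity across
the four exposure cells {pedestrian, bicyclist} x {TBI, no TBI}:

    IC = r_pp - r_pm - r_mp + r_mm

with r_pp the risk in the doubly exposed (pedestrian, TBI) cell. The
proportion of the doubly-exposed risk attributable to the interaction (AP)
is IC / r_pp. Survey uncertainty comes from a stratified cluster bootstrap:
hospitals are resampled with replacement within strata and the quartet, IC
and AP recomputed per replicate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CELLS = ("ped_tbi", "ped_notbi", "bike_tbi", "bike_notbi")


@dataclass(frozen=True)
class RiskQuartet:
    """Weighted fatality risks in the four exposure cells, on a common
    per-``scale``-discharges risk scale."""

    r_pp: float  # pedestrian, TBI
    r_pm: float  # pedestrian, no TBI
    r_mp: float  # bicyclist, TBI
    r_mm: float  # bicyclist, no TBI
    scale: float = 1.0

    def as_tuple(self):
        return (self.r_pp, self.r_pm, self.r_mp, self.r_mm)


@dataclass
class InteractionResult:
    quartet: RiskQuartet
    ic: float                       # plug-in interaction contrast
    attributable_proportion: float  # plug-in IC / r_pp
    ic_boot: float                  # bootstrap replicate means
    ap_boot: float
    ic_ci_low: float
    ic_ci_high: float
    ap_ci_low: float
    ap_ci_high: float
    n_boot: int
    n_dropped: int
    seed: int


def _cell_masks(cohort: pd.DataFrame, tbi_col: str):
    ped = (cohort["mechanism"] == "pedestrian").to_numpy()
    tbi = cohort[tbi_col].to_numpy().astype(bool)
    return {
        "ped_tbi": ped & tbi,
        "ped_notbi": ped & ~tbi,
        "bike_tbi": ~ped & tbi,
        "bike_notbi": ~ped & ~tbi,
    }


def cell_risks(cohort: pd.DataFrame, tbi_col: str = "tbi_primary",
               scale: float = 1e5) -> RiskQuartet:
    """Weighted death risk per cell (default per 100,000 discharges)."""
    w = cohort["weight"].to_numpy(dtype=float)
    d = cohort["died"].to_numpy(dtype=float)
    risks = {}
    for name, mask in _cell_masks(cohort, tbi_col).items():
        denom = float(w[mask].sum())
        if denom == 0:
            raise ValueError(f"empty exposure cell: {name}")
        risks[name] = float((w * d)[mask].sum()) / denom * scale
    return RiskQuartet(risks["ped_tbi"], risks["ped_notbi"],
                       risks["bike_tbi"], risks["bike_notbi"], scale=scale)


def interaction_contrast(q: RiskQuartet) -> float:
    """IC = r_pp - r_pm - r_mp + r_mm (exact arithmetic, same scale as q)."""
    return q.r_pp - q.r_pm - q.r_mp + q.r_mm


def attributable_proportion(ic: float, r_pp: float) -> float:
    """Share of the doubly-exposed risk attributable to the interaction."""
    if r_pp <= 0:
        raise ValueError(f"doubly-exposed risk must be positive, got {r_pp}")
    return ic / r_pp


def _bootstrap_cell_replicates(cohort: pd.DataFrame, reps: int, seed: int,
                               tbi_col: str, scale: float):
    """Stratified cluster-bootstrap replicates of the four cell risks.

    Pre-aggregates to cluster x cell (weight sum, weighted death sum) so that
    a replicate is a sum over resampled cluster rows; resampled weights carry
    the n_h/(n_h-1) rescaling factor. Returns ``(risks, n_dropped)`` where
    ``risks`` has one row per retained replicate, columns ordered as
    :data:`CELLS`; replicates with an empty cell are dropped.
    """
    masks = _cell_masks(cohort, tbi_col)
    w = cohort["weight"].to_numpy(dtype=float)
    wd = w * cohort["died"].to_numpy(dtype=float)
    cl = cohort["cluster_id"].to_numpy()
    st = cohort["stratum_id"].to_numpy()
    clusters, cl_index = np.unique(cl, return_inverse=True)
    n_cl = len(clusters)
    agg = np.zeros((n_cl, 8))
    for j, name in enumerate(CELLS):
        m = masks[name]
        np.add.at(agg[:, 2 * j], cl_index[m], w[m])
        np.add.at(agg[:, 2 * j + 1], cl_index[m], wd[m])
    cluster_stratum = np.empty(n_cl, dtype=st.dtype)
    cluster_stratum[cl_index] = st
    strata_ids = np.unique(cluster_stratum)
    stratum_members = [np.flatnonzero(cluster_stratum == s) for s in strata_ids]

    rng = np.random.default_rng(seed)
    out = []
    dropped = 0
    for _ in range(reps):
        tot = np.zeros(8)
        for members in stratum_members:
            n_h = len(members)
            pick = members[rng.integers(n_h, size=n_h)]
            factor = n_h / (n_h - 1) if n_h > 1 else 1.0
            tot += factor * agg[pick].sum(axis=0)
        denoms = tot[0::2]
        if (denoms == 0).any():
            dropped += 1
            continue
        out.append(tot[1::2] / denoms * scale)
    return np.asarray(out).reshape(-1, 4), dropped


def bootstrap_cell_risks(cohort: pd.DataFrame, reps: int = 1000, seed: int = 0,
                         tbi_col: str = "tbi_primary",
                         scale: float = 1.0) -> dict:
    """Percentile bootstrap CIs for the four cell risks themselves.

    Returns ``{cell: (point, ci_low, ci_high)}`` with the plug-in point
    estimate and 2.5/97.5 bootstrap percentiles.
    """
    q = cell_risks(cohort, tbi_col=tbi_col, scale=scale)
    risk_reps, dropped = _bootstrap_cell_replicates(cohort, reps, seed, tbi_col,
                                                    scale)
    if dropped > reps / 2:
        raise ValueError(f"{dropped}/{reps} bootstrap replicates had an empty "
                         "exposure cell; design too sparse")
    points = dict(zip(CELLS, q.as_tuple()))
    out = {}
    for j, name in enumerate(CELLS):
        lo, hi = np.percentile(risk_reps[:, j], [2.5, 97.5])
        out[name] = (points[name], float(lo), float(hi))
    return out


def bootstrap_interaction(cohort: pd.DataFrame, reps: int = 1000, seed: int = 0,
                          tbi_col: str = "tbi_primary",
                          scale: float = 1e5) -> InteractionResult:
    """Stratified cluster bootstrap of the interaction contrast and AP.

    Hospitals (clusters) are resampled with replacement within their strata;
    resampled weights carry the n_h/(n_h-1) rescaling factor. Replicates in
    which an exposure cell comes up empty are dropped and counted; more than
    50% dropped replicates aborts (the design is too sparse to bootstrap).
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    quartet = cell_risks(cohort, tbi_col=tbi_col, scale=scale)
    ic = interaction_contrast(quartet)
    ap = attributable_proportion(ic, quartet.r_pp)

    risk_reps, dropped = _bootstrap_cell_replicates(cohort, reps, seed, tbi_col,
                                                   scale)
    ics, aps = [], []
    for r in risk_reps:
        ic_b = r[0] - r[1] - r[2] + r[3]
        ics.append(ic_b)
        aps.append(ic_b / r[0] if r[0] > 0 else np.nan)
    if dropped > reps / 2:
        raise ValueError(
            f"{dropped}/{reps} bootstrap replicates had an empty exposure "
            "cell; design too sparse")
    ics = np.asarray(ics)
    aps = np.asarray(aps)
    ic_lo, ic_hi = np.percentile(ics, [2.5, 97.5])
    ap_lo, ap_hi = np.percentile(aps, [2.5, 97.5])
    return InteractionResult(
        quartet=quartet, ic=ic, attributable_proportion=ap,
        ic_boot=float(ics.mean()), ap_boot=float(np.nanmean(aps)),
        ic_ci_low=float(ic_lo), ic_ci_high=float(ic_hi),
        ap_ci_low=float(ap_lo), ap_ci_high=float(ap_hi),
        n_boot=len(ics), n_dropped=dropped, seed=seed)
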