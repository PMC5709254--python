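"""Design-based estimation for the stratified single-cluster sample.

Totals use the with-replacement first-stage approximation: within stratum h
with n_h sampled clusters and weighted cluster totals t_hi,

    Var(total) = sum_h  n_h / (n_h - 1) * sum_i (t_hi - tbar_h)^2 .

Domain (subpopulation) totals are handled by zero contribution — every
sampled cluster keeps its membership in the variance computation whether or
not it contains domain records. Ratio and percent-change uncertainty uses the
Monte-Carlo simulation method: independent normal draws around the two
survey estimates, percentile interval of the per-draw statistic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.96


@dataclass
class SurveyEstimate:
    point: float
    se: float
    ci_low: float
    ci_high: float
    n_records: int
    design_df: int

    @classmethod
    def from_point_se(cls, point, se, n_records=0, design_df=0):
        return cls(point, se, point - Z95 * se, point + Z95 * se,
                   n_records, design_df)


@dataclass
class RateEstimate:
    numerator: SurveyEstimate
    denominator: float
    unit: str
    scale: float
    rate: float
    ci_low: float
    ci_high: float


def weighted_total(records: pd.DataFrame, domain=None) -> SurveyEstimate:
    """Survey-weighted total of a domain indicator with stratified-cluster SE.

    ``domain`` is a boolean mask aligned with ``records`` (or ``None`` for
    the whole population). A stratum with a single sampled cluster cannot
    contribute a variance term; it is treated as a certainty unit (zero
    contribution) with a warning.
    """
    if len(records) == 0:
        return SurveyEstimate.from_point_se(0.0, 0.0, 0, 0)
    w = records["weight"].to_numpy(dtype=float)
    if domain is None:
        ind = np.ones(len(records))
    else:
        ind = np.asarray(domain, dtype=float)
        if ind.shape[0] != len(records):
            raise ValueError("domain indicator length mismatch")
    contrib = w * ind
    cluster_tot = (
        pd.DataFrame({
            "stratum": records["stratum_id"].to_numpy(),
            "cluster": records["cluster_id"].to_numpy(),
            "z": contrib,
        })
        .groupby(["stratum", "cluster"], sort=True)["z"].sum()
    )
    point = float(contrib.sum())
    var = 0.0
    n_clusters = 0
    for _, z in cluster_tot.groupby(level=0, sort=True):
        n_h = len(z)
        n_clusters += n_h
        if n_h == 1:
            warnings.warn(
                "stratum with a single cluster treated as certainty unit "
                "(zero variance contribution)", stacklevel=2)
            continue
        zv = z.to_numpy()
        var += n_h / (n_h - 1) * float(((zv - zv.mean()) ** 2).sum())
    se = float(np.sqrt(var))
    design_df = n_clusters - cluster_tot.index.get_level_values(0).nunique()
    return SurveyEstimate.from_point_se(point, se, int(ind.sum()), design_df)


def weighted_proportion(records: pd.DataFrame, domain, base=None) -> float:
    """Weighted share of ``domain`` among ``base`` (whole table by default)."""
    w = records["weight"].to_numpy(dtype=float)
    d = np.asarray(domain, dtype=float)
    b = np.ones(len(records)) if base is None else np.asarray(base, dtype=float)
    denom = float((w * b).sum())
    if denom == 0:
        raise ValueError("empty base domain")
    return float((w * d * b).sum()) / denom


def compute_rate(numerator: SurveyEstimate, denominator: float, scale: float,
                 unit: str = "") -> RateEstimate:
    """Rate = numerator / denominator x scale, CI scaled alongside."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    f = scale / denominator
    return RateEstimate(
        numerator=numerator, denominator=denominator, unit=unit, scale=scale,
        rate=numerator.point * f,
        ci_low=numerator.ci_low * f, ci_high=numerator.ci_high * f)


def simulate_ratio(a: SurveyEstimate, b: SurveyEstimate, kind: str = "ratio",
                   draws: int = 1000, seed: int = 0) -> SurveyEstimate:
    """Simulation-method CI for a ratio or percent change of two estimates.

    Draws ``a* ~ N(a.point, a.se)`` and ``b* ~ N(b.point, b.se)``
    independently; the statistic per draw is ``a*/b*`` (``kind='ratio'``) or
    ``(a* - b*)/a* x 100`` (``kind='percent_change'``, with ``a`` the earlier
    period so a decline is positive). The point estimate is the median of the
    draws and the CI the 2.5/97.5 percentiles. Draws with a non-positive
    denominator are rejected and resampled (count reported via warning).
    """
    if draws < 2:
        raise ValueError("draws must be >= 2")
    if kind not in ("ratio", "percent_change"):
        raise ValueError(f"unknown kind {kind!r}")
    if kind == "ratio" and b.point == 0:
        raise ValueError("ratio denominator point estimate is zero")
    rng = np.random.default_rng(seed)
    vals = np.empty(draws)
    filled = 0
    rejected = 0
    while filled < draws:
        m = draws - filled
        a_star = rng.normal(a.point, a.se, size=m)
        b_star = rng.normal(b.point, b.se, size=m)
        if kind == "ratio":
            ok = b_star > 0
            stat = np.where(ok, a_star / np.where(ok, b_star, 1.0), np.nan)
        else:
            ok = a_star > 0
            stat = np.where(ok, (a_star - b_star) / np.where(ok, a_star, 1.0) * 100.0,
                            np.nan)
        kept = stat[ok]
        vals[filled:filled + len(kept)] = kept
        filled += len(kept)
        rejected += int(m - ok.sum())
    if rejected:
        warnings.warn(f"simulate_ratio: {rejected} draws rejected and resampled",
                      stacklevel=2)
    point = float(np.median(vals))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    est = SurveyEstimate(point, float(np.std(vals, ddof=1)), float(lo), float(hi),
                         draws, min(a.design_df, b.design_df))
    return est


def linear_trend(yearly_values: pd.Series):
    """OLS of an annual series on calendar year.

    Returns ``(slope, se, p)`` with a two-sided p-value from the t
    distribution on n-2 degrees of freedom. Requires at least three distinct
    years.
    """
    years = np.asarray(yearly_values.index, dtype=float)
    vals = np.asarray(yearly_values, dtype=float)
    if len(years) < 3:
        raise ValueError("linear_trend requires at least 3 years")
    if np.ptp(years) == 0:
        raise ValueError("year predictor is constant")
    res = stats.linregress(years, vals)
    return float(res.slope), float(res.stderr), float(res.pvalue)
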