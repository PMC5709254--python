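"""Synthetic stratified single-cluster ED visit generator.

Emulates the design of a national ED survey sample — hospitals (clusters)
sampled within strata at a fixed sampling fraction, every visit at a sampled
hospital included with weight ``1/fraction`` — with a known ground-truth
mechanism mix, severity and TBI prevalence, and fatality process, so that
every downstream stage (cohort extraction, ICISS, Barell/TBI typing, survey
estimation, fatality modelling, interaction) can be tested against truth.

The fatality process has two modes:

``logistic``
    death ~ Bernoulli(expit(b0 + b_age*age + b_female*female + b_severe*severe
    + b_tc*trauma + b_ped*ped + b_tbi*tbi + b_ped_tbi*ped*tbi)) — mirrors the
    adjusted-odds-ratio model fitted downstream.

``risk_additive``
    death probability specified directly on the risk scale,
    ``r_base + ped*risk_ped + tbi*risk_tbi + ped*tbi*risk_interaction``, which
    makes the additive interaction contrast exactly specifiable (IC equals the
    ``risk_interaction`` term by construction).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .records import CORE_COLUMNS, REGIONS, validate_records

MECHANISMS = ("pedestrian", "bicyclist", "other_injury", "non_injury")
TBI_LEVELS = ("none", "type3", "type2", "type1")

# Diagnosis-code pools drawn from the packaged vocabulary (hand-auditable
# against barell_cells.csv / tbi_types.csv).
TBI_POOLS = {
    "type1": ["85400", "85406", "85221", "85110", "80025", "80140"],
    "type2": ["8509", "85011", "85012", "80002", "80056"],
    "type3": ["8500", "80001", "80301"],
}
SEVERE_POOL = ["8600", "86500", "86401", "86121"]
MINOR_POOL = [
    "82020", "82021", "82100", "82382", "92400", "92410", "8910", "9164",
    "81342", "81200", "81400", "92320", "88100", "8730", "8020", "920",
    "9102", "8472",
]
NON_INJURY_POOL = ["4660", "486", "78060", "5589", "0349", "7862"]
ECODE_POOLS = {
    "pedestrian": ["E8147", "E8127", "E8107", "E8197", "E8157", "E8260"],
    "bicyclist": ["E8136", "E8126", "E8106", "E8196", "E8166"],
    "other_injury": ["E8859", "E9175", "E9168", "E8889"],
}
PLACE_ECODE = "E8499"  # place-of-occurrence code, mechanism-neutral


class GeneratorConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def _uniform_ages() -> tuple:
    return tuple([1.0 / 20] * 20)


@dataclass(frozen=True)
class FatalitySpec:
    """Fatality process parameters (see module docstring for the two modes)."""

    mode: str = "logistic"
    # logistic mode: log-odds terms
    intercept: float = -4.94
    age: float = float(np.log(0.7))
    female: float = float(np.log(0.9))
    severe: float = float(np.log(16.9))
    trauma_center: float = float(np.log(0.9))
    pedestrian: float = float(np.log(2.4))
    tbi: float = float(np.log(6.3))
    pedestrian_tbi: float = float(np.log(2.0))
    # risk_additive mode: probabilities on the risk scale
    r_base: float = 0.008
    risk_ped: float = 0.002
    risk_tbi: float = 0.019
    risk_interaction: float = 0.023

    def death_probability(self, age, female, severe, trauma, ped, tbi):
        """Vectorized per-visit death probability."""
        age = np.asarray(age, dtype=float)
        if self.mode == "logistic":
            eta = (self.intercept + self.age * age + self.female * female
                   + self.severe * severe + self.trauma_center * trauma
                   + self.pedestrian * ped + self.tbi * tbi
                   + self.pedestrian_tbi * ped * tbi)
            return expit(eta)
        if self.mode == "risk_additive":
            p = (self.r_base + self.risk_ped * ped + self.risk_tbi * tbi
                 + self.risk_interaction * ped * tbi)
            return np.clip(p + 0.0 * age, 0.0, 1.0)
        raise GeneratorConfigError(f"unknown fatality mode {self.mode!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic survey sample.

    Defaults follow the published national profile of the 2006-2012 pediatric
    pedestrian/bicyclist cohort where a value is printed (pedestrian:bicyclist
    72.7:27.3 within the cohort; severe-injury probability ~9.5% pedestrian /
    9.2% bicyclist vs ~1% background; TBI 6.3% of pedestrian and 7.6% of
    bicyclist injuries split ~26/67/7 across Types I/II/III; fatality log-odds
    echoing the published adjusted odds ratios). The cohort's share of all
    visits is deliberately inflated relative to the real 0.21% so test-scale
    datasets contain a workable cohort.
    """

    n_strata: int = 8
    clusters_per_stratum: int = 6
    visits_per_cluster_mean: int = 200
    sampling_fraction: float = 0.2
    years: tuple = tuple(range(2006, 2013))
    age_distribution: tuple = field(default_factory=_uniform_ages)
    p_female: float = 0.40
    mechanism_mix: dict = field(default_factory=lambda: {
        "pedestrian": 0.08, "bicyclist": 0.03,
        "other_injury": 0.30, "non_injury": 0.59,
    })
    p_trauma_center: float = 0.30
    severity_model: dict = field(default_factory=lambda: {
        "pedestrian": 0.095, "bicyclist": 0.092,
        "other_injury": 0.02, "non_injury": 0.005,
    })
    tbi_model: dict = field(default_factory=lambda: {
        "pedestrian": {"none": 0.937, "type3": 0.0041, "type2": 0.0425, "type1": 0.0164},
        "bicyclist": {"none": 0.9241, "type3": 0.0049, "type2": 0.0512, "type1": 0.0198},
        "other_injury": {"none": 0.99, "type3": 0.001, "type2": 0.007, "type1": 0.002},
        "non_injury": {"none": 1.0, "type3": 0.0, "type2": 0.0, "type1": 0.0},
    })
    fatality: FatalitySpec = field(default_factory=FatalitySpec)
    p_truncated_tbi: float = 0.0   # chance a TBI primary code is cut to 4 digits
    p_second_ecode: float = 0.2    # chance of a trailing place-of-occurrence E-code
    seed: int = 0

    # -- validation ------------------------------------------------------
    def validate(self) -> "GeneratorConfig":
        def check_prop(name, value):
            if not (0.0 <= value <= 1.0):
                raise GeneratorConfigError(f"{name} must be in [0, 1], got {value}")

        if self.n_strata < 1 or self.clusters_per_stratum < 1:
            raise GeneratorConfigError("n_strata and clusters_per_stratum must be >= 1")
        if len(self.years) == 0:
            raise GeneratorConfigError("years must be non-empty")
        if not (0.0 < self.sampling_fraction <= 1.0):
            raise GeneratorConfigError(
                f"sampling_fraction must be in (0, 1], got {self.sampling_fraction}")
        for name in ("p_female", "p_trauma_center", "p_truncated_tbi", "p_second_ecode"):
            check_prop(name, getattr(self, name))
        ages = np.asarray(self.age_distribution, dtype=float)
        if len(ages) != 20 or (ages < 0).any() or abs(ages.sum() - 1.0) > 1e-9:
            raise GeneratorConfigError(
                "age_distribution must be 20 non-negative probabilities summing to 1")
        if set(self.mechanism_mix) != set(MECHANISMS):
            raise GeneratorConfigError(f"mechanism_mix must have keys {MECHANISMS}")
        for k, v in self.mechanism_mix.items():
            check_prop(f"mechanism_mix[{k}]", v)
        if abs(sum(self.mechanism_mix.values()) - 1.0) > 1e-9:
            raise GeneratorConfigError("mechanism_mix must sum to 1 within 1e-9")
        for m in MECHANISMS:
            check_prop(f"severity_model[{m}]", self.severity_model[m])
            row = self.tbi_model[m]
            if set(row) != set(TBI_LEVELS):
                raise GeneratorConfigError(f"tbi_model[{m}] must have keys {TBI_LEVELS}")
            for k, v in row.items():
                check_prop(f"tbi_model[{m}][{k}]", v)
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise GeneratorConfigError(f"tbi_model[{m}] must sum to 1 within 1e-9")
        return self

    @property
    def weight(self) -> float:
        return 1.0 / self.sampling_fraction


def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["years"] = list(config.years)
    d["age_distribution"] = list(config.age_distribution)
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "fatality" in d and isinstance(d["fatality"], dict):
        d["fatality"] = FatalitySpec(**d["fatality"])
    if "years" in d:
        d["years"] = tuple(d["years"])
    if "age_distribution" in d:
        d["age_distribution"] = tuple(d["age_distribution"])
    return GeneratorConfig(**d)


# ---------------------------------------------------------------------------
def _draw_categorical(rng, prob_matrix, row_index):
    """Per-row categorical draw where row ``i`` uses ``prob_matrix[row_index[i]]``."""
    cum = np.cumsum(prob_matrix, axis=1)
    u = rng.random(len(row_index))
    return (u[:, None] > cum[row_index]).sum(axis=1)


def _pick(rng, pool, size):
    return np.asarray(pool, dtype=object)[rng.integers(len(pool), size=size)]


def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a seeded synthetic visit table.

    Identical ``config`` (including ``seed``) yields byte-identical output.
    Ground-truth columns (``gt_mechanism``, ``gt_severe``, ``gt_tbi_type``,
    ``gt_death_prob``) are carried alongside the observable fields for use as
    test oracles; the analysis pipeline never reads them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_clusters = config.n_strata * config.clusters_per_stratum
    cluster_stratum = np.repeat(np.arange(config.n_strata), config.clusters_per_stratum)
    cluster_trauma = (rng.random(n_clusters) < config.p_trauma_center).astype(np.int8)
    sizes = rng.poisson(config.visits_per_cluster_mean, size=n_clusters)
    n = int(sizes.sum())

    cluster_id = np.repeat(np.arange(n_clusters), sizes)
    stratum_id = cluster_stratum[cluster_id]
    trauma = cluster_trauma[cluster_id]
    region = np.asarray(REGIONS, dtype=object)[stratum_id % len(REGIONS)]

    year = np.asarray(config.years)[rng.integers(len(config.years), size=n)]
    age = rng.choice(20, size=n, p=np.asarray(config.age_distribution, dtype=float))
    female = (rng.random(n) < config.p_female).astype(np.int8)

    mix = np.array([config.mechanism_mix[m] for m in MECHANISMS])
    mech_idx = _draw_categorical(rng, mix[None, :], np.zeros(n, dtype=int))
    mechanism = np.asarray(MECHANISMS, dtype=object)[mech_idx]

    sev_p = np.array([config.severity_model[m] for m in MECHANISMS])
    severe = (rng.random(n) < sev_p[mech_idx]).astype(np.int8)

    tbi_probs = np.array([[config.tbi_model[m][t] for t in TBI_LEVELS] for m in MECHANISMS])
    tbi_idx = _draw_categorical(rng, tbi_probs, mech_idx)
    tbi_type = np.asarray(TBI_LEVELS, dtype=object)[tbi_idx]
    has_tbi = (tbi_idx > 0).astype(np.int8)

    ped = (mechanism == "pedestrian").astype(np.int8)
    p_death = config.fatality.death_probability(age, female, severe, trauma, ped, has_tbi)
    died = (rng.random(n) < p_death).astype(np.int8)

    # --- diagnosis codes ------------------------------------------------
    primary = np.empty(n, dtype=object)
    injury = mechanism != "non_injury"
    for t, pool in TBI_POOLS.items():
        mask = tbi_type == t
        primary[mask] = _pick(rng, pool, int(mask.sum()))
    if config.p_truncated_tbi > 0:
        tbi_mask = has_tbi.astype(bool)
        trunc = tbi_mask & (rng.random(n) < config.p_truncated_tbi)
        primary[trunc] = [c[:4] if len(c) == 5 else c for c in primary[trunc]]
    else:
        # keep the rng call sequence identical whether or not truncation is on
        rng.random(n)
    mask = injury & ~has_tbi.astype(bool) & severe.astype(bool)
    primary[mask] = _pick(rng, SEVERE_POOL, int(mask.sum()))
    mask = injury & ~has_tbi.astype(bool) & ~severe.astype(bool)
    primary[mask] = _pick(rng, MINOR_POOL, int(mask.sum()))
    primary[~injury] = _pick(rng, NON_INJURY_POOL, int((~injury).sum()))

    n_extra = rng.binomial(2, 0.35, size=n) * injury
    extra1 = _pick(rng, MINOR_POOL, n)
    extra2 = _pick(rng, MINOR_POOL, n)
    sev_extra = _pick(rng, SEVERE_POOL, n)
    dx_codes = []
    sev_bool = severe.astype(bool)
    for i in range(n):
        codes = [primary[i]]
        if sev_bool[i] and injury[i]:
            codes.append(sev_extra[i])
        if n_extra[i] >= 1:
            codes.append(extra1[i])
        if n_extra[i] == 2:
            codes.append(extra2[i])
        dx_codes.append("|".join(codes))

    # --- external-cause codes ------------------------------------------
    first_ecode = np.empty(n, dtype=object)
    first_ecode[:] = ""
    for m, pool in ECODE_POOLS.items():
        mask = mechanism == m
        first_ecode[mask] = _pick(rng, pool, int(mask.sum()))
    second = injury & (rng.random(n) < config.p_second_ecode)
    ecodes = [
        (f"{first_ecode[i]}|{PLACE_ECODE}" if second[i] else str(first_ecode[i]))
        if injury[i] else ""
        for i in range(n)
    ]

    df = pd.DataFrame({
        "visit_id": np.arange(n),
        "year": year.astype(int),
        "age": age.astype(np.int16),
        "female": female,
        "stratum_id": stratum_id,
        "cluster_id": cluster_id,
        "weight": np.full(n, config.weight),
        "ecodes": ecodes,
        "dx_codes": dx_codes,
        "died": died,
        "trauma_level12": trauma,
        "region": region,
        "gt_mechanism": mechanism,
        "gt_severe": severe,
        "gt_tbi_type": tbi_type,
        "gt_death_prob": p_death,
    })
    return validate_records(df)


def true_risks(config: GeneratorConfig) -> dict:
    """Population fatality risks for the four {pedestrian, TBI} x {+, -} cells
    implied by the fatality parameters, marginalized over the configured
    covariate distribution by exhaustive enumeration of the discrete grid.

    ``pedestrian-`` means the bicyclist arm (the cohort contrast), not all
    non-pedestrian visits. Returned on the probability scale with keys
    ``ped_tbi``, ``ped_notbi``, ``bike_tbi``, ``bike_notbi``.
    """
    config.validate()
    fat = config.fatality
    ages = np.arange(20)
    p_age = np.asarray(config.age_distribution, dtype=float)
    out = {}
    for key, ped, tbi in [("ped_tbi", 1, 1), ("ped_notbi", 1, 0),
                          ("bike_tbi", 0, 1), ("bike_notbi", 0, 0)]:
        mech = "pedestrian" if ped else "bicyclist"
        p_sev = config.severity_model[mech]
        risk = 0.0
        for female, pf in ((0, 1 - config.p_female), (1, config.p_female)):
            for severe, ps in ((0, 1 - p_sev), (1, p_sev)):
                for trauma, pt in ((0, 1 - config.p_trauma_center),
                                   (1, config.p_trauma_center)):
                    probs = fat.death_probability(ages, female, severe, trauma, ped, tbi)
                    risk += pf * ps * pt * float(np.dot(p_age, probs))
        out[key] = risk
    return out
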