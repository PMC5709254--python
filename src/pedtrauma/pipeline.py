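"""End-to-end pipeline: generate/read -> cohort -> ICISS -> Barell -> survey
tables -> fatality model -> additive interaction.

``run_pipeline`` emits a report bundle into the output directory:

``table1_counts.csv``   annual weighted injury/death totals by mechanism (SEs)
``rates.csv``           annual rates per 10^4 population, per 10^4 ED
                        discharges, per 10^8 vehicle-miles, with trend rows in
                        ``trends.csv``
``table2_tbi.csv``      TBI-grade injuries/deaths/case-fatality table
``table3_model.csv``    fatality-model coefficients and adjusted ORs
                        (+ ``table3_model.txt`` rendered report)
``interaction.json``    risk quartet, IC, AP, bootstrap CI
``manifest.json``       config hash, seeds, and record counts at every stage
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import assets, cohort as cohort_mod, interaction as interaction_mod
from . import survey
from .barell import annotate_tbi
from .iciss import ICISSScorer, SRRTable
from .model import SingleClassError, fit_fatality_model, render_odds_ratio_table
from .records import read_records
from .synthetic import GeneratorConfig, config_from_dict, config_to_dict, generate


@dataclass
class PipelineConfig:
    generator: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    input_path: str | None = None        # read records instead of generating
    denominator_path: str | None = None  # packaged table when None
    srr_source: str = "estimate"         # "estimate" or a path to an SRR CSV
    severity_threshold: float = 0.94
    min_count: int = 10
    bootstrap_reps: int = 1000
    bootstrap_seed: int = 0
    sim_draws: int = 1000
    sim_seed: int = 0
    risk_scale: float = 1e5
    include_year: bool = False
    output_dir: str = "pedtrauma_out"

    def validate(self):
        if not 0 < self.severity_threshold < 1:
            raise ValueError("severity_threshold must be in (0, 1)")
        if self.bootstrap_reps < 2 or self.sim_draws < 2:
            raise ValueError("bootstrap_reps and sim_draws must be >= 2")
        if self.generator is None and self.input_path is None:
            raise ValueError("either a generator config or an input path is required")
        return self


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if "generator" in d and isinstance(d["generator"], dict):
        d["generator"] = config_from_dict(d["generator"])
    return PipelineConfig(**d)


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        return pipeline_config_from_dict(yaml.safe_load(fh))


def _config_hash(cfg: PipelineConfig) -> str:
    d = dataclasses.asdict(cfg)
    if cfg.generator is not None:
        d["generator"] = config_to_dict(cfg.generator)
    blob = yaml.safe_dump(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_csv(df: pd.DataFrame, path):
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the in-memory
    results keyed like the files. Identical config (and seeds) produces a
    byte-identical bundle."""
    cfg.validate()
    outdir = pathlib.Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_sha256": _config_hash(cfg),
                      "seeds": {"generator": None if cfg.generator is None
                                else cfg.generator.seed,
                                "bootstrap": cfg.bootstrap_seed,
                                "simulation": cfg.sim_seed},
                      "stages": {}}
    results: dict = {}

    # --- stage 1: records ----------------------------------------------
    if cfg.input_path is not None:
        records = read_records(cfg.input_path)
    else:
        records = generate(cfg.generator)
    manifest["stages"]["records"] = {"n": int(len(records))}

    # --- stage 2: cohort -----------------------------------------------
    cohort, summary = cohort_mod.extract_cohort(records, return_summary=True)
    manifest["stages"]["cohort"] = summary

    # --- stage 3: ICISS severity ---------------------------------------
    if cfg.srr_source == "estimate":
        scorer = ICISSScorer(min_count=cfg.min_count, threshold=cfg.severity_threshold)
        scorer.fit(records)
    else:
        scorer = ICISSScorer(threshold=cfg.severity_threshold,
                             srr_table=SRRTable.from_csv(cfg.srr_source))
        scorer.fit(records)
    cohort = scorer.transform(cohort)
    all_scored = scorer.transform(records)
    scorer.srr_table_.to_csv(outdir / "srr_table.csv")
    manifest["stages"]["iciss"] = {
        "n_srr_codes": len(scorer.srr_table_),
        "n_cohort_severe": int(cohort["severe"].fillna(0).sum()),
    }

    # --- stage 4: Barell / TBI -----------------------------------------
    cohort = annotate_tbi(cohort)
    manifest["stages"]["barell"] = {
        "n_unmappable_primary": int((~cohort["barell_mappable"]).sum()),
    }
    _write_csv(cohort.drop(columns=[c for c in cohort.columns
                                    if c.startswith("gt_")]),
               outdir / "cohort.csv")

    # --- stage 5: survey tables ----------------------------------------
    mech_of = cohort.set_index("visit_id")["mechanism"]
    rec_mech = records["visit_id"].map(mech_of)
    died = records["died"].to_numpy().astype(bool)
    years = sorted(records["year"].unique())

    t1_rows = []
    for year in years:
        in_year = (records["year"] == year).to_numpy()
        row = {"year": int(year)}
        for mech, label in [("pedestrian", "ped"), ("bicyclist", "bike")]:
            dom = in_year & (rec_mech == mech).to_numpy()
            inj = survey.weighted_total(records, dom)
            dth = survey.weighted_total(records, dom & died)
            row[f"{label}_injuries"] = inj.point
            row[f"{label}_injuries_se"] = inj.se
            row[f"{label}_deaths"] = dth.point
            row[f"{label}_deaths_se"] = dth.se
        dom = in_year & rec_mech.notna().to_numpy()
        both_inj = survey.weighted_total(records, dom)
        both_dth = survey.weighted_total(records, dom & died)
        row.update(both_injuries=both_inj.point, both_injuries_se=both_inj.se,
                   both_deaths=both_dth.point, both_deaths_se=both_dth.se)
        t1_rows.append(row)
    table1 = pd.DataFrame(t1_rows)
    _write_csv(table1, outdir / "table1_counts.csv")
    results["table1"] = table1

    denom = (assets.load_denominators() if cfg.denominator_path is None
             else pd.read_csv(cfg.denominator_path))
    denom = denom.set_index("year")
    rate_rows = []
    for year in years:
        in_year = (records["year"] == year).to_numpy()
        dom = in_year & rec_mech.notna().to_numpy()
        inj = survey.weighted_total(records, dom)
        dth = survey.weighted_total(records, dom & died)
        all_visits = survey.weighted_total(records, in_year)
        row = {"year": int(year),
               "injuries": inj.point, "deaths": dth.point,
               "ed_discharges": all_visits.point}
        if all_visits.point > 0:
            r = survey.compute_rate(inj, all_visits.point, 1e4, "ED discharges")
            row["injury_rate_per_10k_discharges"] = r.rate
            row["cfr_per_10k_visits"] = survey.compute_rate(
                dth, inj.point, 1e4, "cohort visits").rate if inj.point > 0 else np.nan
        if year in denom.index:
            pop = float(denom.loc[year, "population_0_19"])
            row["injury_rate_per_10k_pop"] = survey.compute_rate(
                inj, pop, 1e4, "population").rate
            row["death_rate_per_1m_pop"] = survey.compute_rate(
                dth, pop, 1e6, "population").rate
            vmt = float(denom.loc[year, "vmt_millions"]) * 1e6
            row["injury_rate_per_100m_vmt"] = survey.compute_rate(
                inj, vmt, 1e8, "vehicle miles").rate
        rate_rows.append(row)
    rates = pd.DataFrame(rate_rows)
    _write_csv(rates, outdir / "rates.csv")
    results["rates"] = rates

    trend_rows = []
    for col in rates.columns:
        if col in ("year",) or rates[col].isna().any() or len(rates) < 3:
            continue
        slope, se, p = survey.linear_trend(rates.set_index("year")[col])
        trend_rows.append({"series": col, "slope_per_year": slope,
                           "se": se, "p_value": p})
    trends = pd.DataFrame(trend_rows)
    _write_csv(trends, outdir / "trends.csv")
    results["trends"] = trends

    # --- stage 6: TBI-grade table --------------------------------------
    t2_rows = []
    cohort_died = cohort["died"].to_numpy().astype(bool)
    for t in ("type1", "type2", "type3"):
        dom = (cohort["tbi_type"] == t).to_numpy()
        inj = survey.weighted_total(cohort, dom)
        dth = survey.weighted_total(cohort, dom & cohort_died)
        cfr = (survey.compute_rate(dth, inj.point, 100.0, "injuries").rate
               if inj.point > 0 else np.nan)
        t2_rows.append({"tbi_grade": t,
                        "injuries": inj.point, "injuries_se": inj.se,
                        "deaths": dth.point, "deaths_se": dth.se,
                        "cfr_pct": cfr})
    table2 = pd.DataFrame(t2_rows)
    _write_csv(table2, outdir / "table2_tbi.csv")
    results["table2"] = table2

    # --- stage 7: fatality model ---------------------------------------
    model_error = None
    try:
        fit = fit_fatality_model(cohort.dropna(subset=["severe"]),
                                 include_year=cfg.include_year)
        coef_table = fit.odds_ratios.copy()
        coef_table.insert(1, "coefficient",
                          [fit.coefficients[t] for t in coef_table["term"]])
        _write_csv(coef_table, outdir / "table3_model.csv")
        (outdir / "table3_model.txt").write_text(
            render_odds_ratio_table(fit.odds_ratios) + "\n")
        results["model"] = fit
        manifest["stages"]["model"] = {"converged": bool(fit.converged),
                                       "n_weighted": fit.n_weighted,
                                       "dropped_terms": fit.dropped_terms}
    except SingleClassError as exc:
        model_error = str(exc)
        manifest["stages"]["model"] = {"error": model_error}

    # --- stage 8: additive interaction ---------------------------------
    try:
        res = interaction_mod.bootstrap_interaction(
            cohort, reps=cfg.bootstrap_reps, seed=cfg.bootstrap_seed,
            scale=cfg.risk_scale)
        payload = {
            "risk_scale": cfg.risk_scale,
            "quartet": dict(zip(["ped_tbi", "ped_notbi", "bike_tbi", "bike_notbi"],
                                res.quartet.as_tuple())),
            "ic": res.ic,
            "attributable_proportion": res.attributable_proportion,
            "ic_boot_mean": res.ic_boot, "ap_boot_mean": res.ap_boot,
            "ic_ci": [res.ic_ci_low, res.ic_ci_high],
            "ap_ci": [res.ap_ci_low, res.ap_ci_high],
            "n_boot": res.n_boot, "n_dropped": res.n_dropped, "seed": res.seed,
        }
        (outdir / "interaction.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        results["interaction"] = res
        manifest["stages"]["interaction"] = {"n_boot": res.n_boot,
                                             "n_dropped": res.n_dropped}
    except ValueError as exc:
        manifest["stages"]["interaction"] = {"error": str(exc)}

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    results["cohort"] = cohort
    results["records"] = all_scored
    return results
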