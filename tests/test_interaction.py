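"""Interaction contrast, attributable proportion, and cluster bootstrap."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_cohort_frame
from pedtrauma.barell import annotate_tbi
from pedtrauma.cohort import extract_cohort
from pedtrauma.interaction import (RiskQuartet, attributable_proportion,
                                   bootstrap_interaction, cell_risks,
                                   interaction_contrast)
from pedtrauma.synthetic import FatalitySpec, GeneratorConfig, generate


class TestInteractionContrast:
    def test_published_risk_quartet_gives_2310(self):
        q = RiskQuartet(4466.5, 268.1, 1968.3, 79.9)
        assert interaction_contrast(q) == pytest.approx(2310.0, abs=1e-9)

    def test_perfectly_additive_quartet_is_zero(self):
        q = RiskQuartet(r_pp=0.02 + 0.05 - 0.01, r_pm=0.02, r_mp=0.05, r_mm=0.01)
        assert interaction_contrast(q) == pytest.approx(0.0, abs=1e-15)

    def test_unit_case(self):
        assert interaction_contrast(RiskQuartet(1, 0, 0, 0)) == 1

    def test_invariant_to_constant_shift(self):
        q = RiskQuartet(4.0, 2.5, 1.5, 0.5)
        shifted = RiskQuartet(*(r + 13.7 for r in q.as_tuple()))
        assert interaction_contrast(shifted) == pytest.approx(
            interaction_contrast(q))


class TestAttributableProportion:
    def test_published_plug_in_value(self):
        # the bootstrap point estimate published alongside (49.1%) need not
        # equal this plug-in ratio
        assert round(attributable_proportion(2310.0, 4466.5), 4) == 0.5172

    def test_zero_ic(self):
        assert attributable_proportion(0.0, 5.0) == 0.0

    def test_full_attribution(self):
        assert attributable_proportion(3.0, 3.0) == 1.0

    @pytest.mark.parametrize("rpp", [0.0, -1.0])
    def test_nonpositive_risk_rejected(self, rpp):
        with pytest.raises(ValueError):
            attributable_proportion(1.0, rpp)


def quartet_cohort(cells):
    """cells: {(mechanism, tbi): (n_records, n_deaths)}"""
    rows = []
    for (mech, tbi), (n, d) in cells.items():
        for i in range(n):
            rows.append(dict(mechanism=mech, tbi_primary=tbi,
                             died=int(i < d)))
    return make_cohort_frame(rows)


class TestCellRisks:
    def test_uniform_cells(self):
        coh = quartet_cohort({("pedestrian", 1): (100, 1),
                              ("pedestrian", 0): (100, 1),
                              ("bicyclist", 1): (100, 1),
                              ("bicyclist", 0): (100, 1)})
        q = cell_risks(coh, scale=1.0)
        assert q.as_tuple() == (0.01, 0.01, 0.01, 0.01)

    def test_forty_record_fixture_matches_brute_force(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(40):
            rows.append(dict(mechanism=rng.choice(["pedestrian", "bicyclist"]),
                             tbi_primary=int(rng.random() < 0.5),
                             died=int(rng.random() < 0.3)))
        coh = make_cohort_frame(rows)
        q = cell_risks(coh, scale=1.0)
        # independent tally
        df = coh
        for attr, mech, tbi in [("r_pp", "pedestrian", 1), ("r_pm", "pedestrian", 0),
                                ("r_mp", "bicyclist", 1), ("r_mm", "bicyclist", 0)]:
            m = (df.mechanism == mech) & (df.tbi_primary == tbi)
            assert getattr(q, attr) == pytest.approx(
                df.loc[m, "died"].sum() / m.sum())

    def test_all_deaths_in_doubly_exposed_cell(self):
        coh = quartet_cohort({("pedestrian", 1): (10, 10),
                              ("pedestrian", 0): (10, 0),
                              ("bicyclist", 1): (10, 0),
                              ("bicyclist", 0): (10, 0)})
        q = cell_risks(coh, scale=1.0)
        assert q.as_tuple() == (1.0, 0.0, 0.0, 0.0)

    def test_empty_cell_error_names_the_cell(self):
        coh = quartet_cohort({("pedestrian", 1): (5, 1),
                              ("pedestrian", 0): (5, 1),
                              ("bicyclist", 0): (5, 1)})
        with pytest.raises(ValueError, match="bike_tbi"):
            cell_risks(coh)

    def test_ic_scales_linearly_and_ap_is_scale_invariant(self):
        coh = quartet_cohort({("pedestrian", 1): (50, 10),
                              ("pedestrian", 0): (50, 2),
                              ("bicyclist", 1): (50, 4),
                              ("bicyclist", 0): (50, 1)})
        q1 = cell_risks(coh, scale=1.0)
        q2 = cell_risks(coh, scale=1e5)
        ic1, ic2 = interaction_contrast(q1), interaction_contrast(q2)
        assert ic2 == pytest.approx(ic1 * 1e5)
        assert attributable_proportion(ic1, q1.r_pp) == pytest.approx(
            attributable_proportion(ic2, q2.r_pp))


def balanced_cluster_cohort(n_clusters=6, strata=2):
    """Every cluster holds the identical mix of cell records."""
    rows = []
    for c in range(n_clusters):
        for mech in ("pedestrian", "bicyclist"):
            for tbi in (0, 1):
                for i in range(10):
                    rows.append(dict(mechanism=mech, tbi_primary=tbi,
                                     died=int(i < (3 if (mech == "pedestrian"
                                                         and tbi) else 1)),
                                     cluster_id=c, stratum_id=c % strata))
    return make_cohort_frame(rows)


class TestBootstrap:
    def test_identical_clusters_give_zero_width_ci(self):
        coh = balanced_cluster_cohort()
        res = bootstrap_interaction(coh, reps=50, seed=4, scale=1.0)
        assert res.ap_ci_low == res.ap_ci_high == pytest.approx(
            res.attributable_proportion)
        assert res.ic_ci_high - res.ic_ci_low == pytest.approx(0.0, abs=1e-12)

    def test_seeded_determinism(self):
        coh = balanced_cluster_cohort()
        coh.loc[coh.index[:40], "died"] = (np.arange(40) % 3 == 0).astype(int)
        a = bootstrap_interaction(coh, reps=2, seed=9)
        b = bootstrap_interaction(coh, reps=2, seed=9)
        assert a == b

    def test_reps_validation(self):
        with pytest.raises(ValueError):
            bootstrap_interaction(balanced_cluster_cohort(), reps=1)

    def test_sparse_design_aborts(self):
        """Three cells each confined to a single cluster out of many: most
        replicates lose a cell and the bootstrap refuses to report."""
        rows = []
        n_cl = 30
        for c in range(n_cl):
            for i in range(5):
                rows.append(dict(mechanism="bicyclist", tbi_primary=0,
                                 died=int(i == 0), cluster_id=c, stratum_id=0))
        rows.append(dict(mechanism="pedestrian", tbi_primary=1, died=1,
                         cluster_id=0, stratum_id=0))
        rows.append(dict(mechanism="pedestrian", tbi_primary=0, died=0,
                         cluster_id=1, stratum_id=0))
        rows.append(dict(mechanism="bicyclist", tbi_primary=1, died=0,
                         cluster_id=2, stratum_id=0))
        coh = pd.DataFrame(rows)
        coh["weight"] = 1.0
        coh["year"] = 2006
        with pytest.raises(ValueError, match="sparse"):
            bootstrap_interaction(coh, reps=200, seed=5)

    def test_plug_in_ap_close_to_bootstrap_mean_on_balanced_data(self):
        cfg = GeneratorConfig(n_strata=4, clusters_per_stratum=12,
                              visits_per_cluster_mean=400,
                              mechanism_mix={"pedestrian": 0.45,
                                             "bicyclist": 0.45,
                                             "other_injury": 0.05,
                                             "non_injury": 0.05},
                              fatality=FatalitySpec(
                                  mode="risk_additive", r_base=0.02,
                                  risk_ped=0.01, risk_tbi=0.05,
                                  risk_interaction=0.05),
                              tbi_model={
                                  m: ({"none": 0.7, "type3": 0.05,
                                       "type2": 0.15, "type1": 0.1}
                                      if m != "non_injury" else
                                      {"none": 1.0, "type3": 0.0,
                                       "type2": 0.0, "type1": 0.0})
                                  for m in ("pedestrian", "bicyclist",
                                            "other_injury", "non_injury")},
                              seed=21)
        coh = annotate_tbi(extract_cohort(generate(cfg)))
        res = bootstrap_interaction(coh, reps=600, seed=2, scale=1.0)
        assert res.ap_boot == pytest.approx(res.attributable_proportion,
                                            abs=0.05)


def _zero_interaction_config(seed):
    fat = FatalitySpec(mode="risk_additive", r_base=0.01, risk_ped=0.01,
                       risk_tbi=0.03, risk_interaction=0.0)
    tbi_row = {"none": 0.75, "type3": 0.02, "type2": 0.13, "type1": 0.10}
    return GeneratorConfig(
        n_strata=4, clusters_per_stratum=25, visits_per_cluster_mean=150,
        mechanism_mix={"pedestrian": 0.45, "bicyclist": 0.45,
                       "other_injury": 0.05, "non_injury": 0.05},
        tbi_model={"pedestrian": tbi_row, "bicyclist": dict(tbi_row),
                   "other_injury": dict(tbi_row),
                   "non_injury": {"none": 1.0, "type3": 0.0, "type2": 0.0,
                                  "type1": 0.0}},
        fatality=fat, seed=seed)


def test_zero_interaction_ap_cis_cover_zero():
    """Risk-scale additive generator with no interaction: the bootstrap AP
    interval covers 0 in at least 90% of 30 seeded replicates."""
    n_reps, reps = 30, 200
    covered = 0
    for rep in range(n_reps):
        coh = annotate_tbi(extract_cohort(generate(
            _zero_interaction_config(5000 + rep))))
        res = bootstrap_interaction(coh, reps=reps, seed=rep, scale=1.0)
        covered += res.ap_ci_low <= 0.0 <= res.ap_ci_high
    assert covered >= 0.9 * n_reps, f"{covered}/{n_reps}"
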