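"""Cohort statistics: closed-form oracles, planted-effect recovery, BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from octaquant.stats import (
    age_stratified_analysis,
    analyze_site,
    bh_adjust,
    chi_square_independence,
    collapse_rings,
    demographics_table,
    density_rnfl_correlation,
    faz_group_regression,
    fit_density_model,
    quadrant_contrasts,
    welch_t,
)
from octaquant.synthetic import CohortSimConfig, add_rnfl_column, simulate_density_records

from oracles import brute_force_bh, brute_force_chi2_2x2, brute_force_chi2_general


# --- demographics ----------------------------------------------------------

def test_sex_table_chi_square_worked_example():
    """The 2x2 sex-by-diagnosis table (17,22 / 39,12) gives chi2 ~ 10.16, p = 0.0014."""
    stat, p, dof = chi_square_independence([[17, 22], [39, 12]])
    assert dof == 1
    assert stat == pytest.approx(brute_force_chi2_2x2(17, 22, 39, 12), rel=1e-12)
    assert p == pytest.approx(0.0014, abs=5e-5)


def test_chi_square_matches_direct_summation(rng):
    for _ in range(20):
        table = rng.integers(5, 60, size=(2, int(rng.integers(2, 5))))
        stat, _, _ = chi_square_independence(table)
        assert stat == pytest.approx(brute_force_chi2_general(table), rel=1e-10)


def test_identical_groups_t_is_zero():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    t, p = welch_t(x, x.copy())
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_demographics_table_and_degenerate_variable():
    cohort = pd.DataFrame({
        "subject": [f"S{i}" for i in range(20)],
        "diagnosis": ["control"] * 10 + ["ssd"] * 10,
        "age": np.r_[np.arange(10) + 30.0, np.arange(10) + 35.0],
        "sex": ["M", "F"] * 10,
        "ssi": [8.0] * 20,  # quality index with no variation in the data
    })
    with pytest.warns(UserWarning, match="no variation"):
        table = demographics_table(cohort, continuous=("age", "ssi"), categorical=("sex",))
    ssi_row = table[table["variable"] == "ssi"].iloc[0]
    assert np.isnan(ssi_row["p"])
    age_row = table[table["variable"] == "age"].iloc[0]
    assert age_row["p"] < 0.05


# --- Benjamini-Hochberg ----------------------------------------------------

def test_bh_worked_example():
    adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_p_unchanged():
    np.testing.assert_allclose(bh_adjust([0.321]), [0.321])


def test_bh_matches_brute_force(rng):
    for _ in range(50):
        p = rng.random(int(rng.integers(1, 12)))
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(list(p)), atol=1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
def test_bh_dominates_raw_and_is_monotone(pvals):
    adj = bh_adjust(pvals)
    assert (adj >= np.asarray(pvals) - 1e-12).all()
    order = np.argsort(pvals, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# --- mixed model, contrasts, ring collapse ---------------------------------

def test_degenerate_random_effects_match_ols():
    """With zero planted variance components the fixed effects equal OLS."""
    import statsmodels.formula.api as smf

    cfg = CohortSimConfig(n_control=10, n_ssd=10, subject_sd=0.0, eye_sd=0.0, seed=7)
    rec = simulate_density_records(cfg, "onh")
    fit = fit_density_model(rec)
    regional = rec[rec["quadrant"].isin(["superior", "nasal", "inferior", "temporal"])]
    ols = smf.ols("density ~ C(diagnosis, Treatment('control'))"
                  " * C(quadrant, Treatment('inferior')) + age + C(sex) + C(ring)",
                  regional).fit()
    np.testing.assert_allclose(fit.result.fe_params.to_numpy(), ols.params.to_numpy(),
                               atol=1e-6)


def test_planted_deficit_detected_single_cohort():
    """A large temporal deficit yields a positive (control - SSD), significant
    temporal contrast and a negative SSD x temporal interaction."""
    cfg = CohortSimConfig(n_control=40, n_ssd=40, temporal_deficit=0.4, seed=11)
    rec = simulate_density_records(cfg, "onh", seed=124)
    analysis = analyze_site(rec)
    temporal = analysis.contrasts.set_index("quadrant").loc["temporal"]
    assert temporal["estimate"] > 0
    assert temporal["p_adjusted"] < 0.01
    inter = analysis.interactions.set_index("quadrant").loc["temporal"]
    assert inter["estimate"] < 0
    others = analysis.contrasts.set_index("quadrant").drop("temporal")
    assert temporal["estimate"] > others["estimate"].abs().max()


def test_null_contrasts_near_zero():
    cfg = CohortSimConfig(n_control=40, n_ssd=40, temporal_deficit=0.0, seed=13)
    rec = simulate_density_records(cfg, "onh", seed=321)
    contrasts = analyze_site(rec).contrasts
    assert (contrasts["estimate"].abs() < 2.5 * contrasts["se"]).all()


def test_collapse_when_rings_identical():
    cfg = CohortSimConfig(n_control=8, n_ssd=8, seed=17)
    rec = simulate_density_records(cfg, "onh")
    # force inner == outer exactly
    inner = rec[rec["ring"] == "inner"].copy()
    outer = inner.copy()
    outer["ring"] = "outer"
    rec_eq = pd.concat([inner, outer], ignore_index=True)
    collapsed, did, ring_p = collapse_rings(rec_eq)
    assert did
    assert ring_p > 0.9
    assert set(collapsed["ring"]) == {"collapsed"}
    # collapsed density is the inner/outer mean, here equal to the inner value
    merged = collapsed.merge(inner, on=["subject", "eye", "quadrant"], suffixes=("_c", "_i"))
    np.testing.assert_allclose(merged["density_c"], merged["density_i"])


def test_no_collapse_with_planted_ring_offset():
    cfg = CohortSimConfig(n_control=10, n_ssd=10, residual_sd=0.005, seed=19)
    rec = simulate_density_records(cfg, "onh")
    rec.loc[rec["ring"] == "outer", "density"] -= 0.05  # offset >> noise
    out, did, ring_p = collapse_rings(rec)
    assert not did
    assert ring_p < 0.001
    assert out is rec


def test_collapsed_density_is_ring_mean():
    cfg = CohortSimConfig(n_control=6, n_ssd=6, seed=24)
    rec = simulate_density_records(cfg, "onh")
    collapsed, did, _ = collapse_rings(rec)
    assert did
    manual = (rec[rec["quadrant"].isin(["superior", "nasal", "inferior", "temporal"])]
              .groupby(["subject", "eye", "quadrant"])["density"].mean())
    merged = collapsed.set_index(["subject", "eye", "quadrant"])["density"]
    np.testing.assert_allclose(merged.sort_index(), manual.sort_index())


def test_contrast_bh_uses_step_up_oracle():
    cfg = CohortSimConfig(n_control=20, n_ssd=20, temporal_deficit=0.2, seed=29)
    rec = simulate_density_records(cfg, "onh")
    contrasts = quadrant_contrasts(fit_density_model(rec))
    np.testing.assert_allclose(contrasts["p_adjusted"],
                               brute_force_bh(list(contrasts["p_raw"])), atol=1e-12)


# --- age stratification ----------------------------------------------------

def test_age_cutoff_boundary_is_young():
    """A subject aged exactly 30 falls in the young stratum."""
    cfg = CohortSimConfig(n_control=12, n_ssd=12,
                          age_deficit_interaction={"young": 0.5, "old": 0.0}, seed=31)
    rec = simulate_density_records(cfg, "onh")
    rec.loc[rec["subject"] == "C001", "age"] = 30.0
    strat = age_stratified_analysis(rec)
    young_subjects = set(rec.loc[rec["age"] <= 30, "subject"])
    assert "C001" in young_subjects
    assert set(strat.young.fit.records["subject"]) == young_subjects


def test_young_only_deficit_pattern():
    """Deficit planted only in the young stratum: young temporal contrast
    significant, old not, and the pooled diagnosis x age interaction present."""
    cfg = CohortSimConfig(n_control=45, n_ssd=45,
                          age_deficit_interaction={"young": 0.3, "old": 0.0}, seed=12)
    rec = simulate_density_records(cfg, "onh", seed=125)
    strat = age_stratified_analysis(rec)
    young_t = strat.young.contrasts.set_index("quadrant").loc["temporal"]
    old_t = strat.old.contrasts.set_index("quadrant").loc["temporal"]
    assert young_t["p_adjusted"] < 0.05
    assert old_t["p_adjusted"] > 0.05
    assert strat.age_interaction_p < 0.05
    assert strat.age_interaction_coef > 0  # deficit shrinks with age


# --- FAZ regression and RNFL correlations ----------------------------------

def _faz_table(rng, n_ctrl=30, n_ssd=30, ssd_scale=1.0):
    rows = []
    for grp, n, scale in (("control", n_ctrl, 1.0), ("ssd", n_ssd, ssd_scale)):
        for i in range(n):
            rows.append({"subject": f"{grp}{i}", "diagnosis": grp,
                         "area_mm2": float(rng.normal(0.30 * scale, 0.05)),
                         "acircularity": float(1.0 + abs(rng.normal(0.3, 0.1)))})
    return pd.DataFrame(rows)


def test_faz_regression_null(rng):
    res = faz_group_regression(_faz_table(rng))
    assert abs(res["coef"]) < 0.05
    assert res["control_mean"] == pytest.approx(0.30, abs=0.05)
    assert res["control_sd"] > 0


def test_faz_regression_detects_planted_shrinkage(rng):
    res = faz_group_regression(_faz_table(rng, ssd_scale=0.8))
    assert res["coef"] < 0
    assert res["p"] < 0.05


def test_faz_regression_errors(rng):
    small = _faz_table(rng, n_ctrl=2, n_ssd=5)
    with pytest.raises(ValueError, match="3 eyes"):
        faz_group_regression(small)
    const = _faz_table(rng)
    const["area_mm2"] = 0.3
    with pytest.raises(ValueError, match="constant"):
        faz_group_regression(const)


def test_rnfl_correlation_recovers_planted_slope():
    cfg = CohortSimConfig(n_control=40, n_ssd=40, seed=37)
    rec = add_rnfl_column(simulate_density_records(cfg, "onh"), slope=200.0,
                          noise_sd=2.0, seed=1)
    table = density_rnfl_correlation(rec)
    assert (table["r"] > 0.5).all()
    # degenerate: constant RNFL flagged, not crashed
    rec2 = rec.copy()
    rec2["rnfl_thickness"] = 95.0
    table2 = density_rnfl_correlation(rec2)
    assert table2["degenerate"].all()
    assert table2["r"].isna().all()
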