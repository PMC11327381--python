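import numpy as np
import pandas as pd
import pytest

from daylongenv.segments_io import AnalysisConfig
from daylongenv.stats_models import (
    DegenerateDesignError,
    compare_models,
    cross_sectional_slopes,
    fit_group_model,
    fit_productivity_model,
    lrt_group_effect,
    sensitivity_rerun,
    voc_duration_slopes,
)
from daylongenv.synth_cohort import (
    simulate_hourly_table,
    simulate_productivity_cohort,
)

GROUPS = ["CI", "CA_MATCH", "HA_MATCH"]


def _group_term(level):
    return f"C(hearing_group, Treatment('CI'))[T.{level}]"


# -- fit_group_model ----------------------------------------------------------


def test_parameter_recovery_group_effects():
    # planted deviations: CA +5, HA -5 around a CI mean of 0
    table = simulate_hourly_table(
        n_children=30,
        n_hours=16,
        group_effects={"CI": 0.0, "CA_MATCH": 5.0, "HA_MATCH": -5.0},
        child_sd=1.0,
        noise_sd=1.0,
        rng=np.random.default_rng(12345),
    )
    result = fit_group_model(table, "y", ("child",))
    ca = result.coefficients[_group_term("CA_MATCH")]
    ha = result.coefficients[_group_term("HA_MATCH")]
    assert abs(ca.estimate - 5.0) < 2 * ca.se
    assert abs(ha.estimate - (-5.0)) < 2 * ha.se


def test_treatment_coding_recovers_group_means(rng):
    # balanced, no random structure: coefficients are exact group-mean
    # differences from the CI reference
    table = simulate_hourly_table(
        n_children=30, n_hours=4,
        group_effects={"CI": 10.0, "CA_MATCH": 12.0, "HA_MATCH": 7.0},
        child_sd=0.5, noise_sd=0.5, rng=rng,
    )
    means = table.groupby("hearing_group")["y"].mean()
    result = fit_group_model(table, "y", ("child",))
    icept = result.coef("Intercept")
    # balanced design: fixed effects reproduce group means within tolerance
    assert icept == pytest.approx(means["CI"], abs=0.05)
    assert icept + result.coef(_group_term("CA_MATCH")) == pytest.approx(
        means["CA_MATCH"], abs=0.05
    )
    assert icept + result.coef(_group_term("HA_MATCH")) == pytest.approx(
        means["HA_MATCH"], abs=0.05
    )


def test_crossed_hour_intercepts(rng):
    table = simulate_hourly_table(n_children=18, n_hours=6, rng=rng)
    # plant an hour effect so the crossed component is real
    table["y"] += table["hour_index"] * 0.5
    result = fit_group_model(table, "y", ("child", "hour"))
    assert result.n_groups == {"child": 18, "hour": 6}
    assert result.method == "REML"


def test_constant_outcome_does_not_crash(rng):
    table = simulate_hourly_table(n_children=9, n_hours=3, rng=rng)
    table["y"] = 4.2
    result = fit_group_model(table, "y", ("child",))
    assert result.coef(_group_term("CA_MATCH")) == pytest.approx(0.0, abs=1e-8)
    assert result.coef(_group_term("HA_MATCH")) == pytest.approx(0.0, abs=1e-8)


def test_single_level_group_rejected(rng):
    table = simulate_hourly_table(n_children=9, n_hours=3, rng=rng)
    table["hearing_group"] = "CI"
    with pytest.raises(DegenerateDesignError):
        fit_group_model(table, "y", ("child",))


def test_nonfinite_outcome_rejected(rng):
    table = simulate_hourly_table(n_children=9, n_hours=3, rng=rng)
    table.loc[0, "y"] = np.nan
    with pytest.raises(ValueError):
        fit_group_model(table, "y", ("child",))


def test_aic_identity_on_ml_fit(rng):
    table = simulate_hourly_table(n_children=15, n_hours=4, rng=rng)
    result = fit_group_model(table, "y", ("child",), reml=False)
    assert result.aic == pytest.approx(
        2 * result.k_params - 2 * result.loglik
    )


# -- compare_models -----------------------------------------------------------


def test_compare_identical_models(rng):
    table = simulate_hourly_table(n_children=15, n_hours=4, rng=rng)
    m = fit_group_model(table, "y", ("child",), reml=False)
    comp = compare_models(m, m)
    assert comp.chi2 == 0.0
    assert comp.df == 0
    assert comp.delta_aic == pytest.approx(2 * comp.df)


def test_df_counts_extra_terms(rng):
    table = simulate_hourly_table(n_children=15, n_hours=4, rng=rng)
    comp = lrt_group_effect(table, "y", ("child",))
    assert comp.df == 2  # CA_MATCH and HA_MATCH deviations


def test_reml_fits_rejected(rng):
    table = simulate_hourly_table(n_children=15, n_hours=4, rng=rng)
    m = fit_group_model(table, "y", ("child",), reml=True)
    with pytest.raises(ValueError):
        compare_models(m, m)


def test_chi2_grows_with_effect_size(rng):
    chis = []
    for effect in (0.0, 1.0, 2.0, 4.0):
        table = simulate_hourly_table(
            n_children=60, n_hours=6,
            group_effects={"CI": 0.0, "CA_MATCH": effect, "HA_MATCH": -effect},
            child_sd=0.5, noise_sd=1.0,
            rng=np.random.default_rng(7),  # common random numbers
        )
        chis.append(lrt_group_effect(table, "y", ("child",)).chi2)
    assert chis == sorted(chis)
    assert chis[-1] > chis[0] + 10


def test_mean_centering_leaves_lrt_unchanged(rng):
    table = simulate_hourly_table(n_children=20, n_hours=4, rng=rng)
    table["age"] = np.repeat(
        rng.uniform(20, 60, size=20), 4
    )
    table["y"] += 0.1 * table["age"]
    raw = table.copy()
    centered = table.copy()
    centered["age"] = centered["age"] - centered["age"].mean()
    comp_raw = lrt_group_effect(raw, "y", ("child",), covariates=("age",))
    # covariates are centered inside the fitting routine, so pre-centering
    # must be a no-op for the test statistic
    comp_centered = lrt_group_effect(
        centered, "y", ("child",), covariates=("age",)
    )
    assert comp_raw.chi2 == pytest.approx(comp_centered.chi2, rel=1e-6)


# -- cross-sectional slopes ---------------------------------------------------


def _per_child(n=18, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in GROUPS:
        ages = rng.uniform(20, 60, size=n)
        for i, age in enumerate(ages):
            rows.append(
                {
                    "child_id": f"{g}{i}",
                    "hearing_group": g,
                    "chrono_age_mo": age,
                    "hearing_age_mo": age if g != "CI" else age - 15,
                    "outcome": 10 + 21 * age,
                }
            )
    return pd.DataFrame(rows)


def test_perfect_line():
    table = _per_child()
    for s in cross_sectional_slopes(table, "outcome", "CHRONO"):
        assert s.beta == pytest.approx(21.0)
        assert s.pearson_r == pytest.approx(1.0)


def test_permutation_oracle():
    rng = np.random.default_rng(42)
    table = _per_child()
    sub = table[table["hearing_group"] == "CI"].copy()
    betas, rs = [], []
    for _ in range(1000):
        sub["outcome"] = rng.permutation(sub["outcome"].to_numpy())
        (s,) = [
            x
            for x in cross_sectional_slopes(sub, "outcome", "CHRONO")
            if x.group == "CI"
        ]
        betas.append(s.beta)
        rs.append(s.pearson_r)
    # permutation destroys the age relationship
    se = np.std(betas) / np.sqrt(len(betas))
    assert abs(np.mean(betas)) < 3 * se + 1e-9
    assert abs(np.mean(rs)) < 0.05


def test_small_group_flagged_unavailable():
    table = _per_child(n=2)
    for s in cross_sectional_slopes(table, "outcome", "CHRONO"):
        assert not s.available
        assert np.isnan(s.beta)


def test_hearing_basis_restricted_to_ci():
    table = _per_child()
    slopes = cross_sectional_slopes(
        table, "outcome", "HEARING", AnalysisConfig()
    )
    assert [s.group for s in slopes] == ["CI"]


def test_hearing_basis_applies_experience_floor():
    table = _per_child()
    ci = table["hearing_group"] == "CI"
    table.loc[ci, "hearing_age_mo"] = np.where(
        np.arange(ci.sum()) < 2, 8.0, 20.0
    )
    (s,) = cross_sectional_slopes(table, "outcome", "HEARING", AnalysisConfig())
    assert s.n == 16


def test_voc_duration_slope_recovers_planted(rng):
    # segment-level durations with child intercepts: slope 6 ms/month
    rows = []
    ages = rng.uniform(20, 55, size=40)
    for i, age in enumerate(ages):
        intercept = rng.normal(0, 50)
        durs = 900 + 6.0 * age + intercept + rng.normal(0, 200, size=150)
        rows.extend(
            {"child_id": f"ha{i}", "duration_ms": d} for d in durs
        )
    dur_tbl = pd.DataFrame(rows)
    per_child = pd.DataFrame(
        {
            "child_id": [f"ha{i}" for i in range(40)],
            "hearing_group": "HA_MATCH",
            "chrono_age_mo": ages,
            "hearing_age_mo": ages,
        }
    )
    (s,) = voc_duration_slopes(dur_tbl, per_child, "CHRONO")
    assert s.group == "HA_MATCH"
    assert s.beta == pytest.approx(6.0, abs=1.5)


# -- productivity model -------------------------------------------------------


def test_group_slope_arithmetic_noise_free():
    # exact planted slopes: CI 2.22, deviations +1.44 / +1.31
    table = simulate_productivity_cohort(
        n_per_group=18,
        turn_slopes={"CI": 2.22, "CA_MATCH": 3.66, "HA_MATCH": 3.53},
        age_slope=0.0,
        noise_sd=0.0,
        rng=np.random.default_rng(3),
    )
    result = fit_productivity_model(table)
    assert result.group_slopes["CI"] == pytest.approx(2.22, abs=1e-8)
    assert result.group_slopes["CA_MATCH"] == pytest.approx(3.66, abs=1e-8)
    assert result.group_slopes["HA_MATCH"] == pytest.approx(3.53, abs=1e-8)
    term = "ctc_per_hr:C(hearing_group, Treatment('CI'))[T.CA_MATCH]"
    assert result.model.coef(term) == pytest.approx(1.44, abs=1e-8)


def test_productivity_recovery_with_noise(rng):
    table = simulate_productivity_cohort(
        n_per_group=60,
        turn_slopes={"CI": 2.2, "CA_MATCH": 3.7, "HA_MATCH": 3.5},
        rng=rng,
    )
    result = fit_productivity_model(table)
    ci_se = result.model.coefficients["ctc_per_hr"].se
    assert abs(result.group_slopes["CI"] - 2.2) < 2 * ci_se
    for g, truth in (("CA_MATCH", 3.7), ("HA_MATCH", 3.5)):
        term = f"ctc_per_hr:C(hearing_group, Treatment('CI'))[T.{g}]"
        est = result.model.coefficients[term]
        assert abs((2.2 + est.estimate) - truth) < 2.5 * est.se


def test_interaction_lrt_df(rng):
    table = simulate_productivity_cohort(n_per_group=20, rng=rng)
    result = fit_productivity_model(table)
    assert result.interaction_test.df == 2
    assert result.interaction_test.chi2 >= 0


# -- sensitivity rerun --------------------------------------------------------


def _sensitivity_tables(rng, n=20):
    table = simulate_productivity_cohort(n_per_group=n, rng=rng)
    table["awc_per_hr"] = 500 + 20 * table["chrono_age_mo"] + rng.normal(
        0, 100, size=len(table)
    )
    table["adult_sec_per_hr"] = table["awc_per_hr"] / 4.0
    return table


def test_excluding_absent_child_is_noop(rng, caplog):
    table = _sensitivity_tables(rng)
    cfg = AnalysisConfig(exclude_child_ids=("ghost",))
    with caplog.at_level("WARNING"):
        result = sensitivity_rerun(table, config=cfg)
    assert "ghost" in caplog.text
    assert (result["shifts"]["shift"].abs() < 1e-9).all()


def test_excluding_one_child_is_stable(rng):
    table = _sensitivity_tables(rng, n=60)
    victim = table["child_id"].iloc[0]
    cfg = AnalysisConfig(exclude_child_ids=(victim,))
    result = sensitivity_rerun(table, config=cfg)
    prod_full = result["full"]["productivity"]
    prod_red = result["reduced"]["productivity"]
    for term, est in prod_full.model.coefficients.items():
        red = prod_red.model.coefficients[term]
        if est.se > 0:
            assert abs(red.estimate - est.estimate) < 2 * est.se


def test_planted_outlier_moves_slope_toward_oracle(rng):
    table = _sensitivity_tables(rng, n=25)
    # plant an extreme-leverage CI child
    idx = table.index[table["hearing_group"] == "CI"][0]
    table.loc[idx, "ctc_per_hr"] = 500.0
    table.loc[idx, "cvc_per_hr"] = 5000.0
    victim = table.loc[idx, "child_id"]
    cfg = AnalysisConfig(exclude_child_ids=(victim,))
    result = sensitivity_rerun(table, config=cfg)
    # oracle: refit on the remaining rows directly
    remaining = table[table["child_id"] != victim]
    oracle = fit_productivity_model(remaining)
    red = result["reduced"]["productivity"]
    assert red.group_slopes["CI"] == pytest.approx(
        oracle.group_slopes["CI"]
    )
    full = result["full"]["productivity"]
    assert abs(red.group_slopes["CI"] - oracle.group_slopes["CI"]) < abs(
        full.group_slopes["CI"] - oracle.group_slopes["CI"]
    )


def test_emptying_a_group_rejected(rng):
    table = _sensitivity_tables(rng, n=3)
    ci_ids = tuple(table.loc[table["hearing_group"] == "CI", "child_id"])
    cfg = AnalysisConfig(exclude_child_ids=ci_ids)
    with pytest.raises(DegenerateDesignError):
        sensitivity_rerun(table, config=cfg)
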