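"""Vital-rate estimators against hand-computable and ground-truth cases."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from grassipm import default_truth, generate_census
from grassipm.census import validate_individuals, validate_subplots
from grassipm import vital_rates as vr

from conftest import make_individuals


def _subplots(rows):
    df = pd.DataFrame(rows)
    for col, default in (
        ("species", "syn"), ("year", 2018), ("plot", "p1"),
        ("climate", "ambient"), ("management", "grazing"),
    ):
        if col not in df:
            df[col] = default
    return validate_subplots(df)


# -- survival / reproduction ------------------------------------------------

def test_half_survival_everywhere_gives_flat_logistic():
    z = np.tile(np.linspace(-1, 3, 40), 2)
    survived = np.array([True] * 40 + [False] * 40)
    ind = make_individuals(z=z, survived=survived, z1=z)
    fit = vr.fit_survival(ind, stratification="single")["all"]
    assert fit.intercept == pytest.approx(0.0, abs=1e-6)
    assert fit.slope == pytest.approx(0.0, abs=1e-6)


def test_all_survive_triggers_penalized_fallback():
    z = np.linspace(-1, 3, 200)
    ind = make_individuals(z=z, survived=np.ones(200, bool), z1=z)
    fit = vr.fit_survival(ind, stratification="single")["all"]
    assert fit.penalized
    fitted = expit(fit.intercept + fit.slope * z)
    assert fitted.min() >= 0.99


def test_no_reproduction_fallback_probability_near_zero():
    z = np.linspace(-1, 3, 200)
    ind = make_individuals(z=z, survived=np.ones(200, bool), z1=z,
                           reproductive=np.zeros(200, bool))
    fit = vr.fit_reproduction(ind, stratification="single")["all"]
    assert fit.penalized
    fitted = expit(fit.intercept + fit.slope * z)
    assert fitted.max() <= 0.01


def test_size_independent_reproduction_gives_zero_slope():
    rng = np.random.default_rng(8)
    z = rng.normal(1, 1, 4000)
    repro = rng.random(4000) < 0.5
    ind = make_individuals(z=z, survived=np.ones(4000, bool), reproductive=repro)
    fit = vr.fit_reproduction(ind, stratification="single")["all"]
    assert abs(fit.slope) < 3 * fit.se_slope + 1e-9
    assert abs(fit.slope) < 0.1


# -- growth -----------------------------------------------------------------

def test_identity_growth_recovered_exactly():
    z = np.linspace(-1, 3, 50)
    ind = make_individuals(z=z, survived=np.ones(50, bool), z1=z)
    fit = vr.fit_growth(ind, stratification="single")["all"]
    assert fit.intercept == pytest.approx(0.0, abs=1e-10)
    assert fit.slope == pytest.approx(1.0, abs=1e-10)
    assert fit.sd == pytest.approx(0.0, abs=1e-10)


def test_two_point_growth_is_saturated_interpolation(caplog):
    ind = make_individuals(z=[0.0, 2.0], survived=[True, True], z1=[0.5, 3.5])
    with caplog.at_level("WARNING"):
        fit = vr.fit_growth(ind, stratification="single")["all"]
    assert fit.slope == pytest.approx(1.5)
    assert fit.intercept == pytest.approx(0.5)
    assert fit.sd == 0.0
    assert any("saturated" in r.message for r in caplog.records)


def test_growth_skips_stratum_without_survivors(caplog):
    ind = make_individuals(z=[0.0, 1.0], survived=[False, False])
    with caplog.at_level("WARNING"):
        fits = vr.fit_growth(ind, stratification="single")
    assert fits == {}


# -- seeds ------------------------------------------------------------------

def test_constant_seed_output_gives_log_constant_intercept():
    z = np.linspace(-1, 3, 100)
    heads = np.full(100, 2)
    ind = make_individuals(z=z, survived=np.ones(100, bool),
                           reproductive=np.ones(100, bool), seed_heads=heads)
    seed_heads = pd.DataFrame(
        {"species": "syn", "plot": ["p1", "p1"], "head_id": ["h1", "h2"],
         "seed_count": [5, 5]}
    )
    fit = vr.fit_seeds(ind, seed_heads, stratification="single")["all"]
    assert fit.intercept == pytest.approx(np.log(10.0), abs=1e-6)
    assert fit.slope == pytest.approx(0.0, abs=1e-6)


def test_missing_plot_head_samples_fall_back_to_species_mean(caplog):
    z = np.linspace(0, 2, 50)
    ind = make_individuals(z=z, survived=np.ones(50, bool),
                           reproductive=np.ones(50, bool),
                           seed_heads=np.full(50, 3), plot="p2")
    seed_heads = pd.DataFrame(
        {"species": "syn", "plot": ["p9", "p9"], "head_id": ["h1", "h2"],
         "seed_count": [6, 10]}
    )
    with caplog.at_level("WARNING"):
        counts = vr.individual_seed_counts(ind, seed_heads)
    np.testing.assert_allclose(counts, 3 * 8.0)
    assert any("species-wide mean" in r.message for r in caplog.records)


# -- discrete rates ----------------------------------------------------------

def test_single_subplot_ratios_are_exact():
    sub = _subplots(
        [dict(subplot="s1", total_seeds=100.0, fall_seedlings=5,
              spring_seedlings=2, new_plants=2)]
    )
    ind = make_individuals(z=[0.1, 0.4, 0.2], survived=[True] * 3,
                           is_new=[True, True, True])
    d = vr.estimate_discrete_rates(sub, ind, stratification="single")["all"]
    assert d.recruit_fall == pytest.approx(0.05)
    assert d.recruit_spring == pytest.approx(0.02)
    assert d.establishment == pytest.approx(2 / 7)


def test_establishment_single_ratio():
    sub = _subplots(
        [dict(subplot="s1", total_seeds=50.0, fall_seedlings=6,
              spring_seedlings=4, new_plants=2)]
    )
    ind = make_individuals(z=[0.1, 0.2], survived=[True, True], is_new=[True, True])
    d = vr.estimate_discrete_rates(sub, ind, stratification="single")["all"]
    assert d.establishment == pytest.approx(0.2)


def test_zero_seed_subplots_excluded_from_theta(caplog):
    sub = _subplots(
        [
            dict(subplot="s1", total_seeds=100.0, fall_seedlings=10,
                 spring_seedlings=0, new_plants=1),
            dict(subplot="s2", total_seeds=100.0, fall_seedlings=30,
                 spring_seedlings=0, new_plants=1),
            dict(subplot="s3", total_seeds=0.0, fall_seedlings=0,
                 spring_seedlings=0, new_plants=0),
        ]
    )
    ind = make_individuals(z=[0.1, 0.2], survived=[True, True], is_new=[True, True])
    with caplog.at_level("INFO"):
        d = vr.estimate_discrete_rates(sub, ind, stratification="single")["all"]
    assert d.recruit_fall == pytest.approx(0.2)
    assert any("zero seeds" in r.message for r in caplog.records)


def test_establishment_above_one_clipped_with_warning(caplog):
    sub = _subplots(
        [dict(subplot="s1", total_seeds=10.0, fall_seedlings=2,
              spring_seedlings=0, new_plants=5)]
    )
    ind = make_individuals(z=[0.1, 0.2], survived=[True, True], is_new=[True, True])
    with caplog.at_level("WARNING"):
        d = vr.estimate_discrete_rates(sub, ind, stratification="single")["all"]
    assert d.establishment == 1.0
    assert any("clipped" in r.message for r in caplog.records)


def test_pooled_aggregation_uses_ratio_of_totals():
    sub = _subplots(
        [
            dict(subplot="s1", total_seeds=100.0, fall_seedlings=10,
                 spring_seedlings=5, new_plants=1),
            dict(subplot="s2", total_seeds=300.0, fall_seedlings=10,
                 spring_seedlings=5, new_plants=1),
        ]
    )
    ind = make_individuals(z=[0.1, 0.2], survived=[True, True], is_new=[True, True])
    d = vr.estimate_discrete_rates(
        sub, ind, stratification="single", aggregation="pooled"
    )["all"]
    assert d.recruit_fall == pytest.approx(20 / 400)


# -- treatment extraction ----------------------------------------------------

def _params_with(overrides):
    from grassipm.synthetic import DEFAULT_PARAM_VALUES
    from grassipm.params import VitalRateParams

    out = {}
    for combo, patch in overrides.items():
        vals = dict(DEFAULT_PARAM_VALUES)
        vals.update(patch)
        out[combo] = VitalRateParams(**vals, stratum=combo)
    return out


def test_main_effects_are_parameter_means():
    combos = _params_with(
        {
            "ambient_grazing": {"surv_int": 0.2, "recruit_fall": 0.1},
            "ambient_mowing": {"surv_int": 0.4, "recruit_fall": 0.2},
            "future_grazing": {"surv_int": 0.6, "recruit_fall": 0.3},
            "future_mowing": {"surv_int": 0.8, "recruit_fall": 0.4},
        }
    )
    full = vr.extract_treatment_params(combos)
    assert full["ambient"].surv_int == pytest.approx(0.3)
    assert full["grazing"].recruit_fall == pytest.approx(0.2)
    assert full["mowing"].recruit_fall == pytest.approx(0.3)


def test_identical_combinations_give_identical_main_effects(truth_params):
    combos = _params_with({c: {} for c in vr.COMBINATIONS})
    full = vr.extract_treatment_params(combos)
    for effect in vr.MAIN_EFFECTS:
        np.testing.assert_allclose(
            full[effect].to_array(), combos["ambient_grazing"].to_array()
        )


def test_missing_combination_blocks_main_effects():
    combos = _params_with({c: {} for c in vr.COMBINATIONS})
    del combos["future_mowing"]
    with pytest.raises(vr.FitError, match="future_mowing"):
        vr.extract_treatment_params(combos)


# -- ground-truth recovery ---------------------------------------------------

def test_single_stratum_recovery_from_generator():
    """Survival/growth/reproduction/seed regressions recover the generating
    parameters on a moderate synthetic census."""
    truth = default_truth(seed=21, n_individuals=3000, n_years=2)
    ind, sub, heads = generate_census(truth)
    ind = validate_individuals(ind)
    sel = ind[(ind["climate"] == "ambient") & (ind["management"] == "grazing")]
    p = truth.params["ambient_grazing"]
    s = vr.fit_survival(sel, "single")["all"]
    assert s.intercept == pytest.approx(p.surv_int, abs=0.15)
    assert s.slope == pytest.approx(p.surv_slope, abs=0.15)
    g = vr.fit_growth(sel, "single")["all"]
    assert g.intercept == pytest.approx(p.grow_int, abs=0.1)
    assert g.slope == pytest.approx(p.grow_slope, abs=0.1)
    assert g.sd == pytest.approx(p.grow_sd, abs=0.05)


def test_factorial_equals_separate_fits(small_census):
    """The saturated interaction fit reproduces per-combination estimates
    from independent single-stratum fits."""
    ind, sub, heads = small_census
    fact = vr.fit_survival(ind, "factorial")
    for combo in vr.COMBINATIONS:
        climate, management = combo.split("_")
        sel = ind[(ind["climate"] == climate) & (ind["management"] == management)]
        single = vr.fit_survival(sel, "single")["all"]
        assert fact[combo].intercept == pytest.approx(single.intercept, abs=1e-6)
        assert fact[combo].slope == pytest.approx(single.slope, abs=1e-6)


def test_mixed_growth_fit_extracts_population_coefficients(small_census):
    ind, _, _ = small_census
    plain = vr.fit_growth(ind, "factorial")
    mixed = vr.fit_growth(ind, "factorial", plot_random_effect=True)
    for combo in vr.COMBINATIONS:
        # no plot effects were simulated, so the fixed coefficients agree
        assert mixed[combo].intercept == pytest.approx(plain[combo].intercept, abs=0.05)
        assert mixed[combo].slope == pytest.approx(plain[combo].slope, abs=0.05)
        assert mixed[combo].sd > 0
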