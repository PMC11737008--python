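"""Bootstrap, permutation, sensitivity, LTRE and effect-size behaviour."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from grassipm import (
    bootstrap_lambda,
    build_kernel,
    compute_lambda,
    ltre,
    permutation_test,
    phenology_regression,
    sensitivity,
)
from grassipm.params import PARAM_NAMES, PARAM_PROCESS
from grassipm.perturbation import (
    StratumArrays,
    _combo_subset,
    effect_size,
    fit_single_stratum,
    fit_stratum_arrays,
    flowering_duration,
)
from grassipm import vital_rates as vr

L, U = -2.0, 5.0


# -- fast resampling path ----------------------------------------------------

def test_array_fast_path_matches_dataframe_path(small_census):
    ind, sub, heads = small_census
    ia = _combo_subset(ind, "ambient_grazing")
    sa = _combo_subset(sub, "ambient_grazing")
    fast = fit_stratum_arrays(StratumArrays.from_frames(ia, sa, heads))
    slow = fit_single_stratum(ia, sa, heads)
    np.testing.assert_allclose(fast.to_array(), slow.to_array(), atol=1e-10)


# -- bootstrap ---------------------------------------------------------------

def test_bootstrap_degenerate_data_has_zero_spread(degenerate_tables):
    ind, sub, heads = degenerate_tables
    dist = bootstrap_lambda(ind, sub, heads, "ambient_grazing",
                            n_boot=50, seed=3, lower=0.5, upper=3.0, n_bins=30)
    assert len(dist.lambdas) == 50
    assert np.ptp(dist.lambdas) == 0.0
    assert dist.sd_log_lambda == 0.0


def test_bootstrap_deterministic_given_seed(small_census):
    ind, sub, heads = small_census
    a = bootstrap_lambda(ind, sub, heads, "ambient_grazing", n_boot=25, seed=9,
                         n_bins=30)
    b = bootstrap_lambda(ind, sub, heads, "ambient_grazing", n_boot=25, seed=9,
                         n_bins=30)
    np.testing.assert_array_equal(a.lambdas, b.lambdas)


def test_bootstrap_sd_stable_across_seeds():
    """Monte-Carlo error of the bootstrap SD is small at 500 replicates."""
    from grassipm import default_truth, generate_census
    from grassipm.census import validate_individuals, validate_subplots

    truth = default_truth(seed=17, n_individuals=1000, n_plots=5,
                          n_subplots=6, n_years=2)
    ind, sub, heads = generate_census(truth)
    ind = validate_individuals(ind)
    sub = validate_subplots(sub)
    a = bootstrap_lambda(ind, sub, heads, "ambient_grazing", n_boot=500, seed=1,
                         n_bins=30)
    b = bootstrap_lambda(ind, sub, heads, "ambient_grazing", n_boot=500, seed=2,
                         n_bins=30)
    rel = abs(a.sd_log_lambda - b.sd_log_lambda) / a.sd_log_lambda
    assert rel < 0.10


def test_bootstrap_mean_tracks_point_estimate(small_census):
    ind, sub, heads = small_census
    ia = _combo_subset(ind, "ambient_grazing")
    sa = _combo_subset(sub, "ambient_grazing")
    from grassipm.perturbation import _bounds_from_data

    lo, up = _bounds_from_data(ia)
    point = compute_lambda(
        build_kernel(fit_single_stratum(ia, sa, heads), lo, up, n_bins=50),
        cross_check=False,
    )[1]
    dist = bootstrap_lambda(ind, sub, heads, "ambient_grazing", n_boot=400,
                            seed=4, lower=lo, upper=up, n_bins=50)
    # bootstrap mean within a few bootstrap SDs of the point estimate
    assert abs(dist.mean_log_lambda - point) < 3 * dist.sd_log_lambda


def test_bootstrap_main_effect_averages_two_combinations(small_census):
    ind, sub, heads = small_census
    dist = bootstrap_lambda(ind, sub, heads, "ambient", n_boot=20, seed=5,
                            n_bins=30)
    assert len(dist.lambdas) == 20
    assert np.isfinite(dist.lambdas).all()


# -- permutation -------------------------------------------------------------

def _degenerate_four_plots():
    rows = []
    for plot, mgmt in [("p1", "grazing"), ("p2", "grazing"),
                       ("p3", "mowing"), ("p4", "mowing")]:
        for k in range(12):
            rows.append(
                dict(individual_id=f"{plot}-{k}", species="syn", year=2018,
                     plot=plot, subplot=f"{plot}-s1", climate="ambient",
                     management=mgmt, size_t0=5.0, survived=True, size_t1=6.0,
                     reproductive=True, seed_heads=2, seeds_total=30.0,
                     is_new=True)
            )
    ind = pd.DataFrame(rows)
    sub = pd.DataFrame(
        [
            dict(species="syn", year=2018, plot=p, subplot=f"{p}-s1",
                 climate="ambient", management=m, total_seeds=360.0,
                 fall_seedlings=12, spring_seedlings=6, new_plants=4)
            for p, m in [("p1", "grazing"), ("p2", "grazing"),
                         ("p3", "mowing"), ("p4", "mowing")]
        ]
    )
    heads = pd.DataFrame(
        {"species": "syn", "plot": ["p1", "p2", "p3", "p4"],
         "head_id": ["h1"] * 4, "seed_count": [15] * 4}
    )
    from grassipm.census import validate_individuals, validate_subplots

    return validate_individuals(ind), validate_subplots(sub), heads


def test_permutation_degenerate_statistic_gives_p_one():
    ind, sub, heads = _degenerate_four_plots()
    res = permutation_test(ind, sub, heads, "management", n_perm=50, seed=0,
                           lower=0.5, upper=3.0, n_bins=20)
    assert res.exhaustive          # C(4,2) = 6 assignments enumerated
    assert res.observed == 0.0
    assert res.p_value == 1.0


def test_permutation_needs_two_plots_per_group(small_census):
    ind, sub, heads = small_census
    one_plot = ind[ind["plot"].isin(["ag-p1", "am-p1", "am-p2"])]
    sub_sel = sub[sub["plot"].isin(["ag-p1", "am-p1", "am-p2"])]
    with pytest.raises(ValueError, match="2 plots"):
        permutation_test(one_plot, sub_sel, heads, "management", n_perm=10, seed=0)


def test_permutation_detects_large_treatment_effect():
    from grassipm import default_truth, generate_census
    from grassipm.census import validate_individuals

    truth = default_truth(
        seed=13, n_individuals=400, n_years=2, n_subplots=4,
        param_overrides={
            "ambient_mowing": {"surv_int": 1.7, "seed_int": 2.7},
            "future_mowing": {"surv_int": 1.7, "seed_int": 2.7},
        },
    )
    ind, sub, heads = generate_census(truth)
    ind = validate_individuals(ind)
    res = permutation_test(ind, sub, heads, "management", n_perm=100, seed=1,
                           n_bins=30)
    assert res.p_value < 0.05
    assert res.observed < 0  # grazing minus mowing


def test_permutation_p_value_in_unit_interval(small_census):
    ind, sub, heads = small_census
    res = permutation_test(ind, sub, heads, "climate", n_perm=30, seed=2,
                           n_bins=30)
    assert 0 < res.p_value <= 1


# -- sensitivities -----------------------------------------------------------

def test_forward_and_central_differences_agree(truth_params):
    fwd = sensitivity(truth_params, L, U, n_bins=100, step=0.001, method="forward")
    ctr = sensitivity(truth_params, L, U, n_bins=100, step=1e-6, method="central")
    for name in PARAM_NAMES:
        assert fwd[name] == pytest.approx(ctr[name], rel=0.01), name


def test_dead_fecundity_pathway_has_zero_recruitment_sensitivity(truth_params):
    p = replace(truth_params, seed_int=-50.0)
    sens = sensitivity(p, L, U, n_bins=60)
    for name in ("recruit_fall", "recruit_spring"):
        assert abs(sens[name]) < 1e-10
    # establishment still routes the (empty) seedling class, so it is tiny too
    assert abs(sens["establishment"]) < 1e-10


def test_sensitivity_deterministic(truth_params):
    a = sensitivity(truth_params, L, U, n_bins=50)
    b = sensitivity(truth_params, L, U, n_bins=50)
    assert a == b


def test_invalid_perturbation_flagged_not_skipped(truth_params):
    p = replace(truth_params, grow_sd=0.0004)
    with pytest.warns(RuntimeWarning, match="grow_sd"):
        sens = sensitivity(p, L, U, n_bins=40, step=0.001, method="central")
    assert np.isnan(sens["grow_sd"])
    assert np.isfinite(sens["surv_int"])


# -- LTRE --------------------------------------------------------------------

def test_ltre_identical_sets_all_zero(truth_params):
    res = ltre(truth_params, truth_params, L, U, n_bins=60)
    assert res.delta_lambda == 0.0
    assert all(c == 0.0 for c in res.contributions.values())


def test_ltre_single_parameter_difference_lands_on_its_process(truth_params):
    a = replace(truth_params, seed_int=truth_params.seed_int + 0.04)
    res = ltre(a, truth_params, L, U, n_bins=100)
    total = sum(abs(c) for c in res.contributions.values())
    assert res.process_contributions["reproduction"] / total >= 0.95


def test_ltre_first_order_accuracy(truth_params):
    rng = np.random.default_rng(3)
    shifts = dict(zip(PARAM_NAMES, rng.uniform(-0.05, 0.05, len(PARAM_NAMES))))
    for name in ("grow_sd", "recruit_size_sd", "recruit_fall",
                 "recruit_spring", "establishment"):
        shifts[name] = abs(shifts[name])  # keep SDs/rates valid
    a = replace(truth_params, **{
        k: getattr(truth_params, k) + v for k, v in shifts.items()
    })
    res = ltre(a, truth_params, L, U, n_bins=100)
    assert res.delta_lambda != 0
    rel = abs(res.total_contribution - res.delta_lambda) / abs(res.delta_lambda)
    assert rel < 0.1


def test_ltre_groups_sum_exactly_and_scale_to_one(truth_params):
    a = replace(truth_params, surv_int=0.3, seed_int=2.1, recruit_fall=0.035)
    res = ltre(a, truth_params, L, U, n_bins=80)
    regrouped = {p: 0.0 for p in res.process_contributions}
    for name, c in res.contributions.items():
        regrouped[PARAM_PROCESS[name]] += c
    for proc, val in res.process_contributions.items():
        assert val == regrouped[proc]
    assert sum(abs(v) for v in res.scaled_contributions.values()) == pytest.approx(
        1.0, abs=1e-12
    )


def test_ltre_at_reference_a_reduces_to_sensitivity_times_difference(truth_params):
    d = 0.02
    b = replace(truth_params, surv_int=truth_params.surv_int - d)
    res = ltre(truth_params, b, L, U, n_bins=60, reference="a")
    sens = sensitivity(truth_params, L, U, n_bins=60)
    assert res.contributions["surv_int"] == pytest.approx(d * sens["surv_int"])
    others = [v for k, v in res.contributions.items() if k != "surv_int"]
    assert all(v == 0.0 for v in others)


# -- effect sizes and phenology ----------------------------------------------

def test_effect_size_sign_convention():
    es = effect_size({"grazing": 1.2, "mowing": 1.0, "ambient": 0.9, "future": 1.1})
    by_axis = {e.axis: e for e in es}
    assert by_axis["management"].value == pytest.approx(0.2)
    assert by_axis["management"].preference == "grazing"
    assert by_axis["climate"].value == pytest.approx(-0.2)
    assert by_axis["climate"].preference == "future"


def test_effect_size_zero_when_levels_equal():
    es = effect_size({"grazing": 1.0, "mowing": 1.0})
    assert es[0].value == 0.0


def test_flowering_duration_is_inclusive():
    assert flowering_duration(5, 6) == 2   # May through June
    assert flowering_duration(4, 12) == 9


def test_phenology_regression_recovers_exact_linear_relation():
    pheno = pd.DataFrame(
        {"species": list("abcde"), "start_month": [4, 5, 5, 6, 7],
         "end_month": [12, 6, 9, 7, 12]}
    )
    duration = pheno["end_month"] - pheno["start_month"] + 1
    eff = pd.DataFrame(
        {"species": list("abcde"), "axis": "management",
         "value": 0.03 * duration - 0.1}
    )
    fit = phenology_regression(eff, pheno)
    row = fit[(fit["axis"] == "management") & (fit["predictor"] == "duration")].iloc[0]
    assert row["slope"] == pytest.approx(0.03, abs=1e-10)
    assert row["intercept"] == pytest.approx(-0.1, abs=1e-10)


def test_phenology_regression_constant_effects_zero_slope():
    pheno = pd.DataFrame(
        {"species": list("abcd"), "start_month": [4, 5, 6, 7],
         "end_month": [6, 7, 9, 12]}
    )
    eff = pd.DataFrame(
        {"species": list("abcd"), "axis": "climate", "value": [0.2] * 4}
    )
    fit = phenology_regression(eff, pheno)
    assert np.allclose(fit["slope"], 0.0, atol=1e-12)


def test_phenology_regression_refuses_fewer_than_three_species():
    pheno = pd.DataFrame(
        {"species": ["a", "b"], "start_month": [4, 5], "end_month": [6, 7]}
    )
    eff = pd.DataFrame({"species": ["a", "b"], "axis": "climate", "value": [0.1, 0.2]})
    with pytest.raises(ValueError, match="3 species"):
        phenology_regression(eff, pheno)
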