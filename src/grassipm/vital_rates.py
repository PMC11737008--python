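"""Vital-rate regressions and treatment-specific parameter extraction.

Seven components are estimated per stratum:

* survival — logistic regression of survival to t1 on log size z;
* growth — Gaussian regression of log size at t1 (z') on z, with the
  residual SD as a third parameter;
* reproduction probability — logistic regression of flowering on z;
* seed number — log-link Poisson regression of per-individual seed count
  (seed heads x mean seeds per head) on z;
* fall and spring recruitment — mean per-subplot seedlings-per-seed ratios;
* establishment — mean per-subplot new-plants-per-seedling ratio;
* recruit size — mean and SD of log sizes of first-recorded plants.

With ``stratification="factorial"`` the regressions are fitted jointly with
full size x climate x management interactions and per-combination
(intercept, slope) pairs are assembled from coefficient sums; main-effect
parameter sets are the arithmetic means of the two combinations sharing a
factor level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .params import VitalRateParams, mean_params

logger = logging.getLogger(__name__)

COMBINATIONS = ("ambient_grazing", "ambient_mowing", "future_grazing", "future_mowing")
MAIN_EFFECTS = {
    "ambient": ("ambient_grazing", "ambient_mowing"),
    "future": ("future_grazing", "future_mowing"),
    "grazing": ("ambient_grazing", "future_grazing"),
    "mowing": ("ambient_mowing", "future_mowing"),
}

#: Ridge strength of the penalized fallback used under complete separation.
SEPARATION_RIDGE_ALPHA = 1e-4


class FitError(RuntimeError):
    pass


@dataclass
class ComponentFit:
    """(intercept, slope) of one regression component in one stratum."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    n: int
    sd: float | None = None          # growth residual SD
    penalized: bool = False


# ---------------------------------------------------------------------------
# core array-level fits (shared by the model API and the resampling loops)
# ---------------------------------------------------------------------------

def logistic_fit(y: np.ndarray, X: np.ndarray, start_params=None):
    """Bernoulli GLM with logit link; penalized ridge fallback under
    complete or quasi-complete separation.

    Returns (params, bse, penalized).
    """
    y = np.asarray(y, dtype=float)
    separated = y.min() == y.max()
    if not separated:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    start_params=start_params
                )
                eta = X @ res.params
                if np.all(np.isfinite(res.bse)) and np.max(np.abs(eta)) < 30:
                    return res.params, res.bse, False
            except Exception:
                pass
        separated = True
    if separated:
        logger.warning("separation in Bernoulli fit; using ridge-penalized fallback")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=SEPARATION_RIDGE_ALPHA, L1_wt=0.0
        )
    return np.asarray(res.params), np.full(X.shape[1], np.nan), True


def poisson_fit(y: np.ndarray, X: np.ndarray, start_params=None, groups=None):
    """Poisson GLM with log link. Returns (params, bse).

    When ``groups`` (plot labels) is given, standard errors are
    cluster-robust: seed counts estimated as heads x plot-mean seeds per
    head share the plot-level sampling error of that mean, so classical
    Poisson SEs would be badly optimistic.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(np.asarray(y, float), X, family=sm.families.Poisson())
        if groups is not None and len(np.unique(groups)) > 1:
            try:
                res = model.fit(
                    start_params=start_params,
                    cov_type="cluster",
                    cov_kwds={"groups": np.asarray(groups)},
                )
            except np.linalg.LinAlgError:
                # deficient design (near-empty cells): classical SEs instead
                logger.warning("cluster-robust seed-model covariance singular; "
                               "falling back to classical SEs")
                res = model.fit(start_params=start_params)
        else:
            res = model.fit(start_params=start_params)
    return res.params, res.bse


def linear_fit(y: np.ndarray, X: np.ndarray):
    """OLS fit; returns (params, bse, residual SD with df correction)."""
    res = sm.OLS(np.asarray(y, float), X).fit()
    dof = max(len(y) - X.shape[1], 1)
    sd = float(np.sqrt(res.ssr / dof))
    return res.params, res.bse, sd


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _factorial_design(z, climate, management):
    """Full size x climate x management interaction design (8 columns).

    Treatment coding with ambient/grazing as references, so per-combination
    intercepts and slopes are sums of coefficient subsets.
    """
    z = np.asarray(z, float)
    ic = (np.asarray(climate) == "future").astype(float)
    im = (np.asarray(management) == "mowing").astype(float)
    return np.column_stack(
        [np.ones_like(z), z, ic, im, ic * im, z * ic, z * im, z * ic * im]
    )


def _combo_coeffs(params, bse):
    """Per-combination (intercept, slope) and their SEs from the 8-column
    factorial fit, via linear contrasts."""
    out = {}
    for combo in COMBINATIONS:
        climate, management = combo.split("_")
        ic = 1.0 if climate == "future" else 0.0
        im = 1.0 if management == "mowing" else 0.0
        c_int = np.array([1.0, 0.0, ic, im, ic * im, 0.0, 0.0, 0.0])
        c_slp = np.array([0.0, 1.0, 0.0, 0.0, 0.0, ic, im, ic * im])
        # SEs via naive (diagonal) error propagation when the covariance is
        # unavailable (penalized fits); exact contrast variance otherwise
        out[combo] = (
            float(c_int @ params),
            float(c_slp @ params),
            float(np.sqrt(np.nansum((c_int * bse) ** 2))),
            float(np.sqrt(np.nansum((c_slp * bse) ** 2))),
        )
    return out


def _strata(individuals: pd.DataFrame, stratification: str):
    if stratification == "factorial":
        for combo in COMBINATIONS:
            climate, management = combo.split("_")
            yield combo, (individuals["climate"] == climate) & (
                individuals["management"] == management
            )
    elif stratification == "single":
        yield "all", pd.Series(True, index=individuals.index)
    else:
        raise ValueError(f"unknown stratification {stratification!r}")


def _binary_component(
    individuals: pd.DataFrame, response: str, stratification: str, min_n: int = 2
) -> dict[str, ComponentFit]:
    """Shared machinery for the survival and reproduction logistic fits."""
    fits: dict[str, ComponentFit] = {}
    if stratification == "factorial":
        y = individuals[response].to_numpy(float)
        X = _factorial_design(
            individuals["z"], individuals["climate"], individuals["management"]
        )
        if len(y) < min_n:
            raise FitError(f"too few records ({len(y)}) for {response} fit")
        params, bse, penalized = logistic_fit(y, X)
        per_combo = _combo_coeffs(params, bse)
        counts = individuals.groupby(["climate", "management"], observed=True).size()
        for combo, (a, b, sa, sb) in per_combo.items():
            climate, management = combo.split("_")
            n = int(counts.get((climate, management), 0))
            fits[combo] = ComponentFit(a, b, sa, sb, n, penalized=penalized)
    else:
        for name, mask in _strata(individuals, stratification):
            sub = individuals[mask]
            if len(sub) < min_n:
                logger.warning("stratum %s skipped for %s: n=%d", name, response, len(sub))
                continue
            y = sub[response].to_numpy(float)
            z = sub["z"].to_numpy(float)
            X = np.column_stack([np.ones_like(z), z])
            params, bse, penalized = logistic_fit(y, X)
            fits[name] = ComponentFit(
                float(params[0]), float(params[1]), float(bse[0]), float(bse[1]),
                len(sub), penalized=penalized,
            )
    return fits


# ---------------------------------------------------------------------------
# the seven fitting operations
# ---------------------------------------------------------------------------

def fit_survival(individuals: pd.DataFrame, stratification: str = "factorial"):
    """Logistic regression of survival to t1 on log size."""
    return _binary_component(individuals, "survived", stratification)


def fit_reproduction(individuals: pd.DataFrame, stratification: str = "factorial"):
    """Logistic regression of flowering at t0 on log size."""
    return _binary_component(individuals, "reproductive", stratification)


def mixed_linear_fit(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """Gaussian mixed model with a random intercept per plot; returns
    population-level (fixed) coefficients with the plot effect at zero.

    Falls back to OLS with a warning when the plot variance component is
    degenerate or the optimiser fails.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(np.asarray(y, float), X, groups=np.asarray(groups)).fit()
        re_var = float(np.squeeze(res.cov_re))
        if not np.isfinite(re_var) or re_var <= 1e-10:
            raise FitError("degenerate plot variance component")
        sd = float(np.sqrt(res.scale))
        return np.asarray(res.fe_params), np.asarray(res.bse_fe), sd
    except Exception as exc:  # noqa: BLE001 - any optimiser failure
        logger.warning("mixed growth fit failed (%s); refitting without the "
                       "plot term", exc)
        return linear_fit(y, X)


def fit_growth(
    individuals: pd.DataFrame,
    stratification: str = "factorial",
    plot_random_effect: bool = False,
):
    """Gaussian regression of z' on z among survivors.

    The residual SD (with degrees-of-freedom correction) is the third
    growth parameter. With ``plot_random_effect=True``, the factorial fit
    carries a random intercept per plot (the experiment's nesting) and the
    population-level coefficients are extracted. Saturated two-point strata
    fit exactly with SD 0 and a warning; strata with fewer than 3
    survivors are skipped.
    """
    surv = individuals[individuals["survived"]]
    fits: dict[str, ComponentFit] = {}
    if stratification == "factorial":
        if len(surv) < 3:
            raise FitError(f"too few survivors ({len(surv)}) for growth fit")
        y = surv["z1"].to_numpy(float)
        X = _factorial_design(surv["z"], surv["climate"], surv["management"])
        if plot_random_effect:
            params, bse, sd = mixed_linear_fit(y, X, surv["plot"].to_numpy())
        else:
            params, bse, sd = linear_fit(y, X)
        per_combo = _combo_coeffs(params, bse)
        counts = surv.groupby(["climate", "management"], observed=True).size()
        for combo, (a, b, sa, sb) in per_combo.items():
            climate, management = combo.split("_")
            fits[combo] = ComponentFit(
                a, b, sa, sb, int(counts.get((climate, management), 0)), sd=sd
            )
        return fits
    for name, mask in _strata(surv, stratification):
        sub = surv[mask]
        if len(sub) < 3:
            if len(sub) == 2:
                z = sub["z"].to_numpy(float)
                y = sub["z1"].to_numpy(float)
                if z[0] != z[1]:
                    slope = (y[1] - y[0]) / (z[1] - z[0])
                    logger.warning("growth stratum %s saturated (n=2); SD set to 0", name)
                    fits[name] = ComponentFit(
                        float(y[0] - slope * z[0]), float(slope),
                        np.nan, np.nan, 2, sd=0.0,
                    )
                    continue
            logger.warning("growth stratum %s skipped: <3 usable survivors", name)
            continue
        z = sub["z"].to_numpy(float)
        X = np.column_stack([np.ones_like(z), z])
        params, bse, sd = linear_fit(sub["z1"].to_numpy(float), X)
        fits[name] = ComponentFit(
            float(params[0]), float(params[1]), float(bse[0]), float(bse[1]),
            len(sub), sd=sd,
        )
    return fits


def seeds_per_head_means(seed_heads: pd.DataFrame | None):
    """Per-plot mean seeds per head plus the species-wide fallback mean."""
    if seed_heads is None or len(seed_heads) == 0:
        return {}, np.nan
    per_plot = seed_heads.groupby("plot")["seed_count"].mean().to_dict()
    return per_plot, float(seed_heads["seed_count"].mean())


def individual_seed_counts(
    individuals: pd.DataFrame, seed_heads: pd.DataFrame | None
) -> np.ndarray:
    """Estimated per-individual seed output: heads x plot mean seeds/head.

    Plots without lab samples fall back to the species-wide mean (logged).
    """
    per_plot, overall = seeds_per_head_means(seed_heads)
    if not per_plot:
        if "seeds_total" in individuals.columns:
            logger.warning(
                "no seeds-per-head samples; using recorded per-individual totals"
            )
            return individuals["seeds_total"].to_numpy(float)
        raise FitError("no seeds-per-head data and no recorded seed totals")
    plots = individuals["plot"].to_numpy()
    missing = [p for p in np.unique(plots) if p not in per_plot]
    if missing:
        logger.warning(
            "no seeds-per-head sample for plot(s) %s; species-wide mean used", missing
        )
    mult = np.array([per_plot.get(p, overall) for p in plots])
    return np.round(individuals["seed_heads"].to_numpy(float) * mult)


def fit_seeds(
    individuals: pd.DataFrame,
    seed_heads: pd.DataFrame | None = None,
    stratification: str = "factorial",
):
    """Poisson (log link) regression of per-individual seed count on log
    size, among reproductive individuals only."""
    rep = individuals[individuals["reproductive"]].copy()
    if len(rep) == 0:
        raise FitError("no reproductive individuals; seed model cannot be fitted")
    rep["_seed_count"] = individual_seed_counts(rep, seed_heads)
    fits: dict[str, ComponentFit] = {}
    if stratification == "factorial":
        y = rep["_seed_count"].to_numpy(float)
        X = _factorial_design(rep["z"], rep["climate"], rep["management"])
        params, bse = poisson_fit(y, X, groups=rep["plot"].to_numpy())
        per_combo = _combo_coeffs(params, bse)
        counts = rep.groupby(["climate", "management"], observed=True).size()
        for combo, (a, b, sa, sb) in per_combo.items():
            climate, management = combo.split("_")
            n = int(counts.get((climate, management), 0))
            if n == 0:
                logger.warning("seed stratum %s empty; skipped", combo)
                continue
            fits[combo] = ComponentFit(a, b, sa, sb, n)
        return fits
    for name, mask in _strata(rep, stratification):
        sub = rep[mask]
        if len(sub) == 0:
            logger.warning("seed stratum %s skipped: no reproductive plants", name)
            continue
        z = sub["z"].to_numpy(float)
        X = np.column_stack([np.ones_like(z), z])
        params, bse = poisson_fit(
            sub["_seed_count"].to_numpy(float), X, groups=sub["plot"].to_numpy()
        )
        fits[name] = ComponentFit(
            float(params[0]), float(params[1]), float(bse[0]), float(bse[1]), len(sub)
        )
    return fits


@dataclass
class DiscreteRates:
    recruit_fall: float
    recruit_spring: float
    establishment: float
    recruit_size_mean: float
    recruit_size_sd: float
    n_subplot_years: int
    n_new_plants: int


def estimate_discrete_rates(
    subplots: pd.DataFrame,
    individuals: pd.DataFrame,
    stratification: str = "factorial",
    aggregation: str = "per_subplot",
    eta_individuals: pd.DataFrame | None = None,
) -> dict[str, DiscreteRates]:
    """Recruitment, establishment and recruit-size parameters per stratum.

    Fall/spring recruitment are means of per-subplot-year seedling/seed
    ratios over rows with nonzero seed totals; establishment is the mean of
    per-subplot new-plants/seedlings ratios over rows with seedlings,
    clipped to 1 (a proportion) with a warning when it exceeds 1.
    ``aggregation="pooled"`` instead uses ratio-of-totals estimators.
    Recruit size is the mean/SD of log sizes of first-recorded plants;
    ``eta_individuals`` overrides which records supply those (per-year
    fitting passes the following census, where a transition's recruits are
    first recorded).
    """
    if aggregation not in ("per_subplot", "pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    eta_source = individuals if eta_individuals is None else eta_individuals
    out: dict[str, DiscreteRates] = {}
    for name, mask in _strata(subplots, stratification):
        sub = subplots[mask]
        if stratification == "factorial":
            climate, management = name.split("_")
            ind = eta_source[
                (eta_source["climate"] == climate)
                & (eta_source["management"] == management)
            ]
        else:
            ind = eta_source
        with_seeds = sub[sub["total_seeds"] > 0]
        n_dropped = len(sub) - len(with_seeds)
        if n_dropped:
            logger.info(
                "stratum %s: %d subplot-years with zero seeds excluded from "
                "recruitment ratios", name, n_dropped,
            )
        if len(with_seeds) == 0:
            logger.warning("stratum %s skipped: no subplot-years with seeds", name)
            continue
        if aggregation == "per_subplot":
            theta_f = float(
                (with_seeds["fall_seedlings"] / with_seeds["total_seeds"]).mean()
            )
            theta_s = float(
                (with_seeds["spring_seedlings"] / with_seeds["total_seeds"]).mean()
            )
        else:
            tot = float(with_seeds["total_seeds"].sum())
            theta_f = float(with_seeds["fall_seedlings"].sum()) / tot
            theta_s = float(with_seeds["spring_seedlings"].sum()) / tot
        with_seedlings = sub[sub["seedlings_total"] > 0]
        if len(with_seedlings) == 0:
            logger.warning("stratum %s skipped: no seedlings for establishment", name)
            continue
        if aggregation == "per_subplot":
            estab = float(
                (with_seedlings["new_plants"] / with_seedlings["seedlings_total"]).mean()
            )
        else:
            estab = float(with_seedlings["new_plants"].sum()) / float(
                with_seedlings["seedlings_total"].sum()
            )
        if estab > 1.0:
            logger.warning(
                "stratum %s: establishment estimate %.3f > 1 clipped to 1", name, estab
            )
            estab = 1.0
        new = ind[ind["is_new"]]
        if len(new) < 2:
            logger.warning(
                "stratum %s skipped: <2 new plants for the recruit-size distribution",
                name,
            )
            continue
        z_new = new["z"].to_numpy(float)
        out[name] = DiscreteRates(
            recruit_fall=theta_f,
            recruit_spring=theta_s,
            establishment=estab,
            recruit_size_mean=float(z_new.mean()),
            recruit_size_sd=float(z_new.std(ddof=1)),
            n_subplot_years=len(with_seeds),
            n_new_plants=len(new),
        )
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_params(
    survival: dict, growth: dict, reproduction: dict, seeds: dict, discrete: dict,
    species: str = "",
) -> dict[str, VitalRateParams]:
    """Combine the five component fits into full 14-parameter sets, one per
    stratum present in all components."""
    strata = set(survival) & set(growth) & set(reproduction) & set(seeds) & set(discrete)
    out = {}
    for name in sorted(strata):
        s, g, r, f, d = survival[name], growth[name], reproduction[name], seeds[name], discrete[name]
        p = VitalRateParams(
            surv_int=s.intercept, surv_slope=s.slope,
            grow_int=g.intercept, grow_slope=g.slope, grow_sd=g.sd,
            repr_int=r.intercept, repr_slope=r.slope,
            seed_int=f.intercept, seed_slope=f.slope,
            recruit_fall=d.recruit_fall, recruit_spring=d.recruit_spring,
            establishment=d.establishment,
            recruit_size_mean=d.recruit_size_mean, recruit_size_sd=d.recruit_size_sd,
            species=species, stratum=name,
        )
        p.se = {
            "surv_int": s.se_intercept, "surv_slope": s.se_slope,
            "grow_int": g.se_intercept, "grow_slope": g.se_slope,
            "repr_int": r.se_intercept, "repr_slope": r.se_slope,
            "seed_int": f.se_intercept, "seed_slope": f.se_slope,
        }
        p.n_obs = {
            "survival": s.n, "growth": g.n, "reproduction": r.n, "seeds": f.n,
            "subplot_years": d.n_subplot_years, "new_plants": d.n_new_plants,
        }
        out[name] = p
    return out


def extract_treatment_params(
    combo_params: dict[str, VitalRateParams]
) -> dict[str, VitalRateParams]:
    """Add the four main-effect parameter sets to the four combinations.

    Each main-effect parameter is the arithmetic mean of the two
    corresponding combination parameters (e.g. the ambient survival
    intercept is the mean of the ambient-grazing and ambient-mowing
    intercepts); the rule applies identically to all 14 parameters.
    """
    missing = [c for c in COMBINATIONS if c not in combo_params]
    if missing:
        raise FitError(
            f"main effects unavailable: missing combination fit(s) {missing}"
        )
    out = dict(combo_params)
    for effect, (a, b) in MAIN_EFFECTS.items():
        out[effect] = mean_params(combo_params[a], combo_params[b], stratum=effect)
    return out


def fit_all(
    individuals: pd.DataFrame,
    subplots: pd.DataFrame,
    seed_heads: pd.DataFrame | None = None,
    stratification: str = "factorial",
    aggregation: str = "per_subplot",
    species: str = "",
    main_effects: bool = True,
    plot_random_effect: bool = False,
    eta_individuals: pd.DataFrame | None = None,
) -> dict[str, VitalRateParams]:
    """Run all seven component fits and assemble parameter sets per stratum
    (plus main effects under factorial stratification)."""
    params = assemble_params(
        fit_survival(individuals, stratification),
        fit_growth(individuals, stratification, plot_random_effect=plot_random_effect),
        fit_reproduction(individuals, stratification),
        fit_seeds(individuals, seed_heads, stratification),
        estimate_discrete_rates(
            subplots, individuals, stratification, aggregation,
            eta_individuals=eta_individuals,
        ),
        species=species,
    )
    if stratification == "factorial" and main_effects:
        try:
            params = extract_treatment_params(params)
        except FitError as exc:
            logger.warning("main-effect parameter sets unavailable: %s", exc)
    return params
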