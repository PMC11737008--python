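"""Treatment inference and decomposition on top of the fitted IPMs.

* bootstrap resampling of the census (individuals and subplots) to put an
  uncertainty distribution on lambda per stratum;
* plot-level permutation tests for treatment differences in lambda;
* finite-difference sensitivities of lambda to each of the 14 parameters;
* life-table-response-experiment (LTRE) decomposition of a lambda
  difference into per-parameter contributions, grouped into five
  demographic processes and scaled to proportional influence;
* treatment effect sizes on lambda and the simple phenology regressions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations as _combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import vital_rates as vr
from .kernel import DEFAULT_NBINS, build_kernel, compute_lambda, size_bounds
from .params import PARAM_NAMES, PARAM_PROCESS, PROCESSES, VitalRateParams, mean_params

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 1000
DEFAULT_N_PERM = 1000
DEFAULT_SENS_STEP = 0.001
_SD_FLOOR = 1e-6   # stands in for a zero residual SD on degenerate resamples

COMBINATIONS = vr.COMBINATIONS
MAIN_EFFECTS = vr.MAIN_EFFECTS


# ---------------------------------------------------------------------------
# shared fitting helpers
# ---------------------------------------------------------------------------

def _combo_subset(df: pd.DataFrame, combo: str) -> pd.DataFrame:
    climate, management = combo.split("_")
    return df[(df["climate"] == climate) & (df["management"] == management)]


def _bounds_from_data(individuals) -> tuple[float, float]:
    """Observed log-size range padded by half the pooled growth residual SD."""
    surv = individuals[individuals["survived"]]
    if len(surv) >= 3:
        z = surv["z"].to_numpy(float)
        X = np.column_stack([np.ones_like(z), z])
        _, _, grow_sd = vr.linear_fit(surv["z1"].to_numpy(float), X)
    else:
        grow_sd = float(individuals["z"].std() or 1.0)
    return size_bounds(individuals["z"].to_numpy(), grow_sd)


def fit_single_stratum(individuals, subplots, seed_heads) -> VitalRateParams:
    """Fit all vital rates for one homogeneous stratum of data."""
    params = vr.fit_all(
        individuals, subplots, seed_heads, stratification="single",
        main_effects=False,
    )
    if "all" not in params:
        raise vr.FitError("stratum could not be fitted (a component was skipped)")
    return params["all"]


class StratumArrays:
    """Column arrays for one stratum, for the resampling hot loops.

    Holds exactly the inputs of the single-stratum estimation path (log
    sizes, outcomes, estimated per-individual seed counts computed once
    from the plot-level seeds-per-head means, subplot-year counts and
    recruit log sizes) so bootstrap replicates and permutations can refit
    without DataFrame overhead. ``fit_stratum_arrays`` applies the same
    estimators as :func:`fit_single_stratum`.
    """

    __slots__ = (
        "z", "survived", "z1", "reproductive", "seed_y", "is_new",
        "total_seeds", "fall", "spring", "seedlings", "new_plants",
    )

    def __init__(self, **cols):
        for k in self.__slots__:
            setattr(self, k, cols[k])

    @classmethod
    def from_frames(cls, individuals, subplots, seed_heads) -> "StratumArrays":
        seed_y = np.zeros(len(individuals))
        rep_mask = individuals["reproductive"].to_numpy(bool)
        if rep_mask.any():
            seed_y[rep_mask] = vr.individual_seed_counts(
                individuals[rep_mask], seed_heads
            )
        return cls(
            z=individuals["z"].to_numpy(float),
            survived=individuals["survived"].to_numpy(bool),
            z1=individuals["z1"].to_numpy(float),
            reproductive=rep_mask,
            seed_y=seed_y,
            is_new=individuals["is_new"].to_numpy(bool),
            total_seeds=subplots["total_seeds"].to_numpy(float),
            fall=subplots["fall_seedlings"].to_numpy(float),
            spring=subplots["spring_seedlings"].to_numpy(float),
            seedlings=subplots["seedlings_total"].to_numpy(float),
            new_plants=subplots["new_plants"].to_numpy(float),
        )

    _IND = ("z", "survived", "z1", "reproductive", "seed_y", "is_new")
    _SUB = ("total_seeds", "fall", "spring", "seedlings", "new_plants")

    def resample(self, rng: np.random.Generator) -> "StratumArrays":
        """Individuals and subplot-years resampled with replacement."""
        ii = rng.integers(0, len(self.z), len(self.z))
        jj = rng.integers(0, len(self.total_seeds), len(self.total_seeds))
        cols = {k: getattr(self, k)[ii] for k in self._IND}
        cols.update({k: getattr(self, k)[jj] for k in self._SUB})
        return StratumArrays(**cols)

    @classmethod
    def concat(cls, parts) -> "StratumArrays":
        return cls(
            **{
                k: np.concatenate([getattr(p, k) for p in parts])
                for k in cls.__slots__
            }
        )


def fit_stratum_arrays(
    d: StratumArrays, start: VitalRateParams | None = None
) -> VitalRateParams:
    """Single-stratum vital-rate fit on column arrays.

    Identical estimators to the DataFrame path (tested for agreement);
    ``start`` warm-starts the GLM iterations with a previous solution.
    """
    ones = np.ones_like(d.z)
    X = np.column_stack([ones, d.z])

    sp = None if start is None else np.array([start.surv_int, start.surv_slope])
    (a_s, b_s), _, _ = _two(vr.logistic_fit(d.survived.astype(float), X, start_params=sp))

    surv = d.survived
    if surv.sum() < 3:
        raise vr.FitError("fewer than 3 survivors; growth unfittable")
    Xg = np.column_stack([ones[surv], d.z[surv]])
    (a_g, b_g), _, sd_g = vr.linear_fit(d.z1[surv], Xg)
    if sd_g <= 0:
        # zero-variance (degenerate) data: treat growth as a point mass so
        # the kernel still builds; deterministic, so resampling adds no spread
        logger.warning("degenerate growth residual SD; floored at %g", _SD_FLOOR)
        sd_g = _SD_FLOOR

    rp = None if start is None else np.array([start.repr_int, start.repr_slope])
    (a_p, b_p), _, _ = _two(vr.logistic_fit(d.reproductive.astype(float), X, start_params=rp))

    rep = d.reproductive
    if rep.sum() < 2:
        raise vr.FitError("fewer than 2 reproductive plants; seed model unfittable")
    Xf = np.column_stack([ones[rep], d.z[rep]])
    fp = None if start is None else np.array([start.seed_int, start.seed_slope])
    (a_f, b_f), _ = vr.poisson_fit(d.seed_y[rep], Xf, start_params=fp)

    with_seeds = d.total_seeds > 0
    if not with_seeds.any():
        raise vr.FitError("no subplot-years with seeds; recruitment unfittable")
    theta_f = float(np.mean(d.fall[with_seeds] / d.total_seeds[with_seeds]))
    theta_s = float(np.mean(d.spring[with_seeds] / d.total_seeds[with_seeds]))
    with_sl = d.seedlings > 0
    if not with_sl.any():
        raise vr.FitError("no seedlings; establishment unfittable")
    estab = min(1.0, float(np.mean(d.new_plants[with_sl] / d.seedlings[with_sl])))

    new_z = d.z[d.is_new]
    if new_z.size < 2:
        raise vr.FitError("fewer than 2 new plants; recruit-size distribution unfittable")
    eta_sd = float(new_z.std(ddof=1))
    if eta_sd <= 0:
        logger.warning("degenerate recruit-size SD; floored at %g", _SD_FLOOR)
        eta_sd = _SD_FLOOR

    return VitalRateParams(
        surv_int=float(a_s), surv_slope=float(b_s),
        grow_int=float(a_g), grow_slope=float(b_g), grow_sd=sd_g,
        repr_int=float(a_p), repr_slope=float(b_p),
        seed_int=float(a_f), seed_slope=float(b_f),
        recruit_fall=theta_f, recruit_spring=theta_s, establishment=estab,
        recruit_size_mean=float(new_z.mean()), recruit_size_sd=eta_sd,
    )


def _two(fit_result):
    params, bse, penalized = fit_result
    return (params[0], params[1]), bse, penalized


def stratum_lambda(
    individuals, subplots, seed_heads, stratum,
    lower=None, upper=None, n_bins=DEFAULT_NBINS, eviction="renorm",
) -> float:
    """Point-estimate lambda for a combination or main-effect stratum,
    fitting each involved combination separately and averaging parameters
    for main effects."""
    combos = [stratum] if stratum in COMBINATIONS else list(MAIN_EFFECTS[stratum]) \
        if stratum in MAIN_EFFECTS else [None]
    if lower is None or upper is None:
        lo, up = _bounds_from_data(individuals)
        lower = lo if lower is None else lower
        upper = up if upper is None else upper
    fitted = []
    for combo in combos:
        ind = individuals if combo is None else _combo_subset(individuals, combo)
        sub = subplots if combo is None else _combo_subset(subplots, combo)
        fitted.append(fit_single_stratum(ind, sub, seed_heads))
    p = fitted[0] if len(fitted) == 1 else mean_params(*fitted, stratum=stratum)
    k = build_kernel(p, lower, upper, n_bins=n_bins, eviction=eviction)
    return compute_lambda(k, cross_check=False)[0]


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class LambdaDistribution:
    """Bootstrap distribution of lambda for one stratum."""

    stratum: str
    lambdas: np.ndarray
    seed: int
    n_dropped: int = 0

    @property
    def mean_log_lambda(self) -> float:
        return float(np.mean(np.log(self.lambdas)))

    @property
    def sd_log_lambda(self) -> float:
        if len(self.lambdas) < 2 or np.ptp(self.lambdas) == 0.0:
            return 0.0  # exactly degenerate replicates: no rounding noise
        return float(np.std(np.log(self.lambdas), ddof=1))


def bootstrap_lambda(
    individuals, subplots, seed_heads, stratum,
    n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
    lower=None, upper=None, n_bins: int = DEFAULT_NBINS, eviction="renorm",
    max_dropped_frac: float = 0.1,
) -> LambdaDistribution:
    """Nonparametric bootstrap of lambda for one stratum.

    Each replicate resamples individual records with replacement (the
    sampling unit of the regression rates) and subplot-year rows with
    replacement (the sampling unit of the discrete rates), refits all vital
    rates and rebuilds the kernel on the stratum's fixed [L, U] domain.
    Failed replicates are dropped with a log entry; more than
    ``max_dropped_frac`` failures is a hard error. Deterministic given
    ``seed``.
    """
    if stratum in COMBINATIONS:
        combos = [stratum]
    elif stratum in MAIN_EFFECTS:
        combos = list(MAIN_EFFECTS[stratum])
    else:
        combos = [None]
    rng = np.random.default_rng(seed)
    if lower is None or upper is None:
        lo, up = _bounds_from_data(individuals)
        lower = lo if lower is None else lower
        upper = up if upper is None else upper

    combo_data, starts = [], []
    for combo in combos:
        ind = individuals if combo is None else _combo_subset(individuals, combo)
        sub = subplots if combo is None else _combo_subset(subplots, combo)
        if len(ind) == 0 or len(sub) == 0:
            raise vr.FitError(f"no data for stratum component {combo!r}")
        arrays = StratumArrays.from_frames(ind, sub, seed_heads)
        combo_data.append(arrays)
        try:
            starts.append(fit_stratum_arrays(arrays))
        except vr.FitError:
            starts.append(None)

    lams, dropped = [], 0
    for _ in range(n_boot):
        try:
            fitted = [
                fit_stratum_arrays(arrays.resample(rng), start=start)
                for arrays, start in zip(combo_data, starts)
            ]
            p = fitted[0] if len(fitted) == 1 else mean_params(*fitted, stratum=stratum)
            k = build_kernel(p, lower, upper, n_bins=n_bins, eviction=eviction)
            lams.append(compute_lambda(k, cross_check=False)[0])
        except (vr.FitError, ValueError) as exc:
            dropped += 1
            logger.info("bootstrap replicate dropped: %s", exc)
    if dropped > max_dropped_frac * n_boot:
        raise vr.FitError(
            f"{dropped}/{n_boot} bootstrap replicates failed (> {max_dropped_frac:.0%})"
        )
    return LambdaDistribution(
        stratum=stratum, lambdas=np.asarray(lams), seed=seed, n_dropped=dropped
    )


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    factor: str
    within: dict
    observed: float            # lambda_A - lambda_B
    p_value: float
    n_perm: int
    exhaustive: bool
    level_a: str = ""
    level_b: str = ""


def _plot_level_map(individuals: pd.DataFrame, factor: str) -> dict[str, str]:
    levels = individuals.groupby("plot", observed=True)[factor].agg(
        lambda s: s.iloc[0]
    )
    multi = individuals.groupby("plot", observed=True)[factor].nunique()
    if (multi > 1).any():
        raise ValueError(f"factor {factor!r} varies within a plot; not permutable")
    return levels.to_dict()


def permutation_test(
    individuals, subplots, seed_heads, factor: str,
    within: dict | None = None,
    n_perm: int = DEFAULT_N_PERM, seed: int = 0,
    lower=None, upper=None, n_bins: int = DEFAULT_NBINS, eviction="renorm",
) -> PermutationResult:
    """Plot-level permutation test for a difference in lambda.

    The two groups are the levels of ``factor`` ("climate" or
    "management"), optionally restricted by ``within`` (e.g.
    ``{"climate": "ambient"}`` tests management within ambient climate).
    Treatments are applied at the plot scale, so whole plots are the
    exchangeable units: the null is built by reassigning factor levels
    across plots keeping plot memberships intact, refitting both groups and
    recomputing T = lambda_A - lambda_B. Two-sided p-value with the add-one
    estimator; all distinct reassignments are enumerated when there are at
    most ``n_perm`` of them.
    """
    ind, sub = individuals, subplots
    for col, val in (within or {}).items():
        ind = ind[ind[col] == val]
        sub = sub[sub[col] == val]
    plot_levels = _plot_level_map(ind, factor)
    levels = sorted(set(plot_levels.values()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 levels of {factor!r}, got {levels}")
    level_a, level_b = levels
    plots = sorted(plot_levels)
    group_a = [p for p in plots if plot_levels[p] == level_a]
    if len(group_a) < 2 or len(plots) - len(group_a) < 2:
        raise ValueError("need at least 2 plots per group for plot-level permutation")

    arrays_by_plot = {
        p: StratumArrays.from_frames(
            ind[ind["plot"] == p], sub[sub["plot"] == p], seed_heads
        )
        for p in plots
    }

    if lower is None or upper is None:
        lo, up = _bounds_from_data(ind)
        lower = lo if lower is None else lower
        upper = up if upper is None else upper

    start = {"a": None, "b": None}

    def stat(a_plots: tuple) -> float:
        a_set = set(a_plots)
        da = StratumArrays.concat([arrays_by_plot[p] for p in a_plots])
        db = StratumArrays.concat(
            [arrays_by_plot[p] for p in plots if p not in a_set]
        )
        pa = fit_stratum_arrays(da, start=start["a"])
        pb = fit_stratum_arrays(db, start=start["b"])
        if start["a"] is None:
            start["a"], start["b"] = pa, pb   # warm-start later refits
        ka = build_kernel(pa, lower, upper, n_bins=n_bins, eviction=eviction)
        kb = build_kernel(pb, lower, upper, n_bins=n_bins, eviction=eviction)
        return compute_lambda(ka, cross_check=False)[0] - compute_lambda(
            kb, cross_check=False
        )[0]

    observed = stat(tuple(group_a))
    # with equal group sizes the two-sided statistic |T| is invariant under
    # swapping the groups, so complementary assignments form one class;
    # anchoring the first plot in group A enumerates each class once
    balanced = 2 * len(group_a) == len(plots)
    n_total = math.comb(len(plots), len(group_a))
    if balanced:
        n_total //= 2
    rng = np.random.default_rng(seed)
    if n_total <= n_perm:
        if balanced:
            assignments = (
                (plots[0],) + rest
                for rest in _combinations(plots[1:], len(group_a) - 1)
            )
        else:
            assignments = _combinations(plots, len(group_a))
        stats_null, skipped = [], 0
        for assignment in assignments:
            try:
                stats_null.append(stat(assignment))
            except vr.FitError as exc:
                skipped += 1
                logger.info("permutation assignment skipped: %s", exc)
        if skipped > 0.1 * n_total:
            raise vr.FitError(f"{skipped}/{n_total} permutations unfittable")
        n_extreme = sum(abs(t) >= abs(observed) - 1e-15 for t in stats_null)
        p_value = n_extreme / len(stats_null)
        return PermutationResult(
            factor, within or {}, observed, float(p_value), len(stats_null), True,
            level_a, level_b,
        )
    count, done, skipped = 0, 0, 0
    for _ in range(n_perm):
        assignment = tuple(rng.choice(plots, size=len(group_a), replace=False))
        try:
            t = stat(assignment)
        except vr.FitError as exc:
            skipped += 1
            logger.info("permutation replicate skipped: %s", exc)
            continue
        done += 1
        if abs(t) >= abs(observed) - 1e-15:
            count += 1
    if skipped > 0.1 * n_perm:
        raise vr.FitError(f"{skipped}/{n_perm} permutation replicates unfittable")
    p_value = (1 + count) / (1 + done)
    return PermutationResult(
        factor, within or {}, observed, float(p_value), done, False,
        level_a, level_b,
    )


# ---------------------------------------------------------------------------
# sensitivities and LTRE
# ---------------------------------------------------------------------------

def sensitivity(
    params: VitalRateParams, lower, upper,
    n_bins: int = DEFAULT_NBINS, step: float = DEFAULT_SENS_STEP,
    method: str = "forward", eviction: str = "renorm",
) -> dict[str, float]:
    """Finite-difference sensitivities of lambda to each of the 14
    parameters.

    Default is a forward difference with absolute step 0.001 on every
    parameter. ``method="central"`` uses a symmetric difference (same
    step). A perturbation that violates a parameter invariant (e.g. a
    negative SD) is flagged with a warning and reported as NaN rather than
    silently skipped.
    """
    base_kernel = build_kernel(params, lower, upper, n_bins=n_bins, eviction=eviction)
    lam0 = compute_lambda(base_kernel, cross_check=False)[0]
    out: dict[str, float] = {}
    for name in PARAM_NAMES:
        try:
            if method == "forward":
                p_up = params.perturbed(name, step)
                p_up.validate()
                lam_up = build_kernel(
                    p_up, lower, upper, n_bins=n_bins, eviction=eviction
                )
                out[name] = (compute_lambda(lam_up, cross_check=False)[0] - lam0) / step
            elif method == "central":
                p_up = params.perturbed(name, step / 2)
                p_dn = params.perturbed(name, -step / 2)
                p_up.validate()
                p_dn.validate()
                lam_up = compute_lambda(
                    build_kernel(p_up, lower, upper, n_bins=n_bins, eviction=eviction),
                    cross_check=False,
                )[0]
                lam_dn = compute_lambda(
                    build_kernel(p_dn, lower, upper, n_bins=n_bins, eviction=eviction),
                    cross_check=False,
                )[0]
                out[name] = (lam_up - lam_dn) / step
            else:
                raise ValueError(f"unknown method {method!r}")
        except ValueError as exc:
            warnings.warn(
                f"sensitivity to {name!r} undefined at step {step}: {exc}",
                RuntimeWarning,
            )
            out[name] = np.nan
    return out


@dataclass
class LTREResult:
    """Decomposition of a lambda difference between two parameter sets."""

    pair: tuple[str, str]
    delta_lambda: float
    sensitivities: dict[str, float]
    contributions: dict[str, float]
    reference: str

    @property
    def total_contribution(self) -> float:
        return float(sum(self.contributions.values()))

    @property
    def process_contributions(self) -> dict[str, float]:
        out = {p: 0.0 for p in PROCESSES}
        for name, c in self.contributions.items():
            out[PARAM_PROCESS[name]] += c
        return out

    @property
    def scaled_contributions(self) -> dict[str, float]:
        total = sum(abs(c) for c in self.contributions.values())
        if total == 0:
            return {k: 0.0 for k in self.contributions}
        return {k: c / total for k, c in self.contributions.items()}

    @property
    def scaled_process_contributions(self) -> dict[str, float]:
        scaled = self.scaled_contributions
        out = {p: 0.0 for p in PROCESSES}
        for name, c in scaled.items():
            out[PARAM_PROCESS[name]] += c
        return out


def ltre(
    params_a: VitalRateParams, params_b: VitalRateParams, lower, upper,
    n_bins: int = DEFAULT_NBINS, reference: str = "midpoint",
    step: float = DEFAULT_SENS_STEP, eviction: str = "renorm",
) -> LTREResult:
    """Life table response experiment for a pair of strata.

    The difference in lambda, ``delta_lambda = lambda_A - lambda_B``, is
    decomposed into per-parameter contributions
    ``(alpha_i_A - alpha_i_B) * d lambda / d alpha_i`` with sensitivities
    evaluated at a reference parameter set: the elementwise midpoint of A
    and B by default (``reference`` may also be ``"a"`` or ``"b"``).
    Contributions are grouped into the five demographic processes and
    scaled so their absolute values sum to 1.
    """
    lam_a = compute_lambda(
        build_kernel(params_a, lower, upper, n_bins=n_bins, eviction=eviction),
        cross_check=False,
    )[0]
    lam_b = compute_lambda(
        build_kernel(params_b, lower, upper, n_bins=n_bins, eviction=eviction),
        cross_check=False,
    )[0]
    if reference == "midpoint":
        ref = mean_params(params_a, params_b, stratum="midpoint")
    elif reference == "a":
        ref = params_a
    elif reference == "b":
        ref = params_b
    else:
        raise ValueError(f"unknown reference policy {reference!r}")
    sens = sensitivity(
        ref, lower, upper, n_bins=n_bins, step=step, eviction=eviction
    )
    diff = params_a.to_array() - params_b.to_array()
    contributions = {
        name: float(d * sens[name]) for name, d in zip(PARAM_NAMES, diff)
    }
    return LTREResult(
        pair=(params_a.stratum or "A", params_b.stratum or "B"),
        delta_lambda=float(lam_a - lam_b),
        sensitivities=sens,
        contributions=contributions,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# effect sizes and phenology regressions
# ---------------------------------------------------------------------------

@dataclass
class EffectSize:
    species: str
    axis: str       # "management" or "climate"
    value: float    # grazing - mowing, or ambient - future

    @property
    def preference(self) -> str:
        if self.axis == "management":
            return "grazing" if self.value > 0 else "mowing"
        return "ambient" if self.value > 0 else "future"


def effect_size(lambdas: dict[str, float], species: str = "") -> list[EffectSize]:
    """Treatment effect sizes on lambda from a main-effect lambda table.

    Positive values indicate a preference for grazing (management axis) or
    for the ambient climate (climate axis).
    """
    out = []
    if "grazing" in lambdas and "mowing" in lambdas:
        out.append(
            EffectSize(species, "management", float(lambdas["grazing"] - lambdas["mowing"]))
        )
    else:
        logger.warning("management effect size skipped: missing main-effect lambda")
    if "ambient" in lambdas and "future" in lambdas:
        out.append(
            EffectSize(species, "climate", float(lambdas["ambient"] - lambdas["future"]))
        )
    else:
        logger.warning("climate effect size skipped: missing main-effect lambda")
    return out


def flowering_duration(start_month, end_month):
    """Flowering duration in months, inclusive of both endpoints (May to
    June is 2 months). Accepts scalars or array-likes."""
    return end_month - start_month + 1


def phenology_regression(
    effect_sizes: pd.DataFrame, phenology: pd.DataFrame
) -> pd.DataFrame:
    """OLS of treatment effect sizes on flowering phenology across species.

    ``effect_sizes`` needs columns (species, axis, value); ``phenology``
    needs (species, start_month, end_month), already averaged over
    treatments. One simple linear model is fitted per axis and per
    predictor (flowering duration, mean start month); fewer than 3 species
    with both quantities is refused.
    """
    pheno = phenology.copy()
    pheno["duration"] = flowering_duration(
        pheno["start_month"], pheno["end_month"]
    )
    merged = effect_sizes.merge(pheno, on="species", how="inner")
    rows = []
    for axis in sorted(merged["axis"].unique()):
        sub = merged[merged["axis"] == axis].dropna(subset=["value"])
        for predictor in ("duration", "start_month"):
            pts = sub.dropna(subset=[predictor])
            if len(pts) < 3:
                raise ValueError(
                    f"need >= 3 species for the {axis} ~ {predictor} regression, "
                    f"got {len(pts)}"
                )
            X = sm.add_constant(pts[predictor].to_numpy(float))
            res = sm.OLS(pts["value"].to_numpy(float), X).fit()
            rows.append(
                dict(
                    axis=axis, predictor=predictor,
                    intercept=float(res.params[0]), slope=float(res.params[1]),
                    p_value=float(res.pvalues[1]), r_squared=float(res.rsquared),
                    n=int(len(pts)),
                )
            )
    return pd.DataFrame(rows)
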