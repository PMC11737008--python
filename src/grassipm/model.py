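"""Model/Results facade tying the census data to the fitted IPMs.

``PlantDemographyModel`` holds validated census tables for one species and
a fitting configuration; ``fit()`` returns a ``DemographyResults`` carrying
the per-stratum parameter sets, kernels and growth rates, with bootstrap,
permutation, sensitivity and LTRE analyses as methods, in the spirit of a
statsmodels model/results pair::

    model = PlantDemographyModel.from_truth(default_truth(seed=1))
    res = model.fit()
    print(res.summary())
    res.ltre("ambient_grazing", "ambient_mowing").process_contributions
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import census, perturbation, vital_rates as vr
from .census import flag_quasi_extinct
from .kernel import (
    DEFAULT_NBINS,
    IPMKernel,
    build_kernel,
    compute_lambda,
    size_bounds,
)
from .params import PARAM_NAMES, VitalRateParams

logger = logging.getLogger(__name__)


class PlantDemographyModel:
    """Size-structured demographic model for one species in a 2x2
    climate x management experiment.

    Parameters
    ----------
    individuals, subplots, seed_heads
        Census tables (see :mod:`grassipm.census`); validated and
        log-transformed on construction if not already.
    stratification
        ``"factorial"`` (default) fits joint regressions with full
        size x climate x management interactions and extracts one
        parameter set per treatment combination plus the four main-effect
        sets; ``"single"`` pools everything into one stratum.
    by_year
        Fit one model per annual transition instead of pooling years.
    n_bins, eviction
        Kernel discretisation settings.
    bounds
        Optional (L, U) integration limits on the log-size scale; default
        is the observed range padded by ``pad_factor`` growth SDs, shared
        across strata so lambdas are comparable.
    """

    def __init__(
        self,
        individuals: pd.DataFrame,
        subplots: pd.DataFrame,
        seed_heads: pd.DataFrame | None = None,
        stratification: str = "factorial",
        aggregation: str = "per_subplot",
        by_year: bool = False,
        n_bins: int = DEFAULT_NBINS,
        eviction: str = "renorm",
        bounds: tuple[float, float] | None = None,
        pad_factor: float = 0.5,
        apply_quasi_extinction: bool = True,
        plot_random_effect: bool = False,
    ):
        if "z" not in individuals.columns:
            individuals = census.validate_individuals(individuals)
        if "seedlings_total" not in subplots.columns:
            subplots = census.validate_subplots(subplots)
        self.individuals = individuals
        self.subplots = subplots
        self.seed_heads = seed_heads
        self.stratification = stratification
        self.aggregation = aggregation
        self.by_year = by_year
        self.n_bins = n_bins
        self.eviction = eviction
        self.bounds = bounds
        self.pad_factor = pad_factor
        self.apply_quasi_extinction = apply_quasi_extinction
        self.plot_random_effect = plot_random_effect
        species = individuals["species"].unique()
        if len(species) > 1:
            raise ValueError(
                f"one model per species; got {list(species)} (filter first)"
            )
        self.species = str(species[0]) if len(species) else ""

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_csv(cls, individuals_path, subplots_path, seed_heads_path=None, **kw):
        ind, sub, heads = census.read_census(
            individuals_path, subplots_path, seed_heads_path
        )
        return cls(ind, sub, heads, **kw)

    @classmethod
    def from_truth(cls, truth, **kw):
        """Build a model on a synthetic census generated from ground truth."""
        from .synthetic import generate_census

        ind, sub, heads = generate_census(truth)
        return cls(census.validate_individuals(ind), sub, heads, **kw)

    # -- fitting -----------------------------------------------------------
    def _fit_once(self, individuals, subplots, eta_individuals=None):
        params = vr.fit_all(
            individuals,
            subplots,
            self.seed_heads,
            eta_individuals=eta_individuals,
            stratification=self.stratification,
            aggregation=self.aggregation,
            species=self.species,
            main_effects=True,
            plot_random_effect=self.plot_random_effect,
        )
        return params

    def fit(self) -> "DemographyResults":
        """Fit all vital rates, build the kernels and compute lambda per
        stratum."""
        quasi = flag_quasi_extinct(self.individuals)
        extinct = {q.stratum for q in quasi if q.extinct}
        ind = self.individuals
        sub = self.subplots
        if self.apply_quasi_extinction and extinct:
            logger.warning(
                "quasi-extinct strata excluded from fitting: %s", sorted(extinct)
            )
            keep = ~(
                (ind["climate"].astype(str) + "_" + ind["management"].astype(str)).isin(extinct)
            )
            ind = ind[keep]
            keep_s = ~(
                (sub["climate"].astype(str) + "_" + sub["management"].astype(str)).isin(extinct)
            )
            sub = sub[keep_s]

        if self.bounds is not None:
            bounds = self.bounds
        else:
            surv = ind[ind["survived"]]
            if len(surv) >= 3:
                z = surv["z"].to_numpy(float)
                X = np.column_stack([np.ones_like(z), z])
                _, _, grow_sd = vr.linear_fit(surv["z1"].to_numpy(float), X)
            else:
                grow_sd = float(ind["z"].std() or 1.0)
            bounds = size_bounds(ind["z"].to_numpy(), grow_sd, self.pad_factor)

        if self.by_year:
            params: dict[str, VitalRateParams] = {}
            for year in sorted(ind["year"].unique()):
                iy = ind[ind["year"] == year]
                sy = sub[sub["year"] == year]
                # recruits of this transition are first recorded next spring
                eta = ind[(ind["year"] == year + 1) & ind["is_new"]]
                try:
                    fitted = self._fit_once(iy, sy, eta_individuals=eta)
                except vr.FitError as exc:
                    logger.warning("transition %s skipped: %s", year, exc)
                    continue
                for stratum, p in fitted.items():
                    params[f"{year}/{stratum}"] = p
        else:
            params = self._fit_once(ind, sub)

        return DemographyResults(
            model=self,
            params=params,
            bounds=bounds,
            quasi_extinction=quasi,
            fit_individuals=ind,
            fit_subplots=sub,
        )


@dataclass
class DemographyResults:
    """Fitted vital rates, kernels and growth rates for every stratum."""

    model: PlantDemographyModel
    params: dict[str, VitalRateParams]
    bounds: tuple[float, float]
    quasi_extinction: list
    fit_individuals: pd.DataFrame
    fit_subplots: pd.DataFrame
    _kernels: dict[str, IPMKernel] = field(default_factory=dict)

    @property
    def strata(self) -> list[str]:
        return list(self.params)

    def kernel(self, stratum: str) -> IPMKernel:
        if stratum not in self._kernels:
            self._kernels[stratum] = build_kernel(
                self.params[stratum],
                *self.bounds,
                n_bins=self.model.n_bins,
                eviction=self.model.eviction,
            )
        return self._kernels[stratum]

    def lambda_(self, stratum: str) -> float:
        return compute_lambda(self.kernel(stratum), cross_check=False)[0]

    @property
    def lambdas(self) -> dict[str, float]:
        return {s: self.lambda_(s) for s in self.strata}

    @property
    def log_lambdas(self) -> dict[str, float]:
        return {s: float(np.log(v)) for s, v in self.lambdas.items()}

    def params_frame(self) -> pd.DataFrame:
        """Tidy per-stratum parameter table with standard errors and n."""
        rows = []
        for stratum, p in self.params.items():
            for name in PARAM_NAMES:
                rows.append(
                    dict(
                        species=p.species, stratum=stratum, parameter=name,
                        estimate=float(getattr(p, name)),
                        se=float(p.se.get(name, np.nan)),
                    )
                )
        return pd.DataFrame(rows)

    def lambda_table(self) -> pd.DataFrame:
        rows = [
            dict(stratum=s, lam=self.lambda_(s), log_lam=float(np.log(self.lambda_(s))))
            for s in self.strata
        ]
        return pd.DataFrame(rows)

    # -- inference ---------------------------------------------------------
    def bootstrap_lambda(self, stratum: str, n_boot: int = perturbation.DEFAULT_N_BOOT,
                         seed: int = 0):
        """Bootstrap distribution of lambda for one stratum (resampling
        individuals and subplot-years with replacement)."""
        return perturbation.bootstrap_lambda(
            self.fit_individuals, self.fit_subplots, self.model.seed_heads,
            stratum, n_boot=n_boot, seed=seed,
            lower=self.bounds[0], upper=self.bounds[1],
            n_bins=self.model.n_bins, eviction=self.model.eviction,
        )

    def permutation_test(self, factor: str, within: dict | None = None,
                         n_perm: int = perturbation.DEFAULT_N_PERM, seed: int = 0):
        """Plot-level permutation test for a treatment difference in lambda."""
        return perturbation.permutation_test(
            self.fit_individuals, self.fit_subplots, self.model.seed_heads,
            factor, within=within, n_perm=n_perm, seed=seed,
            lower=self.bounds[0], upper=self.bounds[1],
            n_bins=self.model.n_bins, eviction=self.model.eviction,
        )

    def sensitivity(self, stratum: str, step: float = perturbation.DEFAULT_SENS_STEP,
                    method: str = "forward") -> dict[str, float]:
        """Finite-difference sensitivities of lambda to all 14 parameters."""
        return perturbation.sensitivity(
            self.params[stratum], *self.bounds, n_bins=self.model.n_bins,
            step=step, method=method, eviction=self.model.eviction,
        )

    def ltre(self, stratum_a: str, stratum_b: str, reference: str = "midpoint"):
        """LTRE decomposition of lambda(A) - lambda(B)."""
        return perturbation.ltre(
            self.params[stratum_a], self.params[stratum_b], *self.bounds,
            n_bins=self.model.n_bins, reference=reference,
            eviction=self.model.eviction,
        )

    def effect_sizes(self):
        """Management (grazing - mowing) and climate (ambient - future)
        effect sizes on lambda from the main-effect strata."""
        lams = {
            s: self.lambda_(s)
            for s in ("grazing", "mowing", "ambient", "future")
            if s in self.params
        }
        return perturbation.effect_size(lams, species=self.model.species)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary: lambdas per stratum, then the 14
        parameters (with SEs where defined)."""
        buf = io.StringIO()
        buf.write(f"Plant demography IPM fit: species={self.model.species!r}\n")
        buf.write(
            f"log-size domain [{self.bounds[0]:.3f}, {self.bounds[1]:.3f}], "
            f"{self.model.n_bins} bins, eviction={self.model.eviction!r}\n"
        )
        extinct = [q for q in self.quasi_extinction if q.extinct]
        if extinct:
            buf.write(
                "quasi-extinct strata: "
                + ", ".join(f"{q.stratum} (n={q.n_total}, flowering={q.n_flowering})"
                            for q in extinct)
                + "\n"
            )
        buf.write("\nstratum                    lambda    log lambda\n")
        for s in self.strata:
            lam = self.lambda_(s)
            buf.write(f"{s:<25s} {lam:8.4f} {np.log(lam):12.4f}\n")
        buf.write("\nparameter          " + "".join(f"{s[:12]:>14s}" for s in self.strata) + "\n")
        for name in PARAM_NAMES:
            buf.write(f"{name:<18s}")
            for s in self.strata:
                buf.write(f"{getattr(self.params[s], name):14.4f}")
            buf.write("\n")
        return buf.getvalue()

    def __repr__(self) -> str:
        return (
            f"<DemographyResults species={self.model.species!r} "
            f"strata={self.strata}>"
        )
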