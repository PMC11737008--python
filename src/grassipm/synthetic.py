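"""Synthetic census generator with known ground truth.

Emulates the sampling design of a 2x2 factorial climate x land-management
grassland experiment: climate in {ambient, future} crossed with management
in {grazing, mowing}, five replicate plots per combination, subplots nested
in plots, and annual April-to-April censuses plus one autumn seedling count.

Individuals carry size-dependent Bernoulli survival, Gaussian growth on the
log-size scale, Bernoulli flowering and Poisson expected seed output;
subplots convert their seed totals into fall and spring seedlings and those
seedlings into next spring's new plants, whose log sizes are drawn from a
Gaussian recruit-size distribution. Each generated dataset stores the full
parameter set that produced it, so every downstream estimator can be tested
against a known answer without any field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit as _expit

from .params import VitalRateParams

CLIMATES = ("ambient", "future")
MANAGEMENTS = ("grazing", "mowing")
COMBINATIONS = tuple(f"{c}_{m}" for c in CLIMATES for m in MANAGEMENTS)


@dataclass
class GroundTruth:
    """Design plus the generating vital-rate parameters, one set per
    treatment combination."""

    params: dict[str, VitalRateParams]
    n_individuals: dict[str, int]
    n_plots: int = 5
    n_subplots: int = 8
    n_years: int = 4                      # annual transitions simulated
    start_year: int = 2018
    init_size_mean: float = 1.0           # log-size scale
    init_size_sd: float = 1.0
    seeds_per_head_mean: float = 15.0
    seeds_per_head_dispersion: float = 40.0   # NB size; CV ~ 0.3 per head
    heads_sampled_per_plot_year: int = 4      # 2 heads at each of 2 visits
    species: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        missing = [c for c in COMBINATIONS if c not in self.params]
        if missing:
            raise ValueError(f"missing treatment combinations: {missing}")
        for combo, p in self.params.items():
            p.validate()
            if self.n_individuals.get(combo, 0) < 1:
                raise ValueError(f"need >= 1 individual for combination {combo!r}")
        if self.n_plots < 1 or self.n_subplots < 1 or self.n_years < 1:
            raise ValueError("n_plots, n_subplots and n_years must all be >= 1")
        if self.init_size_sd <= 0:
            raise ValueError("init_size_sd must be > 0")
        if self.seeds_per_head_mean <= 0 or self.seeds_per_head_dispersion <= 0:
            raise ValueError("seeds-per-head mean and dispersion must be > 0")

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "design": {
                "n_individuals": dict(self.n_individuals),
                "n_plots": self.n_plots,
                "n_subplots": self.n_subplots,
                "n_years": self.n_years,
                "start_year": self.start_year,
                "species": self.species,
                "seed": self.seed,
            },
            "initial_size": {"mean": self.init_size_mean, "sd": self.init_size_sd},
            "seeds_per_head": {
                "mean": self.seeds_per_head_mean,
                "dispersion": self.seeds_per_head_dispersion,
                "sampled_per_plot_year": self.heads_sampled_per_plot_year,
            },
            "params": {c: p.to_dict() for c, p in self.params.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        d = doc["design"]
        return cls(
            params={
                c: VitalRateParams(**vals, stratum=c, species=d["species"])
                for c, vals in doc["params"].items()
            },
            n_individuals={k: int(v) for k, v in d["n_individuals"].items()},
            n_plots=int(d["n_plots"]),
            n_subplots=int(d["n_subplots"]),
            n_years=int(d["n_years"]),
            start_year=int(d["start_year"]),
            init_size_mean=float(doc["initial_size"]["mean"]),
            init_size_sd=float(doc["initial_size"]["sd"]),
            seeds_per_head_mean=float(doc["seeds_per_head"]["mean"]),
            seeds_per_head_dispersion=float(doc["seeds_per_head"]["dispersion"]),
            heads_sampled_per_plot_year=int(doc["seeds_per_head"]["sampled_per_plot_year"]),
            species=d["species"],
            seed=int(d["seed"]),
        )


#: Vital-rate truth used by :func:`default_truth`. Chosen once to mimic a
#: perennial with strong size dependence of every rate and a slightly
#: growing population (log lambda modestly above zero).
DEFAULT_PARAM_VALUES: dict[str, float] = {
    "surv_int": 0.2,
    "surv_slope": 0.7,
    "grow_int": 0.4,
    "grow_slope": 0.8,
    "grow_sd": 0.6,
    "repr_int": -2.0,
    "repr_slope": 1.0,
    "seed_int": 2.0,
    "seed_slope": 0.5,
    "recruit_fall": 0.03,
    "recruit_spring": 0.015,
    "establishment": 0.3,
    "recruit_size_mean": -0.5,
    "recruit_size_sd": 0.4,
}

#: Default initial cohort per combination, patterned on the pooled sample
#: sizes of the most abundant study species (a perennial grass).
DEFAULT_N_INDIVIDUALS: dict[str, int] = {
    "ambient_grazing": 1141,
    "ambient_mowing": 1079,
    "future_grazing": 1075,
    "future_mowing": 1353,
}


def default_truth(
    seed: int = 0,
    n_individuals: dict[str, int] | int | None = None,
    param_overrides: dict[str, dict[str, float]] | None = None,
    **design_kwargs,
) -> GroundTruth:
    """Ground truth under the default study conditions.

    ``param_overrides`` maps combination name -> {parameter: value} and is
    applied on top of the shared defaults, letting tests create treatment
    effects of known size.
    """
    if n_individuals is None:
        n_ind = dict(DEFAULT_N_INDIVIDUALS)
    elif isinstance(n_individuals, int):
        n_ind = {c: n_individuals for c in COMBINATIONS}
    else:
        n_ind = dict(n_individuals)
    params = {}
    for combo in COMBINATIONS:
        vals = dict(DEFAULT_PARAM_VALUES)
        if param_overrides and combo in param_overrides:
            vals.update(param_overrides[combo])
        params[combo] = VitalRateParams(**vals, stratum=combo, species="synthetic")
    return GroundTruth(params=params, n_individuals=n_ind, seed=seed, **design_kwargs)


def _nbinom_args(mean: float, dispersion: float) -> tuple[float, float]:
    # numpy's (n, p) parameterisation from mean and size/dispersion k:
    # var = mean + mean^2 / k
    n = dispersion
    p = dispersion / (dispersion + mean)
    return n, p


def _draw_recruits(rng: np.random.Generator, total_seeds: np.ndarray, rate: float) -> np.ndarray:
    """Seedlings per subplot: binomial thinning when the per-seed rate is a
    probability, Poisson when an observed ratio exceeds one."""
    n = np.round(total_seeds).astype(int)
    if rate <= 1.0:
        return rng.binomial(n, rate)
    return rng.poisson(rate * n)


def generate_census(truth: GroundTruth):
    """Simulate the full census.

    Returns
    -------
    individuals : pandas.DataFrame
        One row per individual per annual transition (its fate from April
        year t to April year t+1), including raw and log sizes, survival,
        flowering status, seed-head count and total seed output.
    subplots : pandas.DataFrame
        One row per subplot per transition: total seeds, fall and spring
        seedling counts, their sum, and the number of new plants next spring.
    seed_heads : pandas.DataFrame
        Lab-style seeds-per-head samples, a few heads per plot.

    The simulation is deterministic given ``truth.seed``; independent
    substreams are spawned per table and per year so the draws do not
    interleave across treatment combinations.
    """
    truth.validate()
    root = np.random.SeedSequence(truth.seed)
    ss_by_combo = {c: s for c, s in zip(COMBINATIONS, root.spawn(len(COMBINATIONS)))}
    ss_heads = root.spawn(1)[0]

    ind_rows: list[pd.DataFrame] = []
    sub_rows: list[dict] = []

    for combo in COMBINATIONS:
        climate, management = combo.split("_")
        p = truth.params[combo]
        rng = np.random.default_rng(ss_by_combo[combo])
        n0 = truth.n_individuals[combo]

        prefix = climate[0] + management[0]  # ag, am, fg, fm
        plot_ids = [f"{prefix}-p{i + 1}" for i in range(truth.n_plots)]
        # cohort spread over plots and subplots as evenly as the counts allow
        plot_idx = rng.integers(0, truth.n_plots, size=n0)
        sub_idx = rng.integers(0, truth.n_subplots, size=n0)

        z = rng.normal(truth.init_size_mean, truth.init_size_sd, size=n0)
        plot = np.array([plot_ids[i] for i in plot_idx])
        subplot = np.array([f"{plot[i]}-s{sub_idx[i] + 1}" for i in range(n0)])
        is_new = np.zeros(n0, dtype=bool)
        next_id = n0
        ids = np.array([f"{combo}-{i}" for i in range(n0)])

        per_head_mu = truth.seeds_per_head_mean

        for year_off in range(truth.n_years):
            year = truth.start_year + year_off
            n = z.size
            if n == 0:
                # population locally extinct: still record empty subplot census
                for pl in plot_ids:
                    for s in range(truth.n_subplots):
                        sub_rows.append(
                            dict(
                                species=truth.species, year=year, plot=pl,
                                subplot=f"{pl}-s{s + 1}", climate=climate,
                                management=management, total_seeds=0.0,
                                fall_seedlings=0, spring_seedlings=0,
                                new_plants=0,
                            )
                        )
                break

            survived = rng.random(n) < _expit(p.surv_int + p.surv_slope * z)
            z1 = np.full(n, np.nan)
            z1[survived] = rng.normal(
                p.grow_int + p.grow_slope * z[survived], p.grow_sd
            )
            flowering = rng.random(n) < _expit(p.repr_int + p.repr_slope * z)
            mu_seeds = np.exp(p.seed_int + p.seed_slope * z)
            heads = np.zeros(n, dtype=int)
            # head count tracks the expected seed load: stochastic rounding
            # of mu/m keeps E[heads] = mu/m (hence E[total seeds] = mu)
            # while leaving most seed-count variation to the per-head draws
            expected_heads = mu_seeds[flowering] / per_head_mu
            base = np.floor(expected_heads)
            heads[flowering] = (
                base + (rng.random(base.size) < expected_heads - base)
            ).astype(int)
            nb_n, nb_p = _nbinom_args(per_head_mu, truth.seeds_per_head_dispersion)
            seeds_total = np.zeros(n)
            has_heads = heads > 0
            if has_heads.any():
                # total over h iid NB(k, p) heads is NB(k*h, p)
                seeds_total[has_heads] = rng.negative_binomial(
                    nb_n * heads[has_heads], nb_p
                ).astype(float)

            ind_rows.append(
                pd.DataFrame(
                    {
                        "individual_id": ids,
                        "species": truth.species,
                        "year": year,
                        "plot": plot,
                        "subplot": subplot,
                        "climate": climate,
                        "management": management,
                        "size_t0": np.exp(z),
                        "survived": survived,
                        "size_t1": np.where(survived, np.exp(z1), np.nan),
                        "reproductive": flowering,
                        "seed_heads": heads,
                        "seeds_total": seeds_total,
                        "is_new": is_new,
                    }
                )
            )

            # subplot-level seed rain -> seedlings -> next year's new plants
            sub_frame = pd.DataFrame(
                {"plot": plot, "subplot": subplot, "seeds": seeds_total}
            )
            seed_sums = sub_frame.groupby(["plot", "subplot"])["seeds"].sum().to_dict()

            new_z, new_plot, new_sub = [], [], []
            for pl in plot_ids:
                for s in range(truth.n_subplots):
                    sub = f"{pl}-s{s + 1}"
                    s_j = float(seed_sums.get((pl, sub), 0.0))
                    rf = int(_draw_recruits(rng, np.array([s_j]), p.recruit_fall)[0])
                    rs = int(_draw_recruits(rng, np.array([s_j]), p.recruit_spring)[0])
                    rsum = rf + rs
                    estab = min(p.establishment, 1.0)
                    ni = int(rng.binomial(rsum, estab)) if rsum > 0 else 0
                    sub_rows.append(
                        dict(
                            species=truth.species, year=year, plot=pl, subplot=sub,
                            climate=climate, management=management,
                            total_seeds=s_j, fall_seedlings=rf,
                            spring_seedlings=rs, new_plants=ni,
                        )
                    )
                    if ni > 0 and year_off + 1 < truth.n_years:
                        new_z.extend(
                            rng.normal(p.recruit_size_mean, p.recruit_size_sd, size=ni)
                        )
                        new_plot.extend([pl] * ni)
                        new_sub.extend([sub] * ni)

            # assemble next April's census: survivors plus new recruits
            keep = survived
            z_next = z1[keep]
            plot_next = plot[keep]
            sub_next = subplot[keep]
            ids_next = ids[keep]
            n_new = len(new_z)
            new_ids = np.array([f"{combo}-{next_id + i}" for i in range(n_new)])
            next_id += n_new
            z = np.concatenate([z_next, np.array(new_z, dtype=float)])
            plot = np.concatenate([plot_next, np.array(new_plot, dtype=object)])
            subplot = np.concatenate([sub_next, np.array(new_sub, dtype=object)])
            ids = np.concatenate([ids_next, new_ids])
            is_new = np.concatenate(
                [np.zeros(keep.sum(), dtype=bool), np.ones(n_new, dtype=bool)]
            )

    individuals = pd.concat(ind_rows, ignore_index=True)

    subplots = pd.DataFrame(sub_rows)
    subplots["seedlings_total"] = (
        subplots["fall_seedlings"] + subplots["spring_seedlings"]
    )

    # lab seeds-per-head samples: a couple of heads per plot per transition
    # year, pooled into one flat table (the table has no year dimension)
    rng_h = np.random.default_rng(ss_heads)
    nb_n, nb_p = _nbinom_args(truth.seeds_per_head_mean, truth.seeds_per_head_dispersion)
    n_samples = truth.heads_sampled_per_plot_year * truth.n_years
    head_rows = []
    for combo in COMBINATIONS:
        climate, management = combo.split("_")
        for i in range(truth.n_plots):
            pl = f"{climate[0]}{management[0]}-p{i + 1}"
            counts = rng_h.negative_binomial(nb_n, nb_p, size=n_samples)
            for j, c in enumerate(counts):
                head_rows.append(
                    dict(
                        species=truth.species, plot=pl, head_id=f"{pl}-h{j + 1}",
                        seed_count=int(c),
                    )
                )
    seed_heads = pd.DataFrame(head_rows)

    return individuals, subplots, seed_heads
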