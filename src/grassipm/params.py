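"""The 14-parameter vital-rate set that defines one integral projection model.

A stratum (a treatment combination, a main-effect level, or a single pooled
population) is fully described by 14 numbers: a logistic survival regression
(intercept, slope on log size), a Gaussian growth regression (intercept,
slope, residual SD), a logistic reproduction-probability regression
(intercept, slope), a log-link Poisson seed-count regression (intercept,
slope), mean fall and spring per-seed recruitment rates, a seedling
establishment probability, and the mean and SD of the log-size distribution
at which recruits enter the continuous class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical ordering of the 14 IPM parameters.
PARAM_NAMES: tuple[str, ...] = (
    "surv_int",
    "surv_slope",
    "grow_int",
    "grow_slope",
    "grow_sd",
    "repr_int",
    "repr_slope",
    "seed_int",
    "seed_slope",
    "recruit_fall",
    "recruit_spring",
    "establishment",
    "recruit_size_mean",
    "recruit_size_sd",
)

#: Demographic process each parameter belongs to, used to group LTRE
#: contributions into the five classic stages.
PARAM_PROCESS: dict[str, str] = {
    "surv_int": "survival",
    "surv_slope": "survival",
    "grow_int": "growth",
    "grow_slope": "growth",
    "grow_sd": "growth",
    "repr_int": "reproduction",
    "repr_slope": "reproduction",
    "seed_int": "reproduction",
    "seed_slope": "reproduction",
    "recruit_fall": "recruitment",
    "recruit_spring": "recruitment",
    "establishment": "establishment",
    "recruit_size_mean": "establishment",
    "recruit_size_sd": "establishment",
}

PROCESSES: tuple[str, ...] = (
    "survival",
    "growth",
    "reproduction",
    "recruitment",
    "establishment",
)

#: Parameters that must stay strictly positive (SDs) or nonnegative (rates).
_POSITIVE = ("grow_sd", "recruit_size_sd")
_NONNEGATIVE = ("recruit_fall", "recruit_spring", "establishment")


@dataclass
class VitalRateParams:
    """Complete parameter set for one IPM stratum.

    Regression parameters are on the link scale: logit for survival and
    reproduction probability, natural log for seed counts. Sizes are natural
    log of the raw field measurement (cm^2 basal area or leaf count).
    """

    surv_int: float
    surv_slope: float
    grow_int: float
    grow_slope: float
    grow_sd: float
    repr_int: float
    repr_slope: float
    seed_int: float
    seed_slope: float
    recruit_fall: float
    recruit_spring: float
    establishment: float
    recruit_size_mean: float
    recruit_size_sd: float
    species: str = ""
    stratum: str = ""
    se: dict[str, float] = field(default_factory=dict)
    n_obs: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {name!r} is not finite: {v}")
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be > 0")
        for name in _NONNEGATIVE:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be >= 0")

    def to_array(self) -> np.ndarray:
        """Parameters as a length-14 vector in canonical order."""
        return np.array([getattr(self, k) for k in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values, **labels) -> "VitalRateParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(
                f"expected {len(PARAM_NAMES)} parameters, got shape {values.shape}"
            )
        return cls(**dict(zip(PARAM_NAMES, values)), **labels)

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in PARAM_NAMES}

    def perturbed(self, name: str, step: float) -> "VitalRateParams":
        """Copy with one parameter shifted by ``step`` (used by sensitivities)."""
        if name not in PARAM_NAMES:
            raise KeyError(name)
        return replace(self, **{name: getattr(self, name) + step})


def mean_params(a: VitalRateParams, b: VitalRateParams, stratum: str = "") -> VitalRateParams:
    """Elementwise arithmetic mean of two parameter sets.

    This is the rule used to form main-effect parameter sets: e.g. the
    ambient-climate survival intercept is the mean of the ambient-grazing and
    ambient-mowing intercepts, and likewise for all 14 parameters.
    """
    out = VitalRateParams.from_array(
        (a.to_array() + b.to_array()) / 2.0,
        species=a.species,
        stratum=stratum,
    )
    out.n_obs = {
        k: a.n_obs.get(k, 0) + b.n_obs.get(k, 0)
        for k in set(a.n_obs) | set(b.n_obs)
    }
    return out
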