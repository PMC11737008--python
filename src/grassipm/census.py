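"""Census table schemas, CSV I/O, validation and the quasi-extinction filter.

Three flat tables drive the whole pipeline:

``individuals``
    one row per individual per annual (April-to-April) transition — raw size
    at t0, survival to t1, raw size at t1, flowering status at t0, seed-head
    count, and whether the plant was first recorded at t0;
``subplots``
    one row per 50x50 cm subplot per transition — total seeds produced,
    fall and spring seedling counts and next spring's new plants;
``seed_heads``
    seeds-per-head lab samples, a few heads per plot.

Log sizes (natural log of the raw measurement) are computed once at ingest;
every model downstream operates on the log scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLIMATES = ("ambient", "future")
MANAGEMENTS = ("grazing", "mowing")

INDIVIDUAL_COLUMNS = [
    "individual_id", "species", "year", "plot", "subplot", "climate",
    "management", "size_t0", "survived", "size_t1", "reproductive",
    "seed_heads", "seeds_total", "is_new",
]
SUBPLOT_COLUMNS = [
    "species", "year", "plot", "subplot", "climate", "management",
    "total_seeds", "fall_seedlings", "spring_seedlings", "seedlings_total",
    "new_plants",
]
SEED_HEAD_COLUMNS = ["species", "plot", "head_id", "seed_count"]

#: Quasi-extinction thresholds: a stratum is dropped when it has fewer than
#: 25 individuals total AND fewer than 10 flowering individuals.
QE_MIN_TOTAL = 25
QE_MIN_FLOWERING = 10


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """Rows violate the census invariants; the message lists row numbers."""


@dataclass
class QuasiExtinctionStatus:
    species: str
    stratum: str
    n_total: int
    n_flowering: int

    @property
    def extinct(self) -> bool:
        return self.n_total < QE_MIN_TOTAL and self.n_flowering < QE_MIN_FLOWERING


def _require_columns(df: pd.DataFrame, columns, table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing column(s): {missing}")


def _bad_rows(mask: pd.Series) -> str:
    rows = list(np.flatnonzero(np.asarray(mask)))
    shown = ", ".join(str(r) for r in rows[:20])
    more = "" if len(rows) <= 20 else f" (+{len(rows) - 20} more)"
    return shown + more


def validate_individuals(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and annotate the individuals table.

    Adds log-size columns ``z`` (= ln size_t0) and ``z1`` (= ln size_t1,
    NaN for non-survivors). Raises :class:`ValidationError` naming the
    offending 0-based row numbers on any invariant violation.
    """
    _require_columns(df, INDIVIDUAL_COLUMNS, "individuals")
    df = df.copy()
    for col in ("survived", "reproductive", "is_new"):
        df[col] = df[col].astype(bool)
    df["year"] = df["year"].astype(int)
    df["seed_heads"] = df["seed_heads"].astype(int)

    problems = []
    nonpos = ~(df["size_t0"] > 0)
    if nonpos.any():
        problems.append(f"size_t0 <= 0 or missing at rows: {_bad_rows(nonpos)}")
    bad_t1 = df["survived"] & ~(df["size_t1"] > 0)
    if bad_t1.any():
        problems.append(f"survivors without positive size_t1 at rows: {_bad_rows(bad_t1)}")
    bad_heads = (~df["reproductive"]) & (df["seed_heads"] > 0)
    if bad_heads.any():
        problems.append(
            f"seed heads on non-reproductive plants at rows: {_bad_rows(bad_heads)}"
        )
    neg_heads = df["seed_heads"] < 0
    if neg_heads.any():
        problems.append(f"negative seed-head counts at rows: {_bad_rows(neg_heads)}")
    bad_climate = ~df["climate"].isin(CLIMATES)
    if bad_climate.any():
        problems.append(f"unknown climate labels at rows: {_bad_rows(bad_climate)}")
    bad_mgmt = ~df["management"].isin(MANAGEMENTS)
    if bad_mgmt.any():
        problems.append(f"unknown management labels at rows: {_bad_rows(bad_mgmt)}")
    if problems:
        raise ValidationError("individuals table invalid: " + "; ".join(problems))

    df["z"] = np.log(df["size_t0"].to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        df["z1"] = np.log(df["size_t1"].to_numpy(dtype=float))
    df.loc[~df["survived"], "z1"] = np.nan
    return df


def validate_subplots(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, [c for c in SUBPLOT_COLUMNS if c != "seedlings_total"], "subplots")
    df = df.copy()
    if "seedlings_total" not in df.columns:
        df["seedlings_total"] = df["fall_seedlings"] + df["spring_seedlings"]
    problems = []
    for col in ("total_seeds", "fall_seedlings", "spring_seedlings", "new_plants"):
        neg = df[col] < 0
        if neg.any():
            problems.append(f"negative {col} at rows: {_bad_rows(neg)}")
    bad_sum = df["seedlings_total"] != df["fall_seedlings"] + df["spring_seedlings"]
    if bad_sum.any():
        problems.append(f"seedlings_total inconsistent at rows: {_bad_rows(bad_sum)}")
    if problems:
        raise ValidationError("subplots table invalid: " + "; ".join(problems))
    df["year"] = df["year"].astype(int)
    extra = [c for c in df.columns if c not in SUBPLOT_COLUMNS]
    return df[SUBPLOT_COLUMNS + extra]


def validate_seed_heads(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, SEED_HEAD_COLUMNS, "seed_heads")
    df = df.copy()
    neg = df["seed_count"] < 0
    if neg.any():
        raise ValidationError(
            f"seed_heads table invalid: negative counts at rows: {_bad_rows(neg)}"
        )
    return df


def read_census(individuals_path, subplots_path, seed_heads_path=None):
    """Read and validate the three census CSVs.

    Returns ``(individuals, subplots, seed_heads)`` with log sizes added;
    ``seed_heads`` is ``None`` when no path is given (the seed model then
    falls back to a species-wide mean supplied by the caller).
    """
    individuals = validate_individuals(pd.read_csv(individuals_path))
    subplots = validate_subplots(pd.read_csv(subplots_path))
    heads = None
    if seed_heads_path is not None:
        heads = validate_seed_heads(pd.read_csv(seed_heads_path))
    logger.info(
        "census read: %d individual-transitions, %d subplot-years",
        len(individuals), len(subplots),
    )
    return individuals, subplots, heads


def write_census(individuals, subplots, seed_heads, out_dir):
    """Write the three tables as UTF-8, '.'-decimal CSVs into ``out_dir``.

    Returns the three file paths. Derived columns (log sizes) are dropped so
    a read-write-read cycle is the identity on the stored schema.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p_ind = out / "individuals.csv"
    p_sub = out / "subplots.csv"
    p_heads = out / "seed_heads.csv"
    individuals[INDIVIDUAL_COLUMNS].to_csv(p_ind, index=False)
    subplots[SUBPLOT_COLUMNS].to_csv(p_sub, index=False)
    seed_heads[SEED_HEAD_COLUMNS].to_csv(p_heads, index=False)
    return p_ind, p_sub, p_heads


def combination_counts(individuals: pd.DataFrame) -> pd.DataFrame:
    """Per species x treatment-combination row counts (pooled over years)."""
    out = (
        individuals.groupby(["species", "climate", "management"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    return out


def flag_quasi_extinct(
    individuals: pd.DataFrame, year: int | None = None
) -> list[QuasiExtinctionStatus]:
    """Apply the quasi-extinction rule per species x treatment combination.

    A stratum is quasi-extinct when it holds fewer than 25 individuals total
    and fewer than 10 flowering individuals in the census of ``year``
    (default: the latest year present). Both thresholds are strict, so
    exactly 25 individuals or exactly 10 flowering plants keeps the stratum.
    Strata absent from the census count as zero and are therefore extinct.
    """
    if year is None:
        year = int(individuals["year"].max())
    sub = individuals[individuals["year"] == year]
    statuses = []
    for species in sorted(individuals["species"].unique()):
        for climate in CLIMATES:
            for management in MANAGEMENTS:
                sel = sub[
                    (sub["species"] == species)
                    & (sub["climate"] == climate)
                    & (sub["management"] == management)
                ]
                statuses.append(
                    QuasiExtinctionStatus(
                        species=species,
                        stratum=f"{climate}_{management}",
                        n_total=int(len(sel)),
                        n_flowering=int(sel["reproductive"].sum()),
                    )
                )
    return statuses
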