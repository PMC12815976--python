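"""Virtual patient population generator.

Builds the covariate table that drives the population-PK simulation: age,
sex, body weight (sex- and age-dependent with Gaussian noise), baseline
serum albumin and baseline tumor size (both log-normal), and a binary
anti-drug-antibody (ADA) status.  All sampling is driven by a single master
seed; each covariate draws from its own independent substream so that
adding or removing one column never perturbs the others.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "PopulationValidationError",
    "PopulationParseError",
    "sample_weight",
    "sample_covariates",
    "generate_population",
    "write_population",
    "read_population",
    "POPULATION_COLUMNS",
]

POPULATION_COLUMNS = ["subject_id", "age", "sex", "weight", "albumin", "tumor_size", "ada"]

#: weights at or below this (kg) are treated as unphysical and the noise
#: draw is repeated; practically never triggered at the default noise SDs
MIN_WEIGHT_KG = 20.0


class PopulationValidationError(ValueError):
    """A PopulationSpec field violates its constraint; the message names the field."""


class PopulationParseError(ValueError):
    """A population table file could not be parsed."""


@dataclass(frozen=True)
class PopulationSpec:
    """Generative model of the virtual trial population.

    Defaults reproduce the study conditions: 1000 oncology subjects, ages
    uniform on [20, 80] years, even odds of male sex, weight linear in age
    with sex-specific intercept and noise, albumin log-normal with median
    42 g/L, tumor size log-normal with ln-scale location 4.2 (median
    ~66.7 mm), and 40% probability of anti-drug antibodies.
    """

    n_subjects: int = 1000
    age_min: float = 20.0
    age_max: float = 80.0
    p_male: float = 0.5
    weight_intercept_f: float = 65.0   # kg at the 40-year reference age
    weight_intercept_m: float = 85.0
    weight_age_slope: float = 0.75     # kg per year
    weight_sd_f: float = 3.5           # kg
    weight_sd_m: float = 10.0
    albumin_log_median: float = 42.0   # g/L, natural-scale median
    albumin_log_sd: float = 0.10       # ln-scale SD
    tumor_log_location: float = 4.2    # ln(mm)
    tumor_log_sd: float = 0.70         # ln-scale SD
    p_ada: float = 0.40
    seed: int = 20260928

    def __post_init__(self) -> None:
        if not (isinstance(self.n_subjects, (int, np.integer)) and self.n_subjects >= 1):
            raise PopulationValidationError(
                f"n_subjects must be a positive integer, got {self.n_subjects!r}")
        if not 0.0 <= self.p_male <= 1.0:
            raise PopulationValidationError(f"p_male must be in [0, 1], got {self.p_male}")
        if not 0.0 <= self.p_ada <= 1.0:
            raise PopulationValidationError(f"p_ada must be in [0, 1], got {self.p_ada}")
        if not self.age_min < self.age_max:
            raise PopulationValidationError(
                f"age_min must be < age_max, got age_min={self.age_min}, age_max={self.age_max}")
        for name in ("weight_sd_f", "weight_sd_m", "albumin_log_sd", "tumor_log_sd"):
            if getattr(self, name) < 0:
                raise PopulationValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.albumin_log_median <= 0:
            raise PopulationValidationError(
                f"albumin_log_median must be > 0, got {self.albumin_log_median}")

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PopulationValidationError(f"unknown PopulationSpec field(s): {sorted(unknown)}")
        return cls(**d)


def sample_weight(age, sex, noise, spec: PopulationSpec | None = None):
    """Body weight (kg) from the sex-specific linear-in-age model.

    weight = intercept(sex) + slope * (age - 40) + noise

    where the female/male intercepts are 65/85 kg and the slope 0.75 kg/yr
    by default.  ``noise`` is the realized Gaussian draw in kg, exposed as
    an argument so the formula itself is deterministic and testable.
    Accepts scalars or numpy arrays.
    """
    spec = spec or PopulationSpec()
    sex_arr = np.asarray(sex)
    valid = np.isin(sex_arr, ("male", "female"))
    if not np.all(valid):
        bad = np.unique(sex_arr[~valid]) if sex_arr.ndim else sex_arr
        raise ValueError(f"unknown sex category: {bad!r} (expected 'male' or 'female')")
    intercept = np.where(sex_arr == "male", spec.weight_intercept_m, spec.weight_intercept_f)
    out = intercept + spec.weight_age_slope * (np.asarray(age) - 40.0) + np.asarray(noise)
    if out.ndim == 0:
        return float(out)
    return out


def sample_covariates(rng: np.random.Generator, spec: PopulationSpec | None = None,
                      size: int | None = None):
    """Draw (albumin g/L, tumor size mm) from their log-normal models.

    albumin = exp(N(ln(median), albumin_log_sd));
    tumor   = exp(N(tumor_log_location, tumor_log_sd)).
    """
    spec = spec or PopulationSpec()
    n = 1 if size is None else size
    albumin = np.exp(rng.normal(np.log(spec.albumin_log_median), spec.albumin_log_sd, n))
    tumor = np.exp(rng.normal(spec.tumor_log_location, spec.tumor_log_sd, n))
    if size is None:
        return float(albumin[0]), float(tumor[0])
    return albumin, tumor


def generate_population(spec: PopulationSpec | None = None) -> pd.DataFrame:
    """Generate the virtual patient table; deterministic for a fixed seed.

    Returns a DataFrame with columns subject_id, age, sex, weight, albumin,
    tumor_size, ada (0/1).  One independent RNG substream per covariate.
    """
    spec = spec or PopulationSpec()
    n = int(spec.n_subjects)
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_age, rng_sex, rng_wt, rng_alb, rng_tum, rng_ada = (
        np.random.default_rng(s) for s in streams)

    age = rng_age.uniform(spec.age_min, spec.age_max, n)
    sex = np.where(rng_sex.random(n) < spec.p_male, "male", "female")
    sd = np.where(sex == "male", spec.weight_sd_m, spec.weight_sd_f)
    noise = rng_wt.normal(0.0, 1.0, n) * sd
    weight = sample_weight(age, sex, noise, spec)
    # unphysical-weight guard: redraw the noise for any subject at or below
    # the floor (never triggered at the default SDs)
    bad = weight <= MIN_WEIGHT_KG
    while np.any(bad):
        noise[bad] = rng_wt.normal(0.0, 1.0, int(bad.sum())) * sd[bad]
        weight = sample_weight(age, sex, noise, spec)
        bad = weight <= MIN_WEIGHT_KG
    albumin, tumor = sample_covariates_streams(rng_alb, rng_tum, spec, n)
    ada = (rng_ada.random(n) < spec.p_ada).astype(int)

    return pd.DataFrame({
        "subject_id": np.arange(1, n + 1),
        "age": age,
        "sex": sex,
        "weight": weight,
        "albumin": albumin,
        "tumor_size": tumor,
        "ada": ada,
    })


def sample_covariates_streams(rng_albumin: np.random.Generator,
                              rng_tumor: np.random.Generator,
                              spec: PopulationSpec, n: int):
    """As :func:`sample_covariates` but with one independent stream per column."""
    albumin = np.exp(rng_albumin.normal(np.log(spec.albumin_log_median), spec.albumin_log_sd, n))
    tumor = np.exp(rng_tumor.normal(spec.tumor_log_location, spec.tumor_log_sd, n))
    return albumin, tumor


def write_population(population: pd.DataFrame, path) -> None:
    """Write the population table as comma-delimited text with a header row."""
    missing = [c for c in POPULATION_COLUMNS if c not in population.columns]
    if missing:
        raise PopulationValidationError(f"population table missing column(s): {missing}")
    population[POPULATION_COLUMNS].to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    """Read a population table written by :func:`write_population`.

    Raises :class:`PopulationParseError` on an empty file, missing columns,
    or unparseable values (the message carries the offending line where
    pandas reports one).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise PopulationParseError(f"{path}: empty file, not a population table") from exc
    except (pd.errors.ParserError, OSError) as exc:
        raise PopulationParseError(f"{path}: {exc}") from exc
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise PopulationParseError(f"{path}: missing column(s) {missing}")
    df = df[POPULATION_COLUMNS]
    for col in ("age", "weight", "albumin", "tumor_size"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2  # +1 header, +1 one-based
            raise PopulationParseError(f"{path}: non-numeric value in column '{col}' at line {line}")
        if (vals <= 0).any() and col != "age":
            line = int((vals <= 0).idxmax()) + 2
            raise PopulationParseError(f"{path}: nonpositive {col} at line {line}")
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        line = int(bad_sex.idxmax()) + 2
        raise PopulationParseError(f"{path}: invalid sex value at line {line}")
    if not df["ada"].isin([0, 1]).all():
        raise PopulationParseError(f"{path}: ada column must be 0/1")
    df["ada"] = df["ada"].astype(int)
    df["subject_id"] = df["subject_id"].astype(int)
    return df
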