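"""Two-compartment PK parameterization with covariates and log-normal IIV.

The structural model is linear two-compartment disposition with IV input:
clearance CL (L/day), central volume V1 (L), inter-compartmental clearance
Q (L/day) and peripheral volume V2 (L).  Covariates scale the typical
values multiplicatively (power model for continuous covariates,
proportional shift for binary flags — the universal popPK convention);
inter-individual variability is multiplicative log-normal,
``param_i = typical * exp(eta)`` with ``eta ~ N(0, Omega)``.

Macro (hybrid) constants follow the textbook algebra: alpha and beta are
the roots of ``s^2 - (k10+k12+k21) s + k10*k21 = 0`` with alpha >= beta.
``q = 0`` degenerates cleanly to one compartment (beta = 0, alpha = k10).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ModelConfig",
    "StructuralParams",
    "CovariateEffect",
    "IIVSpec",
    "IndividualParams",
    "PARAM_NAMES",
    "apply_covariates",
    "apply_covariates_table",
    "apply_iiv",
    "draw_etas",
    "individual_params_table",
    "macro_constants",
]

PARAM_NAMES = ("cl", "v1", "q", "v2")


@dataclass(frozen=True)
class StructuralParams:
    """Typical-value disposition parameters (CL, Q in L/day; V1, V2 in L)."""

    cl: float
    v1: float
    q: float
    v2: float

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "v2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.q < 0:
            raise ValueError(f"q must be >= 0, got {self.q}")

    def as_dict(self) -> dict:
        return {p: getattr(self, p) for p in PARAM_NAMES}


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate effect on one disposition parameter.

    kind="power":        param *= (x / reference) ** value
    kind="proportional": param *= (1 + value)     when the binary flag is true
    """

    parameter: str
    covariate: str
    kind: str
    value: float
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"parameter must be one of {PARAM_NAMES}, got {self.parameter!r}")
        if self.kind not in ("power", "proportional"):
            raise ValueError(f"kind must be 'power' or 'proportional', got {self.kind!r}")
        if self.kind == "power":
            if self.reference is None or not self.reference > 0:
                raise ValueError(f"power effect on {self.parameter} requires reference > 0")
        else:
            if self.value <= -1:
                raise ValueError("proportional shift must be > -1")


@dataclass(frozen=True)
class IIVSpec:
    """Log-normal between-subject variability: ln-scale variances + correlation.

    ``omega_sq`` maps parameter name -> omega^2 (ln-scale variance);
    parameters not listed get zero variability.  ``correlation`` is a full
    matrix over PARAM_NAMES order (identity when omitted).
    """

    omega_sq: dict = field(default_factory=dict)
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, v in self.omega_sq.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter in omega_sq: {name!r}")
            if v < 0:
                raise ValueError(f"omega_sq[{name!r}] must be >= 0, got {v}")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            k = len(PARAM_NAMES)
            if corr.shape != (k, k):
                raise ValueError(f"correlation must be {k}x{k} over {PARAM_NAMES}")
            if not np.allclose(corr, corr.T):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(corr), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semidefinite")
            object.__setattr__(self, "correlation", corr)

    def covariance(self) -> np.ndarray:
        """Omega matrix over PARAM_NAMES order."""
        sd = np.sqrt([self.omega_sq.get(p, 0.0) for p in PARAM_NAMES])
        corr = self.correlation if self.correlation is not None else np.eye(len(PARAM_NAMES))
        return np.outer(sd, sd) * corr


@dataclass(frozen=True)
class IndividualParams:
    """Realized per-subject parameters with derived micro/macro constants.

    k10 = cl/v1, k12 = q/v1, k21 = q/v2 (1/day); alpha >= beta are the
    biexponential rates.  When q = 0 the model is one-compartment:
    k12 = k21 = 0, alpha = k10, beta = 0.
    """

    subject_id: int
    cl: float
    v1: float
    q: float
    v2: float
    k10: float = field(init=False)
    k12: float = field(init=False)
    k21: float = field(init=False)
    alpha: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        k10, k12, k21, alpha, beta = macro_constants(self.cl, self.v1, self.q, self.v2)
        object.__setattr__(self, "k10", float(k10))
        object.__setattr__(self, "k12", float(k12))
        object.__setattr__(self, "k21", float(k21))
        object.__setattr__(self, "alpha", float(alpha))
        object.__setattr__(self, "beta", float(beta))

    @property
    def one_compartment(self) -> bool:
        return self.q == 0.0


@dataclass(frozen=True)
class ModelConfig:
    """A complete PK model specification: typical values, covariate effects
    and between-subject variability."""

    structural: StructuralParams
    effects: tuple = ()
    iiv: IIVSpec = field(default_factory=IIVSpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))


def macro_constants(cl, v1, q, v2):
    """(k10, k12, k21, alpha, beta) from (cl, v1, q, v2); vectorized.

    beta is computed as prod/alpha to avoid catastrophic cancellation when
    k10*k21 << (k10+k12+k21)^2.
    """
    cl, v1, q, v2 = (np.asarray(x, dtype=float) for x in (cl, v1, q, v2))
    k10 = cl / v1
    with np.errstate(divide="ignore", invalid="ignore"):
        k12 = np.where(q > 0, q / v1, 0.0)
        k21 = np.where(q > 0, q / v2, 0.0)
    s = k10 + k12 + k21
    p = k10 * k21
    alpha = 0.5 * (s + np.sqrt(np.maximum(s * s - 4.0 * p, 0.0)))
    beta = np.where(alpha > 0, p / np.where(alpha > 0, alpha, 1.0), 0.0)
    if k10.ndim == 0:
        return float(k10), float(k12), float(k21), float(alpha), float(beta)
    return k10, k12, k21, alpha, beta


def _covariate_value(patient, name):
    """Resolve a covariate column from a patient row or table.

    ``female``/``male`` are derived from the ``sex`` column so that sex can
    be used as a binary flag in proportional effects.
    """
    if name == "female":
        return (np.asarray(patient["sex"]) == "female").astype(float)
    if name == "male":
        return (np.asarray(patient["sex"]) == "male").astype(float)
    try:
        return np.asarray(patient[name], dtype=float)
    except (KeyError, IndexError) as exc:
        raise KeyError(f"patient has no covariate {name!r}") from exc


def _effect_multipliers(effects, patient):
    """Per-parameter multiplicative covariate factors (arrays or scalars)."""
    mult = {p: 1.0 for p in PARAM_NAMES}
    for eff in effects:
        x = _covariate_value(patient, eff.covariate)
        if eff.kind == "power":
            if np.any(x <= 0):
                raise ValueError(
                    f"nonpositive covariate {eff.covariate!r} with a power effect on {eff.parameter}")
            mult[eff.parameter] = mult[eff.parameter] * (x / eff.reference) ** eff.value
        else:
            mult[eff.parameter] = mult[eff.parameter] * np.where(x != 0, 1.0 + eff.value, 1.0)
    return mult


def apply_covariates(structural: StructuralParams, effects, patient) -> StructuralParams:
    """Scale typical values by a single patient's covariates.

    Effects compose multiplicatively and are order-independent.  ``patient``
    is any mapping (e.g. a population-table row) exposing the covariate
    columns referenced by the effects.
    """
    mult = _effect_multipliers(effects, patient)
    return replace(structural, **{p: getattr(structural, p) * float(np.asarray(mult[p]))
                                  for p in PARAM_NAMES})


def apply_covariates_table(structural: StructuralParams, effects,
                           population: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`apply_covariates` over a population table.

    Returns a DataFrame with columns cl, v1, q, v2 (one row per subject).
    """
    mult = _effect_multipliers(effects, population)
    n = len(population)
    return pd.DataFrame(
        {p: getattr(structural, p) * np.broadcast_to(np.asarray(mult[p], dtype=float), n).copy()
         for p in PARAM_NAMES},
        index=population.index)


def draw_etas(iiv: IIVSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """n x 4 matrix of ln-scale random effects over PARAM_NAMES order."""
    cov = iiv.covariance()
    if not np.any(cov):
        return np.zeros((n, len(PARAM_NAMES)))
    return rng.multivariate_normal(np.zeros(len(PARAM_NAMES)), cov, size=n,
                                   method="cholesky" if _is_pd(cov) else "eigh")


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


def apply_iiv(typical: StructuralParams, iiv: IIVSpec, rng: np.random.Generator,
              subject_id: int = 0) -> IndividualParams:
    """One subject's realized parameters: typical * exp(eta)."""
    eta = draw_etas(iiv, rng, 1)[0]
    vals = {p: getattr(typical, p) * float(np.exp(e)) for p, e in zip(PARAM_NAMES, eta)}
    return IndividualParams(subject_id=subject_id, **vals)


def individual_params_table(structural: StructuralParams, effects, iiv: IIVSpec,
                            population: pd.DataFrame,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Covariate-scaled, IIV-perturbed parameters for a whole population.

    Returns one row per subject with cl, v1, q, v2 plus the derived
    k10, k12, k21, alpha, beta columns.
    """
    typ = apply_covariates_table(structural, effects, population)
    etas = draw_etas(iiv, rng, len(population))
    out = pd.DataFrame({"subject_id": np.asarray(population["subject_id"], dtype=int)},
                       index=population.index)
    for j, p in enumerate(PARAM_NAMES):
        out[p] = typ[p].to_numpy() * np.exp(etas[:, j])
    k10, k12, k21, alpha, beta = macro_constants(
        out["cl"].to_numpy(), out["v1"].to_numpy(), out["q"].to_numpy(), out["v2"].to_numpy())
    out["k10"], out["k12"], out["k21"], out["alpha"], out["beta"] = k10, k12, k21, alpha, beta
    return out
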