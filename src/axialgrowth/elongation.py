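"""Physiological axial elongation: growth curves, rates and amounts.

An eye can elongate without becoming more myopic: during childhood the
crystalline lens loses power and compensates part of the axial growth.  That
compensated component — the *physiological* elongation — is operationalized
here as the behaviour of the fitted axial-length surface f(age, K-mean, CCT,
WTW, SER, sex) when age advances while the refraction and the corneal
parameters are held fixed:

* the AL–age *curve* at fixed covariates,
* its partial derivative with respect to age, the elongation *rate*
  in mm/year, and
* the definite integral of that rate between two ages, the elongation
  *amount* in mm — identical, by the fundamental theorem of calculus, to the
  difference of the curve at the two ages (the module checks the two routes
  against each other numerically).

A published 96-cell rate grid (two ages × six SER levels × four K-mean levels
× both sexes, at CCT 550 μm and WTW 12 mm) is shipped as a fixture; a linear
rate model can be reconstructed from it by least squares for verification and
for producing rate grids without the clinical data.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import integrate

from .features import FeatureMap, RATE_BASIS, Term
from .model import ALGrowthResults, SingularDesignError, UnsupportedModelError

#: Fixed corneal parameters used for illustration grids: CCT 550 μm, WTW 12 mm.
DEFAULT_FIXED = {"cct": 550.0, "wtw": 12.0}
#: Grid axes of the published rate table.
GRID_AGES = (6.0, 18.0)
GRID_SER = (-1.0, -2.0, -3.0, -4.0, -5.0, -6.0)
GRID_K = (40.0, 42.0, 44.0, 46.0)

_GRID_RESOURCE = "published_elongation_grid.csv"
#: SHA-256 of the packaged grid CSV, to detect accidental edits.
PUBLISHED_GRID_SHA256 = "49cd35a28c3ace344891df8fc90867ed1db724234cc0175133242634d8d88410"


@dataclass(frozen=True)
class CurveSpec:
    """Axes and fixed covariates for a family of AL–age growth curves."""

    model: ALGrowthResults
    fixed: dict = field(default_factory=lambda: dict(DEFAULT_FIXED))
    ser_values: tuple[float, ...] = GRID_SER
    k_values: tuple[float, ...] = GRID_K
    age_range: tuple[float, float] = (6.0, 18.0)
    age_step: float = 0.5

    def __post_init__(self) -> None:
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range min exceeds max")
        if self.age_step <= 0:
            raise ValueError("age_step must be positive")

    @property
    def ages(self) -> np.ndarray:
        lo, hi = self.age_range
        n = int(round((hi - lo) / self.age_step)) + 1 if hi > lo else 1
        return np.linspace(lo, hi, n)


def _covariate_frame(ages: np.ndarray, ser: float, k: float, fixed: dict) -> pd.DataFrame:
    frame = pd.DataFrame({"age": ages, "ser": ser, "k_mean": k})
    for key, val in fixed.items():
        frame[key] = val
    return frame


def al_age_curve(spec: CurveSpec, ser: float, k: float, sex: float | None = None) -> pd.DataFrame:
    """One growth curve: predicted AL at each age with all other covariates fixed."""
    if ser not in spec.ser_values or k not in spec.k_values:
        raise ValueError("requested SER/K-mean not among the spec's grid values")
    fixed = dict(spec.fixed)
    if sex is not None:
        fixed["sex"] = sex
    if "sex" not in fixed:
        raise ValueError("sex must be fixed (in spec.fixed or via the sex argument)")
    frame = _covariate_frame(spec.ages, ser, k, fixed)
    missing = spec.model.feature_map.variables - set(frame.columns) if spec.model.is_linear else set()
    if missing:
        raise ValueError(f"model references covariates not fixed by the curve spec: {sorted(missing)}")
    return pd.DataFrame({"age": spec.ages, "al_predicted": np.asarray(spec.model.predict(frame))})


def d_al_d_age(model: ALGrowthResults, covariates: dict, age: float) -> float:
    """Analytic ∂AL/∂age (mm/year) of a linear-in-coefficients model.

    Tree ensembles and SVR fits carry no differentiable closed form and are
    refused.
    """
    if not model.is_linear:
        raise UnsupportedModelError(
            f"method {model.method!r} has no analytic age derivative"
        )
    factors, dterms = model.feature_map.age_derivative_map()
    point = dict(covariates)
    point["age"] = age
    frame = pd.DataFrame([point])
    total = 0.0
    for b, f, t in zip(model.params_array, factors, dterms):
        if f != 0.0:
            total += b * f * float(t.value(frame)[0])
    return total


def delta_al_phy(
    model: ALGrowthResults,
    covariates: dict,
    age1: float,
    age2: float,
    check_tol: float = 1e-6,
) -> float:
    """Physiological elongation amount f(age2) − f(age1), in mm.

    Also evaluates the same quantity as the composite-Simpson integral of the
    analytic rate (step ≤ 0.1 y) and raises if the two routes disagree beyond
    ``check_tol`` — a self-check of the derivative machinery.
    """
    if age2 < age1:
        raise ValueError("age2 must be >= age1")
    p1 = dict(covariates, age=age1)
    p2 = dict(covariates, age=age2)
    diff = float(model.predict(p2)) - float(model.predict(p1))
    if age2 > age1 and model.is_linear:
        n = max(2, int(np.ceil((age2 - age1) / 0.1)))
        n += n % 2  # Simpson needs an even interval count
        ages = np.linspace(age1, age2, n + 1)
        rates = np.array([d_al_d_age(model, covariates, a) for a in ages])
        quad = float(integrate.simpson(rates, x=ages))
        if abs(quad - diff) > check_tol:
            raise AssertionError(
                f"difference form {diff:.9f} and integral form {quad:.9f} disagree"
            )
    return diff


# -- rate grids -------------------------------------------------------------

class ElongationGrid:
    """Rate values over (age × SER × K-mean × sex) at fixed CCT/WTW.

    Wraps a long-format table with columns ``age, ser, k_mean, sex, dal_dage``
    and offers the marginal means a rate table reports: by sex × age (over all
    SER × K cells) and by K × sex × age (over SER).
    """

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"age", "ser", "k_mean", "sex", "dal_dage"}
        if not required.issubset(table.columns):
            raise ValueError(f"grid table needs columns {sorted(required)}")
        if not np.all(np.isfinite(table["dal_dage"])):
            raise ValueError("grid contains non-finite rate values")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def value(self, age: float, ser: float, k_mean: float, sex: float) -> float:
        t = self.table
        m = (t["age"] == age) & (t["ser"] == ser) & (t["k_mean"] == k_mean) & (t["sex"] == sex)
        if m.sum() != 1:
            raise KeyError((age, ser, k_mean, sex))
        return float(t.loc[m, "dal_dage"].iloc[0])

    def mean_by_sex_age(self) -> pd.DataFrame:
        return self.table.groupby(["sex", "age"])["dal_dage"].mean().reset_index()

    def mean_by_k_sex_age(self) -> pd.DataFrame:
        return self.table.groupby(["k_mean", "sex", "age"])["dal_dage"].mean().reset_index()


def published_elongation_grid(verify_checksum: bool = True) -> ElongationGrid:
    """The packaged 96-cell published rate grid (mm/year)."""
    raw = resources.files("axialgrowth.data").joinpath(_GRID_RESOURCE).read_bytes()
    if verify_checksum and hashlib.sha256(raw).hexdigest() != PUBLISHED_GRID_SHA256:
        raise ValueError("packaged elongation grid failed its checksum")
    from io import BytesIO

    return ElongationGrid(pd.read_csv(BytesIO(raw)))


def build_elongation_grid(
    model: ALGrowthResults,
    ages: tuple[float, ...] = GRID_AGES,
    ser_values: tuple[float, ...] = GRID_SER,
    k_values: tuple[float, ...] = GRID_K,
    fixed: dict | None = None,
) -> ElongationGrid:
    """Evaluate ∂AL/∂age over the full (age × SER × K × sex) grid.

    ``model`` is either an axial-length model (its analytic age derivative is
    taken) or a rate model from :func:`reconstruct_rate_model` (its prediction
    *is* the rate).
    """
    fixed = dict(DEFAULT_FIXED if fixed is None else fixed)
    is_rate = getattr(model, "predicts_rate", False)
    rows = []
    for sex in (1.0, 0.0):
        for k in k_values:
            for ser in ser_values:
                for age in ages:
                    cov = dict(fixed, ser=ser, k_mean=k, sex=sex)
                    if is_rate:
                        rate = float(model.predict(dict(cov, age=age)))
                    else:
                        rate = d_al_d_age(model, cov, age)
                    rows.append({"age": age, "ser": ser, "k_mean": k, "sex": sex,
                                 "dal_dage": rate})
    return ElongationGrid(pd.DataFrame(rows))


class RateModel(ALGrowthResults):
    """Linear model whose prediction is the elongation rate (mm/year), not AL."""

    predicts_rate = True


def reconstruct_rate_model(
    grid: ElongationGrid,
    basis: FeatureMap = RATE_BASIS,
) -> RateModel:
    """Least-squares fit of a linear rate surface to a printed rate grid.

    Returns a :class:`RateModel` predicting mm/year, with the maximum absolute
    per-cell residual stored on ``max_abs_residual`` — a measure of how well a
    low-order surface explains the printed values.
    """
    if len(basis.terms) > 10:
        raise ValueError("rate basis limited to 10 terms")
    X = basis.design_matrix(grid.table)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError("rate basis is singular on the grid axes")
    y = grid.table["dal_dage"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    out = RateModel(
        None, params=beta, feature_map=basis, method="reconstructed_rate",
        sigma=float(np.sqrt(np.mean(resid**2))),
    )
    out.max_abs_residual = float(np.max(np.abs(resid)))
    return out
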