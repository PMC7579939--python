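"""Feature maps for axial-length regression.

A :class:`FeatureMap` is an ordered list of monomial basis terms over the
biometric covariates (age, sex, SER, K-mean, CCT, WTW).  It turns a table of
per-eye records into a design matrix, and — because every term is a monomial —
it knows its own analytic partial derivative with respect to age, which is what
the physiological-elongation machinery differentiates.

Anterior chamber depth (ACD) is deliberately not an admissible model covariate:
it changes systematically with age in children and introducing it alongside age
makes the design collinear.  The cohort generator still simulates ACD because
the lens-power back-calculation consumes it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Covariates a feature map may reference. ``acd`` is excluded by design.
MODEL_VARIABLES = ("age", "sex", "ser", "k_mean", "cct", "wtw")


class MissingCovariateError(KeyError):
    """A prediction input lacks a covariate the feature map references."""


@dataclass(frozen=True)
class Term:
    """A monomial: a product of covariate powers, e.g. ``age^2`` or ``age*k_mean``.

    ``powers`` maps variable name -> positive integer exponent.  The empty
    mapping is the intercept.
    """

    powers: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        for var, p in self.powers:
            if var not in MODEL_VARIABLES:
                raise ValueError(
                    f"term references {var!r}; admissible covariates are {MODEL_VARIABLES}"
                )
            if p < 1:
                raise ValueError("exponents must be positive integers")

    @classmethod
    def make(cls, spec: Mapping[str, int] | str | None = None) -> "Term":
        """Build a term from ``{'age': 2}``, a name like ``'age^2*k_mean'``, or None (intercept)."""
        if spec is None or spec in ("1", "const") or spec == {}:
            return cls(())
        if isinstance(spec, str):
            powers: dict[str, int] = {}
            for factor in spec.split("*"):
                var, _, exp = factor.partition("^")
                var = var.strip()
                powers[var] = powers.get(var, 0) + (int(exp) if exp else 1)
            return cls(tuple(sorted(powers.items())))
        return cls(tuple(sorted((v, int(p)) for v, p in spec.items())))

    @property
    def is_intercept(self) -> bool:
        return not self.powers

    @property
    def name(self) -> str:
        if self.is_intercept:
            return "const"
        return "*".join(v if p == 1 else f"{v}^{p}" for v, p in self.powers)

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(v for v, _ in self.powers)

    def value(self, data: Mapping[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        """Evaluate the monomial column-wise on a record table or mapping."""
        first = next(iter(data.values())) if not isinstance(data, pd.DataFrame) else None
        n = len(data) if isinstance(data, pd.DataFrame) else np.size(first)
        out = np.ones(n, dtype=float)
        for var, p in self.powers:
            try:
                col = np.asarray(data[var], dtype=float)
            except KeyError:
                raise MissingCovariateError(var) from None
            out = out * col**p
        return out

    def age_derivative(self) -> tuple[float, "Term"]:
        """Return (factor, term) with d(self)/d(age) = factor * term.

        The derivative of a monomial ``age^p * rest`` is ``p * age^(p-1) * rest``;
        terms without age differentiate to zero (factor 0, intercept term).
        """
        powers = dict(self.powers)
        p = powers.pop("age", 0)
        if p == 0:
            return 0.0, Term(())
        if p > 1:
            powers["age"] = p - 1
        return float(p), Term(tuple(sorted(powers.items())))


@dataclass(frozen=True)
class FeatureMap:
    """Ordered monomial basis with exactly one intercept and no ACD term."""

    terms: tuple[Term, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n_intercept = sum(t.is_intercept for t in self.terms)
        if n_intercept != 1:
            raise ValueError(f"feature map must contain exactly one intercept, found {n_intercept}")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate terms in feature map")

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "FeatureMap":
        return cls(tuple(Term.make(n) for n in names))

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def variables(self) -> frozenset[str]:
        return frozenset().union(*(t.variables for t in self.terms)) if self.terms else frozenset()

    def design_matrix(self, records: pd.DataFrame | Mapping[str, np.ndarray]) -> np.ndarray:
        """Design matrix: row i, column j = term j evaluated on record i."""
        if len(records) == 0:
            raise ValueError("cannot build a design matrix from zero records")
        return np.column_stack([t.value(records) for t in self.terms])

    def age_derivative_map(self) -> tuple[np.ndarray, "FeatureMap"]:
        """Factors and differentiated terms aligned with ``terms``.

        Returns ``(factors, fm)`` such that for coefficients ``b`` the age
        derivative of the fitted surface is ``(factors * b) @ fm_columns``.
        The differentiated term list may contain duplicates/zero factors; it is
        returned raw (aligned), not compacted, so callers keep coefficient
        alignment.
        """
        pairs = [t.age_derivative() for t in self.terms]
        factors = np.array([f for f, _ in pairs])
        return factors, [t for _, t in pairs]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({"terms": self.term_names})

    @classmethod
    def from_json(cls, s: str) -> "FeatureMap":
        return cls.from_names(json.loads(s)["terms"])


def design_matrix(records: pd.DataFrame, fm: FeatureMap) -> np.ndarray:
    """Functional alias for :meth:`FeatureMap.design_matrix`."""
    return fm.design_matrix(records)


def main_effects(include_corneal_dimensions: bool = False) -> FeatureMap:
    """Main-effects basis: intercept, age, sex, SER, K-mean.

    This is the form of the published cross-sectional regression for this
    population.  ``include_corneal_dimensions`` adds CCT and WTW, which carry
    no signal under the default simulated cohort but are supported so maps
    using them work unchanged.
    """
    names = ["1", "age", "sex", "ser", "k_mean"]
    if include_corneal_dimensions:
        names += ["cct", "wtw"]
    return FeatureMap.from_names(names)


def curved(include_corneal_dimensions: bool = False) -> FeatureMap:
    """Main effects plus age curvature and age interactions.

    Adds age^2, age*ser, age*k_mean and age*sex, giving the fitted surface an
    age-varying elongation rate that can decline with age and differ by SER,
    corneal power and sex — the qualitative behaviour clinical growth data show.
    """
    base = main_effects(include_corneal_dimensions)
    extra = ["age^2", "age*ser", "age*k_mean", "age*sex"]
    return FeatureMap(tuple(base.terms) + tuple(Term.make(n) for n in extra))


#: Basis used to reconstruct a rate model from a published rate grid over
#: (age, SER, K-mean, sex): main effects plus an age-by-K interaction, because
#: published grids show age slopes that vary with corneal power while the SER
#: spacing is age-stable.
RATE_BASIS = FeatureMap.from_names(["1", "age", "ser", "k_mean", "sex", "age*k_mean"])
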