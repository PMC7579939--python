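"""Crystalline lens power back-calculated from biometry by paraxial vergence tracing.

The lens power of a phakic eye is not measured directly; it is inferred from
refraction (SER), corneal power (K-mean), anterior chamber depth and axial
length by propagating vergences through a reduced schematic eye.  The lens is
treated as a single principal plane located a distance *c* behind the anterior
chamber depth — the classic "c constant" device — with an internal refractive
index n:

1. move the spectacle refraction to the corneal vertex over the vertex
   distance v:  S_c = SER / (1 − v·SER/1000);
2. add the corneal power:  V₁ = S_c + K;
3. propagate the reduced distance (ACD + c)/n to the lens plane:
   V₂ = V₁ / (1 − V₁·(ACD + c)/(1000·n));
4. the vergence that must leave the lens to focus on the retina:
   V₃ = 1000·n / (AL − ACD − c);
5. the lens power is the difference:  P_L = V₃ − V₂.

The named procedures (Bennett–Rabbetts and modified Stenström) differ only in
their constant sets: the value of c and the schematic index n, catalogued per
eye model in :func:`constants_catalog`.  Distances are mm, powers diopters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

METHODS = ("bennett_rabbetts", "modified_stenstrom")
EYE_MODELS = ("gullstrand_emsley", "bennett_rabbetts", "customized")

#: c constants (mm) per (method, eye model) and the schematic internal index
#: per eye model.  The customized c values are population means estimated from
#: phakometry; they are inputs here, not fitted.
_C_CONSTANTS: dict[tuple[str, str], float] = {
    ("modified_stenstrom", "gullstrand_emsley"): 2.145,
    ("modified_stenstrom", "bennett_rabbetts"): 2.221,
    ("modified_stenstrom", "customized"): 2.875,
    ("bennett_rabbetts", "gullstrand_emsley"): 2.230,
    ("bennett_rabbetts", "bennett_rabbetts"): 2.306,
    ("bennett_rabbetts", "customized"): 2.891,
}
_N_INTERNAL: dict[str, float] = {
    "gullstrand_emsley": 4.0 / 3.0,
    "bennett_rabbetts": 1.336,
    # the customized eye model keeps the Bennett–Rabbetts schematic index
    "customized": 1.336,
}


@dataclass(frozen=True)
class EyeModelConstants:
    """Schematic-eye constants for lens-power back-calculation."""

    name: str
    n_internal: float
    c: float
    vertex_distance: float = 12.0

    def __post_init__(self) -> None:
        if not 1.0 < self.n_internal < 1.5:
            raise ValueError("n_internal must lie in (1, 1.5)")
        if self.c < 0 or self.vertex_distance < 0:
            raise ValueError("c and vertex_distance must be non-negative")


@dataclass(frozen=True)
class LensPowerResult:
    """Back-calculated lens power (D) with its method and constant set."""

    p_lens: float
    method: str
    eye_model: EyeModelConstants


def eye_model_constants(
    method: str = "bennett_rabbetts",
    eye_model: str = "customized",
    vertex_distance: float = 12.0,
) -> EyeModelConstants:
    """Look up the constant set for one (method, eye model) pair."""
    try:
        c = _C_CONSTANTS[(method, eye_model)]
    except KeyError:
        raise ValueError(f"unknown (method, eye model) pair {(method, eye_model)}") from None
    return EyeModelConstants(name=eye_model, n_internal=_N_INTERNAL[eye_model], c=c,
                             vertex_distance=vertex_distance)


def constants_catalog(vertex_distance: float = 12.0) -> pd.DataFrame:
    """The six (method × eye model) constant rows."""
    rows = [
        {"method": method, "eye_model": em, "c": c, "n_internal": _N_INTERNAL[em],
         "vertex_distance": vertex_distance}
        for (method, em), c in _C_CONSTANTS.items()
    ]
    return pd.DataFrame(rows)


def _spectacle_to_cornea(ser: float, vertex_distance: float) -> float:
    return ser / (1.0 - vertex_distance * ser / 1000.0)


def _cornea_to_spectacle(s_c: float, vertex_distance: float) -> float:
    return s_c / (1.0 + vertex_distance * s_c / 1000.0)


def lens_power(
    record: Mapping[str, float],
    eye: EyeModelConstants,
    method: str = "bennett_rabbetts",
) -> LensPowerResult:
    """Back-calculate the crystalline lens power of one eye.

    ``record`` needs ``ser`` (D), ``k_mean`` (D), ``acd`` (mm) and ``al``
    (mm).  Raises on geometrically impossible eyes (lens plane at or behind
    the retina, non-positive image distance).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    ser, k, acd, al = (float(record[v]) for v in ("ser", "k_mean", "acd", "al"))
    if acd >= al:
        raise ValueError("anterior chamber depth must be smaller than axial length")
    image_dist = al - acd - eye.c
    if image_dist <= 0:
        raise ValueError("lens plane lies at or behind the retina (al - acd - c <= 0)")
    s_c = _spectacle_to_cornea(ser, eye.vertex_distance)
    v1 = s_c + k
    t = (acd + eye.c) / (1000.0 * eye.n_internal)
    denom = 1.0 - t * v1
    if denom <= 0:
        raise ValueError("vergence diverges before the lens plane")
    v2 = v1 / denom
    v3 = 1000.0 * eye.n_internal / image_dist
    return LensPowerResult(p_lens=v3 - v2, method=method, eye_model=eye)


def forward_refraction(
    al: float,
    acd: float,
    k_mean: float,
    p_lens: float,
    eye: EyeModelConstants,
) -> float:
    """Forward problem: the SER an eye with this lens power must have.

    Exact algebraic inverse of :func:`lens_power`, used as the round-trip
    oracle: tracing backwards from the retina through the lens and cornea to
    the spectacle plane.
    """
    image_dist = al - acd - eye.c
    if image_dist <= 0:
        raise ValueError("al - acd - c must be positive")
    v3 = 1000.0 * eye.n_internal / image_dist
    v2 = v3 - p_lens
    t = (acd + eye.c) / (1000.0 * eye.n_internal)
    v1 = v2 / (1.0 + t * v2)
    s_c = v1 - k_mean
    return _cornea_to_spectacle(s_c, eye.vertex_distance)


def lens_powers(
    records: pd.DataFrame,
    eye: EyeModelConstants,
    method: str = "bennett_rabbetts",
) -> np.ndarray:
    """Vectorized per-eye lens powers for a cohort table."""
    return np.array(
        [lens_power(row, eye, method).p_lens for _, row in records.iterrows()]
    )


AGE_GROUPS = (("6-9", 6, 9), ("10-12", 10, 12), ("13-15", 13, 15), ("16-18", 16, 18))


def lens_power_by_age_group(
    records: pd.DataFrame,
    eye: EyeModelConstants,
    method: str = "bennett_rabbetts",
) -> pd.DataFrame:
    """Age-group summary of lens power and axial length.

    Groups are {6–9, 10–12, 13–15, 16–18} on the integer part of age, both
    edges inclusive.  The attached ``p_value`` (same for every row) is a
    one-way ANOVA across groups, the conventional test for an age trend in a
    cross-sectional table; all-equal values return p = 1 by convention.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    p = lens_powers(records, eye, method)
    al = records["al"].to_numpy(dtype=float)
    age_int = np.floor(records["age"].to_numpy(dtype=float)).astype(int)
    rows, group_values = [], []
    for label, lo, hi in AGE_GROUPS:
        m = (age_int >= lo) & (age_int <= hi)
        n = int(m.sum())
        rows.append({
            "age_group": label, "n": n, "pct": 100.0 * n / len(records),
            "p_lens_mean": float(p[m].mean()) if n else np.nan,
            "p_lens_sd": float(np.std(p[m], ddof=1)) if n > 1 else np.nan,
            "al_mean": float(al[m].mean()) if n else np.nan,
            "al_sd": float(np.std(al[m], ddof=1)) if n > 1 else np.nan,
        })
        if n:
            group_values.append(p[m])
    if len(group_values) > 1 and any(np.std(g) > 0 for g in group_values):
        p_val = float(stats.f_oneway(*group_values).pvalue)
    elif len(group_values) > 1 and np.std([g.mean() for g in group_values]) > 0:
        p_val = 0.0  # zero within-group variance but distinct means: certain
    else:
        p_val = 1.0  # all values identical, by convention
    out = pd.DataFrame(rows)
    out["p_value"] = p_val
    return out


def pearson_corr(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
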