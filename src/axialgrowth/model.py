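"""Axial-length growth models, statsmodels-style.

:class:`ALGrowthModel` binds a per-eye biometry table to a feature map and a
fitting method; ``fit()`` returns an :class:`ALGrowthResults` carrying the
coefficients (for linear fits), the residual scale, robust weights,
convergence diagnostics and a ``summary()`` table.

Six fitting methods are supported:

``ols``
    Ordinary least squares on the mapped features.
``robust``
    Iteratively reweighted least squares with Tukey's bisquare weight
    function — the standard outlier-resistant linear fit.  Residuals are
    standardized by a leverage-adjusted MAD scale and the default tuning
    constant 4.685 gives 95% Gaussian efficiency.
``svr_linear`` / ``svr_quadratic`` / ``svr_cubic``
    ε-insensitive linear regression on polynomial maps of degree 1/2/3 of the
    covariates.
``bagged_trees``
    Bootstrap-aggregated regression trees.

The nonlinear methods return results with an opaque predictor in place of
coefficients; their prediction contract is identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMap, MissingCovariateError, main_effects

LINEAR_METHODS = ("ols", "robust")
SVR_METHODS = {"svr_linear": 1, "svr_quadratic": 2, "svr_cubic": 3}
ALL_METHODS = LINEAR_METHODS + tuple(SVR_METHODS) + ("bagged_trees",)

#: Coefficients of the published cross-sectional multiple linear regression of
#: axial length (mm) on age (years), sex (1 = male), K-mean (D) and SER (D)
#: in school-aged myopic children (n = 1011, R^2 = 0.81).
REFERENCE_COEFFICIENTS: dict[str, float] = {
    "const": 40.31,
    "age": 0.056,
    "sex": -0.013,
    "ser": -0.353,
    "k_mean": -0.396,
}


class SingularDesignError(np.linalg.LinAlgError):
    """The design matrix is rank deficient (collinear covariates)."""


class UnsupportedModelError(TypeError):
    """Operation not defined for this model class (e.g. tree ensembles)."""


@dataclass(frozen=True)
class RobustConfig:
    """IRLS settings for the robust linear fit.

    tuning_constant
        Bisquare cut-off in units of robust standard deviations; 4.685 gives
        95% efficiency under Gaussian errors.
    max_iter
        Iteration cap; non-convergence sets a flag, it does not raise.
    tol
        Maximum absolute coefficient change that counts as converged.
    """

    tuning_constant: float = 4.685
    max_iter: int = 50
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.tuning_constant <= 0 or self.max_iter < 1 or self.tol <= 0:
            raise ValueError("invalid RobustConfig")


def bisquare_weight(u: np.ndarray | float) -> np.ndarray | float:
    """Tukey bisquare weight: ``(1 - u^2)^2`` for |u| < 1, else 0."""
    u = np.asarray(u, dtype=float)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return w if w.ndim else float(w)


def _leverage(X: np.ndarray) -> np.ndarray:
    """Diagonal of the hat matrix via thin QR."""
    q, _ = np.linalg.qr(X)
    h = np.sum(q**2, axis=1)
    return np.clip(h, 0.0, 1.0 - 1e-12)


def _solve_wls(X: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    if w is not None:
        sw = np.sqrt(w)
        X = X * sw[:, None]
        y = y * sw
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


class ALGrowthModel:
    """Axial length regressed on biometric covariates through a feature map.

    Parameters
    ----------
    data
        Per-eye records with at least the covariate columns the feature map
        references plus ``al`` (axial length, mm) as the response.
    feature_map
        Monomial basis; defaults to the main-effects preset.
    method
        One of ``ols``, ``robust``, ``svr_linear``, ``svr_quadratic``,
        ``svr_cubic``, ``bagged_trees``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        feature_map: FeatureMap | None = None,
        method: str = "robust",
        response: str = "al",
    ) -> None:
        if method not in ALL_METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {ALL_METHODS}")
        if len(data) == 0:
            raise ValueError("empty data")
        self.data = data.reset_index(drop=True)
        self.feature_map = feature_map if feature_map is not None else main_effects()
        self.method = method
        self.response = response
        self.endog = np.asarray(self.data[response], dtype=float)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        robust_config: RobustConfig | None = None,
        random_state: int | None = 0,
        **hyper,
    ) -> "ALGrowthResults":
        if self.method == "ols":
            return self._fit_ols()
        if self.method == "robust":
            return self._fit_robust(robust_config or RobustConfig())
        if self.method in SVR_METHODS:
            return self._fit_svr(SVR_METHODS[self.method], **hyper)
        return self._fit_bagged_trees(random_state=random_state, **hyper)

    def _design(self) -> np.ndarray:
        X = self.feature_map.design_matrix(self.data)
        if len(self.data) < X.shape[1]:
            raise ValueError(
                f"{len(self.data)} records cannot identify {X.shape[1]} coefficients"
            )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SingularDesignError(
                "design matrix is rank deficient; covariates are collinear "
                "(as happens when ACD is entered alongside age)"
            )
        return X

    def _fit_ols(self) -> "ALGrowthResults":
        X = self._design()
        beta = _solve_wls(X, self.endog)
        resid = self.endog - X @ beta
        sigma = float(np.sqrt(np.mean(resid**2)))
        return ALGrowthResults(self, params=beta, sigma=sigma)

    def _fit_robust(self, cfg: RobustConfig) -> "ALGrowthResults":
        X = self._design()
        y = self.endog
        h = _leverage(X)
        beta = _solve_wls(X, y)
        weights = np.ones_like(y)
        converged = False
        s = 0.0
        for _ in range(cfg.max_iter):
            resid = y - X @ beta
            radj = resid / np.sqrt(1.0 - h)
            s = float(np.median(np.abs(radj)) / 0.6745)
            if s <= np.finfo(float).eps * max(1.0, float(np.abs(y).max())):
                # Degenerate scale (e.g. an exact fit): the OLS solution is
                # already the answer; flag rather than divide by zero.
                warnings.warn("robust scale is zero; returning the least-squares fit")
                ols = self._fit_ols()
                return ALGrowthResults(
                    self, params=ols.params_array, sigma=ols.sigma,
                    weights=np.ones_like(y), converged=True, scale_degenerate=True,
                )
            u = radj / (cfg.tuning_constant * s)
            weights = np.asarray(bisquare_weight(u))
            new_beta = _solve_wls(X, y, weights)
            if np.max(np.abs(new_beta - beta)) < cfg.tol:
                beta = new_beta
                converged = True
                break
            beta = new_beta
        if not converged:
            warnings.warn("robust IRLS did not converge within max_iter")
        return ALGrowthResults(
            self, params=beta, sigma=s, weights=weights, converged=converged,
            robust_config=cfg,
        )

    def _svr_inputs(self) -> tuple[list[str], np.ndarray]:
        cols = sorted(self.feature_map.variables)
        for c in cols:
            if c not in self.data:
                raise MissingCovariateError(c)
        return cols, self.data[cols].to_numpy(dtype=float)

    def _fit_svr(self, degree: int, epsilon: float | None = None, C: float = 1.0) -> "ALGrowthResults":
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import PolynomialFeatures, StandardScaler
        from sklearn.svm import LinearSVR

        cols, X = self._svr_inputs()
        y = self.endog
        if epsilon is None:
            epsilon = 0.1 * float(np.std(y))
        pipe = Pipeline(
            [
                ("poly", PolynomialFeatures(degree=degree, include_bias=False)),
                ("scale", StandardScaler()),
                (
                    "svr",
                    LinearSVR(
                        epsilon=epsilon, C=C, loss="epsilon_insensitive",
                        max_iter=20_000, tol=1e-6, random_state=0,
                    ),
                ),
            ]
        )
        y_center = float(np.mean(y))
        pipe.fit(X, y - y_center)
        pred = pipe.predict(X) + y_center
        sigma = float(np.sqrt(np.mean((y - pred) ** 2)))
        return ALGrowthResults(
            self, predictor=pipe, predictor_cols=cols, predictor_offset=y_center,
            sigma=sigma, epsilon=epsilon,
        )

    def _fit_bagged_trees(
        self,
        n_estimators: int = 30,
        min_samples_leaf: int = 8,
        random_state: int | None = 0,
    ) -> "ALGrowthResults":
        from sklearn.ensemble import BaggingRegressor
        from sklearn.tree import DecisionTreeRegressor

        cols, X = self._svr_inputs()
        y = self.endog
        ens = BaggingRegressor(
            estimator=DecisionTreeRegressor(min_samples_leaf=min_samples_leaf),
            n_estimators=n_estimators,
            random_state=random_state,
        )
        ens.fit(X, y)
        pred = ens.predict(X)
        sigma = float(np.sqrt(np.mean((y - pred) ** 2)))
        return ALGrowthResults(self, predictor=ens, predictor_cols=cols, sigma=sigma)


class ALGrowthResults:
    """Fitted axial-length model: coefficients or predictor, scale, diagnostics.

    For linear fits ``params`` is a Series indexed by term name; nonlinear
    fits expose only :meth:`predict`.  ``sigma`` is the residual scale in mm
    (RMSE for least squares, the robust scale for IRLS).
    """

    def __init__(
        self,
        model: ALGrowthModel | None,
        params: np.ndarray | None = None,
        *,
        feature_map: FeatureMap | None = None,
        method: str | None = None,
        sigma: float = 0.0,
        weights: np.ndarray | None = None,
        converged: bool = True,
        scale_degenerate: bool = False,
        robust_config: RobustConfig | None = None,
        predictor=None,
        predictor_cols: Sequence[str] | None = None,
        predictor_offset: float = 0.0,
        epsilon: float | None = None,
    ) -> None:
        self.model = model
        self.feature_map = feature_map or (model.feature_map if model else None)
        self.method = method or (model.method if model else "ols")
        self.params_array = None if params is None else np.asarray(params, dtype=float)
        self.sigma = float(sigma)
        self.weights = weights
        self.converged = converged
        self.scale_degenerate = scale_degenerate
        self.robust_config = robust_config
        self._predictor = predictor
        self._predictor_cols = list(predictor_cols) if predictor_cols else None
        self._predictor_offset = predictor_offset
        self.epsilon = epsilon
        self.nobs = len(model.data) if model is not None else None

    # -- introspection ------------------------------------------------------

    @property
    def is_linear(self) -> bool:
        return self.params_array is not None

    @property
    def params(self) -> pd.Series | None:
        if self.params_array is None:
            return None
        return pd.Series(self.params_array, index=self.feature_map.term_names)

    # -- prediction ---------------------------------------------------------

    def predict(self, data: pd.DataFrame | Mapping[str, float]) -> np.ndarray | float:
        """Predicted axial length (mm) for a record table or a single mapping."""
        scalar = not isinstance(data, pd.DataFrame)
        frame = pd.DataFrame([data]) if scalar else data
        if self.is_linear:
            X = self.feature_map.design_matrix(frame)
            out = X @ self.params_array
        else:
            for c in self._predictor_cols:
                if c not in frame:
                    raise MissingCovariateError(c)
            out = (
                self._predictor.predict(frame[self._predictor_cols].to_numpy(dtype=float))
                + self._predictor_offset
            )
        return float(out[0]) if scalar else np.asarray(out)

    def resid(self) -> np.ndarray:
        return self.model.endog - np.asarray(self.predict(self.model.data))

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Axial length growth model",
            "=" * 46,
            f"method:      {self.method}",
            f"n obs:       {self.nobs}",
            f"sigma (mm):  {self.sigma:.4f}",
            f"converged:   {self.converged}",
        ]
        if self.is_linear:
            lines.append("-" * 46)
            lines.append(f"{'term':<16}{'coef':>14}")
            for name, b in self.params.items():
                lines.append(f"{name:<16}{b:>14.6g}")
        else:
            lines.append("predictor:   nonparametric (opaque)")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ALGrowthResults method={self.method} nobs={self.nobs} sigma={self.sigma:.4g}>"

    # -- serialization (linear models only; bit-exact reload) ---------------

    def to_json(self) -> str:
        if not self.is_linear:
            raise UnsupportedModelError("only linear models serialize to JSON")
        payload = {
            "feature_map": self.feature_map.term_names,
            # float.hex round-trips exactly
            "coefficients": [b.hex() for b in self.params_array.tolist()],
            "method": self.method,
            "sigma": float(self.sigma).hex(),
            "converged": self.converged,
        }
        if self.robust_config is not None:
            payload["robust_config"] = {
                "tuning_constant": self.robust_config.tuning_constant,
                "max_iter": self.robust_config.max_iter,
                "tol": self.robust_config.tol,
            }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ALGrowthResults":
        d = json.loads(s)
        cfg = d.get("robust_config")
        return cls(
            None,
            params=np.array([float.fromhex(b) for b in d["coefficients"]]),
            feature_map=FeatureMap.from_names(d["feature_map"]),
            method=d["method"],
            sigma=float.fromhex(d["sigma"]),
            converged=d.get("converged", True),
            robust_config=RobustConfig(**cfg) if cfg else None,
        )


def reference_linear_model() -> ALGrowthResults:
    """The published main-effects regression as a ready-made results object.

    AL = 40.31 + 0.056*age − 0.013*sex − 0.396*K_mean − 0.353*SER, with age in
    years, sex coded 1 = male / 0 = female, K-mean and SER in diopters and AL
    in mm.  Its age slope is constant: every eye elongates 0.056 mm/year under
    this surface regardless of covariates.
    """
    fm = main_effects()
    beta = np.array([REFERENCE_COEFFICIENTS[name] for name in fm.term_names])
    return ALGrowthResults(None, params=beta, feature_map=fm, method="ols", sigma=0.378)


def fit_ols(records: pd.DataFrame, fm: FeatureMap | None = None) -> ALGrowthResults:
    """Ordinary least squares fit of AL on the mapped features."""
    return ALGrowthModel(records, fm, method="ols").fit()


def fit_robust(
    records: pd.DataFrame,
    fm: FeatureMap | None = None,
    cfg: RobustConfig | None = None,
) -> ALGrowthResults:
    """Bisquare IRLS fit of AL on the mapped features."""
    return ALGrowthModel(records, fm, method="robust").fit(robust_config=cfg)


def fit_alternative(
    records: pd.DataFrame,
    fm: FeatureMap | None = None,
    method_tag: str = "svr_linear",
    **hyper,
) -> ALGrowthResults:
    """Fit one of the ε-insensitive SVR variants or the bagged-trees ensemble."""
    if method_tag not in tuple(SVR_METHODS) + ("bagged_trees",):
        raise ValueError(f"unknown alternative method {method_tag!r}")
    return ALGrowthModel(records, fm, method=method_tag).fit(**hyper)
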