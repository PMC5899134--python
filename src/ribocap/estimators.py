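"""Scikit-learn-style estimators wrapping the characterise-then-predict
workflow.

``GammaEstimator`` fits the translation model to measured lysate capacities
(one gamma per construct), ``CapacityCalibrator`` is the in vitro -> in vivo
linear map as a regressor, and ``BurdenPipeline`` chains the two:
fit on characterisation data, predict the in vivo burden of new designs.
All three follow the sklearn estimator contract (get_params/set_params,
fitted attributes with trailing underscores) and compose with
sklearn model-selection tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .gamma import AssayConfig, infer_gamma
from .predict import (
    CalibrationFit,
    CalibrationRegistry,
    OperonDesign,
    fit_calibration,
    predict_in_vitro,
    predict_in_vivo,
)

__all__ = ["GammaEstimator", "CapacityCalibrator", "BurdenPipeline"]


def _columns_or_array(X, columns):
    if isinstance(X, pd.DataFrame):
        missing = [c for c in columns if c not in X.columns]
        if missing:
            raise ValueError(f"X is missing columns {missing}")
        return X[list(columns)].to_numpy(dtype=float)
    arr = check_array(X, ensure_2d=True, dtype=float)
    if arr.shape[1] != len(columns):
        raise ValueError(f"X must have {len(columns)} columns {columns}")
    return arr


class GammaEstimator(BaseEstimator):
    """Per-construct inference of the lumped synthesis cost gamma.

    fit(X, y) takes construct covariates X with columns
    ``(rbs_strength, length_bp)`` and measured normalized in vitro
    capacities y (replicates pre-averaged), and inverts the competitive
    translation model for each row.

    Attributes
    ----------
    gamma_ : ndarray of shape (n_constructs,)
    achieved_capacity_ : ndarray, model capacity at the returned gamma
    converged_ : ndarray of bool
    """

    def __init__(self, assay: AssayConfig | None = None, tol: float = 1e-4,
                 bracket: tuple[float, float] = (1e-4, 1e2),
                 on_out_of_range: str = "clip"):
        self.assay = assay
        self.tol = tol
        self.bracket = bracket
        self.on_out_of_range = on_out_of_range

    def fit(self, X, y):
        Xa = _columns_or_array(X, ("rbs_strength", "length_bp"))
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(Xa):
            raise ValueError("X and y have different lengths")
        assay = self.assay or AssayConfig()
        gammas, caps, conv = [], [], []
        for (rbs, length), cap in zip(Xa, y):
            est = infer_gamma(cap, rbs, int(length), assay, tol=self.tol,
                              bracket=self.bracket,
                              on_out_of_range=self.on_out_of_range)
            gammas.append(est.gamma)
            caps.append(est.achieved_capacity)
            conv.append(est.converged)
        self.gamma_ = np.array(gammas)
        self.achieved_capacity_ = np.array(caps)
        self.converged_ = np.array(conv)
        self.n_features_in_ = 2
        return self


class CapacityCalibrator(RegressorMixin, BaseEstimator):
    """Linear in vitro -> in vivo capacity calibration (OLS).

    Predictions are clipped to [0, 1] when ``clip=True``.
    """

    def __init__(self, clip: bool = True, condition: str = ""):
        self.clip = clip
        self.condition = condition

    def fit(self, X, y):
        x = check_array(X, ensure_2d=False, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        fit = fit_calibration(list(zip(x, y)), condition=self.condition)
        self.slope_ = fit.slope
        self.intercept_ = fit.intercept
        self.r_squared_ = fit.r_squared
        self.n_points_ = fit.n_points
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = check_array(X, ensure_2d=False, dtype=float).ravel()
        y = self.slope_ * x + self.intercept_
        return np.clip(y, 0.0, 1.0) if self.clip else y

    def to_fit(self) -> CalibrationFit:
        check_is_fitted(self, "slope_")
        return CalibrationFit(
            slope=self.slope_, intercept=self.intercept_,
            r_squared=self.r_squared_, condition=self.condition,
            n_points=self.n_points_,
        )


class BurdenPipeline(BaseEstimator):
    """Characterise-then-predict in one estimator.

    fit(X, y): X a DataFrame with columns (sample, rbs_strength, length_bp),
    y the measured lysate capacities; learns one gamma per sample.
    calibrate(pairs, condition): registers a per-condition linear map.
    predict(designs, condition=None): predicted in vitro (and, given a
    condition, in vivo) capacity per design; cistrons with unset gamma are
    filled from the fitted table by name.
    """

    def __init__(self, assay: AssayConfig | None = None, tol: float = 1e-4):
        self.assay = assay
        self.tol = tol

    def fit(self, X, y):
        if not isinstance(X, pd.DataFrame) or "sample" not in X.columns:
            raise ValueError("X must be a DataFrame with a 'sample' column")
        est = GammaEstimator(assay=self.assay, tol=self.tol).fit(X, y)
        self.gamma_table_ = pd.DataFrame(
            {
                "sample": X["sample"].to_numpy(),
                "gamma": est.gamma_,
                "achieved_capacity": est.achieved_capacity_,
                "converged": est.converged_,
            }
        )
        self.calibrations_ = CalibrationRegistry()
        return self

    def calibrate(self, pairs, condition: str) -> "BurdenPipeline":
        check_is_fitted(self, "gamma_table_")
        self.calibrations_.add(fit_calibration(pairs, condition=condition))
        return self

    def _fill_gammas(self, design: OperonDesign) -> OperonDesign:
        from .predict import Cistron

        lookup = dict(zip(self.gamma_table_["sample"], self.gamma_table_["gamma"]))
        cistrons = []
        for c in design.cistrons:
            if c.gamma is not None:
                cistrons.append(c)
            elif c.name in lookup:
                cistrons.append(Cistron(c.name, c.rbs_strength, c.length_bp, lookup[c.name]))
            else:
                raise ValueError(
                    f"no fitted gamma for gene {c.name!r} in operon {design.name!r}"
                )
        return OperonDesign(design.name, design.promoter, design.plasmid_conc, tuple(cistrons))

    def predict(self, designs, condition: str | None = None) -> pd.DataFrame:
        check_is_fitted(self, "gamma_table_")
        assay = self.assay or AssayConfig()
        rows = []
        for d in designs:
            filled = self._fill_gammas(d)
            x = predict_in_vitro(filled, assay)
            row = {"design": d.name, "predicted_in_vitro": x}
            if condition is not None:
                fit = self.calibrations_.get(condition)
                row["predicted_in_vivo"] = predict_in_vivo(x, fit)
                row["condition"] = condition
            rows.append(row)
        return pd.DataFrame(rows)
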