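"""Single-hidden-layer tanh neural calibration of concentration.

The calibration function maps the principal-channel intensities x₁…xₙ of a
spectrum to a concentration through three hidden tanh nodes

    Hₖ = tanh(0.5 · (aₖ + bₖ·z₁ + cₖ·z₂ + … )),   k = 1, 2, 3
    ŷ  = α·H₁ + β·H₂ + μ·H₃ + constant

where zⱼ are the centered/scaled feature intensities (raw ion counts span
10⁴–10⁷ and would saturate tanh instantly; the standardization constants are
stored in the model so the closed form stays exactly evaluable on raw
inputs).  No penalty term is used.  Training minimizes the sum of squared
concentration errors by multi-start quasi-Newton (L-BFGS-B with analytic
gradients, default 20 seeded restarts) — the parameter count, 3·(1+n) + 4,
is tiny.

Model selection follows the K-fold rule used for calibration transfer:
split the data into K concentration-stratified folds, fit one model per
fold on the complement, score each on its held-out fold, and keep the model
with the best validation statistics (lowest normalized RMSE; ties broken by
higher r², then lower fold index).

Usage follows the statsmodels pattern::

    model = NeuralCalibration(X, y, feature_mz=features.mz)
    res = model.fit(seed=0)               # NeuralCalibrationResults
    sel = model.fit_kfold(k=5, seed=0)    # KFoldSelection
    sel.results.predict(X_new)
    print(sel.summary())
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

N_HIDDEN = 3

__all__ = [
    "tanh_activation",
    "ANNModel",
    "FitReport",
    "NeuralCalibration",
    "NeuralCalibrationResults",
    "KFoldSelection",
    "ann_predict",
    "train_ann",
    "kfold_select",
    "fit_metrics",
    "ConvergenceError",
]


def tanh_activation(x):
    """Hyperbolic tangent (e²ˣ − 1)/(e²ˣ + 1): odd, strictly increasing,
    saturating in (−1, 1) without overflow."""
    return np.tanh(x)


class ConvergenceError(RuntimeError):
    """Raised when every optimizer restart fails; carries best diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class ANNModel:
    """All constants of the calibration closed form, plus training metadata.

    ``hidden_weights`` has exactly three rows, each ``[aₖ, bₖ, cₖ, …]``
    (bias first, one weight per feature); ``output_weights`` is
    ``[α, β, μ, constant]`` on the concentration scale.
    """

    feature_mz: np.ndarray
    input_center: np.ndarray
    input_scale: np.ndarray
    hidden_weights: np.ndarray  # (3, 1 + n_features)
    output_weights: np.ndarray  # (4,): alpha, beta, mu, constant
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.input_center = np.asarray(self.input_center, dtype=float)
        self.input_scale = np.asarray(self.input_scale, dtype=float)
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        n = len(self.feature_mz)
        if self.hidden_weights.shape != (N_HIDDEN, 1 + n):
            raise ValueError(
                f"hidden_weights must be ({N_HIDDEN}, {1 + n}), got {self.hidden_weights.shape}"
            )
        if self.output_weights.shape != (4,):
            raise ValueError("output_weights must be [alpha, beta, mu, constant]")

    @property
    def n_features(self) -> int:
        return len(self.feature_mz)

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """Hidden activations H₁..H₃ for raw feature intensities X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature vector length {X.shape[1]} does not match model features "
                f"(expected {self.n_features} channels at m/z {self.feature_mz.tolist()})"
            )
        Z = (X - self.input_center) / self.input_scale
        pre = 0.5 * (self.hidden_weights[:, 0] + Z @ self.hidden_weights[:, 1:].T)
        return tanh_activation(pre)

    def predict(self, X: np.ndarray) -> np.ndarray:
        H = self.hidden(X)
        return H @ self.output_weights[:3] + self.output_weights[3]

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "feature_mz": self.feature_mz.tolist(),
            "input_center": self.input_center.tolist(),
            "input_scale": self.input_scale.tolist(),
            "hidden_weights": self.hidden_weights.tolist(),
            "output_weights": self.output_weights.tolist(),
            "training_meta": self.training_meta,
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
        return doc

    @classmethod
    def from_json(cls, doc: dict | str | Path) -> "ANNModel":
        if not isinstance(doc, dict):
            doc = json.loads(Path(doc).read_text())
        return cls(
            feature_mz=doc["feature_mz"],
            input_center=doc["input_center"],
            input_scale=doc["input_scale"],
            hidden_weights=doc["hidden_weights"],
            output_weights=doc["output_weights"],
            training_meta=doc.get("training_meta", {}),
        )


def ann_predict(model: ANNModel, features: np.ndarray) -> np.ndarray:
    """Evaluate the calibration closed form on raw feature intensities."""
    return model.predict(features)


@dataclass(frozen=True)
class FitReport:
    """Normalized RMSE (% of mean actual concentration) and r² for one role."""

    rmse_percent: float
    r_squared: float
    role: str = "training"
    n: int = 0

    def __post_init__(self):
        if self.rmse_percent < 0:
            raise ValueError("rmse_percent must be ≥ 0")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


def fit_metrics(predicted: Sequence[float], actual: Sequence[float],
                role: str = "training", relative: bool = False) -> FitReport:
    """Normalized RMSE and squared Pearson correlation of predicted vs actual.

    rmse_percent = 100·sqrt(mean((pred − actual)²)) / mean(actual); with
    ``relative=True`` the per-point relative form
    100·sqrt(mean(((pred − actual)/actual)²)) is used instead.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have equal length")
    if len(actual) < 3:
        raise ValueError("fit metrics require ≥ 3 points")
    mean_actual = actual.mean()
    if mean_actual == 0:
        raise ValueError("mean(actual) is zero: normalized RMSE undefined")
    if relative:
        if np.any(actual == 0):
            raise ValueError("relative RMSE undefined with zero actual values")
        rmse_pct = 100.0 * np.sqrt(np.mean(((predicted - actual) / actual) ** 2))
    else:
        rmse_pct = 100.0 * np.sqrt(np.mean((predicted - actual) ** 2)) / mean_actual
    sp = predicted.std()
    sa = actual.std()
    if sp == 0 or sa == 0:
        r2 = 0.0
    else:
        r = float(np.corrcoef(predicted, actual)[0, 1])
        r2 = min(r * r, 1.0)
    return FitReport(float(rmse_pct), r2, role=role, n=len(actual))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _sse_and_grad(theta: np.ndarray, Xt: np.ndarray, y: np.ndarray, n_feat: int):
    """Sum of squared errors and gradient for packed parameters.

    ``Xt`` is the design with a leading 1s column; hidden pre-activation is
    0.5·Xt·Wᵀ.
    """
    k = N_HIDDEN * (1 + n_feat)
    W = theta[:k].reshape(N_HIDDEN, 1 + n_feat)
    v = theta[k:k + N_HIDDEN]
    c = theta[k + N_HIDDEN]
    Z = 0.5 * (Xt @ W.T)
    H = np.tanh(Z)
    resid = H @ v + c - y
    sse = float(resid @ resid)
    dH = (2.0 * resid)[:, None] * v[None, :] * (1.0 - H * H)
    gW = 0.5 * (dH.T @ Xt)
    gv = H.T @ (2.0 * resid)
    gc = 2.0 * resid.sum()
    return sse, np.concatenate([gW.ravel(), gv, [gc]])


class NeuralCalibration:
    """Calibration model: principal-channel intensities → concentration.

    Parameters
    ----------
    X : array-like, shape (n_spectra, n_features)
        Feature intensities (raw or normalized — standardization is internal).
    y : array-like, shape (n_spectra,)
        Known concentrations, μg mL⁻¹.
    feature_mz : array-like, optional
        The m/z of each feature column, carried into the fitted model.
    min_distinct_levels : int, default 6
        Training refuses designs with fewer distinct concentration values;
        the calibration working range needs its six levels.
    """

    def __init__(self, X, y, feature_mz=None, min_distinct_levels: int = 6):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y must have the same number of rows")
        n_levels = len(np.unique(self.y))
        if n_levels < min_distinct_levels:
            raise ValueError(
                f"training requires ≥ {min_distinct_levels} distinct concentration "
                f"levels, got {n_levels}"
            )
        self.feature_mz = (
            np.arange(self.X.shape[1], dtype=float)
            if feature_mz is None
            else np.asarray(feature_mz, dtype=float)
        )
        if len(self.feature_mz) != self.X.shape[1]:
            raise ValueError("feature_mz length must match the number of columns of X")
        n_params = N_HIDDEN * (1 + self.X.shape[1]) + 4
        if self.X.shape[0] <= n_params:
            warnings.warn(
                f"small-sample regime: {self.X.shape[0]} spectra for {n_params} "
                "parameters; the fit interpolates rather than smooths",
                UserWarning,
                stacklevel=2,
            )
        # standardization constants (stored on the fitted model)
        self._center = self.X.mean(axis=0)
        scale = self.X.std(axis=0)
        self._scale = np.where(scale > 0, scale, 1.0)
        self._y_center = self.y.mean()
        y_scale = self.y.std()
        self._y_scale = y_scale if y_scale > 0 else 1.0

    @classmethod
    def from_dataframe(cls, df, feature_columns: Sequence, target: str = "concentration",
                       **kwargs) -> "NeuralCalibration":
        return cls(
            df[list(feature_columns)].to_numpy(dtype=float),
            df[target].to_numpy(dtype=float),
            feature_mz=[float(c) for c in feature_columns]
            if all(str(c).replace(".", "", 1).isdigit() for c in feature_columns)
            else None,
            **kwargs,
        )

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = 0, n_restarts: int = 20, maxiter: int = 1500,
            init_scale: float = 0.5) -> "NeuralCalibrationResults":
        """Multi-start L-BFGS-B minimization of the sum of squared errors.

        Deterministic for fixed (data, seed, n_restarts); the best restart by
        SSE wins.
        """
        Z = (self.X - self._center) / self._scale
        Xt = np.hstack([np.ones((Z.shape[0], 1)), Z])
        ys = (self.y - self._y_center) / self._y_scale
        n_feat = Z.shape[1]
        n_params = N_HIDDEN * (1 + n_feat) + 4
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
        best = None
        failures = []
        for restart in range(n_restarts):
            theta0 = rng.normal(0.0, init_scale, size=n_params)
            res = minimize(
                _sse_and_grad,
                theta0,
                args=(Xt, ys, n_feat),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12},
            )
            if not np.isfinite(res.fun):
                failures.append(str(res.message))
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise ConvergenceError(
                "optimizer failed on every restart",
                diagnostics={"n_restarts": n_restarts, "messages": failures},
            )
        k = N_HIDDEN * (1 + n_feat)
        W = best.x[:k].reshape(N_HIDDEN, 1 + n_feat)
        v = best.x[k:k + N_HIDDEN] * self._y_scale
        c = best.x[k + N_HIDDEN] * self._y_scale + self._y_center
        model = ANNModel(
            feature_mz=self.feature_mz,
            input_center=self._center,
            input_scale=self._scale,
            hidden_weights=W,
            output_weights=np.concatenate([v, [c]]),
            training_meta={
                "seed": int(seed),
                "n_restarts": int(n_restarts),
                "maxiter": int(maxiter),
                "sse_standardized": float(best.fun),
                "n_obs": int(len(self.y)),
            },
        )
        return NeuralCalibrationResults(self, model)

    def fit_kfold(self, k: int = 5, seed: int = 0, n_restarts: int = 20,
                  maxiter: int = 1500) -> "KFoldSelection":
        """K-fold model selection, stratified by concentration level.

        Fits K models, each validated on its held-out fold; returns the one
        with the lowest validation RMSE% (ties → higher r², then lower fold
        index) together with its training and validation reports.
        """
        n = len(self.y)
        if k < 2:
            raise ValueError("K must be ≥ 2")
        if k > n:
            raise ValueError(f"K = {k} exceeds the {n} available spectra")
        folds = _stratified_folds(self.y, k, seed)
        fold_fits = []
        for i, hold in enumerate(folds):
            mask = np.zeros(n, dtype=bool)
            mask[hold] = True
            y_val = self.y[mask]
            if len(np.unique(y_val)) < 2 and k < n:
                raise ValueError(
                    f"fold {i} holds fewer than 2 distinct concentration levels; "
                    "validation fit is undefined"
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                sub = NeuralCalibration(
                    self.X[~mask], self.y[~mask], feature_mz=self.feature_mz,
                    min_distinct_levels=2,
                )
            res = sub.fit(seed=seed + i, n_restarts=n_restarts, maxiter=maxiter)
            pred_val = res.model.predict(self.X[mask])
            pred_train = res.fittedvalues
            val_report = (
                fit_metrics(pred_val, y_val, role="validation")
                if len(y_val) >= 3
                else FitReport(
                    100.0 * np.sqrt(np.mean((pred_val - y_val) ** 2)) / y_val.mean(),
                    0.0, role="validation", n=len(y_val))
            )
            train_report = fit_metrics(pred_train, self.y[~mask], role="training")
            fold_fits.append((i, res, train_report, val_report))
        best = min(
            fold_fits,
            key=lambda f: (f[3].rmse_percent, -f[3].r_squared, f[0]),
        )
        i, res, train_report, val_report = best
        pooled_pred = res.model.predict(self.X)
        pooled = fit_metrics(pooled_pred, self.y, role="pooled")
        return KFoldSelection(
            model=self,
            results=res,
            fold_index=i,
            k=k,
            seed=seed,
            training_report=train_report,
            validation_report=val_report,
            pooled_report=pooled,
            fold_reports=[(f[0], f[2], f[3]) for f in fold_fits],
        )


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Near-equal folds, each spanning the concentration levels.

    Within every level, row indices are shuffled and dealt round-robin to the
    folds, so each fold covers the working range.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 193]))
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for level in np.unique(y):
        idx = np.flatnonzero(y == level)
        rng.shuffle(idx)
        for j, row in enumerate(idx):
            folds[(j + offset) % k].append(int(row))
        offset += len(idx)  # rotate so small strata spread over folds
    return [np.array(sorted(f), dtype=int) for f in folds]


class NeuralCalibrationResults:
    """Fitted calibration: parameters, diagnostics, prediction, summary."""

    def __init__(self, model: NeuralCalibration, params: ANNModel):
        self.calibration = model
        self.model = params  # the ANNModel parameter bundle
        self.fittedvalues = params.predict(model.X)
        self.resid = self.fittedvalues - model.y
        report = fit_metrics(self.fittedvalues, model.y, role="training")
        self.rmse_percent = report.rmse_percent
        self.rsquared = report.r_squared
        self.training_report = report

    @property
    def params(self) -> ANNModel:
        return self.model

    def predict(self, X) -> np.ndarray:
        return self.model.predict(X)

    def report(self, X, y, role: str = "validation") -> FitReport:
        return fit_metrics(self.model.predict(X), np.asarray(y, dtype=float), role=role)

    def save(self, path: str | Path) -> None:
        self.model.to_json(path)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Neural calibration (1 hidden layer, 3 tanh nodes, no penalty)",
            "=" * 62,
            f"observations: {len(self.calibration.y):4d}    features: {m.n_features}",
            f"training RMSE%: {self.rmse_percent:8.4f}    r²: {self.rsquared:.6f}",
            "",
            "feature m/z      center           scale",
        ]
        for mz, c, s in zip(m.feature_mz, m.input_center, m.input_scale):
            lines.append(f"  {mz:9.1f}  {c:12.4g}  {s:12.4g}")
        lines.append("")
        lines.append("hidden weights (rows H1..H3: bias, then one weight per feature)")
        for row in m.hidden_weights:
            lines.append("  " + "  ".join(f"{w: .4g}" for w in row))
        a, b, mu, const = m.output_weights
        lines.append(f"output: α={a:.6g}  β={b:.6g}  μ={mu:.6g}  constant={const:.6g}")
        return "\n".join(lines)

    def plot_calibration(self, ax=None):
        """Predicted vs actual concentration scatter with the identity line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.calibration.y
        ax.scatter(y, self.fittedvalues, s=12)
        lim = [0, max(y.max(), self.fittedvalues.max()) * 1.05]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("actual concentration (μg mL⁻¹)")
        ax.set_ylabel("predicted concentration (μg mL⁻¹)")
        return ax


@dataclass
class KFoldSelection:
    """Outcome of K-fold model selection: the winning fit plus reports."""

    model: NeuralCalibration
    results: NeuralCalibrationResults
    fold_index: int
    k: int
    seed: int
    training_report: FitReport
    validation_report: FitReport
    pooled_report: FitReport
    fold_reports: list

    def predict(self, X) -> np.ndarray:
        return self.results.predict(X)

    def summary(self) -> str:
        lines = [
            f"K-fold selection (K={self.k}, seed={self.seed}): fold {self.fold_index} selected",
            f"  training   RMSE% {self.training_report.rmse_percent:8.4f}   r² {self.training_report.r_squared:.6f}",
            f"  validation RMSE% {self.validation_report.rmse_percent:8.4f}   r² {self.validation_report.r_squared:.6f}",
            f"  pooled     RMSE% {self.pooled_report.rmse_percent:8.4f}   r² {self.pooled_report.r_squared:.6f}",
        ]
        return "\n".join(lines) + "\n\n" + self.results.summary()


# -- spec-facing functional wrappers ---------------------------------------

def train_ann(X, y, seed: int = 0, n_restarts: int = 20, feature_mz=None) -> ANNModel:
    """Fit the calibration network and return its parameter bundle."""
    return NeuralCalibration(X, y, feature_mz=feature_mz).fit(
        seed=seed, n_restarts=n_restarts
    ).model


def kfold_select(X, y, k: int = 5, seed: int = 0, n_restarts: int = 20,
                 feature_mz=None) -> tuple[ANNModel, FitReport, FitReport]:
    """K-fold selection returning (model, training report, validation report)."""
    sel = NeuralCalibration(X, y, feature_mz=feature_mz).fit_kfold(
        k=k, seed=seed, n_restarts=n_restarts
    )
    return sel.results.model, sel.training_report, sel.validation_report
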