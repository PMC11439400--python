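"""Class-confidence to continuous-FNU regression.

The classifier emits, per image, confidences x1..x11 over the 11 FNU
classes (top-5 truncated, blanks zero-filled). A multiple linear
regression of the measured turbidity on those confidences,

    y = b0 + b1*x1 + ... + b11*x11,

fitted by weighted least squares, converts the ordinal output into a
continuous FNU estimate. Because each confidence vector concentrates
near its true class, the fitted class coefficients increase with class
index — each coefficient plays the role of (class-typical FNU − b0).

The default WLS weights are 1/max(y, 0.5 FNU), equalizing *relative*
error across the 0-55 range: an error of 2 FNU matters far more in
near-potable water at 1 FNU than in a sediment plume at 50 FNU, which
is also why the evaluation module prefers RRMSE over RMSE. Unit weights
(ordinary least squares) are available via ``weight_rule="unit"``.

A set of published reference coefficients ships with the package
(``load_published``) so predictions can be made without retraining.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from seston.classify import ConfidenceVector

N_CLASSES = 11


def _weights_for(y: np.ndarray, rule: str) -> np.ndarray:
    if rule == "unit":
        return np.ones_like(y)
    if rule == "inverse_fnu":
        return 1.0 / np.maximum(y, 0.5)
    raise ValueError(f"unknown weight_rule {rule!r}")


class ConfidenceRegression:
    """Model: measured FNU regressed on 11 class confidences (WLS).

    Parameters
    ----------
    y : array (n,)
        Measured turbidity in FNU.
    X : array (n, 11)
        Confidence design matrix, entries in [0, 1]; an intercept is
        added internally.
    weights : array (n,), optional
        Positive WLS weights. When omitted, derived from
        ``weight_rule``.
    weight_rule : str
        ``"inverse_fnu"`` (default, weights 1/max(y, 0.5)) or
        ``"unit"`` (ordinary least squares).
    """

    def __init__(self, y, X, weights=None, weight_rule: str = "inverse_fnu"):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_CLASSES:
            raise ValueError(f"X must be n x {N_CLASSES}, got shape {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValueError("y length must match X rows")
        if X.shape[0] <= N_CLASSES + 1:
            raise ValueError(f"need more than {N_CLASSES + 1} observations, got {X.shape[0]}")
        if X.min() < 0.0 or X.max() > 1.0:
            raise ValueError("confidence entries must lie in [0, 1]")
        if weights is None:
            weights = _weights_for(y, weight_rule)
        else:
            weights = np.asarray(weights, dtype=float)
            weight_rule = "explicit"
        if weights.shape != y.shape or np.any(weights <= 0):
            raise ValueError("weights must be positive and match y in length")
        self.y = y
        self.X = X
        self.weights = weights
        self.weight_rule = weight_rule

    @classmethod
    def from_confidences(
        cls, vectors: list[ConfidenceVector], y, **kwargs
    ) -> "ConfidenceRegression":
        """Assemble the design matrix from confidence vectors.

        Vectors with fewer than 5 reported classes are already
        zero-filled by construction; any missing entries are treated as
        0 confidence.
        """
        X = np.vstack([np.asarray(v.x, dtype=float) for v in vectors])
        return cls(np.asarray(y, dtype=float), X, **kwargs)

    def fit(self) -> "RegressionResults":
        """Weighted least squares fit; returns a results object.

        The solution equals the closed-form weighted normal equations
        ``(X'WX)^{-1} X'Wy`` (with intercept column prepended). A
        rank-deficient design raises with the offending columns named.
        """
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            # name collinear confidence columns by testing rank drop
            bad = []
            for j in range(self.X.shape[1]):
                reduced = np.delete(self.X, j, axis=1)
                if np.linalg.matrix_rank(reduced) == rank:
                    bad.append(f"x{j + 1}")
            raise ValueError(
                "rank-deficient confidence design; collinear columns: " + ", ".join(bad)
            )
        # note: a complete one-hot design makes the intercept collinear
        # with the confidence columns; statsmodels' pinv solve handles
        # that (minimum-norm coefficients, exact-fit predictions)
        design = sm.add_constant(self.X, has_constant="add")
        res = sm.WLS(self.y, design, weights=self.weights).fit()
        return RegressionResults(self, res)


@dataclass
class RegressionResults:
    """Fitted confidence-regression: coefficients, uncertainty, diagnostics."""

    model: "ConfidenceRegression"
    _sm_results: object

    @property
    def beta0(self) -> float:
        return float(self._sm_results.params[0])

    @property
    def beta(self) -> np.ndarray:
        """The 11 class coefficients, in class-index order (FNU per unit
        confidence)."""
        return np.asarray(self._sm_results.params[1:])

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self._sm_results.bse)

    @property
    def conf_int(self) -> np.ndarray:
        return np.asarray(self._sm_results.conf_int())

    @property
    def diagnostics(self) -> dict:
        res = self._sm_results
        y = self.model.y
        resid = y - self.predict_matrix(self.model.X)
        rmse = float(np.sqrt(np.mean(resid**2)))
        mean_y = float(np.mean(y))
        rrmse = 100.0 * rmse / mean_y if mean_y != 0 else float("nan")
        return {
            "r2": float(res.rsquared),
            "adj_r2": float(res.rsquared_adj),
            "rmse": rmse,
            "rrmse": rrmse,
            "n_obs": int(res.nobs),
            "df_model": int(res.df_model),
            "df_resid": int(res.df_resid),
            "weight_rule": self.model.weight_rule,
        }

    def predict_matrix(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.beta0 + X @ self.beta

    def predict(self, v, clamp: bool = False) -> float:
        """FNU estimate for one confidence vector (11 entries)."""
        return predict_fnu(self, v, clamp=clamp)

    def summary(self) -> str:
        """Human-readable coefficient table with diagnostics."""
        d = self.diagnostics
        lines = [
            "Confidence-to-FNU weighted least squares",
            f"  n_obs {d['n_obs']}  df_model {d['df_model']}  df_resid {d['df_resid']}",
            f"  adj R2 {d['adj_r2']:.3f}  RMSE {d['rmse']:.3f} FNU  RRMSE {d['rrmse']:.2f}%",
            f"  weights: {d['weight_rule']}",
            "",
            f"  {'term':>10} {'coef':>9} {'std err':>9} {'[0.025':>9} {'0.975]':>9}",
        ]
        ci = self.conf_int
        names = ["const"] + [f"x{i}" for i in range(1, 12)]
        params = self._sm_results.params
        for i, name in enumerate(names):
            lines.append(
                f"  {name:>10} {params[i]:9.2f} {self.bse[i]:9.2f} {ci[i, 0]:9.2f} {ci[i, 1]:9.2f}"
            )
        return "\n".join(lines)


class PublishedModel:
    """Reference coefficients loaded from the bundled table.

    Quacks like :class:`RegressionResults` for prediction: has
    ``beta0``, ``beta`` and ``predict``. Carries no fit diagnostics —
    those belong to the dataset the coefficients were estimated on.
    """

    def __init__(self, beta0: float, beta: np.ndarray, table: pd.DataFrame):
        self.beta0 = float(beta0)
        self.beta = np.asarray(beta, dtype=float)
        self.table = table
        if self.beta.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} class coefficients, got {self.beta.shape}")
        if np.any(np.diff(self.beta) <= 0):
            raise ValueError("class coefficients must be strictly increasing with class index")

    def predict(self, v, clamp: bool = False) -> float:
        return predict_fnu(self, v, clamp=clamp)

    def predict_matrix(self, X) -> np.ndarray:
        return self.beta0 + np.asarray(X, dtype=float) @ self.beta


def load_published(path=None) -> PublishedModel:
    """Load the bundled (or a user-supplied) coefficient table.

    The table has 12 rows (intercept + 11 classes) and the class
    coefficients must increase strictly with class index; a tampered or
    truncated file raises ``ValueError``.
    """
    if path is None:
        ref = importlib.resources.files("seston").joinpath("data/published_coefficients.tsv")
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, sep="\t", comment="#", header=None,
                                names=["class_label", "coefficient", "std_err", "ci_lower", "ci_upper"])
    else:
        table = pd.read_csv(path, sep="\t", comment="#", header=None,
                            names=["class_label", "coefficient", "std_err", "ci_lower", "ci_upper"])
    if len(table) != N_CLASSES + 1:
        raise ValueError(f"coefficient table must have {N_CLASSES + 1} rows, got {len(table)}")
    if table.iloc[0]["class_label"] != "Intercept":
        raise ValueError("first row of coefficient table must be the intercept")
    beta0 = float(table.iloc[0]["coefficient"])
    beta = table.iloc[1:]["coefficient"].to_numpy(dtype=float)
    return PublishedModel(beta0, beta, table)


def predict_fnu(model, v, clamp: bool = False) -> float:
    """Continuous FNU estimate ``b0 + sum_i b_i x_i`` for one vector.

    ``model`` is anything exposing ``beta0`` and ``beta`` (a fit result
    or the published model). With ``clamp=True`` the raw affine output
    is clipped to the instrument range [0, 55] — the end-user-facing
    convention; the library default leaves it raw for analysis.
    """
    x = np.asarray(v.x if isinstance(v, ConfidenceVector) else v, dtype=float)
    if x.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} confidences, got shape {x.shape}")
    est = float(model.beta0 + x @ np.asarray(model.beta))
    if clamp:
        est = float(np.clip(est, 0.0, 55.0))
    return est


def fit_wls(X, y, weights=None, weight_rule: str = "inverse_fnu") -> RegressionResults:
    """Functional wrapper: fit the confidence regression by WLS."""
    return ConfidenceRegression(y, X, weights=weights, weight_rule=weight_rule).fit()
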