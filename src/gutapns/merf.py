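"""Mixed-effect random forest (MERF) for clustered longitudinal outcomes.

The model is

    y_ij = f(x_ij) + b_i + e_ij,     b_i ~ N(0, sigma2_b),  e_ij ~ N(0, sigma2_e)

with a regression forest for the fixed part f and a random intercept b_i
per cluster (here: per subject, whose repeated outcome measurements share
one microbiome profile). Estimation alternates, EM-style:

1. fit the forest on the de-biased responses y_ij - b_i;
2. BLUP the intercepts given the forest: with V_i = sigma2_b·J + sigma2_e·I,
   b_i = sigma2_b · 1' V_i^{-1} (y_i - f(X_i));
3. update the variance components with the standard EM formulas,
   sigma2_e <- (1/N) sum_i [ e_i'e_i + sigma2_e (n_i - sigma2_e tr V_i^{-1}) ]
   sigma2_b <- (1/q) sum_i [ b_i^2 + sigma2_b (1 - sigma2_b 1'V_i^{-1}1) ]
   where e_i = y_i - f(X_i) - b_i;
4. monitor the generalized log-likelihood (GLL)
   sum_i [ e_i'e_i/sigma2_e + b_i^2/sigma2_b + n_i log sigma2_e + log sigma2_b ]
   and stop when its relative change drops below ``tol``.

All V_i operations use the rank-one structure in closed form, so a full
fit costs one forest fit per iteration plus O(N) bookkeeping.

The class follows the statsmodels construction idiom:
``MERF(endog, exog, groups).fit()`` returns a :class:`MERFResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor

__all__ = ["MERF", "MERFResults", "generalized_log_likelihood"]


def generalized_log_likelihood(
    residuals_by_cluster: list[np.ndarray],
    b: np.ndarray,
    sigma2_e: float,
    sigma2_b: float,
) -> float:
    """GLL criterion (up to additive constants); lower is better.

    ``residuals_by_cluster`` holds e_i = y_i - f(X_i) - b_i per cluster.
    When sigma2_b is zero the intercept penalty and its log term are
    omitted (the degenerate no-random-effect limit).
    """
    gll = 0.0
    for e_i, b_i in zip(residuals_by_cluster, b):
        n_i = len(e_i)
        gll += float(e_i @ e_i) / sigma2_e + n_i * math.log(sigma2_e)
        if sigma2_b > 0:
            gll += b_i * b_i / sigma2_b + math.log(sigma2_b)
    return gll


class MERF:
    """Mixed-effect random forest model for a continuous clustered outcome.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Outcome vector.
    exog : DataFrame or array, shape (n, p)
        Feature matrix for the forest (abundances plus covariates).
    groups : array-like, shape (n,)
        Cluster label per row (subject id).
    n_estimators, min_samples_leaf : int
        Forest size and leaf regularization.
    max_features : {"third", "sqrt", ...} or int or float
        Features tried per split; ``"third"`` means ceil(p/3), the
        classical regression-forest heuristic.
    max_iter, tol : EM iteration cap and relative-GLL stopping tolerance.
    random_state : seed for the forest.
    base_learner : optional fitted-API regressor replacing the forest
        (used e.g. to cross-check variance components against a linear
        mixed model).
    """

    def __init__(
        self,
        endog,
        exog,
        groups,
        *,
        n_estimators: int = 300,
        max_features: str | int | float = "third",
        min_samples_leaf: int = 3,
        max_iter: int = 50,
        tol: float = 1e-4,
        random_state: int | None = None,
        base_learner: Any = None,
    ) -> None:
        if isinstance(exog, pd.DataFrame):
            self.feature_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            self.feature_names = [f"x{j}" for j in range(X.shape[1])]
        y = np.asarray(endog, dtype=float).ravel()
        groups = np.asarray(groups)
        if not (len(y) == len(X) == len(groups)):
            raise ValueError("endog, exog and groups must have equal length")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in endog")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in exog")
        labels, codes = np.unique(groups, return_inverse=True)
        if len(labels) < 2:
            raise ValueError("need at least 2 clusters to separate the intercept variance")
        if len(y) < 2:
            raise ValueError("need at least 2 rows")
        self.endog = y
        self.exog = X
        self.group_labels = labels
        self.group_codes = codes
        self.hyperparams = {
            "n_estimators": n_estimators,
            "max_features": max_features,
            "min_samples_leaf": min_samples_leaf,
            "max_iter": max_iter,
            "tol": tol,
            "random_state": random_state,
        }
        self.base_learner = base_learner

    # -- EM fit ------------------------------------------------------------

    def _make_learner(self):
        if self.base_learner is not None:
            return clone(self.base_learner)
        hp = self.hyperparams
        max_features = hp["max_features"]
        if max_features == "third":
            max_features = max(1, math.ceil(self.exog.shape[1] / 3))
        return RandomForestRegressor(
            n_estimators=hp["n_estimators"],
            max_features=max_features,
            min_samples_leaf=hp["min_samples_leaf"],
            random_state=hp["random_state"],
            n_jobs=1,
        )

    def fit(self) -> "MERFResults":
        y, X, codes = self.endog, self.exog, self.group_codes
        q = len(self.group_labels)
        n_i = np.bincount(codes, minlength=q).astype(float)
        N = float(len(y))
        hp = self.hyperparams
        max_iter, tol = hp["max_iter"], hp["tol"]

        b = np.zeros(q)
        sigma2_e, sigma2_b = 1.0, 1.0
        gll_trace: list[float] = []
        converged = False
        learner = None

        for _ in range(max_iter):
            # (i) forest on de-biased responses
            learner = self._make_learner()
            learner.fit(X, y - b[codes])
            f = learner.predict(X)
            resid = y - f  # y_i - f(X_i), before subtracting b

            # (ii) BLUP via the rank-one identity:
            # 1'V_i^{-1} r_i = (sum r_i) / (sigma2_e + n_i sigma2_b)
            sum_resid = np.bincount(codes, weights=resid, minlength=q)
            denom = sigma2_e + n_i * sigma2_b
            b = sigma2_b * sum_resid / denom

            # (iii) EM variance updates
            eps = resid - b[codes]
            sse = np.bincount(codes, weights=eps * eps, minlength=q)
            # tr V_i^{-1} = n_i/sigma2_e - n_i sigma2_b / (sigma2_e * denom)
            tr_vinv = n_i / sigma2_e - n_i * sigma2_b / (sigma2_e * denom)
            new_sigma2_e = float(np.sum(sse + sigma2_e * (n_i - sigma2_e * tr_vinv)) / N)
            # 1'V_i^{-1}1 = n_i / denom
            new_sigma2_b = float(
                np.sum(b * b + sigma2_b * (1.0 - sigma2_b * n_i / denom)) / q
            )
            sigma2_e = max(new_sigma2_e, 1e-12)
            sigma2_b = max(new_sigma2_b, 0.0)

            # (iv) GLL and stopping
            resid_by_cluster = [eps[codes == i] for i in range(q)]
            gll = generalized_log_likelihood(resid_by_cluster, b, sigma2_e, sigma2_b)
            gll_trace.append(gll)
            if len(gll_trace) >= 2:
                prev = gll_trace[-2]
                if abs(gll - prev) / max(abs(gll), 1e-12) < tol:
                    converged = True
                    break

        return MERFResults(
            model=self,
            learner=learner,
            b_hat=pd.Series(b, index=self.group_labels, name="b_hat"),
            sigma2_e=sigma2_e,
            sigma2_b=sigma2_b,
            gll_trace=np.asarray(gll_trace),
            n_iter=len(gll_trace),
            converged=converged,
        )


@dataclass
class MERFResults:
    """Fitted MERF: forest, per-cluster intercepts and variance components."""

    model: MERF = field(repr=False)
    learner: Any = field(repr=False)
    b_hat: pd.Series
    sigma2_e: float
    sigma2_b: float
    gll_trace: np.ndarray
    n_iter: int
    converged: bool

    # -- prediction --------------------------------------------------------

    def predict(self, exog, groups=None) -> np.ndarray:
        """f(X) plus the cluster intercept where the cluster was seen in training.

        Unseen clusters (or ``groups=None``) get the population-level
        forest prediction alone.
        """
        if isinstance(exog, pd.DataFrame):
            if list(exog.columns) != self.model.feature_names:
                raise ValueError("exog columns do not match training features")
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            if X.shape[1] != len(self.model.feature_names):
                raise ValueError(
                    f"expected {len(self.model.feature_names)} features, got {X.shape[1]}"
                )
        pred = self.learner.predict(X)
        if groups is not None:
            offset = self.b_hat.reindex(np.asarray(groups)).fillna(0.0).to_numpy()
            pred = pred + offset
        return pred

    def gll(self, exog, groups, endog) -> float:
        """Evaluate the GLL criterion on (possibly new) clustered data."""
        y = np.asarray(endog, dtype=float)
        groups = np.asarray(groups)
        f = self.predict(exog)  # fixed part only
        labels = np.unique(groups)
        resid_by_cluster = []
        b = []
        for lab in labels:
            mask = groups == lab
            b_i = float(self.b_hat.get(lab, 0.0))
            resid_by_cluster.append(y[mask] - f[mask] - b_i)
            b.append(b_i)
        return generalized_log_likelihood(
            resid_by_cluster, np.asarray(b), self.sigma2_e, self.sigma2_b
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Mixed-Effect Random Forest Results",
            "=" * 44,
            f"No. observations:        {len(self.model.endog)}",
            f"No. clusters:            {len(self.b_hat)}",
            f"No. features:            {len(self.model.feature_names)}",
            f"EM iterations:           {self.n_iter}",
            f"Converged:               {self.converged}",
            f"Residual var sigma2_e:   {self.sigma2_e:.6g}",
            f"Intercept var sigma2_b:  {self.sigma2_b:.6g}",
            f"Final GLL:               {self.gll_trace[-1]:.6g}",
            "=" * 44,
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Serialize results (forest included) to a single joblib archive."""
        path = Path(path)
        payload = {
            "feature_names": self.model.feature_names,
            "hyperparams": self.model.hyperparams,
            "learner": self.learner,
            "b_hat": self.b_hat,
            "sigma2_e": self.sigma2_e,
            "sigma2_b": self.sigma2_b,
            "gll_trace": self.gll_trace,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        joblib.dump(payload, path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MERFResults":
        payload = joblib.load(path)

        class _Stub:  # minimal model surface for prediction
            feature_names = payload["feature_names"]
            hyperparams = payload["hyperparams"]
            endog = np.array([])

        return cls(
            model=_Stub(),
            learner=payload["learner"],
            b_hat=payload["b_hat"],
            sigma2_e=payload["sigma2_e"],
            sigma2_b=payload["sigma2_b"],
            gll_trace=payload["gll_trace"],
            n_iter=payload["n_iter"],
            converged=payload["converged"],
        )
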