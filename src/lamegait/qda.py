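"""Quadratic discriminant analysis over a selected feature subset.

Each behaviour class k is modelled as a multivariate Gaussian with its own
mean vector mu_k, covariance Sigma_k (sample covariance, n_k - 1
denominator, plus a small trace-scaled diagonal shrinkage for
conditioning), and prior pi_k (training frequency by default).  A point v
is assigned to the class maximising the quadratic discriminant

    delta_k(v) = -1/2 ln det Sigma_k
                 - 1/2 (v - mu_k)^T Sigma_k^{-1} (v - mu_k)
                 + ln pi_k

evaluated in the log domain via Cholesky factorisation; posteriors are the
softmax of the delta_k.  Ties are broken by class order.  No feature
standardisation is applied: QDA is equivariant under common affine maps of
the feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .features import FEATURE_NAMES


class GaussianQDA:
    """Quadratic discriminant classifier with class-specific covariances.

    Parameters
    ----------
    shrinkage : float
        Diagonal regularisation weight: ``shrinkage * trace(S)/d`` is added
        to the diagonal of each class covariance (default 1e-6).  Static
        behaviours can yield near-singular covariances; the shrinkage keeps
        every class density proper.
    priors : {'empirical', 'uniform'}
        Class priors from training frequencies or flat.

    Attributes
    ----------
    classes_ : ndarray of class labels, in sorted order.
    means_ : (K, d) per-class means.
    covariances_ : (K, d, d) regularised per-class covariances.
    priors_ : (K,) class priors, summing to 1.
    feature_names_ : list of str, when fitted from a DataFrame.
    """

    def __init__(self, shrinkage: float = 1e-6, priors: str = "empirical"):
        self.shrinkage = shrinkage
        self.priors = priors

    def get_params(self, deep: bool = True) -> dict:
        return {"shrinkage": self.shrinkage, "priors": self.priors}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        if self.priors not in ("empirical", "uniform"):
            raise ValueError("priors must be 'empirical' or 'uniform'")
        if self.shrinkage < 0:
            raise ValueError("shrinkage must be >= 0")
        feature_names = None
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("X must be 2-dimensional with >= 1 feature")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        y = np.asarray(y)
        n, d = X.shape
        classes, y_enc = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_enc)
        if np.any(counts < 2):
            bad = classes[counts < 2]
            raise ValueError(
                f"every class needs >= 2 training rows to estimate a "
                f"covariance; too few for {bad}")
        if np.any(counts <= d) and self.shrinkage == 0:
            bad = classes[counts <= d]
            raise ValueError(
                f"classes {bad} have <= {d} rows, giving singular "
                "covariances; use shrinkage > 0 or more data")
        K = classes.size
        means = np.empty((K, d))
        covs = np.empty((K, d, d))
        for k in range(K):
            Xk = X[y_enc == k]
            means[k] = Xk.mean(axis=0)
            S = np.cov(Xk, rowvar=False, ddof=1).reshape(d, d)
            if self.shrinkage > 0:
                # trace-scaled ridge; unit scale for an all-constant class
                tr = np.trace(S)
                ridge = self.shrinkage * (tr / d if tr > 0 else 1.0)
                S = S + ridge * np.eye(d)
            covs[k] = S
        if self.priors == "uniform":
            pri = np.full(K, 1.0 / K)
        else:
            pri = counts / n
        self.classes_ = classes
        self.means_ = means
        self.covariances_ = covs
        self.priors_ = pri
        self.feature_names_ = feature_names
        # pre-factorise for prediction
        self._chol_ = [linalg.cho_factor(covs[k], lower=True) for k in range(K)]
        self._logdet_ = np.array(
            [2.0 * np.sum(np.log(np.diag(c[0]))) for c in self._chol_])
        return self

    def _check_fitted(self):
        if not hasattr(self, "classes_"):
            raise RuntimeError("classifier not fitted")

    def decision_function(self, X) -> np.ndarray:
        """Quadratic discriminant scores delta_k(v), shape (n, K)."""
        self._check_fitted()
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = self.means_.shape[1]
        if X.shape[1] != d:
            raise ValueError(
                f"feature dimension mismatch: got {X.shape[1]}, model has {d}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        K = self.classes_.size
        delta = np.empty((X.shape[0], K))
        for k in range(K):
            diff = X - self.means_[k]
            solved = linalg.cho_solve(self._chol_[k], diff.T).T
            maha = np.sum(diff * solved, axis=1)
            delta[:, k] = (-0.5 * self._logdet_[k] - 0.5 * maha
                           + np.log(self.priors_[k]))
        return delta

    def predict(self, X) -> np.ndarray:
        delta = self.decision_function(X)
        return self.classes_[np.argmax(delta, axis=1)]  # argmax: first of ties

    def predict_proba(self, X) -> np.ndarray:
        delta = self.decision_function(X)
        delta = delta - delta.max(axis=1, keepdims=True)
        expd = np.exp(delta)
        return expd / expd.sum(axis=1, keepdims=True)


def fit_qda(matrix: pd.DataFrame, feature_subset: list[str],
            shrinkage: float = 1e-6, priors: str = "empirical") -> GaussianQDA:
    """Fit QDA on the given feature columns of a labelled feature matrix."""
    if not feature_subset:
        raise ValueError("feature_subset must be non-empty")
    missing = [f for f in feature_subset if f not in matrix.columns]
    if missing:
        raise ValueError(f"feature matrix missing columns {missing}")
    if "behaviour" not in matrix.columns:
        raise ValueError("feature matrix missing 'behaviour' label column")
    model = GaussianQDA(shrinkage=shrinkage, priors=priors)
    return model.fit(matrix.loc[:, feature_subset], matrix["behaviour"].to_numpy())


def predict_qda(model: GaussianQDA, features) -> tuple:
    """Classify one feature vector; returns (label, posterior vector)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[0] != 1:
        raise ValueError("predict_qda expects a single feature vector")
    label = model.predict(features)[0]
    posterior = model.predict_proba(features)[0]
    return label, posterior


def model_to_json(model: GaussianQDA) -> str:
    model._check_fitted()
    return json.dumps(
        {
            "classes": [str(c) for c in model.classes_],
            "feature_names": model.feature_names_,
            "means": model.means_.tolist(),
            "covariances": model.covariances_.tolist(),
            "priors": model.priors_.tolist(),
            "shrinkage": model.shrinkage,
        },
        indent=2,
    )


def model_from_json(doc: str) -> GaussianQDA:
    data = json.loads(doc)
    model = GaussianQDA(shrinkage=data["shrinkage"])
    model.classes_ = np.array(data["classes"])
    model.means_ = np.array(data["means"], dtype=float)
    model.covariances_ = np.array(data["covariances"], dtype=float)
    model.priors_ = np.array(data["priors"], dtype=float)
    model.feature_names_ = data["feature_names"]
    model._chol_ = [linalg.cho_factor(c, lower=True) for c in model.covariances_]
    model._logdet_ = np.array(
        [2.0 * np.sum(np.log(np.diag(c[0]))) for c in model._chol_])
    return model
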