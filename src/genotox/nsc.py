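"""Nearest shrunken centroids (NSC) classification.

The probability analysis (PA) arm of the TGx-DDI classifier.  For each
gene j and class k the standardized centroid difference is

    d_kj = (xbar_kj - xbar_j) / (m_k * (s_j + s0)),

with xbar_j the overall centroid, xbar_kj the class centroid, s_j the
pooled within-class standard deviation, s0 the median of the s_j (a fudge
factor guarding against near-zero denominators) and
m_k = sqrt(1/n_k - 1/n).  Soft-thresholding by the shrinkage parameter
Delta,

    d'_kj = sign(d_kj) * max(|d_kj| - Delta, 0),

moves each class centroid toward the overall centroid,
xbar'_kj = xbar_j + m_k (s_j + s0) d'_kj, zeroing out genes that do not
discriminate.  A sample x is scored by the discriminant

    delta_k(x) = sum_j (x_j - xbar'_kj)^2 / (s_j + s0)^2  -  2 ln pi_k,

and the class posterior is the softmax of -delta_k / 2.  A condition is
called for a class only when its posterior reaches the probability
threshold (0.90 by default); otherwise the call is indeterminate, which
the downstream vote treats as non-positive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .containers import INDETERMINATE, TrainingSet


class NSCClassifier(ClassifierMixin, BaseEstimator):
    """Nearest shrunken centroids with posterior-probability calls.

    Parameters
    ----------
    delta : float, default 0.0
        Shrinkage threshold applied to the standardized centroid
        differences.  ``delta=0`` reproduces plain nearest (standardized)
        centroids; large deltas collapse both centroids onto the overall
        centroid and the posteriors reduce to the priors.
    priors : {"proportions", "uniform"} or dict, default "proportions"
        Class prior probabilities pi_k.
    threshold : float, default 0.90
        Posterior required before `call` commits to a class.
    """

    def __init__(self, delta: float = 0.0, priors="proportions",
                 threshold: float = 0.90):
        self.delta = delta
        self.priors = priors
        self.threshold = threshold

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y):
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        X_arr, feature_names = _as_matrix(X)
        y_arr = np.asarray(y)
        if X_arr.shape[0] != y_arr.shape[0]:
            raise ValueError("X and y length mismatch")

        classes, inverse, counts = np.unique(y_arr, return_inverse=True,
                                             return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        if (counts < 2).any():
            small = {str(c): int(n) for c, n in zip(classes, counts) if n < 2}
            raise ValueError(f"classes with < 2 members: {small}")

        n, p = X_arr.shape
        overall = X_arr.mean(axis=0)
        centroids = np.vstack([X_arr[inverse == k].mean(axis=0)
                               for k in range(len(classes))])

        within_ss = np.zeros(p)
        for k in range(len(classes)):
            resid = X_arr[inverse == k] - centroids[k]
            within_ss += (resid ** 2).sum(axis=0)
        pooled_sd = np.sqrt(within_ss / (n - len(classes)))
        s0 = float(np.median(pooled_sd))
        denom_sd = pooled_sd + s0
        if np.any(denom_sd == 0.0):
            raise ValueError(
                "pooled within-class sd and fudge factor are both zero; "
                "cannot standardize centroid differences")

        m = np.sqrt(1.0 / counts - 1.0 / n)
        d = (centroids - overall) / (m[:, None] * denom_sd)
        d_shrunk = np.sign(d) * np.maximum(np.abs(d) - self.delta, 0.0)
        shrunken = overall + m[:, None] * denom_sd * d_shrunk

        self.classes_ = classes
        self.class_counts_ = counts
        self.centroid_overall_ = overall
        self.centroids_ = centroids
        self.pooled_sd_ = pooled_sd
        self.s0_ = s0
        self.m_ = m
        self.d_ = d
        self.d_shrunk_ = d_shrunk
        self.shrunken_centroids_ = shrunken
        self.priors_ = self._resolve_priors(classes, counts, n)
        self.n_features_in_ = p
        if feature_names is not None:
            self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        return self

    def _resolve_priors(self, classes, counts, n) -> np.ndarray:
        if isinstance(self.priors, str):
            if self.priors == "proportions":
                pri = counts / n
            elif self.priors == "uniform":
                pri = np.full(len(classes), 1.0 / len(classes))
            else:
                raise ValueError(f"unknown priors spec {self.priors!r}")
        else:
            pri = np.array([self.priors[c] for c in classes], float)
        total = pri.sum()
        if not np.isclose(total, 1.0):
            raise ValueError(f"priors must sum to 1, got {total}")
        return pri

    # -- scoring ----------------------------------------------------------
    def _validate_X(self, X) -> np.ndarray:
        check_is_fitted(self, "shrunken_centroids_")
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                want = set(self.feature_names_in_)
                have = set(X.columns)
                if want != have:
                    raise ValueError(
                        "gene panel mismatch; missing="
                        f"{sorted(want - have)[:5]} extra={sorted(have - want)[:5]}")
                X = X[list(self.feature_names_in_)]
            X = X.to_numpy(float)
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} genes, got {X.shape[1]}")
        return X

    def discriminants(self, X) -> np.ndarray:
        """delta_k(x) per sample and class (lower = closer)."""
        X = self._validate_X(X)
        denom = (self.pooled_sd_ + self.s0_) ** 2
        out = np.empty((X.shape[0], len(self.classes_)))
        for k in range(len(self.classes_)):
            diff = X - self.shrunken_centroids_[k]
            out[:, k] = (diff ** 2 / denom).sum(axis=1) - 2.0 * np.log(
                self.priors_[k])
        return out

    def predict_proba(self, X) -> np.ndarray:
        """Class posteriors: softmax of -delta_k/2 with max-shift stability."""
        disc = self.discriminants(X)
        z = -0.5 * disc
        z -= z.max(axis=1, keepdims=True)
        expz = np.exp(z)
        return expz / expz.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        disc = self.discriminants(X)
        return self.classes_[np.argmin(disc, axis=1)]

    def call(self, X) -> np.ndarray:
        """Thresholded call: the max-posterior class when its posterior
        reaches the threshold, else ``indeterminate``."""
        proba = self.predict_proba(X)
        best = np.argmax(proba, axis=1)
        calls = self.classes_[best].astype(object)
        calls[proba[np.arange(len(best)), best] < self.threshold] = INDETERMINATE
        return calls


# ---------------------------------------------------------------------------
# module-level wrappers used by the pipeline


def train_nsc(training: TrainingSet, delta: float,
              priors="proportions", threshold: float = 0.90) -> NSCClassifier:
    """Fit an `NSCClassifier` on a validated training set."""
    model = NSCClassifier(delta=delta, priors=priors, threshold=threshold)
    return model.fit(training.X, training.y)


def nsc_classify(model: NSCClassifier, profile) -> tuple[str, float]:
    """Classify one biomarker profile; returns (call, P(first class...)).

    ``profile`` may be a `GeneExpressionProfile`, a pandas Series over the
    gene panel, or a plain vector in panel order.  The returned probability
    is the posterior of the class the model's `classes_` lists first that
    is positive-by-convention ("DDI" when present).
    """
    x = _profile_vector(model, profile)
    call = str(model.call(x)[0])
    proba = model.predict_proba(x)[0]
    pos = _positive_index(model.classes_)
    return call, float(proba[pos])


def select_delta_loocv(training: TrainingSet, grid=None,
                       priors="proportions") -> float:
    """Choose the shrinkage Delta by leave-one-chemical-out accuracy.

    Deterministic: evaluates every Delta on the grid by a full LOO pass and
    returns the smallest Delta among the accuracy ties.
    """
    if grid is None:
        grid = np.arange(0.0, 6.01, 0.25)
    grid = np.asarray(list(grid), float)
    if len(grid) == 0 or (grid < 0).any():
        raise ValueError("delta grid must be non-empty with values >= 0")

    X, y = training.X, training.y
    best_delta, best_acc = None, -1.0
    for delta in np.sort(grid):
        correct = total = 0
        for held in X.index:
            X_fit = X.drop(index=held)
            y_fit = y.drop(index=held)
            if y_fit.nunique() < 2 or (y_fit.value_counts() < 2).any():
                warnings.warn(f"LOO fold {held!r} skipped: degenerate classes",
                              stacklevel=2)
                continue
            model = NSCClassifier(delta=float(delta), priors=priors)
            model.fit(X_fit, y_fit)
            pred = model.predict(X.loc[[held]])[0]
            correct += int(pred == y.loc[held])
            total += 1
        acc = correct / total if total else 0.0
        if acc > best_acc + 1e-12:
            best_acc, best_delta = acc, float(delta)
    return best_delta


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    return np.asarray(X, float), None


def _positive_index(classes: np.ndarray) -> int:
    matches = np.flatnonzero(classes == "DDI")
    return int(matches[0]) if len(matches) else 0


def _profile_vector(model, profile):
    from .containers import GeneExpressionProfile

    if isinstance(profile, GeneExpressionProfile):
        profile = profile.log2fc
    if isinstance(profile, pd.Series):
        return profile.to_frame().T
    return np.atleast_2d(np.asarray(profile, float))
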