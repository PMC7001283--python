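"""Hierarchical-clustering branch classification (the "2DC" arm).

Each test condition is clustered together with the full training set using
Euclidean distances and unweighted average linkage (UPGMA).  Cutting the
dendrogram at the root into its two main branches separates the DDI and
non-DDI reference chemicals; the test condition inherits the majority
training label of the branch it lands in.  Test conditions are clustered
one at a time so that similarity between test conditions can never
influence a call (display and inference are decoupled).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .containers import INDETERMINATE, TrainingSet


class BranchClassifier(BaseEstimator):
    """Main-branch membership against the reference dendrogram.

    ``purity`` of a call is the fraction of the co-clustered training
    chemicals sharing the majority label; a root cut that isolates the test
    profile with no training members yields an indeterminate call.
    """

    def __init__(self, method: str = "average", metric: str = "euclidean"):
        self.method = method
        self.metric = metric

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X_arr = X.to_numpy(float)
        else:
            X_arr = np.asarray(X, float)
        if X_arr.shape[0] < 2:
            raise ValueError("need at least two training profiles")
        self.X_ = X_arr
        self.y_ = np.asarray(y)
        self.n_features_in_ = X_arr.shape[1]
        return self

    def _validate_X(self, X) -> np.ndarray:
        check_is_fitted(self, "X_")
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_"):
                want, have = set(self.feature_names_in_), set(X.columns)
                if want != have:
                    raise ValueError(
                        "gene panel mismatch; missing="
                        f"{sorted(want - have)[:5]} extra={sorted(have - want)[:5]}")
                X = X[list(self.feature_names_in_)]
            X = X.to_numpy(float)
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} genes, "
                             f"got {X.shape[1]}")
        return X

    def classify_one(self, x) -> tuple[str, float]:
        """(call, purity) for a single profile clustered with the training set."""
        x = self._validate_X(x)
        if x.shape[0] != 1:
            raise ValueError("classify_one takes a single profile")
        stacked = np.vstack([self.X_, x])
        Z = linkage(stacked, method=self.method, metric=self.metric)
        branches = fcluster(Z, t=2, criterion="maxclust")
        test_branch = branches[-1]
        co_labels = self.y_[branches[:-1] == test_branch]
        if len(co_labels) == 0:
            warnings.warn("test profile isolated at the root cut; "
                          "branch call indeterminate", stacklevel=2)
            return INDETERMINATE, float("nan")
        values, counts = np.unique(co_labels, return_counts=True)
        order = np.lexsort((values, -counts))  # majority, ties alphabetical
        majority = values[order[0]]
        purity = counts[order[0]] / counts.sum()
        return str(majority), float(purity)

    def call(self, X) -> np.ndarray:
        X = self._validate_X(X)
        return np.array([self.classify_one(row[None, :])[0] for row in X],
                        dtype=object)


def hca_classify(training: TrainingSet, profile) -> tuple[str, float]:
    """Branch call and purity for one profile against a training set."""
    from .nsc import _profile_vector

    model = BranchClassifier().fit(training.X, training.y)
    return model.classify_one(_profile_vector(model, profile))
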