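"""PCA-projection classification.

The second arm of the TGx-DDI classifier: principal components are fitted
to the (gene-centered, unscaled) training profiles and test conditions are
projected onto the training loadings.  The first component carries the
DDI / non-DDI separation; the dividing line is drawn at zero on that axis,
with the sign convention that DDI training chemicals score positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .containers import DDI, INDETERMINATE, NON_DDI, TrainingSet


class PCAAxisClassifier(BaseEstimator):
    """Project onto training principal components; call by sign of PC1.

    Centered but not variance-scaled: the biomarker values are log2 ratios
    on a common scale, so scaling would only up-weight noisy genes.
    """

    def __init__(self, positive_class: str = DDI, negative_class: str = NON_DDI):
        self.positive_class = positive_class
        self.negative_class = negative_class

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X_arr = X.to_numpy(float)
        else:
            X_arr = np.asarray(X, float)
        y_arr = np.asarray(y)
        if X_arr.shape[0] < 2:
            raise ValueError("PCA needs at least two training profiles")
        if not (y_arr == self.positive_class).any():
            raise ValueError(f"no {self.positive_class!r} training profiles")

        pca = PCA(svd_solver="full")
        scores = pca.fit_transform(X_arr)
        components = pca.components_.copy()
        # orient PC1 so the positive class sits on the positive side
        if scores[y_arr == self.positive_class, 0].mean() < 0:
            components[0] *= -1.0
            scores[:, 0] *= -1.0

        self.mean_ = pca.mean_
        self.components_ = components
        self.explained_variance_ = pca.explained_variance_
        self.training_scores_ = scores
        self.training_labels_ = y_arr
        self.n_features_in_ = X_arr.shape[1]
        return self

    def _validate_X(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
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

    def transform(self, X) -> np.ndarray:
        """Scores of X on the training components."""
        X = self._validate_X(X)
        return (X - self.mean_) @ self.components_.T

    def decision_function(self, X) -> np.ndarray:
        return self.transform(X)[:, 0]

    def call(self, X) -> np.ndarray:
        """Sign-of-PC1 call; an exact zero score is indeterminate."""
        pc1 = self.decision_function(X)
        calls = np.full(len(pc1), INDETERMINATE, dtype=object)
        calls[pc1 > 0] = self.positive_class
        calls[pc1 < 0] = self.negative_class
        return calls


def pca_fit(training: TrainingSet) -> PCAAxisClassifier:
    """Fit the PCA-projection classifier on a training set."""
    return PCAAxisClassifier().fit(training.X, training.y)


def pca_classify(model: PCAAxisClassifier, profile) -> tuple[str, float]:
    """(call, PC1 score) for one biomarker profile."""
    from .nsc import _profile_vector

    x = _profile_vector(model, profile)
    return str(model.call(x)[0]), float(model.decision_function(x)[0])
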