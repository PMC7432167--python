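"""Applicability-domain definitions behind a single fit/score/decide contract.

Every AD definition is a binary classifier over reactions: ``decide``
returns True for X-inliers.  Score-based methods (leverage, 1-NN distance,
one-class SVM, two-class classifier probability, ensemble variance, GPR
posterior variance) additionally expose a continuous reliability score, and
their decision is a pure function of score and threshold.  Structure-based
methods (bounding box, fragment control, reaction type control) decide
directly.  Zero models (all-in / all-out) and the error-defined perfect
model serve as baselines; composites AND several decisions together.

Model inputs are passed through :class:`ADInputs`, a loose bundle: each
method reads only the fields it needs (the numeric descriptor matrix,
per-reaction signature sets, unseen-fragment sets, cross-validated errors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF
from sklearn.svm import OneClassSVM

from .metrics import y_outlier_flags
from .reaction_graph import CGR, signature_set_from_cgr

__all__ = [
    "ADInputs",
    "ADModel",
    "ADInapplicableWarning",
    "Leverage",
    "ZOneNN",
    "OneClassSVMAD",
    "TwoClassClassifierAD",
    "BoundingBox",
    "FragmentControl",
    "ReactionTypeControl",
    "RandomForestVarianceAD",
    "GaussianProcessAD",
    "OptimisticZero",
    "PessimisticZero",
    "PerfectAD",
    "CompositeAD",
    "twoclass_label",
    "forest_variance",
]


class ADInapplicableWarning(UserWarning):
    """A method degenerated (e.g. 2CC with a single training class)."""


@dataclass
class ADInputs:
    """Bundle of the per-reaction views an AD definition may consume."""

    X: np.ndarray | None = None                      # standardized descriptors
    y: np.ndarray | None = None                      # property values
    cgrs: list[CGR] | None = None                    # condensed graphs
    unseen_fragments: list[frozenset] | None = None  # vs. the fitted vocabulary
    cv_abs_errors: np.ndarray | None = None          # cross-validated |error|
    cv_rmse: float | None = None                     # RMSE of the same errors

    def __len__(self) -> int:
        for attr in (self.X, self.cgrs, self.unseen_fragments, self.cv_abs_errors):
            if attr is not None:
                return len(attr)
        raise ValueError("empty ADInputs")


class ADModel:
    """Base class; subclasses implement _fit and decide (and optionally score)."""

    name: str = "AD"
    #: True when larger scores mean *less* reliable (decision is score <= threshold)
    higher_is_outlier: bool = True

    def fit(self, inputs: ADInputs) -> "ADModel":
        self._fit(inputs)
        self.fitted_ = True
        return self

    def _fit(self, inputs: ADInputs) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def score(self, inputs: ADInputs) -> np.ndarray:
        raise NotImplementedError(f"{self.name} has no continuous score")

    def decide(self, inputs: ADInputs) -> np.ndarray:
        raise NotImplementedError


class _ThresholdModel(ADModel):
    """Score-based model: X-inlier iff score <= threshold (inclusive)."""

    threshold: float | None = None

    def decide(self, inputs: ADInputs) -> np.ndarray:
        return self.score(inputs) <= self.threshold


class Leverage(_ThresholdModel):
    """Hat-matrix leverage h = x^T (X^T X)^+ x with threshold h*.

    The default threshold is h* = 3(M+1)/N where M counts retained
    (non-constant) descriptor columns and N the training reactions.  The
    pseudo-inverse handles the rank deficiency of fragment-count matrices.
    """

    name = "Leverage"

    def __init__(self, h_star: float | None = None):
        self.h_star = h_star

    def _fit(self, inputs: ADInputs) -> None:
        X = np.asarray(inputs.X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("leverage needs at least two training reactions")
        self.pinv_ = np.linalg.pinv(X.T @ X)
        if self.h_star is None:
            m = int(np.count_nonzero(X.std(axis=0) > 0))
            self.threshold = 3.0 * (m + 1) / X.shape[0]
        else:
            self.threshold = float(self.h_star)

    def score(self, inputs: ADInputs) -> np.ndarray:
        X = np.asarray(inputs.X, dtype=float)
        return np.einsum("ij,jk,ik->i", X, self.pinv_, X)


class ZOneNN(_ThresholdModel):
    """Distance to the nearest training reaction with threshold Dc = Z*sigma + <y>.

    <y> and sigma are the mean and standard deviation of the Euclidean
    nearest-neighbour distances inside the training set (self-matches
    excluded).  ``dc`` overrides the Z-derived threshold when given.
    """

    name = "Z-1NN"

    def __init__(self, z: float = 0.5, dc: float | None = None):
        self.z = z
        self.dc = dc

    def _fit(self, inputs: ADInputs) -> None:
        X = np.asarray(inputs.X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("Z-1NN needs at least two training reactions")
        self.train_ = X
        d = self._cross_distances(X, X)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        self.mean_ = float(nn.mean())
        self.sd_ = float(nn.std())
        self.threshold = self.dc if self.dc is not None else self.z * self.sd_ + self.mean_

    @staticmethod
    def _cross_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        sq = np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :] - 2.0 * A @ B.T
        return np.sqrt(np.maximum(sq, 0.0))

    def score(self, inputs: ADInputs) -> np.ndarray:
        return self._cross_distances(np.asarray(inputs.X, dtype=float), self.train_).min(axis=1)


class OneClassSVMAD(ADModel):
    """RBF one-class SVM; X-inlier iff the decision function is non-negative."""

    name = "1-SVM"

    def __init__(self, nu: float = 0.1, gamma: float = 0.01):
        if not (0.0 < nu <= 1.0):
            raise ValueError("nu must be in (0, 1]")
        if gamma <= 0:
            raise ValueError("gamma must be positive")
        self.nu = nu
        self.gamma = gamma

    def _fit(self, inputs: ADInputs) -> None:
        self.svm_ = OneClassSVM(kernel="rbf", nu=self.nu, gamma=self.gamma)
        self.svm_.fit(np.asarray(inputs.X, dtype=float))

    def score(self, inputs: ADInputs) -> np.ndarray:
        # negated decision function so that larger = more outlying
        return -self.svm_.decision_function(np.asarray(inputs.X, dtype=float))

    def decide(self, inputs: ADInputs) -> np.ndarray:
        return self.svm_.predict(np.asarray(inputs.X, dtype=float)) == 1


def twoclass_label(cv_abs_errors: np.ndarray, reference_rmse: float) -> np.ndarray:
    """Y-outlier flags for 2CC training: |error| strictly above 3x RMSE."""
    if reference_rmse <= 0:
        raise ValueError("reference RMSE must be positive")
    return y_outlier_flags(cv_abs_errors, reference_rmse)


class TwoClassClassifierAD(ADModel):
    """Random-forest classifier separating Y-inliers from Y-outliers (2CC).

    X-inlier iff the predicted Y-inlier probability strictly exceeds p*.
    With fewer than two training reactions in either class the method is
    inapplicable: the model records the degeneracy, warns, and decides
    all-inlier.
    """

    name = "2CC"
    higher_is_outlier = False

    def __init__(self, max_features: float = 1.0, p_star: float = 0.5,
                 n_trees: int = 500, random_state: int = 0):
        self.max_features = max_features
        self.p_star = p_star
        self.n_trees = n_trees
        self.random_state = random_state

    def _fit(self, inputs: ADInputs) -> None:
        X = np.asarray(inputs.X, dtype=float)
        flags = twoclass_label(inputs.cv_abs_errors, inputs.cv_rmse)
        self.degenerate_ = int(flags.sum()) < 2 or int((~flags).sum()) < 2
        if self.degenerate_:
            warnings.warn(
                "2CC inapplicable: need at least two Y-outliers and two "
                "Y-inliers in the training set; deciding all-inlier",
                ADInapplicableWarning,
                stacklevel=2,
            )
            self.clf_ = None
            return
        self.clf_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            random_state=self.random_state,
        )
        # class 1 = Y-inlier so predict_proba column order is stable
        self.clf_.fit(X, (~flags).astype(int))

    def score(self, inputs: ADInputs) -> np.ndarray:
        """Predicted Y-inlier probability (higher = more reliable)."""
        if self.clf_ is None:
            return np.ones(len(inputs))
        inlier_col = list(self.clf_.classes_).index(1)
        return self.clf_.predict_proba(np.asarray(inputs.X, dtype=float))[:, inlier_col]

    def decide(self, inputs: ADInputs) -> np.ndarray:
        if self.clf_ is None:
            return np.ones(len(inputs), dtype=bool)
        return self.score(inputs) > self.p_star


class BoundingBox(ADModel):
    """Per-descriptor [min, max] hypercube; bounds are inclusive."""

    name = "BB"

    def _fit(self, inputs: ADInputs) -> None:
        X = np.asarray(inputs.X, dtype=float)
        self.lo_ = X.min(axis=0)
        self.hi_ = X.max(axis=0)

    def decide(self, inputs: ADInputs) -> np.ndarray:
        X = np.asarray(inputs.X, dtype=float)
        return np.all((X >= self.lo_) & (X <= self.hi_), axis=1)


class FragmentControl(ADModel):
    """X-outlier iff the reaction has CGR fragments absent from the training vocabulary."""

    name = "FC"

    def _fit(self, inputs: ADInputs) -> None:
        # the vocabulary lives in the featurizer; nothing to fit here
        pass

    def decide(self, inputs: ADInputs) -> np.ndarray:
        return np.array([len(u) == 0 for u in inputs.unseen_fragments], dtype=bool)


class ReactionTypeControl(ADModel):
    """X-inlier iff every reaction-center signature occurs in the training set.

    A change-free reaction (empty signature set) is an X-outlier.  The
    neighborhood radius R is the only hyperparameter; R = 1 (RTC1) is the
    recommended default.
    """

    name = "RTC"

    def __init__(self, radius: int = 1):
        if radius < 0:
            raise ValueError("radius must be non-negative")
        self.radius = radius

    def _fit(self, inputs: ADInputs) -> None:
        self.signatures_: set[str] = set()
        for g in inputs.cgrs:
            self.signatures_ |= signature_set_from_cgr(g, self.radius)

    def decide(self, inputs: ADInputs) -> np.ndarray:
        out = np.zeros(len(inputs.cgrs), dtype=bool)
        for k, g in enumerate(inputs.cgrs):
            sigs = signature_set_from_cgr(g, self.radius)
            out[k] = bool(sigs) and sigs <= self.signatures_
        return out


def forest_variance(forest: RandomForestRegressor, X: np.ndarray) -> np.ndarray:
    """Population variance of the per-tree predictions of a fitted forest."""
    per_tree = np.stack([t.predict(X) for t in forest.estimators_])
    return per_tree.var(axis=0)


class RandomForestVarianceAD(_ThresholdModel):
    """Ensemble-variance AD: X-inlier iff the per-tree prediction variance <= sigma*.

    An already-fitted forest (typically the QRPR model itself) can be
    shared via ``forest``; otherwise a 500-tree forest is fitted on X, y.
    """

    name = "RFR_VAR"

    def __init__(self, sigma_star: float = np.inf, forest: RandomForestRegressor | None = None,
                 max_features: float = 1.0, n_trees: int = 500, random_state: int = 0):
        self.threshold = sigma_star
        self.forest = forest
        self.max_features = max_features
        self.n_trees = n_trees
        self.random_state = random_state

    def _fit(self, inputs: ADInputs) -> None:
        if self.forest is not None:
            self.forest_ = self.forest
            return
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            random_state=self.random_state,
        )
        self.forest_.fit(np.asarray(inputs.X, dtype=float), np.asarray(inputs.y, dtype=float))

    def score(self, inputs: ADInputs) -> np.ndarray:
        return forest_variance(self.forest_, np.asarray(inputs.X, dtype=float))


class GaussianProcessAD(_ThresholdModel):
    """GPR posterior-variance AD: X-inlier iff the predictive variance <= sigma*.

    The kernel is a fixed RBF, k(x, x') = exp(-gamma * |x - x'|^2), with
    observation noise ``alpha``; the property is standardized internally
    and predictions are rescaled back before use.
    """

    name = "GPR-AD"

    def __init__(self, alpha: float = 0.1, gamma: float = 0.01, sigma_star: float = np.inf):
        self.alpha = alpha
        self.gamma = gamma
        self.threshold = sigma_star

    def _fit(self, inputs: ADInputs) -> None:
        y = np.asarray(inputs.y, dtype=float)
        self.y_mean_ = float(y.mean())
        self.y_sd_ = float(y.std()) or 1.0
        length_scale = 1.0 / np.sqrt(2.0 * self.gamma)
        self.gpr_ = GaussianProcessRegressor(
            kernel=RBF(length_scale=length_scale, length_scale_bounds="fixed"),
            alpha=self.alpha,
            optimizer=None,
        )
        self.gpr_.fit(np.asarray(inputs.X, dtype=float), (y - self.y_mean_) / self.y_sd_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Property prediction rescaled to the original range."""
        return self.gpr_.predict(np.asarray(X, dtype=float)) * self.y_sd_ + self.y_mean_

    def score(self, inputs: ADInputs) -> np.ndarray:
        _, sd = self.gpr_.predict(np.asarray(inputs.X, dtype=float), return_std=True)
        return sd**2


class OptimisticZero(ADModel):
    """Zero model OZ: every reaction is an X-inlier."""

    name = "OZ"

    def _fit(self, inputs: ADInputs) -> None:
        pass

    def decide(self, inputs: ADInputs) -> np.ndarray:
        return np.ones(len(inputs), dtype=bool)


class PessimisticZero(ADModel):
    """Zero model PZ: every reaction is an X-outlier."""

    name = "PZ"

    def _fit(self, inputs: ADInputs) -> None:
        pass

    def decide(self, inputs: ADInputs) -> np.ndarray:
        return np.zeros(len(inputs), dtype=bool)


class PerfectAD(ADModel):
    """Oracle baseline: X-inlier iff |prediction error| <= 3x RMSE.

    Decisions require the evaluated errors themselves (``cv_abs_errors``
    and ``cv_rmse`` on the inputs), so this model is usable only where the
    truth is known - as the upper baseline of a benchmark.
    """

    name = "Perfect"

    def _fit(self, inputs: ADInputs) -> None:
        pass

    def decide(self, inputs: ADInputs) -> np.ndarray:
        return ~y_outlier_flags(inputs.cv_abs_errors, inputs.cv_rmse)


class CompositeAD(ADModel):
    """Logical AND of several AD models (e.g. any method combined with RTC1)."""

    def __init__(self, models: list[ADModel], name: str | None = None):
        if not models:
            raise ValueError("composite needs at least one model")
        self.models = models
        self.name = name or "&".join(m.name for m in models)

    def _fit(self, inputs: ADInputs) -> None:
        for m in self.models:
            m.fit(inputs)

    def decide(self, inputs: ADInputs) -> np.ndarray:
        out = np.ones(len(inputs), dtype=bool)
        for m in self.models:
            out &= m.decide(inputs)
        return out
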