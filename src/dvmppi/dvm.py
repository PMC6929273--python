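"""The Discriminative Vector Machine (DVM).

DVM is a lazy, representation-based classifier.  To label a query y it

1. finds the k nearest training samples X_k = [x_1, ..., x_k] (removing the
   influence of isolated points far from the query),
2. solves a robust regularised reconstruction of y from the neighbor columns,

       min_b  (y - X_k b)' P (y - X_k b) + delta ||b||^2 + gamma b' L b

   where P = diag(p_i) carries Welsch M-estimator weights
   p_i = exp(-r_i^2 / sigma^2) with r = y - X_k b and kernel width
   sigma^2 = theta * (r'r) / d, and L = D - W is the graph Laplacian of the
   cosine-similarity matrix W among the neighbors (manifold regularisation:
   similar neighbors get similar coefficients),
3. assigns the class whose neighbor columns reconstruct y with the smallest
   L2 residual R_i = ||y - X_ki b_ki||, where b_ki is the sub-vector of the
   joint solution belonging to class i.

Because P depends on the residual, the solve alternates between the
closed-form update  b = (X_k' P X_k + delta I + gamma L)^{-1} X_k' P y  and a
refresh of P — the half-quadratic scheme for the Welsch loss; each iteration
does not increase the current surrogate objective.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DVMClassifier",
    "NeighborSet",
    "SolveState",
    "Prediction",
    "similarity_weights",
    "solve_beta",
    "predict_batch",
    "hq_objective",
]

logger = logging.getLogger(__name__)


def similarity_weights(columns: np.ndarray) -> np.ndarray:
    """Cosine-similarity matrix W among neighbor columns.

    ``columns`` is d x k (one neighbor per column).  w_pq is the cosine
    similarity of columns p and q, floored at 0 so that the graph has only
    non-negative edge weights and its Laplacian D - W is positive
    semidefinite (anti-parallel neighbors are simply unconnected); the
    diagonal is 0 (no self-edges) and a zero-norm column has weight 0
    against every other column.
    """
    cols = np.asarray(columns, dtype=float)
    norms = np.linalg.norm(cols, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    unit = cols / safe
    w = np.maximum(unit.T @ unit, 0.0)
    w[:, norms == 0] = 0.0
    w[norms == 0, :] = 0.0
    np.fill_diagonal(w, 0.0)
    return (w + w.T) / 2.0


def _laplacian(w: np.ndarray) -> np.ndarray:
    return np.diag(w.sum(axis=1)) - w


@dataclass
class NeighborSet:
    """k nearest training neighbors of a query, with their similarity graph."""

    columns: np.ndarray  # d x k
    labels: np.ndarray  # k encoded class ids
    W: np.ndarray = field(init=False)
    laplacian: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.W = similarity_weights(self.columns)
        self.laplacian = _laplacian(self.W)


@dataclass
class SolveState:
    """Result of the half-quadratic coefficient solve.

    ``trace`` holds one (before, after) pair of surrogate-objective values per
    iteration, both evaluated under that iteration's weight matrix P; descent
    of the half-quadratic scheme means after <= before in every pair.
    """

    beta: np.ndarray
    weights: np.ndarray  # Welsch weights p_i, one per feature dimension
    sigma: float
    iterations: int
    converged: bool
    trace: list = field(default_factory=list)


@dataclass
class Prediction:
    label: object
    residuals: np.ndarray  # per-class reconstruction residuals R_i
    score: float  # R_noninteract - R_interact; higher = more likely positive


def hq_objective(
    y: np.ndarray,
    columns: np.ndarray,
    beta: np.ndarray,
    p: np.ndarray,
    delta: float,
    gamma: float,
    laplacian: np.ndarray,
) -> float:
    """The fixed-P quadratic surrogate objective of the half-quadratic step."""
    r = y - columns @ beta
    return float(r @ (p * r) + delta * beta @ beta + gamma * beta @ laplacian @ beta)


def _beta_update(
    columns: np.ndarray,
    y: np.ndarray,
    p: np.ndarray,
    delta: float,
    gamma: float,
    laplacian: np.ndarray,
) -> np.ndarray:
    """Closed-form minimiser b = (X'PX + delta I + gamma L)^{-1} X'P y."""
    k = columns.shape[1]
    xtp = columns.T * p  # k x d, equals X' P
    lhs = xtp @ columns + delta * np.eye(k) + gamma * laplacian
    rhs = xtp @ y
    try:
        return np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(lhs)
        raise np.linalg.LinAlgError(
            f"singular neighbor system (condition number {cond:.3e}); "
            "increase delta or gamma"
        ) from exc


def solve_beta(
    y: np.ndarray,
    ns: NeighborSet,
    *,
    delta: float = 1e-3,
    gamma: float = 1e-4,
    theta: float = 1.0,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> SolveState:
    """Half-quadratic solve of the robust reconstruction coefficients.

    Starts from the ridge/Laplacian solution with P = I, then alternates the
    Welsch weight refresh  p_i = exp(-r_i^2 / sigma^2),
    sigma^2 = theta * r'r / d  with the closed-form beta update until the
    coefficient change drops below ``tol`` or ``max_iter`` is reached.  A
    perfect reconstruction (zero residual) sets all weights to 1 and stops.
    """
    y = np.asarray(y, dtype=float)
    cols = np.asarray(ns.columns, dtype=float)
    d = y.shape[0]
    p = np.ones(d)
    beta = _beta_update(cols, y, p, delta, gamma, ns.laplacian)
    sigma = 0.0
    converged = False
    iterations = 0
    trace: list[tuple[float, float]] = []
    for iterations in range(1, max_iter + 1):
        r = y - cols @ beta
        sigma_sq = theta * float(r @ r) / d
        if sigma_sq == 0.0:
            p = np.ones(d)
            sigma = 0.0
            converged = True
            break
        sigma = math.sqrt(sigma_sq)
        p = np.exp(-(r**2) / sigma_sq)
        before = hq_objective(y, cols, beta, p, delta, gamma, ns.laplacian)
        beta_new = _beta_update(cols, y, p, delta, gamma, ns.laplacian)
        trace.append(
            (before, hq_objective(y, cols, beta_new, p, delta, gamma, ns.laplacian))
        )
        step = float(np.linalg.norm(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    return SolveState(
        beta=beta,
        weights=p,
        sigma=sigma,
        iterations=iterations,
        converged=converged,
        trace=trace,
    )


class DVMClassifier(ClassifierMixin, BaseEstimator):
    """Discriminative vector machine: robust kNN-representation classifier.

    A lazy learner: ``fit`` stores (optionally standardized) training
    features; each prediction solves a per-query robust reconstruction over
    the query's k nearest training neighbors and picks the class with the
    smallest reconstruction residual.

    Parameters
    ----------
    k : int or "auto", default "auto"
        Neighbor count.  "auto" uses min(n_train, max(20, ceil(0.1 n_train)))
        — the method is reported to be insensitive to this choice within a
        wide range.
    delta : float, default 1e-3
        Ridge weight on the coefficients.
    gamma : float, default 1e-4
        Manifold (graph-Laplacian) regularisation weight.
    theta : float, default 1.0
        Kernel-width threshold in sigma^2 = theta * mean squared residual;
        larger theta flattens the Welsch weights toward 1.
    max_iter : int, default 20
        Half-quadratic iteration cap.
    tol : float, default 1e-6
        Convergence tolerance on the coefficient update norm.
    neighbor_metric : {"euclidean", "cosine"}, default "euclidean"
        Distance used for the kNN search (cosine similarity is always used
        for the neighbor graph W).
    standardize : bool, default True
        Z-score features using training statistics; the kernel width mixes
        feature dimensions, so comparable scales stabilise the weights.
    class_residual : {"slice", "refit"}, default "slice"
        "slice" evaluates R_i with the class-i sub-vector of the joint
        coefficients; "refit" re-solves the reconstruction restricted to the
        class-i neighbors.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels (binary use: index 0 = non-interacting,
        index 1 = interacting).
    X_ : ndarray of shape (n_train, n_features)
        Stored (standardized) training features.
    y_ : ndarray
        Encoded training labels (indices into ``classes_``).
    mean_, scale_ : ndarray
        Standardization statistics (zero-variance dimensions get scale 1).
    k_ : int
        Resolved neighbor count.
    """

    def __init__(
        self,
        k="auto",
        delta: float = 1e-3,
        gamma: float = 1e-4,
        theta: float = 1.0,
        max_iter: int = 20,
        tol: float = 1e-6,
        neighbor_metric: str = "euclidean",
        standardize: bool = True,
        class_residual: str = "slice",
    ):
        self.k = k
        self.delta = delta
        self.gamma = gamma
        self.theta = theta
        self.max_iter = max_iter
        self.tol = tol
        self.neighbor_metric = neighbor_metric
        self.standardize = standardize
        self.class_residual = class_residual

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-dimensional, got shape {X.shape}")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least 2 classes")
        if self.delta < 0 or self.gamma < 0:
            raise ValueError("delta and gamma must be non-negative")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        n = X.shape[0]
        if self.k == "auto":
            self.k_ = min(n, max(20, math.ceil(0.1 * n)))
        else:
            self.k_ = int(self.k)
            if self.k_ < 1:
                raise ValueError("k must be >= 1")
            if self.k_ > n:
                raise ValueError(
                    f"k={self.k_} exceeds n_train={n}; lower k or add samples"
                )
        if self.neighbor_metric not in ("euclidean", "cosine"):
            raise ValueError(f"unknown neighbor_metric {self.neighbor_metric!r}")
        if self.class_residual not in ("slice", "refit"):
            raise ValueError(f"unknown class_residual {self.class_residual!r}")
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        self.X_ = (X - self.mean_) / self.scale_
        self.y_ = np.searchsorted(self.classes_, y)
        self.n_features_in_ = X.shape[1]
        return self

    # -- per-query machinery ----------------------------------------------

    def _standardize(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.mean_) / self.scale_

    def find_neighbors(self, y: np.ndarray) -> NeighborSet:
        """k nearest stored training samples of an already-standardized query.

        Distance ties are broken by ascending training index (stable sort),
        so predictions are invariant to training-set permutation up to exact
        feature ties.
        """
        check_is_fitted(self, "X_")
        if self.neighbor_metric == "euclidean":
            dist = np.linalg.norm(self.X_ - y, axis=1)
        else:  # cosine distance
            norms = np.linalg.norm(self.X_, axis=1) * np.linalg.norm(y)
            safe = np.where(norms > 0, norms, 1.0)
            dist = 1.0 - (self.X_ @ y) / safe
        idx = np.argsort(dist, kind="stable")[: self.k_]
        return NeighborSet(columns=self.X_[idx].T, labels=self.y_[idx])

    def _residuals(self, y: np.ndarray, ns: NeighborSet, state: SolveState) -> np.ndarray:
        res = np.empty(len(self.classes_))
        for ci in range(len(self.classes_)):
            mask = ns.labels == ci
            if not np.any(mask):
                logger.debug("class %r absent among neighbors", self.classes_[ci])
                res[ci] = float(np.linalg.norm(y))
                continue
            if self.class_residual == "refit":
                sub = NeighborSet(columns=ns.columns[:, mask], labels=ns.labels[mask])
                beta_i = self._solve(y, sub).beta
                res[ci] = float(np.linalg.norm(y - sub.columns @ beta_i))
            else:
                res[ci] = float(
                    np.linalg.norm(y - ns.columns[:, mask] @ state.beta[mask])
                )
        return res

    def _solve(self, y: np.ndarray, ns: NeighborSet) -> SolveState:
        return solve_beta(
            y,
            ns,
            delta=self.delta,
            gamma=self.gamma,
            theta=self.theta,
            max_iter=self.max_iter,
            tol=self.tol,
        )

    def classify(self, y: np.ndarray) -> Prediction:
        """Full DVM decision for one raw (unstandardized) query vector."""
        check_is_fitted(self, "X_")
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_features_in_,):
            raise ValueError(
                f"expected feature vector of length {self.n_features_in_}, "
                f"got shape {y.shape}"
            )
        z = self._standardize(y)
        ns = self.find_neighbors(z)
        state = self._solve(z, ns)
        residuals = self._residuals(z, ns, state)
        label = self.classes_[int(np.argmin(residuals))]
        # binary margin: residual of the negative class minus the positive one
        score = float(residuals[0] - residuals[-1])
        return Prediction(label=label, residuals=residuals, score=score)

    # -- sklearn surface ---------------------------------------------------

    def _predict_all(self, X) -> list[Prediction]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected (n, {self.n_features_in_}) feature matrix, "
                f"got shape {X.shape}"
            )
        preds = []
        for i, row in enumerate(X):
            try:
                preds.append(self.classify(row))
            except ValueError as exc:
                raise ValueError(f"sample {i}: {exc}") from exc
        return preds

    def predict(self, X):
        check_is_fitted(self, "X_")
        return np.array([p.label for p in self._predict_all(X)])

    def decision_function(self, X):
        """Margin R_noninteract - R_interact; higher = more likely positive."""
        check_is_fitted(self, "X_")
        return np.array([p.score for p in self._predict_all(X)])

    def predict_residuals(self, X):
        """Per-class reconstruction residuals, shape (n_samples, n_classes)."""
        check_is_fitted(self, "X_")
        return np.array([p.residuals for p in self._predict_all(X)])


def predict_batch(samples, model: DVMClassifier) -> list[Prediction]:
    """Map :meth:`DVMClassifier.classify` over samples; order preserved.

    Samples are independent, so the result equals the per-sample loop.
    """
    if len(samples) == 0:
        return []
    return model._predict_all(np.atleast_2d(np.asarray(samples, dtype=float)))
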