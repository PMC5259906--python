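"""Radial basis function network classifier.

The network places one Gaussian kernel on every training instance
(centres equal to the training data) with a shared bandwidth sigma
(default 5), and two linear output nodes — one per class:

    g_j(x) = sum_i  w_ji * exp(-||x - mu_i||^2 / (2 sigma^2))

The output weights are solved in closed form by ridge-regularised least
squares against one-hot class targets; no iterative training and no
randomness are involved, so fitting is reproducible bit for bit.  A
residue is called binding when g_pos(x) - g_neg(x) exceeds the decision
threshold (default 0, i.e. argmax of the two nodes); the threshold is
exposed so sensitivity can be traded against specificity on heavily
imbalanced data.

The Gram/design matrices are computed in row blocks so peak additional
memory stays proportional to one block times the number of centres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .io_formats import ParameterError, ConsistencyError

logger = logging.getLogger(__name__)

DEFAULT_SIGMA = 5.0
DEFAULT_RIDGE = 1e-8

_BLOCK = 2048


@dataclass
class TrainingSet:
    """Feature matrix with binary labels; both classes must be present."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ParameterError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ConsistencyError("features and labels disagree in length")
        if np.isnan(self.features).any():
            raise ParameterError("features contain NaN")
        classes = set(np.unique(self.labels))
        if not classes <= {0, 1} or len(classes) != 2:
            raise ParameterError("labels must contain both classes {0, 1}")


@dataclass
class RBFModel:
    """A fitted network: kernel centres, bandwidth, output weights."""

    centers: np.ndarray          # (k, d)
    sigma: float
    weights: np.ndarray          # (2, k); row 0 = negative node, row 1 = positive
    ridge: float = DEFAULT_RIDGE
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be positive, got {self.sigma}")
        if self.weights.shape != (2, self.centers.shape[0]):
            raise ConsistencyError(
                f"weights shape {self.weights.shape} does not match "
                f"{self.centers.shape[0]} centres"
            )

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]


def kernel(x: np.ndarray, mu: np.ndarray, sigma: float) -> float:
    """Gaussian kernel ``exp(-||x - mu||^2 / (2 sigma^2))``; symmetric in (x, mu)."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if x.shape != mu.shape:
        raise ConsistencyError(f"dimension mismatch: {x.shape} vs {mu.shape}")
    d2 = float(np.sum((x - mu) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma * sigma)))


def _design_matrix(X: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    """Kernel activations of every row of X against every centre, blocked."""
    n, k = X.shape[0], centers.shape[0]
    phi = np.empty((n, k), dtype=float)
    c_sq = np.einsum("ij,ij->i", centers, centers)
    inv = 1.0 / (2.0 * sigma * sigma)
    for start in range(0, n, _BLOCK):
        block = X[start : start + _BLOCK]
        d2 = (
            np.einsum("ij,ij->i", block, block)[:, None]
            + c_sq[None, :]
            - 2.0 * block @ centers.T
        )
        np.maximum(d2, 0.0, out=d2)
        np.exp(-d2 * inv, out=d2)
        phi[start : start + block.shape[0]] = d2
    return phi


def fit(
    train: TrainingSet,
    sigma: float = DEFAULT_SIGMA,
    ridge: float = DEFAULT_RIDGE,
    threshold: float = 0.0,
) -> RBFModel:
    """Fit the network with centres equal to the training data.

    Solves, per output node j, the ridge least-squares problem
    ``min_w ||Phi w - y_j||^2 + ridge ||w||^2`` where ``Phi`` is the
    (square) Gram matrix of training points and ``y_j`` the one-hot
    target column of class j.  With distinct centres and ridge -> 0 this
    reproduces the targets exactly (the Gaussian Gram matrix of distinct
    points is positive definite).
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    if ridge < 0:
        raise ParameterError(f"ridge must be non-negative, got {ridge}")
    X = train.features
    phi = _design_matrix(X, X, sigma)
    targets = np.stack([1.0 - train.labels, train.labels.astype(float)], axis=1)
    if np.unique(X, axis=0).shape[0] < X.shape[0]:
        warnings.warn(
            "duplicate training points make the Gram matrix singular; "
            "relying on the ridge term",
            RuntimeWarning,
        )
    # normal equations Phi^T Phi + ridge I (Phi symmetric here)
    gram = phi.T @ phi
    gram[np.diag_indices_from(gram)] += ridge
    rhs = phi.T @ targets
    try:
        coef = scipy.linalg.solve(gram, rhs, assume_a="pos")
    except np.linalg.LinAlgError:
        logger.warning("normal equations not positive definite; using lstsq")
        coef = np.linalg.lstsq(gram, rhs, rcond=None)[0]
    return RBFModel(
        centers=X.copy(),
        sigma=float(sigma),
        weights=coef.T.copy(),
        ridge=float(ridge),
        threshold=float(threshold),
    )


def node_outputs(model: RBFModel, features: np.ndarray) -> np.ndarray:
    """Both output nodes per row: column 0 negative node, column 1 positive."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.n_features:
        raise ConsistencyError(
            f"model expects {model.n_features} features, got {features.shape[1]}"
        )
    phi = _design_matrix(features, model.centers, model.sigma)
    return phi @ model.weights.T


def score(model: RBFModel, features: np.ndarray) -> np.ndarray:
    """Decision scores ``g_pos(x) - g_neg(x)``; higher = more binding-like."""
    g = node_outputs(model, features)
    return g[:, 1] - g[:, 0]


def classify(
    model: RBFModel, features: np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """Binary labels: 1 iff score > threshold (model's threshold by default)."""
    if threshold is None:
        threshold = model.threshold
    return (score(model, features) > threshold).astype(int)


# ---------------------------------------------------------------------------
# Persistence


def save_model(model: RBFModel, path, selection=None, meta: dict | None = None) -> None:
    """Persist a model (plus its SAAP selection and settings) to one .npz archive."""
    from .saap import SAAPSelection  # local import to avoid cycle

    if selection is None:
        selection = SAAPSelection(pairs=[])
    meta = meta or {}
    np.savez(
        Path(path),
        centers=model.centers,
        sigma=np.array([model.sigma]),
        ridge=np.array([model.ridge]),
        threshold=np.array([model.threshold]),
        weights=model.weights,
        n_features=np.array([model.n_features]),
        saap_pairs=np.array(selection.pairs, dtype="U2"),
        saap_alpha=np.array([selection.alpha]),
        saap_max_k=np.array([selection.max_k]),
        meta_keys=np.array(sorted(meta), dtype="U64"),
        meta_values=np.array([str(meta[k]) for k in sorted(meta)], dtype="U64"),
    )


def load_model(path):
    """Load a model archive; returns (RBFModel, SAAPSelection, meta dict)."""
    from .saap import SAAPSelection

    with np.load(Path(path), allow_pickle=False) as data:
        model = RBFModel(
            centers=data["centers"],
            sigma=float(data["sigma"][0]),
            weights=data["weights"],
            ridge=float(data["ridge"][0]),
            threshold=float(data["threshold"][0]),
        )
        selection = SAAPSelection(
            pairs=[str(p) for p in data["saap_pairs"]],
            alpha=float(data["saap_alpha"][0]),
            max_k=int(data["saap_max_k"][0]),
        )
        meta = {
            str(k): str(v) for k, v in zip(data["meta_keys"], data["meta_values"])
        }
    return model, selection, meta
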