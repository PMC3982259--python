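"""Fuzzy membership functions.

Each training sample receives a weight mu in (0, 1] that scales its
misclassification cost; samples far from their own class mean (likely
outliers or label noise) are down-weighted.  Two parametric families are
provided, each in an input-space and a feature-space (kernel) variant:

* linear family:      mu_i = 1 - d_i / (max_j d_j + delta)
* exponential family: mu_i = 2 / (1 + exp(lambda * d_i))

where d_i is the Euclidean distance of sample i to its own-class mean
(computed through the Gram matrix in the feature-space variant) and the
max in the linear family ranges over the sample's own class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import Dataset

__all__ = [
    "MembershipParams",
    "class_means",
    "linear_membership",
    "exponential_membership",
    "feature_space_distances",
    "feature_space_distance",
    "kernel_membership",
    "compute_membership",
]

DEFAULT_DELTA = 1e-6


@dataclass
class MembershipParams:
    """Configuration of the fuzzy-membership assignment.

    family : "linear" or "exponential"
    delta  : small positive constant keeping the linear family strictly
             positive (default 1e-6)
    lam    : steepness of the exponential decay, in [0, 1]; required for
             the exponential family
    space  : "input" (Euclidean distances) or "feature" (kernel-induced)
    """

    family: str = "exponential"
    delta: float = DEFAULT_DELTA
    lam: float | None = None
    space: str = "input"

    def __post_init__(self) -> None:
        if self.family not in ("linear", "exponential"):
            raise ValueError(f"unknown membership family {self.family!r}")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.family == "exponential":
            if self.lam is None:
                raise ValueError("exponential membership requires lam")
            if not 0.0 <= self.lam <= 1.0:
                raise ValueError("lam must lie in [0, 1]")
        if self.space not in ("input", "feature"):
            raise ValueError(f"unknown membership space {self.space!r}")


def class_means(ds: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean of each class's feature vectors."""
    return ds.X[ds.pos_mask].mean(axis=0), ds.X[~ds.pos_mask].mean(axis=0)


def _own_class_distances(ds: Dataset) -> np.ndarray:
    mean_pos, mean_neg = class_means(ds)
    d = np.empty(ds.n_samples)
    d[ds.pos_mask] = np.linalg.norm(ds.X[ds.pos_mask] - mean_pos, axis=1)
    d[~ds.pos_mask] = np.linalg.norm(ds.X[~ds.pos_mask] - mean_neg, axis=1)
    return d


def _linear_from_distances(d: np.ndarray, pos_mask: np.ndarray, delta: float) -> np.ndarray:
    mu = np.empty_like(d)
    for mask in (pos_mask, ~pos_mask):
        mu[mask] = 1.0 - d[mask] / (d[mask].max() + delta)
    return mu


def _exponential_from_distances(d: np.ndarray, lam: float) -> np.ndarray:
    return 2.0 / (1.0 + np.exp(lam * d))


def linear_membership(ds: Dataset, delta: float = DEFAULT_DELTA) -> np.ndarray:
    """Linear fuzzy membership: 1 minus the distance to the own-class mean,
    normalized by that class's maximum distance (plus delta > 0 so the
    farthest sample keeps a strictly positive weight)."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    return _linear_from_distances(_own_class_distances(ds), ds.pos_mask, delta)


def exponential_membership(ds: Dataset, lam: float) -> np.ndarray:
    """Exponential fuzzy membership 2/(1 + exp(lam * d)); lam = 0 gives
    uniform weights of 1."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    return _exponential_from_distances(_own_class_distances(ds), lam)


def feature_space_distances(
    K: np.ndarray, class_members: np.ndarray, tol: float = 1e-8
) -> np.ndarray:
    """Distance of every sample to the feature-space mean of one class.

    Expanding ||phi(x_i) - mean_C phi||^2 through the kernel gives
    K_ii - (2/|C|) sum_{j in C} K_ij + (1/|C|^2) sum_{s,t in C} K_st.
    Radicands in [-tol*scale, 0) are clamped to zero; anything lower
    signals an invalid (non-PSD) kernel matrix.
    """
    members = np.asarray(class_members)
    if members.dtype == bool:
        members = np.flatnonzero(members)
    if members.size == 0:
        raise ValueError("class_members must be non-empty")
    m = members.size
    cross = K[:, members].sum(axis=1) / m
    within = K[np.ix_(members, members)].sum() / (m * m)
    sq = np.diag(K) - 2.0 * cross + within
    scale = max(1.0, float(np.abs(np.diag(K)).max()))
    if np.any(sq < -tol * scale):
        raise ValueError("negative squared feature-space distance: kernel not PSD")
    return np.sqrt(np.clip(sq, 0.0, None))


def feature_space_distance(K: np.ndarray, i: int, class_members, tol: float = 1e-8) -> float:
    """Scalar convenience wrapper around :func:`feature_space_distances`."""
    return float(feature_space_distances(K, np.asarray(class_members), tol=tol)[i])


def kernel_membership(K: np.ndarray, y: np.ndarray, params: MembershipParams) -> np.ndarray:
    """Fuzzy memberships with distances measured in the kernel feature space.

    With the linear kernel this reduces exactly to the input-space
    membership of the same family.
    """
    if params.space != "feature":
        raise ValueError("kernel_membership requires params.space == 'feature'")
    y = np.asarray(y)
    pos = y == 1
    d = np.empty(y.shape[0])
    d[pos] = feature_space_distances(K, pos)[pos]
    d[~pos] = feature_space_distances(K, ~pos)[~pos]
    if params.family == "linear":
        return _linear_from_distances(d, pos, params.delta)
    return _exponential_from_distances(d, params.lam)


def compute_membership(ds: Dataset, params: MembershipParams, K: np.ndarray | None = None) -> np.ndarray:
    """Dispatch on family/space.  Memberships are defined for training data
    only; test samples are never weighted."""
    if params.space == "feature":
        if K is None:
            raise ValueError("feature-space membership requires a Gram matrix")
        return kernel_membership(K, ds.y, params)
    if params.family == "linear":
        return linear_membership(ds, params.delta)
    return exponential_membership(ds, params.lam)
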