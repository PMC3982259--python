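"""Synthetic two-class generators for imbalanced, noisy classification.

The generator emulates the regime the method targets: a large "normal"
class (+1), a small "abnormal" class (-1), a configurable imbalance ratio,
optional far-field outliers (which stress the membership down-weighting)
and optional label flips.  A curved two-arcs shape exercises the kernel
path's nonlinearity.  Ground-truth (pre-flip) labels travel with the
dataset for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datasets import Dataset

__all__ = ["SimSpec", "simulate", "table1_protocols"]


@dataclass
class SimSpec:
    """Study-condition description of one synthetic dataset.

    separation is the distance between class means in units of the base
    within-class standard deviation; outliers are resampled onto a far
    shell at 5-8x the separation; label_noise_rate flips round(rate*N)
    labels (keeping the originals as ground truth).
    """

    n_pos: int
    n_neg: int
    dim: int = 2
    separation: float = 2.5
    cov_scale_pos: float = 1.0
    cov_scale_neg: float = 1.0
    outlier_rate: float = 0.0
    label_noise_rate: float = 0.0
    shape: str = "gaussian"
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("both classes need at least one sample")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        for rate in (self.outlier_rate, self.label_noise_rate):
            if not 0.0 <= rate < 0.5:
                raise ValueError("rates must lie in [0, 0.5)")
        if self.shape not in ("gaussian", "two_arcs"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.cov_scale_pos <= 0 or self.cov_scale_neg <= 0:
            raise ValueError("covariance scales must be > 0")


def _gaussian(spec: SimSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    mean_pos = np.zeros(spec.dim)
    mean_neg = np.zeros(spec.dim)
    mean_neg[0] = spec.separation
    Xp = rng.normal(size=(spec.n_pos, spec.dim)) * spec.cov_scale_pos + mean_pos
    Xn = rng.normal(size=(spec.n_neg, spec.dim)) * spec.cov_scale_neg + mean_neg
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(spec.n_pos, dtype=int), -np.ones(spec.n_neg, dtype=int)])
    return X, y


def _two_arcs(spec: SimSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Interleaved half-circles scaled by the separation, embedded in dim-D."""
    scale = max(spec.separation, 1.0)
    tp = rng.uniform(0.0, np.pi, spec.n_pos)
    tn = rng.uniform(0.0, np.pi, spec.n_neg)
    arc_p = np.column_stack([np.cos(tp), np.sin(tp)]) * scale
    arc_n = np.column_stack([1.0 - np.cos(tn), -np.sin(tn) + 0.5]) * scale
    X2 = np.vstack([arc_p, arc_n])
    X2 += rng.normal(size=X2.shape) * 0.15 * scale * spec.cov_scale_pos
    if spec.dim > 2:
        extra = rng.normal(size=(X2.shape[0], spec.dim - 2)) * spec.cov_scale_pos
        X2 = np.hstack([X2, extra])
    y = np.concatenate([np.ones(spec.n_pos, dtype=int), -np.ones(spec.n_neg, dtype=int)])
    return X2, y


def simulate(spec: SimSpec) -> Dataset:
    """Draw one dataset; deterministic under spec.seed.  Realized outlier and
    flip counts are exactly round(rate * N)."""
    rng = np.random.default_rng(spec.seed)
    X, y = (_gaussian if spec.shape == "gaussian" else _two_arcs)(spec, rng)
    N = X.shape[0]

    n_out = int(round(spec.outlier_rate * N))
    if n_out:
        idx = rng.choice(N, size=n_out, replace=False)
        center = X.mean(axis=0)
        radius = rng.uniform(5.0, 8.0, n_out) * max(spec.separation, 1.0)
        direction = rng.normal(size=(n_out, spec.dim))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        X[idx] = center + radius[:, None] * direction

    true_y = y.copy()
    n_flip = int(round(spec.label_noise_rate * N))
    if n_flip:
        idx = rng.choice(N, size=n_flip, replace=False)
        y = y.copy()
        y[idx] = -y[idx]
    if not (np.any(y == 1) and np.any(y == -1)):  # pathological flip outcome
        y = true_y.copy()

    return Dataset(X=X, y=y, true_y=true_y)


def table1_protocols(seed: int = 0) -> list[SimSpec]:
    """Five specs mirroring the evaluation protocol's training-set shapes:
    (m1, m2, d) = (240,120,9), (80,20,13), (100,10,19), (150,10,6), (180,10,8),
    with the package's default separation/noise conditions."""
    rows = [
        ("breast-like", 240, 120, 9),
        ("heart-like", 80, 20, 13),
        ("hepatitis-like", 100, 10, 19),
        ("liver-like", 150, 10, 6),
        ("diabetes-like", 180, 10, 8),
    ]
    base = SimSpec(
        n_pos=1,
        n_neg=1,
        separation=2.5,
        outlier_rate=0.05,
        label_noise_rate=0.02,
        seed=seed,
    )
    return [
        replace(base, name=name, n_pos=m1, n_neg=m2, dim=d, seed=seed + i)
        for i, (name, m1, m2, d) in enumerate(rows)
    ]
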