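"""Metrics, stratified cross-validation, grid search and repeat-averaged
reporting for imbalanced binary classification.

Sensitivity is the recall on the positive (majority/normal) class,
specificity the recall on the negative (minority/abnormal) class; the
two-way G-mean sqrt(sens*spec) and the three-way G-mean
(sens*spec*acc)^(1/3) summarize both.  Results of repeated runs are
reported as percent mean +/- std in a fixed-width table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .datasets import Dataset, stratified_split
from .kernel import KernelFSVMCIP, KernelSpec, tau_squared
from .linear import HyperParams, LinearFSVMCIP
from .locality import GraphParams
from .membership import MembershipParams

__all__ = [
    "EvalReport",
    "GridSpec",
    "score",
    "make_estimator",
    "cv_select",
    "RepeatedReport",
    "repeated_experiment",
    "format_cell",
    "format_table",
]


@dataclass
class EvalReport:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    gmean2: float
    gmean3: float
    degenerate: bool = False  # a zero-denominator metric was forced to 0


def score(y_true: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """Confusion counts and the five derived rates; empty-denominator rates
    return 0 with the ``degenerate`` flag set."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    degenerate = (tp + fn == 0) or (tn + fp == 0)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / y_true.size
    return EvalReport(
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        gmean2=float(np.sqrt(sens * spec)),
        gmean3=float((sens * spec * acc) ** (1.0 / 3.0)),
        degenerate=degenerate,
    )


@dataclass
class GridSpec:
    """Hyperparameter search sets.  Defaults are the full protocol grids:
    nu in {1, 5, 10, ..., 80}; v1, v2 in {0.001, 0.005, 0.01, 0.05};
    log2(eta) in {-5, -4.5, ..., 6}; t in {0.5, ..., 4.0};
    k in {3, 5, ..., 15}; lambda in {0.1, ..., 1.0}; delta = 1e-6;
    sigma spanning {tau^2/16, ..., 16 tau^2} (resolved against the data)."""

    nu_grid: list = field(default_factory=lambda: [1.0] + [float(v) for v in range(5, 85, 5)])
    v1_grid: list = field(default_factory=lambda: [0.001, 0.005, 0.01, 0.05])
    v2_grid: list = field(default_factory=lambda: [0.001, 0.005, 0.01, 0.05])
    eta_grid: list = field(
        default_factory=lambda: [2.0**p for p in np.arange(-5.0, 6.5, 0.5)]
    )
    t_grid: list = field(default_factory=lambda: [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0])
    k_grid: list = field(default_factory=lambda: [3, 5, 7, 9, 11, 13, 15])
    lambda_grid: list = field(default_factory=lambda: [round(0.1 * i, 1) for i in range(1, 11)])
    sigma_grid: list | None = None  # None => tau^2-based grid from the data
    delta: float = 1e-6

    def combos(self, kind: str, family: str, X: np.ndarray | None = None):
        """Deterministic enumeration of hyperparameter combinations."""
        lam_values = self.lambda_grid if family == "exponential" else [None]
        if kind == "kernel":
            sigmas = self.sigma_grid
            if sigmas is None:
                if X is None:
                    raise ValueError("sigma grid needs data to resolve tau^2")
                t2 = tau_squared(X)
                sigmas = [t2 * 2.0**p for p in range(-4, 5)]
        else:
            sigmas = [None]
        for combo in itertools.product(
            self.nu_grid,
            self.v1_grid,
            self.v2_grid,
            self.eta_grid,
            self.t_grid,
            self.k_grid,
            lam_values,
            sigmas,
        ):
            yield dict(
                zip(["nu", "v1", "v2", "eta", "t", "k", "lam", "sigma"], combo)
            )


def make_estimator(
    kind: str,
    nu: float,
    v1: float,
    v2: float,
    eta: float,
    k: int,
    t: float,
    family: str = "exponential",
    lam: float | None = None,
    delta: float = 1e-6,
    sigma: float | None = None,
    sv_mode: str = "interior",
):
    """Build a linear or kernel estimator from flat hyperparameters."""
    hp = HyperParams(
        nu=nu,
        v1=v1,
        v2=v2,
        eta=eta,
        graph=GraphParams(k=k, t=t),
        membership=MembershipParams(family=family, delta=delta, lam=lam),
    )
    if kind == "linear":
        return LinearFSVMCIP(hp=hp, sv_mode=sv_mode)
    if kind == "kernel":
        spec = KernelSpec(name="rbf", sigma=1.0 if sigma is None else sigma)
        return KernelFSVMCIP(hp=hp, spec=spec, sv_mode=sv_mode)
    raise ValueError(f"unknown estimator kind {kind!r}")


def _subset(ds: Dataset, idx: np.ndarray) -> Dataset:
    return Dataset(X=ds.X[idx], y=ds.y[idx])


def cv_select(
    ds: Dataset,
    kind: str,
    grid: GridSpec,
    folds: int = 5,
    seed: int = 0,
    family: str = "exponential",
    budget: int | None = None,
) -> tuple[dict, dict]:
    """Stratified k-fold grid search.

    Every candidate is scored by mean validation accuracy; ties break by
    higher mean two-way G-mean, then by enumeration order (which is the
    lexicographic order of the grids).  ``budget`` caps the number of
    candidates by a seeded uniform subsample of the full grid.  Returns
    (best_params, best_scores).
    """
    if min(ds.m1, ds.m2) < folds:
        raise ValueError("each class needs at least `folds` members to stratify")
    candidates = list(grid.combos(kind, family, ds.X))
    if budget is not None and len(candidates) > budget:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(candidates), size=budget, replace=False))
        candidates = [candidates[i] for i in keep]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(ds.X, ds.y))
    best = None
    best_key = None
    for params in candidates:
        accs, gms = [], []
        try:
            for tr, va in splits:
                est = make_estimator(
                    kind,
                    nu=params["nu"],
                    v1=params["v1"],
                    v2=params["v2"],
                    eta=params["eta"],
                    k=params["k"],
                    t=params["t"],
                    family=family,
                    lam=params["lam"],
                    delta=grid.delta,
                    sigma=params["sigma"],
                )
                est.fit(_subset(ds, tr))
                rep = score(ds.y[va], est.predict(ds.X[va]))
                accs.append(rep.accuracy)
                gms.append(rep.gmean2)
        except (ValueError, np.linalg.LinAlgError):
            continue  # infeasible or degenerate candidate
        key = (float(np.mean(accs)), float(np.mean(gms)))
        if best_key is None or key > best_key:
            best_key = key
            best = params
    if best is None:
        raise ValueError("no feasible hyperparameter candidate in the grid")
    return best, {"mean_accuracy": best_key[0], "mean_gmean2": best_key[1]}


@dataclass
class RepeatedReport:
    """Per-metric repeat arrays with percent mean +/- std accessors."""

    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray
    gmean2: np.ndarray
    gmean3: np.ndarray

    def mean_std(self, metric: str) -> tuple[float, float]:
        vals = getattr(self, metric)
        return float(np.mean(vals)), float(np.std(vals))

    def cells(self) -> dict[str, str]:
        return {
            m: format_cell(*self.mean_std(m))
            for m in ("sensitivity", "specificity", "accuracy")
        }


def format_cell(mean: float, std: float) -> str:
    """Percent ``mean ± std`` cell, e.g. ``95.87 ± 1.700``."""
    return f"{100 * mean:.2f} ± {100 * std:.3f}"


def repeated_experiment(
    ds: Dataset,
    estimator_factory,
    train_counts: tuple[int, int],
    n_repeats: int = 10,
    seed: int = 0,
) -> RepeatedReport:
    """Repeat (stratified split -> fit -> test-set score) ``n_repeats`` times.

    ``estimator_factory`` is a zero-argument callable returning a fresh
    estimator; split r uses seed ``seed + r``.
    """
    metrics = {m: [] for m in ("sensitivity", "specificity", "accuracy", "gmean2", "gmean3")}
    n_pos, n_neg = train_counts
    for r in range(n_repeats):
        train, test = stratified_split(ds, n_pos, n_neg, seed=seed + r)
        est = estimator_factory()
        est.fit(train)
        rep = score(test.y, est.predict(test.X))
        for m in metrics:
            metrics[m].append(getattr(rep, m))
    return RepeatedReport(**{m: np.asarray(v) for m, v in metrics.items()})


def format_table(rows: dict[str, RepeatedReport]) -> str:
    """Fixed-width report table: Method | Sensitivity | Specificity | Accuracy."""
    header = f"{'Method':<20} {'Sensitivity':>16} {'Specificity':>16} {'Accuracy':>16}"
    lines = [header, "-" * len(header)]
    for name, rep in rows.items():
        c = rep.cells()
        lines.append(
            f"{name:<20} {c['sensitivity']:>16} {c['specificity']:>16} {c['accuracy']:>16}"
        )
    return "\n".join(lines)
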