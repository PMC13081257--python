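"""Ordinal classification performance metrics.

The central metric is the Uniform Ordinal Classification Index (UOC): a
class-imbalance-insensitive misclassification index in [0, 1] (0 = perfect)
for ordered classes, computed by minimising over *consistent paths* through
the confusion matrix -- monotone chains of cells from the top-left to the
bottom-right corner whose true-class and predicted-class orders never oppose
each other.  For class count K, path steps are restricted to right, down and
diagonal moves; with row totals N_r, observed-class count K' and row
indicator 1∂(r), the index at penalty weight ``beta`` and exponent ``gamma``
is

    UOC(beta, gamma) = min over paths of
        1 - [sum_path (n_rc / N_r) 1∂(r)]
            / (K' + (K' / K'^gamma) (sum_all (n_rc / N_r) 1∂(r) |r-c|^gamma)^(1/gamma))
        + (beta / K') sum_path (n_rc / N_r) 1∂(r) |r-c|^gamma

The free parameter ``beta`` is eliminated by trapezoidal integration of the
per-beta minimum over [0, 1].  Because the per-cell costs are additive, the
minimisation is a shortest-path problem solved by dynamic programming;
:func:`enumerate_consistent_paths` provides the exhaustive oracle for small K.

Complementing the ordinal index, per-degree accuracy and bias of the raw r
coefficients are summarised as RMSD and mean bias error, normalised by half
the span between the neighbouring grid expectations so that deviations are
comparable across degrees, with normal-approximation confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .pedigree import DEFAULT_GRID, DegreeGrid

__all__ = [
    "ConfusionMatrix",
    "UOCResult",
    "DeviationSummary",
    "build_confusion",
    "enumerate_consistent_paths",
    "uoc_beta",
    "uoc",
    "mean_uoc_ci",
    "auc_trapezoid",
    "nrmsd",
    "nmbe",
    "deviation_cis",
    "onevsall_metrics",
    "Z_95",
]

#: two-sided 95% normal quantile as used throughout the CI formulas
Z_95 = 1.96


@dataclass
class ConfusionMatrix:
    """Ordered-class contingency table: rows = truth, columns = prediction."""

    labels: tuple[str, ...]
    counts: np.ndarray  # (K, K) non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        K = len(self.labels)
        if self.counts.shape != (K, K):
            raise ValueError("counts must be square and match labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def K(self) -> int:
        return len(self.labels)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def observed_rows(self) -> np.ndarray:
        """Row indicator 1∂(r): 1 where the truth row holds observations."""
        return (self.row_totals > 0).astype(float)

    @property
    def n_observed_classes(self) -> int:
        """K': number of truth classes with at least one observation."""
        return int((self.row_totals > 0).sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("cannot accumulate matrices with different labels")
        return ConfusionMatrix(self.labels, self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


def build_confusion(
    truths: Sequence[str],
    predictions: Sequence[str],
    labels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Accumulate a confusion matrix from paired label sequences."""
    if len(truths) != len(predictions):
        raise ValueError("truths and predictions differ in length")
    if len(truths) == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    if labels is None:
        labels = DEFAULT_GRID.classes
    index = {lab: k for k, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(truths, predictions):
        if t not in index or p not in index:
            raise ValueError(f"unknown class label in ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(tuple(labels), counts)


def enumerate_consistent_paths(K: int) -> Iterator[tuple[tuple[int, int], ...]]:
    """Exhaustively enumerate consistent paths for small K (oracle use).

    A path is a chain of cells from (0, 0) to (K-1, K-1) with steps in
    {right, down, diagonal}; rows and columns are non-decreasing along every
    path, so the true-class and predicted-class orders of any two nodes
    never oppose each other.  The path count is the central Delannoy number.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > 6:
        raise ValueError("exhaustive enumeration is restricted to K <= 6")

    def walk(r: int, c: int, acc: tuple) -> Iterator[tuple]:
        acc = acc + ((r, c),)
        if r == K - 1 and c == K - 1:
            yield acc
            return
        if r + 1 < K:
            yield from walk(r + 1, c, acc)
        if c + 1 < K:
            yield from walk(r, c + 1, acc)
        if r + 1 < K and c + 1 < K:
            yield from walk(r + 1, c + 1, acc)

    yield from walk(0, 0, ())


def _uoc_terms(cm: ConfusionMatrix, gamma: float):
    """Shared pieces of the UOC formula: per-cell share and distance arrays,
    K' and the path-independent denominator."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    K = cm.K
    totals = cm.row_totals.astype(float)
    indicator = cm.observed_rows
    safe_totals = np.where(totals > 0, totals, 1.0)
    share = cm.counts / safe_totals[:, None] * indicator[:, None]
    rows, cols = np.indices((K, K))
    dist = np.abs(rows - cols).astype(float) ** gamma
    K_obs = cm.n_observed_classes
    global_penalty = float((share * dist).sum())
    denom = K_obs + (K_obs / K_obs ** gamma) * global_penalty ** (1.0 / gamma)
    return share, dist, K_obs, denom


def uoc_beta(cm: ConfusionMatrix, beta, gamma: float = 1.0):
    """Minimised UOC at fixed ``beta`` (scalar or array of betas).

    Solved by dynamic programming: each cell contributes the additive cost
    ``-(share / denom) + (beta / K') * share * |r-c|^gamma`` and the
    minimising consistent path is a shortest monotone chain.  Rows without
    observations contribute nothing.  Returns ``1 + min_path cost``, with
    the same shape as ``beta``.
    """
    beta_arr = np.atleast_1d(np.asarray(beta, dtype=float))
    if np.any((beta_arr < 0) | (beta_arr > 1)):
        raise ValueError("beta must lie in [0, 1]")
    share, dist, K_obs, denom = _uoc_terms(cm, gamma)
    K = cm.K
    # cost[r, c, b]: vectorised over the beta grid
    cost = (
        -share[:, :, None] / denom
        + beta_arr[None, None, :] / K_obs * (share * dist)[:, :, None]
    )
    best = np.full((K, K, beta_arr.size), np.inf)
    best[0, 0] = cost[0, 0]
    for r in range(K):
        for c in range(K):
            if r == 0 and c == 0:
                continue
            prev = np.full(beta_arr.size, np.inf)
            if r > 0:
                prev = np.minimum(prev, best[r - 1, c])
            if c > 0:
                prev = np.minimum(prev, best[r, c - 1])
            if r > 0 and c > 0:
                prev = np.minimum(prev, best[r - 1, c - 1])
            best[r, c] = prev + cost[r, c]
    values = 1.0 + best[K - 1, K - 1]
    values = np.clip(values, 0.0, 1.0)  # guard fp jitter at the bounds
    return values if np.ndim(beta) else float(values[0])


@dataclass(frozen=True)
class UOCResult:
    """Per-beta minimised UOC values and their integral over [0, 1]."""

    betas: np.ndarray
    values: np.ndarray
    integrated: float


def uoc(cm: ConfusionMatrix, gamma: float = 1.0, n_grid: int = 101) -> UOCResult:
    """Beta-free UOC: trapezoidal quadrature of the per-beta minimum over an
    even beta grid on [0, 1]."""
    if n_grid < 2:
        raise ValueError("need at least two beta grid points")
    betas = np.linspace(0.0, 1.0, n_grid)
    values = uoc_beta(cm, betas, gamma)
    return UOCResult(betas, values, float(np.trapezoid(values, betas)))


def mean_uoc_ci(values: Sequence[float]) -> tuple[float, float, float]:
    """Mean UOC across replicates with its normal-approximation 95% CI:
    mu +/- 1.96 sigma / sqrt(n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two replicate values")
    mu = float(arr.mean())
    half = Z_95 * float(arr.std(ddof=1)) / math.sqrt(arr.size)
    return mu, mu - half, mu + half


def auc_trapezoid(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Trapezoidal area under a polyline; xs must be strictly increasing."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size < 2 or x.size != y.size:
        raise ValueError("need >= 2 paired points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("xs must be strictly increasing")
    return float(np.trapezoid(y, x))


# ------------------------------------------------------- accuracy and bias

@dataclass
class DeviationSummary:
    """Normalised accuracy (nRMSD) and bias (nMBE) of r estimates for one
    method and degree, with 95% CIs."""

    method: str
    degree: str
    n: int
    denominator: float
    nrmsd: float
    nmbe: float
    nrmsd_ci: tuple[float, float] | None = None
    nmbe_ci: tuple[float, float] | None = None
    sigma_norm: float | None = None  # sd of normalised estimates (for Eq-6 CI)


def degree_denominator(degree: str, grid: DegreeGrid = DEFAULT_GRID) -> float:
    """Half the span between the neighbouring grid expectations,
    ``(r_{k+1} - r_{k-1}) / 2``; edge classes use the mirrored one-sided
    range ``|r_neighbour - r_k|``."""
    k = grid.classes.index(degree)
    r = grid.r_values
    if k == 0:
        return r[1] - r[0]
    if k == len(r) - 1:
        return r[-1] - r[-2]
    return (r[k + 1] - r[k - 1]) / 2.0


def nrmsd(
    estimates: Sequence[float], degree: str, method: str = "",
    grid: DegreeGrid = DEFAULT_GRID,
) -> DeviationSummary:
    """Root-mean-square deviation of r estimates about the degree's expected
    value, normalised by the degree denominator."""
    arr = np.asarray(estimates, dtype=float)
    if arr.size == 0:
        raise ValueError("no estimates supplied")
    r_k = grid.expected_value(degree)
    denom = degree_denominator(degree, grid)
    rmsd = math.sqrt(float(np.mean((arr - r_k) ** 2)))
    mbe = float(np.mean(arr - r_k))
    return DeviationSummary(
        method=method,
        degree=degree,
        n=int(arr.size),
        denominator=denom,
        nrmsd=rmsd / denom,
        nmbe=mbe / denom,
        sigma_norm=float(arr.std(ddof=0)) / denom,
    )


def nmbe(
    estimates: Sequence[float], degree: str, method: str = "",
    grid: DegreeGrid = DEFAULT_GRID,
) -> DeviationSummary:
    """Mean bias error of r estimates, normalised; positive values mean
    overprediction.  Same summary object as :func:`nrmsd`."""
    return nrmsd(estimates, degree, method, grid)


def deviation_cis(summary: DeviationSummary) -> DeviationSummary:
    """Fill in the 95% CIs.

    nRMSD: asymmetric multiplicative interval
    ``nRMSD * [sqrt(1 - q), sqrt(1 + q)]`` with
    ``q = 1.96 sqrt(2) / sqrt(N - 1)``; the lower bound is undefined (NaN)
    when the radicand is negative (small N).  nMBE: symmetric interval
    ``nMBE +/- 1.96 sigma / sqrt(N)`` on the normalised scale.
    """
    n = summary.n
    if n < 2:
        raise ValueError("need at least two observations for CIs")
    q = Z_95 * math.sqrt(2.0) / math.sqrt(n - 1)
    lo = summary.nrmsd * math.sqrt(1.0 - q) if q <= 1.0 else float("nan")
    hi = summary.nrmsd * math.sqrt(1.0 + q)
    summary.nrmsd_ci = (lo, hi)
    sigma = summary.sigma_norm if summary.sigma_norm is not None else 0.0
    half = Z_95 * sigma / math.sqrt(n)
    summary.nmbe_ci = (summary.nmbe - half, summary.nmbe + half)
    return summary


def onevsall_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class one-vs-all reductions: sensitivity, specificity, balanced
    accuracy, precision, F1.  Classes absent from both truth and prediction
    report NaN (undefined), not zero."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    total = counts.sum()
    rows = []
    for k, label in enumerate(cm.labels):
        tp = counts[k, k]
        fn = counts[k].sum() - tp
        fp = counts[:, k].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn + fp == 0:
            rows.append(
                dict(label=label, sensitivity=np.nan, specificity=np.nan,
                     balanced_accuracy=np.nan, precision=np.nan, f1=np.nan)
            )
            continue
        sens = tp / (tp + fn) if tp + fn > 0 else np.nan
        spec = tn / (tn + fp) if tn + fp > 0 else np.nan
        prec = tp / (tp + fp) if tp + fp > 0 else np.nan
        if prec + sens > 0 and not (np.isnan(prec) or np.isnan(sens)):
            f1 = 2 * prec * sens / (prec + sens)
        else:
            f1 = np.nan if (np.isnan(prec) or np.isnan(sens)) else 0.0
        bal = (
            (sens + spec) / 2.0
            if not (np.isnan(sens) or np.isnan(spec))
            else np.nan
        )
        rows.append(
            dict(label=label, sensitivity=sens, specificity=spec,
                 balanced_accuracy=bal, precision=prec, f1=f1)
        )
    return pd.DataFrame(rows).set_index("label")
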