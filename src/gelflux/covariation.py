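"""Covariation of solitary-cell fluxes with detrital particle-class POC fluxes.

Two tools: Spearman rank correlation with a permutation p-value (do cell and
small-detrital fluxes rise and fall together across samples?), and a
principal component analysis of all flux variables after min-max
normalisation to [0, 1], whose first-two-component loadings show which
particle classes co-vary with the solitary cells.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantColumnError, UserInputError

__all__ = [
    "minmax_normalize",
    "normalize_table",
    "pca_first_two_loadings",
    "PCAResult",
    "spearman_rho",
    "SpearmanResult",
]

_TIE_TOL = 1e-12


def minmax_normalize(column: Sequence[float]) -> np.ndarray:
    """(x - min) / (max - min), mapping a column onto [0, 1]."""
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise UserInputError("column must be 1-D with at least 2 entries")
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ConstantColumnError("cannot min-max normalise a constant column")
    return (x - lo) / (hi - lo)


def normalize_table(X: pd.DataFrame, on_constant: str = "raise") -> pd.DataFrame:
    """Min-max normalise every column of a flux feature table.

    ``on_constant='raise'`` (default) rejects constant columns;
    ``'drop'`` removes them (logged via the returned frame's columns).
    """
    out = {}
    for col in X.columns:
        try:
            out[col] = minmax_normalize(X[col].to_numpy(dtype=float))
        except ConstantColumnError:
            if on_constant == "drop":
                continue
            raise
    if len(out) < 2:
        raise UserInputError("need at least 2 non-constant variables")
    return pd.DataFrame(out, index=X.index)


@dataclass(frozen=True)
class PCAResult:
    """Loadings (variables x components), explained-variance shares and scores."""

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    n_components: int
    scores: pd.DataFrame

    def summary(self) -> str:
        lines = [
            "PCA of min-max normalised fluxes "
            f"({self.loadings.shape[0]} variables, {self.n_components} components)"
        ]
        for k in range(self.n_components):
            lines.append(
                f"  PC{k + 1}: {100 * self.explained_variance_ratio[k]:.1f}% of variance"
            )
        return "\n".join(lines)


def pca_first_two_loadings(
    X: pd.DataFrame, matrix: str = "covariance", normalize: bool = True
) -> PCAResult:
    """Loadings of the first two principal components of a flux table.

    Columns are min-max normalised (unless ``normalize=False``, for callers
    that pre-normalise), then the covariance matrix (default; ``'correlation'``
    optional) is eigendecomposed. Loadings are unit-norm eigenvectors with the
    deterministic sign convention that each component's largest-magnitude
    element is positive. With fewer than 2 numerically nonzero eigenvalues a
    single component is reported.
    """
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise UserInputError("PCA needs >= 3 samples and >= 2 variables")
    if (X.to_numpy(dtype=float) < 0).any():
        raise UserInputError("flux features must be non-negative")
    Xn = normalize_table(X) if normalize else X.astype(float)
    V = Xn.to_numpy()
    if matrix == "covariance":
        C = np.cov(V, rowvar=False)
    elif matrix == "correlation":
        C = np.corrcoef(V, rowvar=False)
    else:
        raise UserInputError(f"unknown matrix {matrix!r}")
    w, vecs = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    vecs = vecs[:, order]
    total = w.sum()
    if total <= 0:
        raise UserInputError("degenerate feature table: zero total variance")
    nonzero = int(np.sum(w > 1e-12 * total))
    k = min(2, max(nonzero, 1))
    L = vecs[:, :k].copy()
    for j in range(k):
        i_max = int(np.argmax(np.abs(L[:, j])))
        if L[i_max, j] < 0:
            L[:, j] = -L[:, j]
    comp_names = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(L, index=Xn.columns, columns=comp_names)
    centred = V - V.mean(axis=0)
    scores = pd.DataFrame(centred @ L, index=Xn.index, columns=comp_names)
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=w[:k] / total,
        n_components=k,
        scores=scores,
    )


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str
    n_permutations: int = 0

    def summary(self) -> str:
        return (
            f"Spearman rank = {self.rho:.3g}, p = {self.p_value:.3g} "
            f"({self.method}, n = {self.n})"
        )


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "permutation",
) -> SpearmanResult:
    """Spearman rank correlation with a two-sided permutation p-value.

    rho is the Pearson correlation of mid-ranks (ties get average ranks);
    the p-value counts permutations of one ranking with
    ``|rho_perm| >= |rho_obs|``, ``p = (1 + hits) / (1 + n_perm)``.
    ``method='exact'`` enumerates all n! orderings (n <= 8);
    ``method='asymptotic'`` uses the t approximation for speed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UserInputError("vectors must be 1-D and of equal length")
    n = x.size
    if n < 4:
        raise UserInputError("Spearman needs at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantColumnError("rank correlation undefined for a constant vector")
    rx, ry = _midranks(x), _midranks(y)
    rx_c = rx - rx.mean()
    sx = float(np.sqrt(np.sum(rx_c**2)))

    def rho_of(ry_perm: np.ndarray) -> float:
        ry_c = ry_perm - ry_perm.mean()
        sy = float(np.sqrt(np.sum(ry_c**2)))
        return float(np.dot(rx_c, ry_c) / (sx * sy))

    rho = rho_of(ry)
    if method == "exact":
        if n > 8:
            raise UserInputError("exact enumeration is limited to n <= 8")
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(rho_of(ry[list(perm)])) >= abs(rho) - _TIE_TOL:
                hits += 1
        return SpearmanResult(rho, hits / total, n, "exact", total)
    if method == "asymptotic":
        if abs(rho) >= 1.0:
            return SpearmanResult(rho, 0.0, n, "asymptotic")
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        p = 2 * stats.t.sf(abs(t), df=n - 2)
        return SpearmanResult(rho, float(min(p, 1.0)), n, "asymptotic")
    if method != "permutation":
        raise UserInputError(f"unknown method {method!r}")
    if n_perm < 99:
        raise UserInputError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if abs(rho_of(ry[rng.permutation(n)])) >= abs(rho) - _TIE_TOL:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return SpearmanResult(rho, p, n, "permutation", n_perm)
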