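"""Community composition: Bray-Curtis dissimilarity, PERMANOVA, ordination,
and the threshold-linked sample network.

Samples are rows of a samples-by-taxa matrix of number fluxes. Composition
differences are summarised by the Bray-Curtis dissimilarity
``sum|x - y| / sum(x + y)`` and tested by a permutational multivariate
analysis of variance (PERMANOVA) with an Anderson-style pseudo-F computed
directly from the dissimilarity matrix. Samples whose communities fall below
a dissimilarity threshold are linked into a network whose connected
components are the distinct co-occurring sinking communities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import UserInputError

__all__ = [
    "CommunityMatrix",
    "DissimilarityMatrix",
    "CommunityNetwork",
    "PermanovaResult",
    "bray_curtis",
    "bray_curtis_matrix",
    "permanova",
    "mds_embed",
    "MDSResult",
    "build_similarity_network",
    "network_cluster_composition",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class CommunityMatrix:
    """Samples-by-taxa flux matrix with per-sample metadata.

    ``data`` is indexed by sample id with taxa as columns (cells m-2 d-1);
    ``meta`` shares the index and carries ``site, deployment, depth_m,
    platform``.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise UserInputError("community matrix needs >= 2 samples and >= 2 taxa")
        if (self.data.values < 0).any():
            raise UserInputError("fluxes must be non-negative")
        missing = {"site", "deployment", "depth_m", "platform"} - set(self.meta.columns)
        if missing:
            raise UserInputError(f"sample metadata missing columns: {sorted(missing)}")
        if not self.data.index.equals(self.meta.index):
            raise UserInputError("data and metadata must share the sample index")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square symmetric Bray-Curtis matrix with sample ids."""

    values: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = v.shape[0]
        if v.ndim != 2 or v.shape[1] != n or n != len(self.ids):
            raise UserInputError("dissimilarity matrix must be square with matching ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise UserInputError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise UserInputError("dissimilarity diagonal must be zero")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise UserInputError("Bray-Curtis values must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UserInputError("vectors must be 1-D and of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise UserInputError("fluxes must be non-negative")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise UserInputError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.sum(np.abs(x - y)) / denom)


def bray_curtis_matrix(
    matrix: CommunityMatrix | pd.DataFrame, transform: str | None = None
) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis among samples.

    ``transform=None`` uses raw fluxes (default), ``'relative'`` converts each
    sample to relative abundance first, ``'fourth_root'`` applies x**0.25.
    """
    df = matrix.data if isinstance(matrix, CommunityMatrix) else matrix
    X = df.to_numpy(dtype=float)
    if transform == "relative":
        totals = X.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise UserInputError("relative transform undefined for an all-zero sample")
        X = X / totals
    elif transform == "fourth_root":
        X = X**0.25
    elif transform is not None:
        raise UserInputError(f"unknown transform {transform!r}")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(X[i], X[j])
    return DissimilarityMatrix(values=D, ids=tuple(df.index))


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson pseudo-F from squared dissimilarities and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * idx.size)
    ss_among = max(ss_total - ss_within, 0.0)
    if ss_within <= _TIE_TOL * max(ss_total, 1.0):
        # no within-group spread: either no structure at all (F := 0) or
        # complete separation (F := +inf)
        return math.inf if ss_among > _TIE_TOL else 0.0
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    method: str
    n_samples: int
    n_groups: int

    def summary(self) -> str:
        return (
            f"PERMANOVA: pseudo-F = {self.pseudo_f:.4g}, p = {self.p_value:.4g} "
            f"({self.method}, {self.n_permutations} permutations, "
            f"n = {self.n_samples}, groups = {self.n_groups})"
        )


def permanova(
    D: DissimilarityMatrix,
    groups: Sequence,
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "permutation",
    strata: Sequence | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    The pseudo-F partitions the total sum of squared dissimilarities into
    among- and within-group parts computed directly from ``D``; significance
    is by free permutation of the sample labels,
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``. ``method='exact'``
    enumerates all orderings (small n only). ``strata`` restricts permutation
    to within-stratum shuffles (e.g. depth blocks).
    """
    labels = np.asarray(groups)
    if labels.size != D.n:
        raise UserInputError("one group label per sample is required")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise UserInputError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise UserInputError("every group needs at least 2 samples")
    d2 = D.values**2
    n = D.n
    f_obs = _pseudo_f(d2, codes, uniq.size)

    def perm_f(order: np.ndarray) -> float:
        return _pseudo_f(d2, codes[order], uniq.size)

    if method == "exact":
        if n > 9:
            raise UserInputError("exact enumeration is limited to n <= 9")
        fs = [perm_f(np.asarray(p)) for p in itertools.permutations(range(n))]
        hits = sum(1 for f in fs if f >= f_obs - _TIE_TOL)
        return PermanovaResult(f_obs, hits / len(fs), len(fs), "exact", n, uniq.size)
    if method != "permutation":
        raise UserInputError(f"unknown method {method!r}")
    if n_perm < 99:
        raise UserInputError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    strata_arr = None if strata is None else np.asarray(strata)
    hits = 0
    base = np.arange(n)
    for _ in range(n_perm):
        if strata_arr is None:
            order = rng.permutation(n)
        else:
            order = base.copy()
            for s in np.unique(strata_arr):
                idx = np.flatnonzero(strata_arr == s)
                order[idx] = idx[rng.permutation(idx.size)]
        if perm_f(order) >= f_obs - _TIE_TOL:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(f_obs, p, n_perm, "permutation", n, uniq.size)


@dataclass(frozen=True)
class MDSResult:
    coordinates: pd.DataFrame
    stress: float


def mds_embed(
    D: DissimilarityMatrix,
    dims: int = 2,
    refine: bool = True,
    max_iter: int = 300,
    tol: float = 1e-9,
) -> MDSResult:
    """Metric multidimensional scaling of a dissimilarity matrix.

    Classical (Torgerson) scaling by eigendecomposition of the double-centred
    squared dissimilarities, followed by an iterative stress-minimising
    (Guttman/SMACOF) refinement pass. Returns coordinates and the Kruskal
    stress-1 of the final configuration. Visualisation aid only.
    """
    n = D.n
    if n < 3:
        raise UserInputError("MDS needs at least 3 samples")
    d = D.values
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0.0, None)
    X = V[:, order] * np.sqrt(lam)

    def config_dist(X: np.ndarray) -> np.ndarray:
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def stress1(X: np.ndarray) -> float:
        cd = config_dist(X)
        iu = np.triu_indices(n, 1)
        denom = float((cd[iu] ** 2).sum())
        if denom == 0:
            return 0.0 if float((d[iu] ** 2).sum()) == 0 else 1.0
        return math.sqrt(float(((cd[iu] - d[iu]) ** 2).sum()) / denom)

    if refine:
        prev = stress1(X)
        for _ in range(max_iter):
            cd = config_dist(X)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(cd > 0, d / np.where(cd > 0, cd, 1.0), 0.0)
            Bmat = -ratio
            np.fill_diagonal(Bmat, ratio.sum(axis=1))
            X = Bmat @ X / n
            cur = stress1(X)
            if prev - cur < tol:
                break
            prev = cur
    coords = pd.DataFrame(
        X, index=list(D.ids), columns=[f"MDS{k + 1}" for k in range(dims)]
    )
    return MDSResult(coordinates=coords, stress=stress1(X))


@dataclass(frozen=True)
class CommunityNetwork:
    """Threshold network of samples with similar communities.

    Edges connect pairs strictly below the Bray-Curtis threshold; clusters
    are the connected components, labelled 1..k ordered by earliest
    deployment then shallowest depth of their member samples. Singleton
    components (samples similar to no other) are retained.
    """

    graph: nx.Graph
    clusters: dict[int, tuple[str, ...]]
    threshold: float

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["dissimilarity"]) for u, v, d in self.graph.edges(data=True)]

    def membership(self) -> pd.DataFrame:
        rows = [
            {"sample_id": sid, "cluster": lab}
            for lab, members in self.clusters.items()
            for sid in members
        ]
        return pd.DataFrame(rows, columns=["sample_id", "cluster"])


def build_similarity_network(
    D: DissimilarityMatrix,
    meta: pd.DataFrame | None = None,
    threshold: float = 0.25,
) -> CommunityNetwork:
    """Link samples whose Bray-Curtis dissimilarity is strictly below the
    threshold (ties at the threshold are excluded) and label the connected
    components deterministically.

    ``meta`` (indexed by sample id with ``deployment`` and ``depth_m``)
    orders component labels by earliest deployment then shallowest depth;
    without it, labels follow sample order.
    """
    if not 0 < threshold <= 1:
        raise UserInputError("threshold must be in (0, 1]")
    g = nx.Graph()
    g.add_nodes_from(D.ids)
    for i in range(D.n):
        for j in range(i + 1, D.n):
            if D.values[i, j] < threshold:
                g.add_edge(D.ids[i], D.ids[j], dissimilarity=float(D.values[i, j]))
    comps = [tuple(sorted(c, key=list(D.ids).index)) for c in nx.connected_components(g)]

    def sort_key(members: tuple[str, ...]):
        if meta is not None:
            return min(
                (float(meta.loc[m, "deployment"]), float(meta.loc[m, "depth_m"]))
                for m in members
            )
        return (min(list(D.ids).index(m) for m in members),)

    comps.sort(key=sort_key)
    clusters = {lab: members for lab, members in enumerate(comps, start=1)}
    return CommunityNetwork(graph=g, clusters=clusters, threshold=threshold)


def network_cluster_composition(
    net: CommunityNetwork,
    matrix: CommunityMatrix | pd.DataFrame,
    display_min: float = 0.05,
) -> pd.DataFrame:
    """Mean relative community composition per network cluster.

    Each member sample is converted to relative abundance and averaged;
    taxa below ``display_min`` of a cluster's mean composition are pooled
    into ``other``. Rows sum to 1.
    """
    if not 0 <= display_min < 1:
        raise UserInputError("display_min must be in [0, 1)")
    df = matrix.data if isinstance(matrix, CommunityMatrix) else matrix
    rows = {}
    for lab, members in net.clusters.items():
        sub = df.loc[list(members)].to_numpy(dtype=float)
        totals = sub.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise UserInputError(f"cluster {lab} contains an all-zero sample")
        rows[lab] = (sub / totals).mean(axis=0)
    comp = pd.DataFrame.from_dict(rows, orient="index", columns=df.columns)
    comp.index.name = "cluster"
    shown = comp.where(comp >= display_min, 0.0)
    other = comp.where(comp < display_min, 0.0).sum(axis=1)
    shown["other"] = other
    # drop taxa hidden in every cluster
    keep = [c for c in shown.columns if c == "other" or (shown[c] > 0).any()]
    return shown[keep]
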