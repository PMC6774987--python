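"""Average-linkage clustering with multiscale-bootstrap node support.

Similarity matrices are converted to distances (``d = 1 - LSI``) and
clustered by UPGMA (average linkage).  Node stability is assessed by
multiscale bootstrap: each item's vector of distances to all items is
treated as its feature profile, and for a ladder of scales ``r`` the profile
coordinates are resampled with replacement to size ``ceil(r * m)``,
distances between the resampled profiles are recomputed and reclustered, and
each original node's recovery frequency ``BP_r`` is recorded.  Fitting the
probit-transformed ``BP_r`` against ``(sqrt(r), 1/sqrt(r))`` by weighted
least squares gives signed-distance and curvature coefficients ``(v, c)``
from which the approximately unbiased p-value ``AU = 1 - Phi(v - c)`` and
the plain bootstrap probability ``BP = 1 - Phi(v + c)`` are extrapolated,
with a delta-method standard error.

Nodes with AU above a threshold (default 0.95) are *stable*; the maximal
("highest-level") stable nodes, excluding the root, are the clusters used as
evidence downstream.  The cophenetic correlation coefficient measures how
faithfully the tree's merge heights represent the input distances (> 0.8
conventionally counts as a good representation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from levensong.seqsim import SimilarityMatrix

__all__ = [
    "SupportedDendrogram",
    "StableClusterSet",
    "DEFAULT_SCALES",
    "upgma",
    "multiscale_bootstrap",
    "stable_clusters",
    "cophenetic_correlation",
    "to_newick",
]

#: Default resampling-ratio ladder spanning 1 (ten values, 0.5 to 1.4).
DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


@dataclass
class SupportedDendrogram:
    """A UPGMA tree plus optional per-node bootstrap support.

    ``merges`` is a scipy linkage matrix: row ``k`` merges clusters into
    internal node ``n + k`` at the recorded average-linkage height.  Support
    arrays, when present, are indexed by ``k`` (internal nodes in merge
    order, the last being the root).
    """

    ids: tuple[str, ...]
    merges: np.ndarray
    au: np.ndarray | None = None
    bp: np.ndarray | None = None
    se: np.ndarray | None = None
    #: True for nodes never recovered in any replicate at any scale.
    unobserved: np.ndarray | None = None
    _leafsets: list[frozenset[int]] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("linkage matrix shape inconsistent with ids")
        self._leafsets = _merge_leafsets(self.merges, n)
        if self.au is not None:
            for arr in (self.au, self.bp):
                if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                    raise ValueError("AU/BP values must lie in [0, 1]")

    @property
    def n_leaves(self) -> int:
        return len(self.ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leafset(self, node: int) -> frozenset[int]:
        """Leaf indices under internal node ``k`` (merge order)."""
        return self._leafsets[node]

    def leaf_names(self, node: int) -> frozenset[str]:
        return frozenset(self.ids[i] for i in self._leafsets[node])

    def cophenetic(self) -> np.ndarray:
        """Condensed matrix of pairwise merge heights."""
        return cophenet(self.merges)

    def support_table(self):
        """Node-support table: node id, leaves, au, bp, se."""
        import pandas as pd

        if self.au is None:
            raise ValueError("tree has no support values")
        rows = []
        for k in range(len(self.merges)):
            rows.append(
                {
                    "node_id": k,
                    "leaves": ";".join(sorted(self.leaf_names(k))),
                    "au": self.au[k],
                    "bp": self.bp[k],
                    "se": self.se[k],
                }
            )
        return pd.DataFrame(rows)


def _merge_leafsets(Z: np.ndarray, n: int) -> list[frozenset[int]]:
    sets: list[frozenset[int]] = [frozenset((i,)) for i in range(n)]
    for left, right in Z[:, :2].astype(int):
        sets.append(sets[left] | sets[right])
    return sets[n:]


def upgma(
    distances: np.ndarray, ids: Sequence[str] | None = None
) -> SupportedDendrogram:
    """UPGMA (average-linkage) tree of a square symmetric distance matrix.

    Merge heights are average inter-cluster distances; the implied
    cophenetic distances are ultrametric.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 2 or distances.shape[0] != distances.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(distances, distances.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(distances), 0.0, atol=1e-9):
        raise ValueError("distance matrix diagonal must be 0")
    n = distances.shape[0]
    if ids is None:
        ids = tuple(str(i) for i in range(n))
    Z = linkage(squareform(distances, checks=False), method="average")
    return SupportedDendrogram(ids=tuple(ids), merges=Z)


def _replicate_leafsets(dvec: np.ndarray, n: int) -> set[frozenset[int]]:
    Z = linkage(dvec, method="average")
    return set(_merge_leafsets(Z, n))


def multiscale_bootstrap(
    data: SimilarityMatrix | np.ndarray,
    ids: Sequence[str] | None = None,
    *,
    scales: Sequence[float] = DEFAULT_SCALES,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> SupportedDendrogram:
    """UPGMA tree with multiscale-bootstrap AU/BP/SE node support.

    ``data`` is either a :class:`SimilarityMatrix` (profiles are the rows of
    the derived distance matrix ``1 - LSI``, which is also what is
    clustered) or an ``(m, n)`` profile matrix of ``m`` feature rows for
    ``n`` items (items are clustered on scaled Euclidean profile distance).
    Replicates resample profile rows with replacement; per-node recovery
    frequencies across the scale ladder are extrapolated to AU as described
    in the module docstring.  Deterministic for a fixed ``seed``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    scales = tuple(float(r) for r in scales)
    if not scales or min(scales) <= 0:
        raise ValueError("scales must be positive ratios")
    if not (min(scales) <= 1.0 <= max(scales)):
        raise ValueError("scale ladder must span 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if isinstance(data, SimilarityMatrix):
        ids = data.ids
        D = data.to_distance()
        profiles = D.copy()
    else:
        profiles = np.asarray(data, dtype=float)
        if profiles.ndim != 2:
            raise ValueError("profile matrix must be 2-D (features x items)")
        if ids is None:
            ids = tuple(str(i) for i in range(profiles.shape[1]))
        D = squareform(pdist(profiles.T) / math.sqrt(profiles.shape[0]))
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 items to bootstrap a tree")
    tree = upgma(D, ids)
    base_sets = [tree.leafset(k) for k in range(n - 1)]

    m = profiles.shape[0]
    counts = np.zeros((len(scales), n - 1), dtype=np.int64)
    for si, r in enumerate(scales):
        msub = max(2, math.ceil(r * m))
        scale = math.sqrt(msub)
        for _ in range(B):
            idx = rng.integers(0, m, size=msub)
            dvec = pdist(profiles[idx].T) / scale
            repsets = _replicate_leafsets(dvec, n)
            for k, s in enumerate(base_sets):
                if s in repsets:
                    counts[si, k] += 1

    au, bp, se, unobserved = _fit_au(counts, scales, B)
    return SupportedDendrogram(
        ids=tuple(ids), merges=tree.merges, au=au, bp=bp, se=se,
        unobserved=unobserved,
    )


#: Minimum number of scales with an interior recovery frequency required for
#: the probit extrapolation; below this the node is treated as saturated.
_MIN_FIT_SCALES = 3


def _fit_au(
    counts: np.ndarray, scales: Sequence[float], B: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Probit-WLS extrapolation of per-scale recovery frequencies to AU/BP/SE.

    Scales where the node was recovered in every replicate or none carry no
    usable probit information; they are clipped to ``1/(2B)`` from the
    boundary and excluded from the fit.  A node with fewer than
    ``_MIN_FIT_SCALES`` informative scales is saturated: it gets AU = BP = 1
    (recovered essentially always) or 0 (essentially never), with SE 0.
    """
    n_nodes = counts.shape[1]
    au = np.zeros(n_nodes)
    bp = np.zeros(n_nodes)
    se = np.zeros(n_nodes)
    unobserved = np.zeros(n_nodes, dtype=bool)
    r = np.asarray(scales, dtype=float)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    eps = 1.0 / (2.0 * B)
    for k in range(n_nodes):
        freq = counts[:, k] / B
        if freq.max() == 0:
            unobserved[k] = True
            continue
        interior = (counts[:, k] > 0) & (counts[:, k] < B)
        if interior.sum() < _MIN_FIT_SCALES:
            if freq.mean() >= 0.5:
                au[k] = bp[k] = 1.0
            # else saturated at 0: au = bp = 0 already
            continue
        f = np.clip(freq[interior], eps, 1.0 - eps)
        psi = norm.ppf(1.0 - f)
        w = B * norm.pdf(psi) ** 2 / (f * (1.0 - f))
        Xi = X[interior]
        XtW = Xi.T * w
        A = XtW @ Xi
        try:
            cov = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(A)
        v, c = cov @ (XtW @ psi)
        au[k] = 1.0 - norm.cdf(v - c)
        bp[k] = 1.0 - norm.cdf(v + c)
        var_vc = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
        se[k] = float(norm.pdf(v - c) * math.sqrt(max(var_vc, 0.0)))
    return au, bp, se, unobserved


@dataclass
class StableClusterSet:
    """Maximal dendrogram nodes whose AU support exceeds the threshold."""

    clusters: list[frozenset[str]]
    au_threshold: float

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self) -> int:
        return len(self.clusters)

    def containing(self, item: str) -> frozenset[str] | None:
        for c in self.clusters:
            if item in c:
                return c
        return None


def stable_clusters(
    tree: SupportedDendrogram, au_threshold: float = 0.95
) -> StableClusterSet:
    """Maximal (highest-level) non-root nodes with ``AU > au_threshold``.

    Once a node qualifies, its descendants are not reported (the box is
    drawn at the highest level only).  Singletons are leaves, never nodes,
    so they cannot qualify.  May be empty.
    """
    if tree.au is None:
        raise ValueError("tree has no support values; run multiscale_bootstrap")
    n = tree.n_leaves
    root = 2 * n - 2
    found: list[frozenset[str]] = []

    def visit(node: int, is_root: bool) -> None:
        if node < n:
            return
        k = node - n
        if not is_root and tree.au[k] > au_threshold:
            found.append(tree.leaf_names(k))
            return
        left, right = int(tree.merges[k, 0]), int(tree.merges[k, 1])
        visit(left, False)
        visit(right, False)

    visit(root, True)
    return StableClusterSet(clusters=found, au_threshold=au_threshold)


def cophenetic_correlation(
    tree: SupportedDendrogram, distances: np.ndarray
) -> float:
    """Pearson correlation between input and cophenetic (tree) distances.

    Equals 1 exactly when the input distances are ultrametric (the tree then
    reproduces them).  Undefined for fewer than 3 items.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.shape[0] < 3:
        raise ValueError("cophenetic correlation undefined for < 3 items")
    if distances.shape != (tree.n_leaves, tree.n_leaves):
        raise ValueError("distance matrix does not match tree leaves")
    orig = squareform(distances, checks=False)
    coph = tree.cophenetic()
    if np.std(orig) == 0 or np.std(coph) == 0:
        # degenerate: all distances equal; the tree trivially reproduces them
        return 1.0 if np.allclose(orig, coph) else 0.0
    return float(np.corrcoef(orig, coph)[0, 1])


def _quote_name(name: str) -> str:
    if any(c in name for c in " \t()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: SupportedDendrogram, support: bool = True) -> str:
    """Newick export with ultrametric branch lengths and support labels.

    Leaf depth is half the merge height (so two items at distance 0.4 render
    as ``(A:0.2,B:0.2);``).  Internal nodes carry ``AU=..|BP=..`` labels
    when support is available and requested.
    """
    n = tree.n_leaves

    def depth(node: int) -> float:
        return 0.0 if node < n else float(tree.merges[node - n, 2]) / 2.0

    def render(node: int, parent_depth: float) -> str:
        if node < n:
            return f"{_quote_name(tree.ids[node])}:{parent_depth:.10g}"
        k = node - n
        d = depth(node)
        left = render(int(tree.merges[k, 0]), d)
        right = render(int(tree.merges[k, 1]), d)
        label = ""
        if support and tree.au is not None:
            label = _quote_name(f"AU={tree.au[k]:.3f}|BP={tree.bp[k]:.3f}")
        blen = f":{parent_depth - d:.10g}" if parent_depth is not None else ""
        return f"({left},{right}){label}{blen}"

    root = 2 * n - 2
    k = root - n
    d = depth(root)
    left = render(int(tree.merges[k, 0]), d)
    right = render(int(tree.merges[k, 1]), d)
    label = ""
    if support and tree.au is not None:
        label = _quote_name(f"AU={tree.au[k]:.3f}|BP={tree.bp[k]:.3f}")
    return f"({left},{right}){label};"
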