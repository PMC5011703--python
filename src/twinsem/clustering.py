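"""Factor-count screening and hierarchical clustering of correlation matrices.

Regions are clustered on the distance d(i, j) = 1 - r(i, j), so a
negative correlation maps to a distance greater than one (sign-sensitive
grouping); complete linkage is the default.  The number of clusters is
chosen by mean silhouette width over candidate cuts, skipping cuts that
produce singleton clusters — a one-member cluster has no within-cluster
dissimilarity, receives silhouette 0 by convention, and would otherwise
reward peeling single weakly-attached regions off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .errors import SchemaError, ValidityError


def _validate_correlation(R: np.ndarray, labels=None) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValidityError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8, equal_nan=True):
        raise ValidityError("correlation matrix must be symmetric")
    if np.isnan(R).any():
        lab = labels or list(range(R.shape[0]))
        bad = [(lab[i], lab[j]) for i, j in zip(*np.where(np.isnan(R))) if i < j]
        raise ValidityError(
            f"correlation matrix has undefined entries for pairs {bad}; "
            "resolve undefined correlations upstream")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValidityError("correlation matrix must have a unit diagonal")
    return 0.5 * (R + R.T)


@dataclass
class ScreeResult:
    """Eigenvalue screen of a correlation matrix."""

    eigenvalues: np.ndarray       # sorted descending
    elbow_count: int              # factors preceding the largest consecutive drop
    kaiser_count: int             # eigenvalues strictly greater than 1

    @property
    def suggested(self) -> int:
        """Factor count suggestion: the elbow, capped by the Kaiser rule."""
        return min(self.elbow_count, self.kaiser_count) if self.kaiser_count else 0


def eigen_scree(R, labels=None) -> ScreeResult:
    """Eigenvalues of a correlation matrix with elbow and Kaiser factor counts.

    The elbow count is the number of eigenvalues preceding the largest
    consecutive drop; the Kaiser count applies the strict lambda > 1 rule.
    """
    R = _validate_correlation(R, labels)
    w = np.sort(np.linalg.eigvalsh(R))[::-1]
    drops = w[:-1] - w[1:]
    elbow = int(np.argmax(drops)) + 1 if drops.size else 0
    kaiser = int(np.sum(w > 1.0))
    return ScreeResult(eigenvalues=w, elbow_count=elbow, kaiser_count=kaiser)


@dataclass
class ClusterTree:
    """Dendrogram over labelled items from a correlation-derived distance."""

    labels: list
    linkage_matrix: np.ndarray = field(repr=False)
    linkage: str = "complete"
    distance: str = "one-minus-r"
    distance_matrix: np.ndarray = field(repr=False, default=None)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def cut(self, k: int) -> dict:
        """Partition into k clusters; cluster ids renumbered 1..k in label order."""
        raw = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        remap, out = {}, {}
        for lab in sorted(self.labels):
            c = raw[self.labels.index(lab)]
            remap.setdefault(c, len(remap) + 1)
        for lab, c in zip(self.labels, raw):
            out[lab] = remap[c]
        return out

    def cut_sets(self, k: int) -> list:
        """The k-cluster partition as a list of frozensets of labels."""
        part = self.cut(k)
        groups: dict = {}
        for lab, c in part.items():
            groups.setdefault(c, set()).add(lab)
        return [frozenset(groups[c]) for c in sorted(groups)]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist).rsplit(":", 1)[0] + ";"


def cluster_correlations(R, labels=None, linkage: str = "complete",
                         distance: str = "one-minus-r") -> ClusterTree:
    """Agglomerative clustering of items on d = 1 - r (or 1 - |r|).

    Items are processed in lexicographic label order so the result is
    invariant to the input ordering; ties in the merge sequence are then
    broken deterministically by that order.
    """
    R = _validate_correlation(R, labels)
    n = R.shape[0]
    labels = list(labels) if labels is not None else [f"item_{i + 1}" for i in range(n)]
    if len(labels) != n:
        raise SchemaError("label count does not match matrix dimension")
    order = np.argsort(np.asarray(labels, dtype=object))
    labels_sorted = [labels[i] for i in order]
    R = R[np.ix_(order, order)]
    if distance == "one-minus-r":
        D = 1.0 - R
    elif distance == "one-minus-abs-r":
        D = 1.0 - np.abs(R)
    else:
        raise ValueError("distance must be 'one-minus-r' or 'one-minus-abs-r'")
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage)
    return ClusterTree(labels=labels_sorted, linkage_matrix=Z, linkage=linkage,
                       distance=distance, distance_matrix=D)


def select_k(tree: ClusterTree, k_range=range(2, 7),
             allow_singletons: bool = False) -> int:
    """Cluster count maximising mean silhouette width over candidate cuts.

    Cuts producing singleton clusters are excluded unless none remain
    (or ``allow_singletons``); ties go to the smaller k.  With only two
    leaves the answer is forced to 2.
    """
    if tree.n_leaves < 3:
        return min(2, tree.n_leaves)
    D = tree.distance_matrix
    if D is None:
        raise ValueError("tree carries no distance matrix; build it with cluster_correlations")
    candidates = [k for k in k_range if 2 <= k <= tree.n_leaves - 1]
    scores = []
    for k in candidates:
        assignment = np.array([tree.cut(k)[lab] for lab in tree.labels])
        if len(np.unique(assignment)) < 2:
            continue
        singleton = bool(np.bincount(assignment)[1:].min() == 1)
        width = float(np.mean(silhouette_samples(D, assignment, metric="precomputed")))
        scores.append((k, width, singleton))
    if not scores:
        return 2
    eligible = [s for s in scores if allow_singletons or not s[2]] or scores
    best = max(eligible, key=lambda s: (s[1], -s[0]))
    return int(best[0])
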