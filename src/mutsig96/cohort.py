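"""Cohort classification from signature contributions.

Samples (or signatures) are compared by the correlation-based distance
d(i, j) = 1 - r(v_i, v_j), with r the Pearson correlation, and grouped by
agglomerative hierarchical clustering (complete linkage by default).  A PCA
on the mean-centered contribution matrix (no variance scaling) is available
for cohorts of more than three samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .refit import RefitResult

__all__ = [
    "CohortSummary",
    "Dendrogram",
    "contribution_matrix",
    "pearson_distance_matrix",
    "hierarchical_cluster",
    "pca",
    "summarize_cohort",
]


def contribution_matrix(refits: list[RefitResult]) -> tuple[list[str], np.ndarray]:
    """Stack relative contributions into an N x K matrix (rows sum to 1).

    Returns ``(sample_ids, matrix)``.  All refits must share one catalog.
    """
    if not refits:
        raise ValueError("no refit results supplied")
    names = refits[0].signature_names
    for r in refits[1:]:
        if r.signature_names != names:
            raise ValueError(
                f"refit for {r.sample_id!r} used a different signature catalog"
            )
    M = np.vstack([r.relative_contributions for r in refits])
    return [r.sample_id for r in refits], M


def pearson_distance_matrix(M: np.ndarray, axis: str = "samples") -> np.ndarray:
    """Square matrix of 1 - Pearson correlation between rows or columns.

    ``axis="samples"`` compares rows, ``axis="signatures"`` columns.  Entries
    lie in [0, 2] with an exactly zero diagonal.  A constant (zero-variance)
    vector has no defined correlation and raises.
    """
    M = np.asarray(M, dtype=float)
    if axis == "signatures":
        M = M.T
    elif axis != "samples":
        raise ValueError(f"axis must be 'samples' or 'signatures', got {axis!r}")
    if M.shape[0] < 2:
        raise ValueError("need at least two vectors to compute distances")
    sd = M.std(axis=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        raise ValueError(
            f"zero variance on {axis[:-1]} index {int(flat[0])}; "
            "Pearson distance undefined"
        )
    D = 1.0 - np.corrcoef(M)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over labelled leaves."""

    labels: list[str]
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 linkage encoding

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        tree = sch.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - (0.0 if node.is_leaf() else node.dist), 0.0)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def hierarchical_cluster(
    D: np.ndarray, labels: list[str] | None = None, linkage: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix.

    ``linkage`` is ``complete`` or ``average``.  Merges are deterministic;
    ties resolve to the lowest pair index, so leaf order is stable under
    input order.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"distance matrix must be square, got {D.shape}")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if linkage not in ("complete", "average"):
        raise ValueError(f"linkage must be 'complete' or 'average', got {linkage!r}")
    n = D.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count does not match matrix size")
    if n == 1:
        raise ValueError("cannot cluster a single element")
    condensed = squareform(D, checks=False)
    Z = sch.linkage(condensed, method=linkage)
    return Dendrogram(list(labels), Z)


def pca(M: np.ndarray, n_components: int | None = None):
    """PCA of an N x K matrix: centering only, no variance scaling.

    Gated to cohorts of more than three samples.  The sign of each component
    is fixed so that its largest-magnitude loading is positive.  Returns
    ``(coordinates, explained_variance_fractions, loadings)``.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if n <= 3:
        raise ValueError(
            f"PCA requires more than three samples (got {n}); "
            "gated for small cohorts"
        )
    centered = M - M.mean(axis=0)
    if not centered.any():
        raise ValueError("all samples identical; PCA of zero-variance data undefined")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    total_variance = (s**2).sum()
    # fix component signs: largest-|loading| entry positive
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    if n_components is not None:
        U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    coordinates = U * s
    explained = s**2 / total_variance
    return coordinates, explained, Vt


@dataclass
class CohortSummary:
    """All cohort-level classification outputs in one bundle."""

    sample_ids: list[str]
    signature_names: list[str]
    contribution_matrix: np.ndarray  # N x K, rows sum to 1
    sample_distance: np.ndarray
    signature_distance: np.ndarray | None
    sample_dendrogram: Dendrogram
    signature_dendrogram: Dendrogram | None
    pca_coordinates: np.ndarray | None
    pca_explained: np.ndarray | None


def summarize_cohort(refits: list[RefitResult], linkage: str = "complete") -> CohortSummary:
    """Distance matrices, dendrograms and (when N > 3) PCA for a cohort.

    Signature-axis outputs are skipped when a signature column has zero
    variance across samples (e.g. a signature fit nowhere); sample-axis
    clustering always runs.  PCA is attempted only for N > 3 and silently
    omitted when degenerate.
    """
    sample_ids, M = contribution_matrix(refits)
    if len(sample_ids) < 2:
        raise ValueError("cohort analysis needs at least two samples")
    Ds = pearson_distance_matrix(M, axis="samples")
    sample_dend = hierarchical_cluster(Ds, sample_ids, linkage)
    names = refits[0].signature_names
    try:
        Dk = pearson_distance_matrix(M, axis="signatures")
        sig_dend = hierarchical_cluster(Dk, names, linkage)
    except ValueError:
        Dk, sig_dend = None, None
    coords = explained = None
    if len(sample_ids) > 3:
        try:
            coords, explained, _ = pca(M)
        except ValueError:
            pass
    return CohortSummary(
        sample_ids=sample_ids,
        signature_names=list(names),
        contribution_matrix=M,
        sample_distance=Ds,
        signature_distance=Dk,
        sample_dendrogram=sample_dend,
        signature_dendrogram=sig_dend,
        pca_coordinates=coords,
        pca_explained=explained,
    )
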