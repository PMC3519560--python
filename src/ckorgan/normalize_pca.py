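"""Organ-effect normalization, gene selection, PCA of condition means, and
bootstrap support-tree clustering.

The organ effect dominates the variance of the condition-mean profiles, so
before comparing the *response* patterns of the two organs it is removed
by shifting each gene's five shoot means so that their average equals the
average of its five root means:

    norm(shoot, c) = raw(shoot, c) + mean_c raw(root, c) - mean_c raw(shoot, c)
    norm(root, c)  = raw(root, c)

PCA operates on the 10 condition-mean profiles (not the 40 arrays) of a
restricted gene set — well-detected genes with a strongly significant
effect — using gene-wise centring without scaling (covariance PCA).
Support-tree clustering of the same profiles (Pearson-correlation
distance, average linkage) attaches to each internal branch the fraction
of gene-resampled bootstrap trees containing the same sample bipartition.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import Thresholds
from .design import ORGANS


def organ_normalize(means: pd.DataFrame) -> pd.DataFrame:
    """Remove the per-gene organ main effect from condition means.

    ``means`` has MultiIndex columns (organ, condition); genes with any
    missing cell are dropped.  Root values are returned unchanged; shoot
    values are shifted by the gene's root-minus-shoot average, so the
    per-gene organ main effect of the result is exactly zero.
    """
    complete = means.dropna(axis=0, how="any")
    root = complete.loc[:, "root"]
    shoot = complete.loc[:, "shoot"]
    offset = root.mean(axis=1) - shoot.mean(axis=1)
    norm = complete.copy()
    for cond in shoot.columns:
        norm[("shoot", cond)] = shoot[cond] + offset
    return norm


def select_pca_genes(detection: pd.DataFrame, stats: pd.DataFrame,
                     th: Thresholds | None = None) -> list[str]:
    """Genes with >= ``abb_model_min`` spots above background and at least
    one full-model q <= ``pca_q`` (the minimum over the three effects)."""
    th = th or Thresholds()
    q_cols = [c for c in ("q_organ", "q_condition", "q_interaction")
              if c in stats.columns]
    q_min = stats[q_cols].min(axis=1)
    abb_ok = detection["abb_total"] >= th.abb_model_min
    genes = [g for g in stats.index
             if abb_ok.get(g, False) and pd.notna(q_min[g])
             and q_min[g] <= th.pca_q]
    if not genes:
        raise ValueError("no gene passes the PCA selection; raise pca_q")
    return genes


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    eigenvalue_fractions: np.ndarray
    genes: list[str]


def run_pca(profiles: pd.DataFrame, genes: list[str] | None = None) -> PCAResult:
    """Covariance PCA of sample profiles (rows = samples, columns = genes).

    Genes are centred (no scaling); eigenvalue fractions over all
    components sum to 1; each component's sign is fixed by forcing its
    largest-magnitude gene loading positive.
    """
    if genes is not None:
        profiles = profiles.loc[:, genes]
    n_samples, n_genes = profiles.shape
    if n_samples < 2 or n_genes < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 genes")
    X = profiles.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)   # gene-wise centring
    if not np.any(X):
        raise ValueError("rank-0 matrix: all samples identical")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s ** 2   # proportional to the sample-covariance eigenvalues
    # sign convention: largest-|loading| of each component positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = pd.DataFrame(U * s, index=profiles.index,
                          columns=[f"PC{k + 1}" for k in range(len(s))])
    return PCAResult(scores=scores,
                     eigenvalue_fractions=eig / eig.sum(),
                     genes=list(profiles.columns))


# ---------------------------------------------------------------------------
# support-tree clustering
# ---------------------------------------------------------------------------

def _correlation_linkage(X: np.ndarray) -> np.ndarray:
    d = pdist(X, metric="correlation")
    if not np.all(np.isfinite(d)):
        raise ValueError("constant profile: correlation distance undefined")
    return hierarchy.linkage(d, method="average")

def _bipartitions(link: np.ndarray, n: int) -> set[frozenset[int]]:
    """Non-trivial sample bipartitions (as the smaller-side leaf set) of a
    linkage tree, identified by each internal node's leaf cluster."""
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    parts = set()
    for k, (a, b, _, _) in enumerate(link):
        cluster = members[int(a)] | members[int(b)]
        members[n + k] = cluster
        if 1 < len(cluster) < n:
            parts.add(min(cluster, frozenset(range(n)) - cluster, key=sorted))
    return parts

def _newick(link: np.ndarray, labels: list[str],
            support: dict[frozenset[int], float] | None) -> str:
    tree = hierarchy.to_tree(link)
    n = len(labels)

    def fmt(node):
        if node.is_leaf():
            return labels[node.id], frozenset([node.id])
        ls, lset = fmt(node.left)
        rs, rset = fmt(node.right)
        cluster = lset | rset
        label = ""
        if support is not None and 1 < len(cluster) < n:
            key = min(cluster, frozenset(range(n)) - cluster, key=sorted)
            label = f"{support[key]:.2f}"
        return f"({ls},{rs}){label}", cluster

    text, _ = fmt(tree)
    return text + ";"


@dataclass
class SupportTree:
    linkage: np.ndarray
    labels: list[str]
    support: dict[frozenset[int], float] | None

    def newick(self) -> str:
        return _newick(self.linkage, self.labels, self.support)

    def support_of(self, leaf_names: set[str]) -> float:
        """Bootstrap support of the bipartition separating ``leaf_names``
        from the rest."""
        idx = frozenset(self.labels.index(l) for l in leaf_names)
        n = len(self.labels)
        key = min(idx, frozenset(range(n)) - idx, key=sorted)
        if self.support is None:
            raise ValueError("tree was built without bootstrap supports")
        return self.support[key]


def support_tree(profiles: pd.DataFrame, n_boot: int = 100,
                 seed: int = 0) -> SupportTree:
    """Average-linkage tree of samples over correlation distance, with
    per-branch support = fraction of gene-resampled bootstrap trees
    containing the same sample bipartition.  ``n_boot=0`` returns the tree
    without supports.  Sample order does not affect topology or supports."""
    if profiles.shape[0] < 3:
        raise ValueError("support tree needs >= 3 samples")
    order = sorted(profiles.index)
    profiles = profiles.loc[order]
    X = profiles.to_numpy(dtype=float)
    link = _correlation_linkage(X)
    if n_boot == 0:
        return SupportTree(link, list(profiles.index), None)
    observed = _bipartitions(link, len(order))
    counts = {part: 0 for part in observed}
    rng = np.random.default_rng(seed)
    n_genes = X.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, n_genes, size=n_genes)
        try:
            boot_parts = _bipartitions(_correlation_linkage(X[:, cols]),
                                       len(order))
        except ValueError:  # degenerate resample
            continue
        for part in observed:
            if part in boot_parts:
                counts[part] += 1
    support = {part: counts[part] / n_boot for part in observed}
    return SupportTree(link, list(profiles.index), support)
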