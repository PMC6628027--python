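"""Expression analysis: variable-gene selection, sample clustering and
primary-vs-metastasis differential expression.

The matrix holds non-negative abundances (genes x samples); analyses run
on log2(x + 1). Unsupervised structure uses the most variable genes with
Euclidean distance and average-linkage agglomerative clustering.
Differential expression between primary and metastasis samples (the
thrombus is excluded — it cannot be assigned to either group) uses a
Welch two-sample t-test on log2 values with the fold change computed on
the back-transformed linear scale, and reports genes passing a raw
p-value cutoff together with an absolute fold-change cutoff; no multiple
testing correction is applied by default, matching the reported analysis
style of raw p < 0.01 with |FC| > 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

UP, DOWN = "up_in_metastasis", "down_in_metastasis"
VARIANCE_FLOOR = 1e-8


def log_transform(matrix: pd.DataFrame, pseudo: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudo) transform of a non-negative abundance matrix."""
    if (matrix < 0).any().any():
        raise ValueError("expression values must be non-negative")
    return np.log2(matrix + pseudo)


def select_variable_genes(matrix: pd.DataFrame, n: int = 500) -> list[str]:
    """The ``n`` genes with highest variance across samples (log2 input).

    Deterministic: ties are broken by gene identifier.
    """
    if n > len(matrix):
        warnings.warn(f"requested {n} genes but matrix has {len(matrix)}; "
                      "returning all", stacklevel=2)
        n = len(matrix)
    var = matrix.var(axis=1, ddof=1)
    order = pd.DataFrame({"_var": var.to_numpy(),
                          "_gene": matrix.index.astype(str)},
                         index=matrix.index)
    order.index.name = None
    order = order.sort_values(["_var", "_gene"], ascending=[False, True],
                              kind="stable")
    return list(order.index[:n])


def cluster_samples(matrix: pd.DataFrame, gene_subset=None,
                    method: str = "average"):
    """Agglomerative clustering of samples over a gene subset.

    Euclidean distance on log2 values, average linkage by default.
    Returns ``(linkage_matrix, newick, sample_order)``; the Newick string
    encodes merge heights as branch lengths.
    """
    sub = matrix.loc[gene_subset] if gene_subset is not None else matrix
    X = sub.to_numpy(dtype=float).T
    labels = list(sub.columns)
    if len(labels) < 2:
        raise ValueError("need at least two samples")
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=method)
    newick = _linkage_to_newick(Z, labels)
    return Z, newick, labels


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = max(parent_height - (0.0 if node.is_leaf() else node.dist), 0.0) \
            if parent_height is not None else 0.0
        if node.is_leaf():
            length = parent_height if parent_height is not None else 0.0
            return f"{labels[node.id]}:{length:.6f}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        if parent_height is None:
            return f"({left},{right})"
        return f"({left},{right}):{length:.6f}"

    return rec(tree, None) + ";"


def cut_clusters(Z: np.ndarray, labels: list[str], k: int = 2) -> list[frozenset]:
    """Cut the dendrogram into ``k`` flat clusters of sample labels."""
    assign = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return [frozenset(l for l, a in zip(labels, assign) if a == c)
            for c in sorted(set(assign))]


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # gene, mean_primary, mean_metastasis, fold_change, log2_fc, p, direction

    @property
    def reported(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def n_up(self) -> int:
        return int((self.reported["direction"] == UP).sum())

    @property
    def n_down(self) -> int:
        return int((self.reported["direction"] == DOWN).sum())


def differential_expression(matrix: pd.DataFrame, roles: dict[str, str],
                            fc_threshold: float = 3.0,
                            p_threshold: float = 0.01,
                            pseudo: float = 1.0,
                            correction: str | None = None) -> DifferentialResult:
    """Primary-vs-metastasis differential expression.

    ``matrix`` holds linear-scale abundances; thrombus samples are removed
    before testing. Per gene a Welch t-test compares log2 values between
    groups and the linear fold change is the ratio of back-transformed
    group means; reported genes satisfy both cutoffs. ``correction='bh'``
    optionally applies Benjamini-Hochberg to the p-values (off by
    default).
    """
    prim = [s for s in matrix.columns if roles.get(s) == "primary"]
    mets = [s for s in matrix.columns if roles.get(s) == "metastasis"]
    if len(prim) < 2 or len(mets) < 2:
        raise ValueError("need at least two samples per group")
    logm = log_transform(matrix, pseudo)
    A = logm[mets].to_numpy(dtype=float)   # metastasis group
    B = logm[prim].to_numpy(dtype=float)   # primary group

    va = np.maximum(A.var(axis=1, ddof=1), VARIANCE_FLOOR)
    vb = np.maximum(B.var(axis=1, ddof=1), VARIANCE_FLOOR)
    na, nb = A.shape[1], B.shape[1]
    se2 = va / na + vb / nb
    t = (A.mean(axis=1) - B.mean(axis=1)) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)

    if correction == "bh":
        p = _benjamini_hochberg(p)

    mean_met = (matrix[mets]).mean(axis=1).to_numpy() + pseudo
    mean_prim = (matrix[prim]).mean(axis=1).to_numpy() + pseudo
    ratio = mean_met / mean_prim
    fc = np.where(ratio >= 1, ratio, 1.0 / ratio)
    direction = np.where(ratio >= 1, UP, DOWN)

    table = pd.DataFrame({
        "gene": matrix.index,
        "mean_primary": mean_prim - pseudo,
        "mean_metastasis": mean_met - pseudo,
        "fold_change": fc,
        "log2_fc": np.log2(ratio),
        "p_value": p,
        "direction": direction,
    }).set_index("gene", drop=False)
    table["significant"] = (table["fold_change"] > fc_threshold) & (table["p_value"] < p_threshold)
    return DifferentialResult(table)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
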