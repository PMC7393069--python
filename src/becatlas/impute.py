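"""Markov affinity-based graph imputation of expression.

A cell-cell Markov transition matrix is built from an adaptive gaussian
kernel on a k-nearest-neighbor graph in PC space; raising it to a small
power ``t`` and applying it to the expression matrix diffuses each gene's
values across similar cells, denoising without changing the overall scale.

Imputed values are used only for gene ordering in trajectory heatmaps —
never for clustering, differential expression, module scores, or entropy.
No post-hoc rescaling of the imputed values is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import BecatlasError, NormMatrix, get_logger, knn_no_self

log = get_logger("impute")

__all__ = ["AffinityGraph", "build_markov", "impute"]

DEFAULT_T = 2
DEFAULT_K = 9
DEFAULT_KA = 3


@dataclass
class AffinityGraph:
    """Row-stochastic cells x cells transition matrix with its parameters."""

    M: sp.csr_matrix
    k: int
    ka: int
    bandwidths: np.ndarray

    def __post_init__(self) -> None:
        rs = np.asarray(self.M.sum(axis=1)).ravel()
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise BecatlasError("transition matrix rows must sum to 1")
        if self.M.nnz and self.M.data.min() < 0:
            raise BecatlasError("negative transition probabilities")


def build_markov(pcs: np.ndarray, k: int = DEFAULT_K, ka: int = DEFAULT_KA):
    """Adaptive-bandwidth gaussian kernel over the kNN graph, symmetrized
    and row-normalized.

    Per cell, the bandwidth is the distance to its ka-th nearest neighbor;
    the kernel K_ij = exp(-(d_ij / sigma_i)^2) over the k nearest neighbors.
    """
    pcs = np.asarray(pcs, dtype=float)
    n = pcs.shape[0]
    if not (k > ka >= 1):
        raise BecatlasError("need k > ka >= 1")
    if n < k + 1:
        raise BecatlasError(f"need at least {k + 1} cells")
    # query a few extra neighbors so exact ties at the k-th distance are
    # included for everyone — coincident cells then get identical rows
    dist, ind = knn_no_self(pcs, min(k + 8, n - 1))
    sigma = dist[:, ka - 1].copy()
    sigma[sigma == 0] = np.finfo(float).tiny ** 0.25  # coincident cells
    kth = dist[:, k - 1][:, None]
    keep = dist <= kth + 1e-12
    Kvals = np.exp(-((dist / sigma[:, None]) ** 2)) * keep
    rows = np.repeat(np.arange(n), ind.shape[1])
    K = sp.csr_matrix((Kvals.ravel(), (rows, ind.ravel())), shape=(n, n))
    K.eliminate_zeros()
    K = (K + K.T) * 0.5
    rowsum = np.asarray(K.sum(axis=1)).ravel()
    M = sp.diags(1.0 / rowsum) @ K
    return AffinityGraph(M.tocsr(), k, ka, sigma)


def impute(norm: NormMatrix, graph: AffinityGraph, t: int = DEFAULT_T) -> np.ndarray:
    """Diffuse each gene across the cell graph: imputed = X @ (M^t)^T.

    ``t = 0`` returns the input exactly.  Because M is row-stochastic, a
    constant gene stays exactly constant and imputed values stay within the
    convex hull of the originals.
    """
    if t < 0 or int(t) != t:
        raise BecatlasError("t must be a non-negative integer")
    if graph.M.shape[0] != norm.n_cells:
        raise BecatlasError("graph and matrix dimensions differ")
    out = norm.X.copy()
    for _ in range(int(t)):
        out = (graph.M @ out.T).T
    return out
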