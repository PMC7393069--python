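"""Clustering, subset annotation, label transfer, batch alignment, and
cell-cycle classification.

The core sample is clustered by shared-nearest-neighbor (SNN) graph
community detection (Leiden modularity optimization); the arterial, HEC and
CRP clusters are then subdivided by trajectory distance into near/far
termini (pre-Art/Art, HEC/HEC-late, CRP/CRP-early), yielding 11 subsets.
Other samples receive labels by maximal Pearson correlation with the core
subset centroids over a shared variable-gene list.  Technical batches are
aligned with mutual-nearest-neighbor (MNN) correction vectors, and the same
machinery aligns dividing cells onto their resting counterparts to remove
the cell-cycle effect from embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from . import genescore
from .core import BecatlasError, NormMatrix, get_logger, knn_no_self

log = get_logger("annotate")

__all__ = [
    "pc_embedding",
    "cluster_core",
    "subdivide_termini",
    "centroid_profiles",
    "transfer_labels",
    "mnn_align",
    "classify_cycle",
    "remove_cycle_effect",
]

DEFAULT_RESOLUTION = 0.3
DEFAULT_N_PCS = 20
SNN_K = 20
SNN_PRUNE = 1.0 / 15.0
CYCLE_THRESHOLD = 0.6
SUBDIVISION_QUANTILE = 0.5
MNN_K = 20


def pc_embedding(
    norm: NormMatrix, genes=None, n_pcs: int = DEFAULT_N_PCS, seed: int = 0
) -> np.ndarray:
    """Cells x n_pcs PCA embedding of the (optionally gene-restricted)
    log-normalized matrix."""
    X = norm.X if genes is None else norm.X[norm.gene_index(genes)]
    if X.shape[1] <= n_pcs:
        raise BecatlasError("fewer cells than principal components")
    return PCA(n_components=n_pcs, svd_solver="randomized",
               random_state=seed).fit_transform(X.T)


def _snn_graph(pcs: np.ndarray, k: int = SNN_K) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph."""
    n = pcs.shape[0]
    _, ind = knn_no_self(pcs, k)
    # each cell's neighborhood includes itself for the Jaccard overlap
    ind = np.column_stack([np.arange(n), ind])
    k_eff = ind.shape[1]
    rows = np.repeat(np.arange(n), k_eff)
    A = sp.csr_matrix(
        (np.ones(n * k_eff), (rows, ind.ravel())), shape=(n, n)
    )
    shared = (A @ A.T).tocoo()
    jac = shared.data / (2 * k_eff - shared.data)
    keep = jac >= SNN_PRUNE
    S = sp.csr_matrix(
        (jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )
    S.setdiag(0)
    S.eliminate_zeros()
    return S


def cluster_core(
    norm: NormMatrix,
    hvg,
    resolution: float = DEFAULT_RESOLUTION,
    n_pcs: int = DEFAULT_N_PCS,
    exclude_genes=(),
    seed: int = 0,
    pcs: np.ndarray | None = None,
) -> pd.Series:
    """SNN-graph Leiden clustering of the core sample.

    ``exclude_genes`` removes cell-cycle genes (and any other unwanted
    features) from the HVG list before PCA.  ``pcs`` supplies a precomputed
    (e.g. batch- or cycle-corrected) embedding in the matrix's cell order,
    bypassing the internal PCA.  Cells are canonically re-ordered by id
    internally, so the partition does not depend on input cell order.
    Cluster ids are renumbered by decreasing size.
    """
    features = [g for g in hvg if g not in set(exclude_genes)]
    order = np.argsort(norm.cell_ids.astype(str), kind="stable")
    canon = norm.subset_cells(order)
    if pcs is None:
        pcs = pc_embedding(canon, features, n_pcs=n_pcs, seed=seed)
    else:
        pcs = np.asarray(pcs, dtype=float)[order]
    S = _snn_graph(pcs)
    coo = S.tocoo()
    mask = coo.row < coo.col
    g = ig.Graph(
        n=S.shape[0],
        edges=list(zip(coo.row[mask], coo.col[mask])),
        edge_attrs={"weight": coo.data[mask]},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    lab = np.array(part.membership)
    # rename by decreasing cluster size for stable ids
    sizes = pd.Series(lab).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    lab = np.array([remap[x] for x in lab])
    out = pd.Series(index=canon.cell_ids, data=lab, name="major_cluster")
    out = out.reindex(norm.cell_ids)
    log.info("cluster_core: %d clusters at resolution %.2f", lab.max() + 1,
             resolution)
    return out


def subdivide_termini(
    labels: pd.Series,
    traj,
    root_cells,
    q: float = SUBDIVISION_QUANTILE,
    terminal_map: dict | None = None,
) -> pd.Series:
    """Split terminus clusters by trajectory distance from the root.

    Within each cluster named in ``terminal_map`` (default: Art, HEC, CRP),
    cells beyond the within-cluster quantile ``q`` of distance from
    ``root_cells`` (the capillary hub) receive the far label (Art, HEC-late,
    CRP-early) and the rest the near label (pre-Art, HEC, CRP).  ``q = 1``
    is the identity.
    """
    from .trajectory import distance_from  # local import: no cycle at load

    if terminal_map is None:
        terminal_map = {
            "Art": ("pre-Art", "Art"),
            "HEC": ("HEC", "HEC-late"),
            "CRP": ("CRP", "CRP-early"),
        }
    labels = pd.Series(labels).copy()
    root_dist = distance_from(traj, root_cells)
    for cluster, (near, far) in terminal_map.items():
        mask = (labels == cluster).to_numpy()
        if not mask.any():
            raise BecatlasError(f"terminus cluster {cluster} missing")
        d = root_dist[mask]
        cut = np.quantile(d, q)
        sub = np.where(d > cut, far, near)
        labels.iloc[np.flatnonzero(mask)] = sub
    return labels


def name_clusters(
    norm: NormMatrix, clusters: pd.Series, marker_sets, seed: int = 0
) -> pd.Series:
    """Name each cluster after its best-scoring marker program.

    For every cluster, the mean module score of each candidate marker set is
    computed over the cluster's cells; the cluster takes the name of the
    argmax set.  Several clusters may share a name (they merge).
    """
    clusters = pd.Series(clusters).reindex(norm.cell_ids)
    scores = {}
    for i, s in enumerate(marker_sets):
        scores[s.name] = genescore.module_score(norm, s.genes, seed=seed + i)
    names = sorted(scores)
    S = np.vstack([scores[n] for n in names])
    out = {}
    for c in clusters.dropna().unique():
        m = (clusters == c).to_numpy()
        out[c] = names[int(np.argmax(S[:, m].mean(axis=1)))]
    return clusters.map(out)


def centroid_profiles(norm: NormMatrix, labels: pd.Series, genes) -> pd.DataFrame:
    """Mean log-normalized expression per subset over a shared gene list."""
    idx = norm.gene_index(genes)
    labels = pd.Series(labels).reindex(norm.cell_ids)
    cols = {}
    for s in sorted(labels.dropna().unique()):
        m = (labels == s).to_numpy()
        cols[s] = norm.X[np.ix_(idx, np.flatnonzero(m))].mean(axis=1)
    return pd.DataFrame(cols, index=norm.gene_ids[idx])


def reference_gene_stats(norm: NormMatrix, genes) -> pd.DataFrame:
    """Per-gene mean and standard deviation of the reference sample.

    Used to standardize genes before centroid correlation, so abundant
    shared programs do not dominate the correlation over subset markers.
    """
    idx = norm.gene_index(genes)
    return pd.DataFrame(
        {"mean": norm.X[idx].mean(axis=1), "sd": norm.X[idx].std(axis=1)},
        index=norm.gene_ids[idx],
    )


def transfer_labels(
    query: NormMatrix,
    centroids: pd.DataFrame,
    gene_stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign each query cell the subset of its maximally Pearson-correlated
    centroid profile; record the best correlation as confidence.

    When ``gene_stats`` (reference per-gene mean/sd) is given, genes are
    z-scored with those statistics before the correlation; the same affine
    map is applied to query and centroid, so a query cell equal to a
    centroid still correlates at exactly 1.  Exact ties break to the
    lexicographically first subset name (logged).
    """
    if centroids.shape[1] < 2:
        raise BecatlasError("need at least 2 centroid profiles")
    common = [g for g in centroids.index if g in set(query.gene_ids)]
    if len(common) < 100:
        raise BecatlasError(f"gene overlap {len(common)} < 100")
    Q = query.X[query.gene_index(common)]  # genes x cells
    C = centroids.loc[common].to_numpy()  # genes x subsets
    if np.any(Q.std(axis=0) == 0):
        raise BecatlasError("zero-variance cell expression vector")
    if gene_stats is not None:
        mu = gene_stats.loc[common, "mean"].to_numpy()
        sd = gene_stats.loc[common, "sd"].to_numpy().copy()
        sd[sd == 0] = 1.0
        Q = (Q - mu[:, None]) / sd[:, None]
        C = (C - mu[:, None]) / sd[:, None]
    Qc = Q - Q.mean(axis=0, keepdims=True)
    Cc = C - C.mean(axis=0, keepdims=True)
    qn = np.linalg.norm(Qc, axis=0)
    if np.any(qn == 0):
        raise BecatlasError("zero-variance cell expression vector")
    R = (Qc.T @ Cc) / np.outer(qn, np.linalg.norm(Cc, axis=0))
    names = sorted(centroids.columns)
    order = [list(centroids.columns).index(s) for s in names]
    R = R[:, order]  # lexicographic column order -> argmax breaks ties right
    best = np.argmax(R, axis=1)
    ties = (R == R[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    if ties.any():
        log.info("transfer_labels: %d exact tie(s) broken lexicographically",
                 int(ties.sum()))
    return pd.DataFrame(
        {
            "subset": [names[b] for b in best],
            "transfer_confidence": R[np.arange(len(best)), best],
        },
        index=query.cell_ids,
    )


def _mnn_pairs(ref: np.ndarray, batch: np.ndarray, k: int):
    nn_rb = NearestNeighbors(n_neighbors=min(k, len(ref))).fit(ref)
    nn_br = NearestNeighbors(n_neighbors=min(k, len(batch))).fit(batch)
    ind_b_to_r = nn_rb.kneighbors(batch, return_distance=False)
    ind_r_to_b = nn_br.kneighbors(ref, return_distance=False)
    back = [set(row) for row in ind_r_to_b]
    pairs = [
        (r, b)
        for b, row in enumerate(ind_b_to_r)
        for r in row
        if b in back[r]
    ]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def mnn_align(batches: list, k_mnn: int = MNN_K) -> np.ndarray:
    """Merge batches onto the first by mutual-nearest-neighbor correction.

    Batches are merged in the order given; each batch is paired against the
    growing reference, per-pair correction vectors are smoothed over the
    batch's cells with a gaussian kernel (bandwidth 3x the mean pair
    distance), and the batch is shifted onto the reference.  Returns the
    corrected coordinates stacked in input order; the first batch is
    returned bit-identical.
    """
    if len(batches) < 2:
        raise BecatlasError("need at least 2 batches")
    for b in batches:
        if len(b) < k_mnn:
            raise BecatlasError(f"batch with {len(b)} < k_mnn={k_mnn} cells")
    ref = np.asarray(batches[0], dtype=float)
    corrected = [ref]
    pool = ref
    for bi, batch in enumerate(batches[1:], start=1):
        batch = np.asarray(batch, dtype=float)
        pairs = _mnn_pairs(pool, batch, k_mnn)
        if len(pairs) == 0:
            raise BecatlasError(f"no MNN pairs found for batch {bi}")
        vec = pool[pairs[:, 0]] - batch[pairs[:, 1]]
        # anchor each pair at its midpoint: the two orientations of a mutual
        # pair then share an anchor and their opposite vectors cancel, so
        # identical batches receive (numerically) zero correction
        anchors = 0.5 * (pool[pairs[:, 0]] + batch[pairs[:, 1]])
        pair_dist = np.linalg.norm(vec, axis=1)
        sigma = 3.0 * max(pair_dist.mean(), 1e-12)
        from scipy.spatial.distance import cdist

        shift = np.empty_like(batch)
        for lo in range(0, len(batch), 512):  # chunked: pairs can be many
            chunk = batch[lo:lo + 512]
            d2 = cdist(chunk, anchors, metric="sqeuclidean")
            w = np.exp(-d2 / (2 * sigma**2))
            w_sum = w.sum(axis=1, keepdims=True)
            w_sum[w_sum == 0] = 1.0
            shift[lo:lo + 512] = (w @ vec) / w_sum
        fixed = batch + shift
        corrected.append(fixed)
        pool = np.vstack([pool, fixed])
        log.info("mnn_align: batch %d, %d MNN pairs, mean |correction| %.3g",
                 bi, len(pairs), np.linalg.norm(shift, axis=1).mean())
    return np.vstack(corrected)


def classify_cycle(
    norm: NormMatrix,
    cycle_genes,
    tau: float = CYCLE_THRESHOLD,
    seed: int = 0,
) -> pd.Series:
    """Dividing/resting call from the pooled cell-cycle module score."""
    genes = list(getattr(cycle_genes, "genes", cycle_genes))
    present = norm.gene_index(genes)
    if len(present) < 5:
        raise BecatlasError("fewer than 5 cycle genes present")
    score = genescore.module_score(norm, genes, seed=seed)
    return pd.Series(score > tau, index=norm.cell_ids, name="is_dividing")


def remove_cycle_effect(
    pcs: np.ndarray, is_dividing: np.ndarray, k_mnn: int = MNN_K
) -> np.ndarray:
    """Align dividing cells onto resting cells in PC space.

    Resting cells keep their coordinates bit-identical; dividing cells are
    MNN-corrected onto the resting reference.  Used for embeddings and
    trajectories only — labels and expression are untouched.
    """
    pcs = np.asarray(pcs, dtype=float)
    is_dividing = np.asarray(is_dividing, dtype=bool)
    if not is_dividing.any():
        return pcs
    if is_dividing.sum() < k_mnn or (~is_dividing).sum() < k_mnn:
        log.warning("remove_cycle_effect: class below k_mnn, skipped")
        return pcs
    merged = mnn_align([pcs[~is_dividing], pcs[is_dividing]], k_mnn=k_mnn)
    out = pcs.copy()
    out[~is_dividing] = merged[: (~is_dividing).sum()]
    out[is_dividing] = merged[(~is_dividing).sum():]
    return out
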