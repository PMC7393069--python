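"""KNN-geodesic trajectory space, branch isolation, and smoothing.

Trajectory space is built by sampling L seed cells and computing
single-source shortest-path (geodesic) distances to every cell over a
k-nearest-neighbor graph with Euclidean edge weights in PC space.  The
resulting cells x L distance matrix T captures positions along the branching
manifold; its principal components (tPCs) give a low-dimensional projection
in which branches are isolated by axis-aligned gates.  Cells on a branch are
ordered by geodesic distance from a root population, distances are scaled to
the longest trajectory, and expression is smoothed along the branch with a
gaussian kernel (Nadaraya-Watson) for heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import average, leaves_list
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import pdist

from . import genescore
from .core import BecatlasError, NormMatrix, get_logger, knn_no_self

log = get_logger("trajectory")

__all__ = [
    "TrajectorySpace",
    "BranchPath",
    "tspace",
    "distance_from",
    "isolate_branch",
    "scale_distances",
    "smooth_along",
    "export_trajectory_heatmap",
]

DEFAULT_K = 20
DEFAULT_N_TPC = 5
SMOOTH_BANDWIDTH = 0.05
SMOOTH_GRID = 200
GATE_MARGIN = 0.05


@dataclass
class TrajectorySpace:
    """Geodesic trajectory-distance matrix and its principal components."""

    T: np.ndarray  # cells x L
    tpc: np.ndarray  # cells x n_tpc
    seed_indices: np.ndarray
    k: int
    graph: sp.csr_matrix  # symmetric weighted kNN graph (the metric)
    cell_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.T.shape[0]


@dataclass
class BranchPath:
    """Cells of one isolated trajectory, ordered by distance from the root."""

    branch: str
    cell_indices: np.ndarray  # into the trajectory's cell order
    cell_ids: np.ndarray
    distance: np.ndarray  # from root, non-decreasing along the order
    scaled: np.ndarray | None = None


def _knn_graph(pcs: np.ndarray, k: int) -> sp.csr_matrix:
    n = pcs.shape[0]
    dist, ind = knn_no_self(pcs, k)
    rows = np.repeat(np.arange(n), ind.shape[1])
    G = sp.csr_matrix((dist.ravel(), (rows, ind.ravel())), shape=(n, n))
    return G.maximum(G.T)


def tspace(
    pcs: np.ndarray,
    k: int = DEFAULT_K,
    L: int | None = None,
    seed: int = 0,
    n_tpc: int = DEFAULT_N_TPC,
    cell_ids=None,
) -> TrajectorySpace:
    """Trajectory space from a cells x d PC matrix.

    ``k`` is raised automatically (logged) until the kNN graph is connected.
    Seeds are the first L entries of a seeded permutation of the cells taken
    in canonical (id-sorted) order, so enlarging L only appends columns and
    the result does not depend on input cell order.
    """
    pcs = np.asarray(pcs, dtype=float)
    n = pcs.shape[0]
    if cell_ids is None:
        cell_ids = np.array([f"c{i}" for i in range(n)], dtype=object)
    cell_ids = np.asarray(cell_ids, dtype=object)
    if L is None:
        L = min(100, max(2, n // 20))
    if L > n:
        raise BecatlasError("more seeds than cells")
    while True:
        G = _knn_graph(pcs, k)
        n_comp, _ = connected_components(G, directed=False)
        if n_comp == 1:
            break
        k += max(10, k // 2)
        log.info("tspace: graph disconnected, raising k to %d", k)
        if k >= n:
            raise BecatlasError("could not connect the kNN graph")
    canon = np.argsort(cell_ids.astype(str), kind="stable")
    rng = np.random.default_rng(seed)
    seeds = canon[rng.permutation(n)[:L]]
    T = dijkstra(G, directed=False, indices=seeds).T  # cells x L
    Tc = T - T.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Tc, full_matrices=False)
    # deterministic sign: largest-|loading| coordinate of each component > 0
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    tpc = (U * s)[:, :n_tpc] * signs[:n_tpc][None, :]
    return TrajectorySpace(T, tpc, seeds, k, G, cell_ids)


def distance_from(traj: TrajectorySpace, cells) -> np.ndarray:
    """Geodesic distance from a set of root cells (minimum over sources)."""
    cells = np.asarray(cells)
    if cells.dtype == bool:
        cells = np.flatnonzero(cells)
    if len(cells) == 0:
        raise BecatlasError("empty root cell set")
    d = dijkstra(traj.graph, directed=False, indices=cells, min_only=True)
    return np.asarray(d)


def isolate_branch(
    traj: TrajectorySpace,
    labels: pd.Series,
    branch_subsets,
    root_subsets,
    gates: dict | None = None,
    branch_name: str = "",
) -> BranchPath:
    """Select the cells of one trajectory and order them from the root.

    ``gates`` maps tPC index (0-based, first five) to (lo, hi) intervals —
    a programmatic surrogate for manual gating in tPC projections.  The
    default gate is the bounding box of the branch subsets' tPC1-5
    coordinates with a 5% margin.  The root population is given by
    ``root_subsets`` (early-CRP for arterial/venous paths, CapEC for the
    Vn path).
    """
    labels = pd.Series(labels).reindex(traj.cell_ids)
    member = labels.isin(list(branch_subsets)).to_numpy()
    if gates is None:
        box = traj.tpc[member]
        if not member.any():
            raise BecatlasError("no cells in the named subsets")
        span = box.max(axis=0) - box.min(axis=0)
        gates = {
            j: (box[:, j].min() - GATE_MARGIN * span[j],
                box[:, j].max() + GATE_MARGIN * span[j])
            for j in range(traj.tpc.shape[1])
        }
    inside = member.copy()
    for j, (lo, hi) in gates.items():
        inside &= (traj.tpc[:, j] >= lo) & (traj.tpc[:, j] <= hi)
    if not inside.any():
        raise BecatlasError("branch gate selected no cells")
    roots = labels.isin(list(root_subsets)).to_numpy()
    if not roots.any():
        raise BecatlasError("root subsets have no cells")
    d = distance_from(traj, roots)
    idx = np.flatnonzero(inside)
    order = idx[np.argsort(d[idx], kind="stable")]
    return BranchPath(
        branch=branch_name or "+".join(branch_subsets),
        cell_indices=order,
        cell_ids=traj.cell_ids[order],
        distance=d[order],
    )


def scale_distances(paths: list) -> list:
    """Scale all paths by the maximum distance of the longest path.

    The longest path's far end maps exactly to 1; ratios within every path
    are preserved.
    """
    if not paths:
        raise BecatlasError("no paths to scale")
    global_max = max(p.distance.max() for p in paths)
    if global_max <= 0:
        raise BecatlasError("zero-length path")
    out = []
    for p in paths:
        out.append(
            BranchPath(p.branch, p.cell_indices, p.cell_ids, p.distance,
                       scaled=p.distance / global_max)
        )
    return out


def smooth_along(
    path: BranchPath,
    values: np.ndarray,
    h: float = SMOOTH_BANDWIDTH,
    grid: int = SMOOTH_GRID,
):
    """Gaussian-kernel (Nadaraya-Watson) smoothing along the trajectory.

    ``values`` is aligned with ``path``'s cell order; may be 1-D (one gene)
    or 2-D (genes x cells).  Returns (grid positions, smoothed values).
    """
    if h <= 0:
        raise BecatlasError("bandwidth must be positive")
    s = path.scaled if path.scaled is not None else path.distance
    if len(s) == 0:
        raise BecatlasError("empty path")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != len(s):
        raise BecatlasError("values not aligned with path cells")
    if np.isscalar(grid) or np.ndim(grid) == 0:
        gpos = np.linspace(s.min(), s.max(), int(grid))
    else:
        gpos = np.asarray(grid, dtype=float)
    w = np.exp(-((gpos[:, None] - s[None, :]) ** 2) / (2 * h**2))
    denom = w.sum(axis=1)
    # far outside the data the kernel mass underflows; fall back to the
    # nearest sample so the estimate stays defined
    empty = denom == 0
    if empty.any():
        nearest = np.abs(gpos[empty, None] - s[None, :]).argmin(axis=1)
        w[empty, :] = 0.0
        w[np.flatnonzero(empty), nearest] = 1.0
        denom = w.sum(axis=1)
    smoothed = (values @ w.T) / denom[None, :]
    return gpos, smoothed


def export_trajectory_heatmap(
    path: BranchPath,
    gene_groups: dict,
    imputed: np.ndarray,
    norm: NormMatrix,
    pooled_sets=None,
    h: float = SMOOTH_BANDWIDTH,
    grid: int = SMOOTH_GRID,
    seed: int = 0,
):
    """Smoothed, row-scaled trajectory heatmap with a fixed gene order.

    Gene order within each group comes from hierarchical clustering (average
    linkage, correlation distance) of the *imputed* expression profiles of
    the path's cells; the heatmap values themselves are smoothed from the
    raw log-normalized data and row-scaled so every gene's maximum is 1
    (all-zero rows are exempt and flagged).  A gene listed in two groups
    appears once per group and is clustered independently in each.  Pooled
    gene-set scores (e.g. an oscillatory-shear-stress set) are appended as
    extra rows via the module score.

    Returns (heatmap DataFrame, ordered gene list, flagged all-zero rows).
    """
    cells = path.cell_indices
    rows, row_names = [], []
    lookup = {g: i for i, g in enumerate(norm.gene_ids)}
    for group, genes in gene_groups.items():
        present = [g for g in genes if g in lookup]
        missing = [g for g in genes if g not in lookup]
        if missing:
            log.warning("heatmap: dropped %d absent gene(s) in group %s",
                        len(missing), group)
        if not present:
            continue
        gi = np.array([lookup[g] for g in present])
        if len(present) > 2:
            prof = imputed[np.ix_(gi, cells)]
            sd = prof.std(axis=1)
            safe = prof.copy()
            safe[sd == 0] += np.random.default_rng(0).normal(
                0, 1e-9, size=(int((sd == 0).sum()), prof.shape[1])
            )
            order = leaves_list(average(pdist(safe, metric="correlation")))
        else:
            order = np.arange(len(present))
        for o in order:
            rows.append(norm.X[gi[o], cells])
            row_names.append(f"{group}:{present[o]}")
    gpos, smoothed = smooth_along(path, np.vstack(rows), h=h, grid=grid)
    flagged = []
    for i, name in enumerate(row_names):
        mx = smoothed[i].max()
        if mx > 0:
            smoothed[i] = smoothed[i] / mx
        else:
            flagged.append(name)
    if pooled_sets is not None:
        for s in pooled_sets:
            score = genescore.module_score(norm, s.genes, seed=seed)[cells]
            _, sm = smooth_along(path, score, h=h, grid=gpos)
            smoothed = np.vstack([smoothed, sm])
            row_names.append(f"pooled:{s.name}")
    hm = pd.DataFrame(smoothed, index=row_names, columns=np.round(gpos, 6))
    return hm, row_names, flagged
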