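"""Signaling entropy rate (SR): a potency proxy per cell.

A cell's expression vector x over the genes of an interaction network A
defines a random walk with transition probabilities

    p_ij = A_ij x_j / sum_k A_ik x_k,

i.e. signal flows preferentially toward highly expressed interaction
partners.  The entropy rate of this walk, SR = sum_i pi_i S_i with pi the
stationary distribution and S_i the local Shannon entropy of row i, is
maximal when expression is promiscuously spread over the network (a
multipotent-like state) and low when it is channelled into few paths.
SR is normalized by its network-wide maximum, log lambda_max(A), to [0, 1].

Comparability across cells requires equal transcript counts, so the
pipeline first downsamples every cell to a fixed read depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import preprocess
from .core import BecatlasError, CountMatrix, Network, get_logger

log = get_logger("entropy")

__all__ = [
    "EntropyResult",
    "entropy_rate",
    "entropy_pipeline",
    "make_scale_free_network",
]

EXPR_FLOOR = 1e-8
POWER_TOL = 1e-10
DEFAULT_DEPTH = 1000
TOP_QUANTILE = 0.01


@dataclass
class EntropyResult:
    table: pd.DataFrame  # per cell: sr, sr_norm, retained, top1pct
    depth: int
    network_genes: list


def _largest_component(net: Network) -> Network:
    if net.number_of_nodes() == 0:
        raise BecatlasError("empty network")
    comp = max(nx.connected_components(net), key=len)
    return net.subgraph(comp).copy()


def _stationary(
    P: np.ndarray, tol: float = POWER_TOL, init: np.ndarray | None = None
) -> np.ndarray:
    """Stationary distribution of a row-stochastic irreducible matrix.

    Lazy power iteration (pi <- pi (P + I)/2), which shares P's stationary
    vector but converges even on (near-)bipartite walks.  ``init`` allows a
    warm start, e.g. the detailed-balance solution of a reversible walk.
    """
    n = P.shape[0]
    pi = np.full(n, 1.0 / n) if init is None else init / init.sum()
    for _ in range(100000):
        nxt = 0.5 * (pi + pi @ P)
        nxt /= nxt.sum()
        if np.abs(nxt - pi).max() < tol:
            return nxt
        pi = nxt
    raise BecatlasError("stationary distribution did not converge")


def entropy_rate(expr: np.ndarray, A: np.ndarray, lam_max: float | None = None):
    """SR of one cell's expression vector over adjacency matrix A.

    ``expr`` is ordered like A's rows; a small floor is added to avoid zero
    rows.  Returns (SR, normalized SR).
    """
    x = np.asarray(expr, dtype=float) + EXPR_FLOOR
    A = np.asarray(A, dtype=float)
    W = A * x[None, :]
    rowsum = W.sum(axis=1)
    if np.any(rowsum == 0):
        raise BecatlasError("disconnected node in the network component")
    P = W / rowsum[:, None]
    # the walk is reversible: detailed balance gives pi_i ~ x_i (A x)_i,
    # used as a warm start and confirmed by the iteration
    pi = _stationary(P, init=x * rowsum)
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(P), 0.0)
    S_local = -(P * logP).sum(axis=1)
    sr = float(pi @ S_local)
    if lam_max is None:
        lam_max = float(np.max(np.linalg.eigvalsh(A)))
    return sr, sr / np.log(lam_max)


def entropy_pipeline(
    counts: CountMatrix,
    net: Network,
    depth: int = DEFAULT_DEPTH,
    seed: int = 0,
) -> EntropyResult:
    """Downsample to fixed depth, compute SR per retained cell, flag top 1%."""
    net = _largest_component(net)
    genes = sorted(g for g in net.nodes if g in set(counts.gene_ids))
    sub = net.subgraph(genes)
    sub = _largest_component(sub)
    genes = sorted(sub.nodes)
    if len(genes) < 3:
        raise BecatlasError("network barely overlaps the count matrix")
    ds = preprocess.downsample_reads(counts, depth=depth, seed=seed)
    if ds.n_cells < 10:
        raise BecatlasError("fewer than 10 cells retained after downsampling")
    A = nx.to_numpy_array(sub, nodelist=genes)
    lam_max = float(np.max(np.linalg.eigvalsh(A)))
    gi = {g: i for i, g in enumerate(ds.gene_ids)}
    rows = np.array([gi[g] for g in genes])
    X = np.asarray(ds.X[rows].todense())
    sr = np.empty(ds.n_cells)
    sr_norm = np.empty(ds.n_cells)
    for j in range(ds.n_cells):
        sr[j], sr_norm[j] = entropy_rate(X[:, j], A, lam_max=lam_max)
    n_top = int(np.ceil(TOP_QUANTILE * ds.n_cells))
    top = np.zeros(ds.n_cells, dtype=bool)
    top[np.argsort(sr)[::-1][:n_top]] = True
    retained = pd.Index(counts.cell_ids).isin(ds.cell_ids)
    tab = pd.DataFrame(
        {
            "sr": pd.Series(sr, index=ds.cell_ids).reindex(counts.cell_ids),
            "sr_norm": pd.Series(sr_norm, index=ds.cell_ids).reindex(
                counts.cell_ids
            ),
            "retained": retained,
            "top1pct": pd.Series(top, index=ds.cell_ids)
            .reindex(counts.cell_ids)
            .fillna(False),
        },
        index=counts.cell_ids,
    )
    log.info("entropy_pipeline: %d cells retained, %d flagged top-1%%",
             ds.n_cells, n_top)
    return EntropyResult(tab, depth, genes)


def make_scale_free_network(
    programs: pd.DataFrame,
    n_nodes: int = 300,
    m: int = 3,
    seed: int = 0,
) -> Network:
    """Synthetic scale-free (Barabasi-Albert) interaction network whose hubs
    carry the CRP and capillary-core programs.

    High-degree nodes are assigned to CRP/CRP-early marker and capillary-core
    genes (so cells expressing those programs spread their walk over hubs and
    score high entropy), the lowest-degree nodes to Art and HEC-late markers,
    and the rest to housekeeping genes.
    """
    G = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    degree = dict(G.degree())
    nodes_by_degree = sorted(G.nodes, key=lambda v: (-degree[v], v))
    hub_genes = (
        programs.loc[
            (programs["program"] == "marker")
            & (programs["member_of"] == "CRP-early"), "gene_id"].tolist()
        + programs.loc[
            (programs["program"] == "marker")
            & (programs["member_of"] == "CRP"), "gene_id"].tolist()
        + programs.loc[
            programs["program"] == "capillary_core", "gene_id"].tolist()
    )
    leaf_genes = programs.loc[
        (programs["program"] == "marker")
        & programs["member_of"].isin(["Art", "HEC-late"]),
        "gene_id",
    ].tolist()
    hk = programs.loc[programs["program"] == "housekeeping", "gene_id"].tolist()
    mapping = {}
    leaves = nodes_by_degree[::-1]
    li = 0
    for g in leaf_genes:
        if li >= len(leaves):
            break
        mapping[leaves[li]] = g
        li += 1
    hi = 0
    for v in nodes_by_degree:
        if v in mapping:
            continue
        if hi < len(hub_genes):
            mapping[v] = hub_genes[hi]
            hi += 1
    rest = [v for v in nodes_by_degree if v not in mapping]
    for v, g in zip(rest, hk):
        mapping[v] = g
    unmapped = [v for v in G.nodes if v not in mapping]
    if unmapped:
        raise BecatlasError("not enough genes to label the network")
    return nx.relabel_nodes(G, mapping)
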