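"""Cross-tissue detection of CRP-like cells.

A query cell from another tissue is called CRP-like when two criteria hold
jointly:

1. its expression profile correlates more highly (Pearson) with the CRP
   centroid of the reference atlas than with every other subset centroid;
2. after mutual-nearest-neighbor alignment of the query onto the reference
   PC space, at least ``frac_threshold`` of its ``k_nn`` nearest reference
   cells carry a CRP/CRP-early label — a reproducible surrogate for manual
   co-embedding gating.

Tightening the neighborhood threshold can only shrink the called set, and
the two criteria commute (a conjunction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from . import annotate
from .core import BecatlasError, NormMatrix, get_logger

log = get_logger("crp")

__all__ = ["CrpCallTable", "detect_crp_like", "crp_like_profile"]

DEFAULT_K_NN = 30
DEFAULT_FRAC = 0.5
CRP_LABELS = ("CRP", "CRP-early")


@dataclass
class CrpCallTable:
    table: pd.DataFrame  # per query cell: best_subset, r_crp, nbhd_frac, crp_like
    k_nn: int
    frac_threshold: float


def detect_crp_like(
    query: NormMatrix,
    reference: NormMatrix,
    ref_labels: pd.Series,
    centroids: pd.DataFrame,
    gene_stats: pd.DataFrame | None = None,
    k_nn: int = DEFAULT_K_NN,
    frac_threshold: float = DEFAULT_FRAC,
    n_pcs: int = 20,
    tissue: str = "",
    seed: int = 0,
) -> CrpCallTable:
    """Call CRP-like cells in a query dataset against the reference atlas."""
    common = [g for g in reference.gene_ids if g in set(query.gene_ids)]
    if len(common) < 100:
        raise BecatlasError(f"shared gene list has {len(common)} < 100 genes")
    # criterion 1: maximal centroid correlation = CRP
    transfer = annotate.transfer_labels(query, centroids, gene_stats=gene_stats)
    crp_centroid = "CRP" if "CRP" in centroids.columns else CRP_LABELS[0]
    Q = query.X[query.gene_index(centroids.index)]
    c = centroids[crp_centroid].to_numpy()
    Qc = Q - Q.mean(axis=0, keepdims=True)
    cc = c - c.mean()
    r_crp = (Qc.T @ cc) / (
        np.linalg.norm(Qc, axis=0) * np.linalg.norm(cc) + 1e-300
    )
    crit1 = transfer["subset"].isin(CRP_LABELS).to_numpy()

    # criterion 2: neighborhood agreement after MNN co-embedding
    ref_idx = reference.gene_index(common)
    q_idx = query.gene_index(common)
    joint = np.concatenate([reference.X[ref_idx], query.X[q_idx]], axis=1)
    joint_norm = NormMatrix(
        joint,
        np.array(common, dtype=object),
        np.concatenate([reference.cell_ids, query.cell_ids]),
        np.ones(joint.shape[1]),
    )
    pcs = annotate.pc_embedding(joint_norm, n_pcs=n_pcs, seed=seed)
    ref_pcs, q_pcs = pcs[: reference.n_cells], pcs[reference.n_cells:]
    merged = annotate.mnn_align([ref_pcs, q_pcs])
    q_corr = merged[reference.n_cells:]
    labels = pd.Series(ref_labels).reindex(reference.cell_ids)
    is_crp_ref = labels.isin(CRP_LABELS).to_numpy()
    nn = NearestNeighbors(n_neighbors=min(k_nn, reference.n_cells)).fit(
        merged[: reference.n_cells]
    )
    ind = nn.kneighbors(q_corr, return_distance=False)
    nbhd_frac = is_crp_ref[ind].mean(axis=1)
    crit2 = nbhd_frac >= frac_threshold

    tab = pd.DataFrame(
        {
            "best_subset": transfer["subset"],
            "r_crp": r_crp,
            "nbhd_crp_fraction": nbhd_frac,
            "crp_like": crit1 & crit2,
            "tissue": tissue,
        },
        index=query.cell_ids,
    )
    log.info("detect_crp_like: %d / %d cells called CRP-like (%s)",
             int(tab["crp_like"].sum()), len(tab), tissue or "query")
    return CrpCallTable(tab, k_nn, frac_threshold)


def crp_like_profile(
    calls: CrpCallTable, query: NormMatrix, marker_panel
) -> pd.DataFrame:
    """Mean expression of the CRP marker panel in called vs uncalled cells.

    Panel genes absent from the query are omitted with a log line.  Returns
    an empty frame when no cell was called.
    """
    called = calls.table["crp_like"].reindex(query.cell_ids).to_numpy()
    if not called.any():
        log.info("crp_like_profile: no called cells")
        return pd.DataFrame()
    panel = list(getattr(marker_panel, "genes", marker_panel))
    present = [g for g in panel if g in set(query.gene_ids)]
    for g in panel:
        if g not in set(query.gene_ids):
            log.info("crp_like_profile: panel gene %s absent, omitted", g)
    rows = []
    for g in present:
        gi = query.gene_index([g])[0]
        a = query.X[gi, called]
        b = query.X[gi, ~called]
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        rows.append((g, a.mean(), b.mean(), t, p))
    return pd.DataFrame(
        rows, columns=["gene", "mean_called", "mean_uncalled", "t", "p"]
    ).set_index("gene")
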