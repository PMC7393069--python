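"""Quality filtering, normalization, and per-cell demultiplexing.

Normalization uses pooling-based size-factor deconvolution: cells are placed
on a ring ordered by library size, overlapping pools of several sizes are
summed, each pool's size factor is estimated as the median ratio of its
pooled profile to a reference pseudo-cell, and the per-cell factors are
recovered from the resulting linear system by least squares.  Pooling makes
the estimate robust to genes that are differentially expressed between
subsets, which would bias naive library-size scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import lsqr

from . import genescore
from .core import (
    BecatlasError,
    CountMatrix,
    GeneSetCollection,
    NormMatrix,
    get_logger,
)

log = get_logger("preprocess")

__all__ = [
    "FilterReport",
    "normalize",
    "filter_genes",
    "select_hvg",
    "remove_contaminants",
    "demux_sex",
    "downsample_reads",
]

MIN_CELLS = 3
MIN_MEAN = 0.3
POOL_SIZES = (21, 41, 61, 81, 101)
CONTAMINANT_SCORE_THRESHOLD = 0.8
SEX_MARGIN = 0.1


@dataclass
class FilterReport:
    genes_removed_lowcells: int = 0
    genes_removed_lowmean: int = 0
    cells_removed_by_class: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _ring_order(libsize: np.ndarray, cell_ids: np.ndarray) -> np.ndarray:
    """Deterministic ring ordering: sort by (library size, id), then
    interleave small and large so every pool mixes depths."""
    order = np.lexsort((cell_ids.astype(str), libsize))
    return np.concatenate([order[0::2], order[1::2][::-1]])


def normalize(counts: CountMatrix, pseudocount: float = 1.0) -> NormMatrix:
    """Pooling-deconvolution size factors, then log-transform.

    value = log(count / size_factor + pseudocount), natural log; size
    factors are rescaled to mean 1.
    """
    if counts.n_cells < 2:
        raise BecatlasError("normalize needs at least 2 cells")
    X = counts.X.tocsc().astype(float)
    libsize = np.asarray(X.sum(axis=0)).ravel()
    if np.any(libsize == 0):
        raise BecatlasError("cell(s) with zero total counts")
    n = counts.n_cells
    ring = _ring_order(libsize, counts.cell_ids)
    ref = np.asarray(X.mean(axis=1)).ravel()
    use = ref > 0

    pool_sizes = [p for p in POOL_SIZES if p <= n]
    if not pool_sizes:  # very small data: scale pools down
        pool_sizes = [max(2, n // 2)]
    rows, cols, vals, b = [], [], [], []
    eq = 0
    Xd = np.asarray(X[use].todense())
    refu = ref[use]
    cum = np.cumsum(Xd[:, ring], axis=1)
    cum = np.concatenate([np.zeros((cum.shape[0], 1)), cum], axis=1)
    for size in pool_sizes:
        for start in range(n):
            end = start + size
            if end <= n:
                pooled = cum[:, end] - cum[:, start]
                members = ring[start:end]
            else:  # wrap around the ring
                pooled = (cum[:, n] - cum[:, start]) + cum[:, end - n]
                members = np.concatenate([ring[start:], ring[: end - n]])
            ratio = np.median(pooled / refu)
            rows.extend([eq] * size)
            cols.extend(members)
            vals.extend([1.0] * size)
            b.append(ratio)
            eq += 1
    # low-weight anchor rows tie each factor to its library-size estimate,
    # removing the null space of the pooled system
    w = 0.1
    mean_lib = libsize.mean()
    for j in range(n):
        rows.append(eq)
        cols.append(j)
        vals.append(w)
        b.append(w * libsize[j] / mean_lib * _median_pool_scale())
        eq += 1
    A = sp.csr_matrix((vals, (rows, cols)), shape=(eq, n))
    sf = lsqr(A, np.array(b), atol=1e-10, btol=1e-10)[0]
    if np.any(sf <= 0):
        log.warning("normalize: %d non-positive size factors clipped",
                    int((sf <= 0).sum()))
        sf = np.clip(sf, sf[sf > 0].min() * 0.1, None)
    sf = sf / sf.mean()
    vals_norm = np.log(np.asarray(X.todense()) / sf[None, :] + pseudocount)
    return NormMatrix(
        vals_norm, counts.gene_ids, counts.cell_ids, sf, pseudocount, counts.obs
    )


def _median_pool_scale() -> float:
    # anchor rows and pooled rows share the same scale (reference pseudo-cell
    # has unit size factor), so no extra rescaling is required
    return 1.0


# ---------------------------------------------------------------------------
# gene filtering / HVG
# ---------------------------------------------------------------------------


def filter_genes(norm: NormMatrix, counts: CountMatrix):
    """Drop genes detected in fewer than 3 cells or with mean log-normalized
    expression below 0.3."""
    if not np.array_equal(norm.gene_ids, counts.gene_ids) or not np.array_equal(
        norm.cell_ids, counts.cell_ids
    ):
        raise BecatlasError("norm and counts matrices are not aligned")
    n_nonzero = np.asarray((counts.X > 0).sum(axis=1)).ravel()
    mean_norm = norm.X.mean(axis=1)
    low_cells = n_nonzero < MIN_CELLS
    low_mean = mean_norm < MIN_MEAN
    keep = ~(low_cells | low_mean)
    report = FilterReport(
        genes_removed_lowcells=int(low_cells.sum()),
        genes_removed_lowmean=int((low_mean & ~low_cells).sum()),
        thresholds={"min_cells": MIN_CELLS, "min_mean": MIN_MEAN},
    )
    log.info("filter_genes: kept %d / %d genes", int(keep.sum()), norm.n_genes)
    return norm.subset_genes(keep), report


def select_hvg(norm: NormMatrix, n: int, n_bins: int = 20) -> list:
    """Top-n highly variable genes by mean-binned dispersion z-score.

    Dispersion is variance/mean of the log-normalized values; genes are
    binned by mean expression (equal-frequency, 20 bins) and the dispersion
    is z-scored within each bin.  Ties break lexicographically by gene id;
    constant genes are never selected.
    """
    if n <= 0:
        raise BecatlasError("n must be positive")
    if n > norm.n_genes:
        raise BecatlasError("n exceeds the gene count")
    mean = norm.X.mean(axis=1)
    var = norm.X.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 1e-12, var / np.maximum(mean, 1e-12), 0.0)
    bins = genescore._expression_bins(mean, n_bins, ids=norm.gene_ids)
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        m = bins == b
        sd = disp[m].std()
        z[m] = (disp[m] - disp[m].mean()) / sd if sd > 0 else 0.0
    z[var == 0] = -np.inf
    order = sorted(range(norm.n_genes), key=lambda i: (-z[i], str(norm.gene_ids[i])))
    ranked = [i for i in order if np.isfinite(z[i])]
    return [norm.gene_ids[i] for i in ranked[:n]]


# ---------------------------------------------------------------------------
# supervised cell selection
# ---------------------------------------------------------------------------


def remove_contaminants(
    norm: NormMatrix,
    signatures: GeneSetCollection,
    threshold: float = CONTAMINANT_SCORE_THRESHOLD,
    seed: int = 0,
):
    """Remove cells scoring above ``threshold`` on any contaminant-class
    signature (lymphatic EC, pericytes, FRC, lymphocytes)."""
    if len(signatures) == 0:
        return norm, FilterReport(thresholds={"score": threshold})
    drop = np.zeros(norm.n_cells, dtype=bool)
    removed = {}
    for i, sig in enumerate(signatures):
        present = norm.gene_index(sig.genes)
        if len(present) == 0:
            log.warning("remove_contaminants: no %s signature gene present",
                        sig.name)
            removed[sig.name] = 0
            continue
        score = genescore.module_score(norm, sig.genes, seed=seed + i)
        hit = score > threshold
        removed[sig.name] = int(hit.sum())
        drop |= hit
    report = FilterReport(
        cells_removed_by_class=removed, thresholds={"score": threshold}
    )
    log.info("remove_contaminants: removed %d / %d cells", int(drop.sum()),
             norm.n_cells)
    return norm.subset_cells(~drop), report


def demux_sex(
    norm: NormMatrix,
    y_genes,
    xist_gene: str,
    delta: float = SEX_MARGIN,
    seed: int = 0,
) -> pd.Series:
    """Per-cell sex call from Y-linked vs Xist module scores.

    M if score(Y) - score(Xist) > delta, F if the reverse margin holds,
    otherwise ambiguous.
    """
    genes_y = list(getattr(y_genes, "genes", y_genes))
    if len(norm.gene_index(genes_y)) == 0 or len(norm.gene_index([xist_gene])) == 0:
        raise BecatlasError("both Y-linked genes and Xist must be present")
    s_y = genescore.module_score(norm, genes_y, seed=seed)
    s_x = genescore.module_score(norm, [xist_gene], seed=seed + 1)
    call = np.where(
        s_y - s_x > delta, "M", np.where(s_x - s_y > delta, "F", "ambiguous")
    )
    return pd.Series(call, index=norm.cell_ids, name="sex")


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------


def downsample_reads(counts: CountMatrix, depth: int = 1000, seed: int = 0):
    """Downsample every cell to exactly ``depth`` total reads.

    Reads are drawn without replacement (multivariate hypergeometric), so the
    per-gene expectation matches the original proportions and no gene exceeds
    its original count.  Cells with fewer than ``depth`` reads are dropped
    (entropy comparisons require equal depth).
    """
    if depth <= 0:
        raise BecatlasError("depth must be positive")
    rng = np.random.default_rng(seed)
    X = counts.X.tocsc()
    totals = np.asarray(X.sum(axis=0)).ravel()
    keep = totals >= depth
    if not np.all(keep):
        log.info("downsample_reads: dropped %d cell(s) below depth %d",
                 int((~keep).sum()), depth)
    cols = np.flatnonzero(keep)
    out = sp.lil_matrix((counts.n_genes, len(cols)), dtype=np.int64)
    for j_out, j in enumerate(cols):
        col = X[:, j]
        idx = col.indices
        vals = col.data.astype(np.int64)
        drawn = rng.multivariate_hypergeometric(vals, depth)
        nz = drawn > 0
        out[idx[nz], j_out] = drawn[nz]
    return CountMatrix(
        out.tocsr(),
        counts.gene_ids,
        counts.cell_ids[cols],
        counts.obs.iloc[cols],
    )
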