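"""Per-cell gene-set scoring with expression-matched random controls.

The module score of a gene set in a cell is the mean expression of the set's
genes minus the mean of randomly drawn control genes with similar average
expression: genes are binned by their mean expression across cells, and each
target gene contributes control genes sampled from its own bin.  Subtracting
bin-matched controls removes the depth/abundance component of the raw mean,
so the score reflects set-specific regulation.

The screen over a whole collection (e.g. all GO terms with at least three
expressed genes) produces a sets x cells score matrix; differentially
regulated sets are then found per subset by a one-vs-rest t-test with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BecatlasError, GeneSetCollection, NormMatrix, get_logger

log = get_logger("genescore")

__all__ = [
    "module_score",
    "score_all_sets",
    "go_screen",
    "ScoreMatrix",
    "GoScreenResult",
]

DEFAULT_N_BINS = 24
DEFAULT_N_CTRL = 100


@dataclass
class ScoreMatrix:
    """Sets x cells module-score matrix with control metadata."""

    scores: pd.DataFrame  # index: set names, columns: cell ids
    n_bins: int
    n_ctrl: int
    seed: int
    skipped_sets: list


@dataclass
class GoScreenResult:
    """One-vs-rest t-test results per (set, subset) pair."""

    table: pd.DataFrame  # columns: set, subset, mean_diff, t, p, p_adj, significant
    alpha: float


def _expression_bins(
    mean_expr: np.ndarray, n_bins: int, ids: np.ndarray | None = None
) -> np.ndarray:
    """Equal-frequency bin index per gene, by mean expression.

    Ties resolve by gene id when ``ids`` is given, so the binning does not
    depend on the order genes happen to appear in the matrix.
    """
    if ids is not None:
        order = np.lexsort((np.asarray(ids, dtype=str), mean_expr))
    else:
        order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(len(mean_expr), dtype=int)
    # split ranks into n_bins nearly equal chunks
    chunks = np.array_split(np.arange(len(mean_expr)), n_bins)
    for b, chunk in enumerate(chunks):
        bins[order[chunk]] = b
    return bins


def module_score(
    norm: NormMatrix,
    target_genes,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
    _bins: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell pooled score of ``target_genes`` against bin-matched controls.

    Returns an array of length ``n_cells``.  Deterministic under ``seed``.
    ``_bins`` allows a precomputed shared binning (used by
    :func:`score_all_sets`).
    """
    genes = [g for g in getattr(target_genes, "genes", target_genes)]
    idx = norm.gene_index(genes)
    if len(idx) == 0:
        raise BecatlasError("no target gene present in the matrix")
    if len(idx) < len(genes):
        log.warning(
            "module_score: %d of %d target genes absent", len(genes) - len(idx),
            len(genes),
        )
    mean_expr = norm.X.mean(axis=1)
    bins = (
        _bins if _bins is not None
        else _expression_bins(mean_expr, n_bins, ids=norm.gene_ids)
    )
    rng = np.random.default_rng(seed)
    # bin members in gene-id order, so the control draw is invariant to the
    # order genes appear in the matrix
    by_bin = {}
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        by_bin[b] = members[np.argsort(norm.gene_ids[members].astype(str))]
    ctrl_idx = np.concatenate(
        [rng.choice(by_bin[bins[i]], size=n_ctrl, replace=True) for i in idx]
    )
    target_mean = norm.X[idx].mean(axis=0)
    ctrl_mean = norm.X[ctrl_idx].mean(axis=0)
    return target_mean - ctrl_mean


def score_all_sets(
    norm: NormMatrix,
    sets: GeneSetCollection,
    min_expressed: int = 3,
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> ScoreMatrix:
    """Score every set in the collection; skip sets with fewer than
    ``min_expressed`` genes present in the matrix.

    The expression binning is computed once and shared across sets; each
    set's control draw is seeded by the master seed plus the set's index, so
    a row equals a stand-alone :func:`module_score` run with that derived
    seed and the shared bins.
    """
    if len(sets) == 0:
        raise BecatlasError("empty gene-set collection")
    mean_expr = norm.X.mean(axis=1)
    bins = _expression_bins(mean_expr, n_bins, ids=norm.gene_ids)
    rows, names, skipped = [], [], []
    for i, s in enumerate(sets):
        idx = norm.gene_index(s.genes)
        if len(idx) < min_expressed:
            skipped.append(s.name)
            continue
        rows.append(
            module_score(
                norm, s.genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + i,
                _bins=bins,
            )
        )
        names.append(s.name)
    if skipped:
        log.info("score_all_sets: skipped %d set(s) with <%d expressed genes",
                 len(skipped), min_expressed)
    scores = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, norm.n_cells)),
        index=names,
        columns=norm.cell_ids,
    )
    return ScoreMatrix(scores, n_bins, n_ctrl, seed, skipped)


def go_screen(
    scores: ScoreMatrix,
    labels: pd.Series,
    alpha: float = 0.001,
    pooled: bool = False,
) -> GoScreenResult:
    """One-vs-rest t-test of every scored set in every subset.

    Welch's unequal-variance t by default (``pooled=True`` restores the
    classic pooled-variance form).  Benjamini-Hochberg adjustment is applied
    jointly across all (set, subset) pairs; pairs are significant at adjusted
    p < ``alpha``.
    """
    labels = pd.Series(labels).reindex(scores.scores.columns)
    counts = labels.value_counts()
    usable = [s for s in counts.index if counts[s] >= 3]
    for s in counts.index:
        if counts[s] < 3:
            log.warning("go_screen: subset %s has <3 cells, skipped", s)
    if len(usable) < 2:
        raise BecatlasError("go_screen needs at least 2 subsets with >=3 cells")
    S = scores.scores.to_numpy()
    recs = []
    for subset in usable:
        in_mask = (labels == subset).to_numpy()
        a, b = S[:, in_mask], S[:, ~in_mask]
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=pooled)
        diff = a.mean(axis=1) - b.mean(axis=1)
        for i, name in enumerate(scores.scores.index):
            recs.append((name, subset, diff[i], t[i], p[i]))
    tab = pd.DataFrame(recs, columns=["set", "subset", "mean_diff", "t", "p"])
    tab["p"] = tab["p"].fillna(1.0)
    _, p_adj, _, _ = multipletests(tab["p"], method="fdr_bh")
    tab["p_adj"] = p_adj
    tab["significant"] = tab["p_adj"] < alpha
    # enrichment = significant with a positive shift (two-sided p also picks
    # up depleted sets, which are not "regulated up" in the subset)
    tab["enriched"] = tab["significant"] & (tab["mean_diff"] > 0)
    return GoScreenResult(tab, alpha)
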