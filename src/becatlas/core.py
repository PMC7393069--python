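"""Shared data model, file I/O, and logging for the BEC atlas pipeline.

Conventions used throughout the package:

* matrices are gene-major: rows are genes, columns are cells;
* genes and cells are identified by plain id strings, unique within a matrix;
* indexing is 0-based internally, 1-based only inside MatrixMarket files
  (a requirement of the format itself);
* all randomness is driven by explicit integer seeds.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "BecatlasError",
    "FormatError",
    "DimensionError",
    "CountMatrix",
    "NormMatrix",
    "GeneSet",
    "GeneSetCollection",
    "Network",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "get_logger",
    "stage_seed",
]

log = logging.getLogger("becatlas")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


def get_logger(stage: str) -> logging.Logger:
    """Return the stage-scoped logger (children of the ``becatlas`` root)."""
    return log.getChild(stage)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2**31 from a master seed.

    Uses a hash of the stage *name*, so toggling one stage on or off never
    shifts the randomness of the others.
    """
    import hashlib

    h = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def knn_no_self(X: np.ndarray, k: int):
    """k nearest neighbors of each row, excluding the row itself.

    With coincident points, sklearn may list a duplicate (distance 0) ahead
    of the query itself, so the self entry cannot be dropped by position;
    it is removed by index here.  Returns (distances, indices), each
    n x k.
    """
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, ind = nn.kneighbors(X)
    rows = np.arange(n)
    keep_dist = np.empty((n, k))
    keep_ind = np.empty((n, k), dtype=int)
    for i in rows:
        mask = ind[i] != i
        if mask.sum() == k + 1:  # self not listed at all (many duplicates)
            mask[-1] = False
        keep_dist[i] = dist[i][mask][:k]
        keep_ind[i] = ind[i][mask][:k]
    return keep_dist, keep_ind


class BecatlasError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(BecatlasError):
    """Malformed input file."""


class DimensionError(BecatlasError):
    """Matrix dimensions inconsistent with the accompanying metadata."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(np.unique(ids)) != len(ids):
        raise FormatError(f"duplicate {what} ids")


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with per-cell metadata.

    ``obs`` is indexed by ``cell_ids`` and carries at least a ``sample`` and a
    ``batch`` column for real pipelines; synthetic data adds truth columns.
    """

    X: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    obs: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.X.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DimensionError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.X.nnz and self.X.data.min() < 0:
            raise FormatError("negative counts")
        if self.X.nnz and not np.allclose(self.X.data, np.round(self.X.data)):
            raise FormatError("non-integer counts")
        if self.obs is None:
            self.obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.obs = self.obs.copy()
            if len(self.obs) != len(self.cell_ids):
                raise DimensionError("obs rows do not match cell count")
            self.obs.index = pd.Index(self.cell_ids, name="cell_id")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            self.X[:, idx], self.gene_ids, self.cell_ids[idx], self.obs.iloc[idx]
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(self.X[idx], self.gene_ids[idx], self.cell_ids, self.obs)


@dataclass
class NormMatrix:
    """Dense genes x cells matrix of log-normalized expression values."""

    X: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    size_factors: np.ndarray
    pseudocount: float = 1.0
    obs: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if self.X.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DimensionError("norm matrix shape mismatch")
        if len(self.size_factors) != len(self.cell_ids):
            raise DimensionError("size factor length mismatch")
        if np.any(self.size_factors <= 0):
            raise FormatError("size factors must be strictly positive")
        if not np.all(np.isfinite(self.X)):
            raise FormatError("non-finite normalized values")
        if self.obs is None:
            self.obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.obs = self.obs.copy()
            self.obs.index = pd.Index(self.cell_ids, name="cell_id")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def gene_index(self, genes) -> np.ndarray:
        """0-based row indices of ``genes`` (present genes only, order kept)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "NormMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormMatrix(
            self.X[:, idx],
            self.gene_ids,
            self.cell_ids[idx],
            self.size_factors[idx],
            self.pseudocount,
            self.obs.iloc[idx],
        )

    def subset_genes(self, mask: np.ndarray) -> "NormMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormMatrix(
            self.X[idx],
            self.gene_ids[idx],
            self.cell_ids,
            self.size_factors,
            self.pseudocount,
            self.obs,
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: list

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise FormatError("duplicate gene-set names")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list:
        return [s.name for s in self.sets]


# An undirected simple interaction graph over gene ids.
Network = nx.Graph


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _open_text(path: Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _maybe(path: Path) -> Path:
    """Return ``path`` or its ``.gz`` twin, whichever exists."""
    path = Path(path)
    if path.exists():
        return path
    gz = path.with_name(path.name + ".gz")
    if gz.exists():
        return gz
    raise FileNotFoundError(path)


def read_counts(path) -> CountMatrix:
    """Read a count matrix.

    ``path`` may be a 10x-style directory holding ``matrix.mtx`` +
    ``features.tsv`` + ``barcodes.tsv`` (optionally gzipped), or a dense TSV
    with gene ids in the first column and cell ids in the header.
    """
    path = Path(path)
    if path.is_dir():
        with _open_text(_maybe(path / "matrix.mtx"), "rb") as fh:
            X = scipy.io.mmread(fh)
        with _open_text(_maybe(path / "features.tsv")) as fh:
            genes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        with _open_text(_maybe(path / "barcodes.tsv")) as fh:
            cells = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        if X.shape != (len(genes), len(cells)):
            raise DimensionError(
                f"matrix is {X.shape} but features/barcodes give "
                f"({len(genes)}, {len(cells)})"
            )
        obs = None
        meta = path / "cell_metadata.tsv"
        if meta.exists():
            obs = pd.read_csv(meta, sep="\t", index_col=0, dtype={0: str})
        if X.nnz and (np.any(X.data < 0) or not np.allclose(X.data, np.round(X.data))):
            raise FormatError("counts must be non-negative integers")
        return CountMatrix(sp.csr_matrix(X, dtype=np.int64), genes, cells, obs)
    # dense TSV
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
        raise FormatError("counts must be non-negative integers")
    return CountMatrix(
        sp.csr_matrix(vals.astype(np.int64)), df.index.to_numpy(), df.columns.to_numpy()
    )


def write_counts(counts: CountMatrix, path, gz: bool = False) -> None:
    """Write a 10x-style MatrixMarket triplet directory (deterministic)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gz else ""
    coo = counts.X.tocoo()
    order = np.lexsort((coo.row, coo.col))  # column-major, the 10x convention
    with _open_text(path / f"matrix.mtx{suffix}", "wt") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{counts.n_genes} {counts.n_cells} {coo.nnz}\n")
        for i in order:
            fh.write(f"{coo.row[i] + 1} {coo.col[i] + 1} {int(coo.data[i])}\n")
    with _open_text(path / f"features.tsv{suffix}", "wt") as fh:
        for g in counts.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with _open_text(path / f"barcodes.tsv{suffix}", "wt") as fh:
        for c in counts.cell_ids:
            fh.write(f"{c}\n")
    if counts.obs.shape[1] > 0:
        counts.obs.to_csv(path / "cell_metadata.tsv", sep="\t")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets = []
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"GMT line {lineno}: fewer than 2 columns")
            name, desc = parts[0], parts[1]
            genes = []
            seen = set()
            for g in parts[2:]:
                if g and g not in seen:
                    seen.add(g)
                    genes.append(g)
            sets.append(GeneSet(name, desc, tuple(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with _open_text(Path(path), "wt") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_edge_list(path) -> Network:
    """Read a two-column whitespace-separated undirected edge list.

    Self-loops are dropped with a warning; duplicate edges collapse.
    """
    G = nx.Graph()
    n_self = 0
    with _open_text(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"edge list line {lineno}: fewer than 2 columns")
            a, b = parts[0], parts[1]
            if a == b:
                n_self += 1
                continue
            G.add_edge(a, b)
    if n_self:
        log.warning("read_edge_list: dropped %d self-loop(s)", n_self)
    return G


def write_edge_list(net: Network, path) -> None:
    with _open_text(Path(path), "wt") as fh:
        for a, b in sorted((sorted(e) for e in net.edges()), key=tuple):
            fh.write(f"{a} {b}\n")
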