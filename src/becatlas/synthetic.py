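"""Synthetic lymph-node blood-endothelial-cell (BEC) atlas generator.

Emulates a 10x-style UMI count experiment over a branching vascular manifold
so that every downstream stage of the pipeline can be tested against planted
ground truth.  The generated world contains:

* 11 BEC subsets laid out on three branches that meet at a capillary hub:

  - arterial branch:  CapEC2 -> pre-Art -> Art
  - CRP branch:       CapEC1 -> CRP -> CRP-early
  - venous branch:    TrEC -> HEC -> HEC-late, with a Vn spur leaving the
    trunk between TrEC and HEC (medullary veins branch from proximal HEC)

  CapIfn is an interferon-stimulated capillary population that shares the
  capillary core program but sits off the branch coordinate system.

* per-subset marker programs whose intensity is a smooth logistic function of
  manifold position, so adjacent subsets blend into a continuum rather than
  forming hard blocks;
* high endothelial cells (HEC, HEC-late) with distinctly higher UMI depth
  than all other subsets;
* a cell-division program carried by a subset-dependent fraction of cells,
  concentrated in CRP/CRP-early with smaller contributions from CapEC1 and
  TrEC;
* male cells expressing Y-linked genes and female cells expressing Xist;
* technical batches with per-gene multiplicative shifts;
* non-BEC contaminants (LEC, pericytes, FRC, lymphocytes) with their own
  marker programs and no EC programs.

Counts are negative-binomial draws around depth-scaled program means, thinned
by logistic dropout on the log mean, with the mean pre-compensated so that
per-cell totals still concentrate around the configured subset depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import (
    BecatlasError,
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    get_logger,
)

log = get_logger("synthetic")

__all__ = [
    "SUBSETS",
    "CONTAMINANT_CLASSES",
    "MAJOR_OF",
    "AtlasConfig",
    "generate_atlas",
    "generate_tissue_panel",
    "contaminant_signatures",
    "cycle_gene_set",
    "sex_gene_sets",
    "major_labels",
]

SUBSETS = (
    "Art",
    "pre-Art",
    "HEC",
    "HEC-late",
    "Vn",
    "CapEC1",
    "CapEC2",
    "CapIfn",
    "TrEC",
    "CRP",
    "CRP-early",
)

CONTAMINANT_CLASSES = ("LEC", "pericyte", "FRC", "lymphocyte")

#: terminus subdivisions collapse onto 8 major phenotypes
MAJOR_OF = {
    "Art": "Art",
    "pre-Art": "Art",
    "HEC": "HEC",
    "HEC-late": "HEC",
    "Vn": "Vn",
    "CapEC1": "CapEC1",
    "CapEC2": "CapEC2",
    "CapIfn": "CapIfn",
    "TrEC": "TrEC",
    "CRP": "CRP",
    "CRP-early": "CRP",
}

# branch layout: subset -> (branch, segment start, segment end) in [0, 1]
# manifold coordinates measured as distance from the capillary hub.
_SEGMENTS = {
    "CapEC2": ("arterial", 0.00, 0.40),
    "pre-Art": ("arterial", 0.40, 0.72),
    "Art": ("arterial", 0.72, 1.00),
    "CapEC1": ("crp", 0.00, 0.40),
    "CRP": ("crp", 0.40, 0.75),
    "CRP-early": ("crp", 0.75, 1.00),
    "TrEC": ("venous", 0.00, 0.35),
    "HEC": ("venous", 0.35, 0.70),
    "HEC-late": ("venous", 0.70, 1.00),
    # Vn is a spur off the venous trunk at the TrEC/HEC junction; its
    # coordinate continues the distance-from-hub scale.
    "Vn": ("venous", 0.38, 0.90),
}
_VN_JUNCTION = 0.35

_DEF_PROPORTIONS = {
    "Art": 0.050,
    "pre-Art": 0.060,
    "HEC": 0.150,
    "HEC-late": 0.050,
    "Vn": 0.080,
    "CapEC1": 0.150,
    "CapEC2": 0.200,
    "CapIfn": 0.030,
    "TrEC": 0.060,
    "CRP": 0.090,
    "CRP-early": 0.045,
}
_DEF_CONTAMINANTS = {"LEC": 0.010, "pericyte": 0.008, "FRC": 0.008, "lymphocyte": 0.009}

_DEF_DEPTH = {
    "Art": 4000.0,
    "pre-Art": 4000.0,
    "HEC": 10000.0,
    "HEC-late": 11000.0,
    "Vn": 5000.0,
    "CapEC1": 4500.0,
    "CapEC2": 4500.0,
    "CapIfn": 4500.0,
    "TrEC": 5000.0,
    "CRP": 5000.0,
    "CRP-early": 5000.0,
    "LEC": 3000.0,
    "pericyte": 3000.0,
    "FRC": 3000.0,
    "lymphocyte": 3000.0,
}

_DEF_DIVISION = {
    "Art": 0.005,
    "pre-Art": 0.005,
    "HEC": 0.005,
    "HEC-late": 0.005,
    "Vn": 0.005,
    "CapEC1": 0.035,
    "CapEC2": 0.005,
    "CapIfn": 0.005,
    "TrEC": 0.05,
    "CRP": 0.12,
    "CRP-early": 0.12,
    "LEC": 0.005,
    "pericyte": 0.005,
    "FRC": 0.005,
    "lymphocyte": 0.005,
}

_RAMP_WIDTH = 0.1  # logistic blending width, fraction of branch length
_MARKER_FOLD = 8.0
# HEC differentiation is the most extreme program in the tissue, which makes
# the CRP-to-HEC trajectory the longest; the venous terminus folds encode that
_MARKER_FOLD_BY_SUBSET = {"HEC": 10.0, "HEC-late": 14.0}
_CYCLE_FOLD = 8.0
_SEX_FOLD = 150.0
_CONTAM_FOLD = 10.0
_GO_FOLD = 5.0
_CORE_FOLD = 5.0
_DEPTH_JITTER_SD = 0.25  # lognormal sd of per-cell depth around subset mean


@dataclass
class AtlasConfig:
    """Parameters of the synthetic atlas.

    Defaults are the desk-scale study conditions: 5,000 cells and 2,000
    genes; :func:`preset_8832` gives the full-size preset.
    """

    n_cells: int = 5000
    n_genes: int = 2000
    subset_proportions: dict = field(default_factory=lambda: dict(_DEF_PROPORTIONS))
    contaminant_proportions: dict = field(
        default_factory=lambda: dict(_DEF_CONTAMINANTS)
    )
    marker_program_size: int = 40
    depth_means: dict = field(default_factory=lambda: dict(_DEF_DEPTH))
    division_propensity: dict = field(default_factory=lambda: dict(_DEF_DIVISION))
    sex_fractions: float = 0.5  # male fraction
    n_batches: int = 2
    batch_shift_sd: float = 0.15
    dispersion: float = 2.0  # NB size parameter; np.inf -> Poisson
    dropout_logit_slope: float = 1.0
    dropout_logit_intercept: float = -1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise BecatlasError("n_cells and n_genes must be positive")
        total = sum(self.subset_proportions.values()) + sum(
            self.contaminant_proportions.values()
        )
        if abs(total - 1.0) > 1e-9:
            raise BecatlasError(f"proportions sum to {total!r}, expected 1")
        if set(self.subset_proportions) != set(SUBSETS):
            raise BecatlasError("subset_proportions must cover exactly the 11 subsets")
        for k, v in self.division_propensity.items():
            if not 0.0 <= v <= 1.0:
                raise BecatlasError(f"division propensity for {k} outside [0,1]")
        for k, v in self.depth_means.items():
            if v <= 0:
                raise BecatlasError(f"depth mean for {k} not positive")
        hec_depth = min(self.depth_means["HEC"], self.depth_means["HEC-late"])
        others = [
            v
            for k, v in self.depth_means.items()
            if k in SUBSETS and k not in ("HEC", "HEC-late")
        ]
        if hec_depth <= max(others):
            raise BecatlasError("HEC depth means must exceed every non-HEC subset")
        if not 0.0 <= self.sex_fractions <= 1.0:
            raise BecatlasError("male fraction outside [0,1]")
        if self.batch_shift_sd < 0:
            raise BecatlasError("batch_shift_sd must be non-negative")


def preset_8832() -> AtlasConfig:
    """Full-size preset mirroring the 8,832-cell scale of the real dataset."""
    return AtlasConfig(n_cells=8832)


# ---------------------------------------------------------------------------
# gene program table
# ---------------------------------------------------------------------------

_GO_PROGRAMS = {
    "GO:venous-leukocyte": ("venous", 0.30),  # ramps up along the venous branch
    "GO:arterial-shear": ("arterial", 0.45),
    "GO:stem-spliceosome": ("crp", 0.60),
}


def _build_program_table(cfg: AtlasConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign every gene a program and a baseline mean rate.

    Programs: per-subset markers, the shared capillary core, the cell-cycle
    set, sex genes, contaminant class markers, three planted branch-linked
    gene sets standing in for GO terms, and housekeeping for the remainder.
    """
    m = cfg.marker_program_size
    rows = []
    for s in SUBSETS:
        rows += [("marker", s)] * m
    rows += [("capillary_core", "")] * m
    rows += [("cycle", "")] * m
    rows += [("y_linked", "")] * 6
    rows += [("xist", "")] * 1
    for c in CONTAMINANT_CLASSES:
        rows += [("contaminant_marker", c)] * 20
    for go in _GO_PROGRAMS:
        rows += [("go_set", go)] * 15
    demand = len(rows)
    if cfg.n_genes < demand:
        raise BecatlasError(
            f"n_genes={cfg.n_genes} smaller than total program demand {demand}"
        )
    rows += [("housekeeping", "")] * (cfg.n_genes - demand)
    tab = pd.DataFrame(rows, columns=["program", "member_of"])
    tab.insert(0, "gene_id", [f"g{i:05d}" for i in range(cfg.n_genes)])
    base = rng.lognormal(mean=-1.0, sigma=1.0, size=cfg.n_genes)
    # sex genes are near-silent in the wrong sex
    sexed = tab["program"].isin(["y_linked", "xist"]).to_numpy()
    base[sexed] = 0.02
    tab["baseline_mean"] = base
    return tab.set_index("gene_id", drop=False)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _segment_intensity(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """Logistic ramp up at ``a`` and down at ``b``, width ``_RAMP_WIDTH``."""
    w = _RAMP_WIDTH
    up = _sigmoid((x - a) / w) if a > 0 else np.ones_like(x)
    down = _sigmoid((b - x) / w) if b < 1 else np.ones_like(x)
    return up * down


def _program_intensities(
    subset: np.ndarray, branch: np.ndarray, position: np.ndarray
) -> dict:
    """Per-cell intensity in [0, 1] of every positional expression program."""
    n = len(subset)
    out = {}
    for s, (br, a, b) in _SEGMENTS.items():
        w = np.zeros(n)
        if s == "Vn":
            on = (subset == "Vn")
            u = position[on] - _VN_JUNCTION  # distance along the spur
            w[on] = _sigmoid((u - 0.05) / _RAMP_WIDTH)
        else:
            on = (branch == br) & (subset != "Vn")
            w[on] = _segment_intensity(position[on], a, b)
            # Vn cells near the junction retain trunk programs, decaying
            # with distance along the spur
            vn = subset == "Vn"
            if br == "venous" and vn.any():
                u = position[vn] - _VN_JUNCTION
                w[vn] = _segment_intensity(
                    np.full(vn.sum(), _VN_JUNCTION), a, b
                ) * np.exp(-u / 0.15)
        out[s] = w
    # interferon-stimulated capillaries: own program full-on, off-manifold
    out["CapIfn"] = (subset == "CapIfn").astype(float)
    # shared capillary core: high near the hub on every branch, CapIfn 0.7
    core = np.zeros(n)
    on_branch = branch != ""
    core[on_branch] = _sigmoid((0.45 - position[on_branch]) / _RAMP_WIDTH)
    core[subset == "CapIfn"] = 0.7
    out["capillary_core"] = core
    # planted GO-like branch programs
    for go, (br, onset) in _GO_PROGRAMS.items():
        w = np.zeros(n)
        on = branch == br
        w[on] = _sigmoid((position[on] - onset) / _RAMP_WIDTH)
        out[go] = w
    return out


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _sample_counts(
    mu: np.ndarray, cfg: AtlasConfig, rng: np.random.Generator
) -> np.ndarray:
    """NB(mean mu, size dispersion) draws thinned by logistic dropout."""
    if np.isfinite(cfg.dispersion):
        lam = rng.gamma(cfg.dispersion, mu / cfg.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    p_drop = _dropout_prob(mu, cfg)
    if np.any(p_drop > 0):
        keep = rng.random(size=mu.shape) >= p_drop
        counts = counts * keep
    return counts


def _dropout_prob(mu: np.ndarray, cfg: AtlasConfig) -> np.ndarray:
    if cfg.dropout_logit_intercept <= -15:  # effectively disabled
        return np.zeros_like(mu)
    z = cfg.dropout_logit_intercept - cfg.dropout_logit_slope * np.log(mu + 1e-12)
    return _sigmoid(z)


def _compensate_depth(
    mu: np.ndarray, target: np.ndarray, cfg: AtlasConfig, n_iter: int = 3
) -> np.ndarray:
    """Rescale means so expected post-dropout totals hit the target depths."""
    for _ in range(n_iter):
        expected = (mu * (1.0 - _dropout_prob(mu, cfg))).sum(axis=0)
        mu = mu * (target / np.maximum(expected, 1e-12))[None, :]
    return mu


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_atlas(cfg: AtlasConfig):
    """Generate one synthetic atlas.

    Returns
    -------
    (counts, truth, programs)
        ``counts`` is a :class:`~becatlas.core.CountMatrix`; ``truth`` a
        per-cell DataFrame with planted subset, branch, manifold position,
        division flag, sex, batch, and contaminant flag; ``programs`` the
        per-gene program table.
    """
    rng = np.random.default_rng(cfg.seed)
    programs = _build_program_table(cfg, rng)
    cm, truth, programs = _generate_with_rngs(cfg, programs, rng)
    log.info(
        "generated atlas: %d cells (%d contaminants), %d genes, %d dividing",
        cfg.n_cells,
        int(truth["is_contaminant"].sum()),
        cfg.n_genes,
        int(truth["is_dividing"].sum()),
    )
    return cm, truth, programs


def _expected_means(cfg, programs, subset, branch, position, is_dividing, sex,
                    batch, rng):
    """Depth-scaled expected expression matrix (genes x cells)."""
    n_cells = len(subset)
    base = programs["baseline_mean"].to_numpy()
    F = np.ones((cfg.n_genes, n_cells))

    intens = _program_intensities(subset, branch, position)
    prog = programs["program"].to_numpy()
    member = programs["member_of"].to_numpy()
    for s in SUBSETS:
        rows = np.flatnonzero((prog == "marker") & (member == s))
        fold = _MARKER_FOLD_BY_SUBSET.get(s, _MARKER_FOLD)
        F[rows] *= 1.0 + (fold - 1.0) * intens[s][None, :]
    rows = np.flatnonzero(prog == "capillary_core")
    F[rows] *= 1.0 + (_CORE_FOLD - 1.0) * intens["capillary_core"][None, :]
    for go in _GO_PROGRAMS:
        rows = np.flatnonzero((prog == "go_set") & (member == go))
        F[rows] *= 1.0 + (_GO_FOLD - 1.0) * intens[go][None, :]
    rows = np.flatnonzero(prog == "cycle")
    F[np.ix_(rows, np.flatnonzero(is_dividing))] *= _CYCLE_FOLD
    rows = np.flatnonzero(prog == "y_linked")
    F[np.ix_(rows, np.flatnonzero(sex == "M"))] *= _SEX_FOLD
    rows = np.flatnonzero(prog == "xist")
    F[np.ix_(rows, np.flatnonzero(sex == "F"))] *= _SEX_FOLD
    for c in CONTAMINANT_CLASSES:
        rows = np.flatnonzero((prog == "contaminant_marker") & (member == c))
        F[np.ix_(rows, np.flatnonzero(subset == c))] *= _CONTAM_FOLD

    if cfg.n_batches > 1 and cfg.batch_shift_sd > 0:
        shifts = np.ones((cfg.n_genes, cfg.n_batches))
        shifts[:, 1:] = np.exp(
            rng.normal(0.0, cfg.batch_shift_sd, size=(cfg.n_genes, cfg.n_batches - 1))
        )
        F *= shifts[:, batch]
    else:
        # keep the stream position stable whether or not shifts are planted
        rng.normal(size=(cfg.n_genes, max(cfg.n_batches - 1, 1)))

    rates = base[:, None] * F
    rates /= rates.sum(axis=0, keepdims=True)
    depth_mean = np.array([cfg.depth_means[s] for s in subset])
    depth = depth_mean * rng.lognormal(
        -0.5 * _DEPTH_JITTER_SD**2, _DEPTH_JITTER_SD, size=n_cells
    )
    mu = rates * depth[None, :]
    return _compensate_depth(mu, depth, cfg), depth


def program_mean_profiles(cfg: AtlasConfig, programs: pd.DataFrame) -> pd.DataFrame:
    """Noise-free expected relative expression per subset (segment midpoints).

    Used by tests to check that each planted marker's expected expression
    peaks in its own subset.
    """
    mids, subs = [], []
    for s in SUBSETS:
        if s in _SEGMENTS:
            br, a, b = _SEGMENTS[s]
            mids.append(((a + b) / 2.0, br))
        else:
            mids.append((np.nan, ""))
        subs.append(s)
    subset = np.array(subs, dtype=object)
    branch = np.array([m[1] for m in mids], dtype=object)
    position = np.array([m[0] for m in mids])
    intens = _program_intensities(subset, branch, position)
    base = programs["baseline_mean"].to_numpy()
    prog = programs["program"].to_numpy()
    member = programs["member_of"].to_numpy()
    F = np.ones((len(programs), len(subs)))
    for s in SUBSETS:
        rows = np.flatnonzero((prog == "marker") & (member == s))
        fold = _MARKER_FOLD_BY_SUBSET.get(s, _MARKER_FOLD)
        F[rows] *= 1.0 + (fold - 1.0) * intens[s][None, :]
    rows = np.flatnonzero(prog == "capillary_core")
    F[rows] *= 1.0 + (_CORE_FOLD - 1.0) * intens["capillary_core"][None, :]
    rates = base[:, None] * F
    rates /= rates.sum(axis=0, keepdims=True)
    return pd.DataFrame(rates, index=programs["gene_id"], columns=subs)


def generate_tissue_panel(cfg: AtlasConfig, crp_fraction_by_tissue: dict):
    """Generate per-tissue datasets sharing one gene universe.

    Each tissue carries the requested planted fraction of CRP-like cells
    (cells with the CRP program plus the capillary core program); the
    remaining cells are differentiated subsets.  Used to exercise the
    cross-tissue CRP-like detector.
    """
    if not crp_fraction_by_tissue:
        raise BecatlasError("empty tissue list")
    for t, f in crp_fraction_by_tissue.items():
        if not 0.0 <= f <= 1.0:
            raise BecatlasError(f"CRP fraction for {t} outside [0,1]")
    out = []
    for i, (tissue, frac) in enumerate(sorted(crp_fraction_by_tissue.items())):
        props = {s: 0.0 for s in SUBSETS}
        props["CRP"] = 0.6 * frac
        props["CRP-early"] = 0.4 * frac
        rest = 1.0 - frac
        for s, w in (
            ("CapEC1", 0.28), ("CapEC2", 0.28), ("TrEC", 0.10), ("Vn", 0.10),
            ("Art", 0.08), ("pre-Art", 0.06), ("HEC", 0.06), ("HEC-late", 0.02),
            ("CapIfn", 0.02),
        ):
            props[s] = rest * w
        tcfg = AtlasConfig(
            n_cells=cfg.n_cells,
            n_genes=cfg.n_genes,
            subset_proportions=props,
            contaminant_proportions={c: 0.0 for c in CONTAMINANT_CLASSES},
            marker_program_size=cfg.marker_program_size,
            depth_means=cfg.depth_means,
            division_propensity=cfg.division_propensity,
            sex_fractions=cfg.sex_fractions,
            n_batches=1,
            batch_shift_sd=0.0,
            dispersion=cfg.dispersion,
            dropout_logit_slope=cfg.dropout_logit_slope,
            dropout_logit_intercept=cfg.dropout_logit_intercept,
            seed=cfg.seed,  # shared seed -> shared gene program table
        )
        # same gene table (seeded identically), different cells per tissue
        rng = np.random.default_rng(cfg.seed)
        programs = _build_program_table(tcfg, rng)
        cell_rng = np.random.default_rng((cfg.seed + 7919 * (i + 1)) % (2**31 - 1))
        cm, truth, _ = _generate_with_rngs(tcfg, programs, cell_rng)
        truth["tissue"] = tissue
        truth["is_crp_like"] = truth["true_subset"].isin(["CRP", "CRP-early"])
        cm.obs["sample"] = tissue
        cm = CountMatrix(
            cm.X,
            cm.gene_ids,
            np.array([f"{tissue}:{c}" for c in cm.cell_ids], dtype=object),
            cm.obs,
        )
        truth.index = cm.cell_ids
        truth["cell_id"] = cm.cell_ids
        out.append((cm, truth))
    return out


def _generate_with_rngs(cfg: AtlasConfig, programs: pd.DataFrame, rng):
    """Cell-level generation given a pre-built program table."""
    classes = list(SUBSETS) + list(CONTAMINANT_CLASSES)
    probs = np.array(
        [cfg.subset_proportions[s] for s in SUBSETS]
        + [cfg.contaminant_proportions[c] for c in CONTAMINANT_CLASSES]
    )
    subset = rng.choice(classes, size=cfg.n_cells, p=probs / probs.sum())
    is_contaminant = np.isin(subset, CONTAMINANT_CLASSES)
    branch = np.array(
        [_SEGMENTS[s][0] if s in _SEGMENTS else "" for s in subset], dtype=object
    )
    position = np.full(cfg.n_cells, np.nan)
    for s, (br, a, b) in _SEGMENTS.items():
        on = subset == s
        position[on] = rng.uniform(a, b, size=on.sum())
    prop = np.array([cfg.division_propensity.get(s, 0.0) for s in subset])
    is_dividing = rng.random(cfg.n_cells) < prop
    sex = np.where(rng.random(cfg.n_cells) < cfg.sex_fractions, "M", "F")
    batch = rng.integers(0, cfg.n_batches, size=cfg.n_cells)
    mu, depth = _expected_means(cfg, programs, subset, branch, position,
                                is_dividing, sex, batch, rng)
    counts = _sample_counts(mu, cfg, rng)
    cell_ids = np.array([f"cell{i:05d}" for i in range(cfg.n_cells)], dtype=object)
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "true_subset": subset,
            "branch": branch,
            "manifold_position": position,
            "is_dividing": is_dividing,
            "sex": sex,
            "batch": [f"batch{b}" for b in batch],
            "is_contaminant": is_contaminant,
            "planted_depth": depth,
        }
    ).set_index("cell_id", drop=False)
    obs = truth[["batch"]].copy()
    obs["sample"] = "synthetic"
    cm = CountMatrix(
        sp.csr_matrix(counts), programs["gene_id"].to_numpy(), cell_ids, obs
    )
    return cm, truth, programs


# ---------------------------------------------------------------------------
# derived gene-set helpers
# ---------------------------------------------------------------------------


def contaminant_signatures(programs: pd.DataFrame) -> GeneSetCollection:
    """LEC / pericyte / FRC / lymphocyte marker gene sets (synthetic analogues
    of Prox1/Lyve1/Pdpn, Itga7/Pdgfrb, Pdpn/Ccl19/Pdgfra, Ptprc/Cd52)."""
    sets = []
    for c in CONTAMINANT_CLASSES:
        genes = programs.loc[
            (programs["program"] == "contaminant_marker")
            & (programs["member_of"] == c),
            "gene_id",
        ].tolist()
        sets.append(GeneSet(c, f"{c} contaminant markers", tuple(genes)))
    return GeneSetCollection(sets)


def cycle_gene_set(programs: pd.DataFrame) -> GeneSet:
    """The planted cell-cycle gene program (the known cycle gene list)."""
    genes = programs.loc[programs["program"] == "cycle", "gene_id"].tolist()
    return GeneSet("cell_cycle", "cell-cycle genes", tuple(genes))


def sex_gene_sets(programs: pd.DataFrame):
    """(Y-linked gene set, Xist gene id) for in-silico sex demultiplexing."""
    y = programs.loc[programs["program"] == "y_linked", "gene_id"].tolist()
    xist = programs.loc[programs["program"] == "xist", "gene_id"].tolist()[0]
    return GeneSet("y_linked", "Y-chromosomal genes", tuple(y)), xist


def subset_marker_sets(programs: pd.DataFrame) -> GeneSetCollection:
    """Planted marker programs per subset, as a gene-set collection."""
    sets = []
    for s in SUBSETS:
        genes = programs.loc[
            (programs["program"] == "marker") & (programs["member_of"] == s),
            "gene_id",
        ].tolist()
        sets.append(GeneSet(s, f"{s} marker program", tuple(genes)))
    return GeneSetCollection(sets)


def go_set_collection(programs: pd.DataFrame) -> GeneSetCollection:
    """The planted branch-linked gene sets, as a GMT-style collection."""
    sets = []
    for go in _GO_PROGRAMS:
        genes = programs.loc[
            (programs["program"] == "go_set") & (programs["member_of"] == go),
            "gene_id",
        ].tolist()
        sets.append(GeneSet(go, "planted branch program", tuple(genes)))
    return GeneSetCollection(sets)


def major_labels(subsets) -> np.ndarray:
    """Collapse 11-subset labels onto the 8 major phenotypes."""
    return np.array([MAJOR_OF.get(s, s) for s in subsets], dtype=object)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_config_echo(cfg: AtlasConfig, path) -> None:
    """Plain-text key=value echo of the generator configuration."""
    with open(path, "w") as fh:
        for k, v in sorted(vars(cfg).items()):
            fh.write(f"{k}={v}\n")
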