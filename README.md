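# becatlas

Analysis toolkit for single-cell RNA-seq atlases of lymph-node **blood
vascular endothelial cells (BEC)** — the arteries, capillaries, high
endothelial venules (HEV) and medullary veins that control blood flow and
immune-cell recruitment in lymphoid tissue. The package reimplements, as a
tested and reproducible library, the full analysis chain used to chart this
vasculature at single-cell resolution:

* pooling-deconvolution **normalization** of UMI counts and gene filtering;
* per-cell **module scores** with expression-matched random controls, and a
  screen of whole gene-set collections (e.g. all GO terms) per subset;
* supervised removal of non-BEC contaminants, in-silico **sex
  demultiplexing** (Y-linked vs Xist scores), and **cell-cycle
  classification** from pooled cycle-gene scores;
* SNN-graph **Leiden clustering**, subdivision of terminus clusters along
  trajectories into 11 subsets, centroid-correlation **label transfer**,
  and mutual-nearest-neighbor (**MNN**) batch and cell-cycle alignment;
* KNN-geodesic **trajectory space** (cells x seeds shortest-path distance
  matrix, tPC projections, branch gating, gaussian-kernel smoothing);
* Markov-affinity graph **imputation** (adaptive kernel, t = 2, k = 9,
  ka = 3) for heatmap gene ordering;
* the **signaling entropy rate** SR = Σᵢ πᵢ Sᵢ of an expression-weighted
  random walk pᵢⱼ = Aᵢⱼxⱼ/Σₖ Aᵢₖxₖ on an interaction network — a potency
  proxy, computed after downsampling every cell to 1,000 reads;
* **zero-inflated negative binomial (ZINB)** one-vs-rest differential
  expression with a χ²(1) likelihood-ratio test, BH correction at adjusted
  p < 0.001, and top-50 subset signatures;
* cross-tissue detection of **CRP-like cells** (the Apln⁺ capillary
  resident regenerative population) by centroid correlation plus
  co-embedding neighborhood agreement.

Because the original tissue data are not bundled, the package ships a
first-class **synthetic atlas generator** that plants the structure the
analysis assumes — 11 subsets on a branching vascular manifold with smooth
logistic blending, HEC-high UMI depth, a dividing-cell program concentrated
in CRP, sexes, batches, and contaminants — together with the ground-truth
tables that make every stage testable. See `docs/methods.md` for the
models and design decisions.

## Worked example

```python
from becatlas import synthetic, preprocess, annotate, pipeline

# a 5,000-cell atlas with planted ground truth
cfg = synthetic.AtlasConfig(seed=1)
counts, truth, programs = synthetic.generate_atlas(cfg)

norm = preprocess.normalize(counts)            # pooling size factors
norm, _ = preprocess.filter_genes(norm, counts)
sigs = synthetic.contaminant_signatures(programs)
norm, report = preprocess.remove_contaminants(norm, sigs, seed=1)

dividing = annotate.classify_cycle(norm, synthetic.cycle_gene_set(programs),
                                   seed=1)
tr = truth.loc[norm.cell_ids]
crp = tr.true_subset.isin(["CRP", "CRP-early"]).to_numpy()
print(f"{100 * dividing.to_numpy()[crp].mean():.1f}% of CRP dividing")
print(f"{100 * crp[dividing.to_numpy()].mean():.1f}% of dividing cells are CRP")
```

prints

```
12.2% of CRP dividing
57.3% of dividing cells are CRP
```

— on the synthetic atlas, as in the tissue, only about one in ten CRP
carries a division signature, yet CRP account for the majority of all
dividing endothelial cells (the remainder sits mostly in CapEC1 and TrEC).

The full pipeline — generation, preprocessing, annotation, trajectories,
gene-set screen, imputation, entropy, differential expression, CRP-like
detection — runs from one configuration:

```bash
becatlas run --seed 7 --out runs/demo     # ~5 min, bit-reproducible
```

Each stage writes TSV artifacts and SHA-256 hashes into the run directory;
rerunning with the same seed reproduces every hash exactly.

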