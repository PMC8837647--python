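# spiralst

Digital unrolling and transcriptional-program discovery for Swiss-rolled
spatial transcriptomics sections, with a fully synthetic ground-truth
generator for end-to-end validation.

A "Swiss roll" preparation coils a whole mouse colon into a spiral so the
entire proximal–distal axis fits a single capture area. `spiralst`
re-linearizes such data and analyzes it:

- **io_core** — 10x-style readers (MatrixMarket + features/barcodes TSV +
  tissue positions CSV), non-coding/mitochondrial gene filtering, and a
  variance-stabilizing normalization surrogate (analytic negative-binomial
  Pearson residuals with a pooled overdispersion estimate; genes with
  residual variance above a threshold are flagged variable).
- **synthetic** — Archimedean-spiral tissue generator: a traced base layer,
  layered spot lattices at configurable depths (muscle / lamina propria /
  epithelium), planted spatial programs (proximal/distal bands that double
  as an anticorrelated p53/stem pair, depth layers, follicle hotspots) with
  exclusive marker genes, and negative-binomial counts. Everything is
  seeded and carries ground truth.
- **unroll** — digital unrolling: base-layer pixel extraction from a mask,
  k-nearest-neighbor graph (k = 5), endpoint detection from extremal mean
  kNN distance, minimum-vertex-count path ordering, and spot assignment via
  an 80-px radius and a 35°–125° tangent-angle window. Output is a linear
  coordinate per spot: x = base-point order index, y = distance to the
  matched base point.
- **factorize** — seeded NNMF (non-negative double-SVD initialization) on
  clipped residuals of the variable genes (ribosomal genes excluded), plus
  knee-based top-gene selection: positive loadings, log transform, Gaussian
  smoothing (window 10), unit-invariant knee cut.
- **activity** — footprint pathway activities from a pathway × gene weight
  CSV (z-scored expression dotted with weights, z-scaled per pathway),
  binned-control module scores, the packaged 25-gene proliferating-stem
  signature, Pearson correlation tables with Benjamini–Hochberg adjustment,
  and min–max unit-cube CMY color mapping for 3-D embeddings.
- **enrichment** — co-expression clustering of gene panels (Ward linkage on
  1 − r with zeroed diagonal, cut at k), risk-gene module scores, preranked
  permutation GSEA against factor loadings (with min/max set-size gates),
  and shared-signature extraction (set ∩ top-100 factor genes).
- **cli / pipeline** — a YAML-configured `run-all` orchestrator with a
  manifest (hashes, seeds, versions) plus spatial/unrolled plotting.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end property criteria
(geometry recovery, endpoint/ordering oracles across seeds, planted-factor
NNMF recovery, knee-selection and GSEA correctness against brute-force
oracles, statistical oracles, and byte-level pipeline determinism).

## CLI

```bash
# synthetic dataset with ground truth
spiralst simulate --out sim/ --seed 0

# unroll spots against the traced base-layer mask
spiralst unroll --matrix sim/matrix.mtx --features sim/features.tsv \
    --barcodes sim/barcodes.tsv --positions sim/tissue_positions.csv \
    --mask sim/base_layer_mask.png --radius 80 --angle 35:125 --k 5 \
    --out coords.tsv

# NNMF program discovery (basic-3 / per-sample-20 / merged-20 / custom)
spiralst factorize --matrix sim/matrix.mtx --features sim/features.tsv \
    --barcodes sim/barcodes.tsv --positions sim/tissue_positions.csv \
    --mode basic-3 --seed 0 --out model/

# pathway activities, module scores, GSEA
spiralst pathways --matrix ... --model examples/pathway_model.csv --out pw.tsv
spiralst score-modules --matrix ... --sets examples/ibd_risk_genes.gmt \
    --seed 0 --out modules.tsv
spiralst enrich --sets examples/ibd_risk_genes.gmt --model model/ \
    --nperm 1000 --seed 0 --out enrichment.tsv

# everything from one config
spiralst run-all --config config.yaml --out run/
```

`spiralst run-all` with no config runs the default synthetic pipeline end
to end (simulate → filter/normalize → unroll → factorize → score →
enrich → figures) and is deterministic: rerunning a config reproduces
byte-identical tables.

The files in `examples/` are synthetic fixtures illustrating the input
formats (pathway × gene weight CSV, GMT gene sets); substitute published
weight models and curated gene lists for real analyses.

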