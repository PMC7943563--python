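# nescore

Small cell lung cancer (SCLC) spans a phenotypic continuum from *classic*
neuroendocrine (NE) tumors to *variant*, non-neuroendocrine ones, and the
two ends differ sharply in how visible they are to the immune system.
`nescore` implements the quantitative toolkit for studying that axis from
expression data:

- **NE score.** For a 50-gene signature with two centroids (average log2
  expression in NE and in non-NE cell-line groups), a sample's score is

  ```
  NE score = (r_NE − r_non-NE) / 2
  ```

  where `r_NE` (`r_non-NE`) is the Pearson correlation between the sample's
  signature-gene expression and the NE (non-NE) centroid. Scores lie in
  [−1, +1]; positive predicts NE, negative predicts non-NE, and the
  magnitude reflects confidence.
- **Enrichment machinery** to characterize what tracks the score:
  a Pearson-correlation ranking metric, pre-ranked GSEA with a seeded
  gene-label permutation null (ES, NES, permutation p, BH-adjusted p,
  leading edges), single-sample GSEA (weighted-ECDF rank statistic) for
  MHC I / immune-infiltrate scoring, and a 2×2 sign-proportion chi-squared
  test for "is this gene category negatively associated with the score
  more often than background?".
- **Preprocessing**: TSV/GCT I/O, quantile normalization, log2 transform,
  library-size normalization for scRNA-seq, z-scoring, and cluster
  pseudobulk averaging with min–max scaling.
- **Bench quantifications**: the IHC H-score
  (`3·%strong + 2·%moderate + 1·%weak`, range 0–300), per-area T-cell
  density, and qPCR relative expression (control-gene normalized,
  base-2 exponentiated, parental-median scaled).
- **A seeded synthetic-data generator** that plants a latent NE state,
  signature genes blending the two centroids, an immune program repressed
  as the state rises, a REST-target program induced with it, and neutral
  background — with full ground truth for end-to-end validation.

## Worked example

```python
import numpy as np
import nescore as ns

dataset = ns.generate_dataset(ns.SyntheticConfig(seed=1))
scores, _ = ns.score_matrix(dataset.expr, dataset.signature)
ne = scores.set_index("sample")["ne_score"]
print(np.corrcoef(ne, dataset.truth.ne_state.loc[ne.index])[0, 1])
# 0.9692  — the score recovers the latent NE state

ranked = ns.rank_genes_by_correlation(dataset.expr, ne)
for r in ns.preranked_gsea(ranked, dataset.sets, n_perm=2000, seed=2):
    print(f"{r.set_name:15s} nes={r.nes:+.2f} padj={r.padj:.4g}")
# REST_TARGETS    nes=+2.79 padj=0.001502   (induced with the NE state)
# IMMUNE_PROGRAM  nes=-2.81 padj=0.001502   (repressed in high-NE samples)
# RANDOM_K        nes=-0.50 padj=1          (control: no signal)
```

The numbered drivers under `analysis/` walk the same pipeline
step-by-step (simulate → score → enrichment → associations → bench
arithmetic) and write their tables under `results/`; for example
`analysis/05_quantify.py` reproduces the published SCLC-04 H-score:
`3*1.22 + 2*9.97 + 1*47.81 = 71.41`.

A `nescore` CLI mirrors the library (`nescore score`, `nescore gsea`,
`nescore ssgsea`, `nescore hscore`, `nescore simulate`, ...); run
`nescore --help`.

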