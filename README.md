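# dbk — dissociation-bias kit

Tools for studying how tissue handling distorts droplet single-cell RNA-seq
data. Warm (37 °C) enzymatic dissociation switches on immediate-early and
heat-shock genes (*Fos*, *Jun*, *Hspa1a*, …) and destroys fragile cell types
such as podocytes; cryopreservation loses epithelial cells almost entirely;
methanol fixation keeps composition but leaks ambient RNA into every droplet.
`dbk` packages the computational machinery needed to detect and quantify such
artifacts — and a synthetic-data generator that injects them with known ground
truth, so every stage can be validated end to end without any sequencing data.

It is aimed at computational biologists who benchmark tissue-handling
protocols, build QC pipelines for kidney-like heterogeneous tissues, or need
a tested reference implementation of the analysis recipes below.

## What it implements

- **Synthetic droplet data** (`dbk.simulate`) — multinomial UMI counts per
  cell over ground-truth type profiles, with log-normal depth, per-type
  stress-gene induction, pre-encapsulation depletion, ambient-RNA admixture
  and hemoglobin contamination. Presets `cold_fresh`, `warm_fresh`, `cryo`,
  `methanol`.
- **QC and normalization** (`dbk.qc`) — genes detected in ≥ 10 cells; cells
  with 200–3000 detected genes and < 50 % mitochondrial counts; nuclei
  additionally ≥ 450 (v2) / 900 (v3) UMI with mitochondrial genes removed;
  one-sided MAD filter on the UMI/gene ratio; log-normalization
  `ln(1 + 10⁴·x/Σx)`.
- **Cell annotation** (`dbk.annotation`) — two-iteration reference-plus-
  signature inference: Spearman matching to reference profiles, one-vs-rest
  Wilcoxon marker signatures (detection rate ≥ 0.5, logFC ≥ 1, FDR < 0.05,
  genes in > 2 signatures excluded), binned-control module scores
  `S = mean(X_sig) − mean(X_ctrl)`, Monte-Carlo significance against 1000
  random same-size gene sets with Benjamini–Hochberg correction, reference
  augmentation and a second pass, k-means subcluster refinement for
  confusable types.
- **Statistics** (`dbk.stats`) — per-type Wilcoxon differential expression
  (exact permutation p for small groups, tie-corrected normal approximation
  otherwise); the 17-gene stress score with per-type Monte-Carlo flags;
  S/G2M/G1 cell-cycle calls; per-type 2×2 composition chi-square
  (two-sided, p < 0.001); GeTMM bulk normalization (TMM on
  reads-per-kilobase); marker-based bulk deconvolution by nonnegative least
  squares on the simplex.
- **Pipeline** (`dbk.pipeline`, CLI `dbk`) — simulate → QC → annotate →
  stress/DE/composition with YAML configs, per-stage seeded substreams and a
  consolidated report.

## Worked example

Simulate a warm-dissociated sample (8-fold stress induction in endothelial-
and immune-like cells, fragile podocyte-like type depleted) and test which
types carry a significant stress response:

```python
import dbk

truth = dbk.generate_ground_truth(n_genes=2000, n_types=5, n_markers_per_type=10, seed=1)
warm = dbk.preset_effect("warm_fresh", truth)
cells = dbk.simulate_cells(
    truth, 1500, [0.55, 0.15, 0.12, 0.10, 0.08], warm, depth_mean=5000, seed=5
)
norm = dbk.lognormalize(cells)
stress = dbk.stress_score_by_type(norm, norm.obs["true_type"], seed=7)
print(stress.round(3).to_string(index=False))
```

```
       type  n_cells  mean_score     p     q  significant
  Endo_like      121       1.729 0.001 0.002         True
Immune_like       86       1.734 0.001 0.002         True
    PT_like     1017      -0.268 1.000 1.000        False
  aLOH_like      276      -0.285 1.000 1.000        False
```

The two stress-induced types score ≈ 1.7 (mean log-expression of the 17
stress genes above expression-matched controls) with Monte-Carlo p = 0.001,
the smallest value 1000 null draws can produce; uninduced tubular types score
negative. The podocyte-like type was depleted below the 3-cell reporting
minimum — itself the expected artifact. The same comparison for real data
needs only a count matrix, labels and `dbk.stress_score_by_type`.

Composition shifts are tested the same way from plain counts. Podocytes at
330 of 11,851 cells in one condition versus 3 of 11,257 in another give
2.78 % vs 0.03 % and an overwhelming chi-square (`dbk.composition_from_counts`).

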