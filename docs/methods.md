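# Methods

This note records the models, algorithms and numerical choices behind `dbk`,
in enough detail to re-derive every default.

## Synthetic droplet data

**Count law.** Each cell draws a type *t* from the (depletion-thinned,
renormalized) composition vector, a depth *d* ~ LogNormal with
`E[d] = depth_mean` and σ = 0.3, and a count vector
Multinomial(*d*, *p⁽ᵗ⁾*). The multinomial choice (rather than per-gene
negative binomial) mirrors UMI counting as resampling of a cell's transcript
pool and keeps first/second moments exact, so generator tests can use closed
form moment oracles; between-cell overdispersion enters only through the
log-normal depth.

**Ground truth.** A shared log-normal baseline (σ = 1) over all genes; each
type's markers elevated 20-fold before row normalization. The 17
stress-response genes, 3 hemoglobin genes and 5 mitochondrial genes are
reserved — never markers. Gene lengths are uniform on 500–10,000 bp.

**Artifacts.** A `ProtocolEffect` applies, in order: per-type stress-gene
fold induction (≥ 1); global hemoglobin scaling; row renormalization;
ambient admixture `p ← (1−f)·p⁽ᵗ⁾ + f·p̄` where the ambient pool *p̄* is the
composition-weighted mean of the undepleted types' post-induction profiles
(library sizes are type-independent in expectation, so composition weights
equal library-size weights). Depletion acts before encapsulation as
thinning of the type proportions, modelling fragile cells lost upstream of
the microfluidics.

**Presets** encode the qualitative findings the package is built to detect.
The magnitudes are calibration choices, not measured values — the source
observations are qualitative ("scarcely detected", "induction of stress
genes"):

| preset | stress | depletion | ambient | hemoglobin |
|---|---|---|---|---|
| `cold_fresh` | — | — | 0.01 | ×2 |
| `warm_fresh` | ×8 in endothelial/immune/podocyte-like | podocyte-like 0.01, other sensitive 0.5 | 0.01 | — |
| `cryo` | ×4 everywhere | PT-like 0.005, aLOH-like 0.3, podocyte-like 0.5 | 0.02 | — |
| `methanol` | — | — | 0.15 | ×1.5 |

An 8-fold induction of moderately expressed immediate-early genes yields
per-type mean module scores near 1.7 on the log scale — comfortably
detectable at a few hundred cells per type, without being trivially large.
Retention 0.01 for a 8 %-abundant type leaves a handful of cells out of
thousands, matching "a few cells where hundreds are expected".

What the generator does **not** emulate: doublets, batch effects, intronic
reads of nuclei libraries, gene–gene correlation beyond cell type, or
empty droplets (data are pre-called). Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not robustness to every real-data pathology.

## QC and normalization

Filter order is genes → cells: gene detection (≥ 10 cells) is computed on
the full input so it reflects the whole droplet set, then cell filters run
on the gene-filtered matrix. Gene-range bounds (200–3000) are inclusive;
the mitochondrial bound (50 %) is exclusive. The UMI floor (450 for 10x v2,
900 for v3) applies to nuclei only, and all-nuclei matrices drop
mitochondrial genes outright. The ratio filter removes cells with
UMI/genes > median + 3·MAD, one-sided and with the unscaled MAD (no 1.4826
consistency factor) — the target is only implausibly *high* ratios, and the
raw MAD with a multiplier of 3 is the convention the thresholds were tuned
under. All thresholds are arguments.

Log-normalization is `ln(1 + 10⁴ · x / Σx)` per cell; zeros are preserved
and a zero-total cell is an error naming its barcode.

## Annotation

1. **Reference** — per-type means of library-size-normalized counts from
   labelled data. Vectors whose best Spearman correlation to any other
   vector is < 0.3 are flagged as outliers and excluded from matching (the
   threshold is a design choice; pruning is always logged).
2. **Correlation matching** — Spearman ρ per cell against each retained
   vector over shared genes (≥ 20 required), zeros kept as values, average
   ranks for ties. Constant cells are unmatched with a reason; exact ρ ties
   break to the lexicographically smallest type name, logged.
3. **Signatures** — one-vs-rest Wilcoxon on the matched labels. logFC is
   the natural log of de-logged group means with pseudo-count 1:
   `ln(mean(eˣ¹−1)+1) − ln(mean(eˣ²−1)+1)` — the Seurat-v2-era convention,
   stated here because "logFC ≥ 1" depends on the scale. Candidates need
   detection ≥ 0.5 in-type and logFC ≥ 1; BH runs within each type's tested
   set; types under 10 cells are skipped; genes in more than two signatures
   are moved to an exclusion list.
4. **Scoring** — module score = mean signature expression − mean control
   expression, controls drawn per signature gene (100 draws) from that
   gene's average-expression bin (25 bins; without replacement when the bin
   is large enough). Scores are computed as `X·W` with a sparse ±weights
   matrix, which makes thousand-set Monte-Carlo nulls a single sparse
   product. The bin/control counts follow common module-scoring practice.
5. **Significance** — upper-tail add-one estimator
   `p = (1 + #{null ≥ obs}) / (1 + N)` against N = 1000 random same-size
   sets drawn from the analyzed genes excluding the observed set. The
   add-one form cannot return 0 and is exactly uniform on its N+1 atoms
   under the null. BH is applied across one cell's candidate types.
6. **Assignment** — the argmax-score type if that score is positive, unique
   and q < 0.05; exact score ties leave the cell unassigned (logged).
7. **Iteration** — per-type means of newly assigned query cells are
   appended to the reference and the whole pass repeats once; when
   iteration 1 assigns every cell the second pass is skipped (it is a fixed
   point by construction). Cells never assigned are labelled `unknown`.
8. **Refinement** — cells of confusable types are subclustered (k-means on
   the top-50-PC embedding of z-scored values, clipped at ±10; k-means is a
   deliberate substitution for graph clustering, chosen for determinism
   under a seed). A cluster strictly dominating every other cluster in the
   mean of each marker gene becomes a candidate type; the subset is
   re-scored with its signature added.

Monte-Carlo p-values for assignment are computed per cell (the aggregated
per-type variant is used for the stress score); the per-cell choice gives
cell-level uncertainty and reduces to the aggregated test on averaging
because the score is linear in expression.

## Statistics

**Wilcoxon DE.** Genes are pre-filtered to |logFC| ≥ threshold and
max(pct₁, pct₂) ≥ 0.5; defaults are 0.5 (dissociation comparisons) with 1.0
used for preservation comparisons; bulk tables are filtered at |logFC| ≥ 2,
FDR < 0.05. Small groups (≤ ~20,000 label arrangements, e.g. 8 vs 8) get
the exact two-sided permutation distribution of the rank sum, correct under
ties; larger groups the tie-corrected normal approximation. The exact path
exists because no normal approximation is uniformly within 0.01 of the
permutation p at single-digit group sizes.

**Stress score.** Per-cell module scores over the 17-gene set are averaged
within type; the null scores random same-size sets on the per-type mean
expression matrix — algebraically identical to averaging per-cell null
scores, and hundreds of times faster. Types with < 3 cells are skipped
(mirroring the exclusion of low-count types from the original comparison).
The flag is raw p < 0.01; BH-adjusted q is also reported.

**Cell cycle.** S and G2M module scores; phase = argmax if positive, else
G1.

**Composition.** Per type, a 2×2 Pearson chi-square (type vs rest ×
condition A vs B), two-sided, no Yates correction (counts are large in the
intended use; correction is a flag). Replicates are pooled, matching pooled
published percentages; an exclusion set supports "relative to all non-X
cells" recomputations.

**GeTMM.** Counts → reads-per-kilobase; TMM factors on RPK against the
sample whose upper-quartile RPK fraction is closest to the mean; M and A
trimmed at 30 % / 5 % by rank; weighted mean of M with inverse asymptotic
(delta-method) variances; factors rescaled to geometric mean 1; normalized
value = RPK / (total RPK × factor) × 10⁶. The implementation reproduces the
reference R implementation's factors to 7 digits on random matrices.

**Deconvolution.** Markers per type via the signature machinery at
logFC ≥ 1.5, detection ≥ 0.5, positive only; genes claimed by more than one
type are removed entirely. The basis is each type's mean linear-scale
normalized expression on the marker union; each bulk sample's marker vector
(sum-normalized) is fitted by nonnegative least squares and renormalized to
the simplex. NNLS is a deliberate substitution for the published
support-vector engine — the recipe's substance is the marker selection,
which is implemented verbatim; a rank-deficient basis is an error naming
the collinear types.

## Calibration studies and problem sizes

The calibration module draws exchangeable-null matrices (every gene i.i.d.
Poisson). Monte-Carlo uniformity uses 2000 cells and 2000 replicate
observed sets with 199-draw nulls (the add-one p then lives on a 1/200
grid, so the KS distance from uniform has a 0.005 discreteness floor).
The false-flag study uses 999-draw nulls — with 199 the smallest
attainable p (0.005) makes a 0.01-level test operate at 0.005, i.e. the
flag rate is quantization-limited, not mis-calibrated — and 25 controls per
gene, which changes score variance but not calibration. Recovery
experiments use 5 types × 2000 genes, 1000–2000 cells and depth 5000;
pipeline runs use Monte-Carlo sizes of a few hundred where only decision
quality at q < 0.05 matters, since with 5 candidate types the smallest
achievable q (≈ 0.025 at N = 200) sits well below the threshold.

## Known limitations

- Signature quality degrades when correlation matching is badly wrong;
  the second iteration recovers mislabeled cells only if at least some
  cells of each type were matched correctly in iteration 1.
- Binned controls degenerate on very small gene panels (a signature can
  become its own control pool); use fewer bins for matrices with tens of
  genes.
- The composition test assumes independent cells; pooled replicates with
  strong replicate effects will overstate significance (a stratified mode
  is available).
- Deconvolution inherits the usual marker-basis caveats: proportions are
  transcript-weighted, and types without unique markers cannot be
  estimated.
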