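# Methods

## The assay and its data model

The package analyzes two-channel methylation-sensitive restriction-enzyme
microarrays (the MethDet design). Each patient's genomic DNA is split into
two aliquots: one digested with Hin6I (blocked by CpG methylation at its
GCGC site), one mock-digested. After amplification the digested aliquot is
labeled with Cy3 (test) and the mock aliquot with Cy5 (control), and both
are hybridized competitively to a slide carrying three identical 8×8
subarrays. Per subarray: 56 CpG-island gene probes, 3 positive controls
(full signal in both channels), 2 hybridization controls (nonspecific
binding) and 3 empty spots (background).

Methylation protects a template from digestion, so a gene's test-channel
signal is proportional to its *methylated fraction* m, while the control
channel sees the full template. The analysis variable is

    M = log2(R),   R = control / test  ( = 1/m on latent values )

so larger M means *less* methylation. A between-group effect is described by
the absolute fold change FC = 2^|Δ|, where Δ is the difference of group
means of M between relapsing and non-relapsing tumors.

## Synthetic cohorts

`methdet.synthetic` generates cohorts under these study conditions:

- 123 patients, 19 relapse / 104 non-relapse (matched 19/19 subsets are a
  sampling option);
- the 21 screened genes planted at their published absolute fold changes
  (BRCA1 5.52 … DAPK1 12.37 … MCTS1 1.56), the seven prognostic genes
  flagged; remaining probes of the 56-gene layout carry no group effect;
- within-group standard deviations default to the only published values,
  the panel-level 1.16809 (relapse) and 0.708074 (non-relapse); null probes
  use sd 1.0;
- per gene, latent M values are drawn normally around group means differing
  by exactly `direction × log2(FC)`; the direction of each published effect
  is not printed (FCs are absolute), so it defaults to +1 (relapse shifted
  toward higher M, i.e. hypomethylation) and is configurable per effect —
  a genuinely open question of the design;
- baseline methylated fraction 0.5 in the non-relapse group (centers M at 1
  before normalization; the assay publishes no baseline).

Latent values become spot intensities with: full-template control signal
50 000 units, test signal `50 000 × 2^(−M)`; lognormal multiplicative spot
noise with coefficient of variation 0.1 per spot and channel (replicate
spots share the latent value, not the noise); hybridization-control level
200 units; additive Gaussian background 150 ± 30 floored at 0; spot dropout
probability 0.02. These are realistic magnitudes for a two-color scanner
chosen once for the generator; all are `CohortConfig` fields. The generator
does **not** emulate intensity-dependent dye bias, scanner saturation,
print-tip effects or amplification-bias chemistry — so passing tests
demonstrate the statistical pipeline's correctness under the declared noise
model, not robustness to every artifact of real slides.

Cohorts are bit-reproducible from a single seed and can be written as one
GPR-dialect file per sample plus label and ground-truth tables.

## Spot QC and matrix assembly

Following the assay's processing rules (`methdet.preprocess`):

1. background per channel and subarray = mean foreground of the empty
   spots, subtracted and floored at 1e−6 (slide-level fallback when a
   subarray lost all empty spots to dropout; error when none remain);
2. a spot is informative iff unflagged and both channels' net signals are
   ≥ 2× the slide-level mean of the hybridization-control spots — the
   nonspecific-binding floor. The boundary is inclusive (exactly 2× passes)
   and the rule uses the hybridization controls, not the positive controls,
   because they quantify nonspecific binding; both channels must pass since
   a ratio needs two valid signals;
3. a gene needs ≥ 2 of its 3 replicate spots; its value is the mean of the
   per-spot ratios R;
4. M = log2(R) is lowess-normalized against spot intensity
   A = ½·log2(control·test) per sample (span 0.4, 3 robustifying
   iterations) and the fit subtracted;
5. genes missing in strictly more than 25 % of samples are dropped
   (exactly 25 % is retained).

Binary calls: M ≤ −1 → methylated, M ≥ +1 → unmethylated (2-fold default),
values inside the band take the nearer category with 0 called unmethylated;
missing propagates. Median imputation per gene is applied only where a
consumer needs a complete matrix (the classifiers); clustering and the
per-gene tests consume the missing mask directly.

### When to disable lowess

Lowess normalization assumes most probes are non-differential. On this
56-probe targeted biomarker array that assumption fails whenever many
probes truly differ: with the 21 published effects planted, the average
planted shift (≈ 0.52 on the log2 scale per relapse sample) is partially
absorbed into the per-sample fit and subtracted from *every* gene,
attenuating weak effects below the screen cutoff. Because the simulator
introduces no intensity-dependent dye bias, calibration analyses (including
the acceptance script) run with `normalize=False`; the pipeline default
keeps lowess on, mirroring the published processing for real inputs.

## Differential screen

Per gene, group means of M are compared with a two-sample Student's t-test
(pooled variance, as named; Welch optional — the published test's variance
assumption is unstated, though the power analysis assumes unequal
variances). FC = 2^|Δmean|. The screen retains FC ≥ 1.5 and p < 0.05 — the
fold-change cutoff of the published 21-gene list; the stricter FC ≥ 2 named
elsewhere in the source methods is available via `fc_min`. No multiple-
testing correction is applied, mirroring the original analysis; a
Benjamini–Hochberg column is emitted for information only. Degenerate
zero-variance identical groups report t = 0, p = 1, FC = 1.

## Classifier comparison and panel selection

Six families — PLS, k-nearest neighbors (k = 3), logistic regression,
linear discriminant analysis, a single CART tree, and forward-stepwise
logistic selection by AIC (the closest standard readings of the named
procedures) — are compared by stratified 5-fold cross-validation repeated
10 times; per run the pooled out-of-fold scores give one AUC and the family
with the highest mean AUC wins, ties resolved by the fixed listing order.

Gene importance uses PLS-VIP (2 components by default, capped at
min(n−1, p); the source names no component count):

    VIP_j² = p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ,  mean_j VIP_j² = 1.

VIP is averaged over the CV folds and computed across **all** matrix genes,
with selection (mean VIP > 1) restricted to the screen's candidates. The
full probe background matters: VIP's unit-mean-square normalization makes
">1" a statement relative to the probe population, and renormalizing over a
handful of similarly-informative candidates would force roughly half of
them below 1 regardless of their real strength. A top-k rule is available
as an alternative.

## Accuracy, clustering, power

Panel accuracy fits a PLS score on the panel genes and reports confusion
metrics (sensitivity, specificity, PPV, NPV — undefined ratios are NaN, not
0) at the Youden-J-optimal cutoff (ties toward the more specific cutoff),
plus the Mann–Whitney AUC with ties counted ½. Both evaluation modes are
always reported side by side: resubstitution (the whole-data "whole-model
fit" convention behind the headline published numbers) and cross-validated.
Resubstitution is optimistically biased; the test suite demonstrates the
gap on cohorts whose resubstitution AUC sits near 0.97 — the scale of the
published whole-data fit (with the published panel effects at their
published sds both modes saturate at AUC 1 and the gap vanishes).

Clustering median-centers each panel gene ("deviation from the median"),
uses euclidean distances computed pairwise-complete over shared observed
genes and rescaled by √(p/observed), and agglomerates with centroid linkage
(centroids are missing-aware means recomputed from members, not
Lance–Williams updates, so they stay exact under missingness). Centroid
linkage can invert heights; inversions are permitted and counted rather
than substituting a monotone linkage. The top split defines two branches
whose relapse/non-relapse composition is the concordance report;
majority-branch purity summarizes it (the published tree reached
(13+18)/38 ≈ 82 %). On complete data the agglomeration matches the
reference implementation exactly (verified against scipy in tests). Ties
break toward the smallest cluster-id pair with samples sorted
lexicographically, making results input-order invariant.

Power uses the noncentral t with no equal-variance assumption:
δ = |Δmean| / √(s₁²/n₁ + s₂²/n₂), Welch–Satterthwaite degrees of freedom,
power = P(|T′(df, δ)| > t_crit) two-sided at α = 0.05. The panel-level
computation averages the panel genes per sample first, then feeds the group
statistics of that average to the same routine; per-gene results are
flagged against the 80 % threshold. Group sizes default to the matched
19/19 design; the published panel parameters give power ≈ 1 for 19/19 and
19/104 alike. "BCR"/"BCS" in the published parameter names are read as the
relapse and non-relapse groups — their expansions are not defined in the
source.

## Pipeline and reproducibility

`run_pipeline` chains simulate/read → QC → screen → model comparison →
VIP selection → evaluation → clustering → power, writes every intermediate
as TSV/newick/JSON, and logs per-stage counts so each filter is auditable.
A single master seed fans out via `SeedSequence.spawn` to independent
per-stage streams; re-running with the same config and seed is
bit-identical, and CLI subcommands on the written intermediates reproduce
the same results. Every numeric threshold is a `Thresholds` field.

Problem sizes used by the test suite and the acceptance script — e.g.
matched 19/19 cohorts, 20 sub-seeds for the screen-recovery mode, 10 for
panel selection, 10⁵ replicates per Monte-Carlo power point, 100 seeds for
clustering purity — are the package's chosen desk-scale defaults; all are
parameters.

## Known limitations

- The published real-data accuracy (Table-2-level numbers) is not a
  reproduction target: it requires the original cohort (ArrayExpress
  E-MTAB-3153). An optional rerun on that accession is possible by pointing
  the pipeline at a directory of GPR files plus labels.
- Effect directions and per-gene variances of the published screen are not
  printed; defaults are symmetric and panel-level, so simulated cohorts are
  calibrated in fold change but not in per-gene variance structure.
- The published "PLS K nearest-neighbors with a radial basis machine"
  ranking step is not reproducible from the text; ranking is PLS-VIP.
- Network/pathway analysis of the panel genes is out of scope (external
  services).
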