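# Methods

This note documents the models, estimators and numerical choices behind
netsdecon, and what the synthetic cohorts do and do not establish.

## Expression model and normalization

Counts are normalized to counts-per-million (CPM) per sample — no
gene-length correction, since sorted-nuclei libraries are intron-inclusive
and length correction is ill-defined there — and log-transformed as
log₂(CPM + 1). The pseudocount is fixed at 1. Batch structure is handled
as covariates in the differential models, never inside normalization.
Everything that consumes expression declares the scale it expects
(`linear_pm` or `log2_pm`) and refuses the other.

## Global deconvolution

For sample *x* (CPM) and signature matrix *S* (per-type mean CPM of sorted
samples), fractions solve

  f = argmin ‖W(x − S f)‖²  s.t. f ≥ 0, Σf = 1,

a convex QP solved by a primal active-set method on the KKT system, with
an SLSQP polish as fallback; the solution matches a 0.001-step simplex
grid search to 1e-6 on random instances (tested). *W* is a diagonal gene
weighting. The default (`"model"`) is iteratively reweighted least
squares: an initial fit weighted by inverse mean signature expression,
then two rounds weighting each gene by the inverse of its *fitted*
mixture value. Under RNA-seq-like multiplicative noise (roughly constant
CV per gene) this is the efficient weighting, and deriving weights from
the model prediction rather than the noisy observation keeps it unbiased
— weighting by the observed value instead systematically understates
high-expression components (measured: the granule fraction inflates from
70% to 76% with observation-derived weights). `"mean"` and `"none"` are
available for diagnostics and oracle comparisons.

Because CPM inputs are scale-free, fractions are invariant to library
size; the deconvolution estimates **mRNA fractions**, which equal nuclei
fractions only when per-nucleus RNA content is equal across types. The
simulator exposes this bias rather than hiding it: with granule RNA
content halved, the estimated granule mRNA fraction sits consistently
below the nuclei fraction (tested), mirroring the known tendency of
expression deconvolution to under-represent small-nucleus cell types.

## Comparative (target-vs-rest) deconvolution

Each cell type gets a two-column panel: its signature and the unweighted
mean of all other signatures. The two-component simplex fit has a closed
form — the unconstrained target weight clipped to [0, 1], which is the
exact constrained optimum in one dimension. One panel is emitted per
signature column; the original description counts nine panels for eight
sorted types, an ambiguity we note and resolve as one-per-type.

Panels are fit on the **target's own specific genes** (specificity-index
top-k, or the true markers in simulations). This choice is load-bearing:
at genes specific to the target, every other cell type contributes the
same baseline, so shifts in composition among the remaining types cancel
identically and the similarity fraction is linear in the target's true
mixing weight. Panels built on the union of all types' markers are
instead dominated by the granule block — both a composition-dependent
offset and most of the sampling noise — and cannot resolve rare types
like Purkinje (0.7%). Gene weights are the inverse panel row mean, which
removes the gene-magnitude dependence exactly for marker-disjoint panels.

Condition contrasts use Welch's (unequal-variance, unpaired) t on the
per-sample fractions, BH-corrected across the cell types of one contrast
run; the fold change is the ratio of group means, reported > 1 with an
explicit direction. Flow-cytometry-style percentage tables are compared
with Mann–Whitney U (exact null for pooled n ≤ 20 without ties, normal
approximation with tie correction otherwise).

## Specificity index

For gene *g* and type *A*: rank all genes descending by
mean_A − mean_B of log₂ expression for every other type *B* (average
ranks for ties, so degenerate inputs are well defined), and average the
rank over *B*. The advertised 1,000 iterations are bootstrap resamples of
samples (donors) with replacement within each cell type — the sampling
unit of the underlying algorithm; iteration count and seed are
parameters. SI is invariant to per-gene constants, equals 1 for a gene
expressed only in its type, and is monotone in own-type expression (all
tested). "Specific genes" are the top-k per type (default k = 500;
simulations use k = markers-per-type); tertile cutpoints are the 33%/66%
linear-interpolation quantiles of the type's specific-gene means with
half-open bins [0, q33), [q33, q66), [q66, ∞).

## Differential expression and hidden covariates

Per-gene ordinary least squares on log₂ CPM with a t-test on the
coefficient of interest (condition, or age in years), BH across genes;
zero-variance genes report p = 1 and are flagged. This is an explicit
simplification of the NB/Wald + surrogate-variable stack used on real
data: no dispersion shrinkage, no outlier handling. Hidden covariates are
the top-k principal components of the residuals after regressing out the
primary design (k user-chosen, default 2) — a one-shot stand-in for
iterative surrogate-variable estimation. On synthetic cohorts the stage
is calibrated (null p < 0.05 fraction 0.05 ± 0.02 over 20 runs) and
recovers planted 2-fold effects within ±0.1 log₂ units; real-data
behavior under NB overdispersion will differ, which is why the interface,
not the inference, is the contract.

## GSEA and gene-set scores

Preranked GSEA uses the weighted KS running sum (hit increments
∝ |stat|^p with p = 1, normalized to sum 1; miss decrements 1/(N − n));
the observed ES accumulates sequentially so it is bit-identical to the
canonical walk down the list. Ranked lists drop genes with baseMean < 10
(strict) and break stat ties by gene ID. The null is gene-label
permutation (same-size random sets; sample permutation is impossible for
preranked input), NES divides by the mean same-sign null ES, and FDR
follows the standard pooled-NES procedure. Sets smaller than `min_size`
(default 5) in the universe, or covering the whole universe, are skipped
with a log entry.

The gene-set score of a sample is the mean log₂ expression over the set
(z-scoring per gene available, off by default — the source method's exact
formula is not restated in the text we follow, and the group contrast
Δ = difference of mean scores is consistent with "log₂ fold change in
score" either way). Δ is invariant to per-gene constants but not to
per-sample shifts; that sensitivity is normalization's job. Microglial-
state-style set construction filters an external DE table at padj < 0.05
(strict) and fraction-expressing ≥ 0.25 (inclusive). Signature panels
(A1/A2/PAN, MG states) additionally get a paired-across-genes t-test on
pooled per-gene group means; published panel memberships are user-supplied
GMT files — the repository ships only synthetic stand-ins in tests.

## Transcriptomic aging axis

PC1 of the significant age-associated genes (padj < 0.05 from the
control-donor age regression; ≥ 5 genes and ≥ 20 years of control age
span required), computed over all samples and oriented so the control
PC1-vs-age slope is positive — making the axis invariant to loading sign
flips. Acceleration = (mean disease PC1 − control intercept)/control
slope − mean disease chronological age, i.e. how many years older the
disease group appears on the control age line. If the control correlation
is weak (|r| < 0.3) the acceleration is reported as undefined, never
silently. The statistic is our formalization of "disease samples align
with much older controls"; no published value exists for it.

## Synthetic cohorts

`make_reference` draws shared base means 2^N(1,1) over 2,000 genes and
plants 30 disjoint marker genes per type whose mean is multiplied by the
boost (default 200) in their own type only. The default boost reflects
the 100–1000× enrichment of canonical cerebellar markers (PCP2/CALB1 for
Purkinje, GABRA6 for granule, AIF1 for microglia) in sorted profiles;
a power analysis at the fixed cohort sizes (25 control/12 disease,
dispersion 0.1) shows rare-type fold recovery at ±10% requires markers of
roughly this strength. Marker panels are drawn with equal aggregate
baseline abundance across types: with only a few dozen heavy-tailed genes
per panel, the random panel mass — and hence each type's transcriptome
budget after per-type CPM normalization — would otherwise fluctuate far
more than real marker programs spread over thousands of genes do, turning
a small-sample artifact of the generator into a spurious offset in rare-
type similarity fractions.

Counts are gamma-Poisson with var = μ + φμ² (default dispersion φ = 0.1,
typical for bulk human tissue), library sizes log-normal around 2×10⁶
reads (the study's ~16M scaled to desk size), and a per-donor per-gene
log-normal effect with sd 0.1 on the natural-log scale. Unsorted mixtures
have expectation ∝ Σ_c w_c ρ_c · profile_c with w the nuclei fractions
and ρ the per-type RNA content (ρ ≡ 1 by default). Sorted samples can be
mixed with an ambient pool weighted by the control composition
(granule-dominated) at rate α, emulating ambient RNA in droplet-based
single-nucleus data at pseudobulk level — no per-cell data, FASTQ reads,
or alignment artifacts are simulated.

The control composition preset fixes granule 0.70, Purkinje 0.007,
astrocyte 0.022, oligodendrocyte 0.013 (study estimates); basket 0.060,
Golgi 0.020, OPC 0.065 and microglia 0.113 close the simplex and are
configuration defaults, not literature claims. Disease effects are
applied in **single-effect mode** — one type's fold change per simulated
cohort, with the compensating mass absorbed by the granule fraction (or
redistributed proportionally when granule itself is the target). This is
deliberate: the published per-type ratios come from independent
two-component fits and are not jointly simplex-consistent, so applying
all of them at once cannot reproduce each ratio exactly.

`simulate_age_cohort` plants an aging program (default 100 non-marker
genes drifting ±0.05 log₂/yr with the donor's *transcriptomic* age);
controls sit on the age line, disease donors are drawn young with a +50
year transcriptomic offset.

What passing these tests shows: the estimators are correct, calibrated
and recover their targets under the generative model. What they do not
show: robustness to reference/mixture mismatch (platform effects,
cross-subject signature variation), NB dispersion heterogeneity beyond a
shared φ, or compositional effects of unmodeled cell types — real-data
questions the synthetic cohorts cannot answer.

## Problem sizes and determinism

All simulations run in seconds on one CPU at the sizes above. The
recovery script (`scripts/acceptance.py`) averages each fold-change
estimate over 8 independent replicate cohorts (cohort sizes unchanged) to
report the estimator's expectation rather than a single Monte-Carlo draw;
single-cohort estimates have ~5% relative sampling noise for the rarest
type. Every stochastic stage takes an explicit seed; a seeded pipeline
rerun is byte-identical (tested), and CLI runs record parameters, seeds
and output checksums in a manifest.
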