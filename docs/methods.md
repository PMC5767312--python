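# Methods

## Design and model

The pipeline targets a balanced 2 genotypes (drought-tolerant,
drought-sensitive) × 2 organs (leaf, root) × 2 conditions (control,
drought) single-channel expression experiment with 3 biological
replicates per cell (24 arrays). All statistics run on log2 intensities.

**Normalization.** Ingestion clips linear intensities at a detection
floor (default 1) before log2. Per-chip percentile shift subtracts each
array's 75th percentile; the percentile convention is linear
interpolation between closest ranks, r = 1 + q(n−1) (numpy's default),
fixed so results are bit-stable. Baseline transformation subtracts each
probe's median over *all* 24 samples — not per organ — which keeps
cross-organ values comparable and makes the operation idempotent. Order
is fixed as filter → percentile shift → baseline. Both steps remove
additive per-column / per-row offsets exactly; the post-normalization
zeros (column 75th percentiles, row medians) are bit-exact whenever the
rank lands on an order statistic (n ≡ 1 mod 4 probes for the percentile,
odd sample counts for the median) and at rounding error (≈1e−16)
otherwise.

**Differential expression.** Per organ, each probe gets a 2×2 cell-means
fit: cell means are arithmetic means of log2 values, the error variance
is pooled across the four cells (MSE, df = N − 4 = 8 at 3 replicates).
This is the simplest parameterization consistent with a two-way ANOVA
and with the comparisons actually reported: drought vs control within a
genotype, and tolerant vs sensitive within control. Contrasts are tested
with pooled-variance t statistics, two-sided p from t on the pooled df.
Organ is deliberately not a model factor — each organ is fitted
separately — because every reported contrast is within-organ.
Zero-variance probes use the degenerate rule p = 1 if Δ = 0 else 0, so
noiseless fixtures remain testable rather than being dropped. BH
adjustment (statsmodels' step-up) is applied across all probes,
separately per contrast per organ, matching per-comparison DEG lists.
Fold change is the geometric-ratio scale FC = 2^|Δ|. Calls are inclusive
at the boundary (FC ≥ τ, q ≤ α). Probe→gene collapse: a gene passes in a
direction iff ≥ 1 mapped probe passes; genes passing in both directions
carry a conflict flag, and conflicted genes are excluded from priming
calls by default (configurable).

**Priming rule.** "Differentially expressed in the sensitive genotype
only after drought" is read as *drought-DE in the sensitive genotype*,
not as "DE in the sensitive and not the tolerant genotype": candidate
sets are expected to overlap the tolerant genotype's own drought DEGs,
so overlap is recorded as a flag and summarized, never used to exclude.
Direction consistency compares the sensitive genotype's drought
direction with the sign of the initial contrast (tolerant-higher ⇒
drought-up, tolerant-lower ⇒ drought-down): the sensitive genotype
"catches up" to the tolerant baseline. A stricter variant (requiring
sensitive-only exclusivity) can be expressed by filtering calls on the
overlap flag.

**GO enrichment.** True-path propagation over the is_a/part_of DAG
(child→parent edges; acyclicity checked), then an upper-tail
hypergeometric test per term against the annotated background
(scipy's log-space survival function; exact to enumeration for all
N ≤ 12 at 1e−12). Genes without annotations are excluded from both N and
n. Significance is raw p ≤ 0.01 with minimum mapping entries x ≥ 5 —
raw, not FDR-adjusted, matching the SEA convention whose reported term
p-values are unadjusted; a BH switch exists but is off by default.

**Clustering.** Euclidean distances between samples over the full
normalized probe matrix (all probes, not only DEGs), Ward linkage in the
Ward.D2 dialect (squared-Euclidean criterion, square-root heights) via
scipy; merge heights are monotone. Cutting is by removing the k−1
highest merges.

**qPCR.** Efficiency estimation is a simplified window-of-linearity
procedure: fixed baseline = mean fluorescence of cycles 1–5, log10
regression over every contiguous 4–6-cycle strictly increasing window,
best window by R² (≥ 0.98 per well; per-amplicon E averages wells with
R² ≥ 0.99); the published tool's iterative baseline search is out of
scope. The Pfaffl ratio uses ΔCt = mean Ct(control) − mean Ct(treated)
per amplicon; with E = 2 on both sides it reduces to 2^ΔΔCt to rounding
error. The randomization test reallocates treatment labels of paired
(target, reference) observations without replacement and measures
two-sided extremeness of |log R*|; all distinct reallocations are
enumerated exactly when there are ≤ 10 000 of them (3-vs-3 gives 20),
otherwise 2 000 seeded samples with the add-one p estimate. (40−dCt)
uses mean Ct across replicates. Concordance is Spearman rho with average
ranks and a seeded permutation p.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions every recovery claim refers to.

Construction, on the log2 scale: per-gene baseline ~ N(8, 1.5²); a
per-gene organ offset ~ N(0, organ_effect²) on all genes (organs are
distinct tissues, so most genes differ between them — this is what makes
organ the dominant clustering factor); planted effects as cell-mean
shifts on top. Planted magnitudes are drawn uniform on
[δ, δ + effect_spread] with effect_spread = 2.5 log2 units: the planted
δ values are lower bounds by construction, and real drought responses
span roughly FC 3–40 (≈1.6–5.5 log2), so a point mass at the threshold
would be unrealistic. Defaults: 1200 genes, 1–3 probes per gene,
organ_effect 2.5 > condition_effect 2.0 > genotype_effect 1.5 (the
planted hierarchy the dendrogram must reproduce), 10 DEG genes per
(genotype-class × organ-class × direction) cell = 180 DEGs, 8 primed-high
+ 8 primed-low per organ class (root-only / leaf-only / both) = 48
primed genes with δ_init = 1.5 and δ_drought = 2.0, and 20
initial-difference-only decoys per organ class (constitutive genotype
offsets ≥ genotype_effect, no drought response) that exercise the
priming rule's false-discovery side. A quarter of primed genes also
respond in the tolerant genotype (magnitude drawn with half the spread,
hence usually smaller), so candidate/tolerant-DEG overlap is
represented. Probe values add a constant per-probe offset (σ = 0.3) and
i.i.d. N(0, 0.5²) noise; per-array additive log2 offsets (σ = 0.3;
multiplicative on the linear scale) exercise the percentile shift, which
removes them exactly. All randomness flows from one seed through a
single generator; identical configs give bit-identical output.

Ground-truth labels are re-derived from the stored noiseless cell means
using the analysis thresholds (|Δ| ≥ log2 3 for drought DEGs; initial
|Δ| ≥ 1 and sensitive drought |Δ| ≥ log2 3, direction-consistent, for
priming), so labels and generating means agree exactly and relabelling
from the stored means is a no-op.

GO annotations: a small synthetic DAG (leaf terms → group parents → one
namespace root); every gene picks up each leaf term with probability
0.05; designated terms over-sample their target planted set (root DEGs,
leaf DEGs, primed genes, cycled) by the enrichment factor (default 5;
factor 1 plants nothing and serves as the null). qPCR plates: Ct =
35 − log_E(2^level) with per-amplicon E ~ U[1.8, 2.0], Ct noise 0.15–0.2
cycles, a condition-invariant reference amplicon, and optional raw
curves F(c) = threshold·E^(c−Ct) capped at a plateau for the efficiency
estimator.

**What the generator does not emulate** — and therefore what passing
tests do not show about real arrays: probe-level cross-hybridization and
sequence-dependent affinity, intensity-dependent (nonlinear) array
effects, spatial/scanner artifacts, correlated gene modules beyond the
planted sets, unbalanced designs, or annotation noise in the probe→gene
map. Effects are additive Gaussian on the log2 scale, so the ANOVA's
assumptions hold by construction; real-data violations (heavy tails,
variance–mean dependence) would reduce the quoted sensitivity.

## Problem sizes and numerical choices

Recovery metrics average 10 simulated experiments at the default
conditions (noise σ = 0.5, n = 3); the BH null calibration uses 20
global-null datasets of 2000 single-probe genes; the Ward oracle
comparisons cover all trees up to 6 leaves; the hypergeometric oracle is
exhaustive for N ≤ 12 with exact rational arithmetic. At these sizes the
entire suite runs in well under a minute on one core. Ties in Ward
merging follow scipy's ordering; on continuous simulated data ties have
probability zero and the brute-force oracle agrees without a tie-break
convention mattering. Degenerate inputs (zero-variance probes, empty
contrast lists, flat qPCR curves, cyclic ontologies, reference gene in
the varying set) raise typed errors naming the offender rather than
propagating NaNs.

## Known limitations

* The per-organ replicate count actually hybridized in the motivating
  design is ambiguous; the generator defaults to 3 per cell and makes it
  configurable.
* Published dataset-level counts (e.g. 170/979/589 root DEG classes,
  170/237/99 priming candidates, Spearman 0.8268/0.8507) depend on the
  real arrays and a specific annotation release; this package asserts
  the partition *identities* those counts satisfy and reproduces the
  qualitative structure (hierarchy, recovery, concordance ≥ 0.8) on
  synthetic data, not the numbers themselves. One published
  leaf-exclusive breakdown (239 + 477 + 908 = 1624 vs a stated 1628) is
  internally inconsistent; the identity test asserts the algebraic sum.
* The GEO series-matrix loader is a minimal convenience for local files;
  re-analysis of the real deposited arrays is out of scope.
* Enrichment p-values are raw by convention; with many terms the
  significant list at p ≤ 0.01 carries the usual multiplicity caveat
  (the BH switch addresses this when wanted).
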