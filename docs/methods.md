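# Methods

## Measurement model

A qPCR cycle threshold is, to good approximation, linear in the negative
log2 of template abundance. The package adopts the standard
perfect-efficiency idealization throughout: one log2 unit of expression
equals one cycle, with the sign inverted (more template → lower Ct).
Amplification-efficiency correction and standard-curve quantification are
out of scope.

## Detection

An assay is *detected* when its Ct is non-missing and strictly below the
threshold (default 28 cycles) in every sample in scope. The strict
inequality matters at the boundary: Ct = 28.0 fails. By default the scope
is all samples of all groups jointly, so the detected set is common to
every downstream comparison; a scope argument supports other designs.
A missing (never-amplified) well and a well at or above threshold are
treated identically as "not detected" — the instrument does not
distinguish reliably between the two, and neither does the filter.
Detection is monotone: raising the threshold or shrinking the scope can
only grow the detected set (both properties are tested).

Internal controls (a silent negative control and replicated endogenous
small RNAs) are excluded from the detected set and from all statistics;
QC findings on them annotate and never remove data. An endogenous control
can still be selected explicitly as a reference-gene normalizer.

## Normalization

Global-mean normalization subtracts, per sample, the arithmetic mean Ct
over the **detected** set — not over all assays, since undetected wells
would poison the mean with censored values. Arithmetic mean on the Ct
scale is the geometric mean on the linear scale, the standard choice for
dense panels. Two consequences are used as test invariants: per-sample
additive offsets (pipetting, loading) cancel exactly, and ΔCt sums to
zero within each sample (tolerance 1e−9 × feature count).

Reference-gene normalization subtracts one assay's Ct per sample;
relative quantities follow 2^−ΔΔCt. SEMs use the n−1 standard deviation;
a group of size one reports its value with SEM marked undefined (NaN).

## Fold changes and regulation calling

FC is computed from the difference of group-mean ΔCt (a geometric-mean
ratio), not from averaging per-sample ratios: log-scale averaging is
scale-stable and standard for qPCR. Calling is by thresholds — up if
FC > 1.5, down if FC < 0.6, strict at both boundaries — because with
n = 3 pooled samples per group, per-feature FDR-corrected testing has
essentially no power; an optional pooled t-test on ΔCt is attached for
reporting only. The thresholds are deliberately asymmetric (0.6 ≠ 1/1.5),
so swapping test and reference maps FC → 1/FC but does **not** simply
swap the up and down sets; the exact mapping is asserted in tests.

One subtlety the tests document: with global-mean normalization, a
planted log2 shift of δ on one of n detected features is measured as
δ·(1 − 1/n), because the feature's own shift moves the normalizer. At
n ≈ 340 the attenuation is below 0.3% and irrelevant in practice, but
noiseless recovery tests assert the exact attenuated value rather than
pretending it away.

## Venn partitioning

Two comparisons' regulated sets are partitioned into eight pairwise
disjoint cells: common up/down, unique-to-A and unique-to-B up/down, and
two discordant cells (up in one comparison, down in the other). "Unique
to A" excludes features regulated in B in either direction — the only
convention under which the cells are disjoint, tile the union, and obey
the marginal identities |A_up| = common_up + unique_A_up + discordant.
The implementation is checked cell-by-cell against per-element brute
force on random instances.

## Target integration

Sources differ in evidence and scale, so each gets a configuration:
evidence (validated / predicted), score orientation, and a rescale rule.

* miRDB publishes integer scores on [50, 100] (sub-50 predictions are
  removed upstream by the database itself); the declared fixed range
  [50, 100] → [0.5, 1] is the linear map raw/100, and a score outside the
  declared range is a hard error.
* TargetScan-style context scores are more negative when stronger; they
  are min-max rescaled over the observed scores with a
  ``lower_is_stronger`` flag (which score column a user exports is their
  choice; the orientation flag covers either convention). A degenerate
  table whose scores are all equal rescales to 1.0 — with no spread,
  every record is the strongest observed.
* Validated records (miRTarBase, TarBase) carry an implicit rescaled
  score of 1.0 and bypass the score filter, which by its terms applies to
  *prediction* scores only. TarBase is treated as binary validated
  evidence.

Predicted records with rescaled score < 0.5 (strict) are dropped. Merging
keys on (miRNA, gene): validated beats predicted, otherwise the maximum
rescaled score wins, and provenance accumulates the set of supporting
sources; output is sorted, making the merge order-independent and
idempotent. Gene support then counts distinct regulated miRNAs (one
direction, one condition) per gene, keeping genes with support ≥ 2.
Database tables are consumed as static TSV exports; reproducing the
counts of any particular database release is a versioned exercise outside
the test suite.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) per term (Fisher's exact
enrichment direction), computed via scipy's stable log-space survival
function and verified against exact rational enumeration for every
parameter combination with N ≤ 12. The universe defaults to all genes
annotated to ≥ 1 term, intersected with any user-supplied background;
terms are intersected with the universe before testing and empty terms
are skipped. Benjamini–Hochberg adjustment (statsmodels, verified against
the textbook step-up oracle) runs across all tested terms; significance
is adjusted p < 0.05 and ranking is (p_adj, p, term_id) for determinism.

## Group statistics

The default two-sample test is pooled-variance Student's t (not Welch):
with equal n it reduces to t = Δmean / √(SEM_a² + SEM_b²) on
n_a + n_b − 2 degrees of freedom, and it reproduces the published
seizure-severity EEG p-values (0.4659 / 0.993 / 0.843 at n = 4 per
genotype) from their printed summaries to within print-rounding (±0.002).
The summary-statistics form exists precisely so printed mean ± SEM tables
can be re-tested; the raw-data form agrees with it to 1e−12.

One-way ANOVA uses the classical F; Fisher's LSD post hoc shares the
within-group mean square and its degrees of freedom across all pairs.
"Protected" is implemented as a flag — a pair is marked significant only
when omnibus and pairwise p are both below alpha — rather than by
suppressing pairwise p-values, so non-protected values remain visible.
All-constant input yields F = 0, p = 1 by convention.

## Synthetic data

The generator's defaults are the profiled study's design: 754 assays,
four genotype × treatment groups × 3 samples, pool size 2, four internal
controls (one negative, always missing), technical noise 0.25 cycles,
dropout above 35 cycles. Baselines are drawn from N(28, 3) cycles so that
roughly 44% of assays jointly pass the Ct < 28 filter — matching the
observed detection fraction of this panel design (the real study detected
335 of 754; default-seed simulations land near 340). Planted features
receive a fixed 24-cycle baseline so a planted down-regulation stays
detectable instead of silently dropping out.

Per sample, animal-level draws (baseline − group effect + N(0, σ)) are
averaged over the pool and a second N(0, σ) technical term is added; both
use the same σ for parsimony, giving a sample-level SD of σ√(1 + 1/pool).
Pooling is modelled on the log (Ct) scale for tractability; physically,
pooled RNA mixes on the linear scale, so the simulation slightly
understates pooling's variance reduction for strongly discordant animals.
The generator plants *shifts*, Gaussian noise and censoring only — it
does not emulate assay-specific efficiency differences, correlated
biological programs, or heavy-tailed outliers, so passing recovery tests
demonstrate the pipeline's arithmetic and calling logic, not robustness
to everything real data can do.

Target-database generation draws Bernoulli(density) edges with
source-appropriate score distributions (miRDB uniform on [50, 100],
TargetScan-like negative scores); planted hubs draw their edges from
validated or fixed-range sources so survival of the 0.5 filter is
guaranteed by construction, and the recovery experiments recompute true
support by brute force from the emitted edge lists. Gene-set generation
plants one term from which the query over-samples at a configurable
fraction; at the term's base rate the query carries no signal, which the
calibration test verifies.

All generators are pure functions of (config, seed) and bit-identical
across runs.

## Simulation-study sizes

The stock recovery experiments run the full 754-feature design over 20
seeds (classification: 20 planted features at |log2FC| = 1.58, i.e.
FC = 3 and 1/3) and the target/enrichment recovery over 50 seeds
(hub support exactness; planted term ranked first by adjusted p). These
sizes give stable Monte-Carlo estimates (binomial SE < 0.01 at the
observed rates) while keeping a full run in seconds.

## Known limitations

* No replicate-well collapsing: the Ct matrix is assumed pre-collapsed to
  one value per assay per sample.
* No amplification-curve or melt-curve QC.
* Min-max rescaling makes TargetScan's rescaled scores dependent on the
  exported table's score range; fixed-range sources are unaffected.
* The pipeline never fetches remote data; GEO exports or database
  releases must be converted to the documented TSV dialects by the user.
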