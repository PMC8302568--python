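# Methods

## Problem and data model

`organsim` answers two questions. First, which genes mark one organ against
every other tissue in a bulk RNA-seq atlas? Second, how far has a
differentiating culture progressed from a pluripotent expression state
toward that organ's expression state, as a single percentage?

All statistics operate on a genes × samples abundance matrix in RPKM/FPKM
or TPM, transformed entry-wise to log2(x + 1). The pseudocount-1 transform
is applied uniformly — panel selection and scoring share one scale, which
removes a whole class of silent unit-mismatch bugs. A matrix carries its
unit tag, and re-normalizing an already log-scale matrix is an error rather
than a warning.

### Preprocessing

Atlas preprocessing is explicit configuration, not automated curation:
tissues that would poison specificity testing (sex-specific tissues whose
genes look "specific" merely because most tissues lack them; blood, whose
leukocyte signature contaminates mixtures) are listed in a config and
dropped; sub-tissue labels that should count as one organ (e.g. two heart
sub-regions) are merged by a label mapping. We deliberately do not automate
outlier-tissue detection (e.g. by MDS): which tissues to exclude is a
judgement about the atlas, recorded once in the config.

Genes are optionally restricted to a user-supplied protein-coding ID list,
and genes that are essentially never expressed are removed: a gene is
dropped iff its maximum abundance across all samples is below 1, or its
third quartile is below 1 on the raw scale (equivalently, negative after
log2(x + 1)). The quartile uses linear interpolation between order
statistics (numpy's default) and the estimator is configurable, since
quantile conventions differ between toolchains and the filter sits right at
a threshold. Raw abundances cannot be negative, so a "third quartile < 0"
rule is only meaningful on the log scale; that reading is the one
implemented.

## Panel selection

For a target organ, three nested filters run on the log2 atlas
(`OrganPanelModel.fit()`; survivor sets are provably nested and each step's
per-gene statistic is kept):

1. **t-test intersection** (`alpha`, default 0.05). For each gene, a
   two-sample t-test compares the organ's samples against each other
   tissue's samples separately. A gene survives iff p < α in *every*
   comparison and (by default) the organ mean exceeds the other tissue's
   mean in every comparison. Welch's unequal-variance test is the default —
   tissue groups differ wildly in size and dispersion — with a
   pooled-variance option. The direction requirement exists because an
   intersection of two-sided tests would otherwise admit genes *depleted*
   in the organ; it can be switched off. No multiple-testing correction is
   applied by default (the per-gene statistic is a worst case over
   comparisons, and the next two filters are far more stringent than any
   p-value adjustment); Benjamini–Hochberg over genes is available as an
   option. The reported statistic is the maximum p over all comparisons.

   Degenerate groups: if both groups have zero variance, the test is
   resolved explicitly — equal means give p = 1 (indistinguishable), unequal
   means give p = 0. A tissue with fewer than two samples is an error
   naming the tissue, since no variance can be estimated.

2. **Confidence-interval boundary** (`ci_level`, default 0.99). Per gene,
   the lower bound of the organ mean's CI (LCI) must strictly exceed the
   maximum upper bound (UCI) over all other tissues; the margin
   LCI − max UCI is kept. CIs use the normal approximation
   mean ± z·sd/√n by default, with a Student-t multiplier as an option; at
   the atlas sample sizes this pipeline targets (tens of samples per
   tissue) the two are nearly identical, and the normal form keeps the
   filter's behaviour transparent. A zero-variance group has a width-zero
   CI, which is exactly right for the filter's purpose.

3. **Quantile ratio** (`quantile_q` = 0.75, `ratio_t` = 1.05). The organ's
   upper-quartile expression must strictly exceed `ratio_t` times the
   largest upper quartile among the other tissues. This targets the
   failure mode the CI filter misses: a tissue whose *top quarter* of
   samples rivals the organ even though its mean does not. The ratio
   O_q / max T_q is kept (infinite when the competing quantile is 0).
   Quantiles are computed on the log2 scale by default for internal
   consistency; a raw-scale option exists because the two scales order
   quantile *ratios* differently (log2 compression makes the 1.05
   threshold stricter at high expression and looser near zero), and which
   scale a published panel used may be ambiguous.

All comparisons are strict inequalities; ties fail. The final panel is the
union of step-3 survivors and an optional curated gene list, ordered
lexicographically, with per-gene provenance (`step3_survivor` vs `curated`)
so curated additions are never mistaken for statistical selections.

## Similarity scoring

Scoring needs, besides the panel: K organ reference samples and at least
one (typically two) undifferentiated reference samples, all log2(x + 1).
Two boundary vectors are built per panel gene — u_m, the minimum over
undifferentiated samples, and o_m, the minimum over organ samples. The
minimum (not mean) boundary encodes "the least expression this gene shows
in any true organ sample": any query at or above it is fully organ-like for
that gene.

A query x is clamped to x_m and scored:

* **median clamp** (default): x_mi = median(u_mi, x_i, o_mi). Whenever
  u_m ≤ o_m element-wise this confines x_m to the corridor [u_m, o_m], and
  the score 100·‖u_m − x_m‖₁ / ‖u_m − o_m‖₁ is guaranteed in [0, 100],
  reaching exactly 100 iff x_m = o_m and 0 iff x_m = u_m.
* **min clamp**: x_mi = min(x_i, o_mi), i.e. only the organ side is
  clamped. A query *below* the undifferentiated boundary then inflates
  |u − x| and can push the score above 100; because that artifact has no
  biological reading, reported min-mode scores are capped at 100 by
  default (`cap100`). Both modes exist because both conventions are in
  use; median is the default for every organ as the only mode with a
  guaranteed bound.

Numerics: the score is computed as 100·(num/den), ratio first, so a query
bit-for-bit on the organ boundary scores exactly 100.0. A panel on which
u_m = o_m everywhere has a zero denominator and is an error (the two
reference states are indistinguishable on the panel — no score is
meaningful). A gene with u_mi = o_mi contributes nothing to either norm.
Queries are accepted in TPM or FPKM/RPKM and normalized internally; no
cross-unit conversion is attempted, and mixing units between query and
references is the caller's responsibility (a real workflow often must mix
them, e.g. an RPKM atlas with TPM queries, so it is not an error). Panel
genes missing from a query are a hard error, with an opt-in to impute
them as unexpressed (0 on the log2 scale).

The optional permutation test shuffles the query's values among the panel
genes, re-clamps and re-scores, and reports
p = (1 + #{permuted ≥ observed}) / (1 + n_perm). It asks only whether the
score depends on which gene carries which value — a gene-label association
test, not a calibrated differentiation test — and the add-one convention
keeps p ≥ 1/(n_perm + 1) and makes a permutation-invariant (constant)
query give p = 1.

## Report artifacts

All result views are data tables. The per-gene deviation table ("GEAP"
view) maps query and organ-reference expression onto a linear color scale
over [0, `scale_max`] log2 units (default 10; wide-dynamic-range panels may
need 15) with the organ summarised by its per-gene *median* across
reference samples — a deliberate choice: the minimum defines the score
boundary, but the median is the fairer visual anchor for "typical organ
expression". The differential bar table ranks panel genes by
|query − organ median|. PCA coordinates are computed on centered data via
SVD with a deterministic sign convention (each component's
largest-magnitude loading is positive), so repeated runs are identical.
Figure rendering is cosmetic and intentionally untested.

## Synthetic data

The simulator generates what the selection steps assume and nothing more:
log-normal background (per-gene log2 baseline ~ N(3, 1.5), per-sample
log2 noise sigma = 0.5), and for each tissue a disjoint set of planted
genes shifted up by `effect_delta` log2 units in that tissue only. The
defaults — 6 tissues × 20 samples, 2,000 genes, 50 planted per tissue,
delta = 4 — are a realistic mid-sized recovery experiment: a 16-fold
specific up-shift against ~0.5 log2 units of noise, comparable to a clean
tissue marker. Undifferentiated references are drawn from the same
baselines without any planted shift, emulating a pluripotent line that
carries no organ's signature.

Trajectories interpolate linearly in log2 space between an
undifferentiated profile and an organ profile at mixing weights w ∈ [0, 1],
plus optional noise, and are emitted as raw TPM (2^v − 1) so they traverse
the same normalization path as real data. Because the score is an L1 ratio
and clamping leaves interior points untouched, a noise-free trajectory
scored against its own endpoint profiles scores exactly 100·w % — the
property the monotonicity tests exercise.

What the simulator does *not* model: gene–gene correlation, batch effects,
compositional (library-size) coupling between genes, heavy-tailed
dispersion, and partially shared expression programs between tissues.
Passing the recovery tests therefore shows the selection logic is correct
for location-shift signals, not that real-atlas panels are biologically
complete; on real data, correlated nuisance structure will admit some
co-regulated passengers and the curated-list mechanism exists precisely to
patch what pure statistics misses.

## Problem sizes used in the checks

The test suite and acceptance script run entirely on simulated data:
oracle-equivalence checks use 100 random atlases of ≤ 20 genes × ≤ 5
tissues re-computed gene-by-gene with scalar loops; the planted-recovery
check uses 20 replicates at the simulator defaults (2,000 genes, 6 × 20
samples), pooling precision and recall over replicates; the acceptance
script uses a 600-gene, 5-tissue atlas. These sizes were chosen so the
complete battery runs in well under a minute while keeping every statistic
in its asymptotically comfortable regime.

## Known limitations

* The three steps test location (mean, CI of mean, quantile); genes
  specific in variance or bimodality are invisible to them.
* With exactly two undifferentiated samples the u_m boundary is a minimum
  of two draws — noisy; more undifferentiated references tighten the 0%
  anchor.
* The score is panel-relative: 100% means "indistinguishable from organ on
  the panel genes", not organ-equivalence of the whole transcriptome, and
  scores across different panels are not comparable.
* The permutation p-value is a stand-in association test, not a calibrated
  significance statement about differentiation quality.
* No attempt is made to harmonise RPKM vs TPM; gross unit mismatches
  between query and reference shift scores.
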