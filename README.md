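# organsim

Quantitative organ-similarity scoring for stem-cell-derived organoids and
cells, built on organ-specific gene expression panels selected from a
multi-tissue bulk RNA-seq atlas.

Differentiation protocols turn human pluripotent stem cells into organoids
and specialised cells, but judging *how close* the result is to the real
organ usually rests on a handful of marker genes. `organsim` gives that
judgement a number: a 0–100% transcriptome similarity score between a query
sample and a target organ, together with per-gene deviation tables that say
which panel genes are still under- or over-expressed. It is aimed at stem
cell and organoid labs with bulk RNA-seq of their cultures (TPM or
FPKM/RPKM) and at bioinformaticians building tissue-identity references
from atlases such as GTEx.

## The method

**Panel selection.** From a genes × samples atlas covering many tissues
(log2(x+1)-normalized), genes specific to a target organ are selected in
three steps:

1. *t-test intersection* — for each gene, a two-sample Welch t-test compares
   the organ against every other tissue; the gene survives iff p < α (0.05)
   in **all** comparisons, with the organ mean on top.
2. *Confidence-interval boundary* — the lower bound of the 99% CI of the
   gene's organ mean must exceed the maximum upper 99% CI bound across all
   other tissues (LCI > max UCI), removing genes whose apparent specificity
   rides on high variance elsewhere.
3. *Quantile ratio* — the organ's upper-quartile expression O_q must exceed
   1.05 × the largest upper quartile among the other tissues (strictly),
   removing genes with heavy high-expression tails in other tissues.

Curated, function-associated genes can be merged into the final panel.

**Similarity score.** On the panel genes, two boundary vectors are built on
the log2(x+1) scale: U_m, the per-gene minimum over undifferentiated
reference samples (e.g. hESCs), and O_m, the per-gene minimum over K organ
reference samples. A query x is clamped between them — median mode uses
x_mi = median(u_mi, x_i, o_mi); min mode clamps only the organ side — and
scored as

```
score = 100 · ‖U_m − X_m‖₁ / ‖U_m − O_m‖₁   (%)
```

i.e. the query's L1 progress from the undifferentiated boundary toward the
organ boundary: 0% at U_m, exactly 100% at (or beyond) O_m.

## Worked example

No external data is needed — the built-in simulator plants organ-specific
genes in a log-normal atlas and draws a differentiation trajectory from an
undifferentiated state toward the organ profile:

```python
from organsim import (
    SyntheticAtlasSpec, TrajectorySpec, generate_atlas, generate_trajectory,
    generate_undiff_reference, log2_normalize, tissue_profile,
    OrganPanelModel, OrganSimilarityModel,
)

spec = SyntheticAtlasSpec(n_tissues=6, samples_per_tissue=20, n_genes=2000,
                          n_planted_per_organ=50, seed=0)
atlas, meta, truth = generate_atlas(spec)
atlas_log = log2_normalize(atlas)

res = OrganPanelModel(atlas_log, meta, organ="tissue01").fit()
print(res.summary())

organ_ref = atlas_log.subset_samples(meta.samples_for("tissue01"))
undiff_ref = log2_normalize(generate_undiff_reference(spec))
model = OrganSimilarityModel(res.panel, organ_ref, undiff_ref, mode="median")

traj = generate_trajectory(
    tissue_profile(atlas_log, meta, "tissue01", "mean"),
    undiff_ref.data.mean(axis=1),
    TrajectorySpec(mixing_weights=(0.0, 0.25, 0.5, 0.75, 1.0)),
)
print(model.score(traj).summary())
```

```
Organ-specific gene panel: tissue01
============================================
atlas genes                    2000
atlas samples                   120
tissues                           6
--------------------------------------------
step 1 (t-test, a=0.05)          51
step 2 (CI 99% boundary)         50
step 3 (Q0.75 ratio>1.05)       50
curated additions                 0
final panel size                 50

Organ similarity (tissue01, 50 genes, median clamp)
references: 20 organ, 2 undifferentiated
----------------------------------------------------
sample                     score %     clamped
step01_w0.00                  7.60           0
step02_w0.25                 38.36           0
step03_w0.50                 69.11           0
step04_w0.75                 96.80          22
step05_w1.00                100.00          50
```

The three steps recover exactly the 50 planted tissue01-specific genes
(51 → 50 → 50, one step-1 false positive removed by the CI filter). Scores
rise monotonically along the trajectory from 7.6% (undifferentiated-state
sample, scored against mean profiles rather than the minima it was built
from, hence slightly above 0) to 100% at the organ profile; the `clamped`
column counts panel genes whose expression crossed a boundary and was
replaced by it.

## Command line

The same workflow is available as subcommands:

```bash
organsim simulate --outdir sim --seed 11
organsim build-panel --atlas sim/atlas.tsv --meta sim/meta.tsv \
    --organ tissue01 -o panel.tsv
organsim score --panel panel.tsv --organ-ref organ.tsv \
    --undiff-ref sim/undiff.tsv --query sim/trajectory.tsv --out scores.tsv
organsim report --panel panel.tsv --organ-ref organ.tsv \
    --undiff-ref sim/undiff.tsv --query sim/trajectory.tsv --outdir report/
```

`report` writes `scores.tsv`, `heatmap.tsv`, `pca.tsv`, `geap.tsv`
(per-gene deviation with color bins) and `diffbar.tsv` (genes ranked by
deviation from the organ median).

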