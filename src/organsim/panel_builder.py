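"""Three-step selection of organ-specific gene expression panels.

Given a log2-normalized multi-tissue atlas, a target organ's panel is the
set of genes that

1. differ significantly (two-sample t-test, p < alpha) between the organ
   and *every* other tissue, with the organ mean on top;
2. have a lower 99% confidence bound on their organ mean above the largest
   upper confidence bound among all other tissues (LCI > max UCI); and
3. have an upper-quartile expression in the organ exceeding ``ratio_t``
   times the largest upper quartile among the other tissues (strict, with
   ratio_t = 1.05 by default).

Step 1 finds differential genes, step 2 removes genes whose apparent
specificity rides on high variance elsewhere, and step 3 removes genes
whose top-quartile expression in some other tissue rivals the organ.
A curated gene list (e.g. function-associated genes from the literature)
can be merged into the final panel.

:class:`OrganPanelModel` wraps the three steps in a statsmodels-style
``model.fit() -> results`` interface; the step functions remain available
for direct use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import LOG_UNIT, ExpressionMatrix, SampleMetadata

__all__ = [
    "SelectionParams",
    "GenePanel",
    "OrganPanelModel",
    "OrganPanelResults",
    "step1_ttest_intersection",
    "step2_ci_boundary_filter",
    "step3_quantile_ratio_filter",
    "assemble_panel",
]

STEP3_SURVIVOR = "step3_survivor"
CURATED = "curated"


@dataclass(frozen=True)
class SelectionParams:
    """Tuning knobs of the three selection steps.

    alpha : significance level of the per-tissue t-tests (step 1).
    ci_level : confidence level of the mean CIs (step 2).
    quantile_q : quantile compared across tissues in step 3 (0.75 = upper
        quartile).
    ratio_t : the organ quantile must exceed ``ratio_t`` x the largest other
        quantile (strictly).
    require_higher_in_target : additionally require the organ mean to exceed
        every other tissue mean in step 1, so the panel contains enriched,
        not depleted, genes.
    equal_var : pooled-variance Student t-test instead of Welch.
    ci_method : "normal" for mean +/- z*sd/sqrt(n), "t" for the Student-t
        multiplier.
    step3_scale : "log2" evaluates step-3 quantiles on the log2(x+1) matrix,
        "raw" back-transforms to the raw abundance scale first.
    bh_correct : Benjamini-Hochberg-adjust each gene's worst-case p-value
        across genes before thresholding (off by default).
    """

    alpha: float = 0.05
    ci_level: float = 0.99
    quantile_q: float = 0.75
    ratio_t: float = 1.05
    require_higher_in_target: bool = True
    equal_var: bool = False
    ci_method: str = "normal"
    step3_scale: str = "log2"
    bh_correct: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 < self.quantile_q < 1:
            raise ValueError("quantile_q must be in (0, 1)")
        if self.ratio_t < 1:
            raise ValueError("ratio_t must be >= 1")
        if self.ci_method not in ("normal", "t"):
            raise ValueError("ci_method must be 'normal' or 't'")
        if self.step3_scale not in ("log2", "raw"):
            raise ValueError("step3_scale must be 'log2' or 'raw'")


@dataclass
class GenePanel:
    """An organ's selected gene set with per-gene provenance and statistics.

    ``step_stats`` has one row per gene with columns ``step1_max_p``,
    ``step2_margin`` and ``step3_ratio``; curated genes carry NaN there.
    """

    organ: str
    genes: list[str]
    provenance: dict[str, str]
    step_stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in panel")
        missing = [g for g in self.genes if g not in self.provenance]
        if missing:
            raise ValueError(f"genes without provenance: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for g in self.genes:
            rec = {"gene_id": g, "provenance": self.provenance[g]}
            if g in self.step_stats.index:
                rec.update(self.step_stats.loc[g].to_dict())
            rows.append(rec)
        cols = ["gene_id", "provenance", "step1_max_p", "step2_margin", "step3_ratio"]
        df = pd.DataFrame(rows)
        for c in cols:
            if c not in df.columns:
                df[c] = np.nan
        df[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path, organ: str = "") -> "GenePanel":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        genes = df["gene_id"].tolist()
        prov = dict(zip(genes, df["provenance"]))
        stat_cols = [c for c in ("step1_max_p", "step2_margin", "step3_ratio") if c in df]
        stats_df = df.set_index("gene_id")[stat_cols]
        return cls(organ=organ, genes=genes, provenance=prov, step_stats=stats_df)


# ---------------------------------------------------------------------------
# per-tissue summaries
# ---------------------------------------------------------------------------

def _tissue_groups(
    atlas: ExpressionMatrix, meta: SampleMetadata, organ: str, min_n: int = 2
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Split the atlas columns into the organ block and each other tissue block."""
    if atlas.unit != LOG_UNIT:
        raise ValueError("panel selection operates on the log2-normalized atlas")
    meta.require_covers(atlas)
    tissues = meta.tissues()
    if organ not in tissues:
        raise ValueError(f"organ {organ!r} not among tissues {tissues}")
    col_index = {s: i for i, s in enumerate(atlas.sample_ids)}
    values = atlas.values
    blocks: dict[str, np.ndarray] = {}
    for t in tissues:
        cols = [col_index[s] for s in meta.samples_for(t) if s in col_index]
        if len(cols) < min_n:
            raise ValueError(f"tissue {t!r} has {len(cols)} sample(s); need >= {min_n}")
        blocks[t] = values[:, cols]
    organ_block = blocks.pop(organ)
    return organ_block, blocks


def step1_ttest_intersection(
    atlas: ExpressionMatrix,
    meta: SampleMetadata,
    organ: str,
    params: SelectionParams | None = None,
) -> pd.Series:
    """Genes significant against every other tissue; value = worst-case p.

    For each gene, a two-sample t-test (Welch by default) compares the organ
    samples with each other tissue's samples.  A gene survives when p < alpha
    in all comparisons and (by default) the organ mean is the larger one in
    all of them.  Returns a Series indexed by surviving gene with the maximum
    p-value over the comparisons.
    """
    params = params or SelectionParams()
    organ_block, others = _tissue_groups(atlas, meta, organ)
    n_genes = organ_block.shape[0]
    max_p = np.zeros(n_genes)
    higher_everywhere = np.ones(n_genes, dtype=bool)
    organ_mean = organ_block.mean(axis=1)
    for block in others.values():
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # zero-variance groups are resolved explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(
                organ_block, block, axis=1, equal_var=params.equal_var
            )
        p = np.asarray(res.pvalue, dtype=float)
        # both groups constant: equal means -> indistinguishable (p = 1);
        # different means with zero variance -> t is +-inf, p already 0
        p = np.where(np.isnan(p), 1.0, p)
        max_p = np.maximum(max_p, p)
        if params.require_higher_in_target:
            higher_everywhere &= organ_mean > block.mean(axis=1)
    if params.bh_correct:
        max_p = _bh_adjust(max_p)
    selected = (max_p < params.alpha) & (
        higher_everywhere if params.require_higher_in_target else True
    )
    return pd.Series(max_p[selected], index=np.asarray(atlas.gene_ids)[selected])


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def _ci_halfwidth(sd: np.ndarray, n: int, level: float, method: str) -> np.ndarray:
    if method == "t":
        mult = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    else:
        mult = stats.norm.ppf(0.5 + level / 2.0)
    return mult * sd / np.sqrt(n)


def step2_ci_boundary_filter(
    atlas: ExpressionMatrix,
    meta: SampleMetadata,
    organ: str,
    candidates: Iterable[str],
    params: SelectionParams | None = None,
) -> pd.Series:
    """Genes whose organ LCI clears every other tissue's UCI; value = margin.

    LCI is the lower bound of the ``ci_level`` confidence interval of the
    organ mean; UCI_j the upper bound for tissue j.  Survival requires
    LCI > max_j UCI_j strictly; the returned margin is LCI - max_j UCI_j.
    """
    params = params or SelectionParams()
    candidates = list(candidates)
    if not candidates:
        warnings.warn("empty candidate set for CI filter", stacklevel=2)
        return pd.Series(dtype=float)
    sub = atlas.subset_genes(candidates)
    organ_block, others = _tissue_groups(sub, meta, organ)
    n_o = organ_block.shape[1]
    lci = organ_block.mean(axis=1) - _ci_halfwidth(
        organ_block.std(axis=1, ddof=1), n_o, params.ci_level, params.ci_method
    )
    max_uci = np.full(len(candidates), -np.inf)
    for block in others.values():
        uci = block.mean(axis=1) + _ci_halfwidth(
            block.std(axis=1, ddof=1), block.shape[1], params.ci_level, params.ci_method
        )
        max_uci = np.maximum(max_uci, uci)
    margin = lci - max_uci
    keep = margin > 0
    return pd.Series(margin[keep], index=np.asarray(candidates)[keep])


def step3_quantile_ratio_filter(
    atlas: ExpressionMatrix,
    meta: SampleMetadata,
    organ: str,
    candidates: Iterable[str],
    params: SelectionParams | None = None,
) -> pd.Series:
    """Genes whose organ upper quantile beats ratio_t x every other tissue's.

    Survival requires O_q > ratio_t * max_j T_jq strictly.  The returned
    value is the ratio O_q / max_j T_jq (inf when the max is 0 and O_q > 0,
    NaN when both are 0 — such genes never survive).
    """
    params = params or SelectionParams()
    candidates = list(candidates)
    if not candidates:
        warnings.warn("empty candidate set for quantile filter", stacklevel=2)
        return pd.Series(dtype=float)
    sub = atlas.subset_genes(candidates)
    organ_block, others = _tissue_groups(sub, meta, organ, min_n=1)
    if params.step3_scale == "raw":
        organ_block = np.exp2(organ_block) - 1.0
        others = {t: np.exp2(b) - 1.0 for t, b in others.items()}
    q = params.quantile_q
    o_q = np.quantile(organ_block, q, axis=1)
    max_t = np.max(
        np.stack([np.quantile(b, q, axis=1) for b in others.values()]), axis=0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            max_t > 0, o_q / max_t, np.where(o_q > 0, np.inf, np.nan)
        )
    keep = o_q > params.ratio_t * max_t
    return pd.Series(ratio[keep], index=np.asarray(candidates)[keep])


def assemble_panel(
    organ: str,
    step3_survivors: Iterable[str],
    curated: Sequence[str] = (),
    step_stats: pd.DataFrame | None = None,
    atlas_genes: Iterable[str] | None = None,
) -> GenePanel:
    """Merge step-3 survivors with a curated list into the final panel.

    Curated genes already among the survivors keep their ``step3_survivor``
    provenance; genes are ordered lexicographically for determinism.  When
    ``atlas_genes`` is given, curated genes outside the atlas trigger a
    warning (they cannot be scored against atlas-derived references).
    """
    survivors = set(step3_survivors)
    curated_only = [g for g in curated if g not in survivors]
    if atlas_genes is not None:
        atlas_set = set(atlas_genes)
        orphans = [g for g in curated_only if g not in atlas_set]
        if orphans:
            warnings.warn(
                f"curated genes absent from atlas: {orphans[:10]}", stacklevel=2
            )
    genes = sorted(survivors | set(curated_only))
    provenance = {
        g: (STEP3_SURVIVOR if g in survivors else CURATED) for g in genes
    }
    if step_stats is None:
        step_stats = pd.DataFrame(
            columns=["step1_max_p", "step2_margin", "step3_ratio"], dtype=float
        )
    return GenePanel(organ=organ, genes=genes, provenance=provenance, step_stats=step_stats)


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

class OrganPanelModel:
    """Panel-selection model over a log2-normalized atlas.

    Examples
    --------
    >>> model = OrganPanelModel(atlas, meta, organ="heart")
    >>> res = model.fit()
    >>> res.panel.genes          # doctest: +SKIP
    >>> print(res.summary())     # doctest: +SKIP
    """

    def __init__(
        self,
        atlas: ExpressionMatrix,
        metadata: SampleMetadata,
        organ: str,
        params: SelectionParams | None = None,
        curated: Sequence[str] = (),
    ) -> None:
        if atlas.unit != LOG_UNIT:
            raise ValueError(
                "atlas must be log2-normalized (use expression_io.log2_normalize)"
            )
        metadata.require_covers(atlas)
        self.atlas = atlas
        self.metadata = metadata
        self.organ = organ
        self.params = params or SelectionParams()
        self.curated = list(curated)

    def fit(self) -> "OrganPanelResults":
        p = self.params
        s1 = step1_ttest_intersection(self.atlas, self.metadata, self.organ, p)
        s2 = step2_ci_boundary_filter(self.atlas, self.metadata, self.organ, s1.index, p)
        s3 = step3_quantile_ratio_filter(self.atlas, self.metadata, self.organ, s2.index, p)
        stats_df = pd.DataFrame(
            {
                "step1_max_p": s1.reindex(s3.index),
                "step2_margin": s2.reindex(s3.index),
                "step3_ratio": s3,
            }
        )
        panel = assemble_panel(
            self.organ, s3.index, self.curated, stats_df, self.atlas.gene_ids
        )
        return OrganPanelResults(self, panel, s1, s2, s3)


class OrganPanelResults:
    """Fitted panel plus the per-step survivor statistics."""

    def __init__(
        self,
        model: OrganPanelModel,
        panel: GenePanel,
        step1_pvalues: pd.Series,
        step2_margins: pd.Series,
        step3_ratios: pd.Series,
    ) -> None:
        self.model = model
        self.panel = panel
        self.step1_pvalues = step1_pvalues
        self.step2_margins = step2_margins
        self.step3_ratios = step3_ratios

    @property
    def n_step1(self) -> int:
        return len(self.step1_pvalues)

    @property
    def n_step2(self) -> int:
        return len(self.step2_margins)

    @property
    def n_step3(self) -> int:
        return len(self.step3_ratios)

    def summary(self) -> str:
        p = self.model.params
        lines = [
            f"Organ-specific gene panel: {self.model.organ}",
            "=" * 44,
            f"atlas genes                {self.model.atlas.n_genes:>8d}",
            f"atlas samples              {self.model.atlas.n_samples:>8d}",
            f"tissues                    {len(self.model.metadata.tissues()):>8d}",
            "-" * 44,
            f"step 1 (t-test, a={p.alpha:g})    {self.n_step1:>8d}",
            f"step 2 (CI {p.ci_level:.0%} boundary)   {self.n_step2:>8d}",
            f"step 3 (Q{p.quantile_q:.2f} ratio>{p.ratio_t:g}) {self.n_step3:>8d}",
            f"curated additions          {sum(1 for v in self.panel.provenance.values() if v == CURATED):>8d}",
            f"final panel size           {len(self.panel):>8d}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<OrganPanelResults organ={self.model.organ!r} "
            f"steps={self.n_step1}/{self.n_step2}/{self.n_step3} "
            f"panel={len(self.panel)}>"
        )
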