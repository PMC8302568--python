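"""Result artifacts: score tables, panel heatmap, PCA, deviation tables.

All outputs are plain data tables (TSV); figure rendering is an optional
cosmetic layer on top.  The per-gene deviation table ("gene expression
alteration" view) compares a query sample to the organ reference gene by
gene on a bounded color scale, so over- and under-expressed panel genes are
immediately visible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .expression_io import ExpressionMatrix, LOG_UNIT
from .panel_builder import GenePanel
from .similarity_engine import SimilarityResults

__all__ = [
    "geap_table",
    "pca_coordinates",
    "diff_bar_table",
    "heatmap_table",
    "write_report",
]


def _organ_summary(organ_ref: ExpressionMatrix, genes: Sequence[str]) -> pd.Series:
    """Per-gene median across organ reference samples (log2 scale)."""
    if organ_ref.unit != LOG_UNIT:
        raise ValueError("organ reference must be log2-normalized")
    return organ_ref.data.reindex(list(genes)).median(axis=1)


def _bin_on_scale(values: np.ndarray, scale_max: float, n_bins: int) -> np.ndarray:
    """Linear bin index in [0, n_bins-1]; values are clipped to [0, scale_max]."""
    frac = np.clip(values, 0.0, scale_max) / scale_max
    return np.minimum((frac * n_bins).astype(int), n_bins - 1)


def geap_table(
    query: pd.Series,
    panel: GenePanel,
    organ_ref: ExpressionMatrix,
    scale_max: float = 10.0,
    n_bins: int = 16,
) -> pd.DataFrame:
    """Per-panel-gene deviation of a query from the organ reference.

    ``query`` holds log2(x + 1) expression indexed by gene.  Expression is
    mapped onto a linear color scale from 0 (low) to ``scale_max`` (high);
    ``scale_max`` should sit near the panel's dynamic range (10 is typical,
    wider panels may need 15).  One row per panel gene with the query value,
    the organ median, their difference and both bin indices.
    """
    if scale_max <= 0:
        raise ValueError("scale_max must be > 0")
    genes = list(panel.genes)
    missing = [g for g in genes if g not in query.index]
    if missing:
        raise KeyError(f"query is missing panel genes: {missing[:20]}")
    q = query.loc[genes].to_numpy(dtype=float)
    organ = _organ_summary(organ_ref, genes).to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "query_expression": q,
            "organ_reference_expression": organ,
            "deviation": q - organ,
            "query_bin": _bin_on_scale(q, scale_max, n_bins),
            "organ_bin": _bin_on_scale(organ, scale_max, n_bins),
        }
    )


def pca_coordinates(
    samples: ExpressionMatrix, n_components: int = 2
) -> pd.DataFrame:
    """Centered PCA of samples on the current gene set.

    Rows are samples, columns ``PC1..PCk`` with the explained variance ratio
    attached as ``df.attrs['explained_variance_ratio']``.  Component signs
    follow a deterministic convention: the largest-magnitude gene loading of
    each component is made positive.
    """
    if samples.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    if samples.n_samples < n_components:
        raise ValueError("fewer samples than requested components")
    X = samples.values.T  # samples x genes
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    for k in range(n_components):
        lead = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, lead] < 0:
            pca.components_[k] *= -1
            coords[:, k] *= -1
    df = pd.DataFrame(
        coords,
        index=pd.Index(samples.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    df.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return df


def diff_bar_table(
    query: pd.Series, organ_ref: ExpressionMatrix, panel: GenePanel
) -> pd.DataFrame:
    """Panel genes ranked by |query - organ median|, signed deviations kept."""
    genes = list(panel.genes)
    missing = [g for g in genes if g not in query.index]
    if missing:
        raise KeyError(f"query is missing panel genes: {missing[:20]}")
    dev = query.loc[genes].to_numpy(dtype=float) - _organ_summary(
        organ_ref, genes
    ).to_numpy(dtype=float)
    df = pd.DataFrame({"gene_id": genes, "deviation": dev})
    df["abs_deviation"] = df["deviation"].abs()
    df = df.sort_values(
        ["abs_deviation", "gene_id"], ascending=[False, True], kind="mergesort"
    ).drop(columns="abs_deviation")
    return df.reset_index(drop=True)


def heatmap_table(
    samples: ExpressionMatrix, panel: GenePanel
) -> pd.DataFrame:
    """Panel-gene x sample expression sub-matrix (values untouched)."""
    return samples.data.reindex(list(panel.genes))


def write_report(
    outdir: str | Path,
    results: SimilarityResults,
    queries: ExpressionMatrix,
    scale_max: float = 10.0,
) -> dict[str, Path]:
    """Write the full artifact set for a scored batch.

    Emits ``scores.tsv``, ``heatmap.tsv`` (panel genes x queries + references),
    ``pca.tsv`` (queries + references on panel genes), ``geap.tsv`` and
    ``diffbar.tsv`` (per-query, stacked with a sample_id column).  ``queries``
    must be on the log2 scale already if scores were computed from raw input
    via the model (the model normalizes internally); raw queries are accepted
    and normalized here for consistency.
    """
    from .expression_io import log2_normalize

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = results.model
    panel = model.panel
    if queries.is_raw():
        queries = log2_normalize(queries)

    paths: dict[str, Path] = {}

    paths["scores"] = outdir / "scores.tsv"
    results.to_frame().to_csv(paths["scores"], sep="\t", index=False)

    combined = pd.concat(
        [
            heatmap_table(queries, panel),
            heatmap_table(model.organ_ref, panel),
            heatmap_table(model.undiff_ref, panel),
        ],
        axis=1,
    )
    paths["heatmap"] = outdir / "heatmap.tsv"
    combined.rename_axis("gene_id").to_csv(paths["heatmap"], sep="\t", float_format="%.17g")

    pca_df = pca_coordinates(ExpressionMatrix(combined, LOG_UNIT))
    paths["pca"] = outdir / "pca.tsv"
    pca_df.to_csv(paths["pca"], sep="\t", float_format="%.17g")

    geaps, bars = [], []
    for sample in queries.sample_ids:
        g = geap_table(queries.data[sample], panel, model.organ_ref, scale_max)
        g.insert(0, "sample_id", sample)
        geaps.append(g)
        b = diff_bar_table(queries.data[sample], model.organ_ref, panel)
        b.insert(0, "sample_id", sample)
        bars.append(b)
    paths["geap"] = outdir / "geap.tsv"
    pd.concat(geaps).to_csv(paths["geap"], sep="\t", index=False, float_format="%.17g")
    paths["diffbar"] = outdir / "diffbar.tsv"
    pd.concat(bars).to_csv(paths["diffbar"], sep="\t", index=False, float_format="%.17g")
    return paths
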