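"""Expression-matrix containers, I/O and bulk RNA-seq preprocessing.

The atlas side of the pipeline works on a genes x samples abundance table
(RPKM/FPKM or TPM) plus a sample -> tissue metadata table.  Preprocessing
mirrors a standard multi-tissue atlas workflow: drop confounding tissues
(sex-specific, blood), merge sub-tissues that should count as one organ,
restrict to protein-coding genes, remove genes that are essentially never
expressed, and move to a log2(x + 1) scale for all downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RAW_UNITS",
    "LOG_UNIT",
    "ExpressionMatrix",
    "SampleMetadata",
    "TissueExclusionConfig",
    "load_matrix",
    "write_matrix",
    "load_metadata",
    "apply_tissue_policy",
    "filter_protein_coding",
    "prefilter_low_expression",
    "log2_normalize",
]

#: Abundance units accepted on disk.  ``LOG2P1`` marks a matrix whose entries
#: are log2(x + 1) of one of the raw units; it is normally only produced by
#: :func:`log2_normalize`.
RAW_UNITS = frozenset({"RPKM", "FPKM", "TPM"})
LOG_UNIT = "LOG2P1"
VALID_UNITS = RAW_UNITS | {LOG_UNIT}


class ExpressionMatrixError(ValueError):
    """Contract violation while building or transforming an expression matrix."""


@dataclass
class ExpressionMatrix:
    """A genes x samples abundance matrix with an explicit unit tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene identifier, columns by sample identifier.
        Values must be finite and, for raw units, non-negative.
    unit : str
        One of ``RPKM``, ``FPKM``, ``TPM`` or ``LOG2P1``.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ExpressionMatrixError(
                f"unknown unit {self.unit!r}; expected one of {sorted(VALID_UNITS)}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ExpressionMatrixError(f"duplicate gene IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ExpressionMatrixError(f"duplicate sample IDs: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ExpressionMatrixError("matrix contains non-numeric cells")
        if np.isnan(values).any():
            gi, si = map(int, np.argwhere(np.isnan(values))[0])
            raise ExpressionMatrixError(
                "missing value at gene "
                f"{self.data.index[gi]!r}, sample {self.data.columns[si]!r}"
            )
        if not np.isfinite(values).all():
            raise ExpressionMatrixError("matrix contains non-finite values")
        if (values < 0).any():
            gi, si = map(int, np.argwhere(values < 0)[0])
            raise ExpressionMatrixError(
                f"negative value at gene {self.data.index[gi]!r}, "
                f"sample {self.data.columns[si]!r} (unit {self.unit})"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def is_raw(self) -> bool:
        return self.unit in RAW_UNITS

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return the sub-matrix for ``genes`` (order as given)."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data[list(samples)], self.unit)


@dataclass
class SampleMetadata:
    """Sample annotations: tissue label plus optional sub-tissue and role.

    ``table`` is indexed by sample_id with columns ``tissue`` (required),
    ``subtissue`` and ``role`` (defaulted).  Roles distinguish atlas samples
    from organ references, undifferentiated references and queries.
    """

    table: pd.DataFrame

    ROLES = ("atlas", "organ_reference", "undifferentiated_reference", "query")

    def __post_init__(self) -> None:
        if "tissue" not in self.table.columns:
            raise ValueError("metadata must have a 'tissue' column")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample IDs in metadata")
        tissues = self.table["tissue"]
        if tissues.isna().any() or (tissues.astype(str).str.len() == 0).any():
            raise ValueError("empty tissue label in metadata")
        tbl = self.table.copy()
        if "subtissue" not in tbl.columns:
            tbl["subtissue"] = ""
        if "role" not in tbl.columns:
            tbl["role"] = "atlas"
        self.table = tbl

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    def tissues(self) -> list[str]:
        return self.table["tissue"].unique().tolist()

    def tissue_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "tissue"])

    def samples_for(self, tissue: str) -> list[str]:
        return self.table.index[self.table["tissue"] == tissue].tolist()

    def require_covers(self, m: ExpressionMatrix) -> None:
        missing = [s for s in m.sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing[:10]}")

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.reset_index()
        out = out.rename(columns={out.columns[0]: "sample_id"})
        out.to_csv(path, sep="\t", index=False)


@dataclass
class TissueExclusionConfig:
    """Which tissues to drop outright, and which sub-tissue labels to merge.

    ``merged_subtissues`` maps each original label to its merged label (e.g.
    both heart sub-tissues to plain ``heart``).  A tissue may not be both
    excluded and a merge target.
    """

    excluded_tissues: tuple[str, ...] = ()
    merged_subtissues: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.excluded_tissues) & set(self.merged_subtissues.values())
        if overlap:
            raise ValueError(f"tissues both excluded and merge targets: {sorted(overlap)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TissueExclusionConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(
            excluded_tissues=tuple(cfg.get("excluded_tissues", ())),
            merged_subtissues=dict(cfg.get("merged_subtissues", {})),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_matrix(path: str | Path, unit: str) -> ExpressionMatrix:
    """Read a delimited genes x samples table.

    First column holds gene IDs, header row holds sample IDs; tab or comma
    delimited (sniffed from the header line).  Duplicate IDs, empty cells,
    non-numeric cells and negative raw abundances are load errors.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.name is None and df.shape[1] == 0:
        raise ExpressionMatrixError(f"malformed header in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    bad = df.columns[df.columns.str.startswith("Unnamed:")].tolist()
    if bad:
        raise ExpressionMatrixError(f"malformed header: unnamed columns {bad}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ExpressionMatrixError(f"non-numeric cells in columns {non_numeric[:5]}")
    return ExpressionMatrix(df.astype(float), unit)


def write_matrix(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write the matrix back to delimited text (full float precision)."""
    out = m.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep, float_format="%.17g")


def load_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata table (sample_id, tissue[, subtissue][, role])."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "sample_id"})
    return SampleMetadata(df.set_index("sample_id"))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def apply_tissue_policy(
    m: ExpressionMatrix,
    meta: SampleMetadata,
    cfg: TissueExclusionConfig,
) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Drop excluded tissues and relabel merged sub-tissues.

    Sample order of the survivors is preserved and no retained value is
    touched.  Tissue labels in the config that never occur in the metadata
    trigger a warning, not an error.
    """
    meta.require_covers(m)
    known = set(meta.table["tissue"])
    for label in list(cfg.excluded_tissues) + list(cfg.merged_subtissues):
        if label not in known:
            warnings.warn(f"tissue label {label!r} not present in metadata", stacklevel=2)

    table = meta.table.copy()
    merge = dict(cfg.merged_subtissues)
    relabel = table["tissue"].map(lambda t: merge.get(t, t))
    table.loc[relabel != table["tissue"], "subtissue"] = table["tissue"]
    table["tissue"] = relabel

    keep_mask = ~table["tissue"].isin(set(cfg.excluded_tissues))
    table = table[keep_mask]
    keep_samples = [s for s in m.sample_ids if s in set(table.index)]
    return ExpressionMatrix(m.data[keep_samples], m.unit), SampleMetadata(table)


def filter_protein_coding(m: ExpressionMatrix, coding_ids: Iterable[str]) -> ExpressionMatrix:
    """Keep only genes in ``coding_ids`` (row order preserved)."""
    coding = set(coding_ids)
    if not coding:
        raise ValueError("coding_ids must be non-empty")
    keep = [g for g in m.gene_ids if g in coding]
    if not keep:
        raise ExpressionMatrixError("no genes left after protein-coding filter")
    return ExpressionMatrix(m.data.loc[keep], m.unit)


def prefilter_low_expression(
    m: ExpressionMatrix, quantile_method: str = "linear"
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove never/rarely expressed genes before panel selection.

    A gene is removed iff its maximum abundance across all samples is < 1,
    or its third quartile is < 1 on the raw scale (equivalently its third
    quartile is negative after the log2(x + 1) transform).  The quantile
    estimator defaults to linear interpolation between order statistics and
    is configurable because conventions differ between toolchains.
    """
    if not m.is_raw():
        raise ExpressionMatrixError("low-expression filter expects a raw-unit matrix")
    values = m.values
    max_ok = values.max(axis=1) >= 1.0
    q3 = np.quantile(values, 0.75, axis=1, method=quantile_method)
    q3_ok = q3 >= 1.0
    keep_mask = max_ok & q3_ok
    removed = [g for g, k in zip(m.gene_ids, keep_mask) if not k]
    kept = ExpressionMatrix(m.data.loc[keep_mask], m.unit)
    return kept, removed


def log2_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map every abundance x to log2(x + 1); the unit becomes ``LOG2P1``.

    Applying it to an already log-scale matrix is an error — silent double
    normalization is the classic way to wreck a similarity score.
    """
    if not m.is_raw():
        raise ExpressionMatrixError("matrix already log2-normalized")
    return ExpressionMatrix(np.log2(m.data + 1.0), LOG_UNIT)
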