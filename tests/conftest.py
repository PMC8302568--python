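import numpy as np
import pandas as pd
import pytest

from organsim.expression_io import ExpressionMatrix, SampleMetadata


def make_matrix(values, genes=None, samples=None, unit="TPM"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit)


def make_metadata(tissue_of):
    """tissue_of: dict sample_id -> tissue label."""
    return SampleMetadata(
        pd.DataFrame(
            {"tissue": list(tissue_of.values())},
            index=pd.Index(list(tissue_of.keys()), name="sample_id"),
        )
    )


def block_atlas(tissue_blocks, genes=None, unit="LOG2P1"):
    """Build (atlas, meta) from {tissue: 2-D array of genes x samples}."""
    arrays, samples, tissue_of = [], [], {}
    for tissue, block in tissue_blocks.items():
        block = np.asarray(block, dtype=float)
        arrays.append(block)
        for k in range(block.shape[1]):
            sid = f"{tissue}_{k}"
            samples.append(sid)
            tissue_of[sid] = tissue
    values = np.hstack(arrays)
    m = make_matrix(values, genes=genes, samples=samples, unit=unit)
    return m, make_metadata(tissue_of)


def random_small_atlas(rng, max_genes=20, max_tissues=5):
    """A small random log2-scale atlas for oracle comparisons."""
    n_genes = int(rng.integers(3, max_genes + 1))
    n_tissues = int(rng.integers(2, max_tissues + 1))
    blocks = {}
    for t in range(n_tissues):
        n_samples = int(rng.integers(2, 7))
        base = rng.normal(3.0, 1.0, size=(n_genes, 1))
        blocks[f"t{t}"] = np.abs(base + rng.normal(0, 0.8, size=(n_genes, n_samples)))
    return block_atlas(blocks)


@pytest.fixture
def small_atlas():
    """Deterministic 3-tissue atlas with one obviously organ-specific gene."""
    rng = np.random.default_rng(42)
    blocks = {
        "heart": np.abs(rng.normal(2.0, 0.3, size=(8, 5))),
        "lung": np.abs(rng.normal(2.0, 0.3, size=(8, 5))),
        "liver": np.abs(rng.normal(2.0, 0.3, size=(8, 5))),
    }
    blocks["heart"][0] += 6.0  # planted heart-specific gene g0
    return block_atlas(blocks)


@pytest.fixture
def toy_raw_matrix():
    return make_matrix([[0.0, 1.0], [3.0, 7.0], [15.0, 31.0]])
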