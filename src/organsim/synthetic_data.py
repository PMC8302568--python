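"""Synthetic multi-tissue atlases and differentiation trajectories.

Every stage of the pipeline is testable without external downloads by
simulating the statistical structure the selection steps assume:

* background expression is log-normal — each gene draws a baseline mean on
  the log2 scale and each sample adds independent Gaussian log2 noise;
* each tissue owns a disjoint block of "planted" genes whose log2 mean is
  shifted up by ``effect_delta`` in that tissue only, which is exactly the
  location-shift signal the t-test / CI / quantile filters target;
* differentiation trajectories interpolate linearly (in log2 space) between
  an undifferentiated profile and an organ profile, so the L1 similarity
  score of a noise-free trajectory point at mixing weight w is exactly
  100*w %.

Matrices are emitted in a raw unit (TPM) so they take the same
log2-normalization path as real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, SampleMetadata

__all__ = [
    "SyntheticAtlasSpec",
    "TrajectorySpec",
    "generate_atlas",
    "generate_undiff_reference",
    "generate_trajectory",
    "tissue_profile",
]


@dataclass(frozen=True)
class SyntheticAtlasSpec:
    """Generative parameters of a planted-gene multi-tissue atlas.

    Defaults describe a mid-sized recovery experiment: 6 tissues x 20
    samples, 2,000 genes of which 50 per tissue are planted with a +4 log2
    up-shift over a log-normal background (log2 baseline mean 3, sd 1.5)
    and 0.5 log2 units of per-sample noise.
    """

    n_tissues: int = 6
    samples_per_tissue: int = 20
    n_genes: int = 2000
    n_planted_per_organ: int = 50
    effect_delta: float = 4.0
    baseline_mu: float = 3.0
    baseline_sigma: float = 1.5
    noise_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tissues", "samples_per_tissue", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_planted_per_organ < 0:
            raise ValueError("n_planted_per_organ must be >= 0")
        if min(self.baseline_sigma, self.noise_sigma) < 0:
            raise ValueError("sigmas must be >= 0")
        if self.n_planted_per_organ * self.n_tissues > self.n_genes:
            raise ValueError("planted genes exceed the gene total")


@dataclass(frozen=True)
class TrajectorySpec:
    """A differentiation time course as mixing weights in [0, 1].

    Weight 0 is the undifferentiated profile, weight 1 the organ profile;
    intermediate stages (e.g. definitive endoderm, foregut, organoid)
    correspond to intermediate weights.  ``noise_sigma`` adds per-sample
    log2 noise around the interpolated profile.
    """

    mixing_weights: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.mixing_weights, dtype=float)
        if w.size == 0 or (w < 0).any() or (w > 1).any():
            raise ValueError("mixing weights must be a non-empty sequence in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _tissue_names(n: int) -> list[str]:
    return [f"tissue{i + 1:02d}" for i in range(n)]


def generate_atlas(
    spec: SyntheticAtlasSpec,
) -> tuple[ExpressionMatrix, SampleMetadata, dict[str, set[str]]]:
    """Simulate an atlas; returns (matrix in TPM, metadata, planted truth).

    Gene g in sample s has log2 expression ``mu_g + delta*[planted for s's
    tissue] + N(0, noise_sigma)`` with ``mu_g ~ N(baseline_mu,
    baseline_sigma)``; raw abundance is 2**log2value.  Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    tissues = _tissue_names(spec.n_tissues)
    mu = rng.normal(spec.baseline_mu, spec.baseline_sigma, size=spec.n_genes)

    planted_idx = rng.choice(
        spec.n_genes, size=spec.n_planted_per_organ * spec.n_tissues, replace=False
    )
    truth: dict[str, set[str]] = {}
    delta_col = {}
    for i, tissue in enumerate(tissues):
        idx = planted_idx[
            i * spec.n_planted_per_organ : (i + 1) * spec.n_planted_per_organ
        ]
        truth[tissue] = {genes[j] for j in idx}
        shift = np.zeros(spec.n_genes)
        shift[idx] = spec.effect_delta
        delta_col[tissue] = shift

    sample_ids, tissue_labels, columns = [], [], []
    for tissue in tissues:
        for k in range(spec.samples_per_tissue):
            log2val = (
                mu
                + delta_col[tissue]
                + rng.normal(0.0, spec.noise_sigma, size=spec.n_genes)
            )
            columns.append(np.exp2(log2val))
            sample_ids.append(f"{tissue}_s{k + 1:02d}")
            tissue_labels.append(tissue)

    data = pd.DataFrame(np.column_stack(columns), index=genes, columns=sample_ids)
    meta = SampleMetadata(
        pd.DataFrame({"tissue": tissue_labels}, index=pd.Index(sample_ids, name="sample_id"))
    )
    return ExpressionMatrix(data, "TPM"), meta, truth


def generate_undiff_reference(
    spec: SyntheticAtlasSpec, n_samples: int = 2, seed_offset: int = 1_000_000
) -> ExpressionMatrix:
    """Simulate undifferentiated reference samples (background only).

    Uses the same per-gene baselines as :func:`generate_atlas` under the
    same spec (the baseline draw is the first use of the generator), with no
    planted shift — an expression state carrying none of any organ's
    signature, as a pluripotent line would look under this model.
    """
    rng = np.random.default_rng(spec.seed)
    mu = rng.normal(spec.baseline_mu, spec.baseline_sigma, size=spec.n_genes)
    noise_rng = np.random.default_rng(spec.seed + seed_offset)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    cols = {
        f"undiff_s{k + 1:02d}": np.exp2(
            mu + noise_rng.normal(0.0, spec.noise_sigma, size=spec.n_genes)
        )
        for k in range(n_samples)
    }
    return ExpressionMatrix(pd.DataFrame(cols, index=genes), "TPM")


def tissue_profile(
    atlas: ExpressionMatrix, meta: SampleMetadata, tissue: str, stat: str = "mean"
) -> pd.Series:
    """Per-gene summary profile of one tissue on the atlas's current scale."""
    samples = meta.samples_for(tissue)
    if not samples:
        raise ValueError(f"no samples for tissue {tissue!r}")
    block = atlas.data[samples]
    if stat == "mean":
        return block.mean(axis=1)
    if stat == "median":
        return block.median(axis=1)
    if stat == "min":
        return block.min(axis=1)
    raise ValueError(f"unknown stat {stat!r}")


def generate_trajectory(
    organ_profile: pd.Series,
    undiff_profile: pd.Series,
    spec: TrajectorySpec,
) -> ExpressionMatrix:
    """Simulate query samples along an undifferentiated -> organ trajectory.

    Profiles are log2(x + 1)-scale per-gene vectors on a common gene set.
    Stage s with weight w has log2 value ``(1 - w)*undiff + w*organ +
    N(0, noise_sigma)``, floored at 0; emitted as raw TPM (2**v - 1) so the
    scoring path's log2(x + 1) recovers the interpolation exactly when the
    noise is 0.
    """
    if not organ_profile.index.equals(undiff_profile.index):
        raise ValueError("organ and undifferentiated profiles have different gene sets")
    rng = np.random.default_rng(spec.seed)
    u = undiff_profile.to_numpy(dtype=float)
    o = organ_profile.to_numpy(dtype=float)
    cols = {}
    for s, w in enumerate(spec.mixing_weights):
        log2val = (1.0 - w) * u + w * o
        if spec.noise_sigma > 0:
            log2val = log2val + rng.normal(0.0, spec.noise_sigma, size=u.size)
        log2val = np.maximum(log2val, 0.0)
        cols[f"step{s + 1:02d}_w{w:.2f}"] = np.exp2(log2val) - 1.0
    data = pd.DataFrame(cols, index=organ_profile.index)
    return ExpressionMatrix(data, "TPM")
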