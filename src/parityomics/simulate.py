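"""Synthetic-data generators for every pipeline stage.

Each generator draws from the statistical model its downstream analysis
assumes, with a planted-truth record sufficient to score recovery:

* dose-response transplant tables under the single-hit Poisson model;
* log2 expression with gene-wise variances from a scaled
  inverse-chi-square prior (so moderated-t shrinkage is exactly matched
  to the generative family) and a planted differentially expressed
  subset;
* expression built as site-counts x motif activities plus noise, for
  motif-activity recovery;
* two-population RGB images with an exactly known stained fraction.

One global seed is expanded into independent per-generator substreams,
so adding or re-running one generator never perturbs another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SiteCountMatrix
from .limiting_dilution import DilutionAssay

__all__ = [
    "SimulationConfig",
    "simulate_dilution_assay",
    "simulate_expression_dataset",
    "simulate_motif_dataset",
    "simulate_ihc_image",
]

# fixed substream ids: adding a stream must not renumber existing ones
_STREAMS = {
    "dilution": 1,
    "expression": 2,
    "motif": 3,
    "ihc": 4,
}


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the study conditions: three arrays per donor group,
    log2 expression with baseline ~ N(7, 2^2) and residual sd around
    0.22 (scaled inverse-chi-square prior d0=4, s0^2=0.05), 5% of genes
    shifted by +-1 log2 unit in the parous condition, sparse Poisson
    promoter site counts, and motif activities whose replicate spread
    (sd 0.25) is smaller than typical condition effects.
    """

    seed: int = 0
    n_genes: int = 5000
    n_samples_per_condition: int = 3
    n_motifs: int = 50
    de_fraction: float = 0.05
    de_log2_effect: float = 1.0
    variance_prior_df: float = 4.0
    variance_prior_scale: float = 0.05
    motif_site_rate: float = 0.5
    motif_activity_sd: float = 0.25
    expression_noise_sd: float = 0.5
    image_size: tuple[int, int] = (128, 128)
    positive_fraction: float = 0.25
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples_per_condition", "n_motifs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in ("de_fraction", "positive_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in (
            "variance_prior_df",
            "variance_prior_scale",
            "motif_activity_sd",
            "expression_noise_sd",
            "baseline_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.motif_site_rate < 0:
            raise ValueError("motif_site_rate must be nonnegative")
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image_size must be positive")


def _sample_names(n_per: int) -> tuple[list[str], pd.Series]:
    names = [f"virgin_{i + 1}" for i in range(n_per)] + [
        f"parous_{i + 1}" for i in range(n_per)
    ]
    cond = pd.Series(["virgin"] * n_per + ["parous"] * n_per, index=names)
    return names, cond


def simulate_dilution_assay(
    frequency: float,
    doses,
    n_per_dose,
    seed: int,
    group_label: str = "simulated",
) -> DilutionAssay:
    """Simulate transplant outcomes under the single-hit model.

    Each injection at dose d is positive independently with probability
    1 - exp(-frequency * d).
    """
    d = np.asarray(doses, dtype=float)
    n = np.asarray(n_per_dose, dtype=int)
    if frequency < 0:
        raise ValueError("frequency must be nonnegative")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")
    if d.size != n.size:
        raise ValueError("doses and n_per_dose must align")
    rng = _substream(seed, "dilution")
    p = 1.0 - np.exp(-frequency * d)
    r = rng.binomial(n, p)
    return DilutionAssay(
        doses=tuple(float(x) for x in d),
        n_injected=tuple(int(x) for x in n),
        n_positive=tuple(int(x) for x in r),
        group_label=group_label,
    )


def simulate_expression_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, dict]:
    """Log2 expression for two conditions with a planted DE subset.

    Gene-wise variances are drawn from the scaled inverse-chi-square
    prior (variance_prior_df, variance_prior_scale); a de_fraction
    subset of genes receives a +-de_log2_effect shift in the parous
    condition with random sign.  The truth record lists the planted
    genes and signs.
    """
    rng = _substream(config.seed, "expression")
    G, n_per = config.n_genes, config.n_samples_per_condition
    genes = [f"gene_{i:05d}" for i in range(G)]
    names, cond = _sample_names(n_per)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
    # scaled inverse-chi-square: s^2 = d0 * s0^2 / chi2(d0)
    d0, s0_sq = config.variance_prior_df, config.variance_prior_scale
    gene_var = d0 * s0_sq / rng.chisquare(d0, size=G)
    gene_sd = np.sqrt(gene_var)

    n_de = int(np.floor(config.de_fraction * G))
    if config.de_fraction > 0 and n_de < 1:
        warnings.warn(
            "de_fraction * n_genes < 1: no genes planted", RuntimeWarning, stacklevel=2
        )
    de_idx = rng.choice(G, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effect = np.zeros(G)
    effect[de_idx] = signs * config.de_log2_effect

    noise = rng.normal(0.0, 1.0, size=(G, 2 * n_per)) * gene_sd[:, None]
    values = baseline[:, None] + noise
    values[:, n_per:] += effect[:, None]

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=names), cond
    )
    truth = {
        "de_genes": {genes[i]: float(s) for i, s in zip(de_idx, signs)},
        "de_log2_effect": config.de_log2_effect,
        "gene_variances": dict(zip(genes, gene_var.tolist())),
        "variance_prior": {"df": d0, "scale": s0_sq},
    }
    return expr, truth


def simulate_motif_dataset(
    config: SimulationConfig,
    planted_activity_changes: dict[str, float] | None = None,
) -> tuple[ExpressionMatrix, SiteCountMatrix, dict]:
    """Expression generated as site-counts x motif activities + noise.

    Site counts are sparse Poisson(motif_site_rate) integers; motif
    activities are drawn per sample around condition means of 0
    (virgin) and the planted shift (parous); expression adds Gaussian
    noise and a gene baseline.  All-zero-site motifs are generated as
    drawn and flagged in the truth record.
    """
    planted = dict(planted_activity_changes or {})
    rng = _substream(config.seed, "motif")
    G, M, n_per = config.n_genes, config.n_motifs, config.n_samples_per_condition
    genes = [f"gene_{i:05d}" for i in range(G)]
    motifs = [f"motif_{j:03d}" for j in range(M)]
    unknown = set(planted) - set(motifs)
    if unknown:
        raise ValueError(f"planted changes for unknown motifs: {sorted(unknown)}")
    names, cond = _sample_names(n_per)

    sites = rng.poisson(config.motif_site_rate, size=(G, M)).astype(float)
    shift = np.array([planted.get(m, 0.0) for m in motifs])
    means = np.zeros((M, 2 * n_per))
    means[:, n_per:] = shift[:, None]
    activities = means + rng.normal(0.0, config.motif_activity_sd, size=(M, 2 * n_per))

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
    values = (
        sites @ activities
        + baseline[:, None]
        + rng.normal(0.0, config.expression_noise_sd, size=(G, 2 * n_per))
    )

    site_mat = SiteCountMatrix(pd.DataFrame(sites, index=genes, columns=motifs))
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=names), cond)
    truth = {
        "activities": pd.DataFrame(activities, index=motifs, columns=names),
        "planted_changes": {m: planted.get(m, 0.0) for m in motifs},
        "zero_site_motifs": site_mat.zero_motifs,
        "noise_sd": config.expression_noise_sd,
    }
    return expr, site_mat, truth


def simulate_ihc_image(
    config: SimulationConfig,
    positive_color_mean=(150.0, 80.0, 40.0),
    background_color_mean=(210.0, 205.0, 225.0),
    color_cov=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-color-population RGB image with an exactly known mask.

    Exactly floor(positive_fraction * H * W) pixels are drawn from the
    positive (stain-like) color Gaussian, the rest from background; the
    boolean truth mask is returned alongside the uint8 image.  Default
    colors mimic DAB brown on a light hematoxylin background.
    """
    if color_cov is None:
        color_cov = 25.0 * np.eye(3)
    cov = np.asarray(color_cov, dtype=float)
    if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
        raise ValueError("color_cov must be symmetric 3x3")
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("color_cov must be positive definite")
    for c in (positive_color_mean, background_color_mean):
        arr = np.asarray(c, dtype=float)
        if arr.shape != (3,) or arr.min() < 0 or arr.max() > 255:
            raise ValueError("color means must be RGB triples in [0, 255]")

    rng = _substream(config.seed, "ihc")
    h, w = config.image_size
    n_pix = h * w
    n_pos = int(np.floor(config.positive_fraction * n_pix))
    mask_flat = np.zeros(n_pix, dtype=bool)
    mask_flat[rng.choice(n_pix, size=n_pos, replace=False)] = True

    pixels = np.empty((n_pix, 3))
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal(size=(n_pix, 3))
    pixels[mask_flat] = np.asarray(positive_color_mean) + z[mask_flat] @ chol.T
    pixels[~mask_flat] = np.asarray(background_color_mean) + z[~mask_flat] @ chol.T
    image = np.clip(np.rint(pixels), 0, 255).astype(np.uint8).reshape(h, w, 3)
    return image, mask_flat.reshape(h, w)
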