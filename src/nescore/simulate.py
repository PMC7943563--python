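"""Seeded synthetic expression data with known neuroendocrine structure.

The generator emulates the statistical skeleton the analysis assumes: a
latent NE state s in [-1, 1] per sample; 50 signature genes blending two
anti-correlated centroids as ``(1+s)/2 * NE + (1-s)/2 * nonNE`` plus
Gaussian noise; an immune/interferon program whose expression decreases
with s; a REST-target program increasing with s; and neutral background
genes. Planted gene sets (IMMUNE_PROGRAM, REST_TARGETS, and a size-matched
RANDOM_K control drawn from the background) give the enrichment machinery
ground truth to recover. Everything is driven by one explicit seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .genesets import GeneSetCollection, write_gmt
from .matrix import ExpressionMatrix, write_expression
from .signature import GeneSignature, write_signature


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``immune_effect`` and ``rest_effect`` are slopes of the planted
    programs on the latent NE state (log2 units per unit state);
    ``noise_sd`` is the per-gene Gaussian noise sd in log2 units.
    """

    n_samples: int = 200
    n_signature_genes: int = 50
    n_immune_genes: int = 100
    n_rest_target_genes: int = 100
    n_background_genes: int = 750
    ne_state_distribution: str = "uniform"  # "uniform" | "two_group"
    pi_ne: float = 0.5  # NE fraction under two_group
    immune_effect: float = -2.0
    rest_effect: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_samples, self.n_signature_genes, self.n_immune_genes,
                  self.n_rest_target_genes, self.n_background_genes)
        if any(c <= 0 for c in counts):
            raise ValidationError("all counts must be positive")
        if self.n_signature_genes < 4:
            raise ValidationError("need at least 4 signature genes")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.immune_effect > 0:
            raise ValidationError("immune_effect must be <= 0")
        if self.rest_effect < 0:
            raise ValidationError("rest_effect must be >= 0")
        if self.ne_state_distribution not in ("uniform", "two_group"):
            raise ValidationError(f"unknown ne_state_distribution {self.ne_state_distribution!r}")
        if not 0 < self.pi_ne < 1:
            raise ValidationError("pi_ne must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Latent state and gene-program labels behind a synthetic dataset."""

    ne_state: pd.Series  # per sample
    gene_program: pd.Series  # per gene: signature_ne | signature_non_ne | immune | rest_target | background
    planted_sets: GeneSetCollection


@dataclass
class SyntheticDataset:
    expr: ExpressionMatrix
    truth: SyntheticTruth
    signature: GeneSignature
    sets: GeneSetCollection


def generate_signature(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    perfect_anticorrelation: bool = False,
) -> GeneSignature:
    """Draw a two-centroid signature with anti-correlated centroids.

    Centroids are log2-scale expression levels; the pair is
    rejection-sampled until their Pearson correlation is <= 0. With
    ``perfect_anticorrelation`` the non-NE centroid is the affine
    reflection of the NE centroid about its mean, making the correlation
    exactly -1 (useful for exercising the score's +/-1 extremes).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_signature_genes
    genes = tuple(f"SIG{i:03d}" for i in range(1, n + 1))
    ne = rng.normal(7.0, 1.5, size=n)
    if perfect_anticorrelation:
        non_ne = 2 * ne.mean() - ne
    else:
        non_ne = rng.normal(7.0, 1.5, size=n)
        while np.corrcoef(ne, non_ne)[0, 1] > 0:
            non_ne = rng.normal(7.0, 1.5, size=n)
    return GeneSignature(genes, ne, non_ne, name=f"synthetic (seed={config.seed})")


def _draw_states(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if config.ne_state_distribution == "uniform":
        return rng.uniform(-1.0, 1.0, size=config.n_samples)
    labels = rng.random(config.n_samples) < config.pi_ne
    centers = np.where(labels, 0.6, -0.6)
    return np.clip(centers + rng.normal(0.0, 0.2, size=config.n_samples), -1.0, 1.0)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate an expression matrix plus its ground truth, fully seeded."""
    rng = np.random.default_rng(config.seed)
    signature = generate_signature(config, rng=rng)
    s = _draw_states(config, rng)
    samples = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]

    immune = [f"IMM{i:03d}" for i in range(1, config.n_immune_genes + 1)]
    rest = [f"REST{i:03d}" for i in range(1, config.n_rest_target_genes + 1)]
    background = [f"BG{i:04d}" for i in range(1, config.n_background_genes + 1)]

    blocks, labels = [], []
    # signature genes: convex blend of the centroids along the latent state
    w_ne = (1.0 + s) / 2.0
    sig_mean = np.outer(signature.ne_centroid, w_ne) + np.outer(signature.non_ne_centroid, 1.0 - w_ne)
    blocks.append(sig_mean + rng.normal(0.0, config.noise_sd, size=sig_mean.shape))
    labels.extend(
        "signature_ne" if ne > non else "signature_non_ne"
        for ne, non in zip(signature.ne_centroid, signature.non_ne_centroid)
    )

    def program_block(genes: list[str], slope: float, label: str) -> None:
        baseline = np.clip(rng.normal(6.0, 1.5, size=len(genes)), 0.5, None)
        mean = baseline[:, None] + slope * s[None, :]
        blocks.append(mean + rng.normal(0.0, config.noise_sd, size=mean.shape))
        labels.extend([label] * len(genes))

    program_block(immune, config.immune_effect, "immune")
    program_block(rest, config.rest_effect, "rest_target")
    program_block(background, 0.0, "background")

    gene_ids = list(signature.gene_ids) + immune + rest + background
    values = pd.DataFrame(np.vstack(blocks), index=gene_ids, columns=samples)
    expr = ExpressionMatrix(values, scale="log2",
                            provenance=f"synthetic dataset (seed={config.seed})")

    random_k = sorted(rng.choice(background, size=min(config.n_immune_genes,
                                                      config.n_background_genes),
                                 replace=False).tolist())
    sets = GeneSetCollection(
        {"IMMUNE_PROGRAM": list(immune), "REST_TARGETS": list(rest), "RANDOM_K": random_k},
        source="planted",
    )
    truth = SyntheticTruth(
        ne_state=pd.Series(s, index=samples, name="ne_state"),
        gene_program=pd.Series(labels, index=gene_ids, name="program"),
        planted_sets=sets,
    )
    return SyntheticDataset(expr, truth, signature, sets)


def write_fixtures(dataset: SyntheticDataset, directory) -> dict[str, Path]:
    """Write expression, signature, planted sets and truth as plain text."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "signature": directory / "signature.tsv",
        "gene_sets": directory / "planted_sets.gmt",
        "truth": directory / "truth.tsv",
    }
    write_expression(dataset.expr, paths["expression"])
    write_signature(dataset.signature, paths["signature"])
    write_gmt(dataset.sets, paths["gene_sets"])
    truth = pd.DataFrame({"sample": dataset.truth.ne_state.index,
                          "ne_state": dataset.truth.ne_state.to_numpy()})
    truth.to_csv(paths["truth"], sep="\t", index=False)
    programs = directory / "gene_programs.tsv"
    dataset.truth.gene_program.rename_axis("gene").to_frame().to_csv(programs, sep="\t")
    paths["gene_programs"] = programs
    return paths
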