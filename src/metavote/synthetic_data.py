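"""Multi-study synthetic expression data with planted outcome signal.

The generator emulates the structure of a cross-platform microarray
meta-analysis: several studies measured on two or more "platforms" with
partially overlapping gene sets, a minority metastasis class, a subset of
genes carrying a consistent between-class mean shift in every study, and
per-gene linear platform distortions (multiplicative scale and additive
offset, fixed per gene within a platform).

Generative model, per study:

* baseline log-expression value ~ Normal(0, noise_sd) i.i.d. per gene and
  sample;
* planted genes receive an additive shift of ``effect_size * noise_sd`` in
  metastasis samples only (a standardized mean difference of
  ``effect_size``);
* the whole matrix is then distorted per gene as ``a_g * x + b_g`` with
  ``log a_g ~ Normal(0, platform_scale_sd)`` and
  ``b_g ~ Normal(0, platform_shift_sd)``, drawn once per (platform, gene).

Class counts are fixed by rounding (``round(metastasis_fraction *
samples_per_study)`` metastasis samples in every study), not sampled, so
downstream stratified procedures see identical class balance in every
replicate.  Planted genes always belong to the cross-platform shared gene
set, which guarantees the downstream pool-intersection step can recover
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ConfigurationError, ExpressionStudy, child_seed

DEFAULT_PLATFORMS = ("P1", "P2")


@dataclass
class SimulationConfig:
    """Conditions of a simulated multi-study collection.

    Defaults are the study conditions exercised throughout the test-bed:
    eight feature-definer studies of 60 samples on two platforms of 2000
    genes each, half of them shared, with 50 planted genes at a
    standardized effect of 1.0 and a 25% metastasis class.
    """

    n_studies: int = 8
    genes_per_platform: int = 2000
    shared_gene_fraction: float = 0.5
    n_planted: int = 50
    effect_size: float = 1.0
    samples_per_study: int = 60
    metastasis_fraction: float = 0.25
    platform_assignment: tuple[str, ...] | None = None
    platform_scale_sd: float = 0.25
    platform_shift_sd: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0

    def platforms(self) -> tuple[str, ...]:
        if self.platform_assignment is not None:
            return tuple(self.platform_assignment)
        cycle = DEFAULT_PLATFORMS
        return tuple(cycle[i % len(cycle)] for i in range(self.n_studies))

    @property
    def n_shared(self) -> int:
        return int(round(self.shared_gene_fraction * self.genes_per_platform))

    @property
    def n_metastasis(self) -> int:
        return int(round(self.metastasis_fraction * self.samples_per_study))

    def validate(self) -> None:
        if self.n_studies < 1:
            raise ConfigurationError("n_studies must be >= 1")
        if not (0 < self.shared_gene_fraction <= 1):
            raise ConfigurationError("shared_gene_fraction must be in (0, 1]")
        if self.n_planted < 0 or self.n_planted > self.genes_per_platform:
            raise ConfigurationError("n_planted must be in [0, genes_per_platform]")
        if self.n_planted > self.n_shared:
            raise ConfigurationError(
                "n_planted must not exceed the shared gene count "
                f"({self.n_shared}); planted genes live in the shared set"
            )
        if not (0 < self.metastasis_fraction <= 0.5):
            raise ConfigurationError("metastasis_fraction must be in (0, 0.5]")
        if self.n_metastasis < 2:
            raise ConfigurationError(
                "metastasis_fraction * samples_per_study must be >= 2 "
                "(both classes nonempty)"
            )
        if self.samples_per_study - self.n_metastasis < 2:
            raise ConfigurationError("non-metastasis class must have >= 2 samples")
        if self.platform_scale_sd < 0 or self.platform_shift_sd < 0:
            raise ConfigurationError("platform scale/shift sds must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.platform_assignment is not None and len(
            self.platform_assignment
        ) != self.n_studies:
            raise ConfigurationError(
                "platform_assignment length must equal n_studies"
            )


def _platform_gene_sets(config: SimulationConfig) -> dict[str, list[str]]:
    """Gene symbols per platform: a shared block plus platform-specific genes."""
    n_shared = config.n_shared
    shared = [f"GS{i:05d}" for i in range(n_shared)]
    n_specific = config.genes_per_platform - n_shared
    sets = {}
    for platform in dict.fromkeys(config.platforms()):
        specific = [f"G{platform}_{i:05d}" for i in range(n_specific)]
        sets[platform] = shared + specific
    return sets


def _platform_distortion(
    genes: list[str], scale_sd: float, shift_sd: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    a = np.exp(rng.normal(0.0, scale_sd, size=len(genes))) if scale_sd > 0 else np.ones(len(genes))
    b = rng.normal(0.0, shift_sd, size=len(genes)) if shift_sd > 0 else np.zeros(len(genes))
    return a, b


def simulate_multistudy(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], list[str]]:
    """Generate the configured studies plus the planted-gene ground truth.

    Returns
    -------
    (studies, planted_genes)
        ``studies`` has ``config.n_studies`` entries (role
        ``feature_definer``; callers assign experiment roles), each with its
        platform's full gene set.  ``planted_genes`` lists the symbols that
        carry the between-class mean shift (always shared across platforms).
    """
    config.validate()
    gene_sets = _platform_gene_sets(config)
    planted = [f"GS{i:05d}" for i in range(config.n_planted)]
    platforms = config.platforms()

    distortions = {
        platform: _platform_distortion(
            genes,
            config.platform_scale_sd,
            config.platform_shift_sd,
            child_seed(config.seed, "platform", platform),
        )
        for platform, genes in gene_sets.items()
    }

    n1 = config.n_metastasis
    n0 = config.samples_per_study - n1
    studies = []
    for s in range(config.n_studies):
        platform = platforms[s]
        genes = gene_sets[platform]
        rng = np.random.default_rng(child_seed(config.seed, "study", s))
        mat = rng.normal(0.0, config.noise_sd, size=(len(genes), config.samples_per_study))
        outcome = np.array([1] * n1 + [0] * n0)
        planted_idx = np.arange(config.n_planted)  # shared genes lead each set
        mat[np.ix_(planted_idx, np.where(outcome == 1)[0])] += (
            config.effect_size * config.noise_sd
        )
        a, b = distortions[platform]
        mat = a[:, None] * mat + b[:, None]
        study_id = f"study{s:02d}"
        samples = [f"{study_id}_s{i:03d}" for i in range(config.samples_per_study)]
        studies.append(
            ExpressionStudy(
                study_id=study_id,
                platform=platform,
                expression=pd.DataFrame(mat, index=genes, columns=samples),
                outcome=pd.Series(outcome, index=samples),
            )
        )
    return studies, planted


def apply_platform_effect(
    study: ExpressionStudy, scale_sd: float, shift_sd: float, seed: int
) -> ExpressionStudy:
    """Distort every gene linearly: ``x -> a_g * x + b_g``, fixed per gene.

    ``log a_g ~ Normal(0, scale_sd)`` and ``b_g ~ Normal(0, shift_sd)``.
    Outcome labels are unchanged.  With both sds zero this is the identity.
    """
    if scale_sd < 0 or shift_sd < 0:
        raise ConfigurationError("scale_sd and shift_sd must be >= 0")
    a, b = _platform_distortion(study.gene_ids, scale_sd, shift_sd, seed)
    distorted = study.expression.mul(a, axis=0).add(b, axis=0)
    return study.with_expression(distorted)
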