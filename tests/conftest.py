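"""Shared fixtures: tiny deterministic studies built in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metavote import ExpressionStudy, SimulationConfig, simulate_multistudy


def make_study(
    matrix,
    outcome,
    gene_ids=None,
    study_id="study",
    platform="P1",
    role="feature_definer",
) -> ExpressionStudy:
    """Build an ExpressionStudy from a plain array and 0/1 labels."""
    matrix = np.asarray(matrix, dtype=float)
    n_genes, n_samples = matrix.shape
    gene_ids = list(gene_ids) if gene_ids is not None else [
        f"g{i:03d}" for i in range(n_genes)
    ]
    samples = [f"{study_id}_s{i:03d}" for i in range(n_samples)]
    return ExpressionStudy(
        study_id=study_id,
        platform=platform,
        expression=pd.DataFrame(matrix, index=gene_ids, columns=samples),
        outcome=pd.Series(list(outcome), index=samples),
        role=role,
    )


def signal_study(
    seed: int,
    n_genes: int = 30,
    n_samples: int = 40,
    n_informative: int = 3,
    effect: float = 2.0,
    study_id: str = "sig",
) -> tuple[ExpressionStudy, list[str]]:
    """One study with the first ``n_informative`` genes carrying a shift."""
    rng = np.random.default_rng(seed)
    n1 = n_samples // 4
    y = np.array([1] * n1 + [0] * (n_samples - n1))
    X = rng.normal(size=(n_genes, n_samples))
    X[:n_informative, y == 1] += effect
    study = make_study(X, y, study_id=study_id)
    return study, study.gene_ids[:n_informative]


@pytest.fixture(scope="session")
def small_collection():
    """Four small simulated studies with five planted genes."""
    config = SimulationConfig(
        n_studies=4,
        genes_per_platform=100,
        shared_gene_fraction=0.5,
        n_planted=5,
        effect_size=1.5,
        samples_per_study=40,
        metastasis_fraction=0.25,
        seed=11,
    )
    studies, truth = simulate_multistudy(config)
    return config, studies, truth
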