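"""Per-gene standardization and cross-study gene matching.

Standardization is per gene within a study (each gene row to mean zero,
unit sample standard deviation), computed from that study's own samples —
training and test sets are standardized independently, mirroring a
protocol in which every dataset is normalized up front before any
transfer.  Gene matching restricts a collection of studies to a common,
identically ordered gene set so gene-wise features transfer across them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ExpressionStudy, InputError


def standardize(study: ExpressionStudy) -> ExpressionStudy:
    """Scale each gene row to mean 0 and sample sd 1 across samples.

    Constant genes map to all-zero rows.  Idempotent, and exactly removes
    any per-gene linear distortion ``x -> a*x + b`` (a > 0) applied before
    it.
    """
    if study.n_samples < 2:
        raise InputError(
            f"study {study.study_id}: >= 2 samples required to standardize"
        )
    X = study.expression.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    out = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return study.with_expression(
        pd.DataFrame(out, index=study.expression.index, columns=study.expression.columns)
    )


@dataclass
class GeneMatchedSet:
    """Studies restricted and row-reordered to a common gene list."""

    common_gene_ids: list[str]
    studies: list[ExpressionStudy]


def _collapse_duplicates(study: ExpressionStudy) -> ExpressionStudy:
    """Keep the highest-variance row per duplicated symbol (first on ties)."""
    if study.expression.index.is_unique:
        return study
    var = study.expression.var(axis=1, ddof=1)
    frame = study.expression.assign(_var=var.to_numpy())
    keep_pos = (
        frame.reset_index()
        .groupby(frame.index.name or "index", sort=False)["_var"]
        .idxmax()
        .sort_values()
    )
    collapsed = study.expression.iloc[keep_pos.to_numpy()]
    return study.with_expression(collapsed)


def match_genes(
    studies: list[ExpressionStudy], pool
) -> GeneMatchedSet:
    """Restrict every study to ``pool`` ∩ (genes present in all studies).

    Row order follows the pool order and is identical in every retained
    study.  Duplicate symbols within a study are collapsed to the
    highest-variance row first.
    """
    pool = list(pool)
    if not pool:
        raise InputError("gene pool is empty")
    studies = [_collapse_duplicates(s) for s in studies]
    common = set(studies[0].gene_ids)
    for s in studies[1:]:
        common &= set(s.gene_ids)
    kept = [g for g in pool if g in common]
    if not kept:
        raise InputError(
            "no pool gene is present in every study; supply a larger pool "
            "or fewer studies"
        )
    matched = [s.subset_genes(kept) for s in studies]
    return GeneMatchedSet(common_gene_ids=kept, studies=matched)
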