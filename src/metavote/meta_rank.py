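"""Cross-study rank-based feature selection.

Each gene is ranked within every study by its signed signal-to-noise
ratio ``(mean_1 - mean_0) / (sd_1 + sd_0)`` (rank 1 = most positive, i.e.
highest in the metastasis class), ranks are normalized to ``rank /
(n_genes + 1)`` so studies with different gene counts are comparable, and
the per-gene mean normalized rank across studies is tested for being
significantly high or low.

Significance is assessed by permutation: outcome labels are permuted
independently within each study, statistics re-ranked and mean normalized
ranks recomputed.  Because under permutation the mean normalized ranks of
all genes present in the same number of studies are exchangeable, the null
distribution is pooled across genes within each such stratum.  Pooling
gives the two-sided p-value a resolution of ``1 / (n_genes_in_stratum *
n_permutations)`` rather than ``1 / n_permutations`` — with a per-gene
null and practical permutation counts, no gene could ever clear a
Benjamini-Hochberg threshold in a several-thousand-gene screen.  When the
total number of distinct within-study label assignments is no larger than
the requested number of permutations, the null is enumerated exhaustively
and the p-values are exact.

Genes are declared selected at Benjamini-Hochberg q <= ``fdr_threshold``
(default 0.05).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import ConfigurationError, ExpressionStudy, InputError, child_seed

SD_FLOOR = 1e-8


def signal_to_noise(values_class1, values_class0) -> float:
    """Signed signal-to-noise ratio ``(m1 - m0) / (s1 + s0)``.

    Sample standard deviations (``ddof=1``); the denominator is floored at
    ``1e-8`` so degenerate constant genes do not divide by zero.  A
    positive value means higher expression in the metastasis class.
    """
    x1 = np.asarray(values_class1, dtype=float)
    x0 = np.asarray(values_class0, dtype=float)
    if x1.size < 2 or x0.size < 2:
        raise InputError("each class needs >= 2 values for signal-to-noise")
    denom = max(x1.std(ddof=1) + x0.std(ddof=1), SD_FLOOR)
    return float((x1.mean() - x0.mean()) / denom)


def _s2n_matrix(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Signal-to-noise per gene for many label vectors at once.

    X : (G, n) expression; labels : (n, B) of 0/1 columns.
    Returns (G, B).
    """
    labels = labels.astype(float)
    n1 = labels.sum(axis=0)
    n0 = labels.shape[0] - n1
    if (n1 < 2).any() or (n0 < 2).any():
        raise InputError("each class needs >= 2 samples")
    X2 = X * X
    s1 = X @ labels
    q1 = X2 @ labels
    s_tot = X.sum(axis=1, keepdims=True)
    q_tot = X2.sum(axis=1, keepdims=True)
    m1 = s1 / n1
    m0 = (s_tot - s1) / n0
    var1 = np.maximum(q1 - n1 * m1**2, 0.0) / (n1 - 1)
    var0 = np.maximum((q_tot - q1) - n0 * m0**2, 0.0) / (n0 - 1)
    denom = np.maximum(np.sqrt(var1) + np.sqrt(var0), SD_FLOOR)
    return (m1 - m0) / denom


def _lex_order(gene_ids) -> np.ndarray:
    """Lexicographic rank of each gene id (deterministic tie-break key)."""
    order = np.argsort(np.asarray(gene_ids, dtype=object))
    lex = np.empty(len(gene_ids), dtype=np.int64)
    lex[order] = np.arange(len(gene_ids))
    return lex


def _norm_ranks(s2n: np.ndarray, lex: np.ndarray) -> np.ndarray:
    """Normalized ranks per column: rank 1 = largest statistic.

    Ties are broken by lexicographic gene-id order.  Returns
    ``rank / (G + 1)`` in (0, 1), shape (G, B).
    """
    G, B = s2n.shape
    out = np.empty_like(s2n)
    ranks = np.empty(G, dtype=np.int64)
    for b in range(B):
        order = np.lexsort((lex, -s2n[:, b]))
        ranks[order] = np.arange(1, G + 1)
        out[:, b] = ranks / (G + 1)
    return out


@dataclass
class GeneRankTable:
    """Per-study signal-to-noise values and (normalized) ranks."""

    study_id: str
    table: pd.DataFrame  # index: gene_id; columns: s2n, rank, norm_rank


def rank_within_study(study: ExpressionStudy) -> GeneRankTable:
    """Rank every gene of one study by signed signal-to-noise ratio."""
    if not study.has_both_classes():
        raise InputError(f"study {study.study_id}: both classes required")
    study.require_unique_genes()
    X = study.expression.to_numpy(dtype=float)
    y = study.outcome.to_numpy()[:, None]
    s2n = _s2n_matrix(X, y)[:, 0]
    lex = _lex_order(study.gene_ids)
    norm = _norm_ranks(s2n[:, None], lex)[:, 0]
    n = len(s2n)
    table = pd.DataFrame(
        {
            "s2n": s2n,
            "rank": np.rint(norm * (n + 1)).astype(int),
            "norm_rank": norm,
        },
        index=pd.Index(study.gene_ids, name="gene_id"),
    )
    return GeneRankTable(study.study_id, table)


def mean_rank(
    tables: list[GeneRankTable], min_studies: int | None = None
) -> pd.Series:
    """Per-gene mean normalized rank over the studies containing the gene.

    Genes present in fewer than ``min_studies`` studies (default: all
    studies passed) are dropped.
    """
    if not tables:
        raise InputError("at least one GeneRankTable required")
    if min_studies is None:
        min_studies = len(tables)
    frames = pd.concat(
        [t.table["norm_rank"].rename(t.study_id) for t in tables], axis=1
    )
    counts = frames.notna().sum(axis=1)
    means = frames.mean(axis=1)
    return means[counts >= min_studies].sort_index()


def _exhaustive_label_sets(y: np.ndarray) -> np.ndarray:
    """All distinct 0/1 label vectors with y's class counts: (n, C)."""
    n = len(y)
    n1 = int(y.sum())
    cols = []
    for pos in itertools.combinations(range(n), n1):
        v = np.zeros(n, dtype=np.int64)
        v[list(pos)] = 1
        cols.append(v)
    return np.column_stack(cols)


def total_label_permutations(studies: list[ExpressionStudy]) -> int:
    """Number of distinct joint within-study label assignments."""
    total = 1
    for s in studies:
        y = s.outcome.to_numpy()
        total *= math.comb(len(y), int(y.sum()))
        if total > 10**9:
            return total
    return total


def mean_rank_significance(
    studies: list[ExpressionStudy],
    n_permutations: int = 1000,
    seed: int = 0,
    min_studies: int | None = None,
    fdr_threshold: float = 0.05,
    exhaustive: bool | str = "auto",
) -> pd.DataFrame:
    """Permutation test of per-gene mean normalized rank across studies.

    Two-sided: a gene is extreme if ``|mean_rank - 0.5|`` is at least the
    observed value under the within-study label-permutation null, pooled
    across genes with the same number of contributing studies.  Sampled
    p-values carry a plus-one correction; exhaustive p-values (used
    automatically when the joint permutation space is no larger than
    ``n_permutations``) are exact.

    Returns a DataFrame with one row per retained gene and columns
    ``n_studies, mean_normalized_rank, p_value, q_value, selected``.
    """
    if len(studies) < 2:
        raise InputError("at least two studies required")
    if n_permutations < 100:
        raise ConfigurationError("n_permutations must be >= 100")

    if min_studies is None:
        min_studies = len(studies)

    total = total_label_permutations(studies)
    if exhaustive == "auto":
        exhaustive = total <= n_permutations
    if exhaustive and total > 10**6:
        raise ConfigurationError(
            f"exhaustive enumeration over {total} label assignments is infeasible"
        )

    # Global gene index across studies.
    all_genes = sorted(set(g for s in studies for g in s.gene_ids))
    g_index = {g: i for i, g in enumerate(all_genes)}
    G = len(all_genes)

    per_study = []
    for s in studies:
        if not s.has_both_classes():
            raise InputError(f"study {s.study_id}: both classes required")
        s.require_unique_genes()
        X = s.expression.to_numpy(dtype=float)
        y = s.outcome.to_numpy()
        lex = _lex_order(s.gene_ids)
        idx = np.array([g_index[g] for g in s.gene_ids])
        per_study.append((X, y, lex, idx))

    counts = np.zeros(G, dtype=np.int64)
    obs_sum = np.zeros(G)
    for X, y, lex, idx in per_study:
        counts[idx] += 1
        obs_sum[idx] += _norm_ranks(_s2n_matrix(X, y[:, None]), lex)[:, 0]
    keep = counts >= min_studies
    obs_mean = np.full(G, np.nan)
    obs_mean[keep] = obs_sum[keep] / counts[keep]

    if exhaustive:
        # Enumerate the Cartesian product of per-study label assignments.
        study_norms = []
        sizes = []
        for X, y, lex, idx in per_study:
            L = _exhaustive_label_sets(y)
            study_norms.append(_norm_ranks(_s2n_matrix(X, L), lex))
            sizes.append(L.shape[1])
        B = int(np.prod(sizes))
        null_sum = np.zeros((G, B))
        for s_i, (norms, (X, y, lex, idx)) in enumerate(zip(study_norms, per_study)):
            reps_inner = int(np.prod(sizes[s_i + 1 :]))
            reps_outer = int(np.prod(sizes[:s_i]))
            tiled = np.tile(np.repeat(norms, reps_inner, axis=1), (1, reps_outer))
            null_sum[idx] += tiled
        plus_one = 0
    else:
        B = n_permutations
        null_sum = np.zeros((G, B))
        for s_i, (X, y, lex, idx) in enumerate(per_study):
            rng = np.random.default_rng(child_seed(seed, "perm", s_i))
            L = np.column_stack([rng.permutation(y) for _ in range(B)])
            null_sum[idx] += _norm_ranks(_s2n_matrix(X, L), lex)
        plus_one = 1

    null_mean = np.full((G, B), np.nan)
    null_mean[keep] = null_sum[keep] / counts[keep, None]

    obs_dev = np.abs(obs_mean - 0.5)
    null_dev = np.abs(null_mean - 0.5)

    p = np.full(G, np.nan)
    for k in np.unique(counts[keep]):
        stratum = keep & (counts == k)
        pool = np.sort(null_dev[stratum].ravel())
        n_pool = pool.size
        ge = n_pool - np.searchsorted(pool, obs_dev[stratum], side="left")
        p[stratum] = (plus_one + ge) / (plus_one + n_pool)

    genes = [g for g, k in zip(all_genes, keep) if k]
    pvals = p[keep]
    q = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "n_studies": counts[keep],
            "mean_normalized_rank": obs_mean[keep],
            "p_value": pvals,
            "q_value": q,
            "selected": q <= fdr_threshold,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return out.sort_values(
        ["mean_normalized_rank", "gene_id"], kind="mergesort"
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (thin statsmodels wrapper)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def intersect_pool(
    selected_genes, studies: list[ExpressionStudy]
) -> list[str]:
    """Selected genes present in every study, order preserved."""
    sets = [set(s.gene_ids) for s in studies]
    return [g for g in selected_genes if all(g in gs for gs in sets)]
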