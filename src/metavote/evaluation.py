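"""Balanced accuracy and the repeated downsampled binomial comparison test.

Balanced accuracy (bAcc) is the mean of sensitivity (true-positive rate on
the metastasis class) and specificity (true-negative rate), and is
insensitive to class imbalance.

Two classifiers are compared on an imbalanced test set with a five-step
repeated downsampled test: (1) randomly remove majority-class samples
until the classes are balanced; (2) count the discordant samples — those
correct under method A but not B (``a_only``) and vice versa (``b_only``);
(3) test the two counts for equality with a Pearson chi-square on 1 df
against an even split (a McNemar-style discordant-pair test without
continuity correction; an exact two-sided binomial option is available);
(4) store the p-value; repeat steps 1-3 (default 1000 times); (5) report
the median p-value across repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import InputError, PerformanceSummary


def performance(labels, preds) -> PerformanceSummary:
    """Sensitivity, specificity and balanced accuracy of hard predictions."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(preds, dtype=int)
    if y.shape != p.shape:
        raise InputError("labels and predictions must have equal length")
    pos = y == 1
    neg = y == 0
    if not pos.any() or not neg.any():
        raise InputError("both classes must be present (bAcc undefined otherwise)")
    sens = float((p[pos] == 1).mean())
    spec = float((p[neg] == 0).mean())
    return PerformanceSummary(
        sensitivity=sens,
        specificity=spec,
        bacc=(sens + spec) / 2.0,
        n_samples=int(y.size),
        n_positives=int(pos.sum()),
    )


def downsample_balance(labels, rng: np.random.Generator) -> np.ndarray:
    """Index subset with equal class counts.

    All minority-class samples are retained; majority-class samples are
    drawn uniformly without replacement.  Already-balanced input returns
    every index.  Indices come back sorted.
    """
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise InputError("both classes must be present to downsample")
    minority = 1 if n1 <= n0 else 0
    keep_min = np.where(y == minority)[0]
    maj_idx = np.where(y != minority)[0]
    keep_maj = rng.choice(maj_idx, size=keep_min.size, replace=False)
    return np.sort(np.concatenate([keep_min, keep_maj]))


def binom_chi2(a_only: int, b_only: int, exact: bool = False) -> float:
    """P-value for equality of two discordant counts.

    Default: Pearson chi-square with 1 df of the observed ``(a_only,
    b_only)`` against an even split of ``m = a_only + b_only`` (no
    continuity correction).  With ``exact=True``, the two-sided exact
    binomial test of ``a_only`` successes in ``m`` trials at rate 1/2.
    ``m = 0`` returns 1 by convention.
    """
    if a_only < 0 or b_only < 0:
        raise InputError("discordant counts must be nonnegative")
    m = a_only + b_only
    if m == 0:
        return 1.0
    if exact:
        return float(stats.binomtest(int(a_only), int(m), 0.5).pvalue)
    chi2 = (a_only - b_only) ** 2 / m
    return float(stats.chi2.sf(chi2, df=1))


@dataclass
class ComparisonResult:
    """Pairwise classifier comparison under repeated downsampling."""

    method_a: str
    method_b: str
    n_reps: int
    per_rep: pd.DataFrame  # columns: a_only, b_only, p_value
    median_p: float


def compare_methods(
    labels,
    preds_a,
    preds_b,
    n_reps: int = 1000,
    seed: int = 0,
    exact: bool = False,
    method_a: str = "A",
    method_b: str = "B",
) -> ComparisonResult:
    """Repeated downsampled discordant-count test between two classifiers.

    Per repetition a balanced subset is drawn, the discordant counts on it
    computed and tested; the median p-value over ``n_reps`` repetitions is
    the reported statistic (for an even number of repetitions, the mean of
    the two central order statistics).  Deterministic given ``seed``, and
    symmetric: swapping the two prediction vectors leaves the median p
    unchanged for the same seed.
    """
    y = np.asarray(labels, dtype=int)
    pa = np.asarray(preds_a, dtype=int)
    pb = np.asarray(preds_b, dtype=int)
    if not (y.shape == pa.shape == pb.shape):
        raise InputError("labels and both prediction vectors must have equal length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise InputError("both classes must be present")

    a_only = ((pa == y) & (pb != y)).astype(np.int64)
    b_only = ((pb == y) & (pa != y)).astype(np.int64)

    minority = 1 if n1 <= n0 else 0
    min_idx = np.where(y == minority)[0]
    maj_idx = np.where(y != minority)[0]
    n_min, n_maj = min_idx.size, maj_idx.size

    rng = np.random.default_rng(seed)
    if n_maj == n_min:
        sampled_a = np.full(n_reps, a_only[maj_idx].sum())
        sampled_b = np.full(n_reps, b_only[maj_idx].sum())
    else:
        # Uniform without-replacement subsets, one row per repetition.
        keys = rng.random((n_reps, n_maj))
        pick = np.argsort(keys, axis=1)[:, :n_min]
        sampled_a = a_only[maj_idx][pick].sum(axis=1)
        sampled_b = b_only[maj_idx][pick].sum(axis=1)
    tot_a = a_only[min_idx].sum() + sampled_a
    tot_b = b_only[min_idx].sum() + sampled_b

    m = tot_a + tot_b
    if exact:
        p = np.array(
            [binom_chi2(int(a), int(b), exact=True) for a, b in zip(tot_a, tot_b)]
        )
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = np.where(m > 0, (tot_a - tot_b) ** 2 / np.maximum(m, 1), 0.0)
        p = np.where(m > 0, stats.chi2.sf(chi2, df=1), 1.0)

    per_rep = pd.DataFrame({"a_only": tot_a, "b_only": tot_b, "p_value": p})
    return ComparisonResult(
        method_a=method_a,
        method_b=method_b,
        n_reps=n_reps,
        per_rep=per_rep,
        median_p=float(np.median(p)),
    )
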