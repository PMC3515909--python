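"""Shared domain containers.

The central object is :class:`ExpressionStudy`: one study's log-scale
gene-expression matrix (genes x samples) together with a binary outcome
label per sample (1 = metastasis, 0 = no metastasis), a platform tag and
the role the study plays in a cross-study experiment (feature definer,
training set or independent test set).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ROLES = ("feature_definer", "train", "test")


class ConfigurationError(ValueError):
    """An invalid configuration value, named explicitly in the message."""


class InputError(ValueError):
    """Input data violates a precondition of an operation."""


@dataclass
class ExpressionStudy:
    """One study: genes x samples log-expression with binary outcome labels.

    Parameters
    ----------
    study_id : str
        Unique study identifier.
    platform : str
        Platform tag (e.g. a microarray family); studies on the same
        platform share a gene set.
    expression : pandas.DataFrame
        Genes as rows (index = gene symbols, unique), samples as columns.
        Values are on a log scale.
    outcome : pandas.Series
        Binary outcome per sample, indexed like ``expression.columns``;
        1 marks the metastasis (minority) class.
    role : str
        One of ``feature_definer``, ``train``, ``test``.
    """

    study_id: str
    platform: str
    expression: pd.DataFrame
    outcome: pd.Series
    role: str = "feature_definer"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(
                f"role must be one of {ROLES}, got {self.role!r}"
            )
        if list(self.expression.columns) != list(self.outcome.index):
            raise InputError(
                f"study {self.study_id}: outcome index must match sample columns"
            )
        if self.outcome.isna().any():
            raise InputError(f"study {self.study_id}: missing outcome labels")
        bad = set(np.unique(self.outcome.to_numpy())) - {0, 1}
        if bad:
            raise InputError(
                f"study {self.study_id}: outcome labels must be 0/1, found {sorted(bad)}"
            )
        self.outcome = self.outcome.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    def require_unique_genes(self) -> None:
        """Raise unless gene symbols are unique (duplicate probes collapsed)."""
        if not self.expression.index.is_unique:
            dup = self.expression.index[self.expression.index.duplicated()][:3]
            raise InputError(
                f"study {self.study_id}: duplicate gene symbols {list(dup)}; "
                "collapse duplicates first (see preprocessing.match_genes)"
            )

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    def has_both_classes(self) -> bool:
        y = self.outcome.to_numpy()
        return bool((y == 1).any() and (y == 0).any())

    def class_values(self, gene: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (metastasis values, non-metastasis values) for one gene."""
        row = self.expression.loc[gene].to_numpy(dtype=float)
        y = self.outcome.to_numpy()
        return row[y == 1], row[y == 0]

    def with_expression(self, expression: pd.DataFrame, **kw) -> "ExpressionStudy":
        """Copy of this study with a new expression matrix (labels kept)."""
        return replace(self, expression=expression, **kw)

    def subset_genes(self, genes) -> "ExpressionStudy":
        missing = [g for g in genes if g not in self.expression.index]
        if missing:
            raise InputError(
                f"study {self.study_id}: missing genes {missing[:5]}"
            )
        return self.with_expression(self.expression.loc[list(genes)])


@dataclass
class PerformanceSummary:
    """Sensitivity/specificity/balanced accuracy on a binary task.

    ``bacc`` is exactly ``(sensitivity + specificity) / 2``; sensitivity is
    the true-positive rate on the metastasis class (label 1), specificity
    the true-negative rate on the non-metastasis class (label 0).
    """

    sensitivity: float
    specificity: float
    bacc: float
    n_samples: int
    n_positives: int

    def __post_init__(self) -> None:
        expected = (self.sensitivity + self.specificity) / 2.0
        if abs(self.bacc - expected) > 1e-12:
            raise InputError("bacc must equal (sensitivity + specificity)/2")

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "bacc": self.bacc,
            "n_samples": self.n_samples,
            "n_positives": self.n_positives,
        }


def child_seed(seed: int, *tags) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a master seed and tags.

    String tags are folded in through CRC32 so the derivation is stable
    across processes and platforms.
    """
    import zlib

    entropy = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        if isinstance(t, str):
            entropy.append(zlib.crc32(t.encode("utf8")))
        else:
            entropy.append(int(t) & 0x7FFFFFFF)
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % (2**31))
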