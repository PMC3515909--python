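"""Two-level majority-voting meta-classifier over seven base methods.

Internally (cross-validated) each sample holds 10 votes per method — one
per repetition of 10x10 CV, ordered by repetition index.  Per method the
votes are consolidated by majority of the FIRST NINE votes (nine is odd,
so no ties; the tenth vote is deliberately ignored).  The consolidated
per-method labels, one per each of the seven methods, are then combined by
simple majority (seven is odd, again tie-free).  Externally each method
casts a single vote per sample and only the seven-voter majority applies.

Voting operates on hard labels only; no probability averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import InputError

METHOD_NAMES = ("RF", "LR", "R-SVM", "L-SVM", "P-SVM", "S-SVM", "NNET")


def consolidate_method_votes(votes) -> int:
    """Majority label among the first nine of ten ordered CV votes."""
    v = np.asarray(list(votes), dtype=int)
    if v.size != 10:
        raise InputError(f"exactly 10 votes required, got {v.size}")
    return int(v[:9].sum() * 2 > 9)


def cross_method_vote(labels) -> int:
    """Majority label over the seven per-method votes."""
    v = np.asarray(list(labels), dtype=int)
    if v.size != 7:
        raise InputError(f"exactly 7 method votes required, got {v.size}")
    return int(v.sum() * 2 > 7)


@dataclass
class VoteTable:
    """Per-sample class votes.

    ``mode='internal'``: ``frame`` has columns (sample_id, method, repeat,
    label) with exactly 10 rows per (sample, method).  ``mode='external'``:
    columns (sample_id, method, label) with exactly one row per pair.  The
    method set must be exactly the seven base methods.
    """

    mode: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.mode not in ("internal", "external"):
            raise InputError("mode must be 'internal' or 'external'")
        methods = set(self.frame["method"].unique())
        if methods != set(METHOD_NAMES):
            missing = set(METHOD_NAMES) - methods
            extra = methods - set(METHOD_NAMES)
            raise InputError(
                f"vote table must cover exactly the 7 methods; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        counts = self.frame.groupby(["sample_id", "method"]).size()
        expect = 10 if self.mode == "internal" else 1
        if (counts != expect).any():
            raise InputError(
                f"{self.mode} mode requires exactly {expect} vote(s) per "
                "(sample, method)"
            )


def internal_vote_table(method_votes: dict[str, pd.DataFrame]) -> VoteTable:
    """Build an internal VoteTable from per-method vote matrices.

    ``method_votes[name]`` is a samples x 10 DataFrame (columns = CV
    repetition index 0..9) as produced by ``model_building.cv10x10``.
    """
    rows = []
    for method, votes in method_votes.items():
        long = votes.stack().rename("label").reset_index()
        long.columns = ["sample_id", "repeat", "label"]
        long["method"] = method
        rows.append(long[["sample_id", "method", "repeat", "label"]])
    return VoteTable("internal", pd.concat(rows, ignore_index=True))


def external_vote_table(method_preds: dict[str, pd.Series]) -> VoteTable:
    """Build an external VoteTable from one prediction Series per method."""
    rows = []
    for method, preds in method_preds.items():
        long = preds.rename("label").rename_axis("sample_id").reset_index()
        long["method"] = method
        rows.append(long[["sample_id", "method", "label"]])
    return VoteTable("external", pd.concat(rows, ignore_index=True))


def consolidate_internal(table: VoteTable) -> pd.DataFrame:
    """Per-(sample, method) consolidated label from the first nine votes.

    Returns a samples x methods DataFrame of 0/1 labels.
    """
    if table.mode != "internal":
        raise InputError("internal vote table required")
    frame = table.frame.sort_values(["sample_id", "method", "repeat"])
    cons = (
        frame.groupby(["sample_id", "method"], sort=True)["label"]
        .apply(lambda v: consolidate_method_votes(v.to_numpy()))
        .unstack("method")
    )
    return cons[list(METHOD_NAMES)]


def vote_classify(table: VoteTable) -> pd.Series:
    """Final per-sample label of the voting meta-classifier.

    Internal mode consolidates each method's 10 CV votes to one label
    (majority of the first nine) and then takes the seven-method majority;
    external mode takes the seven-method majority directly.
    """
    if table.mode == "internal":
        per_method = consolidate_internal(table)
    else:
        per_method = table.frame.pivot(
            index="sample_id", columns="method", values="label"
        )[list(METHOD_NAMES)]
    sample_order = table.frame["sample_id"].drop_duplicates()
    per_method = per_method.reindex(sample_order)
    return per_method.apply(
        lambda row: cross_method_vote(row.to_numpy()), axis=1
    ).rename("label")
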