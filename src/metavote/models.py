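"""Model/Results interfaces over the functional pipeline.

Two model classes front the package in the estimator/results idiom:

* :class:`MetaRankModel` — built from a list of studies; ``fit()`` runs
  the cross-study rank meta-analysis and returns
  :class:`MetaRankResults` with the per-gene table, the selected genes
  and a ``summary()``.
* :class:`VotingEnsemble` — built from one training study and a gene
  pool; ``fit()`` runs importance ranking plus forward model building for
  all seven methods and returns :class:`VotingEnsembleResults`, which
  carries the fitted per-method models, their CV diagnostics, internal
  voting labels, ``predict()`` for external studies, ``summary()`` and a
  performance bar plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import meta_rank, model_building, voting
from .evaluation import performance
from .model_building import FittedModel, MethodSpec, default_method_specs
from .types import ExpressionStudy, InputError, PerformanceSummary
from .voting import METHOD_NAMES


class MetaRankModel:
    """Cross-study rank meta-analysis of gene/outcome association.

    Parameters
    ----------
    studies : list of ExpressionStudy
        The feature-definer studies.  Each must contain both outcome
        classes.

    Examples
    --------
    >>> from metavote import MetaRankModel, SimulationConfig, simulate_multistudy
    >>> studies, truth = simulate_multistudy(SimulationConfig(
    ...     n_studies=4, genes_per_platform=100, n_planted=5,
    ...     effect_size=1.5, seed=7))
    >>> res = MetaRankModel(studies).fit(n_permutations=200, seed=1)
    >>> bool(set(truth) <= set(res.table.index))
    True
    """

    def __init__(self, studies: list[ExpressionStudy]):
        if len(studies) < 2:
            raise InputError("MetaRankModel requires at least two studies")
        self.studies = list(studies)

    def fit(
        self,
        n_permutations: int = 1000,
        seed: int = 0,
        min_studies: int | None = None,
        fdr_threshold: float = 0.05,
    ) -> "MetaRankResults":
        table = meta_rank.mean_rank_significance(
            self.studies,
            n_permutations=n_permutations,
            seed=seed,
            min_studies=min_studies,
            fdr_threshold=fdr_threshold,
        )
        return MetaRankResults(self, table, fdr_threshold)


@dataclass
class MetaRankResults:
    """Per-gene mean normalized ranks with permutation significance."""

    model: MetaRankModel
    table: pd.DataFrame
    fdr_threshold: float

    @property
    def selected_genes(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def pool(self, studies: list[ExpressionStudy]) -> list[str]:
        """Selected genes shared by every study in ``studies``."""
        return meta_rank.intersect_pool(self.selected_genes, studies)

    def summary(self, top: int = 10) -> str:
        t = self.table
        lines = [
            "Cross-study rank meta-analysis",
            "==============================",
            f"studies:            {len(self.model.studies)}",
            f"genes tested:       {len(t)}",
            f"selected (q<={self.fdr_threshold:g}): {int(t['selected'].sum())}",
            "",
            f"Top {min(top, len(t))} genes by extremity of mean normalized rank:",
        ]
        dev = (t["mean_normalized_rank"] - 0.5).abs()
        head = t.loc[dev.sort_values(ascending=False).index[:top]]
        lines.append(head.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


class VotingEnsemble:
    """Seven-method voting classifier built from one training study.

    Parameters
    ----------
    train : ExpressionStudy
        Standardized training study (use ``preprocessing.standardize``).
    pool : list of str
        Candidate genes (e.g. from :meth:`MetaRankResults.pool`).
    method_specs : list of MethodSpec, optional
        Defaults to the seven methods with paper-scale grids; pass
        ``default_method_specs(reduced=True)`` for fast runs.
    mode : {'paper', 'clean'}
        Feature-ranking leakage regime for the CV estimates.
    """

    def __init__(
        self,
        train: ExpressionStudy,
        pool,
        method_specs: list[MethodSpec] | None = None,
        mode: str = "paper",
    ):
        self.train = train
        self.pool = list(pool)
        self.method_specs = method_specs or default_method_specs()
        self.mode = mode

    def fit(
        self,
        seed: int = 0,
        max_features: int = 40,
        ranking_trees: int = 300,
        ranking_repeats: int = 5,
    ) -> "VotingEnsembleResults":
        from .types import child_seed

        ranked = model_building.importance_rank(
            self.train,
            self.pool,
            seed=child_seed(seed, "rank"),
            n_trees=ranking_trees,
            n_repeats=ranking_repeats,
        )
        models = {
            spec.name: model_building.forward_select(
                self.train,
                spec,
                ranked,
                seed=child_seed(seed, spec.name),
                max_features=max_features,
                mode=self.mode,
            )
            for spec in self.method_specs
        }
        return VotingEnsembleResults(self, models, ranked, seed)


@dataclass
class VotingEnsembleResults:
    """Fitted per-method models plus the internal voting diagnostics."""

    model: VotingEnsemble
    models: dict[str, FittedModel]
    importance_ranking: list[str] = field(default_factory=list)
    seed: int = 0

    @property
    def cv_votes(self) -> voting.VoteTable:
        return voting.internal_vote_table(
            {name: m.cv_votes for name, m in self.models.items()}
        )

    @property
    def consolidated_labels(self) -> pd.DataFrame:
        """Samples x methods consolidated CV labels (first-nine majority)."""
        return voting.consolidate_internal(self.cv_votes)

    @property
    def internal_vote_labels(self) -> pd.Series:
        return voting.vote_classify(self.cv_votes)

    def internal_performance(self) -> pd.DataFrame:
        """Consolidated CV performance per method and for Voting."""
        labels = self.model.train.outcome
        per_method = self.consolidated_labels
        rows = []
        for name in METHOD_NAMES:
            perf = performance(labels.loc[per_method.index], per_method[name])
            rows.append({"method": name, **perf.as_dict()})
        vote = self.internal_vote_labels
        perf = performance(labels.loc[vote.index], vote)
        rows.append({"method": "Voting", **perf.as_dict()})
        return pd.DataFrame(rows)

    def predict(self, study: ExpressionStudy) -> pd.DataFrame:
        """Per-method external labels plus the seven-voter majority.

        Returns a samples x 8 DataFrame (seven methods and ``Voting``).
        """
        per_method = pd.DataFrame(
            {name: self.models[name].predict(study) for name in METHOD_NAMES}
        )
        table = voting.external_vote_table(
            {name: per_method[name] for name in METHOD_NAMES}
        )
        out = per_method.copy()
        out["Voting"] = voting.vote_classify(table)
        return out

    def summary(self) -> str:
        perf = self.internal_performance()
        lines = [
            "Voting ensemble (7 methods + majority vote)",
            "===========================================",
            f"training study:   {self.model.train.study_id} "
            f"(n={self.model.train.n_samples}, "
            f"metastasis={int(self.model.train.outcome.sum())})",
            f"gene pool:        {len(self.model.pool)} genes, "
            f"mode={self.model.mode!r}",
            "",
            "Selected features and hyperparameters:",
        ]
        for name in METHOD_NAMES:
            m = self.models[name]
            hp = ", ".join(f"{k}={v}" for k, v in sorted(m.hyperparams.items()))
            lines.append(
                f"  {name:<6} k={len(m.features):<3} [{hp or 'no grid'}]"
            )
        lines += ["", "Consolidated 10x10 CV performance:"]
        lines.append(
            perf.to_string(index=False, float_format=lambda v: f"{v:.3f}")
        )
        return "\n".join(lines)

    def plot_performance(self, ax=None):
        """Bar plot of consolidated CV balanced accuracy per method."""
        import matplotlib.pyplot as plt

        perf = self.internal_performance()
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3.5))
        ax.bar(perf["method"], perf["bacc"], color="#4878a8")
        ax.axhline(0.5, color="grey", lw=0.8, ls="--")
        ax.set_ylabel("balanced accuracy")
        ax.set_ylim(0, 1)
        ax.set_title(f"Internal 10x10 CV, study {self.model.train.study_id}")
        return ax
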