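"""End-to-end re-enactment of the three classifier-comparison experiments.

Three validation regimes are run on synthetic multi-study data:

* ``internal`` — every training study is evaluated by 10x10 CV; each
  method's consolidated CV label per sample and the two-level voting label
  are scored and all pairs of the 8 voters (7 methods + Voting) compared;
* ``external-same`` — models trained on one study classify independent
  test studies drawn from the same platform regime;
* ``external-cross`` — the same training study is passed through a
  per-gene linear platform distortion before training, emulating the
  residual cross-platform shift that survives per-gene standardization,
  and the resulting models classify the (undistorted) test studies.

The pipeline per experiment: simulate studies -> rank-based cross-study
feature selection on the feature-definer studies -> intersect the
selected genes with the train/test gene sets -> per-gene standardization
-> RF importance ranking -> forward model building per method -> voting
-> performance and pairwise comparison reports.

A single master seed is split into named sub-seeds (simulate / rank / cv /
compare) so stages can be re-run independently with identical results;
the whole pipeline is deterministic given the master seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import meta_rank, model_building, preprocessing, voting
from .evaluation import compare_methods, performance
from .model_building import FittedModel, MethodSpec, default_method_specs
from .synthetic_data import SimulationConfig, apply_platform_effect, simulate_multistudy
from .types import ConfigurationError, ExpressionStudy, InputError, child_seed
from .voting import METHOD_NAMES

EXPERIMENTS = ("internal", "external-same", "external-cross")
REPORT_METHOD_ORDER = METHOD_NAMES + ("Voting",)


@dataclass
class ExperimentConfig:
    """Everything needed to run one experiment deterministically."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_train: int = 2
    n_test: int = 2
    fdr_threshold: float = 0.05
    min_studies: int | None = None
    n_permutations: int = 200
    method_specs: list[MethodSpec] | None = None
    mode: str = "paper"
    max_features: int = 40
    ranking_trees: int = 300
    ranking_repeats: int = 5
    n_reps_compare: int = 1000
    cross_scale_sd: float = 0.5
    cross_shift_sd: float = 1.0
    seed: int = 0

    def specs(self) -> list[MethodSpec]:
        return self.method_specs or default_method_specs()

    def validate(self) -> None:
        if self.n_train < 1 or self.n_train > self.simulation.n_studies:
            raise ConfigurationError("n_train must be in [1, n_studies]")
        if self.n_test < 1:
            raise ConfigurationError("n_test must be >= 1")
        names = [s.name for s in self.specs()]
        if sorted(names) != sorted(METHOD_NAMES):
            raise ConfigurationError(
                f"method_specs must cover exactly the 7 methods, got {names}"
            )

    def sub_seed(self, *tags) -> int:
        return child_seed(self.seed, *tags)


@dataclass
class ExperimentResult:
    """Machine-readable twin of the per-experiment report tables."""

    experiment: str
    performance: pd.DataFrame  # study, method, sensitivity, specificity, bacc, ...
    mean_performance: pd.DataFrame  # method, sensitivity, specificity, bacc
    comparisons: pd.DataFrame  # method_a, method_b, median_p
    pool: list[str]
    truth_genes: list[str]
    models: dict

    def method_bacc(self, method: str) -> float:
        row = self.mean_performance[self.mean_performance["method"] == method]
        return float(row["bacc"].iloc[0])


def reenactment_config(seed: int = 0) -> ExperimentConfig:
    """Scaled-down study conditions for the three-experiment re-enactment.

    Eight feature-definer studies (the first two doubling as training
    sets) of 40 samples on two 150-gene platforms sharing half their
    genes, 15 planted genes at a standardized effect of 1.5, a 25%
    metastasis class, reduced hyperparameter grids (25-tree forests) and
    at most four features per model.  These sizes keep a full multi-seed
    re-enactment tractable on a single CPU while preserving the
    protocol's ensemble diversity: models with several features are what
    make the seven voters disagree informatively.
    """
    specs = default_method_specs(reduced=True)
    specs = [
        MethodSpec("RF", {"ntree": (25,), "mtry": ("sqrt",)}) if s.name == "RF" else s
        for s in specs
    ]
    return ExperimentConfig(
        simulation=SimulationConfig(
            n_studies=8,
            genes_per_platform=150,
            shared_gene_fraction=0.5,
            n_planted=15,
            effect_size=1.5,
            samples_per_study=40,
            metastasis_fraction=0.25,
        ),
        n_train=2,
        n_test=2,
        n_permutations=100,
        method_specs=specs,
        max_features=4,
        ranking_trees=150,
        ranking_repeats=5,
        seed=seed,
    )


def prepare_studies(
    config: ExperimentConfig,
) -> tuple[list[ExpressionStudy], list[str]]:
    """Simulate feature-definer, training and test studies with roles.

    The first ``n_train`` simulated studies double as training sets (they
    remain feature definers, as in the original design); ``n_test`` extra
    studies are appended as independent test sets on the first training
    study's platform.
    """
    config.validate()
    n_def = config.simulation.n_studies
    base_platforms = list(config.simulation.platforms())
    platforms = base_platforms + [base_platforms[0]] * config.n_test
    sim = dataclasses.replace(
        config.simulation,
        n_studies=n_def + config.n_test,
        platform_assignment=tuple(platforms),
        seed=config.sub_seed("simulate"),
    )
    studies, truth = simulate_multistudy(sim)
    for i, s in enumerate(studies):
        if i < config.n_train:
            s.role = "train"
        elif i < n_def:
            s.role = "feature_definer"
        else:
            s.role = "test"
    return studies, truth


def build_pool(
    config: ExperimentConfig, studies: list[ExpressionStudy]
) -> tuple[list[str], pd.DataFrame]:
    """Rank-significant genes intersected with the train/test gene sets."""
    definers = [s for s in studies if s.role in ("feature_definer", "train")]
    table = meta_rank.mean_rank_significance(
        definers,
        n_permutations=config.n_permutations,
        seed=config.sub_seed("rank"),
        min_studies=config.min_studies,
        fdr_threshold=config.fdr_threshold,
    )
    selected = list(table.index[table["selected"]])
    downstream = [s for s in studies if s.role in ("train", "test")]
    pool = meta_rank.intersect_pool(selected, downstream)
    if not pool:
        raise InputError(
            "no rank-significant gene is shared by all train/test studies; "
            "weaker signal or a higher FDR threshold is needed"
        )
    return pool, table


def _train_all_methods(
    config: ExperimentConfig, train: ExpressionStudy, pool: list[str]
) -> dict[str, FittedModel]:
    ranked = model_building.importance_rank(
        train,
        pool,
        seed=config.sub_seed("cv", train.study_id, "rank"),
        n_trees=config.ranking_trees,
        n_repeats=config.ranking_repeats,
    )
    return {
        spec.name: model_building.forward_select(
            train,
            spec,
            ranked,
            seed=config.sub_seed("cv", train.study_id, spec.name),
            max_features=config.max_features,
            mode=config.mode,
        )
        for spec in config.specs()
    }


def _consolidated_labels(models: dict[str, FittedModel]) -> pd.DataFrame:
    """Samples x methods consolidated CV labels (majority of first nine)."""
    table = voting.internal_vote_table(
        {name: m.cv_votes for name, m in models.items()}
    )
    return voting.consolidate_internal(table)


def _performance_rows(
    study_id: str, labels: pd.Series, per_method: pd.DataFrame, vote: pd.Series
) -> list[dict]:
    rows = []
    for method in REPORT_METHOD_ORDER:
        preds = vote if method == "Voting" else per_method[method]
        perf = performance(labels.loc[preds.index], preds)
        rows.append({"study": study_id, "method": method, **perf.as_dict()})
    return rows


def _mean_performance(per_study: pd.DataFrame) -> pd.DataFrame:
    mean = (
        per_study.groupby("method", sort=False)[
            ["sensitivity", "specificity", "bacc"]
        ]
        .mean()
        .reindex(list(REPORT_METHOD_ORDER))
        .reset_index()
    )
    return mean


def _all_pairs_comparisons(
    config: ExperimentConfig, labels: pd.Series, voter_labels: pd.DataFrame
) -> pd.DataFrame:
    """Pairwise repeated-downsampled comparisons over all 8 voters."""
    voters = list(voter_labels.columns)
    rows = []
    for i, a in enumerate(voters):
        for b in voters[i + 1 :]:
            res = compare_methods(
                labels.to_numpy(),
                voter_labels[a].to_numpy(),
                voter_labels[b].to_numpy(),
                n_reps=config.n_reps_compare,
                seed=config.sub_seed("compare", a, b),
                method_a=a,
                method_b=b,
            )
            rows.append({"method_a": a, "method_b": b, "median_p": res.median_p})
    return pd.DataFrame(rows)


def _prepared_pipeline(config: ExperimentConfig):
    """Shared front end: simulate, select, match, standardize."""
    studies, truth = prepare_studies(config)
    pool, _ = build_pool(config, studies)
    trains = [s for s in studies if s.role == "train"]
    tests = [s for s in studies if s.role == "test"]
    matched = preprocessing.match_genes(trains + tests, pool).studies
    trains_std = [preprocessing.standardize(s) for s in matched[: len(trains)]]
    tests_std = [preprocessing.standardize(s) for s in matched[len(trains) :]]
    return truth, pool, trains_std, tests_std


def _distorted(config: ExperimentConfig, train_std: ExpressionStudy) -> ExpressionStudy:
    return apply_platform_effect(
        train_std,
        config.cross_scale_sd,
        config.cross_shift_sd,
        config.sub_seed("simulate", "cross-distortion"),
    )


def _internal_result(
    config: ExperimentConfig,
    trains_std: list[ExpressionStudy],
    models_by_study: dict[str, dict[str, FittedModel]],
    pool: list[str],
    truth: list[str],
) -> ExperimentResult:
    rows: list[dict] = []
    pooled_labels = []
    pooled_votes = []
    for train in trains_std:
        models = models_by_study[train.study_id]
        per_method = _consolidated_labels(models)
        vote = voting.vote_classify(
            voting.internal_vote_table({n: m.cv_votes for n, m in models.items()})
        )
        labels = train.outcome
        rows.extend(_performance_rows(train.study_id, labels, per_method, vote))
        voters = per_method.copy()
        voters["Voting"] = vote
        pooled_labels.append(labels)
        pooled_votes.append(voters)

    per_study = pd.DataFrame(rows)
    comparisons = _all_pairs_comparisons(
        config, pd.concat(pooled_labels), pd.concat(pooled_votes)
    )
    return ExperimentResult(
        "internal", per_study, _mean_performance(per_study), comparisons,
        pool, truth, models_by_study,
    )


def _external_result(
    config: ExperimentConfig,
    name: str,
    models: dict[str, FittedModel],
    tests_std: list[ExpressionStudy],
    pool: list[str],
    truth: list[str],
    train_study_id: str,
) -> ExperimentResult:
    rows: list[dict] = []
    pooled_labels = []
    pooled_votes = []
    for test in tests_std:
        per_method = pd.DataFrame(
            {name_: m.predict(test) for name_, m in models.items()}
        )[list(METHOD_NAMES)]
        vote = voting.vote_classify(
            voting.external_vote_table(
                {name_: per_method[name_] for name_ in METHOD_NAMES}
            )
        )
        labels = test.outcome
        rows.extend(_performance_rows(test.study_id, labels, per_method, vote))
        voters = per_method.copy()
        voters["Voting"] = vote
        pooled_labels.append(labels)
        pooled_votes.append(voters)

    per_study = pd.DataFrame(rows)
    comparisons = _all_pairs_comparisons(
        config, pd.concat(pooled_labels), pd.concat(pooled_votes)
    )
    return ExperimentResult(
        name, per_study, _mean_performance(per_study), comparisons,
        pool, truth, {train_study_id: models},
    )


def run_internal(config: ExperimentConfig) -> ExperimentResult:
    """Internal 10x10 CV comparison on every training study.

    Per training study, each method's consolidated CV label per sample and
    the internal two-level voting label are scored; the mean over training
    studies is reported, and all 28 voter pairs are compared on the pooled
    samples of the training studies.
    """
    truth, pool, trains_std, _ = _prepared_pipeline(config)
    models_by_study = {
        t.study_id: _train_all_methods(config, t, pool) for t in trains_std
    }
    return _internal_result(config, trains_std, models_by_study, pool, truth)


def run_external(config: ExperimentConfig, same_platform: bool = True) -> ExperimentResult:
    """External validation of models from one training study.

    ``same_platform=True`` trains on the standardized training study and
    classifies the standardized test studies.  ``same_platform=False``
    additionally passes the standardized training study through
    ``apply_platform_effect`` (scale/shift sds from the config) before
    training, without re-standardizing — the injected distortion models
    what normalization fails to remove between platforms.  With both sds
    zero the two regimes are identical.
    """
    truth, pool, trains_std, tests_std = _prepared_pipeline(config)
    train_std = trains_std[0]
    if not same_platform:
        train_std = _distorted(config, train_std)
    models = _train_all_methods(config, train_std, pool)
    name = "external-same" if same_platform else "external-cross"
    return _external_result(
        config, name, models, tests_std, pool, truth, train_std.study_id
    )


def run_all(config: ExperimentConfig) -> dict[str, ExperimentResult]:
    """All three regimes with shared simulation, selection and training.

    The internal regime and the same-platform external regime train
    identical models for the first training study (same data, same derived
    seeds), so those models are fit once; only the cross-platform regime
    needs an extra fit on the distorted training study.  Results are
    identical to calling :func:`run_internal` / :func:`run_external`
    separately.
    """
    truth, pool, trains_std, tests_std = _prepared_pipeline(config)
    models_by_study = {
        t.study_id: _train_all_methods(config, t, pool) for t in trains_std
    }
    train0 = trains_std[0]
    distorted = _distorted(config, train0)
    cross_models = _train_all_methods(config, distorted, pool)
    return {
        "internal": _internal_result(config, trains_std, models_by_study, pool, truth),
        "external-same": _external_result(
            config, "external-same", models_by_study[train0.study_id],
            tests_std, pool, truth, train0.study_id,
        ),
        "external-cross": _external_result(
            config, "external-cross", cross_models, tests_std, pool, truth,
            train0.study_id,
        ),
    }


def run_experiment(
    config: ExperimentConfig, experiment: str, out_dir: str | Path | None = None
) -> ExperimentResult:
    """Run one named experiment; optionally write its report TSVs.

    Reports: ``performance.tsv`` (study, method, sensitivity, specificity,
    bacc, n_samples, n_positives), ``mean_performance.tsv``,
    ``comparisons.tsv`` (method_a, method_b, median_p), ``pool.txt`` and
    ``truth_genes.txt``.  Two runs with the same config and master seed
    produce byte-identical files.
    """
    if experiment == "internal":
        result = run_internal(config)
    elif experiment == "external-same":
        result = run_external(config, same_platform=True)
    elif experiment == "external-cross":
        result = run_external(config, same_platform=False)
    else:
        raise ConfigurationError(
            f"unknown experiment {experiment!r}; choose from {EXPERIMENTS}"
        )
    if out_dir is not None:
        write_reports(result, out_dir)
    return result


def write_reports(result: ExperimentResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    order = {m: i for i, m in enumerate(REPORT_METHOD_ORDER)}
    perf = result.performance.copy()
    perf["_ord"] = perf["method"].map(order)
    perf = perf.sort_values(["study", "_ord"], kind="mergesort").drop(columns="_ord")
    perf.to_csv(out / "performance.tsv", sep="\t", index=False, float_format="%.10g")
    result.mean_performance.to_csv(
        out / "mean_performance.tsv", sep="\t", index=False, float_format="%.10g"
    )
    result.comparisons.to_csv(
        out / "comparisons.tsv", sep="\t", index=False, float_format="%.10g"
    )
    (out / "pool.txt").write_text("\n".join(result.pool) + "\n")
    (out / "truth_genes.txt").write_text("\n".join(result.truth_genes) + "\n")
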