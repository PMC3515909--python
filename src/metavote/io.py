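"""Plain-text serialization of studies, vote tables and predictions.

One study is a pair of TSV files: an expression table (genes as rows,
header = sample ids) and a phenotype sidecar (sample_id, outcome).  A
collection is tied together by ``manifest.tsv`` (study_id, platform, role,
expression, phenotype) plus ``truth_genes.txt`` when the collection is
simulated.  Serialization is byte-stable: identical studies write
identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .types import ExpressionStudy, InputError

FLOAT_FMT = "%.10g"


def write_study(study: ExpressionStudy, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr_path = out / f"{study.study_id}_expression.tsv"
    pheno_path = out / f"{study.study_id}_phenotype.tsv"
    study.expression.rename_axis("gene_id").to_csv(
        expr_path, sep="\t", float_format=FLOAT_FMT
    )
    study.outcome.rename("outcome").rename_axis("sample_id").to_csv(
        pheno_path, sep="\t"
    )
    return {
        "study_id": study.study_id,
        "platform": study.platform,
        "role": study.role,
        "expression": expr_path.name,
        "phenotype": pheno_path.name,
    }


def write_studies(
    studies: list[ExpressionStudy],
    out_dir: str | Path,
    truth_genes: list[str] | None = None,
) -> Path:
    """Write every study plus manifest.tsv (and truth_genes.txt if given)."""
    out = Path(out_dir)
    rows = [write_study(s, out) for s in studies]
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    if truth_genes is not None:
        (out / "truth_genes.txt").write_text("\n".join(truth_genes) + "\n")
    return manifest


def read_study(
    expr_path: str | Path, pheno_path: str | Path, study_id: str, platform: str, role: str
) -> ExpressionStudy:
    expression = pd.read_csv(expr_path, sep="\t", index_col=0)
    pheno = pd.read_csv(pheno_path, sep="\t", index_col=0)
    if "outcome" not in pheno.columns:
        raise InputError(f"{pheno_path}: phenotype file needs an 'outcome' column")
    outcome = pheno["outcome"].reindex(expression.columns)
    return ExpressionStudy(
        study_id=study_id,
        platform=platform,
        expression=expression,
        outcome=outcome,
        role=role,
    )


def read_manifest(manifest_path: str | Path) -> list[ExpressionStudy]:
    """Load every study listed in a manifest.tsv."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    studies = []
    for _, row in manifest.iterrows():
        studies.append(
            read_study(
                base / row["expression"],
                base / row["phenotype"],
                study_id=str(row["study_id"]),
                platform=str(row["platform"]),
                role=str(row["role"]),
            )
        )
    return studies


def write_predictions(preds: pd.Series, path: str | Path) -> None:
    preds.rename("label").rename_axis("sample_id").to_csv(path, sep="\t")


def read_predictions(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame["label"].astype(int)


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
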