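"""Readers and writers: expression matrices, label tables, archive and
cross-validation reports, and the plain-text classifier record.

Matrices are stored features-as-rows (one identifier column, one column per
sample), the orientation of public expression deposits, and transposed to
samples × features internally. Delimiters (tab or comma) are sniffed.
The classifier record is a single JSON object holding the expression
string, ordered class labels, thresholds at full precision, and boundary
flags; parsing reconstructs a structurally identical classifier.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .crossval import CVResult
from .datasets import LabeledDataset
from .evolution import Classifier, FitnessRecord
from .expressions import parse_tree, tree_to_string, validate_tree
from .rules import MulticlassRule

__all__ = [
    "load_dataset",
    "save_dataset",
    "save_archive",
    "save_cv_report",
    "serialize_classifier",
    "parse_classifier",
]


def _read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=index_col)


def load_dataset(matrix_path, labels_path) -> LabeledDataset:
    """Load a features × samples matrix and a (sample, class) label table.

    Samples are matched by identifier and ordered as in the label file.
    Raises informative errors for unknown samples, duplicate feature names,
    and non-numeric cells.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    frame = _read_table(matrix_path, index_col=0)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(
            f"{matrix_path}: duplicate feature names: {dupes[:5]}"
        )
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{matrix_path}: non-numeric value {frame.loc[row, col]!r} "
                f"at feature {row!r}, sample column {col!r}"
            )
        frame[col] = converted
    if frame.isna().any().any():
        raise ValueError(f"{matrix_path}: missing values are not supported")

    labels_frame = pd.read_csv(labels_path, sep=None, engine="python", header=None)
    if labels_frame.shape[1] < 2:
        raise ValueError(
            f"{labels_path}: expected two columns (sample, class), "
            f"got {labels_frame.shape[1]}"
        )
    matrix_samples = [str(c) for c in frame.columns]
    # accept files with or without a header row: a first cell that is not a
    # known sample identifier is taken to be a header
    if str(labels_frame.iloc[0, 0]) not in set(matrix_samples):
        labels_frame = labels_frame.iloc[1:]
    sample_ids = [str(s) for s in labels_frame.iloc[:, 0]]
    classes = [str(c) for c in labels_frame.iloc[:, 1]]
    unknown = [s for s in sample_ids if s not in set(matrix_samples)]
    if unknown:
        raise ValueError(
            f"{labels_path}: samples absent from the matrix: {unknown[:5]}"
        )
    ordered = frame[sample_ids]  # label-file order wins
    return LabeledDataset(
        matrix=ordered.to_numpy(dtype=float).T,
        feature_names=[str(f) for f in frame.index],
        labels=classes,
        sample_ids=sample_ids,
    )


def save_dataset(dataset: LabeledDataset, matrix_path, labels_path) -> None:
    """Write the matrix (features as rows) and label table as TSV."""
    frame = pd.DataFrame(
        dataset.matrix.T, index=dataset.feature_names, columns=dataset.sample_ids
    )
    frame.index.name = "feature"
    frame.to_csv(matrix_path, sep="\t")
    labels = pd.DataFrame(
        {"sample": dataset.sample_ids, "class": dataset.labels}
    )
    labels.to_csv(labels_path, sep="\t", index=False)


def save_archive(members: Iterable[Classifier], path) -> None:
    """Archive TSV: expression, accuracy, complexity, selected features."""
    rows = [
        {
            "expression": m.expression,
            "accuracy": m.fitness.accuracy,
            "complexity": m.fitness.complexity,
            "features": ";".join(sorted(m.feature_set)),
        }
        for m in members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_cv_report(result: CVResult, path, algorithm: str = "CES") -> None:
    """Cross-validation TSV: one detail row per fold plus a summary row
    with the protocol's table columns (accuracy, Tanimoto distance, number
    of selected genes)."""
    rows = []
    for rec in result.records:
        rows.append(
            {
                "row": "fold",
                "algorithm": algorithm,
                "rep": rec.rep,
                "fold": rec.fold,
                "accuracy": rec.accuracy,
                "tanimoto_distance": "",
                "n_selected_genes": len(rec.features),
                "features": ";".join(sorted(rec.features)),
            }
        )
    rows.append(
        {
            "row": "summary",
            "algorithm": algorithm,
            "rep": "",
            "fold": "",
            "accuracy": result.mean_accuracy,
            "tanimoto_distance": result.tanimoto_stability,
            "n_selected_genes": result.mean_n_features,
            "features": "",
        }
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def serialize_classifier(clf: Classifier) -> str:
    """One-line JSON record; thresholds survive at full precision because
    JSON floats use the shortest round-tripping decimal form."""
    record = {
        "expression": tree_to_string(clf.tree),
        "classes": list(clf.rule.ordered_classes),
        "thresholds": [float(t) for t in clf.rule.thresholds],
        "strict_flags": list(clf.rule.strict_flags),
        "accuracy": clf.fitness.accuracy,
        "complexity": clf.fitness.complexity,
    }
    return json.dumps(record)


def parse_classifier(text: str) -> Classifier:
    """Inverse of :func:`serialize_classifier`."""
    record = json.loads(text)
    tree = parse_tree(record["expression"])
    validate_tree(tree)
    rule = MulticlassRule(
        ordered_classes=tuple(record["classes"]),
        thresholds=tuple(record["thresholds"]),
        strict_flags=tuple(record["strict_flags"]),
    )
    return Classifier(
        tree=tree,
        rule=rule,
        fitness=FitnessRecord(
            accuracy=float(record["accuracy"]),
            complexity=int(record["complexity"]),
        ),
    )
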