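"""Delimited-text interchange formats.

All matrices travel as tab-separated text with a label header row/column and
``#``-prefixed header comments recording units and producing parameters.
Connectivity matrices are small (<= 268 x 268), so plain text keeps every
artifact diffable and self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cpm import TrainedCpmModel
from .flow import InformationFlowMatrix
from .panel import GroupScheme, TimeSeriesPanel
from .te import TEMatrix

__all__ = [
    "read_timeseries_panel",
    "write_timeseries_panel",
    "read_group_scheme",
    "write_group_scheme",
    "read_matrix",
    "write_matrix",
    "write_te_matrix",
    "read_te_matrix",
    "write_if_matrix",
    "read_if_matrix",
    "read_behavior",
    "write_behavior",
    "save_model",
    "load_model",
]


def _read_table(path) -> tuple[dict, list[list[str]], list[int]]:
    """Split a file into header comments and tab-separated rows with line numbers."""
    comments: dict[str, str] = {}
    rows: list[list[str]] = []
    linenos: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    comments[key.strip()] = val.strip()
                continue
            rows.append(line.split("\t"))
            linenos.append(lineno)
    return comments, rows, linenos


def _comment_block(comments: dict | None) -> str:
    if not comments:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in comments.items())


def write_timeseries_panel(path, panel: TimeSeriesPanel, comments: dict | None = None):
    """Panel file: nodes as rows, first column node id, header row of timepoints."""
    comments = dict(comments or {})
    comments.setdefault("subject_id", panel.subject_id)
    comments.setdefault("condition", panel.condition)
    with open(path, "w") as fh:
        fh.write(_comment_block(comments))
        fh.write("node_id\t" + "\t".join(str(t) for t in range(panel.n_timepoints)) + "\n")
        for node, row in zip(panel.node_ids, panel.data):
            fh.write(node + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_timeseries_panel(path, subject_id: str | None = None) -> TimeSeriesPanel:
    """Read a panel file, validating rectangularity, finiteness and node ids."""
    comments, rows, linenos = _read_table(path)
    if len(rows) < 2:
        raise ValueError(f"{path}: expected a header row and at least 2 node rows")
    header, data_rows = rows[0], rows[1:]
    width = len(header)
    node_ids: list[str] = []
    data = []
    for row, lineno in zip(data_rows, linenos[1:]):
        if len(row) != width:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(row)} fields, expected {width})"
            )
        node = row[0]
        if node in node_ids:
            raise ValueError(f"{path}:{lineno}: duplicate node id {node!r}")
        node_ids.append(node)
        try:
            data.append([float(v) for v in row[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    arr = np.asarray(data)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: non-finite values in panel")
    return TimeSeriesPanel(
        subject_id=subject_id or comments.get("subject_id", Path(path).stem),
        data=arr,
        node_ids=node_ids,
        condition=comments.get("condition", "other"),
    )


def write_group_scheme(path, table: pd.DataFrame):
    table.to_csv(path, sep="\t", index=False)


def read_group_scheme(path) -> GroupScheme:
    """Read a (node_id, hemisphere, lobe) table into a canonical GroupScheme."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return GroupScheme.from_table(table)


def write_matrix(path, values, labels, comments: dict | None = None):
    """Square labeled matrix as TSV with a header row and label column."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write(_comment_block(comments))
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, values):
            fh.write(lab + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix(path) -> tuple[np.ndarray, list[str], dict]:
    comments, rows, linenos = _read_table(path)
    if not rows:
        raise ValueError(f"{path}: empty matrix file")
    col_labels = rows[0][1:]
    row_labels = []
    data = []
    for row, lineno in zip(rows[1:], linenos[1:]):
        if len(row) != len(col_labels) + 1:
            raise ValueError(f"{path}:{lineno}: ragged row")
        row_labels.append(row[0])
        data.append([float(v) for v in row[1:]])
    if row_labels != col_labels:
        raise ValueError(f"{path}: row and column labels differ")
    return np.asarray(data), row_labels, comments


def write_te_matrix(path, te: TEMatrix, extra: dict | None = None):
    comments = {
        "kind": "te_sparse" if te.sparse else "te_full",
        "units": te.units,
        **(extra or {}),
    }
    write_matrix(path, te.values, te.node_ids, comments)


def read_te_matrix(path) -> TEMatrix:
    values, labels, comments = read_matrix(path)
    return TEMatrix(
        values=values,
        node_ids=labels,
        sparse=comments.get("kind") == "te_sparse",
        units=comments.get("units", "bits"),
    )


def write_if_matrix(path, ifm: InformationFlowMatrix, extra: dict | None = None):
    comments = {"kind": f"if_{ifm.variant}", "units": "bits", **(extra or {})}
    write_matrix(path, ifm.values, ifm.labels, comments)


def read_if_matrix(path) -> InformationFlowMatrix:
    values, labels, comments = read_matrix(path)
    variant = comments.get("kind", "if_full_unrestricted").removeprefix("if_")
    return InformationFlowMatrix(values=values, labels=labels, variant=variant)


def write_behavior(path, subject_ids, scores, comments: dict | None = None):
    with open(path, "w") as fh:
        fh.write(_comment_block(comments))
        fh.write("subject_id\tscore\n")
        for sid, sc in zip(subject_ids, scores):
            fh.write(f"{sid}\t{sc:.17g}\n")


def read_behavior(path) -> tuple[list[str], np.ndarray]:
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"subject_id": str})
    if "subject_id" not in table.columns or "score" not in table.columns:
        raise ValueError(f"{path}: behavior table needs subject_id and score columns")
    return table["subject_id"].tolist(), table["score"].to_numpy(dtype=float)


def save_model(path, model: TrainedCpmModel, extra: dict | None = None):
    payload = {"format": "infoflow-cpm-model/1", **(extra or {}), "model": model.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path) -> TrainedCpmModel:
    with open(path) as fh:
        payload = json.load(fh)
    return TrainedCpmModel.from_dict(payload["model"])
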