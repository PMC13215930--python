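"""Readers and writers for the pipeline's plain-text formats.

CSV is UTF-8, comma-separated, "." decimal; factor ids are F-prefixed in all
files. Every writer/reader pair round-trips (write∘read = identity); malformed
rows raise with their line number. Sets are serialized as sorted ascending
lists — range abbreviations like "4–7" appear only in transcribed source
tables, never in emitted files.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .anp import Judgment
from .ism import RELATION_CODES

__all__ = [
    "factor_sort_key",
    "read_relations_csv",
    "write_relations_csv",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_sets_json",
    "write_sets_json",
    "read_judgments_json",
    "write_judgments_json",
    "write_weight_table_csv",
    "write_factor_sets_csv",
    "write_levels_csv",
]


def factor_sort_key(factor_id: str):
    """Natural sort key: F2 before F10; non F-number ids sort lexically."""
    m = re.fullmatch(r"([A-Za-z]+)(\d+)", factor_id)
    return (m.group(1), int(m.group(2))) if m else (factor_id, -1)


def read_relations_csv(path) -> list[tuple[str, str, str]]:
    """Read relation rows (source_factor, target_factor, code V|A|X|O)."""
    out: list[tuple[str, str, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"source_factor", "target_factor", "code"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: header must contain columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            line = reader.line_num
            src, tgt, code = (
                (row["source_factor"] or "").strip(),
                (row["target_factor"] or "").strip(),
                (row["code"] or "").strip().upper(),
            )
            if not src or not tgt:
                raise ValueError(f"{path}:{line}: empty factor id")
            if code not in RELATION_CODES:
                raise ValueError(
                    f"{path}:{line}: invalid relation code {code!r} "
                    f"(expected one of {'/'.join(RELATION_CODES)})"
                )
            out.append((src, tgt, code))
    return out


def write_relations_csv(relations: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_factor", "target_factor", "code"])
        writer.writerows(relations)


def read_matrix_csv(path, binary: bool = True) -> pd.DataFrame:
    """Read a labelled square matrix (header row + index column of ids)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column factor ids differ")
    if binary:
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{path}: matrix entries must be 0 or 1")
        return df.astype(int)
    return df.astype(float)


def write_matrix_csv(matrix: pd.DataFrame, path, float_format: str | None = None) -> None:
    matrix.to_csv(path, float_format=float_format)


def read_sets_json(path) -> dict[str, list[str]]:
    """Read per-factor sets: {"F13": ["F4", "F5", "F13"], ...}."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected an object mapping factor -> list")
    out: dict[str, list[str]] = {}
    for factor, members in data.items():
        if not isinstance(members, list) or not all(isinstance(x, str) for x in members):
            raise ValueError(f"{path}: set for {factor!r} must be a list of factor ids")
        out[factor] = sorted(members, key=factor_sort_key)
    return out


def write_sets_json(sets: Mapping[str, Iterable[str]], path) -> None:
    payload = {
        f: sorted(members, key=factor_sort_key)
        for f, members in sorted(sets.items(), key=lambda kv: factor_sort_key(kv[0]))
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_judgments_json(path) -> dict[str, Judgment]:
    """Read judgment matrices: a list of {criterion, elements, matrix}.

    Reciprocity and shape are validated on construction.
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a list of judgment objects")
    out: dict[str, Judgment] = {}
    for i, entry in enumerate(data):
        try:
            judgment = Judgment(
                criterion=entry["criterion"],
                elements=tuple(entry["elements"]),
                matrix=np.asarray(entry["matrix"], dtype=float),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: judgment entry {i}: {exc}") from exc
        if judgment.criterion in out:
            raise ValueError(f"{path}: duplicate criterion {judgment.criterion!r}")
        out[judgment.criterion] = judgment
    return out


def write_judgments_json(judgments: Mapping[str, Judgment], path) -> None:
    payload = [
        {
            "criterion": j.criterion,
            "elements": list(j.elements),
            "matrix": j.matrix.tolist(),
        }
        for _, j in sorted(judgments.items(), key=lambda kv: factor_sort_key(kv[0]))
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def write_weight_table_csv(weights: pd.DataFrame, path) -> None:
    """Weight table (factor id, weight to 4 decimals, rank)."""
    out = weights.copy()
    out.index.name = "factor"
    out.to_csv(path, float_format="%.4f")


def write_factor_sets_csv(factor_sets: pd.DataFrame, path) -> None:
    """Reachable/antecedent/intersection table with sets as ';'-joined lists."""
    out = pd.DataFrame(
        {
            col: [
                ";".join(sorted(s, key=factor_sort_key)) for s in factor_sets[col]
            ]
            for col in ("reachable", "antecedent", "intersection")
        },
        index=factor_sets.index,
    )
    out.index.name = "factor"
    out.to_csv(path)


def write_levels_csv(levels: Iterable[Iterable[str]], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["level", "factors"])
        for i, members in enumerate(levels, start=1):
            writer.writerow([i, ";".join(members)])
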