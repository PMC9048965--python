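"""Readers and writers for the package's plain-text formats.

Formats: scaffold-report CSV (genus, scaffold id, one column per carbon in
the token grammar ``re[+q/4i]``), report-matrix CSV (genus, item_id,
status), expression TSV (transcript id + one column per tissue), newick
trees, GraphML graphs and YAML grammar/config files.
"""

from __future__ import annotations

import csv
from dataclasses import asdict
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .codec import (
    CodeStructureError,
    GrammarConfig,
    ScaffoldCode,
    format_code,
    parse_code,
    validate_code,
)
from .coexpression import ExpressionMatrix
from .phylo import Phylogeny, ReportMatrix

__all__ = [
    "read_reports",
    "write_reports",
    "read_scaffold_reports",
    "write_scaffold_reports",
    "dataset_stats",
    "read_expression",
    "write_expression",
    "grammar_to_yaml",
    "grammar_from_yaml",
]


class ParseError(ValueError):
    """Strict parse failure naming line and column."""


def read_reports(path: str | Path) -> ReportMatrix:
    """Report-matrix CSV: genus, item_id, status in {reported, predicted}."""
    pairs = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"genus", "item_id", "status"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise ParseError(f"{path}: header must contain {sorted(need)}")
        for ln, row in enumerate(reader, start=2):
            status = row["status"].strip()
            if status not in ("reported", "predicted"):
                raise ParseError(f"{path}:{ln}: bad status {status!r}")
            pairs.append((row["genus"].strip(), row["item_id"].strip(), status))
    return ReportMatrix.from_pairs(pairs)


def write_reports(matrix: ReportMatrix, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["genus", "item_id", "status"])
        for genus in matrix.genera:
            for item in matrix.items:
                if matrix.reported.loc[genus, item]:
                    w.writerow([genus, item, "reported"])
                elif matrix.predicted.loc[genus, item]:
                    w.writerow([genus, item, "predicted"])


def read_scaffold_reports(
    path: str | Path, config: GrammarConfig
) -> pd.DataFrame:
    """Scaffold-report table: genus, scaffold_id, then one column per carbon.

    Returns a DataFrame with genus, scaffold_id, and the parsed canonical
    ``code`` key; every code is validated against the grammar.  Parse errors
    name line and column.
    """
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        expected = ["genus", "scaffold_id", *config.carbons]
        if [h.strip() for h in header] != expected:
            raise ParseError(
                f"{path}:1: header must be {','.join(expected)}"
            )
        for ln, row in enumerate(reader, start=2):
            if len(row) != len(expected):
                raise ParseError(
                    f"{path}:{ln}: expected {len(expected)} fields, got "
                    f"{len(row)}"
                )
            genus, sid = row[0].strip(), row[1].strip()
            try:
                code = parse_code(",".join(t.strip() for t in row[2:]), config)
            except CodeStructureError as err:
                raise ParseError(f"{path}:{ln}: {err}") from None
            ok, violations = validate_code(code, config)
            if not ok:
                raise ParseError(f"{path}:{ln}: {violations[0]}")
            rows.append(
                {"genus": genus, "scaffold_id": sid, "code": format_code(code)}
            )
    return pd.DataFrame(rows, columns=["genus", "scaffold_id", "code"])


def write_scaffold_reports(
    table: pd.DataFrame, config: GrammarConfig, path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["genus", "scaffold_id", *config.carbons])
        for _, row in table.iterrows():
            code = parse_code(row["code"], config)
            tokens = format_code(code).split(",")
            w.writerow([row["genus"], row["scaffold_id"], *tokens])


def dataset_stats(table: pd.DataFrame) -> dict[str, int]:
    """Record, unique-scaffold, genus-scaffold-pair and genus counts."""
    return {
        "n_records": len(table),
        "n_unique_scaffolds": table["code"].nunique(),
        "n_genus_scaffold_pairs": len(
            table[["genus", "code"]].drop_duplicates()
        ),
        "n_genera": table["genus"].nunique(),
    }


def reports_from_scaffold_table(table: pd.DataFrame) -> ReportMatrix:
    """Collapse a scaffold-report table into a binary report matrix."""
    pairs = [
        (row["genus"], row["code"], "reported") for _, row in table.iterrows()
    ]
    return ReportMatrix.from_pairs(pairs)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Expression TSV: transcript id column then one column per tissue."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t")


def grammar_to_yaml(config: GrammarConfig, path: str | Path) -> None:
    data = {
        "carbons": list(config.carbons),
        "max_real": list(config.max_real),
        "bonds": [list(b) for b in config.bonds],
        "double_bond_bonds": sorted(config.double_bond_bonds),
        "epoxide_bonds": sorted(config.epoxide_bonds),
        "double_bond_max_real": config.double_bond_max_real,
        "epoxide_max_real": config.epoxide_max_real,
        "epoxide_from_saturated": config.epoxide_from_saturated,
        "epoxide_from_double_bond": config.epoxide_from_double_bond,
        "direct_oxidation_carbons": list(config.direct_oxidation_carbons),
        "flag_step_weights": list(config.flag_step_weights),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def grammar_from_yaml(path: str | Path) -> GrammarConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return GrammarConfig(
        carbons=tuple(data["carbons"]),
        max_real=tuple(data["max_real"]),
        bonds=tuple(tuple(b) for b in data["bonds"]),
        double_bond_bonds=frozenset(data.get("double_bond_bonds", [])),
        epoxide_bonds=frozenset(data.get("epoxide_bonds", [])),
        double_bond_max_real=data.get("double_bond_max_real", 0),
        epoxide_max_real=data.get("epoxide_max_real", 1),
        epoxide_from_saturated=data.get("epoxide_from_saturated", True),
        epoxide_from_double_bond=data.get("epoxide_from_double_bond", True),
        direct_oxidation_carbons=tuple(
            data.get("direct_oxidation_carbons", [])
        ),
        flag_step_weights=tuple(
            data.get("flag_step_weights", (2.0, 1.0, 2.0 / 3.0))
        ),
    )
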