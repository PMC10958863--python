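"""Readers and writers for the pipeline's plain-text formats.

Plate tables are long-format CSV (one row per well per timepoint);
expression matrices are TSV with genes in rows; gene sets use GMT; cell
matrices are TSV with a patient-label sidecar; reports and ground truth are
JSON.  All writes are deterministic (sorted keys, fixed float format) so a
re-run with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .growth import PLATE_COLUMNS, ROLES

FLOAT_FORMAT = "%.10g"


def read_plate_table(path) -> pd.DataFrame:
    """Read and validate a long-format plate CSV.

    Schema violations (missing columns, negative viability, unknown role,
    dosed vehicle wells) raise :class:`ParseError` listing the offending
    rows (1-based, excluding the header).
    """
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("timepoint_h", "conc1_nM", "conc2_nM", "viability"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    problems = []
    bad_num = df[["timepoint_h", "conc1_nM", "conc2_nM", "viability"]].isna().any(axis=1)
    problems += [(i, "non-numeric field") for i in df.index[bad_num]]
    problems += [(i, "negative viability") for i in df.index[df["viability"] < 0]]
    problems += [(i, f"unknown role {r!r}")
                 for i, r in df.loc[~df["role"].isin(ROLES), "role"].items()]
    veh_dosed = (df["role"] == "vehicle") & ((df["conc1_nM"] != 0) | (df["conc2_nM"] != 0))
    problems += [(i, "vehicle well with nonzero dose") for i in df.index[veh_dosed]]
    if problems:
        listing = "; ".join(f"row {i + 1}: {msg}" for i, msg in sorted(problems)[:20])
        raise ParseError(f"{path}: {listing}")
    return df[PLATE_COLUMNS]


def write_plate_table(plate: pd.DataFrame, path) -> None:
    plate[PLATE_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV, first column gene ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="gene")


def read_gmt(path) -> dict:
    """GMT gene sets: name <tab> description <tab> genes..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: GMT line needs name, description, >=1 gene")
        sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict, path, description: str = "") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_cells(counts_path, labels_path):
    """Cell matrix TSV (genes x cells) plus patient-label sidecar TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", index_col=0)["patient"]
    return counts, labels


def write_cells(counts: pd.DataFrame, patients: pd.Series, counts_path, labels_path):
    counts.to_csv(counts_path, sep="\t", index_label="gene")
    patients.rename("patient").to_csv(labels_path, sep="\t", index_label="cell")


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, cls=_JsonEncoder) + "\n"
    )


def read_json(path):
    return json.loads(Path(path).read_text())
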