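"""Readers and writers for the pipeline's plain-text formats.

Dialects: TSV with a header row, UTF-8; empty cell in the area matrix =
missing value; GMT lines are ``term<TAB>description<TAB>member...``;
FASTA via biopython (wrapped lines are unwrapped on read).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import AreaMatrix, SchemaError, validate_design

UNIQUE_PEPTIDES_COL = "n_unique_peptides"


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered accession -> sequence mapping."""
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in proteome:
            raise SchemaError(f"duplicate accession in FASTA: {rec.id}")
        proteome[rec.id] = str(rec.seq).upper()
    return proteome


def write_fasta(proteome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in proteome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- TSV tables

def read_area_matrix(path) -> AreaMatrix:
    """Read a protein x run area matrix.

    Expected columns: ``accession``, ``n_unique_peptides``, then one
    column per run id; empty cells parse as missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "accession":
        raise SchemaError(f"{path}: first column must be 'accession', got {df.columns[0]!r}")
    if UNIQUE_PEPTIDES_COL not in df.columns:
        raise SchemaError(f"{path}: missing required column '{UNIQUE_PEPTIDES_COL}'")
    df = df.set_index("accession")
    unique = df.pop(UNIQUE_PEPTIDES_COL).astype(int)
    return AreaMatrix(df.astype(float), unique)


def write_area_matrix(matrix: AreaMatrix, path) -> None:
    out = matrix.areas.copy()
    out.insert(0, UNIQUE_PEPTIDES_COL, matrix.unique_peptides)
    out.rename_axis("accession").to_csv(path, sep="\t", float_format="%.6f", na_rep="")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "run_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'run_id'")
    df = df.set_index("run_id")
    df["replicate"] = df["replicate"].astype(int)
    return validate_design(df)


def write_design(design: pd.DataFrame, path) -> None:
    design.rename_axis("run_id").to_csv(path, sep="\t")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------- GMT

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT term file into term -> member-accession sets."""
    terms: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line needs term, description and >=1 member"
                )
            term = fields[0]
            if term in terms:
                raise SchemaError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = set(fields[2:])
    return terms


def write_gmt(terms: dict[str, set[str]], path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, members in terms.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------- JSON

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
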