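"""Readers and writers for the pipeline's on-disk formats.

Count tables travel as TSV with a ``gene_id`` column followed by one
column per sample; sample metadata is encoded in the column label as
``<strain>_<protocol>_<role>`` (e.g. ``HTS1_TAP_Input``), with an
optional trailing ``gene_type`` column (coding/noncoding).  Sequences
use FASTA via Biopython.  The supplementary-spreadsheet reader ingests
a raw-counts sheet in the same wide layout from an .xlsx workbook.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import CountTable

__all__ = [
    "parse_sample_label",
    "read_count_table",
    "write_count_table",
    "read_counts_xlsx",
    "read_fasta",
    "write_fasta",
    "file_sha256",
]

_ROLES = ("Input", "Bound")


def parse_sample_label(label: str) -> dict[str, str]:
    """Split ``<strain>_<protocol>_<role>`` into metadata fields.

    The strain may itself contain underscores; protocol and role are
    the last two ``_``-separated fields.
    """
    parts = label.rsplit("_", 2)
    if len(parts) != 3 or parts[2] not in _ROLES:
        raise ValueError(
            f"cannot parse sample label {label!r} "
            "(expected <strain>_<protocol>_<role> with role Input|Bound)"
        )
    strain, protocol, role = parts
    return {"strain": strain, "protocol": protocol, "role": role}


def _table_from_wide(df: pd.DataFrame) -> CountTable:
    gene_types = None
    if "gene_type" in df.columns:
        gene_types = df.pop("gene_type")
    meta = {col: parse_sample_label(col) for col in df.columns}
    samples = pd.DataFrame(meta).T
    samples.index.name = "sample"
    return CountTable(counts=df, samples=samples, gene_types=gene_types)


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (gene_id + sample columns [+ gene_type])."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return _table_from_wide(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    if table.gene_types is not None:
        df["gene_type"] = table.gene_types.reindex(df.index).fillna("coding")
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_xlsx(
    path: str | Path,
    sheet: int | str = 0,
    sample_map: dict[str, dict[str, str]] | None = None,
    gene_column: str | None = None,
) -> CountTable:
    """Read a raw-counts sheet from a spreadsheet workbook.

    ``sample_map`` maps spreadsheet column names to
    ``{"strain": ..., "protocol": ..., "role": ...}``; columns not in
    the map are dropped.  Without a map, column names are parsed with
    :func:`parse_sample_label` and unparseable columns are dropped.
    ``gene_column`` names the gene-identifier column (default: first).
    """
    df = pd.read_excel(path, sheet_name=sheet)
    gene_col = gene_column or df.columns[0]
    df = df.set_index(gene_col)
    df.index.name = "gene_id"
    df.index = df.index.astype(str)
    if sample_map is not None:
        keep = [c for c in df.columns if c in sample_map]
        counts = df[keep]
        samples = pd.DataFrame({c: sample_map[c] for c in keep}).T
        samples.index.name = "sample"
        return CountTable(counts=counts, samples=samples)
    parsed = {}
    for col in df.columns:
        try:
            parsed[col] = parse_sample_label(str(col))
        except ValueError:
            continue
    if not parsed:
        raise ValueError(
            f"no parseable sample columns in sheet {sheet!r} of {path}; "
            "provide an explicit sample_map"
        )
    counts = df[list(parsed)]
    samples = pd.DataFrame(parsed).T
    samples.index.name = "sample"
    return CountTable(counts=counts, samples=samples)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> sequence dict (uppercase, as stored)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
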