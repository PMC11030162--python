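"""Readers and writers for every external format the pipeline touches.

Tabular inputs are consumed with strict validation: BLAST tabular
(``-outfmt 6``), 5-column KO annotation TSVs, 2-column CAZyme annotation
TSVs, per-sample count matrices, gene FASTA (lengths only) and KEGG module
flat files (ENTRY/NAME/DEFINITION records separated by ``///``).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .taxonomy import Lineage

_KO_RE = re.compile(r"^K\d{5}$")
_MODULE_RE = re.compile(r"^M\d{5}$")
_CAZY_PREFIXES = ("GH", "GT", "PL", "CE", "AA", "CBM")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class BlastHit:
    """One row of BLAST tabular output (outfmt 6, 12 columns).

    Coordinates are stored as read (1-based inclusive) and never used
    arithmetically; only the bitscore and subject identity matter
    downstream.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore for {self.query_id}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue for {self.query_id}")


@dataclass(frozen=True)
class KofamRow:
    """One KO annotation candidate with its family-specific score cutoff."""

    gene_id: str
    ko_id: str
    score: float
    threshold: float
    evalue: float

    def __post_init__(self) -> None:
        if not _KO_RE.match(self.ko_id):
            raise ValueError(f"malformed KO id {self.ko_id!r}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue for {self.gene_id}")


@dataclass(frozen=True)
class DbcanRow:
    """One CAZyme family call for a gene (e.g. GH18, AA9, CBM5, GH5_5)."""

    gene_id: str
    cazy_family: str

    def __post_init__(self) -> None:
        if not self.cazy_family.startswith(_CAZY_PREFIXES):
            raise ValueError(f"not a CAZy family label: {self.cazy_family!r}")


@dataclass(frozen=True)
class ModuleFlatRecord:
    """One KEGG module flat-file record: id, name and raw DEFINITION."""

    module_id: str
    name: str
    definition: str

    def __post_init__(self) -> None:
        if not _MODULE_RE.match(self.module_id):
            raise ValueError(f"malformed module id {self.module_id!r}")
        if self.definition.count("(") != self.definition.count(")"):
            raise ValueError(f"unbalanced parentheses in DEFINITION of {self.module_id}")


# ---------------------------------------------------------------------------
# BLAST tabular


def read_blast6(path: str | Path) -> list[BlastHit]:
    """Parse a 12-column BLAST tabular file, preserving row order."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(f"{path}: line {lineno}: expected 12 columns, got {len(fields)}")
            try:
                hits.append(
                    BlastHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        align_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_blast6(hits: Iterable[BlastHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:g}\t{h.align_length}"
                f"\t{h.mismatches}\t{h.gap_opens}\t{h.qstart}\t{h.qend}\t{h.sstart}"
                f"\t{h.send}\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Map each FASTA record id (up to first whitespace) to its length in bp."""
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise ParseError(f"{path}: duplicate sequence id {record.id!r}")
        if len(record.seq) == 0:
            raise ParseError(f"{path}: empty sequence for {record.id!r}")
        lengths[record.id] = len(record.seq)
    return lengths


# ---------------------------------------------------------------------------
# KEGG module flat file


def read_module_flatfile(path: str | Path) -> list[ModuleFlatRecord]:
    """Parse ENTRY/NAME/DEFINITION records separated by ``///``.

    Continuation lines (leading whitespace) are joined with a single space.
    """
    records: list[ModuleFlatRecord] = []
    entry: str | None = None
    fields: dict[str, list[str]] = {}
    current: str | None = None

    def flush() -> None:
        nonlocal entry, fields, current
        if entry is None:
            return
        if "DEFINITION" not in fields:
            raise ParseError(f"{path}: module {entry} has no DEFINITION")
        definition = " ".join(fields["DEFINITION"])
        name = " ".join(fields.get("NAME", [""]))
        records.append(ModuleFlatRecord(module_id=entry, name=name, definition=definition))
        entry, fields, current = None, {}, None

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("///"):
                flush()
                continue
            if not line.strip():
                continue
            if line[0].isspace():
                if current is not None:
                    fields.setdefault(current, []).append(line.strip())
                continue
            key, _, rest = line.partition(" ")
            rest = rest.strip()
            if key == "ENTRY":
                entry = rest.split()[0] if rest else ""
                current = None
            else:
                current = key
                fields.setdefault(key, []).append(rest)
    flush()
    return records


def write_module_flatfile(records: Iterable[ModuleFlatRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"ENTRY       {rec.module_id}            Pathway   Module\n")
            if rec.name:
                fh.write(f"NAME        {rec.name}\n")
            fh.write(f"DEFINITION  {rec.definition}\n///\n")


# ---------------------------------------------------------------------------
# Simple TSV tables


def read_kofam_tsv(path: str | Path) -> list[KofamRow]:
    """Read a 5-column KO annotation TSV (gene, KO, score, threshold, evalue)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    required = ["gene_id", "ko_id", "score", "threshold", "evalue"]
    if list(df.columns[:5]) != required:
        raise ParseError(f"{path}: expected columns {required}, got {list(df.columns)}")
    return [
        KofamRow(r.gene_id, r.ko_id, float(r.score), float(r.threshold), float(r.evalue))
        for r in df.itertuples(index=False)
    ]


def write_kofam_tsv(rows: Iterable[KofamRow], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["gene_id", "ko_id", "score", "threshold", "evalue"]).to_csv(
        path, sep="\t", index=False
    )


def read_dbcan_tsv(path: str | Path) -> list[DbcanRow]:
    """Read a 2-column CAZyme annotation TSV (gene, family)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "cazy_family"]:
        raise ParseError(f"{path}: expected columns gene_id, cazy_family")
    return [DbcanRow(r.gene_id, r.cazy_family) for r in df.itertuples(index=False)]


def write_dbcan_tsv(rows: Iterable[DbcanRow], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["gene_id", "cazy_family"]).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count TSV into a samples x genes frame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    out = df.T
    out.index.name = "sample"
    out.columns.name = "gene_id"
    return out


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x genes frame as a gene x sample TSV."""
    out = counts.T
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_taxmap_tsv(path: str | Path) -> "dict[str, Lineage]":
    """Read subject_id -> semicolon-joined lineage."""
    from .taxonomy import Lineage

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if list(df.columns[:2]) != ["subject_id", "lineage"]:
        raise ParseError(f"{path}: expected columns subject_id, lineage")
    return {r.subject_id: Lineage.from_string(r.lineage) for r in df.itertuples(index=False)}


def write_taxmap_tsv(taxmap: "dict[str, Lineage]", path: str | Path) -> None:
    pd.DataFrame(
        [(s, lin.to_string()) for s, lin in taxmap.items()],
        columns=["subject_id", "lineage"],
    ).to_csv(path, sep="\t", index=False)


def read_lineages_tsv(path: str | Path) -> "dict[str, Lineage]":
    """Read gene_id -> lineage; empty lineage strings mean unassigned."""
    from .taxonomy import Lineage

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "gene_id" not in df.columns or "lineage" not in df.columns:
        raise ParseError(f"{path}: expected columns gene_id, lineage")
    return {r.gene_id: Lineage.from_string(r.lineage) for r in df.itertuples(index=False)}


def write_lineages_tsv(lineages: "dict[str, Lineage]", path: str | Path) -> None:
    pd.DataFrame(
        [(g, lin.to_string()) for g, lin in lineages.items()],
        columns=["gene_id", "lineage"],
    ).to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read sample metadata with at least columns sample, putative_status."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    for col in ("sample", "putative_status"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df.set_index("sample")
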