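"""Readers and writers for the external formats the pipeline touches.

Newick trees are handled by :mod:`dendropy`, FASTA by :mod:`Bio.SeqIO`,
and tab-separated tables by :mod:`pandas`.  Every reader validates the
domain invariants (unique tip labels, non-negative branch lengths, 12-column
hit records, required table columns) and raises :class:`FormatError` for
malformed content or :class:`ValidationError` for content that parses but
violates an invariant.  Reader/writer pairs are lossless round trips for
valid inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from dendropy.dataio import newickreader

logger = logging.getLogger("evoscreen")

__all__ = [
    "FormatError",
    "ValidationError",
    "FastaRecord",
    "HitRecord",
    "HIT_COLUMNS",
    "read_newick",
    "write_newick",
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "write_hit_table",
    "hits_to_frame",
    "read_table",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in its declared format."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


#: Column names of the 12-column tabular hit dialect (BLAST outfmt 6).
HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
]


class FastaRecord(NamedTuple):
    """A parsed FASTA record."""

    id: str
    description: str
    seq: str


class HitRecord(NamedTuple):
    """One line of a 12-column tabular similarity-search hit file."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted tree from a Newick file.

    Tip labels must be unique; missing branch lengths are read as 0 with a
    logged warning; negative branch lengths are rejected.
    """
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"{path}: duplicate tip labels: {exc}") from exc
    except Exception as exc:  # dendropy reader errors carry line/column info
        raise FormatError(f"{path}: not parseable as Newick: {exc}") from exc
    return _validate_tree(tree, str(path))


def _validate_tree(tree: dendropy.Tree, source: str) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"{source}: duplicate tip labels: {dupes}")
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # root edge: no subtending branch
            if edge.length is None:
                edge.length = 0.0
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
        elif edge.length < 0:
            raise ValidationError(
                f"{source}: negative branch length {edge.length}"
            )
    if n_missing:
        logger.warning(
            "%s: %d branch length(s) missing, read as 0", source, n_missing
        )
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as Newick with full float precision."""
    tree.write(
        path=str(Path(path)),
        schema="newick",
        real_value_format_specifier=".17g",
        suppress_rooting=True,
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_FASTA_ALPHABET = set("ACGTNacgtn")


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read FASTA records as (id, description, sequence) tuples."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
        while head.isspace():
            head = fh.read(1)
        if head and head != ">":
            raise FormatError(f"{path}: leading non-FASTA content {head!r}")
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq)
            if not seq:
                raise ValidationError(f"{path}: record {rec.id!r} has empty sequence")
            records.append(FastaRecord(rec.id, rec.description, seq))
    except ValidationError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as FASTA: {exc}") from exc
    return records


def write_fasta(records: Iterable[FastaRecord | tuple], path: str | Path) -> None:
    """Write records as 60-column wrapped FASTA.

    Ids must be unique, sequences non-empty over {A, C, G, T, N} (either case).
    """
    recs = [FastaRecord(*r) for r in records]
    seen: set[str] = set()
    for r in recs:
        if not r.seq:
            raise ValidationError(f"record {r.id!r} has empty sequence")
        if r.id in seen:
            raise ValidationError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
        bad = set(r.seq) - _FASTA_ALPHABET
        if bad:
            raise ValidationError(
                f"record {r.id!r} has characters outside ACGTN: {sorted(bad)}"
            )
    bio = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in recs
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# 12-column tabular hits
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tabular hit file (no header), preserving order."""
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                rec = HitRecord(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bit_score=float(parts[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if rec.q_start > rec.q_end:
                raise ValidationError(
                    f"{path}: line {lineno}: q_start > q_end"
                )
            if rec.evalue < 0:
                raise ValidationError(f"{path}: line {lineno}: negative evalue")
            hits.append(rec)
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(x) for x in h) + "\n")


def hits_to_frame(hits: Sequence[HitRecord]) -> pd.DataFrame:
    return pd.DataFrame(hits, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# Generic TSV tables
# ---------------------------------------------------------------------------

def read_table(
    path: str | Path, schema: Sequence[str] | None = None
) -> pd.DataFrame:
    """Read a TSV table with a mandatory header.

    ``schema`` lists required column names; missing columns raise a
    :class:`ValidationError` naming them.  Extra columns and row order are
    preserved; missing numeric values propagate as NaN and their count is
    logged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: not parseable as TSV: {exc}") from exc
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing required columns: {missing}")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("%s: %d missing value(s) propagated as NaN", path, n_missing)
    return df
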