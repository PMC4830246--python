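"""Readers, writers and core record types.

Formats handled here are the pipeline's external surface: FASTA, FASTQ
(Phred+33), 12-column tabular alignment ("outfmt 6"), TSV taxonomy tables
(taxid, parent, rank, name) and abundance TSVs.  Parsers are strict: any
invariant violation raises :class:`ParseError` rather than silently
coercing.  Record parsing itself is delegated to Bio.SeqIO; the wrappers
add validation and stable error reporting.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = set("ACGTN")

TABULAR_COLUMNS = (
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
)


class ParseError(ValueError):
    """Raised when an input file violates a format invariant."""


@dataclass(frozen=True)
class Read:
    """A sequenced fragment.

    ``quals`` are Phred scores (one per base) when present.  ``truth`` is
    the simulated origin label (a family name or ``"background"``) carried
    by synthetic reads; real reads leave it ``None``.
    """

    id: str
    seq: str
    quals: Optional[tuple[int, ...]] = None
    truth: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise ValueError(f"read {self.id}: non-ACGTN characters {sorted(bad)}")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.id}: {len(self.quals)} quality scores for "
                f"{len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column tabular alignment output.

    Coordinates are 1-based inclusive, the tabular convention; internal
    slicing converts once at this boundary.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: q_start > q_end"
            )
        if self.bit_score <= 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: bit_score <= 0")
        if self.evalue < 0 or math.isnan(self.evalue):
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: bad evalue")


@dataclass(frozen=True)
class TaxonomyNode:
    taxid: str
    parent: str
    rank: str
    name: str


@dataclass
class PipelineConfig:
    """Tunable parameters of the screening pipeline.

    ``family_cutoffs`` maps family name -> per-dataset BSR cutoff (a float
    in [0, 1] or the sentinel ``"manual"``); ``family_strategies`` maps
    family name -> resolution strategy name (e.g. ``"hao_hdh"``).
    """

    evalue_cutoff: float = 1e-6
    quality_limit: float = 0.05
    min_length: int = 100
    max_ambiguous: int = 2
    family_cutoffs: dict = field(default_factory=dict)
    family_strategies: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.quality_limit < 1:
            raise ValueError("quality_limit must be in (0, 1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_ambiguous < 0:
            raise ValueError("max_ambiguous must be >= 0")
        for fam, cut in self.family_cutoffs.items():
            if isinstance(cut, str):
                if cut != "manual":
                    raise ValueError(f"{fam}: cutoff must be numeric or 'manual'")
            elif not 0 <= float(cut) <= 1:
                raise ValueError(f"{fam}: cutoff {cut} outside [0, 1]")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _check_unique(ids: set, rid: str, path, recno: int) -> None:
    if rid in ids:
        raise ParseError(f"{path}: duplicate record id {rid!r} (record {recno})")
    ids.add(rid)


def read_fasta(path: Union[str, Path]) -> list[Read]:
    """Read a nucleotide FASTA file into a list of :class:`Read` (order preserved)."""
    path = Path(path)
    reads: list[Read] = []
    seen: set = set()
    for recno, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        _check_unique(seen, rec.id, path, recno)
        try:
            reads.append(Read(id=rec.id, seq=str(rec.seq).upper()))
        except ValueError as exc:
            raise ParseError(f"{path}: record {recno}: {exc}") from exc
    if not reads and path.stat().st_size > 0:
        raise ParseError(f"{path}: no FASTA records parsed (malformed header line 1?)")
    return reads


def read_fastq(path: Union[str, Path]) -> list[Read]:
    """Read a FASTQ file (Phred+33) into a list of :class:`Read`.

    Malformed records (including quality strings whose length differs from
    the sequence) raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    reads: list[Read] = []
    seen: set = set()
    recno = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            recno += 1
            _check_unique(seen, rec.id, path, recno)
            quals = tuple(rec.letter_annotations["phred_quality"])
            try:
                reads.append(Read(id=rec.id, seq=str(rec.seq).upper(), quals=quals))
            except ValueError as exc:
                raise ParseError(f"{path}: record {recno}: {exc}") from exc
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        # Bio.SeqIO raises bare ValueError on malformed FASTQ; each record
        # spans 4 lines, so the failing record starts at line 4*recno + 1.
        raise ParseError(f"{path}: near line {4 * recno + 1}: {exc}") from exc
    return reads


def _to_seqrecord(read: Read) -> SeqRecord:
    rec = SeqRecord(Seq(read.seq), id=read.id, description="")
    if read.quals is not None:
        rec.letter_annotations["phred_quality"] = list(read.quals)
    return rec


def write_fasta(reads: Iterable[Read], path: Union[str, Path]) -> None:
    SeqIO.write((_to_seqrecord(r) for r in reads), str(path), "fasta")


def write_fastq(reads: Iterable[Read], path: Union[str, Path]) -> None:
    recs = []
    for r in reads:
        if r.quals is None:
            raise ValueError(f"read {r.id}: cannot write FASTQ without qualities")
        recs.append(_to_seqrecord(r))
    SeqIO.write(recs, str(path), "fastq")


def read_protein_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read an amino-acid FASTA into an ordered {id: sequence} mapping."""
    path = Path(path)
    seqs: dict[str, str] = {}
    for recno, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate record id {rec.id!r} (record {recno})")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_protein_fasta(seqs: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular alignment

_TAB_TYPES = (str, str, float, int, int, int, int, int, int, int, float, float)


def read_tabular_alignment(path: Union[str, Path]) -> list[AlignmentHit]:
    """Parse 12-column tab-separated alignment output into hits, order preserved."""
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                values = [typ(raw) for typ, raw in zip(_TAB_TYPES, fields)]
                hits.append(AlignmentHit(*values))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_tabular_alignment(hits: Iterable[AlignmentHit], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.2e}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Taxonomy and abundance tables


def read_taxonomy_table(path: Union[str, Path]) -> list[TaxonomyNode]:
    """Read a TSV taxonomy table with columns taxid, parent, rank, name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"taxid", "parent", "rank", "name"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing taxonomy columns {sorted(missing)}")
    return [
        TaxonomyNode(row["taxid"], row["parent"], row["rank"], row["name"])
        for _, row in df.iterrows()
    ]


def write_taxonomy_table(nodes: Iterable[TaxonomyNode], path: Union[str, Path]) -> None:
    pd.DataFrame([dataclasses.asdict(n) for n in nodes]).to_csv(
        path, sep="\t", index=False
    )


def read_abundance_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"family", "dataset", "raw_count", "gene_length", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing abundance columns {sorted(missing)}")
    return df


def write_abundance_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)
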