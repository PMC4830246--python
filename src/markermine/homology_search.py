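"""Six-frame translated homology search of nucleotide reads against
amino-acid reference sets.

Two scorers are supported behind the same result contract:

* ``internal`` -- a desk-scale translated search: each read is translated
  in six frames, candidate references are located through a shared-k-mer
  prefilter, and candidates are scored by local Smith-Waterman (BLOSUM62,
  gap open 11 / extend 1, via Bio.Align's C aligner).  Raw scores are
  converted to bit scores and E-values with the Karlin-Altschul formula
  using the published gapped BLOSUM62 11/1 constants.  E-value parity
  with NCBI BLAST is not promised; downstream decisions depend only on
  score ratios and a permissive cutoff.
* ``external`` -- hits parsed from a 12-column tabular file produced by
  any BLASTx-compatible aligner.

Only hits with E-value <= cutoff are retained.  The per-read best hit is
the maximal bit score, ties broken by smaller E-value then lexicographic
subject id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import AlignmentHit, Read

__all__ = [
    "translate_six_frames",
    "search_reads",
    "search_from_tabular",
    "SearchResult",
    "ReadHit",
    "make_protein_aligner",
    "bit_score",
    "evalue",
]

# Karlin-Altschul constants for gapped BLOSUM62, gap open 11 / extend 1.
LAMBDA = 0.267
K = 0.041
LN2 = math.log(2.0)

_BASES = "TCAG"
_CODE = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {}
for _i, _aa in enumerate(_CODE):
    CODON_TABLE[_BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]] = _aa

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _translate_frame(seq: str) -> str:
    # Codons containing N (or any non-ACGT) translate to 'X'; stops are '*'.
    return "".join(
        CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def translate_six_frames(seq: str) -> list[str]:
    """Translate in frames +1, +2, +3, -1, -2, -3 (standard code)."""
    seq = seq.upper()
    rc = _revcomp(seq)
    return [
        _translate_frame(seq),
        _translate_frame(seq[1:]),
        _translate_frame(seq[2:]),
        _translate_frame(rc),
        _translate_frame(rc[1:]),
        _translate_frame(rc[2:]),
    ]


def bit_score(raw_score: float) -> float:
    return (LAMBDA * raw_score - math.log(K)) / LN2


def evalue(raw_score: float, query_len: int, db_len: int) -> float:
    return query_len * db_len * 2.0 ** (-bit_score(raw_score))


def make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass(frozen=True)
class ReadHit:
    """One read-vs-reference hit (best HSP only; no HSP tiling)."""

    subject_id: str
    raw_score: float
    bit_score: float
    evalue: float
    frame: int  # +1..+3 / -1..-3; 0 when parsed from an external table

    def sort_key(self):
        return (-self.bit_score, self.evalue, self.subject_id)


@dataclass
class SearchResult:
    """Per-read hit lists (E-value filtered, sorted best first)."""

    hits: dict[str, list[ReadHit]]
    alignment_hits: dict[str, AlignmentHit]  # per-read best, detailed

    def best(self, read_id: str) -> Optional[ReadHit]:
        lst = self.hits.get(read_id)
        return lst[0] if lst else None

    @property
    def read_ids(self) -> list[str]:
        return list(self.hits)


FRAMES = (1, 2, 3, -1, -2, -3)


def _kmer_index(references: Mapping[str, str], k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for name, seq in references.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], set()).add(name)
    return index


def _alignment_detail(
    aligner: Align.PairwiseAligner, query: str, subject: str
) -> tuple[int, int, int, int, tuple[int, int, int, int]]:
    """(matches, aln_columns, mismatches, gap_opens, 1-based coords) of the
    best local alignment."""
    aln = aligner.align(query, subject)[0]
    qblocks, sblocks = aln.aligned
    matches = mismatches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        for a, b in zip(query[qs:qe], subject[ss:se]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
        aligned_cols += qe - qs
    gap_opens = len(qblocks) - 1
    gap_cols = 0
    for i in range(1, len(qblocks)):
        gap_cols += max(
            qblocks[i][0] - qblocks[i - 1][1], sblocks[i][0] - sblocks[i - 1][1]
        )
    total_cols = aligned_cols + gap_cols
    coords = (
        int(qblocks[0][0]) + 1,
        int(qblocks[-1][1]),
        int(sblocks[0][0]) + 1,
        int(sblocks[-1][1]),
    )
    return matches, total_cols, mismatches, gap_opens, coords


def search_reads(
    reads: Iterable[Read],
    references: Mapping[str, str],
    evalue_cutoff: float = 1e-6,
    scorer: str = "internal",
    tabular_hits: Optional[Sequence[AlignmentHit]] = None,
    min_read_coverage: Optional[float] = None,
    seed_k: int = 5,
    max_candidates: int = 8,
) -> SearchResult:
    """Screen reads against an amino-acid reference set.

    ``min_read_coverage``, when set, additionally requires the best hit's
    aligned query span to cover at least that fraction of the read length
    (in nucleotides); reads failing it are dropped from the result.  The
    default (None) keeps the pure E-value behaviour.
    """
    reads = list(reads)
    if scorer == "external":
        if tabular_hits is None:
            raise ValueError("external scorer requires tabular_hits")
        return search_from_tabular(tabular_hits, [r.id for r in reads], evalue_cutoff)
    if scorer != "internal":
        raise ValueError(f"unknown scorer {scorer!r}")
    if not references:
        raise ValueError("empty reference set")

    aligner = make_protein_aligner()
    index = _kmer_index(references, seed_k)
    db_len = sum(len(s) for s in references.values())
    hits: dict[str, list[ReadHit]] = {}
    details: dict[str, AlignmentHit] = {}

    for read in reads:
        frames = translate_six_frames(read.seq)
        # Candidate subjects per frame from shared k-mers, capped by seed count.
        best_per_subject: dict[str, ReadHit] = {}
        for frame_no, pep in zip(FRAMES, frames):
            if len(pep) < seed_k:
                continue
            counts: dict[str, int] = {}
            for i in range(len(pep) - seed_k + 1):
                for subj in index.get(pep[i : i + seed_k], ()):
                    counts[subj] = counts.get(subj, 0) + 1
            if not counts:
                continue
            candidates = sorted(counts, key=lambda s: (-counts[s], s))[:max_candidates]
            for subj in candidates:
                raw = aligner.score(pep, references[subj])
                if raw <= 0:
                    continue
                hit = ReadHit(
                    subject_id=subj,
                    raw_score=float(raw),
                    bit_score=bit_score(raw),
                    evalue=evalue(raw, len(pep), db_len),
                    frame=frame_no,
                )
                prev = best_per_subject.get(subj)
                if prev is None or hit.sort_key() < prev.sort_key():
                    best_per_subject[subj] = hit
        qualifying = sorted(
            (h for h in best_per_subject.values() if h.evalue <= evalue_cutoff),
            key=ReadHit.sort_key,
        )
        if not qualifying:
            continue
        best = qualifying[0]
        pep = frames[FRAMES.index(best.frame)]
        matches, cols, mism, gaps, coords = _alignment_detail(
            aligner, pep, references[best.subject_id]
        )
        if min_read_coverage is not None:
            span_nt = 3 * (coords[1] - coords[0] + 1)
            if span_nt < min_read_coverage * len(read):
                continue
        hits[read.id] = qualifying
        details[read.id] = AlignmentHit(
            query_id=read.id,
            subject_id=best.subject_id,
            pct_identity=100.0 * matches / cols if cols else 0.0,
            aln_length=cols,
            mismatches=mism,
            gap_opens=gaps,
            q_start=coords[0],
            q_end=coords[1],
            s_start=coords[2],
            s_end=coords[3],
            evalue=best.evalue,
            bit_score=best.bit_score,
        )
    return SearchResult(hits=hits, alignment_hits=details)


def search_from_tabular(
    tabular_hits: Sequence[AlignmentHit],
    read_ids: Sequence[str],
    evalue_cutoff: float = 1e-6,
) -> SearchResult:
    """Build a SearchResult from externally produced tabular alignment rows."""
    known = set(read_ids)
    unknown = {h.query_id for h in tabular_hits} - known
    if unknown:
        raise KeyError(
            f"tabular hits reference unknown read ids: {sorted(unknown)[:5]}"
        )
    hits: dict[str, list[ReadHit]] = {}
    details: dict[str, AlignmentHit] = {}
    for h in tabular_hits:
        if h.evalue > evalue_cutoff:
            continue
        hits.setdefault(h.query_id, []).append(
            ReadHit(
                subject_id=h.subject_id,
                raw_score=h.bit_score,  # raw score unavailable in tabular output
                bit_score=h.bit_score,
                evalue=h.evalue,
                frame=0,
            )
        )
    for rid, lst in hits.items():
        lst.sort(key=ReadHit.sort_key)
        best = lst[0]
        for h in tabular_hits:
            if h.query_id == rid and h.subject_id == best.subject_id:
                details[rid] = h
                break
    return SearchResult(hits=hits, alignment_hits=details)
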