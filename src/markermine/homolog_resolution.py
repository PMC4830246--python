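"""Second-stage separation of homologous marker genes.

Two members of each homolog pair score against the same amino-acid
reference set, so the primary screen cannot distinguish them:

* hao vs hdh (hydroxylamine oxidoreductase vs hydrazine dehydrogenase):
  reads kept for the combined set are mapped at the nucleotide level
  against reference hdh copies (mismatch penalty 2, indel penalty 3,
  minimum 50% identity over 50% of the read); mapped reads are hdh,
  unmapped reads are hao.
* narG vs nxrA (nitrate reductase vs nitrite oxidoreductase): kept reads
  are searched a second time against two nxrA subset databases; a
  bit-score ratio of the best subset hit to the read's original
  custom-database score >= 0.85 assigns the read to that subset's nxrA
  class, otherwise it stays narG.

"Identity over coverage" follows read-mapper semantics: alignment
identity >= min_identity computed over the aligned columns, and the
aligned read span >= min_read_coverage of the read length.  Both strands
are always searched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align

from .io_formats import Read
from .homology_search import SearchResult, search_reads

__all__ = [
    "MappingParams",
    "MapHit",
    "make_nt_aligner",
    "map_reads",
    "split_hao_hdh",
    "split_narG_nxrA",
]


@dataclass(frozen=True)
class MappingParams:
    """Nucleotide read-mapping parameters (workbench-style)."""

    mismatch_penalty: int = 2
    indel_penalty: int = 3
    min_identity: float = 50.0  # percent, over the aligned columns
    min_read_coverage: float = 50.0  # percent of read length

    def __post_init__(self) -> None:
        if self.mismatch_penalty < 1 or self.indel_penalty < 1:
            raise ValueError("penalties must be >= 1")
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if not 0 < self.min_read_coverage <= 100:
            raise ValueError("min_read_coverage must be in (0, 100]")


@dataclass(frozen=True)
class MapHit:
    reference_id: str
    strand: str  # '+' or '-'
    score: float
    identity: float  # percent over aligned columns
    read_coverage: float  # percent of read length spanned by the alignment


def make_nt_aligner(params: MappingParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -float(params.mismatch_penalty)
    aligner.open_gap_score = -float(params.indel_penalty)
    aligner.extend_gap_score = -float(params.indel_penalty)
    return aligner


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _alignment_stats(
    aligner: Align.PairwiseAligner, read_seq: str, ref: str
) -> Optional[tuple[float, float]]:
    """(identity%, read coverage%) of the best local alignment."""
    aln = aligner.align(read_seq, ref)[0]
    qblocks, sblocks = aln.aligned
    matches = cols = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        cols += qe - qs
        matches += sum(
            a == b for a, b in zip(read_seq[qs:qe], ref[ss:se])
        )
    for i in range(1, len(qblocks)):
        cols += max(
            qblocks[i][0] - qblocks[i - 1][1], sblocks[i][0] - sblocks[i - 1][1]
        )
    if cols == 0:
        return None
    identity = 100.0 * matches / cols
    coverage = 100.0 * (qblocks[-1][1] - qblocks[0][0]) / len(read_seq)
    return identity, coverage


def map_reads(
    reads: Iterable[Read],
    references_nt: Mapping[str, str],
    params: MappingParams = MappingParams(),
) -> tuple[list[Read], list[Read], dict[str, MapHit]]:
    """Partition reads into (mapped, unmapped) against nucleotide references.

    A read maps iff its best local alignment (highest score over all
    references and both strands; score ties broken by reference id then
    forward strand) reaches ``min_identity`` over an aligned span of at
    least ``min_read_coverage`` of the read length.  The partition is
    exhaustive and exclusive; per-read details of the accepted alignment
    are returned for mapped reads.
    """
    references_nt = dict(references_nt)
    if not references_nt:
        raise ValueError("empty reference set")
    aligner = make_nt_aligner(params)
    mapped: list[Read] = []
    unmapped: list[Read] = []
    details: dict[str, MapHit] = {}
    for read in reads:
        scored = []
        for ref_id in sorted(references_nt):
            ref = references_nt[ref_id]
            for strand, seq in (("+", read.seq), ("-", _revcomp(read.seq))):
                score = aligner.score(seq, ref)
                if score > 0:
                    scored.append((-score, ref_id, strand, seq, ref))
        best: Optional[MapHit] = None
        if scored:
            neg_score, ref_id, strand, seq, ref = min(scored)
            stats = _alignment_stats(aligner, seq, ref)
            if stats is not None:
                ident, cov = stats
                if ident >= params.min_identity and cov >= params.min_read_coverage:
                    best = MapHit(ref_id, strand, -neg_score, ident, cov)
        if best is None:
            unmapped.append(read)
        else:
            mapped.append(read)
            details[read.id] = best
    return mapped, unmapped, details


def split_hao_hdh(
    reads: Iterable[Read],
    hdh_references_nt: Mapping[str, str],
    params: MappingParams = MappingParams(
        mismatch_penalty=2, indel_penalty=3, min_identity=50.0, min_read_coverage=50.0
    ),
) -> dict[str, list[Read]]:
    """Two-class partition of BSR-kept hao/hdh reads.

    Reads mapping to the reference hdh copies are classified hdh; the
    rest are hao.  ``|hdh| + |hao| == |input|`` always.
    """
    mapped, unmapped, _ = map_reads(reads, hdh_references_nt, params)
    return {"hdh": mapped, "hao": unmapped}


def split_narG_nxrA(
    reads: Sequence[Read],
    original_scores: Mapping[str, float],
    subset_a: Mapping[str, str],
    subset_b: Mapping[str, str],
    bsr_cutoff: float = 0.85,
    evalue_cutoff: float = 1e-6,
) -> dict[str, list[Read]]:
    """Three-way partition of BSR-kept narG/nxrA reads by a second BSR round.

    ``original_scores`` maps read id -> the read's first-round custom-db
    bit score.  For each read the best hit against each nxrA subset is
    ratioed against that original score; a ratio >= ``bsr_cutoff``
    assigns the subset's nxrA class (the higher ratio wins when both
    qualify; an exact tie is flagged ambiguous), otherwise narG.
    """
    missing = [r.id for r in reads if r.id not in original_scores]
    if missing:
        raise KeyError(f"reads without an original custom score: {missing[:5]}")
    res_a = search_reads(reads, subset_a, evalue_cutoff=evalue_cutoff)
    res_b = search_reads(reads, subset_b, evalue_cutoff=evalue_cutoff)
    out: dict[str, list[Read]] = {"nxrA_A": [], "nxrA_B": [], "narG": [], "ambiguous": []}
    for read in reads:
        orig = original_scores[read.id]
        if orig <= 0:
            raise ValueError(f"{read.id}: nonpositive original score")
        ratios = {}
        for cls, res in (("nxrA_A", res_a), ("nxrA_B", res_b)):
            best = res.best(read.id)
            ratios[cls] = best.bit_score / orig if best else 0.0
        qualifying = {c: r for c, r in ratios.items() if r >= bsr_cutoff}
        if not qualifying:
            out["narG"].append(read)
        elif len(qualifying) == 1:
            out[next(iter(qualifying))].append(read)
        elif ratios["nxrA_A"] == ratios["nxrA_B"]:
            out["ambiguous"].append(read)
        else:
            out[max(qualifying, key=qualifying.get)].append(read)
    return out
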