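"""Iterative-mapping consensus reconstruction of marker genes.

Starting from a related seed sequence, reads are mapped to the current
consensus; a per-column majority base over the read pileup (seed base
where coverage is zero) becomes the next consensus, optionally extended
by reads overhanging the ends; the cycle repeats until the mapped read
set repeats (cycle-safe) or a round limit is reached.  With sufficient
coverage this recovers a (near) full-length gene from a diverged seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import Read
from .homolog_resolution import MappingParams, make_nt_aligner, _revcomp

__all__ = ["IterationState", "iterative_reconstruct"]

_BASE_ORDER = "ACGT"  # majority ties broken in this fixed order
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}


@dataclass
class IterationState:
    round: int
    seed_sequence: str
    mapped_read_ids: frozenset
    consensus: str
    converged: bool
    log: list[str] = field(default_factory=list)


def _best_alignment(aligner, read: Read, consensus: str, params: MappingParams):
    """Best qualifying local alignment of the read (either strand) to the
    consensus, or None.  Returns (oriented_seq, qblocks, sblocks)."""
    best = None
    for seq in (read.seq, _revcomp(read.seq)):
        score = aligner.score(seq, consensus)
        if score <= 0:
            continue
        aln = aligner.align(seq, consensus)[0]
        qb, sb = aln.aligned
        matches = cols = 0
        for (qs, qe), (ss, se) in zip(qb, sb):
            cols += qe - qs
            matches += sum(a == b for a, b in zip(seq[qs:qe], consensus[ss:se]))
        for i in range(1, len(qb)):
            cols += max(qb[i][0] - qb[i - 1][1], sb[i][0] - sb[i - 1][1])
        if cols == 0:
            continue
        identity = 100.0 * matches / cols
        coverage = 100.0 * (qb[-1][1] - qb[0][0]) / len(seq)
        if identity >= params.min_identity and coverage >= params.min_read_coverage:
            if best is None or score > best[0]:
                best = (score, seq, qb, sb)
    if best is None:
        return None
    return best[1], best[2], best[3]


def iterative_reconstruct(
    reads: Sequence[Read],
    seed_nt: str,
    params: MappingParams = MappingParams(),
    max_rounds: int = 20,
    extend_ends: bool = True,
    min_overhang: int = 20,
) -> IterationState:
    """Reconstruct a gene by iterative read mapping against a seed.

    Each round maps all reads against the current consensus (the seed in
    round 1), rebuilds the consensus as the per-column majority base of
    the pileup (ties broken A<C<G<T; seed/consensus base where coverage
    is 0), and optionally extends the consensus with the longest read
    overhang of at least ``min_overhang`` bases at either end.
    Convergence: the mapped read-id set equals one seen in a previous
    round.  Deterministic under fixed inputs.
    """
    if not seed_nt:
        raise ValueError("seed sequence must be non-empty")
    reads = list(reads)
    state = IterationState(
        round=0, seed_sequence=seed_nt, mapped_read_ids=frozenset(),
        consensus=seed_nt, converged=False,
    )
    if not reads:
        state.converged = True
        state.log.append("round 0: no reads; consensus = seed")
        return state

    aligner = make_nt_aligner(params)
    seen_sets: set[frozenset] = set()
    consensus = seed_nt
    for rnd in range(1, max_rounds + 1):
        alignments = []
        for read in reads:
            res = _best_alignment(aligner, read, consensus, params)
            if res is not None:
                alignments.append((read.id, *res))
        mapped_ids = frozenset(rid for rid, *_ in alignments)
        counts = np.zeros((len(consensus), 4), dtype=np.int32)
        left_ext = ""
        right_ext = ""
        left_key = right_key = None
        for rid, seq, qb, sb in alignments:
            for (qs, qe), (ss, se) in zip(qb, sb):
                for off, base in enumerate(seq[qs:qe]):
                    idx = _BASE_INDEX.get(base)
                    if idx is not None:
                        counts[ss + off, idx] += 1
            if extend_ends:
                lead, tail = qb[0][0], len(seq) - qb[-1][1]
                if sb[0][0] == 0 and lead >= min_overhang:
                    if left_key is None or lead > left_key[0] or (
                        lead == left_key[0] and rid < left_key[1]
                    ):
                        left_key = (lead, rid)
                        left_ext = seq[:lead]
                if sb[-1][1] == len(consensus) and tail >= min_overhang:
                    if right_key is None or tail > right_key[0] or (tail == right_key[0] and rid < right_key[1]):
                        right_key = (tail, rid)
                        right_ext = seq[qb[-1][1]:]
        covered = counts.sum(axis=1) > 0
        maj = counts.argmax(axis=1)
        new = [
            _BASE_ORDER[maj[i]] if covered[i] else consensus[i]
            for i in range(len(consensus))
        ]
        new_consensus = left_ext + "".join(new) + right_ext
        state.log.append(
            f"round {rnd}: {len(mapped_ids)} reads mapped, consensus "
            f"{len(new_consensus)} bp"
            + (f" (+{len(left_ext)}/+{len(right_ext)} end extension)"
               if left_ext or right_ext else "")
        )
        state.round = rnd
        state.mapped_read_ids = mapped_ids
        state.consensus = new_consensus
        if mapped_ids in seen_sets:
            state.converged = True
            break
        seen_sets.add(mapped_ids)
        consensus = new_consensus
    return state
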