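"""MEGAN-style lowest-common-ancestor (LCA) taxonomic assignment.

Each read's qualifying hits are the top-scoring ones within a fraction
of the best bit score (default: strictly more than 90% of the top hit),
truncated to a maximum count (default 5, counting the top hit) by
descending score; the read is assigned to the lowest taxonomy node
ancestral to all of them.  The truncation happens after the score
filter, mirroring the reference implementation's documented behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .io_formats import TaxonomyNode
from .homology_search import ReadHit

__all__ = ["Taxonomy", "LcaParams", "assign_lca", "summarize_taxa"]


class Taxonomy:
    """A rooted taxonomy over string node ids.

    Exactly one root (its parent is itself); cycles are rejected at
    construction.
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: dict[str, TaxonomyNode] = {}
        for n in nodes:
            if n.taxid in self.nodes:
                raise ValueError(f"duplicate taxid {n.taxid!r}")
            self.nodes[n.taxid] = n
        roots = [t for t, n in self.nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._depth: dict[str, int] = {self.root: 0}
        for taxid in self.nodes:
            self._resolve_depth(taxid)

    def _resolve_depth(self, taxid: str) -> int:
        if taxid in self._depth:
            return self._depth[taxid]
        seen = []
        t = taxid
        while t not in self._depth:
            if t not in self.nodes:
                raise ValueError(f"parent chain leaves the taxonomy at {t!r}")
            if t in seen:
                raise ValueError(f"cycle in taxonomy involving {t!r}")
            seen.append(t)
            t = self.nodes[t].parent
        d = self._depth[t]
        for s in reversed(seen):
            d += 1
            self._depth[s] = d
        return self._depth[taxid]

    def __contains__(self, taxid: str) -> bool:
        return taxid in self.nodes

    def depth(self, taxid: str) -> int:
        return self._depth[taxid]

    def parent(self, taxid: str) -> str:
        return self.nodes[taxid].parent

    def lineage(self, taxid: str) -> list[str]:
        """Root-to-node path of taxids."""
        path = [taxid]
        while taxid != self.root:
            taxid = self.nodes[taxid].parent
            path.append(taxid)
        return path[::-1]

    def name(self, taxid: str) -> str:
        return self.nodes[taxid].name

    def ancestor_at_rank(self, taxid: str, rank: str) -> Optional[str]:
        for t in self.lineage(taxid):
            if self.nodes[t].rank == rank:
                return t
        return None

    def is_ancestor(self, ancestor: str, taxid: str) -> bool:
        return ancestor in self.lineage(taxid)

    def lca(self, taxids: Sequence[str]) -> str:
        """Lowest common ancestor of one or more nodes."""
        if not taxids:
            raise ValueError("lca of empty set")
        common = None
        for t in taxids:
            if t not in self.nodes:
                raise KeyError(f"taxid {t!r} not in taxonomy")
            path = self.lineage(t)
            if common is None:
                common = path
            else:
                k = 0
                while k < min(len(common), len(path)) and common[k] == path[k]:
                    k += 1
                common = common[:k]
        return common[-1]


@dataclass(frozen=True)
class LcaParams:
    max_hits: int = 5  # counts the top hit itself
    min_score_fraction: float = 0.90  # of the top bit score
    strict: bool = True  # strict: score must exceed the fraction; else >=

    def __post_init__(self) -> None:
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if not 0 < self.min_score_fraction <= 1:
            raise ValueError("min_score_fraction must be in (0, 1]")


HitLike = Union[ReadHit, tuple]


def _as_pairs(hits: Iterable[HitLike]) -> list[tuple[str, float]]:
    pairs = []
    for h in hits:
        if isinstance(h, ReadHit):
            pairs.append((h.subject_id, h.bit_score))
        else:
            subject, score = h
            pairs.append((str(subject), float(score)))
    return pairs


def assign_lca(
    read_hits: Iterable[HitLike],
    subject_to_taxid: Mapping[str, str],
    taxonomy: Taxonomy,
    params: LcaParams = LcaParams(),
) -> str:
    """Assign one read to the LCA of its qualifying hits.

    ``read_hits`` is the read's hit list (ReadHit objects or
    (subject_id, bit_score) pairs).  Every subject must map to a
    taxonomy node.  The best hit always qualifies, so the candidate set
    is never empty.
    """
    pairs = _as_pairs(read_hits)
    if not pairs:
        raise ValueError("assign_lca called with no hits")
    for subject, _ in pairs:
        if subject not in subject_to_taxid:
            raise KeyError(f"subject {subject!r} has no taxonomy mapping")
        if subject_to_taxid[subject] not in taxonomy:
            raise KeyError(f"taxid for subject {subject!r} not in taxonomy")
    pairs.sort(key=lambda p: (-p[1], p[0]))
    top = pairs[0][1]
    threshold = params.min_score_fraction * top
    if params.strict:
        qualifying = [p for p in pairs if p[1] > threshold or p[1] == top]
    else:
        qualifying = [p for p in pairs if p[1] >= threshold]
    qualifying = qualifying[: params.max_hits]
    return taxonomy.lca([subject_to_taxid[s] for s, _ in qualifying])


def summarize_taxa(
    assignments: Mapping[str, Sequence[str]],
    taxonomy: Taxonomy,
    min_fraction: float = 0.01,
    rank: Optional[str] = None,
) -> pd.DataFrame:
    """Per-group read fractions across datasets.

    ``assignments`` maps dataset name -> per-read taxids.  When ``rank``
    is given, each taxid is collapsed to its ancestor at that rank
    (reads with no ancestor at the rank keep their own node's name).
    Groups below ``min_fraction`` in every dataset are pooled into
    ``"other"``; per-dataset fractions (groups + other) sum to 1.
    """
    if not assignments or all(len(v) == 0 for v in assignments.values()):
        raise ValueError("no assignments to summarize")
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for dataset, taxids in assignments.items():
        totals[dataset] = len(taxids)
        for t in taxids:
            if rank is not None:
                anc = taxonomy.ancestor_at_rank(t, rank)
                group = taxonomy.name(anc) if anc else taxonomy.name(t)
            else:
                group = taxonomy.name(t)
            counts.setdefault(group, {}).setdefault(dataset, 0)
            counts[group][dataset] += 1
    datasets = list(assignments)
    rows = {}
    other = {d: 0.0 for d in datasets}
    for group, per in sorted(counts.items()):
        fracs = {d: per.get(d, 0) / totals[d] if totals[d] else 0.0 for d in datasets}
        if max(fracs.values()) > min_fraction:
            rows[group] = fracs
        else:
            for d in datasets:
                other[d] += fracs[d]
    rows["other"] = other
    return pd.DataFrame(rows).T[datasets]
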