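"""Two-database BLAST-score-ratio (BSR) screening.

The core statistic: for every read with a hit to the curated marker
database, the ratio of its best custom-database bit score to its best
background-database (NR-proxy) bit score.  Reads with no background hit
at all are kept -- sequences with low similarity to both databases are
treated as true but divergent positives -- while reads scoring much
better against the background are discarded as false positives.  Each
family carries its own cutoff (kept iff ratio >= cutoff, boundary
inclusive); families curated by eye in the original workflow are modeled
with a ``MANUAL`` sentinel whose records are flagged for review and can
be decided reproducibly through a keep-list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence, Set, Union

import numpy as np

from .homology_search import ReadHit, SearchResult

__all__ = [
    "MANUAL",
    "KEEP_NO_BACKGROUND",
    "BsrRecord",
    "FamilyCutoffs",
    "DEFAULT_CUTOFFS",
    "assign_families",
    "compute_bsr",
    "apply_cutoff",
    "bsr_scatter_data",
    "screen",
]

MANUAL = "manual"
#: Ratio sentinel for reads with no background hit (always kept by numeric cutoffs).
KEEP_NO_BACKGROUND = math.inf

Cutoff = Union[float, str]

# Packaged per-family defaults for the two study datasets ("upper" = the
# suboxic upper station, "core" = the anoxic core station).  '#'-style
# manually-checked families carry the MANUAL sentinel.  nxrA's cutoff is
# the second-round threshold used to separate nxrA from narG.
DEFAULT_CUTOFFS: dict[str, dict[str, Cutoff]] = {
    "nifH": {"upper": MANUAL, "core": MANUAL},
    "amoA": {"upper": MANUAL, "core": MANUAL},
    "hao": {"upper": MANUAL, "core": 0.75},
    "nxrA": {"upper": 0.85, "core": 0.85},
    "narG": {"upper": 0.5, "core": 0.5},
    "nirK": {"upper": 0.55, "core": 0.55},
    "nirS": {"upper": MANUAL, "core": 0.6},
    "norB/norZ": {"upper": 0.8, "core": 0.8},
    "nosZ": {"upper": 0.8, "core": 0.75},
    "nrfA": {"upper": MANUAL, "core": MANUAL},
    "hzsA": {"upper": MANUAL, "core": 0.75},
    "mcrA": {"upper": MANUAL, "core": MANUAL},
    "mmoX": {"upper": MANUAL, "core": MANUAL},
    "pmoA": {"upper": MANUAL, "core": MANUAL},
    "mpnS": {"upper": MANUAL, "core": MANUAL},
    "phnGHI": {"upper": MANUAL, "core": MANUAL},
}


@dataclass
class FamilyCutoffs:
    """Per-family BSR cutoffs for one dataset."""

    cutoffs: dict[str, Cutoff]

    @classmethod
    def defaults(cls, dataset: str) -> "FamilyCutoffs":
        return cls({fam: per[dataset] for fam, per in DEFAULT_CUTOFFS.items()})

    def get(self, family: str) -> Cutoff:
        if family not in self.cutoffs:
            raise KeyError(f"no BSR cutoff configured for family {family!r}")
        return self.cutoffs[family]


@dataclass(frozen=True)
class BsrRecord:
    read_id: str
    family: str
    custom_score: float
    background_score: Optional[float]
    ratio: float  # KEEP_NO_BACKGROUND (inf) when background absent
    decision: str = "undecided"  # kept | discarded | flagged_manual | undecided


def assign_families(
    custom: SearchResult, subject_to_family: Mapping[str, str]
) -> dict[str, tuple[str, ReadHit]]:
    """Assign each custom-positive read to the family of its single best hit.

    One decision per read; the best hit's tie-break (bit score, then
    E-value, then subject id) makes the assignment deterministic.
    """
    out: dict[str, tuple[str, ReadHit]] = {}
    for rid in custom.hits:
        best = custom.best(rid)
        fam = subject_to_family.get(best.subject_id)
        if fam is None:
            raise KeyError(f"subject {best.subject_id!r} has no family mapping")
        out[rid] = (fam, best)
    return out


def compute_bsr(
    read_id: str,
    family: str,
    custom_score: float,
    background_score: Optional[float],
) -> BsrRecord:
    """Build an undecided BSR record from the two best bit scores."""
    if custom_score <= 0:
        raise ValueError(f"{read_id}: nonpositive custom score")
    if background_score is None:
        return BsrRecord(read_id, family, custom_score, None, KEEP_NO_BACKGROUND)
    if background_score <= 0:
        raise ValueError(f"{read_id}: nonpositive background score")
    return BsrRecord(
        read_id, family, custom_score, background_score,
        custom_score / background_score,
    )


def apply_cutoff(
    records: Iterable[BsrRecord],
    cutoffs: FamilyCutoffs,
    keep_list: Optional[Set[str]] = None,
) -> list[BsrRecord]:
    """Decide records against per-family cutoffs.

    Numeric cutoff: kept iff ratio >= cutoff (the no-background sentinel
    always passes).  MANUAL: flagged for review, unless a ``keep_list``
    of read ids is supplied, which decides them reproducibly.
    """
    decided = []
    for rec in records:
        cut = cutoffs.get(rec.family)
        if cut == MANUAL:
            if keep_list is not None:
                decision = "kept" if rec.read_id in keep_list else "discarded"
            else:
                decision = "flagged_manual"
        else:
            decision = "kept" if rec.ratio >= float(cut) else "discarded"
        decided.append(replace(rec, decision=decision))
    return decided


@dataclass
class ScatterData:
    """Arrays for the diagnostic scatter (background vs custom score) and
    ratio histogram; reads with no background hit sit on the y-axis margin
    (x = 0)."""

    x: np.ndarray
    y: np.ndarray
    ratios: np.ndarray  # finite ratios only
    no_background: np.ndarray  # bool mask aligned with x/y
    read_ids: list[str]


def bsr_scatter_data(records: Sequence[BsrRecord]) -> ScatterData:
    if not records:
        raise ValueError("no BSR records")
    x = np.array(
        [r.background_score if r.background_score is not None else 0.0 for r in records]
    )
    y = np.array([r.custom_score for r in records])
    nb = np.array([r.background_score is None for r in records])
    ratios = np.array([r.ratio for r in records if math.isfinite(r.ratio)])
    return ScatterData(x=x, y=y, ratios=ratios, no_background=nb,
                       read_ids=[r.read_id for r in records])


def screen(
    custom: SearchResult,
    background: SearchResult,
    subject_to_family: Mapping[str, str],
    cutoffs: FamilyCutoffs,
    keep_list: Optional[Set[str]] = None,
) -> list[BsrRecord]:
    """Full BSR pass: family assignment, ratio, per-family decision."""
    assignments = assign_families(custom, subject_to_family)
    records = []
    for rid, (fam, best) in sorted(assignments.items()):
        bg_best = background.best(rid)
        records.append(
            compute_bsr(rid, fam, best.bit_score,
                        bg_best.bit_score if bg_best else None)
        )
    return apply_cutoff(records, cutoffs, keep_list=keep_list)
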