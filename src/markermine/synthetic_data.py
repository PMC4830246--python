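"""Mock communities, reference sets with decoys, and reads with ground truth.

The generator emulates the statistical structure the screening pipeline
assumes: a set of community members (each a genome of neutral sequence
with marker genes embedded at known coordinates), curated amino-acid
reference sets for each marker family, and "decoy" reference sets --
homologous-but-off-target proteins derived from the targets by point
substitution -- which play the role of the background (NR-proxy)
database.  Every simulated read carries a truth label, so downstream
keep/discard decisions can be scored exactly.

Marker templates are stored as amino acids and back-translated into the
genomes with the standard genetic code; synonymous codons are sampled
uniformly (seeded), so distinct homologs diverge at silent sites just as
real paralogs do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np

from .io_formats import Read

__all__ = [
    "GenePayload",
    "CommunityMember",
    "CommunityProfile",
    "TruthRow",
    "CommunityRealization",
    "make_reference_set",
    "mutate_protein",
    "mutate_nt",
    "back_translate",
    "random_protein",
    "realize_community",
    "simulate_reads",
    "evaluate_against_truth",
    "PrecisionRecall",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BACKGROUND = "background"

# Standard code, sense codons only (translation table 11 for bacteria;
# identical to table 1 on sense codons).
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_CODE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_CODE):
    if _aa == "*":
        continue
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    _CODONS.setdefault(_aa, []).append(_codon)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``divergence`` to a different residue."""
    if not 0 <= divergence <= 1:
        raise ValueError(f"divergence {divergence} outside [0, 1]")
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < divergence)
    for i in hits:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform sampling over synonymous codons."""
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def mutate_nt(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each nucleotide with probability ``divergence``."""
    if not 0 <= divergence <= 1:
        raise ValueError(f"divergence {divergence} outside [0, 1]")
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < divergence):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def make_reference_set(
    family: str,
    n_targets: int,
    n_decoys: int,
    target_divergence: float,
    decoy_divergence: float,
    seed: int,
    length: int = 350,
    ancestor: Optional[str] = None,
) -> tuple[dict[str, str], dict[str, str]]:
    """Build a (targets, decoys) pair of amino-acid reference sets.

    Targets are drawn around a family ancestor at ``target_divergence``;
    decoys are derived from the targets by point substitution at
    ``decoy_divergence``, making them homologous-but-off-target.
    Deterministic under ``seed``.
    """
    if n_targets < 1 or n_decoys < 1:
        raise ValueError("n_targets and n_decoys must be >= 1")
    for d in (target_divergence, decoy_divergence):
        if not 0 <= d <= 1:
            raise ValueError(f"divergence {d} outside [0, 1]")
    rng = np.random.default_rng(seed)
    if ancestor is None:
        ancestor = random_protein(length, rng)
    targets = {
        f"{family}_t{i:02d}": mutate_protein(ancestor, target_divergence, rng)
        for i in range(n_targets)
    }
    target_seqs = list(targets.values())
    decoys = {
        f"{family}_d{i:02d}": mutate_protein(
            target_seqs[i % n_targets], decoy_divergence, rng
        )
        for i in range(n_decoys)
    }
    return targets, decoys


# ---------------------------------------------------------------------------
# Community model


@dataclass(frozen=True)
class GenePayload:
    """A gene carried by a community member.

    ``label`` is the truth label its reads receive (a marker family name,
    or any other string -- e.g. ``"decoy:nirK"`` -- which the evaluator
    treats as a negative).  Either an amino-acid ``protein`` (back-
    translated at realization time) or an explicit nucleotide ``nt``
    realization may be given; passing ``nt`` keeps silent sites shared
    with a related reference, as for genes that diverged at the
    nucleotide level.
    """

    label: str
    protein: Optional[str] = None
    nt: Optional[str] = None
    copies: int = 1

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copy number must be a non-negative integer")
        if (self.protein is None) == (self.nt is None):
            raise ValueError("give exactly one of protein or nt")
        if self.nt is not None and len(self.nt) % 3:
            raise ValueError("nt payload length must be a multiple of 3")

    @property
    def nt_length(self) -> int:
        return 3 * len(self.protein) if self.protein is not None else len(self.nt)


@dataclass(frozen=True)
class CommunityMember:
    label: str
    lineage: tuple[str, ...]
    abundance: float
    genome_size: int
    payload: tuple[GenePayload, ...] = ()

    def payload_bp(self) -> int:
        return sum(g.nt_length * g.copies for g in self.payload)

    def __post_init__(self) -> None:
        if self.genome_size < self.payload_bp():
            raise ValueError(
                f"{self.label}: genome_size {self.genome_size} smaller than "
                f"payload ({self.payload_bp()} bp)"
            )


@dataclass(frozen=True)
class CommunityProfile:
    members: tuple[CommunityMember, ...]
    background_fraction: float = 0.0
    background_genome_size: int = 50_000

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("community profile has no members")
        total = sum(m.abundance for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"member abundances sum to {total}, expected 1")
        if not 0 <= self.background_fraction < 1:
            raise ValueError("background_fraction must be in [0, 1)")


@dataclass(frozen=True)
class TruthRow:
    taxon: str
    origin: str
    start: int  # genome coordinates of the read, 0-based half-open
    end: int


@dataclass
class CommunityRealization:
    """Concrete genomes for a profile: sequence plus gene feature intervals."""

    profile: CommunityProfile
    genomes: Dict[str, str]
    features: Dict[str, list[tuple[str, int, int]]]  # member -> (label, start, end)

    def gene_bp(self, label: str) -> int:
        return sum(
            e - s
            for feats in self.features.values()
            for lab, s, e in feats
            if lab == label
        )


def _random_nt(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def realize_community(
    profile: CommunityProfile, seed: int
) -> CommunityRealization:
    """Build concrete genome sequences with genes embedded at seeded positions."""
    rng = np.random.default_rng(seed)
    genomes: Dict[str, str] = {}
    features: Dict[str, list[tuple[str, int, int]]] = {}
    for member in profile.members:
        genes: list[tuple[str, str]] = []
        for pay in member.payload:
            nt = pay.nt if pay.nt is not None else back_translate(pay.protein, rng)
            for _ in range(pay.copies):
                genes.append((pay.label, nt))
        gene_bp = sum(len(nt) for _, nt in genes)
        spare = member.genome_size - gene_bp
        # Genes separated by random spacers covering the spare length.
        cuts = np.sort(rng.integers(0, spare + 1, size=len(genes))) if genes else []
        parts: list[str] = []
        feats: list[tuple[str, int, int]] = []
        prev = 0
        pos = 0
        for (label, nt), cut in zip(genes, cuts):
            spacer = _random_nt(int(cut) - prev, rng)
            prev = int(cut)
            parts.append(spacer)
            pos += len(spacer)
            feats.append((label, pos, pos + len(nt)))
            parts.append(nt)
            pos += len(nt)
        parts.append(_random_nt(spare - prev, rng))
        genomes[member.label] = "".join(parts)
        features[member.label] = feats
        assert len(genomes[member.label]) == member.genome_size
    if profile.background_fraction > 0:
        genomes[BACKGROUND] = _random_nt(profile.background_genome_size, rng)
        features[BACKGROUND] = []
    return CommunityRealization(profile, genomes, features)


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_reads(
    profile: CommunityProfile,
    n_reads: int,
    length_mean: float = 230.0,
    length_sd: float = 25.0,
    error_rate: float = 0.01,
    seed: int = 0,
    min_length: int = 110,
    mean_quality: float = 30.0,
    realization: Optional[CommunityRealization] = None,
    truth_overlap: float = 0.5,
) -> tuple[list[Read], dict[str, TruthRow]]:
    """Simulate shotgun reads with per-read ground truth.

    Reads are drawn from member genomes proportionally to
    abundance x genome_size (plus ``background_fraction`` of reads from a
    neutral genome), from a uniformly random position and strand.  A read
    whose overlap with an embedded gene covers at least ``truth_overlap``
    of its length receives that gene's label as truth origin; all other
    reads are labeled ``"background"``.  Errors are i.i.d. substitutions
    at ``error_rate`` plus rare 1-bp indels at a tenth of that rate.
    Fully deterministic under ``seed``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    if realization is None:
        realization = realize_community(profile, seed=int(rng.integers(2**31)))
    members = list(profile.members)
    weights = np.array(
        [m.abundance * m.genome_size for m in members], dtype=float
    )
    weights /= weights.sum()
    labels = [m.label for m in members]
    bg = profile.background_fraction
    indel_rate = error_rate / 10.0
    bases = np.array(list("ACGT"))

    reads: list[Read] = []
    truth: dict[str, TruthRow] = {}
    member_draw = rng.random(n_reads)
    member_idx = rng.choice(len(members), size=n_reads, p=weights)
    lengths = np.clip(
        rng.normal(length_mean, length_sd, size=n_reads).round().astype(int),
        min_length,
        None,
    )
    for i in range(n_reads):
        taxon = BACKGROUND if (bg > 0 and member_draw[i] < bg) else labels[member_idx[i]]
        genome = realization.genomes[taxon]
        length = min(int(lengths[i]), len(genome))
        start = int(rng.integers(0, len(genome) - length + 1))
        end = start + length
        frag = genome[start:end]

        origin = BACKGROUND
        best_overlap = 0
        for label, gs, ge in realization.features.get(taxon, ()):
            overlap = min(end, ge) - max(start, gs)
            if overlap > best_overlap:
                best_overlap = overlap
                if overlap >= truth_overlap * length:
                    origin = label
        if origin == BACKGROUND and best_overlap < truth_overlap * length:
            origin = BACKGROUND

        seq = np.array(list(frag))
        sub_mask = rng.random(length) < error_rate
        for j in np.flatnonzero(sub_mask):
            alt = [b for b in "ACGT" if b != seq[j]]
            seq[j] = alt[rng.integers(3)]
        out = "".join(seq)
        n_indels = rng.poisson(indel_rate * length)
        for _ in range(n_indels):
            pos = int(rng.integers(0, len(out)))
            if rng.random() < 0.5 and len(out) > min_length:
                out = out[:pos] + out[pos + 1 :]
            else:
                out = out[:pos] + str(bases[rng.integers(4)]) + out[pos:]
        if rng.random() < 0.5:
            out = _revcomp(out)
        quals = tuple(
            np.clip(
                rng.normal(mean_quality, 3.0, size=len(out)).round().astype(int), 2, 40
            )
        )
        rid = f"read_{i:07d}"
        reads.append(Read(id=rid, seq=out, quals=quals, truth=origin))
        truth[rid] = TruthRow(taxon=taxon, origin=origin, start=start, end=end)
    return reads, truth


# ---------------------------------------------------------------------------
# Scoring decisions against truth


@dataclass(frozen=True)
class PrecisionRecall:
    precision: Optional[float]
    recall: Optional[float]
    tp: int
    fp: int
    fn: int


def evaluate_against_truth(
    decisions: Mapping[str, str],
    truth: Mapping[str, TruthRow],
    families: Optional[Sequence[str]] = None,
    label_to_family: Optional[Mapping[str, str]] = None,
) -> dict[str, PrecisionRecall]:
    """Per-family precision/recall of kept-read family assignments.

    ``decisions`` maps read id -> assigned family for every *kept* read.
    Truth labels may be finer than screen families (e.g. ``hao`` and
    ``hdh`` both belong to a combined ``hao_hdh`` set); pass
    ``label_to_family`` to collapse them.  Families with zero truth reads
    report recall as None (undefined).
    """
    unknown = set(decisions) - set(truth)
    if unknown:
        raise KeyError(f"decisions reference unknown read ids: {sorted(unknown)[:5]}")

    def fam_of(label: str) -> str:
        if label_to_family is not None:
            return label_to_family.get(label, label)
        return label

    if families is None:
        families = sorted(
            {fam_of(t.origin) for t in truth.values() if t.origin != BACKGROUND}
            | set(decisions.values())
        )
    result = {}
    for fam in families:
        tp = fp = fn = 0
        for rid, row in truth.items():
            true_fam = fam_of(row.origin)
            called = decisions.get(rid)
            if called == fam and true_fam == fam:
                tp += 1
            elif called == fam and true_fam != fam:
                fp += 1
            elif called != fam and true_fam == fam:
                fn += 1
        precision = tp / (tp + fp) if tp + fp else None
        recall = tp / (tp + fn) if tp + fn else None
        result[fam] = PrecisionRecall(precision, recall, tp, fp, fn)
    return result
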