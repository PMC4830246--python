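"""Read-count normalization and abundance estimation.

Raw marker read counts are normalized by gene length and library size
(reads per kilobase of gene per million metagenome reads) and expressed
as a fraction of the normalized count of the single-copy RNA polymerase
beta-subunit gene (rpoB), which stands in for "one per genome".  No
copy-number correction is applied: genes with multiple paralogs per
genome (e.g. the anammox octaheme proteins) can legitimately exceed a
fraction of 1, and this is a documented caveat rather than a bug.

A simple detection-limit estimator converts an observed read count into
an abundance estimate: if every genome (assumed ~3 Mbp) carried the gene
(e.g. the 900 bp nitrogenase marker nifH), ``total_reads x gene/genome``
reads would be expected; the ratio of observed to expected is the
fraction of the community carrying the gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "normalize_count",
    "fraction_of_rpob",
    "estimate_detection_abundance",
    "DetectionEstimate",
    "abundance_table",
    "median_reference_length_bp",
]


def normalize_count(raw_count: int, gene_length_bp: float, total_reads: int) -> float:
    """Normalized read count = raw x 1,000 bp x 1e6 reads / (gene length x total reads).

    Units: reads per kb of gene per million metagenome reads.
    """
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be > 0")
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if raw_count < 0:
        raise ValueError("raw_count must be >= 0")
    return raw_count * 1_000.0 * 1_000_000.0 / (gene_length_bp * total_reads)


def fraction_of_rpob(family_normalized: float, rpob_normalized: float) -> float:
    """Family abundance as a fraction of normalized rpoB.

    May exceed 1 for multi-copy genes.  A zero rpoB denominator is an
    error: without the single-copy reference the fraction is undefined
    (check that rpoB was screened and that its reads survived QC).
    """
    if rpob_normalized <= 0:
        raise ValueError(
            "normalized rpoB count is zero; the per-genome reference is "
            "undefined (was rpoB included in the screen?)"
        )
    if family_normalized < 0:
        raise ValueError("family_normalized must be >= 0")
    return family_normalized / rpob_normalized


@dataclass(frozen=True)
class DetectionEstimate:
    expected_reads: float  # reads expected if every genome carried the gene
    fold_lower: float  # expected / observed; inf when observed == 0
    abundance_percent: float  # 100 x observed / expected


def estimate_detection_abundance(
    observed_reads: int,
    total_reads: int,
    gene_length_bp: float = 900.0,
    genome_size_bp: float = 3_000_000.0,
) -> DetectionEstimate:
    """Abundance of gene carriers implied by an observed read count.

    expected = (gene_length / genome_size) x total_reads; with the
    defaults (900 bp gene, 3 Mbp genome) that is 3 reads per 10,000
    sequenced.
    """
    if gene_length_bp <= 0 or genome_size_bp <= 0 or total_reads <= 0:
        raise ValueError("gene length, genome size and total reads must be > 0")
    if observed_reads < 0:
        raise ValueError("observed_reads must be >= 0")
    expected = gene_length_bp / genome_size_bp * total_reads
    if expected == 0:
        raise ValueError("expected read count is zero")
    fold = math.inf if observed_reads == 0 else expected / observed_reads
    percent = 100.0 * observed_reads / expected
    return DetectionEstimate(expected, fold, percent)


def median_reference_length_bp(reference_aa: Mapping[str, str]) -> float:
    """Median ungapped reference length in bp (amino acids x 3)."""
    if not reference_aa:
        raise ValueError("empty reference set")
    lengths = sorted(3 * len(s.replace("-", "")) for s in reference_aa.values())
    n = len(lengths)
    mid = n // 2
    return float(lengths[mid]) if n % 2 else (lengths[mid - 1] + lengths[mid]) / 2.0


def abundance_table(
    counts: Mapping[str, int],
    gene_lengths_bp: Mapping[str, float],
    total_reads: int,
    dataset: str,
    rpob_family: str = "rpoB",
) -> pd.DataFrame:
    """Per-family abundance table for one dataset.

    Columns mirror the supplementary count tables: raw count, gene
    length, total reads, normalized count, and fraction of normalized
    rpoB (NaN when rpoB is absent from ``counts``).
    """
    rows = []
    rpob_norm: Optional[float] = None
    if rpob_family in counts:
        rpob_norm = normalize_count(
            counts[rpob_family], gene_lengths_bp[rpob_family], total_reads
        )
    for family in counts:
        if family not in gene_lengths_bp:
            raise KeyError(f"no gene length for family {family!r}")
        norm = normalize_count(counts[family], gene_lengths_bp[family], total_reads)
        rows.append(
            {
                "family": family,
                "dataset": dataset,
                "raw_count": counts[family],
                "gene_length": gene_lengths_bp[family],
                "total_reads": total_reads,
                "normalized": norm,
                "rpob_fraction": (
                    fraction_of_rpob(norm, rpob_norm)
                    if rpob_norm and rpob_norm > 0
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
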