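"""Pileup allele counting over BAM alignments.

A thin layer over pysam's pileup engine that tabulates, per reference
position, the reference-matching depth and the depth of each alternative
allele. Alleles use a compact key scheme: SNV alts are the base itself
(``"C"``), insertions are ``"+SEQ"`` (sequence inserted after the anchor
base), deletions are ``"-N"`` (N reference bases deleted after the anchor).
``vcf_alleles`` converts a key to VCF-style (ref, alt) strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

import pysam

MAX_PILEUP_DEPTH = 1_000_000


@dataclass
class AllelicCount:
    """Allele tally at one 1-based reference position."""

    contig: str
    pos: int
    ref_base: str
    ref_count: int = 0
    alt_counts: dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return self.ref_count + sum(self.alt_counts.values())

    @property
    def best_alt(self) -> str | None:
        if not self.alt_counts:
            return None
        return max(self.alt_counts, key=lambda k: (self.alt_counts[k], k))

    @property
    def vaf(self) -> float:
        """Allele fraction of the highest-count alternative allele."""
        d = self.depth
        if d == 0 or not self.alt_counts:
            return 0.0
        return self.alt_counts[self.best_alt] / d

    def allele_fraction(self, key: str) -> float:
        d = self.depth
        return self.alt_counts.get(key, 0) / d if d else 0.0


def allele_key(ref: str, alt: str) -> str:
    """VCF-style (ref, alt) -> compact pileup key."""
    if len(ref) == 1 and len(alt) == 1:
        return alt
    if len(ref) == 1 and len(alt) > 1 and alt[0] == ref:
        return "+" + alt[1:]
    if len(alt) == 1 and len(ref) > 1 and ref[0] == alt:
        return "-" + str(len(ref) - 1)
    raise ValueError(f"unsupported allele pair {ref}>{alt}")


def vcf_alleles(contig: str, pos: int, key: str, ref_sequences: dict[str, str]) -> tuple[str, str]:
    """Compact pileup key -> VCF-style (ref, alt) at a 1-based position."""
    anchor = ref_sequences[contig][pos - 1]
    if key.startswith("+"):
        return anchor, anchor + key[1:]
    if key.startswith("-"):
        n = int(key[1:])
        return ref_sequences[contig][pos - 1 : pos + n], anchor
    return anchor, key


def _column_count(
    column: pysam.PileupColumn,
    contig: str,
    ref_seq: str,
    read_filter: Callable[[pysam.AlignedSegment], bool] | None,
) -> AllelicCount:
    pos = column.reference_pos + 1
    ref_base = ref_seq[column.reference_pos]
    ac = AllelicCount(contig=contig, pos=pos, ref_base=ref_base)
    for pr in column.pileups:
        read = pr.alignment
        if read.is_secondary or read.is_supplementary or read.is_unmapped:
            continue
        if read_filter is not None and not read_filter(read):
            continue
        if pr.is_refskip:
            continue
        if pr.is_del:
            # interior of a deletion; counted at its anchor column
            continue
        base = read.query_sequence[pr.query_position]
        if pr.indel > 0:
            ins = read.query_sequence[pr.query_position + 1 : pr.query_position + 1 + pr.indel]
            key = "+" + ins
            ac.alt_counts[key] = ac.alt_counts.get(key, 0) + 1
        elif pr.indel < 0:
            key = "-" + str(-pr.indel)
            ac.alt_counts[key] = ac.alt_counts.get(key, 0) + 1
        elif base == ref_base:
            ac.ref_count += 1
        else:
            ac.alt_counts[base] = ac.alt_counts.get(base, 0) + 1
    return ac


def count_at_sites(
    bam_path: str | Path,
    ref_sequences: dict[str, str],
    sites: Iterable[tuple[str, int]],
    read_filter: Callable[[pysam.AlignedSegment], bool] | None = None,
) -> dict[tuple[str, int], AllelicCount]:
    """Allele counts at specific (contig, 1-based pos) sites."""
    out: dict[tuple[str, int], AllelicCount] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        refs = set(bam.references)
        for contig, pos in sites:
            if contig not in refs or contig not in ref_sequences:
                out[(contig, pos)] = AllelicCount(contig, pos, "N")
                continue
            ac = AllelicCount(contig, pos, ref_sequences[contig][pos - 1])
            for column in bam.pileup(
                contig, pos - 1, pos, truncate=True,
                min_base_quality=0, max_depth=MAX_PILEUP_DEPTH, stepper="nofilter",
            ):
                ac = _column_count(column, contig, ref_sequences[contig], read_filter)
            out[(contig, pos)] = ac
    return out


def scan_columns(
    bam_path: str | Path,
    ref_sequences: dict[str, str],
    min_depth: int = 1,
    read_filter: Callable[[pysam.AlignedSegment], bool] | None = None,
) -> Iterator[AllelicCount]:
    """Iterate allele counts over every covered column of the alignment."""
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for contig in bam.references:
            if contig not in ref_sequences:
                continue
            ref_seq = ref_sequences[contig]
            for column in bam.pileup(
                contig, min_base_quality=0, max_depth=MAX_PILEUP_DEPTH, stepper="nofilter",
            ):
                if column.nsegments < min_depth:
                    continue
                yield _column_count(column, contig, ref_seq, read_filter)
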