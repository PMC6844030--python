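"""Built-in seed-and-extend read aligner for the synthetic genomes.

A deliberately small aligner sufficient for the package's simulated data:
exact k-mer seeding into a hash index, gapless extension scored by Hamming
distance, and an affine-gap rescue (Biopython PairwiseAligner) for reads
spanning indels. Affine gap costs keep indels contiguous and place them at a
consistent reference position regardless of where a read starts, so pileup
columns see one indel representation per event. The aligner emits
coordinate-sorted, indexed BAM with NM tags so downstream filters (which key
on mapping side and edit distance) behave as they would on production-aligner
output. Ties on edit distance are broken deterministically by (contig name,
position, strand).

Not a general-purpose aligner: no base-quality awareness, no clever MAPQ
model (60 unique / 0 tied), no split or clipped alignments.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam
from Bio import Align

from .simdata import revcomp


@dataclass(frozen=True)
class Placement:
    contig: str
    pos: int  # 0-based leftmost
    strand: str  # "+" | "-"
    cigar: str
    nm: int
    mapq: int


def _make_rescue_aligner() -> Align.PairwiseAligner:
    """Query-global / target-infix affine-gap aligner for gapped rescue."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -4
    a.extend_gap_score = -0.5
    a.end_insertion_score = 0.0  # free flanks on the reference window
    return a


def _path_to_cigar(alignment, query: str, target: str) -> tuple[int, str, int]:
    """(window offset, CIGAR, NM) from a PairwiseAligner path.

    NM counts mismatches inside aligned blocks plus all gap bases, i.e. the
    edit distance of the reported alignment.
    """
    t_blocks, q_blocks = alignment.aligned
    ops: list[tuple[str, int]] = []
    nm = 0
    start = int(t_blocks[0][0])
    first_q = int(q_blocks[0][0])
    if first_q > 0:  # query overhang beyond the window edge
        ops.append(("I", first_q))
        nm += first_q
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks.tolist(), q_blocks.tolist()):
        if prev_t is not None:
            if ts - prev_t:
                ops.append(("D", ts - prev_t))
                nm += ts - prev_t
            if qs - prev_q:
                ops.append(("I", qs - prev_q))
                nm += qs - prev_q
        ops.append(("M", te - ts))
        nm += sum(a != b for a, b in zip(target[ts:te], query[qs:qe]))
        prev_t, prev_q = te, qe
    trailing = len(query) - prev_q
    if trailing:
        ops.append(("I", trailing))
        nm += trailing
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return start, "".join(f"{n}{op}" for op, n in merged), nm


class ToyAligner:
    """Exact k-mer seed index over a reference, with affine-gap rescue."""

    def __init__(
        self,
        sequences: dict[str, str],
        k: int = 21,
        max_nm: int = 10,
        gapless_rescue_nm: int = 5,
    ):
        self.sequences = sequences
        self.contigs = sorted(sequences)
        self.k = k
        self.max_nm = max_nm
        self.gapless_rescue_nm = gapless_rescue_nm
        self._rescue = _make_rescue_aligner()
        self._arrays = {c: np.frombuffer(sequences[c].encode(), dtype=np.uint8) for c in self.contigs}
        self.index: dict[bytes, list[tuple[str, int]]] = {}
        for contig in self.contigs:
            raw = sequences[contig].encode()
            for pos in range(0, len(raw) - k + 1):
                self.index.setdefault(raw[pos : pos + k], []).append((contig, pos))

    def _candidates(self, seq: str) -> set[tuple[str, int]]:
        raw = seq.encode()
        k = self.k
        offsets = {0, max(0, (len(raw) - k) // 2), max(0, len(raw) - k)}
        cands: set[tuple[str, int]] = set()
        for off in offsets:
            for contig, hit in self.index.get(raw[off : off + k], ()):
                cands.add((contig, hit - off))
        return cands

    def align(self, seq: str) -> Placement | None:
        """Best placement of ``seq`` over both strands, or None if unmapped."""
        best: list[tuple[int, str, int, str, str]] = []  # (nm, contig, pos, strand, cigar)
        for strand in "+-":
            oriented = seq if strand == "+" else revcomp(seq)
            n = len(oriented)
            query = np.frombuffer(oriented.encode(), dtype=np.uint8)
            for contig, start in self._candidates(oriented):
                ref = self._arrays[contig]
                if start < 0 or start + n > len(ref):
                    continue
                nm = int((query != ref[start : start + n]).sum())
                cigar = f"{n}M"
                pos = start
                if nm > self.gapless_rescue_nm:
                    win_lo = max(0, start - 8)
                    window = self.sequences[contig][win_lo : start + n + 8]
                    aln = self._rescue.align(window, oriented)[0]
                    off, gapped_cigar, gapped_nm = _path_to_cigar(aln, oriented, window)
                    if gapped_nm < nm:
                        nm, pos, cigar = gapped_nm, win_lo + off, gapped_cigar
                if nm <= self.max_nm:
                    best.append((nm, contig, pos, strand, cigar))
        if not best:
            return None
        best.sort(key=lambda t: t[:4])
        nm, contig, pos, strand, cigar = best[0]
        unique = len(best) == 1 or best[1][0] > nm
        return Placement(contig, pos, strand, cigar, nm, 60 if unique else 0)


def align_fastq(
    reference: dict[str, str],
    fastq1: str | Path,
    fastq2: str | Path,
    out_bam: str | Path,
    k: int = 21,
    max_nm: int = 10,
) -> Path:
    """Align a read pair set to ``reference``; write sorted, indexed BAM."""
    aligner = ToyAligner(reference, k=k, max_nm=max_nm)
    out_bam = Path(out_bam)
    out_bam.parent.mkdir(parents=True, exist_ok=True)
    header = pysam.AlignmentHeader.from_references(
        aligner.contigs, [len(reference[c]) for c in aligner.contigs]
    )
    tid = {c: i for i, c in enumerate(aligner.contigs)}

    with tempfile.TemporaryDirectory() as tmp:
        unsorted = Path(tmp) / "unsorted.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam, \
                pysam.FastxFile(str(fastq1)) as h1, pysam.FastxFile(str(fastq2)) as h2:
            for e1, e2 in zip(h1, h2):
                placements = (aligner.align(e1.sequence), aligner.align(e2.sequence))
                segs = []
                for mate_i, (entry, pl) in enumerate(zip((e1, e2), placements)):
                    a = pysam.AlignedSegment(header)
                    a.query_name = entry.name
                    flag = 0x1 | (0x40 if mate_i == 0 else 0x80)
                    if pl is None:
                        flag |= 0x4
                        a.query_sequence = entry.sequence
                    else:
                        if pl.strand == "-":
                            flag |= 0x10
                            a.query_sequence = revcomp(entry.sequence)
                        else:
                            a.query_sequence = entry.sequence
                        a.reference_id = tid[pl.contig]
                        a.reference_start = pl.pos
                        a.mapping_quality = pl.mapq
                        a.cigarstring = pl.cigar
                        a.set_tag("NM", pl.nm)
                    mate = placements[1 - mate_i]
                    if mate is None:
                        flag |= 0x8
                    else:
                        if mate.strand == "-":
                            flag |= 0x20
                        a.next_reference_id = tid[mate.contig]
                        a.next_reference_start = mate.pos
                        if pl is not None and mate.contig == pl.contig:
                            flag |= 0x2
                    a.flag = flag
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(entry.sequence))
                    segs.append(a)
                for a in segs:
                    bam.write(a)
        pysam.sort("-o", str(out_bam), str(unsorted))
    pysam.index(str(out_bam))
    return out_bam
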