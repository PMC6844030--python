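"""Small BAM bookkeeping helpers shared across modules (pysam-based)."""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Iterable

import pysam

from .simdata import parse_origin


def is_primary(read: pysam.AlignedSegment) -> bool:
    return not (read.is_secondary or read.is_supplementary)


def check_coordinate_sorted(bam: pysam.AlignmentFile) -> None:
    so = (bam.header.get("HD") or {}).get("SO")
    if so != "coordinate":
        raise ValueError(f"alignment must be coordinate-sorted (SO={so!r})")


def sort_index(bam_in: str | Path, bam_out: str | Path | None = None) -> Path:
    bam_in = Path(bam_in)
    bam_out = Path(bam_out) if bam_out else bam_in.with_suffix(".sorted.bam")
    pysam.sort("-o", str(bam_out), str(bam_in))
    pysam.index(str(bam_out))
    return bam_out


def primary_read_ids(bam_path: str | Path) -> set[str]:
    """IDs of all fragments with a primary record (mapped or not)."""
    ids: set[str] = set()
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        for read in bam.fetch(until_eof=True):
            if is_primary(read):
                ids.add(read.query_name)
    return ids


def read_origin_labels(bam_path: str | Path) -> dict[str, str]:
    """Map read ID -> origin parsed from the read-name tag."""
    labels: dict[str, str] = {}
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        for read in bam.fetch(until_eof=True):
            if is_primary(read) and read.query_name not in labels:
                labels[read.query_name] = parse_origin(read.query_name)
    return labels


def fastq_read_ids(fastq: str | Path) -> list[str]:
    with pysam.FastxFile(str(fastq)) as fh:
        return [e.name for e in fh]


def subset_bam(bam_path: str | Path, read_ids: Iterable[str], out_bam: str | Path) -> Path:
    """Write the records whose ID is in ``read_ids``; sort and index."""
    wanted = set(read_ids)
    out_bam = Path(out_bam)
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as src, \
            tempfile.TemporaryDirectory() as tmp:
        unsorted = Path(tmp) / "subset.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", template=src) as dst:
            for read in src.fetch(until_eof=True):
                if read.query_name in wanted:
                    dst.write(read)
        pysam.sort("-o", str(out_bam), str(unsorted))
    pysam.index(str(out_bam))
    return out_bam


def merge_bams(bam_paths: list[str | Path], out_bam: str | Path) -> Path:
    out_bam = Path(out_bam)
    with tempfile.TemporaryDirectory() as tmp:
        merged = Path(tmp) / "merged.bam"
        pysam.merge("-f", str(merged), *[str(p) for p in bam_paths])
        pysam.sort("-o", str(out_bam), str(merged))
    pysam.index(str(out_bam))
    return out_bam


def mean_depth_table(
    bam_paths: list[str | Path], sites: Iterable[tuple[str, int]]
) -> dict[tuple[str, int], float]:
    """Mean per-sample read depth at each (contig, 1-based pos) site.

    Stands in for a cohort mean-coverage resource: the mean over the given
    alignments of the number of primary mapped reads covering the site.
    """
    sites = list(sites)
    totals = {s: 0 for s in sites}
    handles = [pysam.AlignmentFile(str(p)) for p in bam_paths]
    try:
        for contig, pos in sites:
            for bam in handles:
                if contig not in bam.references:
                    continue
                n = bam.count(contig, pos - 1, pos, read_callback=is_primary)
                totals[(contig, pos)] += n
    finally:
        for bam in handles:
            bam.close()
    n_samples = len(bam_paths)
    return {s: totals[s] / n_samples for s in sites}


def write_depth_table(table: dict[tuple[str, int], float], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("contig\tpos\tmean_depth\n")
        for (contig, pos), depth in sorted(table.items()):
            fh.write(f"{contig}\t{pos}\t{depth:.4f}\n")
    return path


def read_depth_table(path: str | Path) -> dict[tuple[str, int], float]:
    table: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig"):
            raise ValueError("depth table must have a contig/pos/mean_depth header")
        for line in fh:
            contig, pos, depth = line.rstrip("\n").split("\t")
            table[(contig, int(pos))] = float(depth)
    return table
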