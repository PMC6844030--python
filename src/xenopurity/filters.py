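"""Read-filtering methods for contaminated alignments.

Three reference-based strategies for removing contaminant reads from a mixed
sample, all operating on read IDs so that both mates of a flagged fragment
are removed together:

* **ConcatRef** — align once to a concatenated host+contaminant reference
  and drop every fragment whose primary alignment lands on a contaminant
  contig. Tie placement (identical score on both sides) is left to the
  upstream aligner's primary designation.
* **DualRef-S (strict)** — align to both references separately and drop every
  fragment that maps to the contaminant reference at all. Maximally
  sensitive, can sacrifice many host reads in conserved regions.
* **DualRef-L (lenient)** — drop only fragments whose contaminant alignment
  is perfect (NM tag 0). By construction its removal set is a subset of
  DualRef-S's.

Secondary and supplementary records never trigger removal; only primary
placements count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .samutils import is_primary, sort_index

CONTAMINANT_PREFIX = "mm_"


@dataclass
class FilterOutcome:
    """Partition of a mixed sample's fragment IDs into retained/removed."""

    retained_ids: set[str]
    removed_ids: set[str]
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        overlap = self.retained_ids & self.removed_ids
        if overlap:
            raise ValueError(f"{len(overlap)} read IDs both retained and removed")

    @property
    def all_ids(self) -> set[str]:
        return self.retained_ids | self.removed_ids


# ---------------------------------------------------------------------------
# ConcatRef

def build_concat_reference(
    host_sequences: dict[str, str],
    contaminant_sequences: dict[str, str],
    prefix: str = CONTAMINANT_PREFIX,
) -> tuple[dict[str, str], dict[str, str]]:
    """Concatenate host and contaminant references in series.

    Contaminant contigs are renamed with ``prefix`` so names stay unique.
    Returns (combined sequences, origin map contig -> 'host'/'contaminant').
    """
    combined = dict(host_sequences)
    origin_map = {c: "host" for c in host_sequences}
    for contig, seq in contaminant_sequences.items():
        name = prefix + contig
        if name in combined:
            raise ValueError(f"contig name collision after prefixing: {name}")
        combined[name] = seq
        origin_map[name] = "contaminant"
    return combined, origin_map


def split_concat_reference(
    combined: dict[str, str], origin_map: dict[str, str], prefix: str = CONTAMINANT_PREFIX
) -> tuple[dict[str, str], dict[str, str]]:
    """Inverse of ``build_concat_reference``."""
    host = {c: s for c, s in combined.items() if origin_map[c] == "host"}
    contaminant = {
        c[len(prefix):] if c.startswith(prefix) else c: s
        for c, s in combined.items() if origin_map[c] == "contaminant"
    }
    return host, contaminant


def write_origin_map(origin_map: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("contig\torigin\n")
        for contig, origin in origin_map.items():
            fh.write(f"{contig}\t{origin}\n")
    return path


def read_origin_map(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            contig, origin = line.rstrip("\n").split("\t")
            out[contig] = origin
    return out


def concatref_filter(bam_path: str | Path, origin_map: dict[str, str]) -> FilterOutcome:
    """Remove fragments whose primary alignment sits on a contaminant contig.

    Fragments unmapped on both sides are retained (they carry no variant
    evidence); a fragment with either mate placed on the contaminant side is
    removed whole.
    """
    removed: set[str] = set()
    all_ids: set[str] = set()
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        unknown = set(bam.references) - set(origin_map)
        if unknown:
            raise ValueError(f"contigs absent from origin map: {sorted(unknown)}")
        for read in bam.fetch(until_eof=True):
            if not is_primary(read):
                continue
            all_ids.add(read.query_name)
            if not read.is_unmapped and origin_map[read.reference_name] == "contaminant":
                removed.add(read.query_name)
    return FilterOutcome(
        retained_ids=all_ids - removed, removed_ids=removed, method="concatref"
    )


# ---------------------------------------------------------------------------
# DualRef

def _contaminant_mapped_ids(contaminant_bam: str | Path, max_nm: int | None) -> set[str]:
    ids: set[str] = set()
    with pysam.AlignmentFile(str(contaminant_bam), check_sq=False) as bam:
        for read in bam.fetch(until_eof=True):
            if not is_primary(read) or read.is_unmapped:
                continue
            if max_nm is not None and read.get_tag("NM") > max_nm:
                continue
            ids.add(read.query_name)
    return ids


def dualref_strict(host_bam: str | Path, contaminant_bam: str | Path) -> FilterOutcome:
    """Remove every fragment that maps to the contaminant reference at all."""
    from .samutils import primary_read_ids

    all_ids = primary_read_ids(host_bam)
    removed = _contaminant_mapped_ids(contaminant_bam, max_nm=None) & all_ids
    return FilterOutcome(
        retained_ids=all_ids - removed, removed_ids=removed, method="dualref_s"
    )


def dualref_lenient(host_bam: str | Path, contaminant_bam: str | Path) -> FilterOutcome:
    """Remove only fragments whose contaminant alignment is perfect (NM=0)."""
    from .samutils import primary_read_ids

    all_ids = primary_read_ids(host_bam)
    removed = _contaminant_mapped_ids(contaminant_bam, max_nm=0) & all_ids
    return FilterOutcome(
        retained_ids=all_ids - removed, removed_ids=removed,
        method="dualref_l", params={"max_nm": 0},
    )


# ---------------------------------------------------------------------------

def write_filtered_alignment(
    bam_path: str | Path, outcome: FilterOutcome, out_bam: str | Path
) -> Path:
    """Write only records of retained fragments; sort and index the result."""
    out_bam = Path(out_bam)
    tmp = out_bam.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as src, \
            pysam.AlignmentFile(str(tmp), "wb", template=src) as dst:
        for read in src.fetch(until_eof=True):
            if read.query_name in outcome.retained_ids:
                dst.write(read)
    sort_index(tmp, out_bam)
    tmp.unlink()
    return out_bam
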