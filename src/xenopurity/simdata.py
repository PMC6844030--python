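"""Synthetic host/contaminant genomes, origin-tagged reads and benchmark mixtures.

This module emulates the data a xenograft-contamination study works with:

* a pair of homologous genomes (a "host", e.g. human, and a "contaminant",
  e.g. mouse) that differ by a controlled rate of SNVs and small indels,
  a fraction of which are heterozygous in the contaminant;
* targeted paired-end sequencing over exome-like capture intervals;
* in silico mixtures of host and contaminant reads at defined contamination
  rates, replicated over random seeds.

Read origin is encoded in the read name (``...|org=host``) so that every
downstream filtering or calling step can be scored against truth without any
side-channel. Coordinates follow VCF conventions: truth sites are 1-based and
indels are anchored on the preceding base; capture targets are 0-based
half-open (BED).
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .variants import normalize_variant

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")

ORIGIN_TAG = "|org="
CANONICAL_RATES = (0.05, 0.10, 0.20, 0.50, 0.80)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def parse_origin(read_name: str) -> str:
    """Origin label encoded in a read name; ``unknown`` when absent."""
    if ORIGIN_TAG in read_name:
        origin = read_name.rsplit(ORIGIN_TAG, 1)[1].split("/")[0].split()[0]
        if origin in ("host", "contaminant"):
            return origin
    return "unknown"


@dataclass(frozen=True)
class TruthSite:
    """One divergent site between host and contaminant (VCF-style)."""

    contig: str
    pos: int  # 1-based; indels anchored on the preceding base
    ref: str
    alt: str
    zygosity: str  # "hom" | "het" (in the contaminant)
    kind: str  # "snv" | "indel"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class GenomePair:
    """A host genome and its diverged contaminant homolog.

    ``contaminant_sequences`` holds the fully substituted haplotype (every
    truth allele applied). Heterozygous sites are expressed at read-simulation
    time by drawing fragments from either this haplotype or the hom-only
    haplotype with equal probability. Contigs present only in the contaminant
    (no host homolog) model contaminant sequence that cannot align to the
    host at all.
    """

    host_sequences: dict[str, str]
    contaminant_sequences: dict[str, str]
    truth_sites: list[TruthSite]
    divergence_rate: float
    het_rate: float
    indel_rate: float
    seed: int
    _hap_cache: dict = field(default_factory=dict, repr=False)

    @property
    def shared_contigs(self) -> list[str]:
        return [c for c in self.host_sequences if c in self.contaminant_sequences]

    @property
    def contaminant_only_contigs(self) -> list[str]:
        return [c for c in self.contaminant_sequences if c not in self.host_sequences]

    def haplotypes(self, contig: str) -> tuple[tuple[str, np.ndarray], tuple[str, np.ndarray]]:
        """(full-alt haplotype, hom-only haplotype), each with a host->hap
        coordinate map (array of length len(host contig)+1, 0-based)."""
        if contig not in self._hap_cache:
            host = self.host_sequences[contig]
            sites = [s for s in self.truth_sites if s.contig == contig]
            full = apply_variants(host, sites)
            hom = apply_variants(host, [s for s in sites if s.zygosity == "hom"])
            self._hap_cache[contig] = (full, hom)
        return self._hap_cache[contig]


def apply_variants(seq: str, sites: Sequence[TruthSite]) -> tuple[str, np.ndarray]:
    """Apply VCF-style variants to ``seq``; return (new sequence, position map).

    ``posmap[i]`` is the coordinate in the returned sequence of host base
    ``i`` (0-based); length is ``len(seq) + 1`` so slices map cleanly.
    """
    out: list[str] = []
    posmap = np.empty(len(seq) + 1, dtype=np.int64)
    cursor = 0  # host coordinate
    offset = 0
    for s in sorted(sites, key=lambda s: s.pos):
        p0 = s.pos - 1
        if p0 < cursor:
            raise ValueError(f"overlapping truth sites near {s.contig}:{s.pos}")
        out.append(seq[cursor:p0])
        posmap[cursor : p0 + 1] = np.arange(cursor, p0 + 1) + offset
        out.append(s.alt)
        offset += len(s.alt) - len(s.ref)
        span = len(s.ref)
        # host bases consumed by the variant map to the allele start
        posmap[p0 + 1 : p0 + span] = posmap[p0] + 1
        cursor = p0 + span
    out.append(seq[cursor:])
    posmap[cursor:] = np.arange(cursor, len(seq) + 1) + offset
    return "".join(out), posmap


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def make_genome_pair(
    n_contigs: int = 1,
    contig_length: int = 100_000,
    divergence_rate: float = 0.01,
    het_rate: float = 0.1,
    indel_rate: float = 0.0005,
    seed: int = 0,
    contaminant_only_fraction: float = 0.1,
) -> GenomePair:
    """Build a host genome and a diverged contaminant homolog.

    SNV positions are drawn per-base at ``divergence_rate``; each divergent
    site is heterozygous in the contaminant with probability ``het_rate``.
    Indels (1-3 bp) are drawn at ``indel_rate``. A contaminant-only contig of
    ``contaminant_only_fraction`` of the shared genome length models
    contaminant sequence with no host homolog.
    """
    for name, v in (("divergence_rate", divergence_rate), ("het_rate", het_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if n_contigs < 1 or contig_length < 1000:
        raise ValueError("need n_contigs >= 1 and contig_length >= 1000")

    rng = np.random.default_rng(seed)
    host: dict[str, str] = {}
    sites: list[TruthSite] = []
    pad = 10  # keep contig ends variant-free so fragments stay in bounds
    for ci in range(1, n_contigs + 1):
        contig = f"chr{ci}"
        seq = _random_seq(rng, contig_length)
        host[contig] = seq
        occupied: set[int] = set()

        snv_pos = np.flatnonzero(rng.random(contig_length) < divergence_rate)
        indel_pos = np.flatnonzero(rng.random(contig_length) < indel_rate)
        events = sorted(
            [(int(p), "snv") for p in snv_pos] + [(int(p), "indel") for p in indel_pos]
        )
        for p0, kind in events:  # p0 is 0-based
            if p0 < pad or p0 >= contig_length - pad:
                continue
            zyg = "het" if rng.random() < het_rate else "hom"
            if kind == "snv":
                if p0 in occupied:
                    continue
                ref = seq[p0]
                alt = rng.choice(BASES[BASES != ord(ref)]).tobytes().decode()
                sites.append(TruthSite(contig, p0 + 1, ref, alt, zyg, "snv"))
                occupied.add(p0)
            else:
                length = int(rng.integers(1, 4))
                span = range(p0, p0 + length + 1)
                if any(q in occupied for q in span):
                    continue
                anchor = seq[p0]
                if rng.random() < 0.5:  # insertion after the anchor
                    ref0, alt0 = anchor, anchor + _random_seq(rng, length)
                else:  # deletion of the bases following the anchor
                    ref0, alt0 = seq[p0 : p0 + 1 + length], anchor
                # store the left-normalized representation so truth matches
                # normalized caller output
                _, npos, nref, nalt = normalize_variant(contig, p0 + 1, ref0, alt0,
                                                        {contig: seq})
                np0 = npos - 1
                ambiguity = range(np0, p0 + length + 1)
                if np0 < pad or any(q in occupied for q in ambiguity):
                    continue
                sites.append(TruthSite(contig, npos, nref, nalt, zyg, "indel"))
                occupied.update(ambiguity)

    contaminant = {c: apply_variants(host[c], [s for s in sites if s.contig == c])[0] for c in host}
    conly_len = int(round(contaminant_only_fraction * n_contigs * contig_length))
    if conly_len >= 1000:
        contaminant["conly1"] = _random_seq(rng, conly_len)

    return GenomePair(
        host_sequences=host,
        contaminant_sequences=contaminant,
        truth_sites=sites,
        divergence_rate=divergence_rate,
        het_rate=het_rate,
        indel_rate=indel_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# capture targets

def make_targets(
    pair: GenomePair,
    genome: str = "host",
    fraction: float = 0.5,
    interval_length: int = 500,
    seed: int = 0,
) -> list[tuple[str, int, int]]:
    """Exome-like capture intervals (0-based half-open), evenly tiled.

    Shared contigs are targeted in host coordinates. For ``genome ==
    "contaminant"`` the contaminant-only contigs are additionally targeted
    (capture pulls down contaminant fragments with no host homolog too).
    """
    if genome not in ("host", "contaminant"):
        raise ValueError("genome must be 'host' or 'contaminant'")
    rng = np.random.default_rng(seed)
    targets: list[tuple[str, int, int]] = []

    def tile(contig: str, length: int) -> None:
        n = max(1, int(fraction * length / interval_length))
        spacing = length / n
        for i in range(n):
            start = int(i * spacing + rng.integers(0, max(1, int(spacing - interval_length))))
            end = min(start + interval_length, length)
            if end - start >= 50:
                targets.append((contig, start, end))

    for contig in pair.shared_contigs:
        tile(contig, len(pair.host_sequences[contig]))
    if genome == "contaminant":
        for contig in pair.contaminant_only_contigs:
            tile(contig, len(pair.contaminant_sequences[contig]))
    return targets


def target_span(targets: Iterable[tuple[str, int, int]]) -> int:
    return sum(end - start for _, start, end in targets)


# ---------------------------------------------------------------------------
# read simulation

def simulate_reads(
    genome_id: str,
    pair: GenomePair,
    targets: Sequence[tuple[str, int, int]],
    mean_depth: float,
    read_length: int = 100,
    insert_size: int = 300,
    error_rate: float = 0.001,
    seed: int = 0,
    sample_id: str | None = None,
    out_prefix: str | Path | None = None,
) -> tuple[Path, Path]:
    """Simulate paired-end reads over capture targets; write gzipped FASTQ.

    Contaminant fragments are drawn from either contaminant haplotype with
    probability 1/2, so heterozygous truth alleles appear in about half of
    the overlapping contaminant reads. Sequencing error is substitution-only
    with constant base quality. Returns the two FASTQ paths
    (``<prefix>_R1.fastq.gz``, ``<prefix>_R2.fastq.gz``).
    """
    if genome_id not in ("host", "contaminant"):
        raise ValueError("genome_id must be 'host' or 'contaminant'")
    if not targets:
        raise ValueError("empty target set")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if out_prefix is None:
        raise ValueError("out_prefix is required")

    rng = np.random.default_rng(seed)
    origin = genome_id
    name_prefix = sample_id or genome_id

    # resolve per-target (sequence(s), host-coordinate bounds)
    host_like = genome_id == "host"
    for contig, start, end in targets:
        bounds = pair.host_sequences if (contig in pair.host_sequences) else pair.contaminant_sequences
        if host_like and contig not in pair.host_sequences:
            raise ValueError(f"target contig {contig} absent from host genome")
        if contig not in bounds or not (0 <= start < end <= len(bounds[contig])):
            raise ValueError(f"target {contig}:{start}-{end} out of contig bounds")

    span = target_span(targets)
    n_pairs = int(round(mean_depth * span / (2 * read_length)))
    lengths = np.array([end - start for _, start, end in targets], dtype=float)
    weights = lengths / lengths.sum()
    target_idx = rng.choice(len(targets), size=n_pairs, p=weights)

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fq1_path = out_prefix.with_name(out_prefix.name + "_R1.fastq.gz")
    fq2_path = out_prefix.with_name(out_prefix.name + "_R2.fastq.gz")
    qual = "I" * read_length

    def add_errors(seq: str) -> str:
        if error_rate <= 0:
            return seq
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        mask = rng.random(len(arr)) < error_rate
        if mask.any():
            idx = np.flatnonzero(mask)
            for i in idx:
                arr[i] = rng.choice(BASES[BASES != arr[i]])
        return arr.tobytes().decode()

    with gzip.open(fq1_path, "wt") as f1, gzip.open(fq2_path, "wt") as f2:
        for serial, ti in enumerate(target_idx):
            contig, start, end = targets[ti]
            center = int(rng.integers(start, end))
            frag_start = center - insert_size // 2

            if host_like or contig in pair.contaminant_only_contigs:
                seq = (
                    pair.host_sequences[contig]
                    if host_like
                    else pair.contaminant_sequences[contig]
                )
                frag_start = int(np.clip(frag_start, 0, max(0, len(seq) - insert_size)))
                frag = seq[frag_start : frag_start + insert_size]
            else:
                (hap_full, map_full), (hap_hom, map_hom) = pair.haplotypes(contig)
                hap, posmap = (hap_full, map_full) if rng.random() < 0.5 else (hap_hom, map_hom)
                hstart = int(posmap[np.clip(frag_start, 0, len(posmap) - 1)])
                hstart = int(np.clip(hstart, 0, max(0, len(hap) - insert_size)))
                frag = hap[hstart : hstart + insert_size]

            if len(frag) < read_length:
                continue  # degenerate contig shorter than a read
            r1 = add_errors(frag[:read_length])
            r2 = add_errors(revcomp(frag[-read_length:]))
            name = f"{name_prefix}:{serial:07d}{ORIGIN_TAG}{origin}"
            f1.write(f"@{name}\n{r1}\n+\n{qual}\n")
            f2.write(f"@{name}\n{r2}\n+\n{qual}\n")
    return fq1_path, fq2_path


# ---------------------------------------------------------------------------
# benchmark mixture design

@dataclass(frozen=True)
class MixtureSpec:
    """One benchmark mixture: which samples, how contaminated, which seed."""

    human_sample_id: str
    mouse_sample_id: str
    contamination_rate: float
    seed: int
    total_reads: int
    n_mouse_reads: int
    n_human_reads: int

    @classmethod
    def build(
        cls, human_sample_id: str, mouse_sample_id: str,
        contamination_rate: float, seed: int, total_reads: int,
    ) -> "MixtureSpec":
        if not 0.0 <= contamination_rate < 1.0:
            raise ValueError("contamination_rate must be in [0, 1)")
        n_mouse = int(round(total_reads * contamination_rate))
        return cls(
            human_sample_id=human_sample_id,
            mouse_sample_id=mouse_sample_id,
            contamination_rate=contamination_rate,
            seed=seed,
            total_reads=total_reads,
            n_mouse_reads=n_mouse,
            n_human_reads=total_reads - n_mouse,
        )


def design_benchmark(
    human_ids: Sequence[str],
    mouse_ids: Sequence[str],
    rates: Sequence[float],
    n_seeds: int,
    total_reads: int = 20_000,
    base_seed: int = 0,
) -> list[MixtureSpec]:
    """Full-factorial mixture design: every human x mouse x rate x seed.

    Contaminant reads make up ``rate`` of each mixture and host reads the
    complementary ``1 - rate``; each cell is replicated ``n_seeds`` times
    with distinct seeds.
    """
    for ids, label in ((human_ids, "human_ids"), (mouse_ids, "mouse_ids")):
        if not ids:
            raise ValueError(f"{label} must be non-empty")
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate IDs in {label}")
    if not rates or n_seeds < 1:
        raise ValueError("need at least one rate and one seed")
    if any(not 0.0 < r < 1.0 for r in rates):
        raise ValueError("rates must lie in (0, 1)")

    specs = []
    counter = itertools.count()
    for h, m, r in itertools.product(human_ids, mouse_ids, rates):
        for _ in range(n_seeds):
            specs.append(MixtureSpec.build(h, m, r, base_seed + next(counter), total_reads))
    return specs


def _read_fastq_pairs(fq1: str | Path, fq2: str | Path) -> list[tuple[str, str, str, str, str]]:
    pairs = []
    with pysam.FastxFile(str(fq1)) as h1, pysam.FastxFile(str(fq2)) as h2:
        for e1, e2 in zip(h1, h2):
            if e1.name != e2.name:
                raise ValueError(f"mate name mismatch: {e1.name} vs {e2.name}")
            pairs.append((e1.name, e1.sequence, e1.quality or "I" * len(e1.sequence),
                          e2.sequence, e2.quality or "I" * len(e2.sequence)))
    return pairs


def make_mixture(
    spec: MixtureSpec,
    human_fastq: tuple[str | Path, str | Path],
    mouse_fastq: tuple[str | Path, str | Path],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Mix host and contaminant FASTQs per ``spec`` (pair-aware, seeded).

    Fragments are sampled without replacement, a read pair being kept or
    dropped atomically, so ``spec.n_mouse_reads`` and ``spec.n_human_reads``
    must be even. Origin tags in read names pass through untouched.
    """
    if spec.n_mouse_reads % 2 or spec.n_human_reads % 2:
        raise ValueError("paired mixing needs even read counts per source; adjust total_reads")
    rng = np.random.default_rng(spec.seed)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fq1_path = out_prefix.with_name(out_prefix.name + "_R1.fastq.gz")
    fq2_path = out_prefix.with_name(out_prefix.name + "_R2.fastq.gz")

    chosen: list[tuple[str, str, str, str, str]] = []
    for (f1, f2), n_reads, label in (
        (human_fastq, spec.n_human_reads, "human"),
        (mouse_fastq, spec.n_mouse_reads, "mouse"),
    ):
        n_pairs = n_reads // 2
        if n_pairs == 0:
            continue
        pairs = _read_fastq_pairs(f1, f2)
        if len(pairs) < n_pairs:
            raise ValueError(
                f"insufficient {label} reads: need {n_pairs} pairs, "
                f"found {len(pairs)} (deficit {n_pairs - len(pairs)})"
            )
        idx = rng.choice(len(pairs), size=n_pairs, replace=False)
        chosen.extend(pairs[i] for i in sorted(idx))

    with gzip.open(fq1_path, "wt") as o1, gzip.open(fq2_path, "wt") as o2:
        for name, s1, q1, s2, q2 in chosen:
            o1.write(f"@{name}\n{s1}\n+\n{q1}\n")
            o2.write(f"@{name}\n{s2}\n+\n{q2}\n")
    return fq1_path, fq2_path


# ---------------------------------------------------------------------------
# plain-text outputs

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def write_truth_table(pair: GenomePair, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tzygosity\tkind\n")
        for s in sorted(pair.truth_sites, key=lambda s: (s.contig, s.pos)):
            fh.write(f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.zygosity}\t{s.kind}\n")
    return path


def write_bed(targets: Sequence[tuple[str, int, int]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for contig, start, end in targets:
            fh.write(f"{contig}\t{start}\t{end}\n")
    return path
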