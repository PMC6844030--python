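"""End-to-end pipelines over the synthetic study: simulate, align, catalog,
calibrate, estimate, filter, blacklist.

These functions glue the module-level operations into the workflows a study
actually runs. All randomness funnels through explicit integer seeds; every
sub-seed is derived arithmetically from the study seed so a whole run is
reproducible from one integer.

Mixtures are evaluated efficiently by alignment reuse: each source sample is
aligned once and a mixture's alignment is the subset of those alignments
matching the fragment IDs the mixture sampled (alignment is per-read, so the
result is identical to aligning the mixed FASTQ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import catalog as catalog_mod
from . import estimator, pileup, simdata
from .aligner import align_fastq
from .samutils import fastq_read_ids, mean_depth_table, merge_bams, subset_bam
from .simdata import GenomePair, MixtureSpec

logger = logging.getLogger(__name__)


@dataclass
class SimulatedSample:
    sample_id: str
    genome_id: str  # "host" | "contaminant"
    fastq1: Path
    fastq2: Path
    bam: Path  # aligned to the host reference
    n_pairs: int


def simulate_and_align(
    pair: GenomePair,
    genome_id: str,
    targets: list[tuple[str, int, int]],
    mean_depth: float,
    seed: int,
    sample_id: str,
    workdir: str | Path,
    reference: dict[str, str] | None = None,
    error_rate: float = 0.001,
) -> SimulatedSample:
    """Simulate one sample's reads and align them (default: host reference)."""
    workdir = Path(workdir)
    fq1, fq2 = simdata.simulate_reads(
        genome_id, pair, targets, mean_depth, seed=seed,
        sample_id=sample_id, error_rate=error_rate,
        out_prefix=workdir / sample_id,
    )
    reference = reference if reference is not None else pair.host_sequences
    bam = align_fastq(reference, fq1, fq2, workdir / f"{sample_id}.bam")
    return SimulatedSample(
        sample_id=sample_id, genome_id=genome_id, fastq1=fq1, fastq2=fq2,
        bam=bam, n_pairs=len(fastq_read_ids(fq1)),
    )


def mixture_alignment(
    spec: MixtureSpec,
    host_sample: SimulatedSample,
    contaminant_sample: SimulatedSample,
    out_bam: str | Path,
) -> Path:
    """Host-reference alignment of a mixture, by subsetting source alignments.

    Samples the same pair-atomic fragments ``make_mixture`` would (seeded by
    the spec), then merges the matching records from the two pre-aligned
    source BAMs.
    """
    if spec.n_mouse_reads % 2 or spec.n_human_reads % 2:
        raise ValueError("paired mixing needs even read counts per source")
    rng = np.random.default_rng(spec.seed)
    out_bam = Path(out_bam)
    parts = []
    for sample, n_reads, label in (
        (host_sample, spec.n_human_reads, "human"),
        (contaminant_sample, spec.n_mouse_reads, "mouse"),
    ):
        n_pairs = n_reads // 2
        if n_pairs == 0:
            continue
        ids = fastq_read_ids(sample.fastq1)
        if len(ids) < n_pairs:
            raise ValueError(f"insufficient {label} reads: need {n_pairs} pairs, "
                             f"found {len(ids)}")
        idx = rng.choice(len(ids), size=n_pairs, replace=False)
        chosen = [ids[i] for i in sorted(idx)]
        part = out_bam.with_suffix(f".{label}.part.bam")
        subset_bam(sample.bam, chosen, part)
        parts.append(part)
    merge_bams(parts, out_bam)
    for p in parts:
        p.unlink(missing_ok=True)
        Path(str(p) + ".bai").unlink(missing_ok=True)
    return out_bam


# ---------------------------------------------------------------------------
# catalog construction on synthetic data

@dataclass
class SyntheticCatalog:
    pair: GenomePair
    catalog: pd.DataFrame
    host_targets: list[tuple[str, int, int]]
    contaminant_targets: list[tuple[str, int, int]]
    mouse_samples: list[SimulatedSample]
    host_samples: list[SimulatedSample]
    mouse_depth_table: dict[tuple[str, int], float]
    human_depth_table: dict[tuple[str, int], float]


def build_synthetic_catalog(
    pair: GenomePair,
    workdir: str | Path,
    n_mouse_samples: int = 3,
    n_host_samples: int = 2,
    mean_depth: float = 50.0,
    seed: int = 0,
    alpha_calibration: float = 0.5,
    target_fraction: float = 0.5,
    min_depth: int = 8,
) -> SyntheticCatalog:
    """Simulate pure samples and build the common-allele catalog.

    Pure contaminant samples (captured with the host exome design, plus the
    contaminant-only contigs) are aligned to the host reference and called;
    alleles shared by every contaminant sample form the catalog. Depth tables
    come from the contaminant samples and a simulated host cohort; with both
    at full depth the effective mixing fraction for H_f is 0.5, which
    ``alpha_calibration`` converts into per-site H_c.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    host_targets = simdata.make_targets(pair, "host", fraction=target_fraction, seed=seed)
    cont_targets = simdata.make_targets(pair, "contaminant", fraction=target_fraction, seed=seed)

    mouse_samples = [
        simulate_and_align(pair, "contaminant", cont_targets, mean_depth,
                           seed=seed * 1000 + 11 + i, sample_id=f"mouse{i + 1}",
                           workdir=workdir)
        for i in range(n_mouse_samples)
    ]
    host_samples = [
        simulate_and_align(pair, "host", host_targets, mean_depth,
                           seed=seed * 1000 + 51 + i, sample_id=f"host{i + 1}",
                           workdir=workdir)
        for i in range(n_host_samples)
    ]

    per_sample = [
        catalog_mod.call_contaminant_alleles(s.bam, pair.host_sequences, min_depth=min_depth)
        for s in mouse_samples
    ]
    common, _ = catalog_mod.intersect_common(per_sample) if len(per_sample) >= 2 else ([], [])
    sites = sorted({(c, p) for c, p, _, _ in common})
    dp_mouse = mean_depth_table([s.bam for s in mouse_samples], sites)
    dp_human = mean_depth_table([s.bam for s in host_samples], sites)
    df = catalog_mod.build_catalog(per_sample, dp_mouse, dp_human,
                                   alpha_calibration=alpha_calibration)
    return SyntheticCatalog(
        pair=pair, catalog=df, host_targets=host_targets,
        contaminant_targets=cont_targets, mouse_samples=mouse_samples,
        host_samples=host_samples, mouse_depth_table=dp_mouse,
        human_depth_table=dp_human,
    )


# ---------------------------------------------------------------------------
# estimation

def sample_hf_values(
    bam_path: str | Path,
    catalog: pd.DataFrame,
    host_sequences: dict[str, str],
) -> list[float]:
    """Catalog-allele frequencies of one sample at every covered catalog site."""
    sites = [(row.contig, int(row.pos)) for row in catalog.itertuples()]
    counts = pileup.count_at_sites(bam_path, host_sequences, sites)
    hf = []
    for row in catalog.itertuples():
        ac = counts[(row.contig, int(row.pos))]
        if ac.depth > 0:
            hf.append(ac.allele_fraction(pileup.allele_key(row.ref, row.alt)))
    return hf


def estimate_alpha_from_alignment(
    bam_path: str | Path,
    catalog: pd.DataFrame,
    host_sequences: dict[str, str],
    model: estimator.CalibrationModel | None = None,
) -> dict[str, float]:
    """Single-sample contamination estimate from an aligned (mixed) sample.

    Returns {alpha_hat, median_hf, n_sites}. An empty catalog (e.g. host and
    contaminant genomes identical) yields alpha_hat = 0 by definition: there
    is no allele evidence of contamination.
    """
    if len(catalog) == 0:
        logger.warning("empty catalog: reporting alpha_hat = 0")
        return {"alpha_hat": 0.0, "median_hf": 0.0, "n_sites": 0}
    hf = sample_hf_values(bam_path, catalog, host_sequences)
    if not hf:
        logger.warning("no covered catalog sites: reporting alpha_hat = 0")
        return {"alpha_hat": 0.0, "median_hf": 0.0, "n_sites": 0}
    alpha_hat = estimator.estimate_alpha(hf, model)
    return {"alpha_hat": alpha_hat, "median_hf": float(np.median(hf)), "n_sites": len(hf)}


def run_estimator_benchmark(
    seed: int = 1,
    rates: tuple[float, ...] = (0.05, 0.10, 0.20, 0.50),
    n_seeds: int = 3,
    calibration_replicates: int = 3,
    contig_length: int = 100_000,
    divergence_rate: float = 0.01,
    het_rate: float = 0.1,
    indel_rate: float = 0.0005,
    mean_depth: float = 50.0,
    total_pairs: int | None = None,
    workdir: str | Path = "scratch/estimator_bench",
) -> dict:
    """Full estimator benchmark: catalog, calibration, and recovery error.

    Builds a synthetic genome pair and catalog, calibrates the median-H_f
    coefficient on held-out single-replicate mixtures, then estimates alpha
    on a separate sample pair mixed at each rate with ``n_seeds`` replicates.
    Returns the calibration model, a tidy results frame and the 95% bound of
    |alpha_hat - alpha|.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    pair = simdata.make_genome_pair(
        n_contigs=1, contig_length=contig_length, divergence_rate=divergence_rate,
        het_rate=het_rate, indel_rate=indel_rate, seed=seed,
    )
    syn = build_synthetic_catalog(pair, workdir, mean_depth=mean_depth, seed=seed)

    # held-out calibration samples and mixtures (one replicate per rate)
    cal_host = simulate_and_align(pair, "host", syn.host_targets, mean_depth,
                                  seed=seed * 1000 + 101, sample_id="host_cal",
                                  workdir=workdir)
    cal_mouse = simulate_and_align(pair, "contaminant", syn.contaminant_targets,
                                   mean_depth, seed=seed * 1000 + 102,
                                   sample_id="mouse_cal", workdir=workdir)
    if total_pairs is None:
        # largest mixture the source samples can supply at every rate,
        # rounded so canonical rates (multiples of 5%) give even read counts
        total_pairs = int(min(cal_host.n_pairs / (1 - min(rates)),
                              cal_mouse.n_pairs / max(rates)))
        total_pairs -= total_pairs % 20
    fit_points = []
    for i, rate in enumerate(rates):
        for rep in range(calibration_replicates):
            spec = MixtureSpec.build("host_cal", "mouse_cal", rate,
                                     seed * 1000 + 200 + i * 10 + rep, total_pairs * 2)
            bam = mixture_alignment(spec, cal_host, cal_mouse,
                                    workdir / f"cal_{int(rate * 100)}_{rep}.bam")
            hf = sample_hf_values(bam, syn.catalog, pair.host_sequences)
            fit_points.append((rate, float(np.median(hf))))
    model = estimator.calibrate(fit_points)

    # query samples, never seen by catalog or calibration
    q_host = simulate_and_align(pair, "host", syn.host_targets, mean_depth,
                                seed=seed * 1000 + 301, sample_id="host_query",
                                workdir=workdir)
    q_mouse = simulate_and_align(pair, "contaminant", syn.contaminant_targets,
                                 mean_depth, seed=seed * 1000 + 302,
                                 sample_id="mouse_query", workdir=workdir)
    rows = []
    for i, rate in enumerate(rates):
        for rep in range(n_seeds):
            spec = MixtureSpec.build("host_query", "mouse_query", rate,
                                     seed * 1000 + 400 + i * 10 + rep, total_pairs * 2)
            bam = mixture_alignment(
                spec, q_host, q_mouse,
                workdir / f"query_{int(rate * 100)}_{rep}.bam")
            est = estimate_alpha_from_alignment(bam, syn.catalog,
                                                pair.host_sequences, model)
            rows.append({
                "alpha_true": rate, "replicate": rep, **est,
                "abs_error": abs(est["alpha_hat"] - rate),
            })
    results = pd.DataFrame(rows)
    err95 = float(np.percentile(results["abs_error"], 97.5))
    return {
        "pair": pair, "catalog": syn.catalog, "synthetic": syn, "model": model,
        "fit_points": fit_points, "results": results, "err95": err95,
    }


# ---------------------------------------------------------------------------
# call set I/O (for blacklist workflows)

def calls_to_vcf(
    calls: list[catalog_mod.VariantCall],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> Path:
    """Write pileup caller output as a VCF 4.2 call set."""
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    header.info.add("VAF", 1, "Float", "Alternative allele fraction")
    header.info.add("DP", 1, "Integer", "Read depth")
    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (c.contig, c.pos)):
            rec = vcf.new_record(contig=call.contig, start=call.pos - 1,
                                 alleles=(call.ref, call.alt))
            rec.info["VAF"] = float(call.vaf)
            rec.info["DP"] = int(call.depth)
            vcf.write(rec)
    return path


def export_study_inputs(pair: GenomePair, workdir: str | Path,
                        target_fraction: float = 0.5, seed: int = 0) -> dict[str, Path]:
    """Write the study's plain-text inputs: FASTAs, truth TSV, target BEDs."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    host_targets = simdata.make_targets(pair, "host", fraction=target_fraction, seed=seed)
    cont_targets = simdata.make_targets(pair, "contaminant", fraction=target_fraction, seed=seed)
    return {
        "host_fasta": simdata.write_fasta(pair.host_sequences, workdir / "host.fa"),
        "contaminant_fasta": simdata.write_fasta(pair.contaminant_sequences,
                                                 workdir / "contaminant.fa"),
        "truth": simdata.write_truth_table(pair, workdir / "truth_sites.tsv"),
        "host_targets": simdata.write_bed(host_targets, workdir / "targets_host.bed"),
        "contaminant_targets": simdata.write_bed(cont_targets, workdir / "targets_contaminant.bed"),
    }
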