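"""Shared fixtures: one small synthetic study built once per session.

Everything is generated at run time from seeds; no stored data files.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from xenopurity import filters, simdata, workflows
from xenopurity.aligner import align_fastq
from xenopurity.simdata import MixtureSpec


@pytest.fixture(scope="session")
def pair():
    """Small host/contaminant genome pair with SNVs, hets and indels."""
    return simdata.make_genome_pair(
        n_contigs=1, contig_length=30_000, divergence_rate=0.01,
        het_rate=0.1, indel_rate=0.001, seed=11,
    )


@pytest.fixture(scope="session")
def zero_divergence_pair():
    return simdata.make_genome_pair(
        n_contigs=1, contig_length=5_000, divergence_rate=0.0,
        het_rate=0.0, indel_rate=0.0, seed=3, contaminant_only_fraction=0.0,
    )


@pytest.fixture(scope="session")
def study(pair, tmp_path_factory):
    """A complete small study: catalog, a 20% mixture, and its alignments.

    The mixture is aligned three ways (host reference, contaminant
    reference, concatenated reference) so every filtering method can run on
    identical input reads.
    """
    wd = tmp_path_factory.mktemp("study")
    syn = workflows.build_synthetic_catalog(pair, wd, mean_depth=30.0, seed=11)

    host_q = workflows.simulate_and_align(
        pair, "host", syn.host_targets, 30.0, seed=11_901,
        sample_id="host_q", workdir=wd)
    mouse_q = workflows.simulate_and_align(
        pair, "contaminant", syn.contaminant_targets, 30.0, seed=11_902,
        sample_id="mouse_q", workdir=wd)

    spec = MixtureSpec.build("host_q", "mouse_q", 0.20, seed=11_903, total_reads=4000)
    fq1, fq2 = simdata.make_mixture(
        spec, (host_q.fastq1, host_q.fastq2), (mouse_q.fastq1, mouse_q.fastq2),
        wd / "mix20")

    concat_ref, origin_map = filters.build_concat_reference(
        pair.host_sequences, pair.contaminant_sequences)
    bam_host = align_fastq(pair.host_sequences, fq1, fq2, wd / "mix20_host.bam")
    bam_cont = align_fastq(pair.contaminant_sequences, fq1, fq2, wd / "mix20_cont.bam")
    bam_concat = align_fastq(concat_ref, fq1, fq2, wd / "mix20_concat.bam")

    from xenopurity.samutils import fastq_read_ids

    labels = {rid: simdata.parse_origin(rid) for rid in fastq_read_ids(fq1)}
    return {
        "pair": pair,
        "workdir": Path(wd),
        "synthetic": syn,
        "catalog": syn.catalog,
        "spec": spec,
        "fastq": (fq1, fq2),
        "bam_host": bam_host,
        "bam_contaminant": bam_cont,
        "bam_concat": bam_concat,
        "origin_map": origin_map,
        "origin_labels": labels,
        "host_query": host_q,
        "mouse_query": mouse_q,
    }
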