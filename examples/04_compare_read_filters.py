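"""Benchmark the three read-filtering methods on one origin-tagged mixture.

Aligns a 20% mixture to the host reference, the contaminant reference and a
concatenated host+contaminant reference, applies ConcatRef, DualRef-S and
DualRef-L, and scores each against the read-name origin truth. Sensitivity
is the fraction of contaminant reads removed; specificity the fraction of
host reads kept; the F-score is their harmonic mean. Also reports the total
H_f reduction over catalog sites and how many sites remain callable
(allele fraction > 5% and > 5 supporting reads).
"""

import tempfile

from xenopurity import bench, filters, pileup, simdata, workflows
from xenopurity.aligner import align_fastq

pair = simdata.make_genome_pair(1, 20_000, 0.01, 0.1, 0.001, seed=7)

with tempfile.TemporaryDirectory() as tmp:
    syn = workflows.build_synthetic_catalog(pair, tmp, mean_depth=30, seed=7)
    host = workflows.simulate_and_align(pair, "host", syn.host_targets, 30,
                                        seed=901, sample_id="h_q", workdir=tmp)
    mouse = workflows.simulate_and_align(pair, "contaminant",
                                         syn.contaminant_targets, 30,
                                         seed=902, sample_id="m_q", workdir=tmp)
    spec = simdata.MixtureSpec.build("h", "m", 0.20, 777, 3000)
    fq1, fq2 = simdata.make_mixture(spec, (host.fastq1, host.fastq2),
                                    (mouse.fastq1, mouse.fastq2), f"{tmp}/mix")

    concat_ref, origin_map = filters.build_concat_reference(
        pair.host_sequences, pair.contaminant_sequences)
    bam_host = align_fastq(pair.host_sequences, fq1, fq2, f"{tmp}/host.bam")
    bam_cont = align_fastq(pair.contaminant_sequences, fq1, fq2, f"{tmp}/cont.bam")
    bam_concat = align_fastq(concat_ref, fq1, fq2, f"{tmp}/concat.bam")

    from xenopurity.samutils import fastq_read_ids
    labels = {r: simdata.parse_origin(r) for r in fastq_read_ids(fq1)}

    outcomes = {
        "ConcatRef": filters.concatref_filter(bam_concat, origin_map),
        "DualRef-S": filters.dualref_strict(bam_host, bam_cont),
        "DualRef-L": filters.dualref_lenient(bam_host, bam_cont),
    }
    sites = [(r.contig, int(r.pos)) for r in syn.catalog.itertuples()]
    before = pileup.count_at_sites(bam_host, pair.host_sequences, sites)
    print(f"{'method':<10} {'sens':>6} {'spec':>6} {'F':>6} "
          f"{'hf_drop':>8} {'callable':>9}")
    for name, outcome in outcomes.items():
        m = bench.score_filter(outcome, labels)
        filtered = filters.write_filtered_alignment(
            bam_host, outcome, f"{tmp}/{name}.bam")
        after = pileup.count_at_sites(filtered, pair.host_sequences, sites)
        drop, _ = bench.hf_reduction(before, after, syn.catalog)
        callable_n = bench.count_callable_hamas(after, syn.catalog)
        print(f"{name:<10} {m.sensitivity:>6.3f} {m.specificity:>6.3f} "
              f"{m.f_score:>6.3f} {drop:>8.2f} {callable_n:>9d}")
    print("\nDualRef-S removes every contaminant-mapped read (max sensitivity,"
          "\nworst specificity); DualRef-L only perfect matches; ConcatRef"
          "\nlets the aligner adjudicate and balances both.")
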