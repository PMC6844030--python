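"""Simulate a host/contaminant benchmark: genomes, reads and mixture design.

Builds a small diverged genome pair, simulates exome-like paired reads from
each genome with origin tags in the read names, and enumerates the canonical
mixture design (every host sample x contaminant sample x contamination rate
x seed replicate).
"""

import tempfile
from collections import Counter
from pathlib import Path

from xenopurity import simdata

pair = simdata.make_genome_pair(
    n_contigs=1, contig_length=20_000, divergence_rate=0.01,
    het_rate=0.1, indel_rate=0.001, seed=7)
kinds = Counter((s.kind, s.zygosity) for s in pair.truth_sites)
print(f"genome pair: {len(pair.truth_sites)} divergent sites "
      f"({dict(kinds)}) on contigs {sorted(pair.contaminant_sequences)}")
print("  -> 'conly1' exists only in the contaminant (no host homolog)")

with tempfile.TemporaryDirectory() as tmp:
    targets = simdata.make_targets(pair, "host", fraction=0.5, seed=7)
    fq1, fq2 = simdata.simulate_reads(
        "host", pair, targets, mean_depth=30, seed=1, out_prefix=Path(tmp) / "host1")
    from xenopurity.samutils import fastq_read_ids
    n = len(fastq_read_ids(fq1))
    print(f"simulated host sample: {n} fragments at 30x over "
          f"{simdata.target_span(targets)} bp of capture targets")

specs = simdata.design_benchmark(
    human_ids=["h1", "h2"], mouse_ids=["m1", "m2", "m3", "m4", "m5"],
    rates=[0.05, 0.10, 0.20, 0.50, 0.80], n_seeds=3)
print(f"benchmark design: {len(specs)} mixtures "
      "(2 host x 5 contaminant x 5 rates x 3 seeds)")
s = specs[0]
print(f"example spec: rate {s.contamination_rate:.0%} -> "
      f"{s.n_mouse_reads} contaminant + {s.n_human_reads} host reads "
      f"of {s.total_reads} total (complementary downsampling)")
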