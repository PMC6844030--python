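"""Benchmark harness: scoring read filters and their downstream effects.

Evaluation follows the origin-tagged read design: every fragment in a mixture
carries a truth label (host or contaminant), so a filter's removal set can be
scored exactly.

Conventions:

* a removed contaminant fragment is a true positive, a retained host fragment
  a true negative;
* sensitivity = fraction of contaminant fragments removed, specificity =
  fraction of host fragments retained;
* the F-score is the harmonic mean of *sensitivity and specificity* (a
  balanced measure of the two) — NOT the conventional precision/recall F1.
  This matches how read filters are compared in the xenograft-filtering
  literature, where class sizes are wildly unbalanced across contamination
  levels.

Also provided: the post-filtering reduction of HAMA allele frequencies,
counting of still-callable HAMA sites, and per-gene RPKM of contaminant reads
(genes with RPKM > 40 are flagged as contamination-sensitive).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .filters import FilterOutcome
from .pileup import AllelicCount, allele_key
from .samutils import is_primary

RPKM_SENSITIVE_THRESHOLD = 40.0


@dataclass(frozen=True)
class ConfusionCounts:
    """Read-level confusion counts for one filter on one mixture."""

    tp: int  # contaminant fragments removed
    fn: int  # contaminant fragments retained
    tn: int  # host fragments retained
    fp: int  # host fragments removed

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class Metrics:
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f_score: float

    @classmethod
    def from_counts(cls, c: ConfusionCounts) -> "Metrics":
        sens = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
        spec = c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
        prec = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
        acc = (c.tp + c.tn) / c.total if c.total else 0.0
        f = 2 * sens * spec / (sens + spec) if sens + spec else 0.0
        return cls(counts=c, sensitivity=sens, specificity=spec,
                   precision=prec, accuracy=acc, f_score=f)


def score_filter(
    outcome: FilterOutcome,
    origin_labels: Mapping[str, str],
    ignore_unknown: bool = False,
) -> Metrics:
    """Score a filter outcome against per-fragment origin truth labels."""
    tp = fn = tn = fp = 0
    for ids, removed in ((outcome.removed_ids, True), (outcome.retained_ids, False)):
        for rid in ids:
            origin = origin_labels.get(rid, "unknown")
            if origin == "contaminant":
                tp += removed
                fn += not removed
            elif origin == "host":
                fp += removed
                tn += not removed
            elif not ignore_unknown:
                raise ValueError(f"read {rid!r} has unknown origin; "
                                 "pass ignore_unknown=True to skip such reads")
    return Metrics.from_counts(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))


def mean_metrics(metrics: Sequence[Metrics]) -> dict[str, float]:
    """Mean of each metric over seed replicates."""
    if not metrics:
        raise ValueError("no metrics to aggregate")
    names = ["sensitivity", "specificity", "precision", "accuracy", "f_score"]
    return {n: sum(getattr(m, n) for m in metrics) / len(metrics) for n in names}


# ---------------------------------------------------------------------------
# allele-frequency effects

def _site_hf(counts: Mapping[tuple[str, int], AllelicCount], row) -> float:
    ac = counts.get((row.contig, row.pos))
    if ac is None:
        return 0.0
    return ac.allele_fraction(allele_key(row.ref, row.alt))


def hf_reduction(
    counts_before: Mapping[tuple[str, int], AllelicCount],
    counts_after: Mapping[tuple[str, int], AllelicCount],
    catalog: pd.DataFrame,
) -> tuple[float, pd.DataFrame]:
    """Signed per-site and total reduction of catalog-allele frequencies.

    The site H_f here is the catalog alt-allele fraction observed in the
    sample pileup before vs after filtering; the total is the plain sum of
    per-site differences (a site whose frequency rose contributes
    negatively).
    """
    rows = []
    for row in catalog.itertuples():
        before = _site_hf(counts_before, row)
        after = _site_hf(counts_after, row)
        rows.append((row.contig, row.pos, row.ref, row.alt, before, after, before - after))
    per_site = pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "alt", "hf_before", "hf_after", "reduction"]
    )
    return float(per_site["reduction"].sum()), per_site


def count_callable_hamas(
    counts: Mapping[tuple[str, int], AllelicCount],
    catalog: pd.DataFrame,
    min_vaf: float = 0.05,
    min_alt: int = 5,
) -> int:
    """Catalog sites still exceeding mutation-calling minimums.

    A site counts when the catalog alt allele's fraction is strictly greater
    than ``min_vaf`` AND its read count strictly greater than ``min_alt``.
    """
    n = 0
    for row in catalog.itertuples():
        ac = counts.get((row.contig, row.pos))
        if ac is None:
            continue
        key = allele_key(row.ref, row.alt)
        alt_count = ac.alt_counts.get(key, 0)
        if alt_count > min_alt and ac.allele_fraction(key) > min_vaf:
            n += 1
    return n


# ---------------------------------------------------------------------------
# gene-level contaminant read quantification

def count_reads_per_gene(bam_path: str | Path, genes: pd.DataFrame) -> dict[str, int]:
    """Distinct primary fragments overlapping each gene interval.

    ``genes`` needs columns gene_id, contig, start, end (0-based half-open).
    """
    counts: dict[str, int] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        refs = set(bam.references)
        for row in genes.itertuples():
            if row.contig not in refs:
                counts[row.gene_id] = 0
                continue
            ids = {
                r.query_name
                for r in bam.fetch(row.contig, row.start, row.end)
                if is_primary(r) and not r.is_unmapped
            }
            counts[row.gene_id] = len(ids)
    return counts


def rpkm_per_gene(
    read_counts: Mapping[str, int],
    genes: pd.DataFrame,
    total_mapped: int,
    sensitive_threshold: float = RPKM_SENSITIVE_THRESHOLD,
) -> pd.DataFrame:
    """RPKM per gene; genes with RPKM strictly above the threshold are
    flagged as contamination-sensitive."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    rows = []
    for row in genes.itertuples():
        length_kb = (row.end - row.start) / 1000.0
        count = read_counts.get(row.gene_id, 0)
        rpkm = count / (length_kb * total_mapped / 1e6)
        rows.append((row.gene_id, row.contig, row.start, row.end,
                     count, rpkm, rpkm > sensitive_threshold))
    return pd.DataFrame(
        rows, columns=["gene_id", "contig", "start", "end", "read_count", "rpkm", "sensitive"]
    )
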