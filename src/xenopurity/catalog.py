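"""HAMA catalog construction: contaminant alleles on the host reference.

A HAMA (host-genome-aligned contaminant allele; "human genome-aligned mouse
allele" in the human/mouse setting) is a site where reads of pure
contaminant origin, aligned to the host reference, consistently carry a
non-reference allele. Such sites masquerade as somatic variants once a host
sample is contaminated. This module:

* calls contaminant alleles per pure contaminant sample with a simple
  threshold pileup caller,
* intersects calls across samples to keep only alleles shared by every
  sample (dropping strain- or individual-specific alleles),
* classifies zygosity (heterozygous if any sample reports het),
* computes per-site H_f and H_c, and assigns a risk tier.

Definitions, with DP_mouse the mean contaminant-sample depth at the site and
DP_human the mean host-cohort depth:

    H_f = DP_mouse / (DP_human + DP_mouse)         (allele frequency)
    H_c = H_f / alpha                              (H_f per unit contamination)

where alpha is the known mixing fraction implied by how H_f was measured
(0.5 when contaminant and host depth tables are both full-depth means).
H_c >= 1 marks a high-risk site: its allele frequency at 1% contamination
already reaches 1%, so it is called readily at typical somatic thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from . import pileup
from .samutils import check_coordinate_sorted

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = [
    "contig", "pos", "ref", "alt", "kind", "zygosity",
    "dp_mouse", "dp_human", "h_f", "h_c", "risk", "n_samples",
]


@dataclass(frozen=True)
class VariantCall:
    """One per-sample pileup call (VCF-style coordinates)."""

    contig: str
    pos: int
    ref: str
    alt: str
    kind: str  # "snv" | "indel"
    zygosity: str  # "hom" | "het"
    vaf: float
    depth: int

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class HamaRecord:
    contig: str
    pos: int
    ref: str
    alt: str
    kind: str
    zygosity: str
    dp_mouse: float
    dp_human: float
    h_f: float
    h_c: float
    risk: str
    n_samples: int


def call_contaminant_alleles(
    bam_path: str | Path,
    ref_sequences: dict[str, str],
    min_depth: int = 8,
    min_vaf_het: float = 0.2,
    min_vaf_hom: float = 0.9,
    min_alt: int = 2,
) -> list[VariantCall]:
    """Threshold pileup caller for contaminant reads aligned to the host.

    Emits one call per site where the top alternative allele reaches
    ``min_vaf_het`` at ``min_depth`` coverage and is supported by at least
    ``min_alt`` reads (single-read evidence is never called); zygosity is hom
    when the fraction reaches ``min_vaf_hom``. Multi-allelic columns keep the
    highest-count alt (others are logged at debug level).
    """
    if not (0 <= min_vaf_het <= min_vaf_hom <= 1):
        raise ValueError("need 0 <= min_vaf_het <= min_vaf_hom <= 1")
    with pysam.AlignmentFile(str(bam_path)) as bam:
        check_coordinate_sorted(bam)
        covered = {c for c, n in zip(bam.references, bam.lengths) if bam.count(c) > 0}
        for contig in bam.references:
            if contig not in covered:
                logger.info("no reads on contig %s; skipped", contig)

    calls: list[VariantCall] = []
    for ac in pileup.scan_columns(bam_path, ref_sequences, min_depth=min_depth):
        if ac.depth < min_depth or not ac.alt_counts:
            continue
        if len(ac.alt_counts) > 1:
            logger.debug("multi-allelic column %s:%d %s", ac.contig, ac.pos, ac.alt_counts)
        key = ac.best_alt
        vaf = ac.allele_fraction(key)
        if vaf < min_vaf_het or ac.alt_counts[key] < min_alt:
            continue
        ref, alt = pileup.vcf_alleles(ac.contig, ac.pos, key, ref_sequences)
        calls.append(VariantCall(
            contig=ac.contig, pos=ac.pos, ref=ref, alt=alt,
            kind="snv" if len(ref) == len(alt) == 1 else "indel",
            zygosity="hom" if vaf >= min_vaf_hom else "het",
            vaf=vaf, depth=ac.depth,
        ))
    return calls


def intersect_common(
    per_sample_lists: list[list[VariantCall]],
) -> tuple[list[tuple[str, int, str, str]], list[set[tuple[str, int, str, str]]]]:
    """Split per-sample call lists into the common allele set and
    per-sample specific sets.

    An allele (contig, pos, ref, alt) is *common* when present in every
    sample; it is *specific* to a sample when present in exactly one.
    """
    if len(per_sample_lists) < 2:
        raise ValueError("need at least two samples to intersect")
    key_sets = [{c.key for c in calls} for calls in per_sample_lists]
    common = set.intersection(*key_sets)
    counts: dict[tuple, int] = {}
    for ks in key_sets:
        for k in ks:
            counts[k] = counts.get(k, 0) + 1
    specific = [{k for k in ks if counts[k] == 1} for ks in key_sets]
    return sorted(common), specific


def classify_zygosity(per_sample_lists: list[list[VariantCall]], key: tuple) -> str:
    """Heterozygous if any sample reports the common allele as het, else hom."""
    zygs = [c.zygosity for calls in per_sample_lists for c in calls if c.key == key]
    if not zygs:
        raise ValueError(f"site {key} not present in any sample")
    return "het" if "het" in zygs else "hom"


def compute_hf(
    site: tuple[str, int],
    mouse_depth_table: dict[tuple[str, int], float],
    human_depth_table: dict[tuple[str, int], float],
) -> float:
    """H_f = DP_mouse / (DP_human + DP_mouse) at one site.

    Raises KeyError when a table does not cover the site, and ValueError
    when the combined depth is zero (undefined frequency).
    """
    dp_mouse = mouse_depth_table[site]
    dp_human = human_depth_table[site]
    total = dp_mouse + dp_human
    if total <= 0:
        raise ValueError(f"zero combined depth at {site}; H_f undefined")
    return dp_mouse / total


def compute_hc(h_f: float, alpha: float) -> float:
    """H_c = H_f / alpha: expected H_f per unit contamination fraction."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return h_f / alpha


def classify_risk(h_c: float, threshold: float = 1.0) -> str:
    """High risk iff H_c >= threshold (default 1)."""
    return "high" if h_c >= threshold else "low"


def build_catalog(
    per_sample_lists: list[list[VariantCall]],
    mouse_depth_table: dict[tuple[str, int], float],
    human_depth_table: dict[tuple[str, int], float],
    alpha_calibration: float = 0.5,
    risk_threshold: float = 1.0,
) -> pd.DataFrame:
    """Full catalog over the common allele set, as a tidy DataFrame.

    ``alpha_calibration`` is the effective mixing fraction at which the
    depth tables measure H_f: with full-depth contaminant and host-cohort
    means on both sides it is 0.5. Sites missing from either depth table,
    or with zero combined depth, are dropped with a warning.
    """
    common, _ = intersect_common(per_sample_lists)
    n_samples = len(per_sample_lists)
    rows = []
    for key in common:
        contig, pos, ref, alt = key
        site = (contig, pos)
        try:
            h_f = compute_hf(site, mouse_depth_table, human_depth_table)
        except KeyError:
            logger.warning("site %s:%d missing from a depth table; dropped", contig, pos)
            continue
        except ValueError:
            logger.warning("site %s:%d has zero combined depth; dropped", contig, pos)
            continue
        h_c = compute_hc(h_f, alpha_calibration)
        rows.append(HamaRecord(
            contig=contig, pos=pos, ref=ref, alt=alt,
            kind="snv" if len(ref) == len(alt) == 1 else "indel",
            zygosity=classify_zygosity(per_sample_lists, key),
            dp_mouse=mouse_depth_table[site], dp_human=human_depth_table[site],
            h_f=h_f, h_c=h_c, risk=classify_risk(h_c, risk_threshold),
            n_samples=n_samples,
        ))
    df = pd.DataFrame([r.__dict__ for r in rows], columns=CATALOG_COLUMNS)
    return df.sort_values(["contig", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# catalog I/O

def write_catalog(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"catalog is missing columns: {sorted(missing)}")
    return df


def catalog_to_bed(df: pd.DataFrame, path: str | Path) -> Path:
    """Catalog sites as BED (0-based half-open over the ref allele span)."""
    path = Path(path)
    with open(path, "w") as fh:
        for row in df.itertuples():
            fh.write(f"{row.contig}\t{row.pos - 1}\t{row.pos - 1 + len(row.ref)}\t"
                     f"{row.ref}>{row.alt}\t{row.h_c:.4f}\t.\n")
    return path


def catalog_to_vcf(df: pd.DataFrame, contig_lengths: dict[str, int], path: str | Path) -> Path:
    """Catalog as VCF 4.2 with HF/HC/RISK INFO fields."""
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    header.info.add("HF", 1, "Float", "HAMA allele frequency")
    header.info.add("HC", 1, "Float", "HAMA allele frequency coefficient")
    header.info.add("RISK", 1, "String", "Risk tier (high/low)")
    path = Path(path)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in df.itertuples():
            rec = vcf.new_record(
                contig=row.contig, start=row.pos - 1, alleles=(row.ref, row.alt)
            )
            rec.info["HF"] = float(row.h_f)
            rec.info["HC"] = float(row.h_c)
            rec.info["RISK"] = row.risk
            vcf.write(rec)
    return path
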