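"""Variant-level HAMA blacklisting of call sets.

After read filtering, a handful of contaminant alleles can still surface as
somatic calls. Blacklisting removes call-set records that match catalog
sites, in one of two modes:

* **strict** — every common catalog allele is blacklisted; safest against
  contaminant-derived calls, but discards more coincidental true variants.
* **lenient** — only high-risk alleles (H_c strictly above a threshold,
  default 1) are blacklisted. Note the deliberate asymmetry with the risk
  *tier* (which uses H_c >= 1): both comparisons share the same threshold
  value but the lenient blacklist uses a strict inequality.

Matching is allele-aware — (contig, pos, ref, alt) after left-normalization —
never position-only, so a genuine variant at a catalog position with a
different alternative allele survives.

A contamination-level-dependent policy choice is provided: strict
blacklisting for heavily contaminated samples (alpha at or above a cutoff,
default 50%), lenient otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from . import pileup
from .variants import VariantKey, normalize_variant

FILTER_TAG = "HAMA_BLACKLIST"


@dataclass(frozen=True)
class BlacklistPolicy:
    mode: str  # "strict" | "lenient"
    hc_threshold: float = 1.0

    def __post_init__(self):
        if self.mode not in ("strict", "lenient"):
            raise ValueError("mode must be 'strict' or 'lenient'")


def choose_policy(alpha_hat: float, cutoff: float = 0.5) -> BlacklistPolicy:
    """Strict blacklisting at or above the contamination cutoff (inclusive
    boundary), lenient below it."""
    return BlacklistPolicy(mode="strict" if alpha_hat >= cutoff else "lenient")


def active_blacklist(
    catalog: pd.DataFrame,
    policy: BlacklistPolicy,
    ref_sequences: dict[str, str] | None = None,
) -> set[VariantKey]:
    """The catalog alleles the policy blacklists, as normalized keys."""
    if policy.mode == "strict":
        subset = catalog
    else:
        subset = catalog[catalog["h_c"] > policy.hc_threshold]
    return {
        normalize_variant(row.contig, int(row.pos), row.ref, row.alt, ref_sequences)
        for row in subset.itertuples()
    }


def _check_contig_compatibility(vcf: pysam.VariantFile, catalog: pd.DataFrame) -> None:
    catalog_contigs = set(catalog["contig"].astype(str))
    vcf_contigs = set(vcf.header.contigs)
    offending = []
    for contig in vcf_contigs - catalog_contigs:
        toggled = contig[3:] if contig.startswith("chr") else "chr" + contig
        if toggled in catalog_contigs:
            offending.append(contig)
    if offending:
        raise ValueError(
            "contig naming mismatch between VCF and catalog "
            f"(e.g. chr-prefix): {sorted(offending)}"
        )


def apply_blacklist(
    vcf_in: str | Path,
    catalog: pd.DataFrame,
    policy: BlacklistPolicy,
    vcf_out: str | Path,
    soft: bool = False,
    ref_sequences: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Filter a VCF against the catalog under a blacklist policy.

    A record is blacklisted iff any of its alternative alleles matches an
    active catalog allele. With ``soft=True`` blacklisted records are kept
    and tagged FILTER=HAMA_BLACKLIST instead of dropped. Returns the removal
    report (one row per blacklisted record).
    """
    blacklist = active_blacklist(catalog, policy, ref_sequences)
    vcf_out = Path(vcf_out)
    rows = []
    with pysam.VariantFile(str(vcf_in)) as src:
        _check_contig_compatibility(src, catalog)
        header = src.header.copy()
        if soft and FILTER_TAG not in header.filters:
            header.filters.add(FILTER_TAG, None, None, "Matches HAMA blacklist")
        with pysam.VariantFile(str(vcf_out), "w", header=header) as dst:
            for rec in src:
                hit = any(
                    normalize_variant(rec.contig, rec.pos, rec.ref, alt, ref_sequences)
                    in blacklist
                    for alt in (rec.alts or ())
                )
                if hit:
                    rows.append((rec.contig, rec.pos, rec.ref,
                                 ",".join(rec.alts or ()), policy.mode))
                    if soft:
                        new = dst.new_record(
                            contig=rec.contig, start=rec.start, alleles=rec.alleles,
                            qual=rec.qual, info=dict(rec.info),
                        )
                        new.filter.add(FILTER_TAG)
                        dst.write(new)
                else:
                    dst.write(rec)
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "mode"])


def evaluate_blacklist(
    removed_variants: Iterable[VariantKey],
    origin_truth: Mapping[VariantKey, str],
) -> dict[str, int]:
    """Count blacklist hits by derivation of the removed variant.

    TP: a removed variant whose allele evidence is contaminant-derived.
    FP: a removed variant that is host-derived (a lost true variant).
    """
    tp = fp = 0
    for key in removed_variants:
        origin = origin_truth.get(key)
        if origin == "contaminant":
            tp += 1
        elif origin == "host":
            fp += 1
        else:
            raise KeyError(f"no origin truth for removed variant {key}")
    return {"tp": tp, "fp": fp}


def derive_variant_origins(
    bam_path: str | Path,
    ref_sequences: dict[str, str],
    variants: Iterable[VariantKey],
) -> dict[VariantKey, str]:
    """Attribute each variant to host or contaminant from read-origin pileups.

    For every variant, alt-supporting reads are partitioned by their origin
    tag; the variant is contaminant-derived when contaminant reads provide
    the majority of the alt support (ties and zero support fall to host, the
    conservative choice for counting lost true variants).
    """
    from .simdata import parse_origin

    variants = list(variants)
    sites = [(c, p) for c, p, _, _ in variants]
    by_origin = {}
    for origin in ("host", "contaminant"):
        by_origin[origin] = pileup.count_at_sites(
            bam_path, ref_sequences, sites,
            read_filter=lambda r, o=origin: parse_origin(r.query_name) == o,
        )
    out: dict[VariantKey, str] = {}
    for key in variants:
        contig, pos, ref, alt = key
        pkey = pileup.allele_key(ref, alt)
        host_alt = by_origin["host"][(contig, pos)].alt_counts.get(pkey, 0)
        cont_alt = by_origin["contaminant"][(contig, pos)].alt_counts.get(pkey, 0)
        out[key] = "contaminant" if cont_alt > host_alt else "host"
    return out
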