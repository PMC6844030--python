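"""Variant-representation helpers shared across modules."""

from __future__ import annotations

VariantKey = tuple[str, int, str, str]


def normalize_variant(
    contig: str, pos: int, ref: str, alt: str,
    ref_sequences: dict[str, str] | None = None,
) -> VariantKey:
    """Left-normalize a VCF-style allele pair (trim shared bases, shift left).

    Shifting requires the reference sequence; without it only prefix/suffix
    trimming is applied, which is sufficient when both sides of a comparison
    were produced by the same normalization.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref_sequences is not None and contig in ref_sequences:
        seq = ref_sequences[contig]
        while len(ref) != len(alt) and ref[-1] == alt[-1] and pos > 1:
            prev = seq[pos - 2]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
    return (contig, pos, ref, alt)
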