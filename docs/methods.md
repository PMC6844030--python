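# Methods

This note documents the models, conventions and design choices behind
`xenopurity`, and what the synthetic benchmark does and does not show.

## Problem setting

Sequencing a patient-derived model yields a mixture: a fraction α of reads
originates from the contaminant genome (mouse), the rest from the host
(human). Contaminant reads that align to the host reference deposit
contaminant-specific alleles — HAMAs — at homologous positions, where they
are indistinguishable from somatic variants by allele evidence alone. The
package catalogs these sites, quantifies their sensitivity to contamination,
estimates α per sample, and removes contamination at the read and the
variant level.

## HAMA catalog

Pure contaminant samples are aligned to the host reference and variant-called
with a threshold pileup caller (defaults: depth ≥ 8, alt fraction ≥ 0.2 to
call, ≥ 0.9 for homozygous, alt reads ≥ 2). The caller deliberately stands in
for a production germline caller: the catalog logic downstream — not the
caller — is the substance, and external call sets can be substituted
anywhere a list of (contig, pos, ref, alt, zygosity) is accepted. Calls
present in **every** contaminant sample form the common catalog (dropping
strain- or individual-specific alleles); a site is heterozygous if *any*
sample reports it heterozygous. Multi-allelic columns keep the
highest-count alternative.

Per site, with `DP_mouse` the mean depth over the contaminant samples and
`DP_human` the mean host-cohort depth (a user-supplied table; the synthetic
pipeline derives it from simulated host samples, standing in for a
population-scale coverage resource):

* `H_f = DP_mouse / (DP_human + DP_mouse)` — undefined at zero combined
  depth; such records are dropped with a warning.
* `H_c = H_f / α_cal`, where `α_cal` is the effective mixing fraction of the
  measurement (0.5 for two full-depth tables; exposed as
  `alpha_calibration`).
* risk tier: high iff `H_c ≥ 1` (inclusive). Note the deliberate asymmetry
  with lenient blacklisting, which uses the strict inequality `H_c > 1` —
  both follow the respective printed definitions, share one threshold value,
  and differ only in the comparison; the boundary class (`H_c == 1`) is
  high-risk but not leniently blacklisted.

Coordinates are 1-based VCF-style throughout; capture targets are 0-based
half-open (BED). Indels are anchored on the preceding base. Internally,
indel calls keep the pileup anchor produced by the aligner (the affine-gap
rescue places a given indel at one consistent reference position across
reads, so per-sample representations agree); comparisons across
representations — blacklist matching, truth evaluation — left-normalize both
sides first (`variants.normalize_variant`).

## Contamination estimation

Per site, `H_f(α) = α · H_c` and hence `α = H_f / H_c`. Aggregated, the
median catalog-allele frequency of one sample is linear in α, giving

`α̂ = median(H_f) / c`,

clamped to [0, 1]. Only catalog sites with nonzero depth in the query sample
contribute; fewer than 100 sites triggers an instability warning; an empty
catalog yields α̂ = 0 by definition (no allele evidence of contamination).
The median of an even-length list is the mean of the central pair. The
default `c = 0.7519` is the published whole-exome human/mouse value;
`calibrate()` fits `c` as the through-origin least-squares slope of
median-`H_f` against known α (weighting each point by α², which the normal
equations imply), and reports a 95% interval of estimation error from
leave-one-out residuals. The linear model is known to bend at very high
contamination (≈80%); modeling that nonlinearity is out of scope.

## Read filtering

All three methods partition **fragment IDs** (both mates removed together,
matching ID-based removal semantics of standard tooling). Secondary and
supplementary records never trigger removal.

* **ConcatRef**: align once to the host+contaminant concatenated reference
  (contaminant contigs prefixed `mm_`); remove fragments whose primary
  alignment sits contaminant-side. Score ties are left to the upstream
  aligner's primary designation; the filter does not re-adjudicate. Fragments
  unmapped on both sides are retained — they carry no variant evidence.
* **DualRef-S**: remove every fragment mapped in the contaminant-reference
  alignment. Maximal sensitivity; on highly homologous genome pairs it
  sacrifices most host reads.
* **DualRef-L**: remove only fragments whose contaminant alignment is perfect
  (NM = 0). By construction `removed(DualRef-L) ⊆ removed(DualRef-S)`, which
  forces sensitivity(S) ≥ sensitivity(L) and specificity(S) ≤ specificity(L).

## Benchmarking

With origin-tagged reads: TP = contaminant fragment removed, TN = host
fragment retained; sensitivity = TP/(TP+FN), specificity = TN/(TN+FP). The
**F-score is the harmonic mean of sensitivity and specificity**, not the
precision/recall F1 — read-class sizes vary wildly across contamination
rates, and this balanced form is the convention in xenograft-filter
comparisons. Replicate metrics are aggregated as plain means. Post-filter
effects are measured as the signed sum over catalog sites of the change in
catalog-allele frequency, and as the count of sites still exceeding
mutation-calling minimums (allele fraction strictly > 5% **and** alt reads
strictly > 5; both configurable). Gene-level contaminant load is RPKM over
supplied gene intervals, with RPKM strictly > 40 flagging a gene as
contamination-sensitive.

## Blacklisting

A call-set record is blacklisted iff one of its alternative alleles matches
an active catalog allele — allele-aware (contig, pos, ref, alt after
left-normalization), never position-only, so a coincidental true variant at
a catalog position with a different allele survives. Strict mode activates
every common catalog allele; lenient mode only `H_c > 1`. Soft mode tags
records `FILTER=HAMA_BLACKLIST` instead of dropping them and preserves
record counts exactly. Removed variants are evaluated against read-origin
truth: a variant is contaminant-derived when contaminant-origin reads supply
the majority of its alt support (ties fall to host — conservative when
counting lost true variants). The contamination-dependent policy picks
strict at α̂ ≥ 0.5 (inclusive boundary, cutoff configurable — the cutoff is
heuristic, not derived).

## Synthetic data generator

The generator emulates the study conditions end to end:

* **Genome pair**: i.i.d. random host contigs; contaminant = host with
  per-base SNV rate 0.01 (about the coding-region divergence scale at which
  ~3% of covered bases carry a contaminant allele), indel rate 5×10⁻⁴,
  and 10% of divergent sites heterozygous in the contaminant (matching the
  observed preponderance of homozygous contaminant alleles). Truth indels
  are stored left-normalized. A contaminant-only contig (10% of the genome)
  models contaminant sequence with no host homolog, so filters can remove
  reads that simply fail to map to the host.
* **Reads**: paired 2×100 bp, insert 300 bp, drawn uniformly over exome-like
  capture intervals (default 50% of each contig in 500 bp tiles) to a target
  mean depth. Heterozygous sites emit either allele with probability ½ via
  two contaminant haplotypes. Sequencing error is substitution-only at
  10⁻³ with constant base quality — error-profile realism is not the object
  of study. Read origin is a read-name suffix (`|org=host`), surviving FASTQ
  round-trips; absence parses as `unknown`.
* **Mixtures**: a mixture at rate r samples `round(total · r)` contaminant
  reads and the complement of host reads, pair-atomically and without
  replacement, deterministically per seed. The canonical design is 2 host ×
  5 contaminant samples × rates {5, 10, 20, 50, 80}% × 3 seed replicates =
  150 mixtures. Pair-atomic sampling requires even per-source read counts.

**What the synthetic data does not show.** Capture is uniform over targets
(no capture-efficiency bias, GC bias or quality structure); host samples
carry no private (somatic or germline) variants, so blacklist
false-positive counts on synthetic data are structurally near zero and the
strict-vs-lenient FP comparison is directional only; divergence is i.i.d.
rather than clustered homology, so absolute filter operating points (e.g.
DualRef specificities) differ from real human/mouse values even though all
orderings and containments hold. Passing tests therefore validate the
machinery and its invariants, not field performance on real exomes.

## The built-in aligner

A seed-and-extend aligner sufficient for these genomes: exact 21-mer
seeding at three read offsets, gapless Hamming extension, and an affine-gap
rescue (Biopython `PairwiseAligner`: match 1, mismatch −2, gap open −4,
extend −0.5, free reference flanks) for reads spanning indels. Affine costs
keep gaps contiguous and, with deterministic tie-breaking, place a given
indel at the same reference coordinate for every read that spans it — which
is what makes pileup indel columns well-defined. NM is the edit distance of
the reported alignment. Reads with best NM > 10 are unmapped; ties on
(NM, contig, position, strand) resolve deterministically, which sends
score-tied ConcatRef fragments to the host side (they carry no divergent
base, mirroring a real aligner's arbitrary primary pick without its
randomness). MAPQ is 60 for unique bests, 0 for ties. External aligners can
be substituted by supplying any coordinate-sorted BAM.

## Benchmark problem sizes

The estimator benchmark runs on a 1-contig 100 kb genome pair at 50× target
depth: 3 contaminant + 2 host samples for the catalog (~700–800 common
alleles), calibration on one held-out sample pair mixed at each rate × 3
replicates, and queries on a second held-out pair at {5, 10, 20, 50}% × 3
replicates. Mixture alignments reuse the per-sample alignments (alignment is
per-read, so subsetting pre-aligned BAMs by the sampled fragment IDs is
exactly equivalent to aligning the mixed FASTQ; the equivalence is asserted
in the tests). At this size the 97.5th percentile of |α̂ − α| lands near one
percentage point; the residual error is dominated by the discreteness of
per-site allele fractions at 50× (the median moves on a lattice of ≈1/depth)
plus calibration-transfer noise, both of which shrink with depth and catalog
size.

## Known limitations

* The pileup caller has no local reassembly; dense variant clusters can
  shadow each other. Indel columns depend on the rescue aligner's (single,
  consistent) gap placement.
* `H_c` from two full-depth tables assumes the contaminant and host depth
  profiles are each representative; with very uneven target coverage the
  0.5 effective mixing fraction is approximate.
* ConcatRef's host-side tie-break retains contaminant fragments that carry
  no divergent base in either mate; these contribute no false alleles but
  cap read-level sensitivity below 1 on homologous contigs.
* Wrappers for external deconvolution tools, somatic-caller integration and
  strain-specific references are out of scope.
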