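# Methods

## The identity panel

The bundled QRC-80 panel (`src/snpqr/data/panel_qrc80.tsv`, build b37,
1-based positions) contains 74 fingerprint SNPs and six auxiliary markers.
The fingerprint markers were chosen, upstream of this package, by a
cascade this package also re-implements for custom panels: intersection of
eight commercial array manifests, minor allele frequency above 0.25 in
each of the five continental 1000 Genomes populations (AFR, EUR, AMR, EAS,
SAS), removal of strand-ambiguous A/T and C/G variants and of anything
with a pathogenic annotation, and one marker per 10 Mb region, keeping the
highest overall MAF. The shipped panel satisfies, and
`validate_panel` checks: 20 autosomes covered (15 and 21 absent), all
overall MAFs > 0.3, minimum adjacent same-chromosome gap 10,138,304 bp
(mean 37.4 Mb).

Only the overall reference-allele frequency is bundled per fingerprint
marker; per-subpopulation frequencies are not part of the resource, so the
simulator and the collision closed form both work on the pooled frequency.

### Auxiliary markers

The panel resource documents the six auxiliary markers with annotations
fixed from dbSNP/literature at packaging time, since they are not part of
the fingerprint math:

- ABO: rs8176719 (exon-6 single-base deletion; the b37 reference carries
  the deletion, so `ref=del`, and DTC files report D/I tokens), rs41302905
  (alt T tags O2), rs8176746 (alt T tags B), rs56392308 (deletion tags the
  A2 subtype). Simulation frequencies are approximate global values
  (O1-deletion 0.63, O2 0.01, B 0.11, A2 0.04) and affect only synthetic
  cohorts, not inference.
- Sex: rs12743401 and rs12734338 lie in paralogous regions of chromosomes
  1 and Y; array chemistry reads both paralogs at once, so apparent
  heterozygosity indicates a Y chromosome. Their coordinates in the
  resource are **provisional placeholders**: marker lookup is rsid-first
  with a chrom:pos fallback, so these positions are never load-bearing for
  real rsid-keyed DTC data, but files keyed only by position will not
  match these two markers.

## Payload and QR dialect

`serialize` emits one two-character token per marker in panel order,
alleles in lexicographic order, missing as `--` — 160 characters for the
bundled panel. A fixed-width missing token (rather than a single dash) is
required for an index-free payload to be decodable; this is a documented
dialect choice, and interoperability with other encoders of the same idea
is not guaranteed (the payload deliberately carries no header or panel
identifier).

The QR layer is a complete model-2 implementation written for this
package: byte mode, versions 1–40 (a 160-character payload lands in
version 9), error-correction level M by default, mask chosen by the four
standard penalty rules, format/version words BCH-protected. Correctness
rests on three independent anchors: (1) the error-correction block table
is validated against each version's symbol geometry (total codewords are
fully determined by the function-pattern layout); (2) the format and
version words reproduce published reference values; (3) the decoder is a
separate path (pixel sampling → format read with error-tolerant matching →
unmask → de-interleave → Reed–Solomon correction, with error magnitudes
obtained by solving the syndrome system exactly over GF(256)), exercised
in tests with randomly damaged symbols. The decoder assumes a clean,
axis-aligned, flat image (as produced by the encoder or any standard
renderer); perspective correction and photographic robustness are out of
scope. Agreement with independent third-party QR readers has not been
verified in-repo; the round-trip contract (decode ∘ encode = identity,
byte for byte) is what the tool relies on and what is tested.

## Match semantics and verdicts

`classify_pair` precedence: missing → perfect (byte-identical tokens) →
permuted (same unordered pair) → strand (token equals the Watson–Crick
complement in the same order) → strand-permuted (unordered pairs equal
after complementation) → mismatch. All four non-missing match classes
count toward concordance. D/I indel alleles have no strand complement and
can only match perfectly or permuted. Because fingerprint markers are
never A/T or C/G, a genotype and its complement cannot both occur
legitimately at a marker, which is what makes the strand scenarios safe.
The classifier is verified exhaustively against a brute-force
permutation/complementation oracle over all token pairs.

`compare_fingerprints` reports per-class counts, the missing count and the
non-missing overlap, and a verdict: *concordant* when matches/compared ≥
0.95, *inconclusive* when fewer than 20 markers could be compared, else
*discordant*. The 0.95 threshold and the minimum informative overlap of 20
are this package's decision rule (the underlying match semantics prescribe
counts, not a cutoff); both are configurable parameters. With an expected
~0.38 background rate between unrelated individuals and per-marker match
variance ≈ 0.24, 20 markers keep the two hypotheses (same sample vs
different samples) many standard deviations apart, while duplicate runs of
the same sample fail 0.95 only with > 4 genotyping errors among 80
markers. The report states concordance, never identity.

## ABO and sex inference

ABO calls enumerate every diplotype consistent with the observed unphased
genotypes: each haplotype is O if it carries the rs8176719 deletion or the
O2 tag, else B if it carries the B tag, else A; the pair of haplotype
alleles gives the group. If exactly one group is consistent it is called.
With no missing markers but several heterozygous ones, phase is resolved
parsimoniously — variant tags placed on distinct haplotypes, the
configuration overwhelmingly more likely in populations — and cis
alternatives are listed in the notes. Missing markers widen the consistent
set: the call degrades to *ambiguous* (with candidates listed) and to
*unknown* only when all four markers are missing. This enumeration makes
the monotone-missingness property structural: dropping a marker can never
flip one concrete group to another. The A2 tag is reported as a note only
and never changes the major group.

Sex: heterozygosity at the chr1/Y markers is male evidence, homozygosity
at all non-missing markers is called female, conflicting non-missing
markers yield *ambiguous* (with only two markers, majority voting is
meaningless), both missing yields *unknown*.

## Panel derivation

`filter_candidates` requires MAF ≥ cutoff in **all five** subpopulations
(the comparison is inclusive at the boundary; exact hits are flagged in
the derivation log), drops strand-ambiguous pairs and user-supplied
exclusions (pathogenicity filtering is an exclusion list, not a database
query, keeping the tool download-free). `prune_by_region` interprets "one
marker per region" as a pairwise same-chromosome spacing constraint,
served greedily in overall-MAF-descending order (ties broken by (chrom,
pos) for determinism) — the strictest reading consistent with the bundled
panel, which satisfies pairwise ≥ 10 Mb spacing. A fixed-tiling
interpretation would permit adjacent markers closer than the region size
across a tile boundary. With `region_size_bp=0` pruning is the identity
(up to sorting). Derived panels always satisfy `validate_panel` at their
own config thresholds provided the reference's overall AF is a population
mixture of the subpopulation AFs (true of any real reference, and of the
test generators).

`cross_tabulate` fills the diagonal with manifest sizes, the upper
triangle with pairwise intersection counts, and the lower triangle of row
*i* with the running intersection of the first *i*+1 manifests in the
given order (hence constant along each row below the diagonal, and
monotone non-increasing down columns).

## Simulation model

Cohorts are drawn under Hardy–Weinberg equilibrium at each marker's
bundled overall frequency, independently across markers — the panel's
≥ 10 Mb spacing exists precisely to justify marker independence — and
independently across individuals. ABO markers use the documented
approximate frequencies; sex markers are drawn conditionally on a 50/50
sex label (females homozygous, males heterozygous). Optional missingness
and genotype-error rates apply per call. Everything is deterministic given
the seed.

What the simulator does *not* emulate: population structure (a single
pooled frequency per marker, no per-subpopulation mode), residual LD,
relatedness, genotyping-platform error profiles, or strand-flip
conventions between vendors (simulated datasets are all on one strand, so
cross-comparisons exercise the strand scenarios only via explicitly
complemented fingerprints in tests). Passing simulation-based tests
therefore demonstrates the pipeline's correctness under the panel's own
model assumptions, not robustness to real-data artefacts.

Problem sizes used by the test suite and the acceptance script — 150,000
individuals for the uniqueness check (matching the biobank-scale test the
panel was designed for), 5,000 pairs for the concordance calibration,
50,000 individuals for HWE goodness-of-fit, 100 random payloads for QR
round-trips — are the package's chosen desk-scale study conditions; the
uniqueness check operates on the vectorized dosage matrix (dosage 0/1/2
identifies the genotype class at a bi-allelic marker, which is sufficient
for collision counting).

## Numerical and degenerate-input choices

- Genotypes are unordered for equality/hashing but preserve observed
  order so the perfect/permuted distinction remains observable.
- Single-letter hemizygous DTC calls (X/Y/MT) are promoted to homozygous
  pairs; the payload format has no one-letter state.
- Alleles that match neither ref/alt nor their complements are kept
  verbatim and scored as mismatches — no silent recoding.
- An empty comparison overlap yields rate 0.0 and verdict *inconclusive*;
  a panel with < 2 markers on any chromosome reports its minimum adjacent
  gap as undefined (`None`) and passes spacing vacuously.
- Concordance thresholds, the QR error-correction level and module scale,
  and derivation cutoffs are all explicit keyword parameters with the
  defaults stated above.

## Known limitations

- The two sex-marker coordinates are provisional (see above).
- ABO inference covers the four bundled tags only; rare alleles (cis-AB,
  weak subgroups) are out of scope, as is full haplotype phasing.
- The QR decoder targets clean rendered images, not photographs.
- Real vendor manifests and the full 1.4M-variant allele-frequency
  reference are not shipped; the derivation and cross-tabulation
  algorithms are exercised on synthetic references and manifests.
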