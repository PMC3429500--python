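# Methods

This note documents the models, rules and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the underlying procedure was
genuinely open.

## Study design and coordinate conventions

The analysis assumes four small-RNA libraries from two genotypes of
trifoliate orange at two developmental stages: WT1/MT1 (juvenile) and
WT2/MT2 (adult), where MT is the early-flowering mutant. Library order is
fixed everywhere as (WT1, WT2, MT1, MT2).

Genomic coordinates are 1-based inclusive at every I/O boundary (GFF3,
the packaged catalog, reported precursor intervals) and 0-based half-open
internally. Under the 1-based inclusive convention the shortest published
precursor (scaffold_14:4093405:4093478) is 74 bp, matching the published
range, which is what fixed the convention. Sequences are stored in DNA
spelling (T); T and U are treated as the same base by all pairing logic,
so RNA-spelled inputs (e.g. mature reference sets) are accepted unchanged.

## Read cleanup

The published pipeline names no specific trimmer, so the rules here were
chosen to be deterministic and testable by enumeration:

- **3′ adapter**: the longest read suffix matching a prefix of the adapter
  with ≥ 7 nt overlap and ≤ 1 mismatch per 7 nt of overlap is removed.
  Reads without an admissible match are dropped as adapter-less (every
  genuine insert, being shorter than the read, must run into the adapter).
- **Quality**: any base below Q10 drops the read (threshold configurable);
  the original platform-specific criteria are not public.
- **5′ contaminants**: reads beginning with ≥ 10 exact nt of the 5′ adapter.
- **Length window**: 18–30 nt inclusive, matching the gel-purified size
  range; the 20–24 nt "Dicer window" is a reporting view, never a filter.
- **Collapsing**: identical inserts become one tag with per-library counts;
  per library, tag counts sum exactly to the clean read total (asserted
  throughout the tests). Length distributions are read-weighted.

## Mapping and classification

Tags are aligned ungapped to both genome strands with at most one
substitution. The index stores all 9-mers of each scaffold; a query's two
non-overlapping 9-mer seeds guarantee by pigeonhole that every ≤1-mismatch
locus is seeded for tags ≥ 18 nt, so the index is exactly equivalent to an
all-offsets brute-force scan (property-tested against an independent
scanner). A 9-mer was chosen over a longer seed because two disjoint
12-mers would only cover tags ≥ 24 nt.

Tags mapping to more than 20 loci are flagged hyper-repetitive and excluded
from miRNA candidacy (the cap is configurable; the original analysis is
silent, and the cap keeps discovery specific without discarding the tally).
A tag inherits a feature's category when an alignment overlaps it by ≥ 50%
of the tag length; with several candidates the precedence
rRNA > tRNA > snRNA > snoRNA > other ncRNA > repeat > miRNA-candidate
applies, reproducing the discard-structural-RNA-first behaviour. Repeats
are excluded from candidacy by default (flag `exclude_repeats`).
Classification partitions every library's clean reads across categories
plus "unannotated" and "unmapped".

## Folding engine

The built-in engine minimises a deliberately small energy model over nested
structures (no pseudoknots): a pair stacked directly on another pair
contributes G-C/C-G −3.0, A-U/U-A −2.0, G-U/U-G −1.0 kcal/mol; closing a
hairpin loop costs +3.0; hairpin loops hold ≥ 3 unpaired bases; bulges,
interior loops and multiloops are free. The dynamic program is O(n³)
(numba-compiled) with an exact traceback; for sequences up to 25 nt it is
verified against exhaustive enumeration of every nested structure
(~1,000 random cases in the test suite).

The model intentionally does **not** reproduce Turner-parameter folders:
published minimum-free-energy values (such as those in the packaged
catalog) are consumed as data and never recomputed. What the model
preserves — and what discovery relies on — is stem geometry: perfect or
near-perfect complements fold back, stronger stems score lower, and a
−18 kcal/mol ceiling still separates designed hairpins (typically −45 and
below under this model) from unstructured windows. Because loop penalties
beyond the hairpin closure are zero, the engine is more eager than a
thermodynamic folder to extend helices using loop/flank bases; the duplex
validator compensates (below). External folders can be substituted behind
the same `fold(sequence) -> HairpinStructure` contract.

## Novel-miRNA discovery

Candidate tags (mapped, non-structural, non-repeat, not hyper-repetitive)
are clustered per scaffold with a 30-nt merge gap. For each cluster the
most abundant tag anchors two windows per strand (upstream-flanked and
downstream-flanked, flank 250 nt, clipped to the scaffold and to 400 nt;
windows shorter than 50 nt are discarded). Since mature and star arms
usually form separate clusters, windows are populated with *every*
candidate tag aligning inside them, not only the anchoring cluster's tags.

A folded window is accepted as a novel miRNA when:

- the most abundant placed tag of length 20–24 nt (the mature) sits on one
  arm — ties in abundance resolve to the leftmost (5′) placement;
- a second, non-overlapping tag (the star) satisfies the duplex geometry;
- window MFE ≤ −18 kcal/mol (the least-negative published precursor
  energy; configurable);
- the precursor span (duplex plus loop, extended along the closing stem)
  is 50–400 nt.

Duplex geometry is inferred from the pairing via the duplex *register*: in
a clean antiparallel duplex i + partner(i) is constant, so the register is
estimated as the median of i + partner(i) over mature bases pairing into
the star interval, and pairs drifting more than 2 from it are treated as
outside the duplex. This makes the 2-nt 3′-overhang test (tolerance ±1 nt,
evaluated on both strands by projecting the register onto the two tag
intervals) robust to end-drift in the simplified fold. At most 4 mature
bases may be unpaired within the duplex (the two 3′-overhang positions
excluded) and the register spread (bulge asymmetry) may not exceed 2 nt.

Accepted calls are deduplicated twice: by mature sequence (keeping the
lowest-energy precursor) and by genomic overlap — the reverse complement
of a hairpin is also a hairpin, so one locus can validate on both strands
with the arms swapped; the call with the more abundant mature wins. Ids
are assigned NovelNN in genomic order.

Conserved calls require an ungapped reference match with ≤ 3 mismatches
over the aligned overlap (length difference ≤ 2 nt; ties go to the first
reference id in sorted order), at least one perfect genome alignment, and
a flanking window folding at or below the same energy ceiling. Families
group reference variants by stripping species prefixes and variant
suffixes (csi-miR166e → miR166); star references keep their family with a
star flag. When one mature sequence is called both ways the conserved call
wins, with a warning.

## Expression profiling

RPM = count × 10⁶ / library size. Two framings coexist because both are
standard: the up/down census compares raw counts strictly (down if the
adult count is lower), while the *differential* flag applies the two-fold
rule to the RPM ratio (ratio > 2 or < 0.5). Ratios use no pseudocount:
detection in exactly one stage yields a stage-only class (differential by
definition) rather than an infinite ratio, and zero in both stages is
"absent". Whether the original ratios used raw or normalised counts is not
stated; RPM is the default and raw counts remain available. Presence sets
(MT-only / WT-only / shared / absent) partition the catalog by genotype
detection; inverse patterns are rows strictly up in one genotype and down
in the other.

## Target prediction

Scoring is positional over the antiparallel duplex (miRNA position 1 = 5′
nucleotide): Watson-Crick 0, G:U wobble 0.5, mismatch 1.0, no gaps. A
window is a site when penalty ≤ 2 *and* the positional rules hold: ≤ 1
mismatch opposite positions 2–11, none at the cleavage site (10–11), ≤ 3
mismatches in 12–21 with no run of three, ≤ 4 mismatches overall. The
published 2–12 and 12–21 windows overlap at 12; position 12 is assigned to
the 3′ regime here (switchable). The penalty weights are the minimal
scheme consistent with those printed rules (no seed-region doubling);
penalty cap and positional rules are applied conjointly, the strictest
reading. Sites are labelled 5′UTR/ORF/3′UTR by their midpoint against the
transcript's annotated ORF boundaries (all-ORF with a warning when
annotation is missing). Duplex ΔG reuses the folding engine's stacking
energies (a paired position stacks when its predecessor is paired), and
the energy ratio ΔG(site)/ΔG(perfect complement) is 1 for perfect sites,
0 with nothing stacked, and non-increasing as pairs are lost.

## RA-PCR cleavage evidence

Inputs are reference-gene-normalised relative quantities of three
amplicons per transcript (5′, middle — spanning the predicted site — and
3′); raw Cq processing and efficiency correction are out of scope. The
middle/3′ ratio (and 5′/3′ when an upstream amplicon exists) is
scale-invariant; a transcript is cleavage-supported when middle/3′ falls
below 0.6 in *every* assayed sample. The 0.6 threshold sits above the
largest published cleavage-consistent ratio (0.51) and well below 1; the
all-samples rule is the strict reading of an unstated requirement. Both
are configurable, and support is monotone in the threshold.

## Synthetic data

The generator emulates what the analysis assumes: scaffolds with embedded
hairpin loci (built as mature + loop + star with the canonical 2-nt 3′
overhang geometry; designed star mismatches are non-complementary
substitutions placed away from the duplex ends, so G:U wobbles arise
naturally), structural-RNA and repeat loci shedding uniformly positioned
18–30-nt degradation fragments (reproducing the roughly half-structural
read fraction of real libraries), per-library expected abundances with
genotype-exclusive and 4-fold stage-effect loci, a star fraction well
below the mature, 3′ adapters on every read, and i.i.d. substitution
errors. Reads per library are drawn with a single multinomial so totals
are conserved exactly; everything is deterministic per seed. A
convenience sampler draws log-normal(μ=3, σ=1.5) expectations when no
explicit abundances are given.

The default benchmark embeds 20 miRNA loci (mature 20–24 nt, 21 nt
commonest; loops 15–60 nt; 0–2 designed mismatches; every locus ≥ 50
expected reads per detected library) among 9 structural, 3 repeat and 6
random loci on two 120-kb scaffolds, with 50,000 reads per library at a
0.1% substitution rate — a desk-scale stand-in for the multi-million-read
libraries of a real experiment, sized so the full pipeline runs in tens of
seconds. On it, novel discovery achieves sensitivity ≥ 0.9 at zero-to-low
false discovery across seeds (asserted in the tests at ≥ 0.9 / ≤ 0.05).

What the generator does **not** emulate: realistic quality-score
distributions, indel errors, ligation biases, paired ends, isomiR
heterogeneity, or multi-million-read scale. Passing tests therefore
demonstrate the pipeline's correctness under its stated assumptions, not
performance on any particular real library.

## Packaged catalog

The catalog of 75 published novel miRNA loci is stored verbatim as
tab-separated text (DNA spelling; strand unset, as the source table gives
none) and validated on load (exactly 75 records, negative energies,
non-negative counts, end > start). One census in its source prose (17
mutant-only loci) disagrees by one with the table it summarises (18
qualifying rows, two of them sharing an identical count pattern that looks
like a duplication); the package reports what the table contains.

## Known limitations

- The folding model's absolute energies are not thermodynamic; only
  orderings and geometry are meaningful.
- Discovery assumes the mature strand is the more abundant arm; loci where
  the star dominates would be reported arms-swapped.
- Conserved-call validation does not require a star read (homology plus a
  folding genomic precursor), so it is more permissive than novel-call
  validation, mirroring standard practice.
- GO/KEGG roll-ups only count genes per term from user-supplied mappings;
  no enrichment statistics are computed because the underlying design has
  no replication to support them.
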