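# Methods

## Problem and model

Centromeric satellite DNA consists of short monomers (alpha satellite:
~171 bp) arranged head-to-tail. Individual monomers within an array
diverge by roughly 20–40%, but most arrays carry a second level of
order: a higher-order repeat (HOR) of *n* monomers that repeats with
>95% identity between copies. The package annotates this structure
from an ordered monomer list alone, with no alignment to a reference
HOR model.

The core quantity is the **next-similar distance**: for monomer *i*,
the smallest lag *d* ≥ 1 such that monomer *i+d* diverges from *i* by
less than the similarity threshold, or 0 if no later monomer does. In
a clean *n*-mer HOR array every monomer's next-similar distance equals
*n*; deletions, insertions and unit-internal duplications perturb the
distances in characteristic ways (a deletion of *k* monomers shortens
the distances of the preceding unit to *n−k* and lengthens those of
the orphaned types to *2n−k*; a duplicated type inside the unit splits
its distance into the two intra/inter-unit spacings).

Three derived views are produced:

* the **period spectrum** (GRM diagram): the histogram of nonzero
  next-similar distances — the monomeric analogue of a Southern-blot
  band ladder;
* the **MD diagram**: monomer ordinal vs next-similar distance, which
  localises HOR regions along the array;
* the **aligned scheme**: monomers as coloured boxes, one column per
  monomer type, each row reading as one (possibly variant) HOR copy.

## Divergence and typing

Divergence is Levenshtein edit distance (edlib, full alignment, no
band by default) normalised by the longer sequence length; the
similarity predicate is *strictly* below the threshold. The default
threshold is 0.05, reflecting the documented 95–99% identity between
HOR copies. The normalisation denominator matters only for unequal
lengths; max-length is the conservative convention and makes one
substitution in a 171-mer exactly 1/171 ≈ 0.585%.

`N` bases mismatch everything, including another `N` (implemented by
masking the two sides with distinct placeholder characters before
alignment), so assembly-gap runs can never create similarity.

Monomer types are the connected components of the next-similar links
{i ↔ i + d_i}. This is single linkage: a chain of <5% steps can join
monomers whose direct divergence slightly exceeds 5%. We chose links
over all-pairs cliques because the links are exactly what the
next-similar vector records; at the 20%+ inter-type divergences of the
fixtures the two definitions coincide. Labels t1, t2, … follow the
first occurrence of each component's earliest member, so the first
monomer of an array is always type t1.

## Region segmentation

HOR regions are read off the next-similar vector with a sliding window
(default 20 monomers, step 1). A window is *periodic* with period *p*
when *p* ≥ 2 is the modal nonzero distance in the window **and**
accounts for at least half of the window's nonzero entries (ties in
the mode go to the smaller period, the minimal repeating unit).
Maximal runs of at least `min_support` (default 3) consecutive windows
agreeing on *p* become candidate regions; overlapping candidates with
different periods are resolved greedily by descending support, and a
candidate trimmed below one window length is dropped.

The majority requirement is what separates signal from noise: in a
true HOR region the dominant period covers nearly all entries of every
window, whereas in a randomly shuffled array the modal distance covers
only ~15–25% of a 20-entry window, so random arrays yield no region at
all. Period-1 runs (consecutive identical monomers) are not HORs and
are excluded by the *n* ≥ 2 constraint. The defaults were chosen so
that the smallest realistic fixture (10 copies of an 8-mer) forms one
region while 100-monomer random arrays form none; both window and
support are exposed on the CLI.

## Canonical unit, copies, classification

Within a region of dominant period *n*, all length-*n* windows of the
type-label sequence are tallied and the modal window fixes the
canonical unit's content. Its phase is then rotated so the unit starts
at the member type that occurs earliest in the region — under
first-occurrence labelling, t1 — matching the aligned-scheme
convention that column 1 is t1. The re-phasing is deliberate: an early
deletion variant can make a rotated window the modal one, and without
re-anchoring every subsequent copy call would be phase-shifted and the
leading partial unit miscounted as a variant.

τ is the number of distinct labels in the unit. The unit is
**Willard's** when every label occurs exactly once (τ = n) and
**Cascading** otherwise (τ < n) — a pure function of the unit's label
multiset.

Copies are tiled greedily left-to-right: at each cursor, candidate
windows of length n−k … n+k (k = `max_indel`, default 4) are scored by
label-level Levenshtein distance to the canonical unit and the best
(ties: length closest to *n*, then shorter) is emitted. Exact matches
are canonical; others are variants with recorded insertion/deletion/
substitution ops against unit positions. Label-level (not
sequence-level) distance is used because variant HORs are defined by
whole-monomer insertions and deletions. A trailing remnant shorter
than n/2 is left untiled and retrievable separately, so concatenating
copies plus remnant always reconstructs the region's label sequence
exactly.

Interleaved arrays (two sub-units alternating inside one region) are
reported as a single region with a composite unit; `repeated_subblocks`
lists the maximal repeated contiguous sub-blocks of the unit to
support dual accounting of sub-unit copies.

## Monomer extraction

`find_monomers` aligns a consensus monomer semi-globally (edlib infix
mode) against each contig and its reverse complement. Hits are
collected by recursive best-first splitting: the best hit of a segment
is recorded, then the flanking segments are searched — the greedy
best-divergence-first tiling of a tandem array. Hits above the
acceptance divergence (default 0.35, inclusive for monomers that
diverge 20–40% from each other), hits overlapping a better hit by more
than 10% of the query length, and hits containing an N-run of ≥5 are
discarded. Reverse-strand hits keep genomic-forward coordinates with
strand "−" and store the reverse-complemented (query-frame) sequence,
so downstream similarity always compares monomers in one frame. The
acceptance divergence is a free parameter because no principled value
exists without knowing the family's depth; it is exposed on the CLI.

## Synthetic fixtures

The generator reproduces the four structured study designs at their
stated sizes, which are also the package's acceptance conditions:

* **canonical**: 10 random 171-bp types, all pairwise divergences
  > 20%, tandem-repeated 10× (100 monomers). Every next-similar
  distance is 10 except the final copy's zeros.
* **variant**: the canonical array with monomers 18, 19, 38, 39
  deleted and the same novel monomer pair inserted after original
  monomers 66 and 86 (insertions anchored to original identities;
  N stays 100). This produces deletion variants (periods 8 and 18),
  insertion variants (period 12), a 22-distance between the two
  insertion sites, and terminal zeros for the second inserted pair.
* **cascading**: unit t1…t6, t2, t7…t10 repeated 10× (110 monomers):
  dominant period 11 with secondary peaks at exactly 5 and 6.
* **random**: 100 uniform draws from the 10 types — no region.

Divergence floors are enforced by rejection sampling; random 171-mers
sit near 50% pairwise divergence, so rejection is rare. Fixtures are
byte-deterministic given their seed; the seedable generator, not any
particular PRNG, is the contract.

For extraction tests a separate **consensus family** generator mutates
a random consensus at 15% per type (types ≤ 20% from the query,
mutually > 12% divergent). Mutually >20%-divergent random types would
sit ~50% from any single consensus — unreachable for a consensus
query and unlike real satellite families, which are consensus-derived.

What the fixtures do **not** emulate: within-type sequence noise is
off by default (a 1–4% substitution mode exists for robustness tests),
monomer lengths are uniform, and arrays are short (~100 monomers).
Passing tests therefore demonstrate the algorithmic contracts —
period recovery, variant calling, classification, extraction recall —
not performance or robustness on megabase centromeres, where within-
type divergence approaches the threshold and regions border each
other.

## Numerical and degenerate-input choices

* Similarity is strict (`divergence < thr`), so a pair at exactly 5%
  is dissimilar.
* Spectrum "dominant period" ties break toward the smaller period.
* The similarity scan is uncapped by default (quadratic worst case,
  linear-ish in practice for periodic arrays); `max_lag` caps it for
  whole-chromosome inputs at the cost of missing longer periods.
* Empty arrays are legal in memory (an extraction can find nothing)
  but refused by the FASTA writer; empty spectra have L = 0 and no
  dominant period.
* A region of a single repeated monomer called at n = 2 yields the
  degenerate unit (t1, t1), τ = 1, Cascading.
* Display parameters (period cut-off 60, start offset, output format)
  never influence any computed value; TSV exports are always complete.

## Problem sizes

All shipped analyses run on arrays of ~100–110 monomers of 171 bp
(≈10⁴ edit-distance calls per array) and synthetic genomes of ≈6 kb;
the full test suite and the acceptance script each complete in
seconds on one CPU.

## Known limitations

* Single-linkage typing can chain types in arrays whose within-type
  noise approaches half the inter-type divergence.
* Greedy copy tiling does not backtrack; a pathological variant
  cluster could locally shift copy boundaries (the reconstruction
  invariant still holds).
* The region segmenter assumes one dominant period per window span;
  two HORs alternating at high frequency are reported as one
  composite region (by design, with sub-block decomposition) rather
  than two interleaved ones.
* Strand-aware HOR orientation calling and cross-genome homology
  comparisons are out of scope.
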