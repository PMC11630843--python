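# grmhor

Detection and annotation of **higher-order repeats (HORs)** in tandem
monomer arrays — the hierarchical structure of centromeric satellite
DNA, where ~171-bp alpha satellite monomers that differ from each
other by 20–40% repeat as blocks of *n* monomers with >95% identity
between block copies.

The package is for researchers annotating centromere organisation in
assembled genomes (or any other tandemly repeated unit, such as
~1.6-kb gene-family repeats): it takes an ordered monomer list and
reports, per HOR array, the repeat order *n*, the number of distinct
monomer types τ, every canonical and variant HOR copy, and the HOR
class — with no prior model of the repeat unit.

## Method

For each monomer *i* of the array, compute the distance (in monomer
units) to the first later monomer within 5% edit-distance divergence:

&nbsp;&nbsp;&nbsp;&nbsp;M = (m₁ᵢ, m₂ᵢ), m₁ᵢ = i, m₂ᵢ = (position of first similar monomer) − i,

with m₂ᵢ = 0 when no later monomer is similar. Divergence is
normalised Levenshtein distance (edlib), strictly below the threshold.
The tally of nonzero m₂ values is the period spectrum

&nbsp;&nbsp;&nbsp;&nbsp;p = (p₁ⱼ, p₂ⱼ), p₁ⱼ = j, p₂ⱼ = |{i : m₂ᵢ = j}|,

whose dominant peak is the HOR order *n* — in a clean *n*-mer array
every similar pair is *n* monomers apart. Monomers connected by
next-similar links form types t1, t2, …; sliding-window analysis of
the m₂ values delineates HOR regions; the modal length-*n* window of
the type-label sequence is the **canonical unit** (τ = distinct types
in it; **Willard's** HOR if τ = n, **Cascading** if a type is
reiterated, τ < n); greedy tiling against the canonical unit calls
each copy as canonical or a variant with its monomer-level
insertions/deletions.

Three views are rendered: the **GRM diagram** (period spectrum), the
**MD diagram** (m₂ vs i, localising regions) and the **aligned
scheme** (one coloured box per monomer, one column per type, one row
per unit copy). A consensus-search front end (`monfind`) extracts the
monomer array from genomic FASTA on both strands, and a synthetic
generator builds ground-truthed arrays and genomes for testing.

## Worked example

Build a cascading array — ten tandem copies of the 11-monomer unit
t1…t6, **t2**, t7…t10 built from ten mutually >20%-divergent 171-bp
monomers — and annotate it:

```python
import grmhor as g

types = g.gen_divergent_monomers(g.FixtureSpec(n_types=10, seed=1))
array = g.build_cascading_array(types, copies=10)
ann = g.annotate_array(array)

print("spectrum:", dict(sorted(ann.spectrum.bins.items())))
print("dominant period:", ann.spectrum.dominant_period())
for s in ann.summaries:
    print(f"region {s.region.first}..{s.region.last}: "
          f"{s.n}mer (tau={s.tau}, {s.hor_class}), "
          f"{s.total_copies} copies ({s.canonical_copies} canonical)")
print("canonical unit:", "-".join(ann.units[0].type_sequence))
```

prints

```
spectrum: {5: 10, 6: 9, 11: 81}
dominant period: 11
region 1..110: 11mer (tau=10, Cascading), 10 copies (10 canonical)
canonical unit: t1-t2-t3-t4-t5-t6-t2-t7-t8-t9-t10
```

Reading the numbers: 81 of the 110 monomers find their next similar
monomer 11 positions away (the HOR order), while the duplicated type
t2 splits into intra-unit spacing 5 (first copy → second copy, 10
occurrences) and inter-unit spacing 6 (second copy → next unit's
first, 9 occurrences — the final unit has no successor). Because t2
appears twice in the 11-monomer unit, τ = 10 < n = 11 and the array
is classified Cascading; all ten copies match the unit exactly, so
all are canonical.

The same pipeline from the shell:

```
$ grmhor monomers.fa
INFO loaded 100 monomers from monomers.fa
INFO threshold=0.05 window=20 min_support=3: 10 types, 1 regions, 10 copies
INFO region 1..100: 10mer (tau=10, Willard), 10 copies (10 canonical)
```

writes `monomers.grm.svg`, `monomers.md.svg`, `monomers.scheme.svg`
and four TSV tables (next-similar vector, spectrum, region summary,
per-copy calls). Useful flags: `--divergence` (similarity threshold),
`--region A..B` / `--start` (re-run on an isolated block, recommended
for whole-chromosome inputs), `--max-period` (display cut-off only),
`--format ps`. Monomer extraction:

```
$ monfind --genome genome.fa --query consensus.fa --out monomers.fa
```

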