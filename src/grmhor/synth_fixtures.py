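"""Synthetic monomer arrays and genomes with known ground truth.

Four artificial array designs exercise every stage of the pipeline:

* **canonical** — a set of mutually divergent monomer types repeated in
  fixed order (a pure Willard's HOR array);
* **canonical with variants** — the canonical array after four fixed
  monomer deletions and two insertions of a novel monomer pair,
  producing deletion and insertion variant copies;
* **cascading** — the second type re-inserted after the sixth within
  every repeat unit, producing an 11-monomer unit with 10 types;
* **random** — monomer types drawn uniformly at random, which carries
  no higher-order organisation.

Base monomer types are random DNA (default 171 bp) rejection-sampled
until all pairwise divergences exceed ``min_inter_type_divergence``
(default 20%, comfortably above twice the 5% similarity threshold so
types can never chain together).  All generators are deterministic
given their seed.

:func:`build_synthetic_genome` embeds an array into a genome with
random flanks, optional N-gaps and optional reverse-complemented
blocks, and records per-monomer ground-truth loci for testing the
consensus search.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .monomer_model import Locus, MonomerArray, MonomerRecord
from .monfinder import reverse_complement
from .similarity import divergence, is_similar, DivergenceThreshold

_BASES = np.array(list("ACGT"))

#: 1-based original positions removed by the variant-fixture edits
CASE2_DELETIONS: Tuple[int, ...] = (18, 19, 38, 39)
#: 1-based original positions after which the novel pair is inserted
CASE2_INSERTIONS_AFTER: Tuple[int, ...] = (66, 86)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic monomer-type pool."""

    n_types: int = 10
    monomer_length: int = 171
    min_inter_type_divergence: float = 0.20
    intra_type_mutation_rate: float = 0.0
    copies: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if self.monomer_length < 10:
            raise ValueError("monomer_length must be >= 10")
        if not 0.0 < self.min_inter_type_divergence < 1.0:
            raise ValueError("min_inter_type_divergence must be in (0,1)")
        if self.min_inter_type_divergence <= 2 * 0.05:
            raise ValueError(
                "min_inter_type_divergence must exceed twice the similarity "
                "threshold so distinct types can never merge"
            )
        if not 0.0 <= self.intra_type_mutation_rate < 0.5:
            raise ValueError("intra_type_mutation_rate must be in [0, 0.5)")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def gen_divergent_monomers(spec: FixtureSpec, max_tries: int = 100) -> List[str]:
    """Draw ``spec.n_types`` random monomers, all pairwise divergences
    strictly above ``spec.min_inter_type_divergence``.

    Deterministic given ``spec.seed``.  Random DNA pairs sit near 50%
    divergence, so rejection is rare at the default 20% floor; a
    ``RuntimeError`` after *max_tries* signals an unsatisfiable spec.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_tries):
        seqs = [_random_sequence(rng, spec.monomer_length) for _ in range(spec.n_types)]
        ok = all(
            divergence(seqs[i], seqs[j]) > spec.min_inter_type_divergence
            for i in range(len(seqs))
            for j in range(i + 1, len(seqs))
        )
        if ok:
            return seqs
    raise RuntimeError(
        f"could not generate {spec.n_types} monomers of length "
        f"{spec.monomer_length} with pairwise divergence > "
        f"{spec.min_inter_type_divergence} in {max_tries} tries"
    )


def gen_consensus_family(
    n_types: int = 10,
    monomer_length: int = 171,
    divergence_from_consensus: float = 0.15,
    min_inter_type_divergence: float = 0.12,
    seed: int = 0,
    max_tries: int = 50,
) -> Tuple[str, List[str]]:
    """A random consensus plus *n_types* monomer types mutated from it.

    Emulates a consensus-derived satellite family: every type lies
    within ``divergence_from_consensus`` of the consensus (substitution
    mutagenesis at that rate) while all pairwise type divergences
    exceed ``min_inter_type_divergence``, so a consensus query finds
    every type yet the similarity threshold keeps the types distinct.
    Deterministic given *seed*.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        consensus = _random_sequence(rng, monomer_length)
        types = [
            _mutate(consensus, divergence_from_consensus, rng)
            for _ in range(n_types)
        ]
        if any(
            divergence(consensus, t) > divergence_from_consensus * 1.1
            for t in types
        ):
            continue
        ok = all(
            divergence(types[i], types[j]) > min_inter_type_divergence
            for i in range(n_types)
            for j in range(i + 1, n_types)
        )
        if ok:
            return consensus, types
    raise RuntimeError(
        "could not generate a consensus family satisfying the divergence bounds"
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = rng.choice([b for b in "ACGT" if b != chars[i]])
    return "".join(chars)


def build_canonical_array(
    monomers: Sequence[str],
    copies: int,
    intra_type_mutation_rate: float = 0.0,
    seed: int = 0,
) -> MonomerArray:
    """Tandem-repeat *monomers* in fixed order *copies* times.

    With a nonzero ``intra_type_mutation_rate`` each copy is
    independently point-mutated (substitutions only), emulating the
    <5% within-type noise of real arrays.
    """
    if not monomers:
        raise ValueError("need at least one monomer")
    rng = np.random.default_rng(seed)
    seqs = [
        _mutate(m, intra_type_mutation_rate, rng)
        for _ in range(copies)
        for m in monomers
    ]
    return MonomerArray.from_sequences(seqs)


def apply_case2_edits(
    array: MonomerArray, novel_pair: Tuple[str, str]
) -> MonomerArray:
    """Apply the fixed variant-producing edits to the 100-monomer
    canonical fixture: delete original monomers 18, 19, 38 and 39 and
    insert the same novel pair after original monomers 66 and 86.

    Positions refer to the original array; insertions are anchored to
    the original monomer identities, so the edited array again has 100
    monomers and the first inserted pair finds the second downstream.
    The novel pair must be dissimilar from every array monomer and from
    each other.
    """
    if array.N != 100:
        raise ValueError(f"expected the 100-monomer canonical fixture, got N={array.N}")
    x, y = novel_pair
    if is_similar(x, y):
        raise ValueError("novel pair members are similar to each other")
    for rec in array:
        if is_similar(rec.sequence, x) or is_similar(rec.sequence, y):
            raise ValueError(
                f"novel pair is similar to array monomer {rec.index}"
            )
    deletions = set(CASE2_DELETIONS)
    out: List[str] = []
    for rec in array:
        if rec.index in deletions:
            continue
        out.append(rec.sequence)
        if rec.index in CASE2_INSERTIONS_AFTER:
            out.extend([x, y])
    return MonomerArray.from_sequences(out)


def build_cascading_array(monomers: Sequence[str], copies: int) -> MonomerArray:
    """Cascading fixture: each unit is t1..t6, t2, t7..t10.

    The second monomer type is re-inserted after the sixth, so a unit
    has ``len(monomers) + 1`` monomers but only ``len(monomers)``
    types.  Designed for the 10-type pool (11mer units) but accepts any
    pool of at least 7 monomers.
    """
    monomers = list(monomers)
    if len(monomers) < 7:
        raise ValueError("cascading fixture needs at least 7 monomer types")
    unit = monomers[:6] + [monomers[1]] + monomers[6:]
    return MonomerArray.from_sequences(unit * copies)


def build_random_array(
    monomers: Sequence[str], length: int, seed: int = 0
) -> MonomerArray:
    """*length* monomers drawn uniformly (with replacement) from the pool."""
    monomers = list(monomers)
    if len(monomers) < 2:
        raise ValueError("need at least two monomers to draw from")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(monomers), size=length)
    return MonomerArray.from_sequences([monomers[i] for i in picks])


def build_synthetic_genome(
    array: MonomerArray,
    out_fasta: Union[str, Path],
    truth_tsv: Optional[Union[str, Path]] = None,
    flank_length: int = 500,
    strand_plan: Optional[Sequence[Tuple[int, int, str]]] = None,
    gaps: Sequence[Tuple[int, int]] = (),
    seed: int = 0,
    contig: str = "synth_contig",
    type_labels: Optional[Sequence[str]] = None,
) -> Tuple[Path, List[dict]]:
    """Embed *array* into a synthetic genome and record ground truth.

    The monomers are concatenated in order with random flanks of
    *flank_length* on both sides.  ``gaps`` lists ``(after_index,
    length)`` N-runs inserted after the given monomer (after the
    containing block when that block is on the minus strand).
    ``strand_plan``
    lists ``(first, last, strand)`` blocks (1-based, inclusive,
    covering 1..N in order); '-' blocks are reverse-complemented as a
    whole, so their monomers appear in reversed genomic order on the
    minus strand.

    Writes the genome FASTA (and the truth TSV when requested) and
    returns the FASTA path plus the per-monomer truth records
    (``index, contig, start, end, strand, type_label`` — 1-based
    inclusive coordinates).
    """
    rng = np.random.default_rng(seed)
    n = array.N
    if strand_plan is None:
        strand_plan = [(1, n, "+")] if n else []
    covered = [i for first, last, _ in strand_plan for i in range(first, last + 1)]
    if covered != list(range(1, n + 1)):
        raise ValueError("strand_plan blocks must cover 1..N in order")
    gap_after = {after: length for after, length in gaps}
    labels = list(type_labels) if type_labels is not None else [""] * n

    pieces: List[str] = [_random_sequence(rng, flank_length)]
    pos = flank_length  # 0-based length so far
    truth: List[dict] = []

    def _record(i: int, start0: int, strand: str) -> None:
        length = len(array.record(i).sequence)
        truth.append(
            {
                "index": i,
                "contig": contig,
                "start": start0 + 1,
                "end": start0 + length,
                "strand": strand,
                "type_label": labels[i - 1],
            }
        )

    for first, last, strand in strand_plan:
        if strand == "+":
            for i in range(first, last + 1):
                seq = array.record(i).sequence
                _record(i, pos, "+")
                pieces.append(seq)
                pos += len(seq)
                if i in gap_after:
                    g = gap_after.pop(i)
                    pieces.append("N" * g)
                    pos += g
        else:
            # the whole block is reverse-complemented: monomer order reverses
            block_seq = reverse_complement(
                "".join(array.record(i).sequence for i in range(first, last + 1))
            )
            off = 0
            for i in range(last, first - 1, -1):
                _record(i, pos + off, "-")
                off += len(array.record(i).sequence)
            pieces.append(block_seq)
            pos += len(block_seq)
            # gap runs inside a minus block land after the block
            for after in [a for a in sorted(gap_after) if first <= a <= last]:
                g = gap_after.pop(after)
                pieces.append("N" * g)
                pos += g
    pieces.append(_random_sequence(rng, flank_length))
    genome = "".join(pieces)

    out_fasta = Path(out_fasta)
    with open(out_fasta, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(genome), 60):
            fh.write(genome[i : i + 60] + "\n")
    truth.sort(key=lambda t: t["start"])
    if truth_tsv is not None:
        with open(truth_tsv, "w") as fh:
            fh.write("index\tcontig\tstart\tend\tstrand\ttype_label\n")
            for t in truth:
                fh.write(
                    f"{t['index']}\t{t['contig']}\t{t['start']}\t{t['end']}\t"
                    f"{t['strand']}\t{t['type_label']}\n"
                )
    return out_fasta, truth
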