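"""The three computational steps behind the repeat-period analysis.

1. **Next-similar vector** ``M``: for every monomer *i* the distance, in
   monomer units, to the first later monomer within the divergence
   threshold (0 if none exists before the end of the array).
2. **Period spectrum** ``p``: the tally of those nonzero distances —
   the data behind the GRM diagram, the monomeric analogue of a
   Southern-blot band pattern.
3. **Monomer typing**: monomers connected by next-similar links are
   grouped into types t1, t2, ... (single linkage via union-find),
   which drive the aligned scheme layout.

The aligned scheme places monomers left-to-right in array order, one
column per type; a new row starts whenever the next monomer's column
would not extend the current row to the right, so each row reads as one
(possibly partial) repeat unit and row-major reading order reproduces
the array.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .monomer_model import MonomerArray
from .similarity import DEFAULT_THRESHOLD, DivergenceThreshold, is_similar


@dataclass(frozen=True)
class NextSimilarVector:
    """Per-monomer ``(position, next-similar distance)`` pairs.

    ``entries[i-1] == (i, d)`` where ``d`` is the smallest lag >= 1 such
    that monomer ``i+d`` diverges from monomer ``i`` by less than the
    threshold, or 0 when no later monomer does.
    """

    entries: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(tuple(e) for e in self.entries))
        n = len(self.entries)
        for pos, (m1, m2) in enumerate(self.entries, start=1):
            if m1 != pos:
                raise ValueError(f"entry {pos}: position component is {m1}")
            if m2 < 0 or m2 > n - pos:
                raise ValueError(f"entry {pos}: distance {m2} outside 0..{n - pos}")

    @property
    def N(self) -> int:
        return len(self.entries)

    @property
    def distances(self) -> List[int]:
        return [m2 for _, m2 in self.entries]

    def distance(self, index: int) -> int:
        """Next-similar distance of the monomer at 1-based *index*."""
        return self.entries[index - 1][1]

    @property
    def n_zero(self) -> int:
        return sum(1 for _, m2 in self.entries if m2 == 0)


@dataclass(frozen=True)
class PeriodSpectrum:
    """Frequency of each nonzero next-similar distance (repeat period)."""

    bins: Dict[int, int]
    L: int

    def __post_init__(self) -> None:
        bins = dict(self.bins)
        object.__setattr__(self, "bins", bins)
        for j, f in bins.items():
            if j < 1 or f < 1:
                raise ValueError(f"invalid spectrum bin {j} -> {f}")
        if bins and self.L != max(bins):
            raise ValueError(f"L={self.L} != max stored period {max(bins)}")
        if not bins and self.L != 0:
            raise ValueError("empty spectrum must have L == 0")

    @property
    def total(self) -> int:
        return sum(self.bins.values())

    def frequency(self, period: int) -> int:
        return self.bins.get(period, 0)

    def dominant_period(self, exclude: Sequence[int] = ()) -> Optional[int]:
        """Period with maximal frequency; ties go to the smaller period
        (the smaller period is the subunit and the minimal repeat unit
        is always reported).  None if no candidate period remains."""
        candidates = [(f, -j) for j, f in self.bins.items() if j not in set(exclude)]
        if not candidates:
            return None
        f, negj = max(candidates)
        return -negj


@dataclass(frozen=True)
class TypeAssignment:
    """Partition of monomers into types t1, t2, ... (first-occurrence order)."""

    labels: Tuple[str, ...]
    groups: Dict[str, Tuple[int, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(
            self, "groups", {k: tuple(v) for k, v in self.groups.items()}
        )

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def n_types(self) -> int:
        return len(self.groups)

    def label_of(self, index: int) -> str:
        """Type label of the monomer at 1-based *index*."""
        return self.labels[index - 1]

    @property
    def first_occurrence_order(self) -> List[str]:
        seen: Dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab)
        return list(seen)


@dataclass(frozen=True)
class AlignedScheme:
    """Grid placement of monomers: one column per type, rows are repeat units."""

    placements: Tuple[Tuple[int, int], ...]  # per monomer, (row, column), 1-based
    column_of_type: Dict[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "placements", tuple(tuple(p) for p in self.placements))
        object.__setattr__(self, "column_of_type", dict(self.column_of_type))

    @property
    def n_rows(self) -> int:
        return max((r for r, _ in self.placements), default=0)

    @property
    def n_columns(self) -> int:
        return max(self.column_of_type.values(), default=0)


def build_next_similar(
    array: MonomerArray,
    thr: DivergenceThreshold = DEFAULT_THRESHOLD,
    max_lag: Optional[int] = None,
) -> NextSimilarVector:
    """Compute the next-similar vector of *array*.

    For each monomer the forward scan stops at the first later monomer
    within the threshold; with ``max_lag`` set, the scan is capped at
    that lag (useful for whole-chromosome inputs, off by default — the
    uncapped scan is quadratic in the worst case).
    """
    seqs = array.sequences
    n = len(seqs)
    entries = []
    for i in range(n):
        limit = n if max_lag is None else min(n, i + 1 + max_lag)
        d = 0
        for j in range(i + 1, limit):
            if is_similar(seqs[i], seqs[j], thr):
                d = j - i
                break
        entries.append((i + 1, d))
    return NextSimilarVector(tuple(entries))


def build_period_spectrum(v: NextSimilarVector) -> PeriodSpectrum:
    """Tally nonzero next-similar distances into the period spectrum."""
    bins = Counter(m2 for _, m2 in v.entries if m2 > 0)
    return PeriodSpectrum(bins=dict(bins), L=max(bins) if bins else 0)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def assign_types(
    array: MonomerArray,
    v: NextSimilarVector,
    thr: DivergenceThreshold = DEFAULT_THRESHOLD,
) -> TypeAssignment:
    """Group monomers into types via the next-similar links of *v*.

    Types are the connected components of the links ``{i <-> i+m2_i}``
    (single linkage: transitive chaining may join monomers whose direct
    divergence slightly exceeds the threshold).  Labels t1, t2, ... are
    assigned by the first occurrence of each component's earliest
    member.  *thr* is accepted for interface symmetry; the links in *v*
    already encode it.
    """
    del thr
    if v.N != array.N:
        raise ValueError(f"vector length {v.N} != array length {array.N}")
    n = array.N
    uf = _UnionFind(n)
    for i, (_, m2) in enumerate(v.entries):
        if m2 > 0:
            uf.union(i, i + m2)
    root_label: Dict[int, str] = {}
    labels: List[str] = []
    for i in range(n):
        r = uf.find(i)
        if r not in root_label:
            root_label[r] = f"t{len(root_label) + 1}"
        labels.append(root_label[r])
    groups: Dict[str, List[int]] = {}
    for i, lab in enumerate(labels, start=1):
        groups.setdefault(lab, []).append(i)
    return TypeAssignment(
        labels=tuple(labels), groups={k: tuple(ps) for k, ps in groups.items()}
    )


def layout_aligned_scheme(
    types: TypeAssignment, canonical_order: Optional[Sequence[str]] = None
) -> AlignedScheme:
    """Place monomers on the aligned-scheme grid.

    Column order is the first-appearance order of types unless
    *canonical_order* (a permutation of the observed labels) overrides
    it.  Monomers are placed in array order; a new row begins whenever
    the current monomer's column does not lie strictly to the right of
    the previous placement — in particular whenever its type already
    occupies a cell in the current row — so row-major reading
    reproduces the array order.
    """
    observed = types.first_occurrence_order
    if canonical_order is None:
        order = observed
    else:
        if sorted(canonical_order) != sorted(observed):
            raise ValueError(
                "canonical_order must be a permutation of the observed type labels"
            )
        order = list(canonical_order)
    column_of_type = {lab: c for c, lab in enumerate(order, start=1)}

    placements: List[Tuple[int, int]] = []
    row = 1
    last_col = 0
    for lab in types.labels:
        col = column_of_type[lab]
        if col <= last_col:
            row += 1
        placements.append((row, col))
        last_col = col
    return AlignedScheme(placements=tuple(placements), column_of_type=column_of_type)


def export_monomer_table(
    v: NextSimilarVector,
    types: Optional[TypeAssignment],
    path: Union[str, Path],
) -> Path:
    """TSV of the next-similar vector: index, next_similar_distance, type_label."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("index\tnext_similar_distance\ttype_label\n")
        for pos, m2 in v.entries:
            lab = types.label_of(pos) if types is not None else ""
            fh.write(f"{pos}\t{m2}\t{lab}\n")
    return path


def export_spectrum(spectrum: PeriodSpectrum, path: Union[str, Path]) -> Path:
    """TSV of the full period spectrum (never truncated for display)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("period\tfrequency\n")
        for j in sorted(spectrum.bins):
            fh.write(f"{j}\t{spectrum.bins[j]}\n")
    return path
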