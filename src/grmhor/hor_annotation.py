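"""Higher-order repeat (HOR) annotation.

From the next-similar vector and the monomer typing this module
delineates contiguous HOR regions, calls each region's canonical unit
(the modal length-*n* type sequence), classifies it as Willard's
(every type occurs once, tau == n) or Cascading (some type reiterated,
tau < n), tiles the region into canonical and variant copies, and
produces per-array summary rows (n, tau, copy counts, class).

Region detection replaces the by-eye reading of an MD diagram with a
sliding-window criterion: a window is called periodic when the modal
nonzero next-similar distance accounts for at least half of the
window's nonzero entries; maximal runs of consecutive windows agreeing
on the same period become regions.  Random monomer arrays produce no
majority period in any window and therefore no region.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .grm_core import (
    NextSimilarVector,
    PeriodSpectrum,
    TypeAssignment,
    build_next_similar,
    build_period_spectrum,
    assign_types,
)
from .monomer_model import Locus, MonomerArray
from .similarity import DEFAULT_THRESHOLD, DivergenceThreshold

WILLARD = "Willard"
CASCADING = "Cascading"


@dataclass(frozen=True)
class HORRegion:
    """Contiguous monomer span dominated by one repeat period.

    ``support`` counts next-similar entries equal to ``dominant_period``
    inside the span.
    """

    first: int
    last: int
    dominant_period: int
    support: int

    def __post_init__(self) -> None:
        if self.last < self.first:
            raise ValueError(f"empty region span {self.first}..{self.last}")
        if self.dominant_period < 2:
            raise ValueError("a HOR has order n >= 2")

    @property
    def span_length(self) -> int:
        return self.last - self.first + 1


@dataclass(frozen=True)
class CanonicalUnit:
    """The modal repeat unit of a region: ``n`` type labels, ``tau`` distinct."""

    type_sequence: Tuple[str, ...]
    tau: int = field(init=False)
    hor_class: str = field(init=False)

    def __post_init__(self) -> None:
        seq = tuple(self.type_sequence)
        object.__setattr__(self, "type_sequence", seq)
        if not seq:
            raise ValueError("canonical unit cannot be empty")
        object.__setattr__(self, "tau", len(set(seq)))
        object.__setattr__(
            self, "hor_class", WILLARD if self.tau == len(seq) else CASCADING
        )

    @property
    def n(self) -> int:
        return len(self.type_sequence)

    @property
    def duplicated_types(self) -> List[str]:
        counts = Counter(self.type_sequence)
        return [lab for lab, c in counts.items() if c > 1]


@dataclass(frozen=True)
class HORCopy:
    """One tiled copy of a region's repeat: canonical or variant."""

    start: int  # 1-based index of the copy's first monomer in the array
    type_sequence: Tuple[str, ...]
    status: str  # "canonical" | "variant"
    edit_ops: Tuple[Tuple, ...]  # ops vs the canonical unit (see label_edit_ops)
    locus: Optional[Locus] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "type_sequence", tuple(self.type_sequence))
        object.__setattr__(self, "edit_ops", tuple(tuple(o) for o in self.edit_ops))
        if self.status not in ("canonical", "variant"):
            raise ValueError(f"bad status {self.status!r}")
        if (self.status == "canonical") != (len(self.edit_ops) == 0):
            raise ValueError("canonical iff no edit ops")

    @property
    def n_monomers(self) -> int:
        return len(self.type_sequence)


@dataclass(frozen=True)
class HORArraySummary:
    """One summary row per HOR region: n, tau, copy counts, class."""

    region: HORRegion
    n: int
    tau: int
    total_copies: int
    canonical_copies: int
    hor_class: str

    def __post_init__(self) -> None:
        if self.canonical_copies > self.total_copies:
            raise ValueError("canonical copies cannot exceed total copies")


def _window_mode(counts: Counter) -> Optional[Tuple[int, int]]:
    """Modal (period, count); ties toward the smaller period."""
    if not counts:
        return None
    count, negp = max((c, -p) for p, c in counts.items())
    return -negp, count


def segment_hor_regions(
    v: NextSimilarVector,
    window: int = 20,
    min_support: int = 3,
    min_fraction: float = 0.5,
) -> List[HORRegion]:
    """Detect HOR regions from the next-similar vector.

    A sliding window of *window* monomers is periodic with period *p*
    (p >= 2) when *p* is the modal nonzero distance in the window and
    covers at least *min_fraction* of the window's nonzero entries.
    Maximal runs of >= *min_support* consecutive windows sharing a
    period become candidate regions; overlapping candidates with
    different periods are resolved greedily by descending support.
    Returns regions sorted by span; may be empty.
    """
    n = v.N
    if window < 2:
        raise ValueError("window must be >= 2")
    if n < window:
        return []
    m2 = v.distances

    counts = Counter(d for d in m2[0:window] if d > 0)
    period_at: List[Optional[int]] = []
    for s in range(0, n - window + 1):
        if s > 0:
            out, new = m2[s - 1], m2[s + window - 1]
            if out > 0:
                counts[out] -= 1
                if counts[out] == 0:
                    del counts[out]
            if new > 0:
                counts[new] += 1
        mode = _window_mode(counts)
        if mode is None:
            period_at.append(None)
            continue
        period, count = mode
        nonzero = sum(counts.values())
        if period >= 2 and count >= min_fraction * nonzero:
            period_at.append(period)
        else:
            period_at.append(None)

    # maximal runs of consecutive windows with the same period
    candidates: List[HORRegion] = []
    run_start = None
    run_period = None
    for s, p in enumerate(period_at + [None]):
        if p != run_period:
            if run_period is not None and s - run_start >= min_support:
                first = run_start + 1
                last = s - 1 + window  # last window's end, 1-based
                support = sum(
                    1 for d in m2[first - 1 : last] if d == run_period
                )
                candidates.append(
                    HORRegion(
                        first=first,
                        last=last,
                        dominant_period=run_period,
                        support=support,
                    )
                )
            run_start, run_period = s, p

    # resolve overlaps greedily by support (strongest region keeps its span)
    accepted: List[HORRegion] = []
    for cand in sorted(candidates, key=lambda r: (-r.support, r.first)):
        first, last = cand.first, cand.last
        for kept in accepted:
            if first <= kept.last and last >= kept.first:  # overlap
                if first >= kept.first:
                    first = max(first, kept.last + 1)
                if last <= kept.last:
                    last = min(last, kept.first - 1)
        if last - first + 1 < window:
            continue
        support = sum(1 for d in m2[first - 1 : last] if d == cand.dominant_period)
        if support < min_support:
            continue
        accepted.append(
            HORRegion(
                first=first,
                last=last,
                dominant_period=cand.dominant_period,
                support=support,
            )
        )
    return sorted(accepted, key=lambda r: r.first)


def call_canonical_unit(
    array: MonomerArray, types: TypeAssignment, region: HORRegion
) -> CanonicalUnit:
    """Call the canonical unit of *region*: the modal length-n window of
    the region's type-label sequence.

    The modal window fixes the unit's content; its phase is then
    rotated so the unit starts at the member type that occurs earliest
    in the region (the region's first monomer type under first-
    occurrence labelling), matching the aligned-scheme convention that
    column 1 holds t1.  Without the rotation a deletion variant early
    in the region can make a phase-shifted rotation modal and shift
    every copy call.  Ties between modal windows are resolved toward
    the earliest offset.  Raises ``ValueError`` when no length-n
    window fits in the region.
    """
    if types.N != array.N:
        raise ValueError("type assignment does not match array")
    n = region.dominant_period
    labels = types.labels[region.first - 1 : region.last]
    if len(labels) < n:
        raise ValueError(
            f"region {region.first}..{region.last} too short for unit length {n}"
        )
    first_occ: Dict[str, int] = {}
    for pos, lab in enumerate(labels):
        first_occ.setdefault(lab, pos)
    windows = Counter(
        tuple(labels[o : o + n]) for o in range(len(labels) - n + 1)
    )
    # among equal-count windows prefer the earliest first-occurring start
    # label, then the earliest offset of appearance
    top_count = max(windows.values())
    tied = [w for w, c in windows.items() if c == top_count]
    tied.sort(key=lambda w: (first_occ[w[0]], _first_offset(labels, w)))
    modal = tied[0]
    # re-phase: start the unit at the earliest-occurring member type
    anchor = min(modal, key=lambda lab: first_occ[lab])
    pivot = modal.index(anchor)
    return CanonicalUnit(type_sequence=modal[pivot:] + modal[:pivot])


def _first_offset(labels: Sequence[str], window: Tuple[str, ...]) -> int:
    n = len(window)
    for o in range(len(labels) - n + 1):
        if tuple(labels[o : o + n]) == window:
            return o
    return len(labels)


def label_edit_ops(
    observed: Sequence[str], unit: Sequence[str]
) -> Tuple[int, List[Tuple]]:
    """Levenshtein distance and ops between label sequences.

    Ops are reported against the canonical *unit* (1-based positions):
    ``("del", pos, label)`` — unit's label at *pos* missing from the copy;
    ``("ins", pos, label)`` — extra label in the copy after unit position *pos*;
    ``("sub", pos, unit_label, observed_label)``.
    """
    a, b = list(observed), list(unit)
    la, lb = len(a), len(b)
    dist = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        dist[i][0] = i
    for j in range(lb + 1):
        dist[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            dist[i][j] = min(
                dist[i - 1][j] + 1,  # extra in observed -> insertion
                dist[i][j - 1] + 1,  # missing from observed -> deletion
                dist[i - 1][j - 1] + cost,
            )
    ops: List[Tuple] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dist[i][j] == dist[i - 1][j - 1] + (
            0 if a[i - 1] == b[j - 1] else 1
        ):
            if a[i - 1] != b[j - 1]:
                ops.append(("sub", j, b[j - 1], a[i - 1]))
            i, j = i - 1, j - 1
        elif i > 0 and dist[i][j] == dist[i - 1][j] + 1:
            ops.append(("ins", j, a[i - 1]))
            i -= 1
        else:
            ops.append(("del", j, b[j - 1]))
            j -= 1
    ops.reverse()
    return dist[la][lb], ops


def enumerate_hor_copies(
    array: MonomerArray,
    types: TypeAssignment,
    region: HORRegion,
    unit: CanonicalUnit,
    max_indel: int = 4,
) -> List[HORCopy]:
    """Tile *region* greedily left-to-right into HOR copies.

    At each cursor the window of length n-k..n+k (k = *max_indel*)
    minimising label-level edit distance to the canonical unit is
    emitted; exact matches are canonical, others variant with recorded
    edit ops.  A trailing remnant shorter than n/2 labels is left
    untiled (see :func:`region_tail`).
    """
    n = unit.n
    labels = list(types.labels[region.first - 1 : region.last])
    copies: List[HORCopy] = []
    cursor = 0
    min_tail = math.ceil(n / 2)
    while len(labels) - cursor >= min_tail:
        best = None
        lo = max(1, n - max_indel)
        hi = min(len(labels) - cursor, n + max_indel)
        for length in range(lo, hi + 1):
            cand = tuple(labels[cursor : cursor + length])
            d, ops = label_edit_ops(cand, unit.type_sequence)
            key = (d, abs(length - n), length)
            if best is None or key < best[0]:
                best = (key, length, cand, ops)
        _, length, cand, ops = best
        start = region.first + cursor
        copies.append(
            HORCopy(
                start=start,
                type_sequence=cand,
                status="canonical" if not ops else "variant",
                edit_ops=tuple(ops),
                locus=array.record(start).locus,
            )
        )
        cursor += length
    return copies


def region_tail(
    types: TypeAssignment, region: HORRegion, copies: Sequence[HORCopy]
) -> Tuple[str, ...]:
    """Labels of the trailing remnant of *region* left untiled by *copies*."""
    consumed = sum(c.n_monomers for c in copies)
    return tuple(types.labels[region.first - 1 + consumed : region.last])


def summarize_arrays(
    annotated: Sequence[Tuple[HORRegion, CanonicalUnit, Sequence[HORCopy]]],
) -> List[HORArraySummary]:
    """One summary row per annotated region (n, tau, copy counts, class)."""
    rows = []
    for region, unit, copies in annotated:
        rows.append(
            HORArraySummary(
                region=region,
                n=unit.n,
                tau=unit.tau,
                total_copies=len(copies),
                canonical_copies=sum(1 for c in copies if c.status == "canonical"),
                hor_class=unit.hor_class,
            )
        )
    return rows


def repeated_subblocks(
    unit: CanonicalUnit, min_length: int = 2
) -> List[Tuple[Tuple[str, ...], int]]:
    """Maximal repeated contiguous sub-blocks of a composite unit.

    Supports the dual accounting of interleaved arrays (a composite
    unit reported together with its internally repeated sub-units).
    Returns (block, occurrence count) pairs, longest first; blocks
    contained in a kept longer block are suppressed.
    """
    seq = unit.type_sequence
    n = len(seq)
    found: List[Tuple[Tuple[str, ...], int]] = []

    def _contains(big: Tuple[str, ...], small: Tuple[str, ...]) -> bool:
        return any(
            big[i : i + len(small)] == small for i in range(len(big) - len(small) + 1)
        )

    for length in range(n - 1, min_length - 1, -1):
        counts = Counter(tuple(seq[i : i + length]) for i in range(n - length + 1))
        for block, c in sorted(counts.items()):
            if c >= 2 and not any(_contains(kb, block) for kb, _ in found):
                found.append((block, c))
    return found


@dataclass(frozen=True)
class ArrayAnnotation:
    """Full annotation of one monomer array (the end-to-end pipeline result)."""

    array: MonomerArray
    vector: NextSimilarVector
    spectrum: PeriodSpectrum
    types: TypeAssignment
    regions: Tuple[HORRegion, ...]
    units: Tuple[CanonicalUnit, ...]
    copies: Tuple[Tuple[HORCopy, ...], ...]  # per region
    summaries: Tuple[HORArraySummary, ...]


def annotate_array(
    array: MonomerArray,
    thr: DivergenceThreshold = DEFAULT_THRESHOLD,
    window: int = 20,
    min_support: int = 3,
    max_indel: int = 4,
    max_lag: Optional[int] = None,
) -> ArrayAnnotation:
    """Run the full pipeline: next-similar vector, spectrum, typing,
    region segmentation, canonical-unit calls, copy tiling, summaries."""
    v = build_next_similar(array, thr, max_lag=max_lag)
    spectrum = build_period_spectrum(v)
    types = assign_types(array, v)
    regions = segment_hor_regions(v, window=window, min_support=min_support)
    units = []
    all_copies = []
    for region in regions:
        unit = call_canonical_unit(array, types, region)
        units.append(unit)
        all_copies.append(
            tuple(enumerate_hor_copies(array, types, region, unit, max_indel))
        )
    summaries = summarize_arrays(list(zip(regions, units, all_copies)))
    return ArrayAnnotation(
        array=array,
        vector=v,
        spectrum=spectrum,
        types=types,
        regions=tuple(regions),
        units=tuple(units),
        copies=tuple(all_copies),
        summaries=tuple(summaries),
    )


def export_summary(
    summaries: Sequence[HORArraySummary], path: Union[str, Path]
) -> Path:
    """TSV with the per-array summary columns."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "region_first\tregion_last\tn\tn_monomer_types\tn_hor_copies\t"
            "n_canonical_copies\thor_class\n"
        )
        for s in summaries:
            fh.write(
                f"{s.region.first}\t{s.region.last}\t{s.n}\t{s.tau}\t"
                f"{s.total_copies}\t{s.canonical_copies}\t{s.hor_class}\n"
            )
    return path


def export_copies(
    annotated: Sequence[Tuple[HORRegion, CanonicalUnit, Sequence[HORCopy]]],
    path: Union[str, Path],
) -> Path:
    """BED-like TSV of HOR copies (genomic columns blank without loci)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tstatus\tn\tfirst_monomer\tlabels\n")
        for region, unit, copies in annotated:
            for c in copies:
                if c.locus is not None:
                    contig, start, end = c.locus.contig, c.locus.start, c.locus.end
                else:
                    contig, start, end = "", "", ""
                fh.write(
                    f"{contig}\t{start}\t{end}\t{c.status}\t{unit.n}\t"
                    f"{c.start}\t{'-'.join(c.type_sequence)}\n"
                )
    return path
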