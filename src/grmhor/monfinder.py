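"""Consensus-based monomer extraction from genomic FASTA.

A single consensus monomer (for alpha satellite, ~171 bp) is aligned
semi-globally (infix mode) against every contig and its reverse
complement.  Non-overlapping hits within the acceptance divergence are
collected recursively: the best hit in a segment is recorded and the
flanking segments are searched in turn, which yields the greedy
best-divergence-first tiling of a tandem array.  Reverse-strand hits
are reported in genomic-forward coordinates with strand '-', and their
stored sequence is reverse-complemented into the query frame so that
downstream similarity compares all monomers in one frame.

Assembly-gap runs of N are never part of a reported monomer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

import edlib
from Bio import SeqIO

from .monomer_model import Locus, MonomerArray, MonomerRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")

# hits containing an N-run at least this long are discarded outright
_MAX_N_RUN = 5
# fraction of the query length two hits may share before they conflict
_MAX_OVERLAP_FRAC = 0.1


def reverse_complement(s: str) -> str:
    """Reverse complement over the ACGTN alphabet (N maps to N)."""
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid characters for reverse complement: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsensusQuery:
    """The consensus monomer used as the search query.

    ``max_divergence`` is the acceptance threshold for a hit; the
    default 0.35 is inclusive enough for monomers that diverge 20-40%
    from one another (hence roughly up to ~35% from a consensus).
    """

    sequence: str
    max_divergence: float = 0.35

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 50:
            raise ValueError(f"consensus too short ({len(seq)} bp; need >= 50)")
        if not 0.0 < self.max_divergence < 0.5:
            raise ValueError(
                f"max_divergence must be in (0, 0.5), got {self.max_divergence}"
            )
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"invalid characters in consensus: {sorted(bad)}")


@dataclass(frozen=True)
class _Hit:
    contig: str
    start: int  # 0-based inclusive, genomic-forward
    end: int  # 0-based inclusive
    strand: str
    divergence: float
    sequence: str  # query-frame sequence


def _collect_hits(query: str, target: str, k: int) -> List[Tuple[int, int, int]]:
    """Greedy best-first non-overlapping infix hits of *query* in *target*.

    Returns (start, end, edit_distance) with 0-based inclusive ends.
    The best-scoring hit of a segment is recorded, then the left and
    right remainders are searched recursively.
    """
    hits: List[Tuple[int, int, int]] = []
    # (segment string, offset into original target)
    stack: List[Tuple[int, int]] = [(0, len(target))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < len(query) // 2:
            continue
        res = edlib.align(query, target[lo:hi], mode="HW", task="locations", k=k)
        if res["editDistance"] < 0:
            continue
        start, end = res["locations"][0]
        hits.append((lo + start, lo + end, res["editDistance"]))
        stack.append((lo, lo + start))
        stack.append((lo + end + 1, hi))
    return sorted(hits)


def _has_n_run(seq: str, max_run: int = _MAX_N_RUN) -> bool:
    return "N" * max_run in seq


def find_monomers(
    genome: Union[str, Path], query: ConsensusQuery
) -> MonomerArray:
    """Extract the ordered monomer array of *genome*.

    Searches every contig on both strands, resolves overlapping hits
    greedily by ascending divergence then position, and returns the
    survivors sorted by (contig, start) with loci and strand, numbered
    1..N.  An empty array (with a logged warning) means no hits — not
    an error.
    """
    genome = Path(genome)
    q = query.sequence
    k = int(len(q) * query.max_divergence * 1.5) + 1  # generous band; exact check below
    all_hits: List[_Hit] = []
    for contig in SeqIO.parse(str(genome), "fasta"):
        fwd = str(contig.seq).upper()
        rev = reverse_complement(fwd)
        L = len(fwd)
        for strand, target in (("+", fwd), ("-", rev)):
            for s, e, dist in _collect_hits(q, target, k):
                hit_seq = target[s : e + 1]
                div = dist / max(len(q), len(hit_seq))
                if div > query.max_divergence:
                    continue
                if _has_n_run(hit_seq):
                    continue
                if strand == "+":
                    g_start, g_end = s, e
                else:
                    g_start, g_end = L - 1 - e, L - 1 - s
                all_hits.append(
                    _Hit(
                        contig=contig.id,
                        start=g_start,
                        end=g_end,
                        strand=strand,
                        divergence=div,
                        sequence=hit_seq,
                    )
                )

    # greedy overlap resolution: best divergence first, earlier position on ties
    max_overlap = int(len(q) * _MAX_OVERLAP_FRAC)
    kept: List[_Hit] = []
    for hit in sorted(all_hits, key=lambda h: (h.divergence, h.contig, h.start)):
        conflict = False
        for other in kept:
            if other.contig != hit.contig:
                continue
            overlap = min(hit.end, other.end) - max(hit.start, other.start) + 1
            if overlap > max_overlap:
                conflict = True
                break
        if not conflict:
            kept.append(hit)

    kept.sort(key=lambda h: (h.contig, h.start))
    if not kept:
        log.warning("no monomers found in %s", genome)
        return MonomerArray(())
    records = tuple(
        MonomerRecord(
            index=i,
            sequence=h.sequence,
            locus=Locus(
                contig=h.contig, start=h.start + 1, end=h.end + 1, strand=h.strand
            ),
        )
        for i, h in enumerate(kept, start=1)
    )
    return MonomerArray(records)
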