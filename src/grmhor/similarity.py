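"""Pairwise monomer divergence and the similarity predicate.

Two monomers belong to the same type when their normalised Levenshtein
edit distance is strictly below a divergence threshold (default 5%,
reflecting the >95% identity between copies of a higher-order repeat).
Distances are computed with edlib; the normalisation denominator is the
longer of the two sequences, so one substitution in a 171-bp monomer
gives 1/171 ~ 0.585%.

``N`` bases (assembly-gap placeholders) mismatch every base, including
another ``N``: a gap run must never create similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib


@dataclass(frozen=True)
class DivergenceThreshold:
    """Similarity cut-off as a fraction in (0, 1); strict comparison."""

    value: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.value < 1.0:
            raise ValueError(f"threshold must be in (0,1), got {self.value}")


DEFAULT_THRESHOLD = DivergenceThreshold(0.05)


def _mask_n(a: str, b: str) -> tuple:
    # Distinct placeholders on each side force N<->N (and N<->base) mismatches.
    return a.replace("N", "!"), b.replace("N", "?")


def divergence(a: str, b: str) -> float:
    """Normalised edit distance ``editDistance(a, b) / max(len(a), len(b))``.

    Symmetric; 0 iff the sequences are identical (and N-free).
    Raises ``ValueError`` on an empty sequence.
    """
    if not a or not b:
        raise ValueError("divergence undefined for empty sequences")
    a2, b2 = _mask_n(a, b)
    d = edlib.align(a2, b2, mode="NW", task="distance")["editDistance"]
    return d / max(len(a), len(b))


def is_similar(a: str, b: str, thr: DivergenceThreshold = DEFAULT_THRESHOLD) -> bool:
    """True iff ``divergence(a, b) < thr.value`` (strictly).

    Uses a banded alignment capped just above the threshold, so
    dissimilar pairs return early.
    """
    if not a or not b:
        raise ValueError("similarity undefined for empty sequences")
    denom = max(len(a), len(b))
    # dist/denom < thr  <=>  dist <= ceil(thr*denom) - 1 when thr*denom is
    # integral, else dist <= floor(thr*denom); cap the band one above to
    # keep the exact check below authoritative.
    cap = int(math.floor(thr.value * denom)) + 1
    a2, b2 = _mask_n(a, b)
    d = edlib.align(a2, b2, mode="NW", task="distance", k=cap)["editDistance"]
    if d < 0:
        return False
    return d / denom < thr.value
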