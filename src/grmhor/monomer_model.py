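"""Core data model for tandem monomer arrays.

A monomer array is an ordered list of DNA monomers (alpha satellite
monomers are ~171 bp) as they occur head-to-tail along a genomic
sequence.  Monomers are numbered 1..N in array order; each may carry an
optional genomic locus parsed from its FASTA header.

Header dialect for loci::

    >chr20:100-270(+)

i.e. ``<contig>:<start>-<end>(<strand>)`` with 1-based inclusive
coordinates.  Headers that do not match the pattern are accepted; the
record simply has no locus.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Union

VALID_BASES = frozenset("ACGTN")

_LOCUS_RE = re.compile(
    r"^(?P<contig>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)$"
)


@dataclass(frozen=True)
class Locus:
    """Genomic interval of a monomer: 1-based, inclusive on both ends."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid locus interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_header(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class MonomerRecord:
    """One monomer: 1-based ordinal ``index`` in the array, its DNA
    ``sequence`` (uppercase, over ACGTN) and an optional genomic
    ``locus`` whose span must equal the sequence length."""

    index: int
    sequence: str
    locus: Optional[Locus] = None

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"monomer index must be >= 1, got {self.index}")
        if not self.sequence:
            raise ValueError(f"monomer {self.index}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"monomer {self.index}: invalid characters {sorted(bad)} "
                "(sequences must be uppercase ACGTN)"
            )
        if self.locus is not None and self.locus.length != len(self.sequence):
            raise ValueError(
                f"monomer {self.index}: locus span {self.locus.length} != "
                f"sequence length {len(self.sequence)}"
            )

    def with_index(self, index: int) -> "MonomerRecord":
        return MonomerRecord(index=index, sequence=self.sequence, locus=self.locus)


@dataclass(frozen=True)
class MonomerArray:
    """Ordered monomer list; indices are exactly 1..N.

    May be empty (e.g. a consensus search that found nothing), but the
    FASTA reader/writer refuse empty input/output.
    """

    records: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        for pos, rec in enumerate(self.records, start=1):
            if rec.index != pos:
                raise ValueError(
                    f"record at position {pos} carries index {rec.index}; "
                    "indices must be exactly 1..N in order"
                )

    @property
    def N(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MonomerRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MonomerRecord:
        """0-based positional access (use ``.record(i)`` for 1-based)."""
        return self.records[i]

    def record(self, index: int) -> MonomerRecord:
        """1-based access matching reported monomer indices."""
        if not 1 <= index <= self.N:
            raise IndexError(f"monomer index {index} outside 1..{self.N}")
        return self.records[index - 1]

    @property
    def sequences(self) -> list:
        return [r.sequence for r in self.records]

    def subarray(self, first: int, last: int) -> "MonomerArray":
        """Monomers ``first..last`` (1-based, inclusive), renumbered 1..n."""
        if not (1 <= first <= last <= self.N):
            raise ValueError(f"invalid range {first}..{last} for array of {self.N}")
        return MonomerArray(
            tuple(
                rec.with_index(i)
                for i, rec in enumerate(self.records[first - 1 : last], start=1)
            )
        )

    @staticmethod
    def from_sequences(seqs, loci=None) -> "MonomerArray":
        loci = loci if loci is not None else [None] * len(list(seqs))
        seqs = list(seqs)
        return MonomerArray(
            tuple(
                MonomerRecord(index=i, sequence=s, locus=l)
                for i, (s, l) in enumerate(zip(seqs, loci), start=1)
            )
        )


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_locus_header(header: str) -> Optional[Locus]:
    """Parse ``<contig>:<start>-<end>(<strand>)``; None if no match."""
    m = _LOCUS_RE.match(header.strip())
    if m is None:
        return None
    return Locus(
        contig=m.group("contig"),
        start=int(m.group("start")),
        end=int(m.group("end")),
        strand=m.group("strand"),
    )


def read_monomer_fasta(path: Union[str, Path]) -> MonomerArray:
    """Read an ordered monomer array from FASTA.

    Records are numbered 1..N in file order.  Lowercase is normalised
    to uppercase.  Headers matching the locus dialect populate the
    record's locus; all other headers are accepted without one.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        On an empty file, a file not starting with '>', a record with
        an empty sequence, a locus/sequence length mismatch, or
        characters outside ACGTN (message names the record number).
    """
    path = Path(path)
    records = []
    with _open_text(path) as fh:
        header: Optional[str] = None
        chunks: list = []
        first_payload = True

        def _flush():
            if header is None:
                return
            seq = "".join(chunks).upper()
            n = len(records) + 1
            try:
                locus = parse_locus_header(header)
                records.append(MonomerRecord(index=n, sequence=seq, locus=locus))
            except ValueError as exc:
                raise ValueError(f"FASTA record {n} ({header!r}): {exc}") from None

        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                chunks = []
                first_payload = False
            else:
                if first_payload:
                    raise ValueError(
                        f"{path}: not FASTA (first non-empty line must start with '>')"
                    )
                chunks.append(line.strip())
        _flush()
    if not records:
        raise ValueError(f"{path}: empty FASTA (no records)")
    return MonomerArray(tuple(records))


def write_monomer_fasta(
    array: MonomerArray, path: Union[str, Path], width: int = 60
) -> Path:
    """Write *array* as FASTA, regenerating locus headers.

    Records without a locus get a ``mon_<index>`` header.  Refuses an
    empty array.  Round-trips: ``read_monomer_fasta(write_monomer_fasta(a)) == a``.
    """
    if array.N == 0:
        raise ValueError("refusing to write an empty monomer array")
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for rec in array:
            header = (
                rec.locus.to_header() if rec.locus is not None else f"mon_{rec.index:06d}"
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
    return path
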