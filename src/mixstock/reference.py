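"""Haplotype calling against a fixed-length reference library.

Haplotypes are identified by exact comparison of a query control-region
sequence against a library of named haplotype sequences over a common
alignment window (763 bp for the leatherback library).  IUPAC ambiguity
codes match any base in their expansion.  A query matching no library
sequence is reported as an orphan together with its nearest library
haplotype and the Hamming distance to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = ["ReferenceLibrary", "HaplotypeCall", "read_reference_library", "call_haplotype"]

ORPHAN = "ORPHAN"

# base -> frozenset of unambiguous bases it can stand for
_EXPANSION = {b: frozenset(v) for b, v in ambiguous_dna_values.items()}
_EXPANSION.update({b.lower(): v for b, v in _EXPANSION.items()})


class SequenceError(ValueError):
    """Raised for queries that cannot be compared against the library."""


@dataclass(frozen=True)
class ReferenceLibrary:
    """Named haplotype sequences of equal length."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"library sequences have unequal lengths: {sorted(lengths)}")
        for name, seq in self.sequences.items():
            bad = set(seq) - set(_EXPANSION)
            if bad:
                raise ValueError(f"non-nucleotide characters {sorted(bad)} in {name!r}")

    @property
    def window(self) -> int:
        """Alignment window length (763 for the leatherback library)."""
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class HaplotypeCall:
    """Result of calling one query sequence.

    ``haplotype`` is the library id on an exact match, or ``"ORPHAN"``;
    orphans carry the nearest library haplotype and its Hamming distance.
    """

    haplotype: str
    nearest: str | None = None
    distance: int | None = None

    @property
    def is_orphan(self) -> bool:
        return self.haplotype == ORPHAN


def read_reference_library(path: str | Path) -> ReferenceLibrary:
    """Read a reference library from FASTA; record ids name the haplotypes."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate haplotype id {rec.id!r} in library")
        seqs[rec.id] = str(rec.seq).upper()
    return ReferenceLibrary(seqs)


def _compatible(a: str, b: str) -> bool:
    try:
        return not _EXPANSION[a].isdisjoint(_EXPANSION[b])
    except KeyError as exc:
        raise SequenceError(f"non-nucleotide character {exc.args[0]!r}") from exc


def hamming(a: str, b: str) -> int:
    """Positions where the IUPAC expansions of *a* and *b* are disjoint."""
    return sum(not _compatible(x, y) for x, y in zip(a, b))


def call_haplotype(seq: str, lib: ReferenceLibrary) -> HaplotypeCall:
    """Identify *seq* against the library over its alignment window.

    The query is left-anchored: it is trimmed to the first ``lib.window``
    bases.  An exact (ambiguity-aware) match returns that haplotype;
    otherwise the call is an orphan annotated with the nearest haplotype.

    Raises
    ------
    SequenceError
        If the trimmed query is shorter than the window or contains
        non-nucleotide characters.
    ValueError
        If more than one library haplotype matches exactly (degenerate
        library or fully ambiguous query).
    """
    if not lib.sequences:
        raise ValueError("empty reference library")
    query = seq.strip().upper()
    if len(query) < lib.window:
        raise SequenceError(
            f"query length {len(query)} shorter than the {lib.window}-bp window"
        )
    query = query[: lib.window]
    bad = set(query) - set(_EXPANSION)
    if bad:
        raise SequenceError(f"non-nucleotide characters {sorted(bad)} in query")

    distances = {name: hamming(query, ref) for name, ref in lib.sequences.items()}
    exact = [name for name, d in distances.items() if d == 0]
    if len(exact) == 1:
        return HaplotypeCall(haplotype=exact[0])
    if len(exact) > 1:
        raise ValueError(f"query matches multiple library haplotypes: {sorted(exact)}")
    nearest = min(distances, key=lambda k: (distances[k], k))
    return HaplotypeCall(haplotype=ORPHAN, nearest=nearest, distance=distances[nearest])
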