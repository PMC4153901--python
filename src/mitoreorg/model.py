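"""Core genome model: annotated circular mitochondrial genomes.

Coordinates are 0-based half-open on the genome circle.  A feature that
wraps the numbering origin is represented with ``start > end`` (``end``
taken modulo the genome length), so feature length is always
``(end - start) % length``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "GeneFeature",
    "MitoGenome",
    "FEATURE_KINDS",
    "revcomp",
    "CoordinateError",
]

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "CR", "OL", "noncoding")

_COMP = str.maketrans("ACGTUacgtuNRYKMSWBDHVnrykmswbdhv",
                      "TGCAAtgcaaNYRMKSWVHDBnyrmkswvhdb")


class CoordinateError(ValueError):
    """A feature does not fit the genome's coordinate system."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMP)[::-1]


@dataclass
class GeneFeature:
    """One annotated feature on a mitochondrial genome.

    ``name`` uses MitoZoa-style normalized tokens (cox1, nad5, trnL(CUN),
    trnS(AGY), rrnS, rrnL, CR, OL, ...).  ``copy_index`` numbers repeated
    occurrences of the same name consecutively from 1 in genome scan order.
    """

    name: str
    kind: str
    strand: str
    start: int
    end: int
    pseudogene: bool = False
    copy_index: int = 1
    anticodon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def length(self, genome_length: int) -> int:
        n = (self.end - self.start) % genome_length
        if n == 0:
            raise CoordinateError(
                f"feature {self.name} has zero length on a {genome_length} bp circle"
            )
        return n

    def wraps_origin(self) -> bool:
        return self.end <= self.start


@dataclass
class MitoGenome:
    """An annotated (usually circular) mitochondrial genome."""

    id: str
    length: int
    circular: bool = True
    sequence: Optional[str] = None
    features: list[GeneFeature] = field(default_factory=list)

    def validate(self) -> None:
        if self.length <= 0:
            raise CoordinateError(f"{self.id}: non-positive genome length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise CoordinateError(
                f"{self.id}: sequence length {len(self.sequence)} != LOCUS length {self.length}"
            )
        for f in self.features:
            if not (0 <= f.start < self.length):
                raise CoordinateError(
                    f"{self.id}:{f.name}: start {f.start} outside [0, {self.length})"
                )
            if f.end > self.length or f.end < 0:
                raise CoordinateError(
                    f"{self.id}:{f.name}: end {f.end} outside [0, {self.length}]"
                )
            if not self.circular and f.wraps_origin():
                raise CoordinateError(
                    f"{self.id}:{f.name}: feature wraps the origin of a linear record"
                )
            f.length(self.length)

    def sorted_features(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: (f.start, f.end))

    def assign_copy_indices(self) -> None:
        """Renumber copy_index per name, consecutive from 1 in scan order."""
        seen: dict[str, int] = {}
        for f in self.sorted_features():
            seen[f.name] = seen.get(f.name, 0) + 1
            f.copy_index = seen[f.name]

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Sense-strand sequence of a feature (wrap- and strand-aware)."""
        if self.sequence is None:
            raise ValueError(f"{self.id}: genome has no sequence")
        if feat.wraps_origin():
            sub = self.sequence[feat.start:] + self.sequence[: feat.end]
        else:
            sub = self.sequence[feat.start: feat.end]
        return revcomp(sub) if feat.strand == "-" else sub

    def rotated(self, k: int) -> "MitoGenome":
        """Return a copy with the coordinate origin moved by k bp.

        Base at old coordinate ``k`` becomes coordinate 0.  Annotation
        content is unchanged; only the arbitrary numbering moves.
        """
        k %= self.length
        seq = None
        if self.sequence is not None:
            seq = self.sequence[k:] + self.sequence[:k]
        feats = [
            replace(f, start=(f.start - k) % self.length,
                    end=(f.end - k) % self.length)
            for f in self.features
        ]
        g = MitoGenome(self.id, self.length, self.circular, seq, feats)
        g.assign_copy_indices()
        return g
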