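"""Core record types shared across the pipeline.

Coordinates are 1-based inclusive internally (UniProt feature convention);
conversion to 0-based half-open intervals happens only at the BED boundary
in :mod:`tmvarscape.io_formats`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

#: Fixed amino-acid order used for all 20x20 matrices (rows = mutated/wild-type
#: residue, columns = mutant residue).
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
STANDARD_AAS = frozenset(AA_ORDER)


class VariantClass(enum.Enum):
    """UniProt-style classification of a missense variant."""

    DISEASE = "Disease"
    POLYMORPHISM = "Polymorphism"
    UNCLASSIFIED = "Unclassified"


class Region(enum.Enum):
    """Three-state membrane topology: Inside (cytosolic), Membrane, Outside."""

    INSIDE = "I"
    MEMBRANE = "M"
    OUTSIDE = "O"


class Subregion(enum.Enum):
    """Refinement of topology segments for multi-pass proteins.

    Terminals are the regions before the first and after the last TM segment;
    every other non-membrane segment is a loop.
    """

    N_TERMINAL = "N_TERMINAL"
    LOOP = "LOOP"
    C_TERMINAL = "C_TERMINAL"
    TM = "TM"


class RecordError(ValueError):
    """A record violates one of its structural invariants."""


@dataclass(frozen=True)
class VariantRecord:
    """One missense substitution on a protein.

    ``position`` is the 1-based residue index of the substituted residue;
    ``ref_aa``/``alt_aa`` are one-letter codes of the wild-type and mutant
    residues.
    """

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    classification: VariantClass
    disease_names: tuple[str, ...] = ()
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise RecordError(f"position must be >= 1, got {self.position}")
        for label, aa in (("ref_aa", self.ref_aa), ("alt_aa", self.alt_aa)):
            if aa not in STANDARD_AAS:
                raise RecordError(f"{label} {aa!r} is not a standard residue")
        if self.ref_aa == self.alt_aa:
            raise RecordError(f"synonymous change {self.ref_aa}->{self.alt_aa}")

    @property
    def substitution(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class TopologySegment:
    """A maximal run of residues sharing one topology state.

    ``start``/``end`` are 1-based inclusive. ``subregion`` is derived by
    :func:`tmvarscape.topology_mapping.label_subregions` and is ``None``
    until then for non-membrane segments.
    """

    region: Region
    start: int
    end: int
    subregion: Subregion | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise RecordError(f"segment start {self.start} > end {self.end}")
        if self.region is Region.MEMBRANE:
            if self.subregion is None:
                self.subregion = Subregion.TM
            elif self.subregion is not Subregion.TM:
                raise RecordError("membrane segment must have subregion TM")
        elif self.subregion is Subregion.TM:
            raise RecordError("only membrane segments may be TM")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class ProteinRecord:
    """A protein sequence together with its ordered topology segments."""

    protein_id: str
    sequence: str
    segments: list[TopologySegment] = field(default_factory=list)

    @property
    def tm_count(self) -> int:
        return sum(1 for s in self.segments if s.region is Region.MEMBRANE)

    @property
    def is_tmp(self) -> bool:
        return self.tm_count >= 1

    @property
    def length(self) -> int:
        return len(self.sequence) if self.sequence else (
            self.segments[-1].end if self.segments else 0
        )

    def validate(self) -> None:
        """Check the segment-tiling invariants; raise :class:`RecordError`.

        Segments must tile ``[1, length]`` with no gaps or overlaps and
        consecutive segments must differ in region.
        """
        if not self.segments:
            raise RecordError(f"{self.protein_id}: no topology segments")
        if self.segments[0].start != 1:
            raise RecordError(
                f"{self.protein_id}: first segment starts at "
                f"{self.segments[0].start}, not 1"
            )
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.start != prev.end + 1:
                kind = "overlap" if cur.start <= prev.end else "gap"
                raise RecordError(
                    f"{self.protein_id}: {kind} between segments at "
                    f"{prev.end}/{cur.start}"
                )
            if cur.region is prev.region:
                raise RecordError(
                    f"{self.protein_id}: consecutive segments share region "
                    f"{cur.region.value}"
                )
        if self.sequence and self.segments[-1].end != len(self.sequence):
            raise RecordError(
                f"{self.protein_id}: segments end at {self.segments[-1].end} "
                f"but sequence has {len(self.sequence)} residues"
            )

    def segment_at(self, position: int) -> TopologySegment:
        """Return the unique segment containing ``position`` (binary search)."""
        lo, hi = 0, len(self.segments) - 1
        while lo <= hi:
            mid = (lo + hi) // 2
            seg = self.segments[mid]
            if position < seg.start:
                hi = mid - 1
            elif position > seg.end:
                lo = mid + 1
            else:
                return seg
        raise RecordError(
            f"{self.protein_id}: position {position} outside topology"
        )

    def residue(self, position: int) -> str:
        return self.sequence[position - 1]
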