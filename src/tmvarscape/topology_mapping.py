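"""Assign variants to topology segments and compute region denominators.

The mapping is the point-in-tiling intersection the pipeline is built on:
each retained variant lands in exactly one segment of its protein's
topology. Variants are filtered on the way in — unclassified variants,
disease variants ambiguously associated with multiple diseases, records
whose reference residue disagrees with the sequence, unknown proteins and
out-of-range positions are dropped and individually counted so that the
bookkeeping is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .records import (
    ProteinRecord,
    RecordError,
    Region,
    Subregion,
    VariantClass,
    VariantRecord,
)


@dataclass(frozen=True)
class RegionAssignment:
    """One variant placed on its topology segment."""

    variant: VariantRecord
    region: Region
    subregion: Subregion | None
    segment_index: int
    offset: int  # 0-based offset from segment start

    @property
    def in_tmp(self) -> bool:
        return self.subregion is not None


@dataclass
class DropLog:
    """Why input variants were excluded; conserves the input count."""

    n_input: int = 0
    n_assigned: int = 0
    unclassified: int = 0
    ambiguous: int = 0
    mismatch: int = 0
    unknown_protein: int = 0
    out_of_range: int = 0
    details: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return (
            self.unclassified
            + self.ambiguous
            + self.mismatch
            + self.unknown_protein
            + self.out_of_range
        )

    def is_conserved(self) -> bool:
        return self.n_input == self.n_assigned + self.n_dropped


def is_ambiguous(variant: VariantRecord) -> bool:
    """A disease variant associated with more than one distinct disease."""
    return (
        variant.classification is VariantClass.DISEASE
        and len(set(variant.disease_names)) > 1
    )


def label_subregions(protein: ProteinRecord) -> ProteinRecord:
    """Derive N-terminal / loop / C-terminal / TM labels for a TMP (in place).

    The segment before the first membrane segment is the N-terminal, the one
    after the last membrane segment the C-terminal, every other non-membrane
    segment a loop; single-pass proteins therefore have no loops.
    """
    if not protein.is_tmp:
        raise RecordError(f"{protein.protein_id} is not a transmembrane protein")
    m_indices = [
        i for i, s in enumerate(protein.segments) if s.region is Region.MEMBRANE
    ]
    first_m, last_m = m_indices[0], m_indices[-1]
    for i, seg in enumerate(protein.segments):
        if seg.region is Region.MEMBRANE:
            seg.subregion = Subregion.TM
        elif i < first_m:
            seg.subregion = Subregion.N_TERMINAL
        elif i > last_m:
            seg.subregion = Subregion.C_TERMINAL
        else:
            seg.subregion = Subregion.LOOP
    return protein


def assign_regions(
    variants: Iterable[VariantRecord],
    proteome: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
) -> tuple[list[RegionAssignment], DropLog]:
    """Intersect variants with topology; return assignments and the drop log.

    Filtering rules: unclassified variants and multi-disease ("ambiguous")
    disease variants are excluded from the analysis; variants on proteins
    absent from the proteome, at positions beyond the sequence, or whose
    reference residue mismatches the sequence are dropped and logged.
    Subregion labels are derived for every TMP before assignment; non-TMP
    assignments carry ``subregion=None``.
    """
    if isinstance(proteome, Mapping):
        by_id = dict(proteome)
    else:
        by_id = {p.protein_id: p for p in proteome}
    for protein in by_id.values():
        if protein.is_tmp and any(
            s.subregion is None for s in protein.segments
        ):
            label_subregions(protein)

    assignments: list[RegionAssignment] = []
    log = DropLog()
    for variant in variants:
        log.n_input += 1
        protein = by_id.get(variant.protein_id)
        if protein is None:
            log.unknown_protein += 1
            log.details.append((variant.protein_id, "unknown protein"))
            continue
        if variant.classification is VariantClass.UNCLASSIFIED:
            log.unclassified += 1
            continue
        if is_ambiguous(variant):
            log.ambiguous += 1
            continue
        if variant.position > protein.length:
            log.out_of_range += 1
            log.details.append(
                (variant.protein_id, f"position {variant.position} beyond end")
            )
            continue
        if protein.sequence and protein.residue(variant.position) != variant.ref_aa:
            log.mismatch += 1
            log.details.append(
                (
                    variant.protein_id,
                    f"ref {variant.ref_aa} != sequence "
                    f"{protein.residue(variant.position)} at {variant.position}",
                )
            )
            continue
        segment = protein.segment_at(variant.position)
        assignments.append(
            RegionAssignment(
                variant=variant,
                region=segment.region,
                subregion=segment.subregion if protein.is_tmp else None,
                segment_index=protein.segments.index(segment),
                offset=variant.position - segment.start,
            )
        )
        log.n_assigned += 1
    return assignments, log


def region_lengths(
    proteome: Iterable[ProteinRecord], stratify_by: str = "region"
) -> dict[str, int]:
    """Total residues per region (I/M/O) or per subregion label.

    Subregion stratification covers TMPs only (labels are derived on the
    fly where missing); region stratification sums over all proteins given.
    """
    totals: dict[str, int] = {}
    for protein in proteome:
        if stratify_by == "subregion":
            if not protein.is_tmp:
                continue
            if any(s.subregion is None for s in protein.segments):
                label_subregions(protein)
            for seg in protein.segments:
                key = seg.subregion.value
                totals[key] = totals.get(key, 0) + seg.length
        elif stratify_by == "region":
            for seg in protein.segments:
                key = seg.region.value
                totals[key] = totals.get(key, 0) + seg.length
        else:
            raise ValueError(f"unknown stratification {stratify_by!r}")
    return totals


def tm_count_distribution(
    protein_sets: Mapping[str, Sequence[ProteinRecord]], max_tm: int = 12
) -> dict[str, dict[int, float]]:
    """Fraction of proteins with k membrane segments (k = 1..max_tm) per set.

    The denominator is every protein in the set, including those above
    ``max_tm`` (they are excluded from display only), so reported fractions
    need not sum to 1.
    """
    out: dict[str, dict[int, float]] = {}
    for name, proteins in protein_sets.items():
        n = len(proteins)
        dist: dict[int, float] = {}
        if n:
            for k in range(1, max_tm + 1):
                count = sum(1 for p in proteins if p.tm_count == k)
                if count:
                    dist[k] = count / n
        out[name] = dist
    return out
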