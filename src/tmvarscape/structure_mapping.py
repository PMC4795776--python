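"""Variant density profiles along the membrane normal.

With structures expressed in the membrane frame (z along the membrane
normal, origin at the bilayer center), proteins are cut into slices of
fixed width parallel to the membrane plane; per slice the number of
residues, disease mutations and polymorphisms are summed, and relative
frequencies are the class counts divided by the residue count of the same
slice. Pooling across proteins is ratio-of-sums: counts are summed
slice-wise before dividing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .records import VariantClass
from .topology_mapping import RegionAssignment


@dataclass
class SliceProfile:
    """Per-slice residue and variant counts along z.

    Keys of ``slices`` are slice indices k covering ``[k*w, (k+1)*w)``.
    A residue may carry several variants, so class counts are not bounded
    by the residue count.
    """

    slice_width: float
    slices: dict[int, dict[str, int]] = field(default_factory=dict)
    unmapped: int = 0  # variants on residues without coordinates

    def _slot(self, k: int) -> dict[str, int]:
        return self.slices.setdefault(
            k, {"residues": 0, "disease": 0, "polymorphism": 0}
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabulate reported slices (residue count >= 1) with frequencies."""
        rows = []
        for k in sorted(self.slices):
            s = self.slices[k]
            if s["residues"] < 1:
                continue
            rows.append(
                {
                    "z_low": k * self.slice_width,
                    "z_high": (k + 1) * self.slice_width,
                    "residues": s["residues"],
                    "disease": s["disease"],
                    "polymorphism": s["polymorphism"],
                    "f_disease": s["disease"] / s["residues"],
                    "f_polymorphism": s["polymorphism"] / s["residues"],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "z_low",
                "z_high",
                "residues",
                "disease",
                "polymorphism",
                "f_disease",
                "f_polymorphism",
            ],
        )


def slice_index(z: float, width: float) -> int:
    """Slice containing z under the half-open floor convention."""
    return math.floor(z / width)


def slice_profile(
    z_map: Mapping[tuple[str, int], float],
    assignments: Iterable[RegionAssignment],
    slice_width: float = 1.0,
) -> SliceProfile:
    """Build the per-slice profile for one set of membrane-frame coordinates.

    Every residue with a coordinate contributes to the slice
    ``floor(z / width)``; a variant contributes the class count of its
    residue's slice. Variants whose residue has no coordinate are counted
    as unmapped. Unclassified assignments are ignored.
    """
    if slice_width <= 0:
        raise ValueError("slice_width must be positive")
    profile = SliceProfile(slice_width=slice_width)
    for z in z_map.values():
        profile._slot(slice_index(z, slice_width))["residues"] += 1
    for a in assignments:
        cls = a.variant.classification
        if cls is VariantClass.DISEASE:
            label = "disease"
        elif cls is VariantClass.POLYMORPHISM:
            label = "polymorphism"
        else:
            continue
        key = (a.variant.protein_id, a.variant.position)
        z = z_map.get(key)
        if z is None:
            profile.unmapped += 1
            continue
        profile._slot(slice_index(z, slice_width))[label] += 1
    return profile


def aggregate_profiles(profiles: Iterable[SliceProfile]) -> SliceProfile:
    """Pool profiles by summing counts slice-wise (ratio of sums).

    All inputs must share the slice width; frequencies of the pooled
    profile are total class counts over total residues per slice, which in
    general differs from averaging per-protein frequencies.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to aggregate")
    width = profiles[0].slice_width
    pooled = SliceProfile(slice_width=width)
    for p in profiles:
        if p.slice_width != width:
            raise ValueError(
                f"slice width mismatch: {p.slice_width} != {width}"
            )
        pooled.unmapped += p.unmapped
        for k, s in p.slices.items():
            slot = pooled._slot(k)
            for label, count in s.items():
                slot[label] += count
    return pooled
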