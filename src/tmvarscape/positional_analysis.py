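"""Position-within-TM statistics: center distances and natural residues.

A TM residue's position is expressed as its sequence offset from the
segment's most central residue, normalized by segment length, so segments
of different lengths are comparable: d = 0 at the center and |d| approaches
0.5 at the membrane boundaries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .records import ProteinRecord, Region, TopologySegment


class DistanceSource(enum.Enum):
    NATURAL_RESIDUE = "natural_residue"
    DISEASE_VARIANT = "disease_variant"
    POLYMORPHISM_VARIANT = "polymorphism_variant"


@dataclass(frozen=True)
class CenterDistanceRecord:
    source: DistanceSource
    identity: str  # residue (e.g. "R") or substitution (e.g. "G>R")
    d: float  # signed normalized distance, in [-0.5, 0.5]


def center_distance(position: int, segment: TopologySegment) -> float:
    """Signed normalized distance of ``position`` from the segment center.

    The center is the most central actual residue, ``floor((start+end)/2)``
    (the lower median for even-length segments), and the offset is divided
    by the segment length in residues.
    """
    if segment.region is not Region.MEMBRANE:
        raise ValueError("center distance is defined for membrane segments")
    if position not in segment:
        raise ValueError(
            f"position {position} outside segment {segment.start}-{segment.end}"
        )
    center = (segment.start + segment.end) // 2
    return (position - center) / segment.length


def center_distance_histogram(
    records: Iterable[CenterDistanceRecord],
    bin_width: float = 0.05,
    absolute: bool = True,
) -> pd.DataFrame:
    """Relative-frequency histogram of center distances per source.

    Bins are half-open ``[k*w, (k+1)*w)``; with ``absolute=True`` the
    histogram is over |d| (distance from the center regardless of side).
    Frequencies sum to 1 within each source. Columns: bin_start, bin_end,
    source, frequency.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    by_source: dict[str, list[float]] = {}
    for rec in records:
        d = abs(rec.d) if absolute else rec.d
        by_source.setdefault(rec.source.value, []).append(d)
    rows = []
    for source in sorted(by_source):
        values = np.asarray(by_source[source])
        bins = np.floor(values / bin_width).astype(int)
        uniq, counts = np.unique(bins, return_counts=True)
        freqs = counts / counts.sum()
        for k, f in zip(uniq, freqs):
            rows.append(
                {
                    "bin_start": k * bin_width,
                    "bin_end": (k + 1) * bin_width,
                    "source": source,
                    "frequency": f,
                }
            )
    return pd.DataFrame(
        rows, columns=["bin_start", "bin_end", "source", "frequency"]
    )


def natural_residue_positions(
    proteome: Iterable[ProteinRecord], residue: str = "R"
) -> tuple[list[CenterDistanceRecord], dict[int, int]]:
    """Occurrences of a residue inside TM segments, with host-protein counts.

    Scans every membrane segment for ``residue``, emitting one center
    distance record per occurrence, and tallies how many host proteins fall
    in each TM-count category (e.g. the naturally membrane-embedded
    arginines concentrating in 7-TM receptors).
    """
    records: list[CenterDistanceRecord] = []
    per_tm_count: dict[int, int] = {}
    for protein in proteome:
        found = False
        for seg in protein.segments:
            if seg.region is not Region.MEMBRANE:
                continue
            for pos in range(seg.start, seg.end + 1):
                if protein.sequence[pos - 1] == residue:
                    found = True
                    records.append(
                        CenterDistanceRecord(
                            source=DistanceSource.NATURAL_RESIDUE,
                            identity=residue,
                            d=center_distance(pos, seg),
                        )
                    )
        if found:
            k = protein.tm_count
            per_tm_count[k] = per_tm_count.get(k, 0) + 1
    return records, per_tm_count
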