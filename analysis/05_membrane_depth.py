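#!/usr/bin/env python
"""Map variants onto membrane-frame 3D coordinates and profile their
density along the membrane normal in 1 A slices (relative frequency =
class count / residue count per slice, pooled over proteins as a ratio
of sums).
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import numpy as np

from tmvarscape import io_formats
from tmvarscape.structure_mapping import slice_profile
from tmvarscape.topology_mapping import assign_regions

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = DATA.parent / "tables"


def main() -> None:
    sequences = io_formats.read_fasta(DATA / "sequences.fasta")
    proteome, _ = io_formats.read_topology(
        DATA / "topology.xml", "htp_xml", sequences=sequences
    )
    variants, _ = io_formats.read_variants(DATA / "variants.tsv", "tsv")
    assignments, _ = assign_regions(variants, proteome)

    frame = json.loads((DATA / "membrane_frame.json").read_text())
    rotation = np.asarray(frame["rotation"])
    translation = np.asarray(frame["translation"])
    z_map = {}
    for pdb in sorted((DATA / "structures").glob("*.pdb")):
        z_map.update(
            io_formats.read_structure_frame(
                pdb, rotation, translation, protein_id=pdb.stem
            )
        )

    profile = slice_profile(z_map, assignments, slice_width=1.0)
    table = profile.to_frame()
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "zprofile.tsv", sep="\t", index=False,
                 float_format="%.4f")
    core = table[(table.z_low >= -15) & (table.z_high <= 15)]
    outer = table[(table.z_low < -15) | (table.z_high > 15)]
    print(f"{len(table)} slices, {profile.unmapped} variants without coordinates")
    for name, band in (("bilayer core (|z|<15)", core), ("outside core", outer)):
        if band.residues.sum():
            print(f"{name}: disease {100 * band.disease.sum() / band.residues.sum():.3f}"
                  f" / polymorphism {100 * band.polymorphism.sum() / band.residues.sum():.3f}"
                  " per 100 residues")
    print(f"wrote {OUT / 'zprofile.tsv'}")


if __name__ == "__main__":
    main()
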