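"""Synthetic proteomes, variant sets and structures for end-to-end testing.

The generator emulates the statistical structure the analysis assumes:
topologies with 0-14 membrane segments in which a membrane segment always
separates an inside from an outside segment; TM sequence stretches enriched
in hydrophobic residues; variant classes with distinct, configurable
substitution spectra (defaults: the empirical human TM spectra of
:mod:`tmvarscape.tm_spectra`, so disease variants are enriched for Gly->Arg
and Leu->Pro in the membrane while polymorphisms favour symmetric
non-polar exchanges); and ideal-helix coordinates with the membrane normal
along z. Everything is deterministic given the master seed, with
per-protein substreams derived by stable hashing of the protein id so
generation order does not matter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import io_formats
from .records import (
    AA_INDEX,
    AA_ORDER,
    ProteinRecord,
    Region,
    TopologySegment,
    VariantClass,
    VariantRecord,
)
from .tm_spectra import DISEASE_TM_PERCENT, POLYMORPHISM_TM_PERCENT

#: Ideal alpha-helix parameters: rise per residue along the axis (A),
#: rotation per residue (degrees) and backbone radius (A).
HELIX_RISE = 1.5
HELIX_TURN_DEG = 100.0
HELIX_RADIUS = 2.3

#: Half-thickness of the hydrophobic core; TM helices cross z in
#: [-HALF_BILAYER, +HALF_BILAYER] and loops extend beyond it.
HALF_BILAYER = 15.0
LOOP_Z_STEP = 1.0
LOOP_Z_CAP = 55.0

_DISEASE_VOCABULARY = (
    "Synthetic channelopathy 1",
    "Synthetic receptor dysplasia",
    "Synthetic transporter deficiency",
    "Synthetic storage disease",
    "Synthetic neuropathy 2",
)

_NONPOLAR_IDX = np.array([AA_INDEX[a] for a in "ACGILMFPWV"])


def _uniform_offdiag() -> np.ndarray:
    m = np.ones((20, 20))
    np.fill_diagonal(m, 0.0)
    return m / m.sum()


def _default_tm_count_weights() -> np.ndarray:
    # 0 = non-TMP; bitopic proteins and 7-TM receptors dominate, with
    # smaller 10/12-TM transporter classes and a rare >12 tail.
    w = np.array(
        [0.25, 0.22, 0.07, 0.05, 0.06, 0.03, 0.04, 0.15,
         0.02, 0.02, 0.035, 0.02, 0.025, 0.005, 0.005]
    )
    return w / w.sum()


def _default_composition() -> dict[str, np.ndarray]:
    # order: A R N D C Q E G H I L K M F P S T W Y V
    tm = np.array(
        [0.09, 0.015, 0.02, 0.015, 0.02, 0.015, 0.02, 0.07, 0.02, 0.11,
         0.16, 0.01, 0.04, 0.09, 0.03, 0.05, 0.05, 0.03, 0.035, 0.11]
    )
    soluble = np.array(
        [0.07, 0.06, 0.045, 0.055, 0.02, 0.045, 0.07, 0.065, 0.025, 0.05,
         0.09, 0.06, 0.02, 0.035, 0.06, 0.08, 0.055, 0.01, 0.03, 0.055]
    )
    return {
        "I": soluble / soluble.sum(),
        "M": tm / tm.sum(),
        "O": soluble / soluble.sum(),
    }


def _default_class_spectra() -> dict[tuple[str, str], np.ndarray]:
    disease_tm = DISEASE_TM_PERCENT / DISEASE_TM_PERCENT.sum()
    poly_tm = POLYMORPHISM_TM_PERCENT / POLYMORPHISM_TM_PERCENT.sum()
    uniform = _uniform_offdiag()
    return {
        ("Disease", "M"): disease_tm,
        ("Polymorphism", "M"): poly_tm,
        ("Disease", "I"): uniform.copy(),
        ("Disease", "O"): uniform.copy(),
        ("Polymorphism", "I"): uniform.copy(),
        ("Polymorphism", "O"): uniform.copy(),
    }


def _default_rates() -> dict[tuple[str, str], float]:
    # per-residue Poisson rates; membrane regions carry the highest
    # variant density of the three topological regions.
    return {
        ("Polymorphism", "I"): 6e-3,
        ("Polymorphism", "M"): 9e-3,
        ("Polymorphism", "O"): 6e-3,
        ("Disease", "I"): 3e-3,
        ("Disease", "M"): 6e-3,
        ("Disease", "O"): 3e-3,
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    ``class_spectra`` rows are renormalized (diagonal zeroed) into the
    conditional distribution of the mutant residue given the wild-type;
    ``variant_rates`` are expected variants per residue per class and
    region; ``tm_count_weights[k]`` is the probability of a protein with k
    membrane segments (k = 0 means non-TMP).
    """

    n_proteins: int = 200
    seed: int = 0
    tm_count_weights: np.ndarray = field(default_factory=_default_tm_count_weights)
    segment_length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "TM": (17, 25),
            "N_TERMINAL": (10, 60),
            "LOOP": (5, 30),
            "C_TERMINAL": (10, 60),
            "NON_TMP": (120, 600),
        }
    )
    composition: dict[str, np.ndarray] = field(default_factory=_default_composition)
    class_spectra: dict[tuple[str, str], np.ndarray] = field(
        default_factory=_default_class_spectra
    )
    variant_rates: dict[tuple[str, str], float] = field(default_factory=_default_rates)
    unclassified_rate: float = 5e-4
    multi_disease_fraction: float = 0.05

    def validate(self) -> None:
        if not np.isclose(self.tm_count_weights.sum(), 1.0, atol=1e-9):
            raise ValueError("tm_count_weights must sum to 1")
        for key, (lo, hi) in self.segment_length_ranges.items():
            if not (1 <= lo <= hi):
                raise ValueError(f"infeasible length range for {key}: ({lo}, {hi})")
        for region, comp in self.composition.items():
            if not np.isclose(comp.sum(), 1.0, atol=1e-9):
                raise ValueError(f"composition for {region} must sum to 1")
        if self.composition["M"][_NONPOLAR_IDX].sum() < 0.6:
            raise ValueError(
                "TM composition must place >= 60% mass on hydrophobic residues"
            )
        for key, spec in self.class_spectra.items():
            if not np.isclose(spec.sum(), 1.0, atol=1e-9):
                raise ValueError(f"class spectrum {key} must sum to 1")
        if any(rate < 0 for rate in self.variant_rates.values()):
            raise ValueError("variant rates must be non-negative")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _rng(seed: int, stream: int, protein_id: str) -> np.random.Generator:
    """Per-protein substream keyed by a stable hash of the protein id."""
    return np.random.default_rng([seed, stream, zlib.crc32(protein_id.encode())])


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def generate_proteome(config: SyntheticConfig) -> list[ProteinRecord]:
    """Draw a proteome of ``n_proteins`` with alternating I/M/O topologies."""
    config.validate()
    ranges = config.segment_length_ranges
    proteome = []
    for i in range(config.n_proteins):
        pid = f"SYN{i:05d}"
        rng = _rng(config.seed, 1, pid)
        k = int(rng.choice(len(config.tm_count_weights), p=config.tm_count_weights))
        segments: list[TopologySegment] = []
        pos = 1

        def add(region: Region, lo: int, hi: int) -> None:
            nonlocal pos
            length = int(rng.integers(lo, hi + 1))
            segments.append(TopologySegment(region, pos, pos + length - 1))
            pos += length

        if k == 0:
            add(Region.OUTSIDE, *ranges["NON_TMP"])
        else:
            side = Region.INSIDE if rng.random() < 0.5 else Region.OUTSIDE
            add(side, *ranges["N_TERMINAL"])
            for j in range(k):
                add(Region.MEMBRANE, *ranges["TM"])
                side = Region.OUTSIDE if side is Region.INSIDE else Region.INSIDE
                if j < k - 1:
                    add(side, *ranges["LOOP"])
                else:
                    add(side, *ranges["C_TERMINAL"])
        length = segments[-1].end
        seq = np.empty(length, dtype="U1")
        for seg in segments:
            comp = config.composition[seg.region.value]
            idx = rng.choice(20, size=seg.length, p=comp)
            seq[seg.start - 1 : seg.end] = [AA_ORDER[j] for j in idx]
        protein = ProteinRecord(pid, "".join(seq), segments)
        protein.validate()
        proteome.append(protein)
    return proteome


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def generate_variants(
    proteome: Sequence[ProteinRecord], config: SyntheticConfig
) -> list[VariantRecord]:
    """Scatter variants over the proteome.

    Per protein, region and class the variant count is Poisson with mean
    ``rate * region length``; each variant picks a position uniformly in
    the segment, takes the sequence residue there as wild-type, and draws
    the mutant from the class spectrum row of that wild-type (diagonal
    zeroed, renormalized). Disease variants receive one disease name from a
    fixed vocabulary, or two distinct names with probability
    ``multi_disease_fraction`` (making them ambiguous and removable).
    """
    config.validate()
    uniform = _uniform_offdiag()
    variants: list[VariantRecord] = []
    classes = (
        VariantClass.POLYMORPHISM,
        VariantClass.DISEASE,
        VariantClass.UNCLASSIFIED,
    )
    for protein in proteome:
        rng = _rng(config.seed, 2, protein.protein_id)
        counter = 0
        for seg in protein.segments:
            region = seg.region.value
            for cls in classes:
                if cls is VariantClass.UNCLASSIFIED:
                    rate = config.unclassified_rate
                    spectrum = uniform
                else:
                    rate = config.variant_rates.get((cls.value, region), 0.0)
                    spectrum = config.class_spectra.get((cls.value, region), uniform)
                n = int(rng.poisson(rate * seg.length))
                for _ in range(n):
                    position = int(rng.integers(seg.start, seg.end + 1))
                    ref = protein.residue(position)
                    row = spectrum[AA_INDEX[ref]].copy()
                    row[AA_INDEX[ref]] = 0.0
                    total = row.sum()
                    if total == 0:
                        raise ValueError(
                            f"class spectrum for {cls.value}/{region} has an "
                            f"all-zero row for residue {ref}"
                        )
                    alt = AA_ORDER[int(rng.choice(20, p=row / total))]
                    names: tuple[str, ...] = ()
                    if cls is VariantClass.DISEASE:
                        picks = rng.choice(
                            len(_DISEASE_VOCABULARY),
                            size=2
                            if rng.random() < config.multi_disease_fraction
                            else 1,
                            replace=False,
                        )
                        names = tuple(_DISEASE_VOCABULARY[p] for p in picks)
                    counter += 1
                    variants.append(
                        VariantRecord(
                            protein_id=protein.protein_id,
                            position=position,
                            ref_aa=ref,
                            alt_aa=alt,
                            classification=cls,
                            disease_names=names,
                            variant_id=f"VAR_{protein.protein_id}_{counter:04d}",
                        )
                    )
    return variants


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass
class StructureSet:
    """Membrane-frame coordinates for the TMPs of a synthetic proteome.

    The frame is the identity (coordinates are generated directly in the
    membrane frame: z along the normal, origin at the bilayer center).
    """

    coords: dict[str, dict[int, tuple[float, float, float]]]
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def z_map(self) -> dict[tuple[str, int], float]:
        return {
            (pid, pos): xyz[2]
            for pid, residues in self.coords.items()
            for pos, xyz in residues.items()
        }


def generate_structures(
    proteome: Sequence[ProteinRecord], config: SyntheticConfig
) -> StructureSet:
    """Lay TMP residues on ideal geometry in the membrane frame.

    TM residues follow an ideal helix (rise 1.5 A/residue) crossing the
    bilayer, with consecutive TM segments alternating crossing direction;
    loop and terminal residues sit beyond the +-15 A core with |z| growing
    by 1 A per residue away from the nearest membrane boundary, capped, on
    positive z for inside (cytosolic) segments and negative z for outside
    segments. Non-TMPs contribute nothing.
    """
    coords: dict[str, dict[int, tuple[float, float, float]]] = {}
    for protein in proteome:
        if not protein.is_tmp:
            continue
        rng = _rng(config.seed, 3, protein.protein_id)
        phase = float(rng.uniform(0, 360.0))
        residues: dict[int, tuple[float, float, float]] = {}
        segments = protein.segments
        for si, seg in enumerate(segments):
            length = seg.length
            if seg.region is Region.MEMBRANE:
                if si > 0:
                    prev_side = 1.0 if segments[si - 1].region is Region.INSIDE else -1.0
                else:  # membrane-first topology: infer from the next segment
                    prev_side = -1.0 if segments[si + 1].region is Region.INSIDE else 1.0
                for i in range(length):
                    z = prev_side * HELIX_RISE * ((length - 1) / 2 - i)
                    angle = np.deg2rad(phase + HELIX_TURN_DEG * (seg.start + i))
                    residues[seg.start + i] = (
                        HELIX_RADIUS * np.cos(angle),
                        HELIX_RADIUS * np.sin(angle),
                        z,
                    )
            else:
                side = 1.0 if seg.region is Region.INSIDE else -1.0
                for i in range(length):
                    if si == 0:  # N-terminal: approaches the membrane
                        dist = (length - 1) - i
                    elif si == len(segments) - 1:  # C-terminal: leaves it
                        dist = i
                    else:  # loop: out and back
                        dist = min(i, length - 1 - i)
                    z = side * min(
                        HALF_BILAYER + LOOP_Z_STEP * (dist + 1), LOOP_Z_CAP
                    )
                    angle = np.deg2rad(phase + HELIX_TURN_DEG * (seg.start + i))
                    residues[seg.start + i] = (
                        (HELIX_RADIUS + 2.0) * np.cos(angle),
                        (HELIX_RADIUS + 2.0) * np.sin(angle),
                        z,
                    )
        coords[protein.protein_id] = residues
    return StructureSet(coords=coords)


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_synthetic_inputs(
    proteome: Sequence[ProteinRecord],
    variants: Iterable[VariantRecord],
    outdir: str | Path,
    structures: StructureSet | None = None,
    topology_dialect: str = "htp_xml",
) -> dict[str, str]:
    """Emit the generated cohort in the formats the pipeline reads.

    Writes the variant table (tsv dialect), the topology annotation
    (htp_xml or tsv), the FASTA sequences and, if structures are given,
    one CA-only PDB per TMP plus the membrane-frame matrix (identity).
    Returns a manifest mapping artifact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    variants_path = outdir / "variants.tsv"
    io_formats.write_variants_tsv(variants, variants_path)
    manifest["variants"] = str(variants_path)

    if topology_dialect == "htp_xml":
        topo_path = outdir / "topology.xml"
        io_formats.write_topology_xml(proteome, topo_path)
    elif topology_dialect == "tsv":
        topo_path = outdir / "topology.tsv"
        io_formats.write_topology_tsv(proteome, topo_path)
    else:
        raise ValueError(f"unknown topology dialect {topology_dialect!r}")
    manifest["topology"] = str(topo_path)

    fasta_path = outdir / "sequences.fasta"
    io_formats.write_fasta(
        {p.protein_id: p.sequence for p in proteome}, fasta_path
    )
    manifest["fasta"] = str(fasta_path)

    if structures is not None:
        struct_dir = outdir / "structures"
        struct_dir.mkdir(exist_ok=True)
        for pid, residues in structures.coords.items():
            io_formats.write_ca_pdb(residues, struct_dir / f"{pid}.pdb")
        frame_path = outdir / "membrane_frame.json"
        frame_path.write_text(
            __import__("json").dumps(
                {
                    "rotation": structures.rotation.tolist(),
                    "translation": structures.translation.tolist(),
                },
                indent=1,
            )
        )
        manifest["structures"] = str(struct_dir)
        manifest["frame"] = str(frame_path)
    return manifest
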