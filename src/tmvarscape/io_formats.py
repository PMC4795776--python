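"""Readers and writers for every external format the pipeline touches.

Supported formats: variant tables (UniProt ``humsavar``-style flat file and a
plain TSV dialect), topology annotations (a documented XML dialect and TSV),
FASTA sequences, BED export/import (0-based half-open), minimal PDB (CA atoms)
with a membrane-frame transformation, and TSV/JSON result matrices.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1
from lxml import etree

from .records import (
    AA_ORDER,
    ProteinRecord,
    RecordError,
    Region,
    Subregion,
    TopologySegment,
    VariantClass,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_SUBSTITUTION_RE = re.compile(r"^p\.([A-Za-z]{3})(\d+)([A-Za-z]{3})$")


class FormatError(ValueError):
    """Fatal, file-level parsing failure."""


@dataclass
class ParseReport:
    """Outcome of parsing one input file: accepted vs. skipped lines."""

    n_records: int = 0
    n_skipped: int = 0
    skips: list[tuple[int, str]] = field(default_factory=list)

    def skip(self, lineno: int, reason: str) -> None:
        self.n_skipped += 1
        self.skips.append((lineno, reason))
        logger.debug("line %d skipped: %s", lineno, reason)


def parse_substitution(text: str) -> tuple[str, int, str]:
    """Decode a ``p.Gly380Arg``-style substitution to ``("G", 380, "R")``.

    Raises :class:`FormatError` for malformed strings or non-standard
    residues (e.g. ``Sec``, ``Ter``).
    """
    m = _SUBSTITUTION_RE.match(text.strip())
    if m is None:
        raise FormatError(f"unparseable substitution {text!r}")
    three_ref, pos, three_alt = m.groups()
    try:
        ref = protein_letters_3to1[three_ref.capitalize()]
        alt = protein_letters_3to1[three_alt.capitalize()]
    except KeyError as exc:
        raise FormatError(f"non-standard residue in {text!r}") from exc
    if ref not in AA_ORDER or alt not in AA_ORDER:
        raise FormatError(f"non-standard residue in {text!r}")
    return ref, int(pos), alt


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def read_variants(
    path: str | Path, dialect: str = "tsv"
) -> tuple[list[VariantRecord], ParseReport]:
    """Read a missense-variant table.

    ``humsavar`` dialect: the UniProt flat file; the data section starts
    after the underscore ruler line and ends at the first blank line.
    Columns (whitespace-separated): gene, accession, variant FTId,
    ``p.RefPosAlt`` change, classification, dbSNP id, disease name.

    ``tsv`` dialect: one header line naming the columns ``protein_id``,
    ``variant_id``, ``substitution``, ``classification``, ``disease``;
    multiple disease names are ``|``-separated.

    Individual malformed lines are skipped and counted in the report;
    a missing file or (for tsv) a malformed header is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"variant file not found: {path}")
    if dialect == "humsavar":
        return _read_humsavar(path)
    if dialect == "tsv":
        return _read_variants_tsv(path)
    raise FormatError(f"unknown variant dialect {dialect!r}")


_CLASS_BY_TOKEN = {c.value: c for c in VariantClass}


def _variant_from_fields(
    protein_id: str,
    variant_id: str,
    change: str,
    classification: str,
    disease: str,
) -> VariantRecord:
    ref, pos, alt = parse_substitution(change)
    try:
        cls = _CLASS_BY_TOKEN[classification]
    except KeyError as exc:
        raise FormatError(f"unknown classification {classification!r}") from exc
    if ref == alt:
        raise FormatError(f"synonymous change {change!r}")
    names = tuple(
        n.strip() for n in disease.split("|") if n.strip() and n.strip() != "-"
    )
    return VariantRecord(
        protein_id=protein_id,
        position=pos,
        ref_aa=ref,
        alt_aa=alt,
        classification=cls,
        disease_names=names,
        variant_id=variant_id,
    )


def _read_humsavar(path: Path) -> tuple[list[VariantRecord], ParseReport]:
    report = ParseReport()
    records: list[VariantRecord] = []
    in_data = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not in_data:
            # ruler of underscores separates the banner from the data
            if line and set(line.strip()) <= {"_", " "} and "_" in line:
                in_data = True
            continue
        if not line.strip():
            break  # blank line starts the footer
        fields = line.split(maxsplit=6)
        if len(fields) < 5:
            report.skip(lineno, f"too few columns: {line[:40]!r}")
            continue
        gene, acc, ftid, change, category = fields[:5]
        disease = fields[6].strip() if len(fields) == 7 else ""
        try:
            records.append(
                _variant_from_fields(acc, ftid, change, category, disease)
            )
        except (FormatError, RecordError) as exc:
            report.skip(lineno, str(exc))
            continue
        report.n_records += 1
    return records, report


_TSV_VARIANT_COLUMNS = [
    "protein_id",
    "variant_id",
    "substitution",
    "classification",
    "disease",
]


def _read_variants_tsv(path: Path) -> tuple[list[VariantRecord], ParseReport]:
    report = ParseReport()
    records: list[VariantRecord] = []
    lines = path.read_text().splitlines()
    if not lines:
        return records, report
    header = lines[0].rstrip("\n").split("\t")
    if header != _TSV_VARIANT_COLUMNS:
        raise FormatError(
            f"bad variant TSV header {header!r}; expected {_TSV_VARIANT_COLUMNS}"
        )
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            report.skip(lineno, f"expected 5 columns, got {len(fields)}")
            continue
        try:
            records.append(_variant_from_fields(*fields))
        except (FormatError, RecordError) as exc:
            report.skip(lineno, str(exc))
            continue
        report.n_records += 1
    return records, report


def write_variants_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Serialize variants in the tsv dialect (inverse of ``read_variants``)."""
    lines = ["\t".join(_TSV_VARIANT_COLUMNS)]
    one_to_three = {v: k for k, v in protein_letters_3to1.items()}
    for v in records:
        sub = f"p.{one_to_three[v.ref_aa]}{v.position}{one_to_three[v.alt_aa]}"
        lines.append(
            "\t".join(
                [
                    v.protein_id,
                    v.variant_id,
                    sub,
                    v.classification.value,
                    "|".join(v.disease_names),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def read_topology(
    path: str | Path,
    dialect: str = "tsv",
    sequences: Mapping[str, str] | None = None,
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """Read per-protein topology annotations.

    ``tsv`` dialect: columns ``protein_id``, ``region`` (I/M/O), ``start``,
    ``end``; segments of one protein on consecutive rows in order.
    ``htp_xml`` dialect: ``<proteins><protein id=..><sequence>..</sequence>
    <region type="I" from="1" to="10"/>..</protein></proteins>``.

    ``sequences`` (e.g. from :func:`read_fasta`) attaches sequences to
    proteins that carry none in the file. Returns accepted records and a
    list of ``(protein_id, reason)`` rejections for proteins whose segments
    do not tile the sequence.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"topology file not found: {path}")
    if dialect == "tsv":
        raw = _read_topology_tsv(path)
    elif dialect == "htp_xml":
        raw = _read_topology_xml(path)
    else:
        raise FormatError(f"unknown topology dialect {dialect!r}")

    accepted: list[ProteinRecord] = []
    rejected: list[tuple[str, str]] = []
    for record, parse_error in raw:
        if parse_error is not None:
            rejected.append((record.protein_id, parse_error))
            logger.warning("rejected %s: %s", record.protein_id, parse_error)
            continue
        if not record.sequence and sequences and record.protein_id in sequences:
            record.sequence = sequences[record.protein_id].upper()
        try:
            record.validate()
        except RecordError as exc:
            rejected.append((record.protein_id, str(exc)))
            logger.warning("rejected %s: %s", record.protein_id, exc)
            continue
        accepted.append(record)
    return accepted, rejected


_REGION_BY_LETTER = {r.value: r for r in Region}


def _read_topology_tsv(
    path: Path,
) -> list[tuple[ProteinRecord, str | None]]:
    header_expected = ["protein_id", "region", "start", "end"]
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != header_expected:
        raise FormatError(f"bad topology TSV header; expected {header_expected}")
    by_protein: dict[str, ProteinRecord] = {}
    errors: dict[str, str] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        pid, letter, start, end = line.split("\t")
        record = by_protein.setdefault(pid, ProteinRecord(pid, "", []))
        if letter not in _REGION_BY_LETTER:
            errors.setdefault(pid, f"unknown region letter {letter!r}")
            continue
        try:
            record.segments.append(
                TopologySegment(_REGION_BY_LETTER[letter], int(start), int(end))
            )
        except RecordError as exc:
            errors.setdefault(pid, str(exc))
    return [(rec, errors.get(pid)) for pid, rec in by_protein.items()]


def _read_topology_xml(
    path: Path,
) -> list[tuple[ProteinRecord, str | None]]:
    tree = etree.parse(str(path))
    out: list[tuple[ProteinRecord, str | None]] = []
    for node in tree.getroot().iterfind("protein"):
        pid = node.get("id")
        if pid is None:
            raise FormatError("protein element without id attribute")
        seq_node = node.find("sequence")
        sequence = (seq_node.text or "").strip().upper() if seq_node is not None else ""
        segments = []
        error = None
        for reg in node.iterfind("region"):
            letter = reg.get("type")
            if letter not in _REGION_BY_LETTER:
                error = f"unknown region letter {letter!r}"
                break
            try:
                segments.append(
                    TopologySegment(
                        _REGION_BY_LETTER[letter],
                        int(reg.get("from")),
                        int(reg.get("to")),
                    )
                )
            except RecordError as exc:
                error = str(exc)
                break
        out.append((ProteinRecord(pid, sequence, segments), error))
    return out


def write_topology_tsv(proteome: Iterable[ProteinRecord], path: str | Path) -> None:
    lines = ["protein_id\tregion\tstart\tend"]
    for protein in proteome:
        for seg in protein.segments:
            lines.append(
                f"{protein.protein_id}\t{seg.region.value}\t{seg.start}\t{seg.end}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_topology_xml(proteome: Iterable[ProteinRecord], path: str | Path) -> None:
    root = etree.Element("proteins")
    for protein in proteome:
        node = etree.SubElement(root, "protein", id=protein.protein_id)
        if protein.sequence:
            etree.SubElement(node, "sequence").text = protein.sequence
        for seg in protein.segments:
            etree.SubElement(
                node,
                "region",
                type=seg.region.value,
                **{"from": str(seg.start), "to": str(seg.end)},
            )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences into ``{accession: uppercase sequence}``.

    UniProt-style ``sp|P22607|FGFR3_HUMAN`` ids are normalized to the bare
    accession. Duplicate ids are fatal.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id.split("|")[1] if "|" in rec.id else rec.id
        if pid in sequences:
            raise FormatError(f"duplicate FASTA id {pid!r}")
        sequences[pid] = str(rec.seq).upper()
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def to_bed(records: Sequence[ProteinRecord] | Sequence[VariantRecord]) -> list[str]:
    """Convert records to BED lines (0-based half-open, chrom = protein id).

    Residue ``i`` (1-based) maps to the interval ``[i-1, i)``; a segment
    ``[s, e]`` (1-based inclusive) maps to ``[s-1, e)``. The name column
    carries enough payload for the conversion to be invertible.
    """
    lines: list[str] = []
    for rec in records:
        if isinstance(rec, ProteinRecord):
            for seg in rec.segments:
                name = seg.region.value
                if seg.subregion is not None:
                    name += f"|{seg.subregion.value}"
                lines.append(
                    f"{rec.protein_id}\t{seg.start - 1}\t{seg.end}\t{name}"
                )
        elif isinstance(rec, VariantRecord):
            name = "|".join(
                [
                    f"{rec.ref_aa}>{rec.alt_aa}",
                    rec.classification.value,
                    rec.variant_id,
                    ";".join(rec.disease_names),
                ]
            )
            lines.append(
                f"{rec.protein_id}\t{rec.position - 1}\t{rec.position}\t{name}"
            )
        else:
            raise TypeError(f"cannot BED-convert {type(rec).__name__}")
    return lines


def topology_from_bed(lines: Iterable[str]) -> list[ProteinRecord]:
    """Inverse of :func:`to_bed` for topology segments (sequences are not
    carried by BED and come back empty)."""
    by_protein: dict[str, ProteinRecord] = {}
    for line in lines:
        pid, start, end, name = line.rstrip("\n").split("\t")
        parts = name.split("|")
        region = _REGION_BY_LETTER[parts[0]]
        subregion = Subregion[parts[1]] if len(parts) > 1 else None
        rec = by_protein.setdefault(pid, ProteinRecord(pid, "", []))
        rec.segments.append(
            TopologySegment(region, int(start) + 1, int(end), subregion)
        )
    return list(by_protein.values())


def variants_from_bed(lines: Iterable[str]) -> list[VariantRecord]:
    """Inverse of :func:`to_bed` for variant records."""
    out = []
    for line in lines:
        pid, start, end, name = line.rstrip("\n").split("\t")
        change, classification, variant_id, diseases = name.split("|")
        ref, alt = change.split(">")
        out.append(
            VariantRecord(
                protein_id=pid,
                position=int(start) + 1,
                ref_aa=ref,
                alt_aa=alt,
                classification=_CLASS_BY_TOKEN[classification],
                disease_names=tuple(d for d in diseases.split(";") if d),
                variant_id=variant_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_structure_frame(
    pdb_path: str | Path,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    protein_id: str | None = None,
) -> dict[tuple[str, int], float]:
    """Map ``(protein_id, residue position)`` to membrane-frame z (Å).

    ``rotation`` (3x3) and ``translation`` (3,) define the membrane frame
    transformation ``z = (R·x + t)[2]`` applied to each CA coordinate, as
    provided by PDBTM-style metadata; identity/zero by default. Residues
    without a CA atom are absent from the map. For altloc'd CAs the first
    encountered atom is kept.
    """
    import gemmi

    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
    if R.shape != (3, 3) or t.shape != (3,):
        raise FormatError("rotation must be 3x3 and translation length 3")

    structure = gemmi.read_structure(str(pdb_path))
    pid = protein_id or structure.name or Path(pdb_path).stem
    zmap: dict[tuple[str, int], float] = {}
    for model in structure:
        for chain in model:
            for residue in chain:
                ca = residue.find_atom("CA", "*")
                if ca is None:
                    continue
                key = (pid, residue.seqid.num)
                if key in zmap:
                    continue
                x = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
                zmap[key] = float((R @ x + t)[2])
        break  # first model only
    if not zmap:
        raise FormatError(f"no CA atoms in {pdb_path}")
    return zmap


def write_ca_pdb(
    coords: Mapping[int, tuple[float, float, float]], path: str | Path
) -> None:
    """Write a minimal CA-only PDB (one chain A, GLY placeholder residues)."""
    lines = []
    for serial, (pos, (x, y, z)) in enumerate(sorted(coords.items()), start=1):
        lines.append(
            f"ATOM  {serial:5d}  CA  GLY A{pos:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix(
    matrix: np.ndarray,
    path: str | Path,
    fmt: str = "tsv",
    labels: Sequence[str] = tuple(AA_ORDER),
) -> None:
    """Write a square labelled matrix as TSV or JSON.

    Rows and columns follow the fixed amino-acid order
    ``A R N D C Q E G H I L K M F P S T W Y V``. Float matrices (percent
    scale) are written with 2 decimals, integer matrices as integers.
    """
    matrix = np.asarray(matrix)
    if matrix.shape != (len(labels), len(labels)):
        raise FormatError(
            f"matrix shape {matrix.shape} does not match {len(labels)} labels"
        )
    is_int = np.issubdtype(matrix.dtype, np.integer)

    def cell(v: float) -> str:
        return str(int(v)) if is_int else f"{v:.2f}"

    if fmt == "tsv":
        lines = ["\t".join(["%"] + list(labels))]
        for lab, row in zip(labels, matrix):
            lines.append("\t".join([lab] + [cell(v) for v in row]))
        Path(path).write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        payload = {
            "labels": list(labels),
            "data": [[int(v) if is_int else round(float(v), 2) for v in row]
                     for row in matrix],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise FormatError(f"unknown matrix format {fmt!r}")


def read_matrix(path: str | Path, fmt: str = "tsv") -> np.ndarray:
    """Read back a matrix written by :func:`write_matrix`."""
    path = Path(path)
    if fmt == "tsv":
        lines = path.read_text().splitlines()
        rows = [line.split("\t")[1:] for line in lines[1:]]
        flat = [v for row in rows for v in row]
        if all(re.fullmatch(r"-?\d+", v) for v in flat):
            return np.array(rows, dtype=int)
        return np.array(rows, dtype=float)
    if fmt == "json":
        payload = json.loads(path.read_text())
        return np.array(payload["data"])
    raise FormatError(f"unknown matrix format {fmt!r}")
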