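"""End-to-end orchestration: load inputs, run every analysis stage, write
tables and the machine-readable run report.

The pipeline composes the other modules: variants are intersected with
topology, substitution and polarity spectra are computed per stratum with
bootstrap dispersions and positional-permutation significance, TM
center-distance profiles and (when structures are available) membrane-depth
slice profiles are produced. A single master seed governs every random
stage; stage streams are derived from it deterministically.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, io_formats
from .positional_analysis import (
    CenterDistanceRecord,
    DistanceSource,
    center_distance,
    center_distance_histogram,
    natural_residue_positions,
)
from .records import (
    AA_ORDER,
    ProteinRecord,
    Region,
    Subregion,
    VariantClass,
    VariantRecord,
)
from .structure_mapping import SliceProfile, slice_profile
from .substitution_stats import (
    POLARITY_ORDER,
    BootstrapResult,
    PermutationResult,
    SubstitutionMatrix,
    bootstrap_sd,
    count_substitutions,
    permutation_null,
    polarity_matrix,
    predictive_values,
    region_frequency,
    to_percent,
)
from .topology_mapping import (
    DropLog,
    RegionAssignment,
    assign_regions,
    region_lengths,
    tm_count_distribution,
)

logger = logging.getLogger(__name__)

_CLASS_LABELS = (VariantClass.DISEASE.value, VariantClass.POLYMORPHISM.value)


@dataclass
class Options:
    """Tunable knobs of one pipeline run (defaults follow the method)."""

    seed: int = 0
    bootstrap_reps: int = 10
    bootstrap_fraction: float = 0.9
    perm_reps: int = 100
    pv_threshold: int = 100
    bin_width: float = 0.05
    slice_width: float = 1.0


@dataclass
class PipelineConfig:
    variants: str
    topology: str
    fasta: str = ""
    variants_dialect: str = "tsv"
    topology_dialect: str = "htp_xml"
    structures_dir: str = ""
    frame: str = ""
    output_dir: str = "results/run"
    options: Options = field(default_factory=Options)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        inputs = raw.get("inputs", {})
        out = raw.get("output", {})
        opts = Options(**raw.get("options", {}))
        return cls(
            variants=inputs.get("variants", ""),
            topology=inputs.get("topology", ""),
            fasta=inputs.get("fasta", ""),
            variants_dialect=inputs.get("variants_dialect", "tsv"),
            topology_dialect=inputs.get("topology_dialect", "htp_xml"),
            structures_dir=inputs.get("structures_dir", ""),
            frame=inputs.get("frame", ""),
            output_dir=out.get("dir", "results/run"),
            options=opts,
        )

    def to_toml_text(self) -> str:
        o = self.options
        return "\n".join(
            [
                "[inputs]",
                f'variants = "{self.variants}"',
                f'variants_dialect = "{self.variants_dialect}"',
                f'topology = "{self.topology}"',
                f'topology_dialect = "{self.topology_dialect}"',
                f'fasta = "{self.fasta}"',
                f'structures_dir = "{self.structures_dir}"',
                f'frame = "{self.frame}"',
                "",
                "[options]",
                f"seed = {o.seed}",
                f"bootstrap_reps = {o.bootstrap_reps}",
                f"bootstrap_fraction = {o.bootstrap_fraction}",
                f"perm_reps = {o.perm_reps}",
                f"pv_threshold = {o.pv_threshold}",
                f"bin_width = {o.bin_width}",
                f"slice_width = {o.slice_width}",
                "",
                "[output]",
                f'dir = "{self.output_dir}"',
                "",
            ]
        )


@dataclass
class RunReport:
    """Accounting of one run: conserved input counts, rates, manifest."""

    seed: int
    version: str = __version__
    variants_read: int = 0
    parse_skipped: int = 0
    proteins_accepted: int = 0
    proteins_rejected: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    mapped_tmp: dict[str, int] = field(default_factory=dict)
    mapped_non_tmp: dict[str, int] = field(default_factory=dict)
    proteins_with_class_tmp: dict[str, int] = field(default_factory=dict)
    proteins_with_class_non_tmp: dict[str, int] = field(default_factory=dict)
    rates_tmp: dict[str, float] = field(default_factory=dict)
    rates_non_tmp: dict[str, float] = field(default_factory=dict)
    structures_skipped: bool = False
    unmapped_variants: int = 0
    manifest: dict[str, str] = field(default_factory=dict)

    def is_conserved(self) -> bool:
        mapped = sum(self.mapped_tmp.values()) + sum(self.mapped_non_tmp.values())
        return self.variants_read == mapped + sum(self.dropped.values())

    def to_json(self) -> str:
        from dataclasses import asdict

        return json.dumps(asdict(self), indent=1)


@dataclass
class AnalysisResult:
    """Everything one run computes, before serialization."""

    assignments: list[RegionAssignment]
    drop_log: DropLog
    report: RunReport
    region_matrices: dict[tuple[str, str], SubstitutionMatrix]
    subregion_matrices: dict[tuple[str, str], SubstitutionMatrix]
    region_freq: dict[tuple[str, str], float]
    subregion_freq: dict[tuple[str, str], float]
    tm_count_dist: dict[str, dict[int, float]]
    polarity_bootstrap: dict[str, BootstrapResult]
    spectrum_bootstrap: dict[str, BootstrapResult]
    permutation: dict[tuple[str, str], PermutationResult]
    predictive: pd.DataFrame
    center_hist: pd.DataFrame
    natural_r_tm_counts: dict[int, int]
    gly_arg_tm_counts: dict[int, int]
    profile: SliceProfile | None


def _per_residue_rates(
    proteome: Sequence[ProteinRecord],
    assignments: Sequence[RegionAssignment],
    tmp: bool,
) -> tuple[dict[str, int], dict[str, int], dict[str, float]]:
    """Counts, distinct-protein counts and per-residue rates per class.

    The rate denominator is the total residue count of the proteins of the
    set that carry at least one mapped variant of that class.
    """
    lengths = {p.protein_id: p.length for p in proteome if p.is_tmp == tmp}
    counts: dict[str, int] = {}
    carriers: dict[str, set[str]] = {}
    for a in assignments:
        if a.variant.protein_id not in lengths:
            continue
        cls = a.variant.classification.value
        counts[cls] = counts.get(cls, 0) + 1
        carriers.setdefault(cls, set()).add(a.variant.protein_id)
    n_proteins = {cls: len(pids) for cls, pids in carriers.items()}
    rates = {}
    for cls, pids in carriers.items():
        denom = sum(lengths[p] for p in pids)
        if denom:
            rates[cls] = counts[cls] / denom
    return counts, n_proteins, rates


def _tm_statistic(cls: VariantClass, kind: str):
    """Matrix statistic over a subsample: percent spectrum of TM assignments
    of one class (20x20) or its polarity collapse (3x3)."""

    def stat(sample: Sequence[RegionAssignment]) -> np.ndarray:
        tm = [
            a
            for a in sample
            if a.subregion is Subregion.TM and a.variant.classification is cls
        ]
        matrices = count_substitutions(tm, stratify_by="subregion")
        key = (Subregion.TM.value, cls.value)
        if key not in matrices:
            return np.zeros((20, 20) if kind == "spectrum" else (3, 3))
        matrix = matrices[key]
        if kind == "spectrum":
            return to_percent(matrix)
        pol = polarity_matrix(matrix)
        return 100.0 * pol.counts / pol.total

    return stat


def run_analysis(
    proteome: Sequence[ProteinRecord],
    variants: Sequence[VariantRecord],
    options: Options | None = None,
    z_map: Mapping[tuple[str, int], float] | None = None,
) -> AnalysisResult:
    """Run every analysis stage on in-memory inputs."""
    options = options or Options()
    assignments, drop_log = assign_regions(variants, proteome)
    tmps = [p for p in proteome if p.is_tmp]
    non_tmps = [p for p in proteome if not p.is_tmp]
    tmp_ids = {p.protein_id for p in tmps}
    tmp_assignments = [a for a in assignments if a.in_tmp]

    report = RunReport(seed=options.seed)
    report.variants_read = drop_log.n_input
    report.dropped = {
        "unclassified": drop_log.unclassified,
        "ambiguous": drop_log.ambiguous,
        "mismatch": drop_log.mismatch,
        "unknown_protein": drop_log.unknown_protein,
        "out_of_range": drop_log.out_of_range,
    }
    counts_tmp, nprot_tmp, rates_tmp = _per_residue_rates(
        proteome, assignments, tmp=True
    )
    counts_non, nprot_non, rates_non = _per_residue_rates(
        proteome, assignments, tmp=False
    )
    report.mapped_tmp = counts_tmp
    report.mapped_non_tmp = counts_non
    report.proteins_with_class_tmp = nprot_tmp
    report.proteins_with_class_non_tmp = nprot_non
    report.rates_tmp = rates_tmp
    report.rates_non_tmp = rates_non

    region_matrices = count_substitutions(tmp_assignments, "region")
    subregion_matrices = count_substitutions(tmp_assignments, "subregion")
    region_freq = region_frequency(
        tmp_assignments, region_lengths(tmps, "region"), "region"
    )
    subregion_freq = region_frequency(
        tmp_assignments, region_lengths(tmps, "subregion"), "subregion"
    )

    def carriers(cls: VariantClass) -> list[ProteinRecord]:
        ids = {
            a.variant.protein_id
            for a in assignments
            if a.variant.classification is cls and a.variant.protein_id in tmp_ids
        }
        return [p for p in tmps if p.protein_id in ids]

    tm_count_dist = tm_count_distribution(
        {
            "all_tmps": tmps,
            "with_disease": carriers(VariantClass.DISEASE),
            "with_polymorphism": carriers(VariantClass.POLYMORPHISM),
        }
    )

    polarity_bootstrap = {}
    spectrum_bootstrap = {}
    for cls in (VariantClass.DISEASE, VariantClass.POLYMORPHISM):
        n_cls = sum(
            1 for a in tmp_assignments if a.variant.classification is cls
        )
        if n_cls < 10:
            continue
        polarity_bootstrap[cls.value] = bootstrap_sd(
            tmp_assignments,
            _tm_statistic(cls, "polarity"),
            fraction=options.bootstrap_fraction,
            n_reps=options.bootstrap_reps,
            seed=options.seed,
        )
        spectrum_bootstrap[cls.value] = bootstrap_sd(
            tmp_assignments,
            _tm_statistic(cls, "spectrum"),
            fraction=options.bootstrap_fraction,
            n_reps=options.bootstrap_reps,
            seed=options.seed + 1,
        )

    permutation = permutation_null(
        tmp_assignments,
        tmps,
        n_reps=options.perm_reps,
        seed=options.seed + 2,
    )

    tm_key_d = (Region.MEMBRANE.value, VariantClass.DISEASE.value)
    tm_key_p = (Region.MEMBRANE.value, VariantClass.POLYMORPHISM.value)
    empty = SubstitutionMatrix(
        ("M", "empty"), np.zeros((20, 20), dtype=np.int64)
    )
    predictive = predictive_values(
        region_matrices.get(tm_key_d, empty),
        region_matrices.get(tm_key_p, empty),
        threshold=options.pv_threshold,
    )

    by_id = {p.protein_id: p for p in proteome}
    distance_records: list[CenterDistanceRecord] = []
    gly_arg_carriers: dict[str, None] = {}
    for a in tmp_assignments:
        if a.subregion is not Subregion.TM:
            continue
        protein = by_id[a.variant.protein_id]
        segment = protein.segments[a.segment_index]
        d = center_distance(a.variant.position, segment)
        if a.variant.classification is VariantClass.POLYMORPHISM:
            distance_records.append(
                CenterDistanceRecord(
                    DistanceSource.POLYMORPHISM_VARIANT,
                    f"{a.variant.ref_aa}>{a.variant.alt_aa}",
                    d,
                )
            )
        elif (
            a.variant.classification is VariantClass.DISEASE
            and a.variant.ref_aa == "G"
            and a.variant.alt_aa == "R"
        ):
            distance_records.append(
                CenterDistanceRecord(DistanceSource.DISEASE_VARIANT, "G>R", d)
            )
            gly_arg_carriers.setdefault(a.variant.protein_id)
    natural_records, natural_r_tm_counts = natural_residue_positions(tmps, "R")
    distance_records.extend(natural_records)
    center_hist = center_distance_histogram(
        distance_records, bin_width=options.bin_width, absolute=True
    )
    gly_arg_tm_counts: dict[int, int] = {}
    for pid in gly_arg_carriers:
        k = by_id[pid].tm_count
        gly_arg_tm_counts[k] = gly_arg_tm_counts.get(k, 0) + 1

    profile = None
    if z_map is not None:
        profile = slice_profile(z_map, assignments, options.slice_width)
        report.unmapped_variants = profile.unmapped
    else:
        report.structures_skipped = True

    return AnalysisResult(
        assignments=assignments,
        drop_log=drop_log,
        report=report,
        region_matrices=region_matrices,
        subregion_matrices=subregion_matrices,
        region_freq=region_freq,
        subregion_freq=subregion_freq,
        tm_count_dist=tm_count_dist,
        polarity_bootstrap=polarity_bootstrap,
        spectrum_bootstrap=spectrum_bootstrap,
        permutation=permutation,
        predictive=predictive,
        center_hist=center_hist,
        natural_r_tm_counts=natural_r_tm_counts,
        gly_arg_tm_counts=gly_arg_tm_counts,
        profile=profile,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _write_matrix_block(
    result: PermutationResult, path: Path
) -> None:
    """OBS / AVG / STD / Z blocks, one after another, per stratum file."""
    blocks = [
        ("OBS", result.obs.astype(int)),
        ("AVG", result.avg),
        ("STD", result.std),
        ("(OBS-AVG)/STD", result.z),
    ]
    lines = []
    for title, matrix in blocks:
        lines.append(title)
        lines.append("\t".join(["%"] + list(AA_ORDER)))
        for lab, row in zip(AA_ORDER, matrix):
            cells = [
                str(int(v))
                if np.issubdtype(matrix.dtype, np.integer)
                else ("NA" if np.isnan(v) else f"{v:.2f}")
                for v in row
            ]
            lines.append("\t".join([lab] + cells))
        lines.append("")
    path.write_text("\n".join(lines))


def write_outputs(result: AnalysisResult, outdir: str | Path) -> dict[str, str]:
    """Write every table of one analysis; returns the output manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def register(name: str, path: Path) -> Path:
        manifest[name] = str(path)
        return path

    for (label, cls), matrix in sorted(result.region_matrices.items()):
        p = register(
            f"counts_region_{label}_{cls}",
            outdir / f"counts_region_{label}_{cls}.tsv",
        )
        io_formats.write_matrix(matrix.counts, p)
        if matrix.total:
            p = register(
                f"percent_region_{label}_{cls}",
                outdir / f"percent_region_{label}_{cls}.tsv",
            )
            io_formats.write_matrix(to_percent(matrix), p)
    for (label, cls), matrix in sorted(result.subregion_matrices.items()):
        p = register(
            f"counts_subregion_{label}_{cls}",
            outdir / f"counts_subregion_{label}_{cls}.tsv",
        )
        io_formats.write_matrix(matrix.counts, p)

    for cls, boot in result.polarity_bootstrap.items():
        p = register(f"polarity_TM_{cls}", outdir / f"polarity_TM_{cls}.tsv")
        lines = ["\t".join(["%"] + list(POLARITY_ORDER))]
        for i, row_label in enumerate(POLARITY_ORDER):
            cells = [
                f"{boot.mean[i, j]:.2f}±{boot.sd[i, j]:.2f}"
                for j in range(3)
            ]
            lines.append("\t".join([row_label] + cells))
        p.write_text("\n".join(lines) + "\n")

    freq_rows = [
        {"stratum": label, "class": cls, "per_residue": f}
        for (label, cls), f in sorted(
            list(result.region_freq.items()) + list(result.subregion_freq.items())
        )
    ]
    p = register("region_frequency", outdir / "region_frequency.tsv")
    pd.DataFrame(freq_rows).to_csv(p, sep="\t", index=False)

    rows = []
    for set_name, dist in result.tm_count_dist.items():
        for k, frac in sorted(dist.items()):
            rows.append({"set": set_name, "tm_count": k, "fraction": frac})
    p = register("tm_count_distribution", outdir / "tm_count_distribution.tsv")
    pd.DataFrame(rows, columns=["set", "tm_count", "fraction"]).to_csv(
        p, sep="\t", index=False
    )

    for (label, cls), perm in sorted(result.permutation.items()):
        p = register(
            f"permutation_{label}_{cls}", outdir / f"permutation_{label}_{cls}.tsv"
        )
        _write_matrix_block(perm, p)

    p = register("predictive_values", outdir / "predictive_values.tsv")
    result.predictive.to_csv(p, sep="\t", index=False, float_format="%.4f")

    p = register("center_distance_histogram", outdir / "center_distance_histogram.tsv")
    result.center_hist.to_csv(p, sep="\t", index=False, float_format="%.6f")

    rows = [
        {"tm_count": k, "set": "natural_arginine", "proteins": v}
        for k, v in sorted(result.natural_r_tm_counts.items())
    ] + [
        {"tm_count": k, "set": "gly_arg_disease", "proteins": v}
        for k, v in sorted(result.gly_arg_tm_counts.items())
    ]
    p = register("residue_tm_count_distribution", outdir / "residue_tm_count_distribution.tsv")
    pd.DataFrame(rows, columns=["tm_count", "set", "proteins"]).to_csv(
        p, sep="\t", index=False
    )

    if result.profile is not None:
        p = register("zprofile", outdir / "zprofile.tsv")
        result.profile.to_frame().to_csv(
            p, sep="\t", index=False, float_format="%.4f"
        )
    return manifest


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Load the configured inputs, run the analysis, write all artifacts."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("[load] reading inputs")
    sequences = io_formats.read_fasta(config.fasta) if config.fasta else None
    proteome, rejected = io_formats.read_topology(
        config.topology, config.topology_dialect, sequences=sequences
    )
    variants, parse_report = io_formats.read_variants(
        config.variants, config.variants_dialect
    )
    z_map = None
    if config.structures_dir:
        rotation, translation = np.eye(3), np.zeros(3)
        if config.frame:
            frame = json.loads(Path(config.frame).read_text())
            rotation = np.asarray(frame["rotation"])
            translation = np.asarray(frame["translation"])
        z_map = {}
        for pdb in sorted(Path(config.structures_dir).glob("*.pdb")):
            z_map.update(
                io_formats.read_structure_frame(
                    pdb, rotation, translation, protein_id=pdb.stem
                )
            )
    logger.info("[analyze] %d proteins, %d variants", len(proteome), len(variants))
    result = run_analysis(proteome, variants, config.options, z_map=z_map)
    result.report.parse_skipped = parse_report.n_skipped
    result.report.proteins_accepted = len(proteome)
    result.report.proteins_rejected = len(rejected)
    manifest = write_outputs(result, outdir)
    result.report.manifest = manifest

    (outdir / "run_report.json").write_text(result.report.to_json() + "\n")
    (outdir / "effective_config.toml").write_text(config.to_toml_text())
    (outdir / "summary.txt").write_text(summarize(result) + "\n")
    logger.info("[done] outputs in %s", outdir)
    return result.report


def summarize(result: AnalysisResult) -> str:
    """Human-readable digest: counts, rates, top predictive values, top z."""
    r = result.report
    lines = [
        "tmvarscape run summary",
        "======================",
        f"variants read: {r.variants_read}",
        f"dropped: {r.dropped}",
        f"mapped in TMPs: {r.mapped_tmp} "
        f"(proteins {r.proteins_with_class_tmp})",
        f"mapped in non-TMPs: {r.mapped_non_tmp} "
        f"(proteins {r.proteins_with_class_non_tmp})",
        "per-residue rates, TMPs: "
        + ", ".join(f"{c}={v:.3e}" for c, v in sorted(r.rates_tmp.items())),
        "per-residue rates, non-TMPs: "
        + ", ".join(f"{c}={v:.3e}" for c, v in sorted(r.rates_non_tmp.items())),
    ]
    if len(result.predictive):
        lines.append("top predictive values (TM):")
        for _, row in result.predictive.head(5).iterrows():
            lines.append(
                f"  {row.ref_aa}>{row.alt_aa}: PV={row.predictive_value:.3f} "
                f"(D={row.disease}, P={row.polymorphism})"
            )
    top_z: list[tuple[float, str]] = []
    for (label, cls), perm in result.permutation.items():
        z = perm.z
        flat = [
            (z[i, j], f"{label}/{cls} {AA_ORDER[i]}>{AA_ORDER[j]}")
            for i in range(20)
            for j in range(20)
            if not np.isnan(z[i, j])
        ]
        top_z.extend(flat)
    if top_z:
        lines.append("top permutation z-scores:")
        for value, label in sorted(top_z, reverse=True)[:5]:
            lines.append(f"  {label}: z={value:+.2f}")
    if result.profile is not None:
        lines.append(
            f"z-profile: {len(result.profile.slices)} slices, "
            f"{result.profile.unmapped} unmapped variants"
        )
    elif r.structures_skipped:
        lines.append("z-profile: skipped (no structures configured)")
    return "\n".join(lines)
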