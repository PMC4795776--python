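import numpy as np
import pytest

from tmvarscape import synthetic_data as sd
from tmvarscape.io_formats import write_topology_xml, write_variants_tsv
from tmvarscape.records import AA_INDEX, Region, VariantClass


def test_generator_is_deterministic_and_order_independent(tmp_path, small_cohort):
    config, proteome, variants = small_cohort
    proteome2 = sd.generate_proteome(config)
    variants2 = sd.generate_variants(list(reversed(proteome2)), config)
    a = tmp_path / "a.tsv"
    b = tmp_path / "b.tsv"
    write_variants_tsv(variants, a)
    write_variants_tsv(sorted(variants2, key=lambda v: v.variant_id), b)
    write_variants_tsv(sorted(variants, key=lambda v: v.variant_id), a)
    assert a.read_bytes() == b.read_bytes()
    xa, xb = tmp_path / "a.xml", tmp_path / "b.xml"
    write_topology_xml(proteome, xa)
    write_topology_xml(proteome2, xb)
    assert xa.read_bytes() == xb.read_bytes()


def test_different_seed_changes_output(small_cohort):
    config, proteome, _ = small_cohort
    other = sd.generate_proteome(config.with_seed(config.seed + 1))
    assert any(
        p.sequence != q.sequence for p, q in zip(proteome, other)
    )


@pytest.mark.parametrize("k", [0, 7])
def test_tm_count_weights_pin_topology(k):
    weights = np.zeros(15)
    weights[k] = 1.0
    config = sd.SyntheticConfig(n_proteins=25, seed=3, tm_count_weights=weights)
    proteome = sd.generate_proteome(config)
    assert all(p.tm_count == k for p in proteome)


def test_topologies_alternate_and_validate(small_cohort):
    _, proteome, _ = small_cohort
    for protein in proteome:
        protein.validate()
        non_m = [s.region for s in protein.segments if s.region is not Region.MEMBRANE]
        # a membrane segment always separates inside from outside
        for prev, cur in zip(non_m, non_m[1:]):
            assert prev is not cur


def test_infeasible_length_range_is_fatal():
    config = sd.SyntheticConfig(n_proteins=5)
    config.segment_length_ranges["TM"] = (25, 17)
    with pytest.raises(ValueError, match="infeasible"):
        sd.generate_proteome(config)


def test_tm_composition_hydrophobic_fraction_recovered():
    config = sd.SyntheticConfig(n_proteins=300, seed=9)
    proteome = sd.generate_proteome(config)
    hydrophobic = set("ACGILMFPWV")
    n_tm = n_hydro = 0
    for protein in proteome:
        for seg in protein.segments:
            if seg.region is Region.MEMBRANE:
                chunk = protein.sequence[seg.start - 1 : seg.end]
                n_tm += len(chunk)
                n_hydro += sum(c in hydrophobic for c in chunk)
    p = config.composition["M"][[AA_INDEX[a] for a in hydrophobic]].sum()
    sd_binom = np.sqrt(n_tm * p * (1 - p))
    assert abs(n_hydro - n_tm * p) < 3 * sd_binom


def test_zero_rate_class_emits_no_variants(small_cohort):
    config, proteome, _ = small_cohort
    rates = {k: (0.0 if k[0] == "Disease" else v) for k, v in config.variant_rates.items()}
    cfg = sd.SyntheticConfig(
        n_proteins=config.n_proteins, seed=config.seed, variant_rates=rates
    )
    variants = sd.generate_variants(proteome, cfg)
    assert all(v.classification is not VariantClass.DISEASE for v in variants)


def test_forced_gly_arg_spectrum():
    # all-Gly membrane segments + a G->R-only spectrum force the outcome
    spec = np.zeros((20, 20))
    spec[AA_INDEX["G"], AA_INDEX["R"]] = 1.0
    composition = sd._default_composition()
    gly_only = np.zeros(20)
    gly_only[AA_INDEX["G"]] = 1.0
    composition["M"] = gly_only
    config = sd.SyntheticConfig(
        n_proteins=40, seed=4, composition=composition,
        class_spectra={("Disease", "M"): spec},
        variant_rates={("Disease", "M"): 0.02},
        unclassified_rate=0.0,
    )
    proteome = sd.generate_proteome(config)
    variants = sd.generate_variants(proteome, config)
    tm_disease = [v for v in variants if v.classification is VariantClass.DISEASE]
    assert tm_disease
    assert all(v.ref_aa == "G" and v.alt_aa == "R" for v in tm_disease)


def test_all_zero_spectrum_row_is_fatal():
    spec = np.zeros((20, 20))
    spec[AA_INDEX["G"], AA_INDEX["R"]] = 1.0  # every other row zero
    config = sd.SyntheticConfig(
        n_proteins=40,
        seed=4,
        class_spectra={("Disease", "M"): spec},
        variant_rates={("Disease", "M"): 0.05},
        unclassified_rate=0.0,
    )
    proteome = sd.generate_proteome(config)
    with pytest.raises(ValueError, match="all-zero row for residue"):
        sd.generate_variants(proteome, config)


def test_multi_disease_fraction_produces_ambiguous_variants(small_cohort):
    _, _, variants = small_cohort
    disease = [v for v in variants if v.classification is VariantClass.DISEASE]
    multi = [v for v in disease if len(set(v.disease_names)) > 1]
    assert disease and multi  # the removal filter has something to remove


def test_spectrum_parameter_recovery_per_row():
    """Row-conditional mutant distributions are recovered within 3 SD."""
    config = sd.SyntheticConfig(n_proteins=500, seed=2)
    proteome = sd.generate_proteome(config)
    variants = sd.generate_variants(proteome, config)
    by_id = {p.protein_id: p for p in proteome}
    counts = np.zeros((20, 20))
    for v in variants:
        if v.classification is not VariantClass.DISEASE:
            continue
        seg = by_id[v.protein_id].segment_at(v.position)
        if seg.region is Region.MEMBRANE:
            counts[AA_INDEX[v.ref_aa], AA_INDEX[v.alt_aa]] += 1
    spec = config.class_spectra[("Disease", "M")]
    checked = violations = 0
    for i in range(20):
        n_row = counts[i].sum()
        if n_row < 5:
            continue
        row = spec[i].copy()
        row[i] = 0.0
        row /= row.sum()
        for j in range(20):
            if i == j:
                continue
            checked += 1
            sd_cell = np.sqrt(n_row * row[j] * (1 - row[j]))
            if abs(counts[i, j] - n_row * row[j]) > 3 * max(sd_cell, 1e-12):
                violations += 1
    assert checked > 100
    assert violations <= max(1, int(0.005 * checked))


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _single_tm_protein(tm_len: int):
    weights = np.zeros(15)
    weights[1] = 1.0
    config = sd.SyntheticConfig(n_proteins=1, seed=8, tm_count_weights=weights)
    config.segment_length_ranges["TM"] = (tm_len, tm_len)
    proteome = sd.generate_proteome(config)
    return config, proteome


def test_structures_tm_helix_span_and_crossing():
    config, proteome = _single_tm_protein(21)
    structures = sd.generate_structures(proteome, config)
    protein = proteome[0]
    (tm,) = [s for s in protein.segments if s.region is Region.MEMBRANE]
    zs = [
        structures.coords[protein.protein_id][p][2]
        for p in range(tm.start, tm.end + 1)
    ]
    assert max(zs) - min(zs) == pytest.approx(30.0)  # 20 * 1.5 A
    assert min(zs) < 0 < max(zs)
    # midpoint of an odd-length TM sits at the bilayer center
    mid = (tm.start + tm.end) // 2
    assert abs(structures.coords[protein.protein_id][mid][2]) < 1.5


def test_structures_alternate_crossing_direction():
    weights = np.zeros(15)
    weights[4] = 1.0
    config = sd.SyntheticConfig(n_proteins=3, seed=5, tm_count_weights=weights)
    structures = sd.generate_structures(
        sd.generate_proteome(config), config
    )
    for protein in sd.generate_proteome(config):
        tms = [s for s in protein.segments if s.region is Region.MEMBRANE]
        directions = [
            np.sign(
                structures.coords[protein.protein_id][s.end][2]
                - structures.coords[protein.protein_id][s.start][2]
            )
            for s in tms
        ]
        assert all(a == -b for a, b in zip(directions, directions[1:]))


def test_structures_non_tmp_is_empty():
    weights = np.zeros(15)
    weights[0] = 1.0
    config = sd.SyntheticConfig(n_proteins=4, seed=6, tm_count_weights=weights)
    proteome = sd.generate_proteome(config)
    structures = sd.generate_structures(proteome, config)
    assert structures.coords == {}
    assert structures.z_map == {}


def test_loop_residues_lie_beyond_the_bilayer_core():
    config = sd.SyntheticConfig(n_proteins=30, seed=7)
    proteome = sd.generate_proteome(config)
    structures = sd.generate_structures(proteome, config)
    for protein in proteome:
        if not protein.is_tmp:
            continue
        for seg in protein.segments:
            if seg.region is Region.MEMBRANE:
                continue
            side = 1.0 if seg.region is Region.INSIDE else -1.0
            for pos in range(seg.start, seg.end + 1):
                z = structures.coords[protein.protein_id][pos][2]
                assert side * z > sd.HALF_BILAYER
                assert abs(z) <= sd.LOOP_Z_CAP
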