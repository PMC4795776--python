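import numpy as np
import pytest

from tmvarscape import substitution_stats as ss
from tmvarscape import synthetic_data as sd
from tmvarscape.records import (
    AA_INDEX,
    AA_ORDER,
    Region,
    Subregion,
    TopologySegment,
    VariantClass,
    VariantRecord,
)
from tmvarscape.topology_mapping import RegionAssignment, assign_regions

from conftest import null_true_spectra


def _assignment(ref, alt, region=Region.MEMBRANE, cls=VariantClass.DISEASE):
    variant = VariantRecord("P1", 5, ref, alt, cls, ("d",))
    sub = Subregion.TM if region is Region.MEMBRANE else Subregion.LOOP
    return RegionAssignment(variant, region, sub, 0, 4)


# ---------------------------------------------------------------------------
# counting and normalization
# ---------------------------------------------------------------------------

def test_single_gly_arg_disease_variant():
    matrices = ss.count_substitutions([_assignment("G", "R")])
    matrix = matrices[("M", "Disease")]
    assert matrix.total == 1
    assert matrix.cell("G", "R") == 1
    percent = ss.to_percent(matrix)
    assert percent[AA_INDEX["G"], AA_INDEX["R"]] == 100.0


def test_empty_input_and_zero_total():
    assert ss.count_substitutions([]) == {}
    with pytest.raises(ValueError):
        ss.to_percent(np.zeros((20, 20)))


def test_counts_match_brute_force_tally(small_cohort):
    _, proteome, variants = small_cohort
    assignments, _ = assign_regions(variants, proteome)
    matrices = ss.count_substitutions(assignments, "region")
    tally: dict[tuple, int] = {}
    for a in assignments:
        key = (a.region.value, a.variant.classification.value,
               a.variant.ref_aa, a.variant.alt_aa)
        tally[key] = tally.get(key, 0) + 1
    for (label, cls), matrix in matrices.items():
        for i, ref in enumerate(AA_ORDER):
            for j, alt in enumerate(AA_ORDER):
                assert matrix.counts[i, j] == tally.get((label, cls, ref, alt), 0)


def test_percent_sums_to_100(small_cohort):
    _, proteome, variants = small_cohort
    assignments, _ = assign_regions(variants, proteome)
    for matrix in ss.count_substitutions(assignments, "region").values():
        assert ss.to_percent(matrix).sum() == pytest.approx(100.0, abs=1e-6)


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pair, expected",
    [
        (("G", "R"), ("non-polar", "charged")),
        (("V", "L"), ("non-polar", "non-polar")),
        (("S", "Y"), ("polar", "polar")),
        (("R", "D"), ("charged", "charged")),
        (("N", "H"), ("polar", "charged")),
    ],
)
def test_polarity_classes(pair, expected):
    assert ss.polarity_classes(*pair) == expected


def test_polarity_partition_is_5_10_5():
    assert len(ss.POLAR) == 5 and len(ss.NONPOLAR) == 10 and len(ss.CHARGED) == 5
    assert ss.POLAR | ss.NONPOLAR | ss.CHARGED == set(AA_ORDER)
    with pytest.raises(ValueError):
        ss.polarity_classes("X", "A")


def test_polarity_matrix_totals_and_single_cell(small_cohort):
    single = ss.count_substitutions([_assignment("G", "R")])[("M", "Disease")]
    pol = ss.polarity_matrix(single)
    assert pol.counts[1, 0] == 1 and pol.total == 1  # non-polar -> charged
    _, proteome, variants = small_cohort
    assignments, _ = assign_regions(variants, proteome)
    for matrix in ss.count_substitutions(assignments, "region").values():
        assert ss.polarity_matrix(matrix).total == matrix.total


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def test_region_frequency_forced_ratio():
    assignments = [_assignment("G", "R") for _ in range(5)]
    freq = ss.region_frequency(assignments, {"M": 1000})
    assert freq[("M", "Disease")] == pytest.approx(5e-3)
    assert ss.region_frequency([], {"M": 1000}) == {}


def test_region_frequency_recovers_configured_rates():
    config = sd.SyntheticConfig(n_proteins=500, seed=2)
    proteome = sd.generate_proteome(config)
    variants = sd.generate_variants(proteome, config)
    tmps = [p for p in proteome if p.is_tmp]
    assignments, _ = assign_regions(variants, proteome)
    tmp_assignments = [a for a in assignments if a.in_tmp]
    from tmvarscape.topology_mapping import region_lengths

    lengths = region_lengths(tmps, "region")
    freq = ss.region_frequency(tmp_assignments, lengths, "region")
    retained = 1.0 - config.multi_disease_fraction  # ambiguous removal
    for (label, cls), value in freq.items():
        if cls == "Unclassified":
            continue
        rate = config.variant_rates[(cls, label)]
        if cls == "Disease":
            rate *= retained
        lam = rate * lengths[label]
        assert abs(value * lengths[label] - lam) < 3 * np.sqrt(lam)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _tm_disease_percent(sample):
    matrices = ss.count_substitutions(sample, "region")
    key = ("M", "Disease")
    if key not in matrices:
        return np.zeros((20, 20))
    return ss.to_percent(matrices[key])


def test_bootstrap_full_fraction_has_zero_sd(small_cohort):
    _, proteome, variants = small_cohort
    assignments, _ = assign_regions(variants, proteome)
    result = ss.bootstrap_sd(
        assignments, _tm_disease_percent, fraction=1.0, n_reps=5, seed=0
    )
    assert np.all(result.sd == 0.0)


def test_bootstrap_seeds_agree_within_reported_sd(small_cohort):
    _, proteome, variants = small_cohort
    assignments, _ = assign_regions(variants, proteome)
    a = ss.bootstrap_sd(assignments, _tm_disease_percent, seed=1)
    b = ss.bootstrap_sd(assignments, _tm_disease_percent, seed=2)
    gap = np.abs(a.mean - b.mean)
    assert np.all(gap <= a.sd + b.sd + 1e-9)


def test_bootstrap_mean_tracks_dominant_cell():
    assignments = [_assignment("G", "R")] * 80 + [_assignment("L", "P")] * 20
    result = ss.bootstrap_sd(assignments, _tm_disease_percent, seed=3)
    cell = result.mean[AA_INDEX["G"], AA_INDEX["R"]]
    assert abs(cell - 80.0) <= 2 * max(result.sd[AA_INDEX["G"], AA_INDEX["R"]], 1.0)


def test_bootstrap_rejects_bad_fraction(small_cohort):
    _, proteome, variants = small_cohort
    assignments, _ = assign_regions(variants, proteome)
    with pytest.raises(ValueError):
        ss.bootstrap_sd(assignments, _tm_disease_percent, fraction=1.5)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def test_permutation_no_events_yields_no_strata(small_cohort):
    _, proteome, _ = small_cohort
    tmps = [p for p in proteome if p.is_tmp]
    assert ss.permutation_null([], tmps, n_reps=10, seed=0) == {}


def test_permutation_z_detects_constructed_enrichment():
    spectra = null_true_spectra()
    boosted = spectra[("Disease", "M")].copy()
    boosted[AA_INDEX["G"], AA_INDEX["R"]] *= 10
    boosted /= boosted.sum()
    spectra[("Disease", "M")] = boosted
    config = sd.SyntheticConfig(
        n_proteins=400, seed=6, class_spectra=spectra, multi_disease_fraction=0.0
    )
    proteome = sd.generate_proteome(config)
    variants = sd.generate_variants(proteome, config)
    assignments, _ = assign_regions(variants, proteome)
    tmps = [p for p in proteome if p.is_tmp]
    results = ss.permutation_null(
        [a for a in assignments if a.in_tmp], tmps, n_reps=100, seed=6
    )
    assert results[("M", "Disease")].z_cell("G", "R") > 3


def test_permutation_undefined_cells_are_flagged(small_cohort):
    _, proteome, variants = small_cohort
    assignments, _ = assign_regions(variants, proteome)
    tmps = [p for p in proteome if p.is_tmp]
    results = ss.permutation_null(
        [a for a in assignments if a.in_tmp], tmps, n_reps=20, seed=1
    )
    for res in results.values():
        undefined = res.undefined_cells
        for ref, alt in undefined:
            assert np.isnan(res.z[AA_INDEX[ref], AA_INDEX[alt]])
        assert np.isfinite(res.z[res.std > 0]).all()


def test_permutation_conditional_model_runs(small_cohort):
    _, proteome, variants = small_cohort
    assignments, _ = assign_regions(variants, proteome)
    tmps = [p for p in proteome if p.is_tmp]
    results = ss.permutation_null(
        [a for a in assignments if a.in_tmp],
        tmps,
        n_reps=10,
        seed=2,
        alt_model="conditional",
    )
    for res in results.values():
        assert res.avg.sum() == pytest.approx(res.obs.sum())


# ---------------------------------------------------------------------------
# symmetry probe
# ---------------------------------------------------------------------------

def test_symmetric_spectra_recover_symmetric_matrix():
    """A symmetric exchange spectrum on a symmetric composition yields a
    symmetric recovered count matrix within sampling error."""
    pair_idx = [AA_INDEX[a] for a in "VILM"]
    spec = np.zeros((20, 20))
    for i in pair_idx:
        for j in pair_idx:
            if i != j:
                spec[i, j] = 1.0
    spec /= spec.sum()
    comp = np.zeros(20)
    comp[pair_idx] = 0.25  # all hydrophobic, so the composition invariant holds
    composition = sd._default_composition()
    composition["M"] = comp
    config = sd.SyntheticConfig(
        n_proteins=400,
        seed=13,
        composition=composition,
        class_spectra={("Polymorphism", "M"): spec},
        variant_rates={("Polymorphism", "M"): 0.02},
        unclassified_rate=0.0,
    )
    proteome = sd.generate_proteome(config)
    variants = sd.generate_variants(proteome, config)
    assignments, _ = assign_regions(variants, proteome)
    counts = ss.count_substitutions(
        [a for a in assignments if a.in_tmp], "region"
    )[("M", "Polymorphism")].counts
    total = counts.sum()
    assert total > 500
    for i in pair_idx:
        for j in pair_idx:
            if i >= j:
                continue
            n = counts[i, j] + counts[j, i]
            # under symmetry each direction is Binomial(n, 1/2)
            assert abs(counts[i, j] - n / 2) <= 3 * np.sqrt(n * 0.25) + 1e-9


# ---------------------------------------------------------------------------
# predictive values
# ---------------------------------------------------------------------------

def _matrix_with(cells, cls):
    counts = np.zeros((20, 20), dtype=np.int64)
    for (ref, alt), n in cells.items():
        counts[AA_INDEX[ref], AA_INDEX[alt]] = n
    return ss.SubstitutionMatrix(("M", cls), counts)


def test_predictive_value_threshold_rule():
    disease = _matrix_with({("G", "R"): 150, ("L", "P"): 60}, "Disease")
    poly = _matrix_with({("G", "R"): 50, ("L", "P"): 30}, "Polymorphism")
    table = ss.predictive_values(disease, poly, threshold=100)
    assert len(table) == 1  # L>P omitted: 90 <= 100
    row = table.iloc[0]
    assert (row.ref_aa, row.alt_aa) == ("G", "R")
    assert row.predictive_value == pytest.approx(0.75)


def test_predictive_value_recovers_configured_odds():
    config = sd.SyntheticConfig(n_proteins=500, seed=2)
    proteome = sd.generate_proteome(config)
    variants = sd.generate_variants(proteome, config)
    assignments, _ = assign_regions(variants, proteome)
    matrices = ss.count_substitutions(
        [a for a in assignments if a.in_tmp], "region"
    )
    table = ss.predictive_values(
        matrices[("M", "Disease")], matrices[("M", "Polymorphism")], threshold=10
    )
    row = table[(table.ref_aa == "G") & (table.alt_aa == "R")]
    assert len(row) == 1
    d, p = int(row.disease.iloc[0]), int(row.polymorphism.iloc[0])
    pv = d / (d + p)
    # expected odds from composition x conditional spectra x rates
    tm_comp = config.composition["M"]

    def joint(cls):
        spec = config.class_spectra[(cls, "M")]
        row_ = spec[AA_INDEX["G"]].copy()
        row_[AA_INDEX["G"]] = 0
        return (
            config.variant_rates[(cls, "M")]
            * tm_comp[AA_INDEX["G"]]
            * row_[AA_INDEX["R"]]
            / row_.sum()
        )

    d_rate = joint("Disease") * (1 - config.multi_disease_fraction)
    p_rate = joint("Polymorphism")
    expected = d_rate / (d_rate + p_rate)
    se = np.sqrt(expected * (1 - expected) / (d + p))
    assert abs(pv - expected) <= 3 * se + 0.02
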