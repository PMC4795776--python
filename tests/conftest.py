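import numpy as np
import pytest
from hypothesis import settings

from tmvarscape import synthetic_data as sd
from tmvarscape.records import ProteinRecord, Region, TopologySegment

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def simple_protein() -> ProteinRecord:
    """Single-pass protein: I 1-10, M 11-30, O 31-60."""
    protein = ProteinRecord(
        "P00001",
        "M" * 10 + "L" * 20 + "S" * 30,
        [
            TopologySegment(Region.INSIDE, 1, 10),
            TopologySegment(Region.MEMBRANE, 11, 30),
            TopologySegment(Region.OUTSIDE, 31, 60),
        ],
    )
    protein.validate()
    return protein


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by read-only tests."""
    config = sd.SyntheticConfig(n_proteins=120, seed=11)
    proteome = sd.generate_proteome(config)
    variants = sd.generate_variants(proteome, config)
    return config, proteome, variants


def null_true_spectra() -> dict[tuple[str, str], np.ndarray]:
    """Spectra whose rows all equal one marginal: mutant independent of
    wild-type, matching the positional-permutation null."""
    m = np.ones(20) / 20.0
    spec = np.tile(m, (20, 1))
    np.fill_diagonal(spec, 0.0)
    spec /= spec.sum()
    return {
        (cls, region): spec.copy()
        for cls in ("Disease", "Polymorphism")
        for region in "IMO"
    }
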