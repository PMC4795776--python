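"""Substitution spectra, their dispersions and significance.

For each (topological stratum, variant class) the module tallies a 20x20
substitution matrix, expresses it as percent of the stratum total, collapses
it onto the charged / non-polar / polar partition, estimates cell-wise
dispersion by repeated 90% subsampling, and tests cell-wise enrichment
against a positional-randomization null: mutated sites are re-drawn
uniformly from the residues of the same topological region and paired with
mutant residues drawn from the observed mutant-residue marginal, so the
null preserves where mutations fall and what they mutate to, but severs the
link between the wild-type residue and its substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    AA_INDEX,
    AA_ORDER,
    ProteinRecord,
    Region,
    VariantClass,
)
from .topology_mapping import RegionAssignment

#: The fixed polarity partition of the 20 standard residues: 5 polar,
#: 10 non-polar, 5 charged.
POLAR = frozenset("NQSTY")
NONPOLAR = frozenset("ACGILMFPWV")
CHARGED = frozenset("RDEHK")
POLARITY_ORDER = ("charged", "non-polar", "polar")

_POLARITY_OF = {aa: "polar" for aa in POLAR}
_POLARITY_OF.update({aa: "non-polar" for aa in NONPOLAR})
_POLARITY_OF.update({aa: "charged" for aa in CHARGED})


def polarity_classes(ref_aa: str, alt_aa: str) -> tuple[str, str]:
    """Polarity class of the wild-type and mutant residue."""
    try:
        return _POLARITY_OF[ref_aa], _POLARITY_OF[alt_aa]
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from exc


@dataclass
class SubstitutionMatrix:
    """20x20 substitution counts for one (stratum, class), diagonal zero."""

    stratum: tuple[str, str]  # (region/subregion label, class label)
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (20, 20):
            raise ValueError(f"expected 20x20 counts, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative substitution count")
        if np.diagonal(self.counts).any():
            raise ValueError("diagonal must be structurally zero")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def cell(self, ref_aa: str, alt_aa: str) -> int:
        return int(self.counts[AA_INDEX[ref_aa], AA_INDEX[alt_aa]])


@dataclass
class PolarityMatrix:
    """3x3 counts over (charged, non-polar, polar); diagonal may be nonzero."""

    stratum: tuple[str, str]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def count_substitutions(
    assignments: Iterable[RegionAssignment], stratify_by: str = "region"
) -> dict[tuple[str, str], SubstitutionMatrix]:
    """Tally one substitution matrix per (stratum label, class label).

    ``stratify_by="region"`` uses I/M/O labels; ``"subregion"`` uses
    N_TERMINAL/LOOP/C_TERMINAL/TM and covers TMP assignments only.
    """
    if stratify_by not in ("region", "subregion"):
        raise ValueError(f"unknown stratification {stratify_by!r}")
    tallies: dict[tuple[str, str], np.ndarray] = {}
    for a in assignments:
        if stratify_by == "region":
            label = a.region.value
        else:
            if a.subregion is None:
                continue
            label = a.subregion.value
        key = (label, a.variant.classification.value)
        matrix = tallies.setdefault(key, np.zeros((20, 20), dtype=np.int64))
        matrix[AA_INDEX[a.variant.ref_aa], AA_INDEX[a.variant.alt_aa]] += 1
    return {key: SubstitutionMatrix(key, m) for key, m in tallies.items()}


def to_percent(matrix: SubstitutionMatrix | np.ndarray) -> np.ndarray:
    """Counts as percent of the stratum total (cells sum to 100)."""
    counts = matrix.counts if isinstance(matrix, SubstitutionMatrix) else matrix
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot take percentages of an empty matrix")
    return 100.0 * counts / total


_POLARITY_INDEX = {name: i for i, name in enumerate(POLARITY_ORDER)}
# 20-vector mapping amino-acid index -> polarity class index
_AA_TO_POLARITY = np.array([_POLARITY_INDEX[_POLARITY_OF[a]] for a in AA_ORDER])


def polarity_matrix(matrix: SubstitutionMatrix) -> PolarityMatrix:
    """Collapse a 20x20 matrix onto the 3x3 polarity classes."""
    out = np.zeros((3, 3), dtype=np.int64)
    for i in range(20):
        for j in range(20):
            out[_AA_TO_POLARITY[i], _AA_TO_POLARITY[j]] += matrix.counts[i, j]
    return PolarityMatrix(matrix.stratum, out)


def region_frequency(
    assignments: Iterable[RegionAssignment],
    lengths: Mapping[str, int],
    stratify_by: str = "region",
) -> dict[tuple[str, str], float]:
    """Variants per residue for each (stratum label, class), normalizing the
    per-stratum counts by the total residues of that stratum."""
    counts: dict[tuple[str, str], int] = {}
    for a in assignments:
        if stratify_by == "region":
            label = a.region.value
        else:
            if a.subregion is None:
                continue
            label = a.subregion.value
        key = (label, a.variant.classification.value)
        counts[key] = counts.get(key, 0) + 1
    out = {}
    for (label, cls), n in sorted(counts.items()):
        length = lengths.get(label, 0)
        if length <= 0:
            continue  # zero-length stratum: excluded
        out[(label, cls)] = n / length
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Cell-wise mean and SD of a matrix statistic over subsample replicates."""

    mean: np.ndarray
    sd: np.ndarray
    n_reps: int
    fraction: float
    seed: int


def bootstrap_sd(
    assignments: Sequence[RegionAssignment],
    statistic: Callable[[Sequence[RegionAssignment]], np.ndarray],
    fraction: float = 0.9,
    n_reps: int = 10,
    seed: int = 0,
    replace: bool = False,
) -> BootstrapResult:
    """Dispersion of a matrix statistic under repeated class-stratified
    subsampling.

    Each replicate draws ``floor(fraction * n_c)`` assignments per variant
    class (without replacement by default; ``replace=True`` gives the
    classical bootstrap), recomputes ``statistic`` on the union, and the
    cell-wise mean and standard deviation over replicates are returned.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    by_class: dict[VariantClass, list[RegionAssignment]] = {}
    for a in assignments:
        by_class.setdefault(a.variant.classification, []).append(a)

    reps = []
    for _ in range(n_reps):
        sample: list[RegionAssignment] = []
        for group in by_class.values():
            k = int(np.floor(fraction * len(group)))
            idx = rng.choice(len(group), size=k, replace=replace)
            sample.extend(group[i] for i in idx)
        reps.append(np.asarray(statistic(sample), dtype=float))
    stack = np.stack(reps)
    sd = stack.std(axis=0, ddof=0)
    # cells constant across replicates have exactly zero dispersion
    # (avoids ulp noise from the mean subtraction, e.g. at fraction=1.0)
    sd[np.ptp(stack, axis=0) == 0] = 0.0
    return BootstrapResult(
        mean=stack.mean(axis=0),
        sd=sd,
        n_reps=n_reps,
        fraction=fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# positional-randomization null
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Observed vs. resampled-null substitution counts with per-cell z.

    ``z`` is ``(OBS - AVG) / STD`` where the null STD is positive and NaN
    where it is zero; those cells are listed in ``undefined_cells``.
    """

    stratum: tuple[str, str]
    obs: np.ndarray
    avg: np.ndarray
    std: np.ndarray
    z: np.ndarray
    n_reps: int
    seed: int
    n_events: int

    @property
    def undefined_cells(self) -> list[tuple[str, str]]:
        mask = (self.std == 0) & ~np.eye(20, dtype=bool)
        return [
            (AA_ORDER[i], AA_ORDER[j]) for i, j in zip(*np.nonzero(mask))
        ]

    def z_cell(self, ref_aa: str, alt_aa: str) -> float:
        return float(self.z[AA_INDEX[ref_aa], AA_INDEX[alt_aa]])


def _region_pools(
    proteome: Iterable[ProteinRecord],
) -> dict[str, np.ndarray]:
    """Amino-acid indices of all residues per region over the TMPs."""
    pools: dict[str, list[int]] = {r.value: [] for r in Region}
    for protein in proteome:
        if not protein.is_tmp:
            continue
        for seg in protein.segments:
            for aa in protein.sequence[seg.start - 1 : seg.end]:
                idx = AA_INDEX.get(aa)
                if idx is not None:  # non-standard residues excluded
                    pools[seg.region.value].append(idx)
    return {k: np.asarray(v, dtype=np.int64) for k, v in pools.items()}


def permutation_null(
    assignments: Sequence[RegionAssignment],
    proteome: Sequence[ProteinRecord],
    n_reps: int = 100,
    seed: int = 0,
    alt_model: str = "marginal",
) -> dict[tuple[str, str], PermutationResult]:
    """Positional-randomization significance per (region, class) stratum.

    For each observed mutation event of a stratum, every replicate draws a
    uniform random residue from the pooled sequence content of that region
    across all TMPs as the null wild-type, and a mutant residue from the
    observed mutant marginal of the stratum (``alt_model="marginal"``, the
    default) or from the observed row conditional of the sampled wild-type
    (``alt_model="conditional"``; rows never observed fall back to the
    marginal), resampling until mutant differs from wild-type. Null matrices
    are tallied per replicate; z is (OBS - AVG)/STD per cell.
    """
    if alt_model not in ("marginal", "conditional"):
        raise ValueError(f"unknown alt model {alt_model!r}")
    observed = count_substitutions(
        [a for a in assignments if a.in_tmp], stratify_by="region"
    )
    pools = _region_pools(proteome)
    rng = np.random.default_rng(seed)
    results: dict[tuple[str, str], PermutationResult] = {}
    for key in sorted(observed):
        region_label, _ = key
        obs = observed[key].counts
        n_events = int(obs.sum())
        pool = pools.get(region_label, np.empty(0, dtype=np.int64))
        if pool.size == 0:
            raise ValueError(
                f"empty residue pool for region {region_label!r}"
            )
        marginal = obs.sum(axis=0).astype(float)
        marginal /= marginal.sum()
        if alt_model == "conditional":
            row_p = obs.astype(float)
            row_sums = row_p.sum(axis=1)
            row_p[row_sums == 0] = marginal  # unseen wild-types
            row_p = row_p / row_p.sum(axis=1, keepdims=True)
        null = np.zeros((n_reps, 20, 20), dtype=np.int64)
        for rep in range(n_reps):
            refs = pool[rng.integers(0, pool.size, size=n_events)]
            if alt_model == "marginal":
                alts = rng.choice(20, size=n_events, p=marginal)
                collide = alts == refs
                while collide.any():
                    alts[collide] = rng.choice(
                        20, size=int(collide.sum()), p=marginal
                    )
                    collide = alts == refs
            else:
                alts = np.empty(n_events, dtype=np.int64)
                for i, r in enumerate(refs):
                    a = rng.choice(20, p=row_p[r])
                    while a == r:
                        a = rng.choice(20, p=row_p[r])
                    alts[i] = a
            np.add.at(null[rep], (refs, alts), 1)
        avg = null.mean(axis=0)
        std = null.std(axis=0, ddof=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(std > 0, (obs - avg) / np.where(std > 0, std, 1), np.nan)
        results[key] = PermutationResult(
            stratum=key,
            obs=obs,
            avg=avg,
            std=std,
            z=z,
            n_reps=n_reps,
            seed=seed,
            n_events=n_events,
        )
    return results


# ---------------------------------------------------------------------------
# predictive values
# ---------------------------------------------------------------------------

def predictive_values(
    tm_disease: SubstitutionMatrix,
    tm_polymorphism: SubstitutionMatrix,
    threshold: int = 100,
) -> pd.DataFrame:
    """Disease fraction per frequent TM substitution type.

    For each (wild-type, mutant) pair with combined disease + polymorphism
    count above ``threshold``, the predictive value is
    ``disease / (disease + polymorphism)``. Returns a table sorted by
    predictive value, highest first.
    """
    rows = []
    for i, ref in enumerate(AA_ORDER):
        for j, alt in enumerate(AA_ORDER):
            if i == j:
                continue
            d = int(tm_disease.counts[i, j])
            p = int(tm_polymorphism.counts[i, j])
            if d + p > threshold:
                rows.append(
                    {
                        "ref_aa": ref,
                        "alt_aa": alt,
                        "disease": d,
                        "polymorphism": p,
                        "total": d + p,
                        "predictive_value": d / (d + p),
                    }
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "ref_aa",
            "alt_aa",
            "disease",
            "polymorphism",
            "total",
            "predictive_value",
        ],
    )
    return frame.sort_values(
        ["predictive_value", "total"], ascending=False, kind="mergesort"
    ).reset_index(drop=True)
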