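# Methods

## Scope and model

`tmvarscape` analyses missense variation on α-helical transmembrane
proteins through a three-state topology model: every residue is Inside
(cytosolic), Membrane or Outside. Topologies are ordered segment lists
tiling `[1, L]` with no gaps or overlaps and no two consecutive segments
sharing a state; a protein is a TMP if it has ≥ 1 membrane segment.
For multi-pass proteins the non-membrane segments are refined into
N-terminal (before the first TM), C-terminal (after the last TM) and loops
(everything between); single-pass proteins therefore have no loops.
Re-entrant loops and signal peptides are outside the model.

Variants are point substitutions `(protein, position, ref→alt)` labelled
Disease, Polymorphism or Unclassified. Filtering before any statistic:
unclassified variants are excluded; Disease variants associated with more
than one distinct disease name are treated as ambiguous and removed;
variants whose reference residue disagrees with the sequence, on unknown
proteins, or beyond the sequence end are dropped. Each category is counted
separately and the run report checks input = assigned + Σ dropped.
Mismatches are dropped rather than fatal because real releases carry
isoform-offset noise.

## Statistics

**Substitution spectra.** Per (stratum, class), a 20×20 count matrix over
the fixed residue order `A R N D C Q E G H I L K M F P S T W Y V`
(structurally zero diagonal), reported as percent of the stratum total, so
each table sums to 100. Strata are either regions (I/M/O) or subregions
(N-terminal/loop/C-terminal/TM). Non-standard residues (X, U, B, Z) stay
in sequences for coordinate bookkeeping but never enter counts.

**Polarity classes.** The fixed partition: polar {N, Q, S, T, Y},
non-polar {A, C, G, I, L, M, F, P, W, V}, charged {R, D, E, H, K}. The 3×3
polarity matrix is the exact aggregation of the 20×20 counts (its diagonal
may be non-zero, e.g. V→L) and always totals its parent.

**Bootstrap dispersion.** Each of 10 replicates draws ⌊0.9·n_c⌋
assignments per class without replacement and recomputes the percent
statistic; per-cell mean and SD over replicates are reported. Sampling is
stratified by class, and a classical with-replacement bootstrap is
available behind a flag. At fraction 1.0 every replicate is the full
sample; cells constant across replicates report SD exactly 0 (ulp noise
from the mean subtraction is explicitly zeroed).

**Positional-permutation null.** For each (region, class) stratum with n
observed events: each of 100 replicates draws n wild-type residues
uniformly from the pooled residue content of that region over all TMPs
(pooled across the proteome, not per protein; per-protein sampling was the
alternative reading and the pooled choice is the implemented default) and
pairs each with a mutant drawn from the stratum's observed mutant-residue
marginal, resampling until mutant ≠ wild-type. This keeps *where* mutations
fall and *what they mutate to* fixed while severing the wild-type/mutant
association, which is exactly what a positional-randomization null should
test. The alternative of drawing the mutant from the observed conditional
given the sampled wild-type is available (`alt_model="conditional"`) for
sensitivity analysis. Per cell, z = (OBS − AVG)/STD; cells with STD = 0
are reported as undefined rather than ±∞, and the number of tested cells
is exposed so users can apply a multiple-testing correction (none is
applied by default — raw z-ratios are the method's output).

**Predictive value.** For TM substitution types with combined count
D + P > 100, PV = D/(D+P). The threshold of 100 is meaningful at
real-proteome scale (~3000 TM variants); synthetic cohorts rarely reach
it, so the acceptance script also reports the Gly→Arg disease fraction
directly from the count matrices.

**Center distance.** For a TM residue at position i in segment
[s, e] of length L, the center is the actual residue ⌊(s+e)/2⌋ (lower
median for even L — "most central" must name a residue, and a
deterministic tie-break is required) and d = (i − center)/L ∈ [−0.5, 0.5].
Signed d is kept internally; histograms default to |d| with half-open bins
[k·w, (k+1)·w), w = 0.05 by default (the binning is configurable; 0.05 is
a choice, not a derived value).

**Membrane-depth profile.** With coordinates in the membrane frame
(z along the normal, origin at the bilayer center; the frame is applied as
rotation+translation to CA atoms, and inside segments sit at positive z in
the synthetic geometry), residues fall in slice ⌊z/w⌋, w = 1 Å. Relative
frequency per class = class count / residue count per slice; pooling
across proteins sums counts first (ratio of sums, not mean of ratios —
the two differ whenever proteins contribute unequal residue counts).
Variants on residues without coordinates are excluded and reported as an
unmapped count. Slices with no residues are omitted.

## Synthetic cohorts

The generator emulates the inputs the pipeline consumes, not evolution:

- **Topology.** TM-count k ∈ 0..14 drawn from a weight vector (defaults:
  25% non-TMP, modes at 1 and 7 TM, smaller 10/12 classes, rare >12 tail —
  the qualitative shape of the human TM proteome). Segment lengths uniform
  in per-subregion ranges (TM 17–25 residues; terminals 10–60; loops 5–30;
  non-TMPs 120–600). Sides alternate so a membrane segment always
  separates inside from outside.
- **Sequences.** Per-region residue compositions; the TM composition
  places 75% mass on the ten non-polar residues (validated ≥ 60%), with
  arginine rare in membranes; terminals/loops use a generic soluble
  composition.
- **Variants.** Per (protein, segment, class), count ~ Poisson(rate ×
  length); rates per residue default to polymorphism 6/9/6 ×10⁻³ and
  disease 3/6/3 ×10⁻³ for I/M/O (membrane highest), plus a small
  unclassified rate (5×10⁻⁴) so the exclusion filter has work to do.
  Position uniform in the segment; wild-type = the sequence residue there;
  mutant drawn from the class spectrum row of the wild-type (diagonal
  zeroed, renormalized — spectra are row-conditionals, so only row shapes
  matter). TM spectra default to the empirical human TM substitution
  tables embedded in `tm_spectra.py`; I/O spectra default to uniform
  off-diagonal. 5% of disease variants get two disease names to exercise
  the ambiguity filter.
- **Structures.** TM residues on an ideal helix (rise 1.5 Å/residue,
  100°/residue) crossing the ±15 Å core, consecutive TM segments
  alternating direction; loop/terminal residues beyond ±15 Å with |z|
  growing 1 Å/residue from the nearest membrane boundary, capped at 55 Å,
  cytosolic side positive. The emitted frame is the identity because
  coordinates are generated directly in the membrane frame.
- **Determinism.** One master seed; per-protein substreams are derived by
  hashing the protein id (CRC32) with the seed and a stream tag, so
  results do not depend on generation or insertion order.

What passing on synthetic data shows — and what it does not: the tests
certify the bookkeeping, the estimators and the null construction. The
generator has no codon structure (so it cannot reproduce CpG-driven
arginine mutability), no isoform noise, no correlation between variant
density and protein family, and uniform within-segment variant placement
(so depth profiles are flat by construction unless a test seeds structure
deliberately). Conclusions about real proteomes require the real release
files.

## Numerical and design choices

- Internal coordinates are 1-based inclusive (UniProt convention); BED
  export is 0-based half-open, with the conversion localized in
  `io_formats.to_bed` and inverses provided for round-trip checking.
- The embedded empirical TM tables print the 19th column header
  ambiguously in the source material; it is treated as tyrosine — the only
  reading consistent with a 20-residue order.
- Per-residue rates in the run report divide each class count by the total
  residues of the proteins carrying ≥ 1 variant of that class (this is the
  denominator consistent with the published headline rates).
- The TM-count distribution keeps proteins with > 12 TM segments in the
  denominator and merely omits them from the displayed k range, so
  fractions need not sum to 1.
- z-band checks on near-Poisson counts: a ±3 z band is only meaningful
  where null cell means are ≳ 2–3; below that, discreteness alone pushes
  more than 1% of cells past |z| = 3. The calibration test therefore runs
  a denser cohort (800 proteins, 4× rates, null means ≈ 2.8/cell). The
  analysis pipeline itself is unaffected — it reports raw z whatever the
  counts, flagging STD = 0 cells as undefined.
- Problem sizes: the reference study condition is 500 proteins
  (~1 500 variants); the calibration cohort is 800 proteins at 4× rates;
  permutation uses 100 replicates and bootstrap 10, matching the method's
  stated replicate counts.

## Real-data path and limitations

`read_variants(..., dialect="humsavar")` parses the UniProt flat file
(data section delimited by the underscore ruler and the first blank line);
`read_topology(..., dialect="htp_xml")` reads a documented stand-in XML
dialect (`<protein id><sequence/><region type from to/></protein>`) — the
exact schema of the original database export is not public, so a thin
adapter point is left for the real file. Structures for sequence-only
proteins are not found by homology search; an explicit residue↔coordinate
mapping is required. Enrichment analysis against pathway databases and
literature curation of misclassified variants are out of scope.
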