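"""Empirical TM-region substitution spectra of human transmembrane proteins.

Relative frequencies (percent of all substitutions in the TM stratum) of
amino-acid substitutions observed in human TMPs, for natural polymorphisms
and disease-associated mutations separately. Rows are the wild-type
(mutated) residue, columns the mutant residue, both in the fixed order
A R N D C Q E G H I L K M F P S T W Y V. The disease spectrum is dominated
by Gly->Arg and Leu->Pro; the polymorphism spectrum by symmetric
non-polar <-> non-polar exchanges (Val<->Ile, Val<->Leu, Phe->Leu).

These serve as the default TM spectra of the synthetic-variant generator
(:mod:`tmvarscape.synthetic_data`), where each row is renormalized into a
conditional distribution of the mutant residue given the wild-type.
"""

from __future__ import annotations

import numpy as np

_POLYMORPHISM_TM_PERCENT_ROWS = [
    "0 0 0 0.12 0 0 0.31 0.43 0 0 0 0 0 0 0.74 1.05 5.54 0 0 4.06",
    "0 0 0 0 0.49 0.55 0 0.25 0.37 0 0.18 0.06 0.12 0 0.18 0.06 0 0.31 0 0",
    "0 0 0 0.25 0 0 0 0 0.06 0.25 0 0.31 0 0 0 0.62 0.06 0 0 0",
    "0.06 0 0.25 0 0 0 0.12 0.12 0.12 0 0 0 0 0 0 0 0 0 0.06 0",
    "0 0.55 0 0 0 0 0 0.31 0 0 0 0 0 0.12 0 0.43 0 0.43 0.55 0",
    "0 0.37 0 0 0 0 0 0 0.18 0 0 0 0 0 0 0 0 0 0 0",
    "0.12 0 0 0.06 0 0.06 0 0 0 0 0 0.06 0 0 0 0 0 0 0 0.06",
    "0.55 0.74 0 0.43 0.43 0 0.37 0 0 0 0 0 0 0 0 1.29 0 0.12 0 0.43",
    "0 0.62 0.12 0 0 0.06 0 0 0 0 0 0 0 0 0 0 0 0 0 0",
    "0 0 0.43 0 0 0 0 0 0 0 0.68 0 0.92 0.55 0 0.12 3.69 0 0 6.09",
    "0 0.37 0 0 0 0.31 0 0 0.25 1.05 0 0 0.8 3.26 1.6 0.55 0 0.12 0 2.34",
    "0 0.25 0.12 0 0 0 0 0 0 0 0 0 0.12 0 0 0 0 0 0 0",
    "0 0.06 0 0 0 0 0 0 0 1.05 0.86 0.18 0 0 0 0 1.78 0 0 2.71",
    "0 0 0 0 0.55 0 0 0 0 0.06 4.49 0 0 0 0 1.23 0 0 0.31 0.62",
    "0.06 0.18 0 0 0 0.06 0 0 0.06 0 0.8 0 0 0 0 0.86 0.12 0 0 0",
    "0.74 0.18 0.55 0 0.55 0 0 0.98 0 0.25 1.11 0 0 0.62 0.8 0 0.62 0.06 0.12 0",
    "2.71 0.25 0.18 0 0 0 0 0 0 1.48 0 0.31 1.66 0 0.43 0.55 0 0 0 0",
    "0 0.18 0 0 0.37 0 0 0.06 0 0 0.12 0 0 0 0 0.12 0 0 0 0",
    "0 0 0.06 0 1.35 0 0 0 0.74 0 0 0 0 0.18 0 0.18 0 0 0 0",
    "1.78 0 0 0.18 0 0 0.25 0.8 0 7.01 2.28 0 4.37 0.55 0 0 0 0 0 0",
]

_DISEASE_TM_PERCENT_ROWS = [
    "0 0 0 1.39 0 0 0.98 0.46 0 0.05 0 0 0 0 1.19 0.26 2.53 0 0 2.68",
    "0 0 0 0 1.08 1.14 0.05 0.15 1.39 0 0.36 0 0.05 0 0.36 0.26 0 0.83 0 0",
    "0 0 0 0.62 0 0 0 0 0.1 0.36 0 0.72 0 0 0 0.77 0.15 0 0.21 0",
    "0 0 0.88 0 0 0 0.15 0.26 0.15 0 0 0 0 0 0 0 0 0 0.67 0.21",
    "0 1.65 0 0 0 0 0 0.15 0 0 0 0 0 0.15 0 0.21 0 0.26 0.98 0",
    "0 0.36 0 0 0 0 0.05 0 0.15 0 0.1 0.15 0 0 0.21 0 0 0 0 0",
    "0 0 0 0.1 0 0.05 0 0.36 0 0 0 0.93 0 0 0 0 0 0 0 0",
    "0.72 6.91 0 2.63 0.41 0 1.7 0 0 0 0.05 0.05 0 0 0 1.7 0 0.26 0 1.91",
    "0 0.77 0.05 0.05 0 0.21 0 0 0 0 0.05 0 0 0 0.21 0 0 0 0.46 0",
    "0 0.21 0.83 0 0 0 0 0 0 0 0.26 0.31 0.41 0.72 0 0.31 0.62 0 0 0.67",
    "0 1.81 0 0 0 0.26 0 0 0.46 0.21 0 0 0.15 1.14 5.47 0.46 0 0.26 0 0.88",
    "0 0 0.1 0 0 0 0.1 0 0 0 0 0 0 0 0 0 0.1 0 0 0",
    "0 0.67 0 0 0 0 0 0 0 1.03 0.31 0.83 0 0 0 0 0.98 0 0 1.08",
    "0 0 0 0 0.46 0 0 0 0 0.1 1.81 0 0 0 0 1.14 0.05 0 0.05 0.36",
    "0.21 0.72 0 0 0 0.15 0 0 0.1 0 1.81 0 0 0 0 1.08 0.1 0 0 0",
    "0 1.34 0.67 0 0.36 0 0 0.1 0 0.57 1.29 0 0 1.55 1.14 0 0.1 0.36 0.57 0",
    "0.46 1.14 0.41 0 0 0 0 0 0 0.98 0 0.46 1.65 0 0.52 0.15 0 0 0 0",
    "0 1.19 0 0 0.72 0 0 0.05 0 0 0.21 0 0 0 0 0.41 0 0 0 0",
    "0 0 0.1 0.15 1.6 0 0 0 0.62 0 0 0 0 0 0 0.36 0 0 0 0",
    "0.72 0 0 0.62 0 0 0.41 0.31 0 1.7 0.57 0 2.06 1.03 0 0 0 0 0 0",
]

def _parse(rows: list[str]) -> np.ndarray:
    out = np.array([[float(v) for v in row.split()] for row in rows])
    assert out.shape == (20, 20)
    return out


#: Percent matrices (cells sum to ~100 up to printed rounding).
POLYMORPHISM_TM_PERCENT = _parse(_POLYMORPHISM_TM_PERCENT_ROWS)
DISEASE_TM_PERCENT = _parse(_DISEASE_TM_PERCENT_ROWS)
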