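#!/usr/bin/env python
"""Generate the synthetic study cohort and write it in the pipeline's
input formats (variant TSV, topology XML, FASTA, CA-only PDBs + frame).

The cohort is the reference study condition used throughout: 500 proteins
drawn from a TM-count distribution dominated by bitopic and 7-TM proteins,
hydrophobic TM stretches, and variant classes whose membrane substitution
spectra follow the empirical human TM spectra (disease: Gly->Arg/Leu->Pro
enriched; polymorphism: symmetric non-polar exchanges).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from tmvarscape import synthetic_data as sd
from tmvarscape.pipeline import Options, PipelineConfig

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    config = sd.SyntheticConfig(n_proteins=500, seed=SEED)
    proteome = sd.generate_proteome(config)
    variants = sd.generate_variants(proteome, config)
    structures = sd.generate_structures(proteome, config)
    manifest = sd.write_synthetic_inputs(
        proteome, variants, OUT, structures=structures
    )
    n_tmp = sum(p.is_tmp for p in proteome)
    print(f"proteins: {len(proteome)} ({n_tmp} TMPs), variants: {len(variants)}")
    for name, path in manifest.items():
        print(f"  {name}: {path}")

    pipeline_config = PipelineConfig(
        variants=str(OUT / "variants.tsv"),
        topology=str(OUT / "topology.xml"),
        fasta=str(OUT / "sequences.fasta"),
        structures_dir=str(OUT / "structures"),
        frame=str(OUT / "membrane_frame.json"),
        output_dir=str(OUT.parent / "run"),
        options=Options(seed=SEED),
    )
    cfg_path = OUT / "pipeline.toml"
    cfg_path.write_text(pipeline_config.to_toml_text())
    print(f"  pipeline config: {cfg_path}")


if __name__ == "__main__":
    main()
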