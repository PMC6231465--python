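#!/usr/bin/env python
"""Generate the synthetic study inputs with serialised ground truth.

Produces under results/simulated/:
  genome/        two-regime density genome (VCF, GFF3, truth-state BED)
  cohort/        five-sample inbred cohort at mixed F on a ~2-kb SNP lattice
  lineage/       per-family A/Ka table + GO map with planted fast categories

Everything downstream (02-05) consumes these files through the package's
readers, exactly as a real cohort would enter the pipeline.
"""

from pathlib import Path

import pandas as pd

from milupop.simulate import (SimConfig, simulate_family_table,
                              simulate_genome, simulate_inbred_cohort)

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"

# the cohort's per-sample inbreeding levels (mixed, to exercise ranking)
SAMPLE_F = {"lib2": 0.16, "lib3": 0.13, "lib4": 0.11, "lib5": 0.14,
            "lib6": 0.12}


def main() -> None:
    genome_cfg = SimConfig(seed=SEED, n_scaffolds=10,
                           scaffold_length=10_000_000)
    bundle = simulate_genome(genome_cfg, out_dir=OUT / "genome")
    print(f"genome: {len(bundle.variants):,} SNPs on "
          f"{len(bundle.scaffolds)} scaffolds "
          f"({bundle.scaffolds.total_length/1e6:.0f} Mb) -> {OUT/'genome'}")

    cohort_cfg = SimConfig(seed=SEED + 1, n_scaffolds=10,
                           scaffold_length=10_000_000)
    cohort = simulate_inbred_cohort(cohort_cfg, sample_F=SAMPLE_F,
                                    out_dir=OUT / "cohort")
    print(f"cohort: {len(cohort.variants):,} sites x "
          f"{cohort.variants.n_samples} samples at F = {SAMPLE_F}")

    fam_cfg = SimConfig(seed=SEED + 2, n_categories=200,
                        families_per_category=30, n_planted=10,
                        planted_fold=2.0)
    table, gomap, truth = simulate_family_table(fam_cfg)
    lin = OUT / "lineage"
    lin.mkdir(parents=True, exist_ok=True)
    table.to_csv(lin / "family_table.tsv", sep="\t", index=False)
    with open(lin / "go_map.tsv", "w") as fh:
        for fam in table["family_id"]:
            for go in sorted(gomap[fam]):
                fh.write(f"{fam}\t{go}\n")
    truth.to_json(lin / "truth.json")
    print(f"lineage: {len(table):,} families in {fam_cfg.n_categories} GO "
          f"categories, {len(truth.planted_go_ids)} planted at "
          f"{fam_cfg.planted_fold}x")


if __name__ == "__main__":
    main()
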