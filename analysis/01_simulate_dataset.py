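#!/usr/bin/env python
"""Simulate the working dataset: a herd-scale genotype panel with dense
local LD, a point-normal genetic architecture and a single quantitative
trait with gender/farm/year effects and a slaughter-age covariate.

Writes PLINK RAW genotypes and a phenotype table under scratch/ (they are
regenerated on demand) and a small summary under results/.
"""

from pathlib import Path

import numpy as np

from gpcattle.data import write_phenotypes, write_plink_raw
from gpcattle.simulate import SimulationConfig, simulate_dataset

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "dataset"
RESULTS = Path(__file__).resolve().parents[1] / "results"

CONFIG = SimulationConfig(
    n_individuals=600, n_markers=2000, heritability_true=0.4,
    architecture="point_normal", pi_true=0.95, ld_decay=0.95,
    maf_range=(0.01, 0.5), missing_rate=0.03, trait_name="cw", seed=2024)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    geno, pheno, truth = simulate_dataset(CONFIG)
    # write the raw (pre-imputation) genotypes so downstream QC is honest
    from gpcattle.simulate import simulate_genotypes
    raw = simulate_genotypes(CONFIG)
    write_plink_raw(raw, SCRATCH / "herd.raw")
    write_phenotypes(pheno, SCRATCH / "herd.pheno.tsv")
    np.savetxt(SCRATCH / "herd.true_effects.tsv", truth.marker_effects)

    sa2, se2 = truth.variance_components
    with open(RESULTS / "01_dataset_summary.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"n_individuals\t{raw.n_samples}\n")
        fh.write(f"n_markers\t{raw.n_markers}\n")
        fh.write(f"missing_fraction\t{np.ma.getmaskarray(raw.dosages).mean():.4f}\n")
        fh.write(f"true_sigma_a2\t{sa2:.6f}\n")
        fh.write(f"true_sigma_e2\t{se2:.6f}\n")
        fh.write(f"true_h2\t{sa2 / (sa2 + se2):.4f}\n")
        fh.write(f"nonzero_marker_effects\t{(truth.marker_effects != 0).sum()}\n")
    print(f"dataset: {raw.n_samples} animals x {raw.n_markers} markers, "
          f"true h2 = {sa2 / (sa2 + se2):.3f}")
    print(f"wrote {SCRATCH}/herd.raw and {RESULTS}/01_dataset_summary.tsv")


if __name__ == "__main__":
    main()
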