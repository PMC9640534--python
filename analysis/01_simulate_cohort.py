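#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes a PLINK PED/MAP pair, a phenotype table and the ground-truth
diplotype/mixture table under scratch/cohort/ (bulky, regenerable).  The defaults mirror the real
study: 5470 subjects, H2 haplotype frequency 0.159, 22 indicator SNPs in the
17q21.31 region with 2% missingness and rare genotype errors, and children
counts from the zero-inflated negative-binomial process at the published
effect sizes.
"""

from pathlib import Path

from inv17q.simulate import SimConfig, write_fixture

OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"

if __name__ == "__main__":
    cfg = SimConfig(seed=1)
    paths = write_fixture(cfg, OUT)
    print(f"simulated cohort: {cfg.n_subjects} subjects, "
          f"{cfg.n_indicator_snps} indicator + {cfg.n_noise_snps} noise SNPs")
    for name, p in paths.items():
        print(f"  {name}: {p.relative_to(OUT.parent.parent)}")
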