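#!/usr/bin/env python
"""Call H1/H2 inversion diplotypes on the simulated cohort.

Reads scratch/cohort/, seeds the three-group partition from high-coverage
SNPs, admits indicator SNPs, assigns every subject by maximum similarity and
writes per-subject calls (scratch/inversion_calls.tsv) plus an indicator-SNP
sidecar (results/inversion_calls.json).  Prints group sizes, the
representative SNP and accuracy against the planted truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from inv17q import caller, genotype_io

BASE = Path(__file__).resolve().parent.parent
SCRATCH = BASE / "scratch"
RESULTS = BASE / "results"

if __name__ == "__main__":
    gm, _ = genotype_io.read_ped_map(SCRATCH / "cohort/genotypes.ped", SCRATCH / "cohort/genotypes.map")
    res = caller.call_inversion(gm)
    rows = [
        {"subject_id": s, "label": res.labels[s], "mismatches": res.mismatches[s],
         "best_score": round(res.best_score[s], 4)}
        for s in gm.subjects
    ]
    pd.DataFrame(rows).to_csv(SCRATCH / "inversion_calls.tsv", sep="\t", index=False)
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "inversion_calls.json").write_text(res.to_json())

    truth = pd.read_csv(SCRATCH / "cohort/truth.tsv", sep="\t")
    acc = float(np.mean(res.labels_array(gm.subjects) == truth["diplotype"].to_numpy()))
    h2 = caller.h2_frequency(res)
    print(f"group sizes: {res.group_sizes}")
    print(f"indicator SNPs: {len(res.indicator_set)}; representative: {res.representative_snp}")
    print(f"H2 allele frequency: {h2:.4f} (study estimate 0.159)")
    print(f"accuracy vs planted truth: {100 * acc:.2f}%")
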