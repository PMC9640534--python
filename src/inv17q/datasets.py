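"""Small published reference tables used as worked-example inputs.

The only dataset here is the genotype x children-count cross-tabulation of
rs12373123 — the representative tag SNP of the 17q21.31 H1/H2 inversion —
observed in a cohort of Polish volunteers (both sexes combined, women aged
>= 45 and men >= 55).  The C allele tags the H2 lineage; CC is the
H2-homozygote class.  Descriptive statistics (group means, allele-dosage
rows, dominance/recessive contrasts, H2 prevalence) are recomputed from
these counts by :mod:`inv17q.pipeline`, not stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# rows: genotype class; columns: number of children 0..13
_RS12373123_COUNTS = {
    "CC": [6, 7, 19, 7, 0, 1, 0, 0, 0, 1, 0, 0, 1, 1],
    "CT": [65, 66, 217, 107, 56, 22, 14, 2, 1, 1, 3, 0, 0, 0],
    "TT": [132, 218, 539, 308, 132, 43, 27, 6, 6, 4, 2, 1, 0, 0],
}


def rs12373123_nci_counts() -> pd.DataFrame:
    """Genotype x NCI cross-tabulation for rs12373123 (Polish cohort).

    Index: genotype class (CC = H2/H2, CT = H1/H2, TT = H1/H1); columns:
    integer numbers of children 0..13; values: subject counts.
    """
    df = pd.DataFrame(_RS12373123_COUNTS).T
    df.columns = np.arange(df.shape[1])
    df.index.name = "genotype"
    return df
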