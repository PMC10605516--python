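"""Packaged reference tables.

Ships the published 2x2 contingency tables of TSC1, ERBB3 and FGFR3
mutation status versus the binary risk groups in the TCGA urothelial
bladder carcinoma cohort (n = 412).  These counts are the exact inputs
for the reported mutation odds ratios and serve as a fixture for the
association layer.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_mutation_tables"]


def load_mutation_tables() -> dict[str, pd.DataFrame]:
    """2x2 mutation tables keyed by gene.

    Each table has rows (low, high) risk group and columns (wild_type,
    mutated), matching the orientation convention of
    :func:`historiskscore.association.fisher_or`.
    """
    path = resources.files("historiskscore.data") / "mutation_tables.csv"
    raw = pd.read_csv(path)
    out: dict[str, pd.DataFrame] = {}
    for gene, sub in raw.groupby("gene", sort=True):
        t = sub.set_index("risk_group")[["wild_type", "mutated"]].loc[["low", "high"]]
        out[str(gene)] = t
    return out
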