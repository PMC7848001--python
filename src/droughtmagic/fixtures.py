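"""Packaged transcriptions of the published significant-SNP tables.

``table1`` lists the SNPs reported for growth-habit change and the
tolerance indices for maturity, flowering time and 100-seed weight
(14 + 18 + 5 + 5 rows); ``table2`` lists the 35 SNPs reported for the
grain-yield tolerance index.  Columns: trait, snp_id, chrom, pos (1-based
bp), lod, maf (percent).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

EXPECTED_ROWS = {
    "table1": {"habit_change": 14, "maturity": 18, "flowering": 5, "seed_weight": 5},
    "table2": {"grain_yield": 35},
}


def load_fixture(table_id: str) -> pd.DataFrame:
    if table_id not in EXPECTED_ROWS:
        raise KeyError(f"unknown fixture {table_id!r}; choose from {sorted(EXPECTED_ROWS)}")
    ref = resources.files("droughtmagic.data").joinpath(f"{table_id}.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    counts = df["trait"].value_counts().to_dict()
    if counts != EXPECTED_ROWS[table_id]:
        raise ValueError(f"fixture {table_id} row counts {counts} are corrupted")
    return df
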