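"""Aggregate cleaned stomachs into the group-level PPMR table.

Writes the full table to scratch and a compact per-species summary to
results/group_summary.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from paths import GROUPS_CSV, INGEST_DIR, RESULTS

from ppmr.cli import run

if __name__ == "__main__":
    status = run([
        "compute-ppmr", "--input", str(INGEST_DIR / "diet_clean.csv"),
        "--min-n", "10", "--out", str(GROUPS_CSV),
    ])
    if status:
        sys.exit(status)
    groups = pd.read_csv(GROUPS_CSV)
    summary = (
        groups.groupby("species")
        .agg(
            n_groups=("R_bio", "size"),
            n_pred=("n_pred", "sum"),
            R_bio_med=("R_bio", "median"),
            R_num_med=("R_num", "median"),
        )
        .round(2)
        .reset_index()
    )
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "group_summary.csv", index=False)
    print(summary.to_string(index=False))
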