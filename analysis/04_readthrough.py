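"""Premature-stop-codon readthrough per mutant and construct.

Joins the readthrough endpoint signals with the activity records,
normalizes each mutant's signal to wild type per construct and then by
the mutant's translation activity. Reports the mutants with the highest
activity-normalized readthrough.
"""

import argparse
from pathlib import Path

import pandas as pd

from ptcmap.readthrough import readthrough_table


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panel"))
    ap.add_argument("--activity", type=Path, default=Path("results/activity_records.tsv"))
    ap.add_argument("--wt-id", default="WT")
    ap.add_argument("--floor", type=float, default=0.02)
    ap.add_argument("--out", type=Path, default=Path("results/readthrough_records.tsv"))
    args = ap.parse_args(argv)

    signals = pd.read_csv(args.panel / "readthrough_signals.tsv", sep="\t")
    activity = pd.read_csv(args.activity, sep="\t")
    table = readthrough_table(signals, activity, wt_id=args.wt_id, floor=args.floor)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)

    defined = table[table["defined"] & (table["sample_id"] != args.wt_id)]
    top = (
        defined.groupby("sample_id")["normalized_readthrough"]
        .mean()
        .nlargest(5)
    )
    n_undef = int((~table["defined"]).sum())
    print(f"readthrough records: {len(table)} rows -> {args.out}")
    print(f"  undefined (activity < {args.floor:g}): {n_undef} records")
    print("  top normalized readthrough (mean over constructs):")
    for sid, val in top.items():
        print(f"    {sid}: {val:.2f}")


if __name__ == "__main__":
    main()
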