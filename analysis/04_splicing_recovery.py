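#!/usr/bin/env python
"""Analyze splicing events: dPSI, filters, reversals and PSR%.

Pools junction reads per group, computes PSI/dPSI, applies the event
filter (|dPSI| > 25, >= 10 reads per group, adjusted p < 0.05), and
reports per arm how many filtered events the treatment reversed.
"""
import argparse
from pathlib import Path

import pandas as pd

from txrescue import summarize_events
from txrescue.pipeline import FLOAT_FORMAT


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/splicing"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    events = pd.read_csv(args.datadir / "events.tsv", sep="\t")
    design = pd.read_csv(args.datadir / "events_design.tsv", sep="\t", index_col=0)["group"]
    arms = [g for g in design.unique() if g not in ("CNT", "DM1")]

    table = summarize_events(events, design, "CNT", "DM1", arms)
    table.to_csv(args.outdir / "splice_events.tsv", sep="\t", float_format=FLOAT_FORMAT)

    n_pass = int(table["passes_filter"].sum())
    genes = table.loc[table["passes_filter"], "gene"].nunique()
    print(f"{n_pass} of {len(table)} events pass the filter ({genes} genes)")
    for arm in arms:
        rev = table[f"reversed_{arm}"].fillna(False).to_numpy(bool)
        psr = table.loc[rev, f"psr_{arm}"]
        print(f"{arm}: {int(rev.sum())} of {n_pass} filtered events reversed, "
              f"mean PSR {psr.mean():.1f}%")


if __name__ == "__main__":
    main()
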