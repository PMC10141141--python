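#!/usr/bin/env python
"""Hard-target specificity: does the treatment spare known miRNA targets?

A site-blocking (blockmiR-like) oligo should leave the miRNA's other
experimentally supported targets untouched, while silencing the miRNA
itself (antagomiR-like) perturbs them. Counts treatment-altered hard
targets per arm from the saved DGE tables.
"""
import argparse
from pathlib import Path

import pandas as pd

from txrescue import hard_target_report
from txrescue.pipeline import FLOAT_FORMAT


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--dgedir", type=Path, default=Path("results/dge"))
    parser.add_argument("--outdir", type=Path, default=Path("results/specificity"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    truth = pd.read_csv(args.datadir / "truth.tsv", sep="\t", index_col=0)
    targets = list(truth.index[truth["is_hard_target"]])
    dges = {}
    for path in sorted(args.dgedir.glob("dge_DM1_vs_*.tsv")):
        arm = path.stem.removeprefix("dge_DM1_vs_")
        dges[arm] = pd.read_csv(path, sep="\t", index_col=0)

    report = hard_target_report(dges, targets)
    report["matrix"].to_csv(args.outdir / "hard_target_matrix.tsv", sep="\t",
                            float_format=FLOAT_FORMAT)
    print(f"{report['n_present']} of {report['n_targets']} hard targets expressed "
          f"({len(report['missing'])} below the expression filter)")
    for arm, n in report["altered_counts"].items():
        print(f"{arm}: {n} of {report['n_present']} hard targets altered")


if __name__ == "__main__":
    main()
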