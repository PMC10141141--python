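#!/usr/bin/env python
"""Score % Recovery of disease-related genes per treatment arm.

Computes the per-gene % Recovery of every disease-related gene for each
arm, bins it (unrecovered / partial / total / over), calls directional
reversals, and reports the cross-arm intersection ratio of recovered
genes.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from txrescue import (
    CountMatrix,
    disease_related_genes,
    normalize_counts,
    recovery_summary,
    recovery_table,
    reversal_calls,
)
from txrescue.pipeline import FLOAT_FORMAT, _plain


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--dgedir", type=Path, default=Path("results/dge"))
    parser.add_argument("--outdir", type=Path, default=Path("results/recovery"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    matrix = CountMatrix.read(args.datadir / "counts.tsv", args.datadir / "design.tsv")
    arms = [g for g in matrix.groups if g not in ("CNT", "DM1")]
    _, norm = normalize_counts(matrix)
    cnt_dm1 = pd.read_csv(args.dgedir / "dge_CNT_vs_DM1.tsv", sep="\t", index_col=0)
    disease_set = disease_related_genes(cnt_dm1)

    tables = {}
    for arm in arms:
        table = recovery_table(
            norm, matrix.design, "CNT", "DM1", arm, disease_genes=disease_set.index
        )
        tables[arm] = table
        table.to_csv(args.outdir / f"recovery_{arm}.tsv", sep="\t", float_format=FLOAT_FORMAT)
        counts = table["category"].value_counts().to_dict()
        trt = pd.read_csv(args.dgedir / f"dge_DM1_vs_{arm}.tsv", sep="\t", index_col=0)
        _, rev = reversal_calls(disease_set, trt)
        print(f"{arm}: categories {counts}")
        print(f"{arm}: {rev['n_reversals']} reversals among {rev['n_treatment_altered']} "
              f"treatment-altered genes ({rev['reversal_fraction_pct']:.1f}%)")

    summary = recovery_summary(tables)
    with open(args.outdir / "summary.json", "w") as fh:
        json.dump(_plain(summary), fh, indent=2, sort_keys=True)
    for pair, stats in summary["pairs"].items():
        print(f"{pair}: recovered-gene intersection ratio "
              f"{stats['recovered_intersection_ratio']:.3f} "
              f"({stats['shared_recovered']} shared)")


if __name__ == "__main__":
    main()
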