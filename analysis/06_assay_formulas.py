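#!/usr/bin/env python
"""Demonstrate the assay-level formulas on simulated measurements.

Fits a TC50 from a simulated viability curve, computes 2^-ddCt relative
expression from a simulated Ct table, and normalizes simulated grip and
fiber-count records.
"""
import argparse

import numpy as np

from txrescue import (
    central_nuclei_percent,
    fit_tc50,
    generate_dose_response,
    generate_fiber_counts,
    generate_grip_records,
    generate_qpcr,
    percent_normal_force,
    relative_expression_ddct,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    args = parser.parse_args()
    seed = args.seed

    curve = generate_dose_response(150.0, hill=1.0, noise_sd=5.0, seed=seed)
    fit = fit_tc50(curve["dose_nm"], curve["response_pct"])
    print(f"TC50: true 150 nM, fitted {fit.tc50_nm:.1f} nM (hill {fit.hill:.2f}) "
          f"from {len(curve)} noisy wells")

    records = generate_qpcr(
        {"Scramble": 0.0, "BlockmiR": 1.0, "AntagomiR": 1.5},
        calibrator_group="Scramble", technical_sd=0.2, seed=seed,
    )
    rq = relative_expression_ddct(records, "Scramble")
    for group in rq.index:
        print(f"2^-ddCt {group}: relative expression {rq.loc[group, 'rel_expression']:.2f}")

    grips = generate_grip_records(post_over_pre=1.15, seed=seed)
    pre_cols = [c for c in grips.columns if c.startswith("pre_")]
    post_cols = [c for c in grips.columns if c.startswith("post_")]
    forces = [
        percent_normal_force(row[pre_cols], row[post_cols], row["body_weight_g"])
        for _, row in grips.iterrows()
    ]
    print(f"grip: mean percent normal force {np.mean(forces):.2f} %/g over {len(grips)} mice")

    fibers = generate_fiber_counts({"PBS": 0.30, "Treated": 0.18, "FVB": 0.01}, seed=seed)
    for group, sub in fibers.groupby("group", sort=False):
        pcts = [central_nuclei_percent(c, t) for c, t in zip(sub["central_nuclei"], sub["total_fibers"])]
        print(f"central nuclei {group}: {np.mean(pcts):.1f}% of fibers")


if __name__ == "__main__":
    main()
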