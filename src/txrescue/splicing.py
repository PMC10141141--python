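"""Percent-spliced-in (PSI) analysis: dPSI, event filters, reversals, PSR.

PSI of an alternative event is 100 * inclusion / (inclusion + exclusion)
junction reads; group PSI is computed from counts pooled across a group's
samples (merging reads first, as read-count-based splicing pipelines do),
and dPSI is the difference between two group PSIs in percentage points.

Events are screened with the published filters: |dPSI| above a minimum
(default 25 percentage points), at least ``min_reads`` pooled reads per
group, and a BH-adjusted Fisher exact p-value below alpha. A treatment
"reverses" an event when its dPSI relative to disease opposes the disease
shift's sign and moves at least ``min_move`` points. Percent splicing
recovery (PSR%) is the recovery-analogous ratio on the PSI scale.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .dge import adjust_pvalues
from .errors import DataError

DEFAULT_MIN_DPSI = 25.0
DEFAULT_MIN_READS = 10
DEFAULT_MIN_MOVE = 5.0
#: PSR denominator guard, percentage points
DEFAULT_PSR_EPS = 1.0


def compute_psi(inclusion, exclusion):
    """PSI = 100 * inc / (inc + exc); NaN at zero coverage; scalars or arrays."""
    inc = np.asarray(inclusion, float)
    exc = np.asarray(exclusion, float)
    if np.any(inc < 0) or np.any(exc < 0):
        raise DataError("junction read counts must be non-negative")
    total = inc + exc
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = np.where(total > 0, 100.0 * inc / np.where(total > 0, total, 1.0), np.nan)
    if psi.ndim == 0:
        return float(psi)
    return psi


def test_event(inc_a: int, exc_a: int, inc_b: int, exc_b: int) -> float:
    """Two-sided Fisher exact p-value on the pooled 2x2 inclusion table."""
    table = np.array([[inc_a, exc_a], [inc_b, exc_b]])
    if np.any(table < 0):
        raise DataError("junction read counts must be non-negative")
    return float(fisher_exact(table, alternative="two-sided")[1])


def pool_by_group(events: pd.DataFrame, design: pd.Series) -> pd.DataFrame:
    """Pool inclusion/exclusion reads per event and group.

    ``events`` is long format with columns event_id, gene, sample,
    inclusion, exclusion. Returns a wide frame indexed by event_id with the
    gene and, per group, ``inc_<group>`` / ``exc_<group>`` columns.
    """
    required = {"event_id", "gene", "sample", "inclusion", "exclusion"}
    if not required.issubset(events.columns):
        raise DataError(f"event table must have columns {sorted(required)}")
    unknown = set(events["sample"]) - set(design.index)
    if unknown:
        raise DataError(f"event samples missing from design: {sorted(unknown)[:5]}")
    ev = events.copy()
    ev["group"] = ev["sample"].map(design)
    pooled = ev.groupby(["event_id", "group"], sort=False)[["inclusion", "exclusion"]].sum()
    genes = ev.groupby("event_id", sort=False)["gene"].first()
    wide = pooled.unstack("group")
    out = pd.DataFrame(index=wide.index)
    out["gene"] = genes
    for group in pooled.index.get_level_values("group").unique():
        out[f"inc_{group}"] = wide[("inclusion", group)].fillna(0).astype(np.int64)
        out[f"exc_{group}"] = wide[("exclusion", group)].fillna(0).astype(np.int64)
    return out


def event_reversal(dpsi_disease, dpsi_treatment, min_move: float = DEFAULT_MIN_MOVE):
    """True when the treatment shift opposes the disease shift by >= min_move.

    Either dPSI being NaN yields pandas NA (undefined). Works on scalars or
    arrays; array results use the nullable boolean dtype.
    """
    d = np.asarray(dpsi_disease, float)
    t = np.asarray(dpsi_treatment, float)
    scalar = d.ndim == 0 and t.ndim == 0
    d, t = np.atleast_1d(d), np.atleast_1d(t)
    defined = ~(np.isnan(d) | np.isnan(t))
    flag = defined & (np.sign(d) * np.sign(t) < 0) & (np.abs(t) >= min_move)
    result = pd.array(flag, dtype="boolean")
    result[~defined] = pd.NA
    if scalar:
        return result[0]
    return result


def percent_splicing_recovery(
    psi_control, psi_disease, psi_treated, eps: float = DEFAULT_PSR_EPS
):
    """PSR% = 100 * (psi_treated - psi_disease) / (psi_control - psi_disease).

    Undefined (NaN) when the control and disease PSIs are within ``eps``
    percentage points of each other.
    """
    c = np.asarray(psi_control, float)
    d = np.asarray(psi_disease, float)
    t = np.asarray(psi_treated, float)
    denom = c - d
    with np.errstate(divide="ignore", invalid="ignore"):
        psr = np.where(np.abs(denom) < eps, np.nan, 100.0 * (t - d) / denom)
    if psr.ndim == 0:
        return float(psr)
    return psr


def summarize_events(
    events: pd.DataFrame,
    design: pd.Series,
    control: str,
    disease: str,
    arms: Sequence[str] = (),
    min_dpsi: float = DEFAULT_MIN_DPSI,
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = 0.05,
    min_move: float = DEFAULT_MIN_MOVE,
    psr_eps: float = DEFAULT_PSR_EPS,
) -> pd.DataFrame:
    """Full per-event analysis for a control/disease(/arms) design.

    Computes pooled PSI per group, the disease dPSI (disease minus control),
    Fisher p-values with BH adjustment, the event filter, and per arm the
    treatment dPSI (arm minus disease), reversal flag and PSR%.
    """
    pooled = pool_by_group(events, design)
    for g in [control, disease, *arms]:
        if f"inc_{g}" not in pooled.columns:
            raise DataError(f"group {g!r} has no samples in the event table")

    table = pooled.copy()
    for g in [control, disease, *arms]:
        table[f"reads_{g}"] = table[f"inc_{g}"] + table[f"exc_{g}"]
        table[f"psi_{g}"] = compute_psi(table[f"inc_{g}"], table[f"exc_{g}"])
    table["dpsi_disease"] = table[f"psi_{disease}"] - table[f"psi_{control}"]

    pvals = np.array(
        [
            test_event(
                row[f"inc_{disease}"],
                row[f"exc_{disease}"],
                row[f"inc_{control}"],
                row[f"exc_{control}"],
            )
            for _, row in table.iterrows()
        ]
    )
    table["pvalue"] = pvals
    table["padj"] = adjust_pvalues(pvals)
    table["passes_filter"] = _filter_mask(
        table, control, disease, min_dpsi=min_dpsi, min_reads=min_reads, alpha=alpha
    )

    for arm in arms:
        dpsi_trt = table[f"psi_{arm}"] - table[f"psi_{disease}"]
        table[f"dpsi_{arm}"] = dpsi_trt
        enough_reads = table[f"reads_{arm}"] >= min_reads
        rev = event_reversal(table["dpsi_disease"], dpsi_trt, min_move=min_move)
        table[f"reversed_{arm}"] = pd.array(
            table["passes_filter"].to_numpy() & enough_reads.to_numpy(), dtype="boolean"
        ) & rev
        table[f"psr_{arm}"] = percent_splicing_recovery(
            table[f"psi_{control}"], table[f"psi_{disease}"], table[f"psi_{arm}"], eps=psr_eps
        )
    return table


def _filter_mask(
    table: pd.DataFrame,
    control: str,
    disease: str,
    min_dpsi: float,
    min_reads: int,
    alpha: float,
) -> np.ndarray:
    dpsi = table["dpsi_disease"].to_numpy(float)
    padj = table["padj"].to_numpy(float)
    ok = ~np.isnan(dpsi) & ~np.isnan(padj)
    mask = ok.copy()
    mask &= np.abs(np.where(ok, dpsi, 0.0)) > min_dpsi
    mask &= np.where(ok, padj, 1.0) < alpha
    for g in (control, disease):
        mask &= table[f"reads_{g}"].to_numpy() >= min_reads
    return mask


def filter_events(
    table: pd.DataFrame,
    min_dpsi: float = DEFAULT_MIN_DPSI,
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = 0.05,
    control: str | None = None,
    disease: str | None = None,
) -> pd.DataFrame:
    """Rows of a summarized event table passing the published filters.

    When ``control``/``disease`` are omitted they are inferred from the
    ``reads_<group>`` columns (all such groups must pass the read floor).
    Idempotent and invariant to event order.
    """
    if control is not None and disease is not None:
        groups = [control, disease]
    else:
        groups = [c[len("reads_") :] for c in table.columns if c.startswith("reads_")]
    if not groups:
        raise DataError("filter_events needs reads_<group> columns")
    dpsi = table["dpsi_disease"].to_numpy(float)
    padj = table["padj"].to_numpy(float)
    ok = ~np.isnan(dpsi) & ~np.isnan(padj)
    mask = ok & (np.abs(np.where(ok, dpsi, 0.0)) > min_dpsi) & (np.where(ok, padj, 1.0) < alpha)
    for g in groups:
        mask &= table[f"reads_{g}"].to_numpy() >= min_reads
    return table.loc[mask]
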