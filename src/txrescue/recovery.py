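"""Per-gene % Recovery scoring, recovery bins, reversals and specificity.

% Recovery measures how far a treatment moved a gene's mean expression back
toward the healthy control level:

    pct = 100 * (mean_treated - mean_disease) / (mean_control - mean_disease)

0% means the treatment left the disease signature untouched, 100% means it
restored the control mean exactly, and values above 150% are over-shoot.
Genes whose control and disease means nearly coincide (|difference| below a
guard epsilon, default one normalized count) get an undefined score: the
ratio is numerically meaningless there.

Bins follow the published legend: unrecovered < 10%, partial [10, 50),
total [50, 150], over > 150. Negative recoveries (treatment moved
expression further from control) fall in "unrecovered".
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

CATEGORIES = ("unrecovered", "partial", "total", "over")
UNDEFINED = "undefined"
DEFAULT_BINS = (10.0, 50.0, 150.0)
DEFAULT_EPS = 1.0
#: categories counted as "recovered" when intersecting arms
RECOVERED_CATEGORIES = ("partial", "total", "over")


def percent_recovery(mean_control, mean_disease, mean_treated, eps: float = DEFAULT_EPS):
    """% Recovery of the treated mean toward control; NaN when guarded.

    Accepts scalars or aligned arrays. Negative means raise; a denominator
    below ``eps`` in absolute value yields NaN (undefined), never an error.
    """
    c = np.asarray(mean_control, float)
    d = np.asarray(mean_disease, float)
    t = np.asarray(mean_treated, float)
    if np.any(c < 0) or np.any(d < 0) or np.any(t < 0):
        raise DataError("group means must be non-negative")
    denom = c - d
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(np.abs(denom) < eps, np.nan, 100.0 * (t - d) / denom)
    if pct.ndim == 0:
        return float(pct)
    return pct


def classify_recovery(pct, bins: Sequence[float] = DEFAULT_BINS):
    """Map % Recovery values to categories.

    unrecovered: pct < bins[0]; partial: [bins[0], bins[1]); total:
    [bins[1], bins[2]]; over: > bins[2]; NaN passes through as "undefined".
    """
    lo, mid, hi = bins
    if not lo < mid < hi:
        raise DataError("recovery bins must be strictly increasing")
    p = np.asarray(pct, float)
    out = np.full(p.shape, UNDEFINED, dtype=object)
    defined = ~np.isnan(p)
    out[defined & (p < lo)] = "unrecovered"
    out[defined & (p >= lo) & (p < mid)] = "partial"
    out[defined & (p >= mid) & (p <= hi)] = "total"
    out[defined & (p > hi)] = "over"
    if p.ndim == 0:
        return str(out[()])
    return out


def recovery_table(
    norm_counts: pd.DataFrame,
    design: pd.Series,
    control: str,
    disease: str,
    treated: str,
    genes: Iterable[str] | None = None,
    disease_genes: Iterable[str] | None = None,
    eps: float = DEFAULT_EPS,
    bins: Sequence[float] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Per-gene recovery table for one treatment arm.

    ``norm_counts`` are size-factor-normalized counts (genes x samples).
    Rows cover ``genes`` if given, else the disease gene set if given, else
    every gene. ``disease_genes`` only sets the ``is_disease_gene`` flag.
    """
    for g in (control, disease, treated):
        if not (design == g).any():
            raise DataError(f"group {g!r} not present in the design")
    if genes is None:
        genes = list(disease_genes) if disease_genes is not None else list(norm_counts.index)
    else:
        genes = list(genes)
    missing = [g for g in genes if g not in norm_counts.index]
    if missing:
        raise DataError(f"genes absent from the count matrix: {missing[:5]}...")
    sub = norm_counts.loc[genes]

    def group_mean(group: str) -> np.ndarray:
        samples = design.index[design == group]
        return sub[list(samples)].mean(axis=1).to_numpy()

    m_c, m_d, m_t = group_mean(control), group_mean(disease), group_mean(treated)
    pct = percent_recovery(m_c, m_d, m_t, eps=eps)
    disease_set = set(disease_genes) if disease_genes is not None else set()
    table = pd.DataFrame(
        {
            "mean_control": m_c,
            "mean_disease": m_d,
            "mean_treated": m_t,
            "pct_recovery": pct,
            "category": classify_recovery(pct, bins=bins),
            "is_disease_gene": [g in disease_set for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return table


# ----------------------------------------------------------------- reversals
def disease_related_genes(
    dge_control_vs_disease: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 1.0
) -> pd.DataFrame:
    """Altered genes of the control-vs-disease contrast with their direction.

    The recorded direction is the disease direction: "up" means the gene is
    over-expressed in disease relative to control.
    """
    mask = (dge_control_vs_disease["padj"] < alpha) & (
        dge_control_vs_disease["log2fc"].abs() >= lfc_threshold
    )
    sub = dge_control_vs_disease.loc[mask]
    return pd.DataFrame(
        {"disease_direction": np.where(sub["log2fc"] > 0, "up", "down")}, index=sub.index
    )


def reversal_calls(
    disease_genes: pd.DataFrame,
    dge_treated_vs_disease: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Flag disease-related genes the treatment altered in the opposing direction.

    ``disease_genes`` is the frame from :func:`disease_related_genes`.
    Returns the per-gene frame and a summary with the reversal fraction
    among all treatment-altered genes; disease genes missing from the
    treated contrast are reported, not silently dropped.
    """
    present = [g for g in disease_genes.index if g in dge_treated_vs_disease.index]
    missing = [g for g in disease_genes.index if g not in dge_treated_vs_disease.index]
    sub = dge_treated_vs_disease.loc[present]
    trt_altered = (sub["padj"] < alpha) & (sub["log2fc"].abs() >= lfc_threshold)
    trt_direction = np.where(sub["log2fc"] > 0, "up", "down")
    opposing = trt_direction != disease_genes.loc[present, "disease_direction"].to_numpy()
    reversal = trt_altered.to_numpy() & opposing

    flags = pd.DataFrame(
        {
            "disease_direction": disease_genes.loc[present, "disease_direction"],
            "treatment_altered": trt_altered.to_numpy(),
            "treatment_direction": np.where(trt_altered, trt_direction, "none"),
            "reversal": reversal,
        },
        index=pd.Index(present, name="gene"),
    )
    n_treatment_altered = int(
        (
            (dge_treated_vs_disease["padj"] < alpha)
            & (dge_treated_vs_disease["log2fc"].abs() >= lfc_threshold)
        ).sum()
    )
    n_reversals = int(reversal.sum())
    summary = {
        "n_disease_genes": int(len(disease_genes)),
        "n_treatment_altered": n_treatment_altered,
        "n_reversals": n_reversals,
        "reversal_fraction_pct": (
            100.0 * n_reversals / n_treatment_altered if n_treatment_altered else float("nan")
        ),
        "missing_genes": missing,
    }
    return flags, summary


def intersection_ratio(set_a: Iterable, set_b: Iterable) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty (with a warning)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("intersection ratio of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


def recovery_summary(tables: Mapping[str, pd.DataFrame]) -> dict:
    """Category counts per arm plus cross-arm shared/exclusive breakdowns.

    All tables must share one gene universe. Undefined genes are excluded
    from the category counts and reported separately.
    """
    if not tables:
        raise DataError("recovery_summary needs at least one treatment arm")
    arms = list(tables)
    universe = tables[arms[0]].index
    for arm in arms[1:]:
        if not tables[arm].index.equals(universe):
            raise DataError("recovery tables have mismatched gene universes")

    summary: dict = {"arms": {}, "pairs": {}}
    cat_sets: dict[str, dict[str, set]] = {}
    for arm in arms:
        t = tables[arm]
        counts = {c: int((t["category"] == c).sum()) for c in CATEGORIES}
        summary["arms"][arm] = {
            "category_counts": counts,
            "n_undefined": int((t["category"] == UNDEFINED).sum()),
            "n_genes": int(len(t)),
        }
        cat_sets[arm] = {c: set(t.index[t["category"] == c]) for c in CATEGORIES}
        cat_sets[arm]["recovered"] = set().union(
            *(cat_sets[arm][c] for c in RECOVERED_CATEGORIES)
        )
    for i, arm_a in enumerate(arms):
        for arm_b in arms[i + 1 :]:
            rec_a, rec_b = cat_sets[arm_a]["recovered"], cat_sets[arm_b]["recovered"]
            pair = {
                "recovered_intersection_ratio": (
                    intersection_ratio(rec_a, rec_b) if (rec_a or rec_b) else 0.0
                ),
                "shared_recovered": len(rec_a & rec_b),
                f"exclusive_{arm_a}": len(rec_a - rec_b),
                f"exclusive_{arm_b}": len(rec_b - rec_a),
                "per_category_intersection_ratio": {
                    c: (
                        intersection_ratio(cat_sets[arm_a][c], cat_sets[arm_b][c])
                        if (cat_sets[arm_a][c] or cat_sets[arm_b][c])
                        else 0.0
                    )
                    for c in CATEGORIES
                },
            }
            summary["pairs"][f"{arm_a}|{arm_b}"] = pair
    return summary


# -------------------------------------------------------------- hard targets
def read_target_list(path) -> list[str]:
    """Read a hard-target list: one gene symbol per line, '#' comments allowed."""
    targets = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                targets.append(line)
    if not targets:
        raise DataError(f"target list {path} is empty")
    return targets


def hard_target_report(
    dges: Mapping[str, pd.DataFrame],
    targets: Sequence[str],
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> dict:
    """Per-target log2 fold changes and altered flags across contrasts.

    ``dges`` maps a contrast name to its DGE table. Targets absent from
    every contrast are listed under "missing" and not counted. Returns a
    dict with the per-target matrix, per-contrast altered counts, and the
    missing list.
    """
    if not targets:
        raise DataError("hard-target list is empty")
    if not dges:
        raise DataError("hard_target_report needs at least one contrast")
    seen = set()
    for dge in dges.values():
        seen.update(dge.index)
    present = [t for t in targets if t in seen]
    missing = [t for t in targets if t not in seen]
    if not present:
        raise DataError("no hard target intersects the tested genes")

    matrix = pd.DataFrame(index=pd.Index(present, name="gene"))
    counts: dict[str, int] = {}
    for name, dge in dges.items():
        sub = dge.reindex(present)
        altered = (sub["padj"] < alpha) & (sub["log2fc"].abs() >= lfc_threshold)
        altered = altered.fillna(False)
        matrix[f"log2fc__{name}"] = sub["log2fc"]
        matrix[f"altered__{name}"] = altered.astype(bool)
        counts[name] = int(altered.sum())
    return {
        "matrix": matrix,
        "altered_counts": counts,
        "missing": missing,
        "n_targets": len(targets),
        "n_present": len(present),
    }
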