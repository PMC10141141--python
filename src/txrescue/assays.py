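"""Assay-level formulas: viability/TC50, 2^-ddCt, pixel intensity, grip, nuclei.

Each function implements one printed formula verbatim:

* percent inhibition of an MTS viability signal,
  100 - (transfected - mean media-only) * 100 / mean untransfected;
* TC50 from a least-squares four-parameter logistic (4PL) fit on
  log10-transformed doses;
* relative qPCR expression by the 2^-ddCt method, calibrated to a
  reference gene and a calibrator group;
* mean pixel intensity = thresholded gray-value sum / area;
* percent normal force = 100 * (mean post-treatment grip / mean
  pre-treatment grip) / body weight;
* central-nuclei percentage of muscle fibers.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DataError


# ------------------------------------------------------------ dose response
def four_param_logistic(log10_dose, bottom, top, log_tc50, hill):
    """4PL response at log10 dose: bottom..top with midpoint at log_tc50."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_tc50 - log10_dose) * hill))


def percent_inhibition(abs_transfected, mean_media_only, mean_untransfected):
    """Normalized viability signal on the inhibition scale (0 = fully viable)."""
    if mean_untransfected <= 0:
        raise DataError("mean untransfected-control absorbance must be positive")
    a = np.asarray(abs_transfected, float)
    out = 100.0 - (a - mean_media_only) * 100.0 / mean_untransfected
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class DoseResponseCurve:
    """A fitted 4PL dose-response curve; tc50_nm is on the concentration scale."""

    doses_nm: np.ndarray
    responses: np.ndarray
    bottom: float
    top: float
    log_tc50: float
    hill: float
    tc50_nm: float
    converged: bool
    degenerate: bool
    rss: float


def fit_tc50(
    doses_nm: Sequence[float],
    responses: Sequence[float],
    free_asymptotes: bool = False,
) -> DoseResponseCurve:
    """Least-squares 4PL fit on log10 dose; TC50 back on the nM scale.

    The responses are percent-normalized by construction (0 = fully
    viable, 100 = fully inhibited), so by default the asymptotes are fixed
    at 0 and 100 and only the midpoint and hill slope are fitted (the
    normalized-response model); pass ``free_asymptotes=True`` for the
    fully free four-parameter fit, parameterized as (bottom, span,
    log_tc50, hill) with span >= 0 so bottom <= top always holds.

    Requires at least four distinct positive doses. A flat response profile
    or persistent non-convergence yields a flagged degenerate result rather
    than an exception.
    """
    doses = np.asarray(doses_nm, float)
    resp = np.asarray(responses, float)
    if doses.shape != resp.shape:
        raise DataError("doses and responses must align")
    if np.any(doses <= 0):
        raise DataError("doses must be positive")
    if not np.all(np.isfinite(resp)):
        raise DataError("responses must be finite")
    if len(np.unique(doses)) < 4:
        raise DataError("fit_tc50 needs at least 4 distinct doses")

    x = np.log10(doses)
    lo_x, hi_x = x.min(), x.max()

    def degenerate_result() -> DoseResponseCurve:
        return DoseResponseCurve(
            doses, resp, float("nan"), float("nan"), float("nan"), float("nan"),
            float("nan"), converged=False, degenerate=True,
            rss=float(((resp - resp.mean()) ** 2).sum()),
        )

    if np.ptp(resp) < 1e-9:
        return degenerate_result()

    if free_asymptotes:
        def model(x, bottom, span, log_tc50, hill):
            return four_param_logistic(x, bottom, bottom + span, log_tc50, hill)

        bounds = (
            [resp.min() - 100.0, 0.0, lo_x - 3.0, -20.0],
            [resp.max() + 100.0, 400.0, hi_x + 3.0, 20.0],
        )
        starts = [(resp.min(), np.ptp(resp), np.median(x), h) for h in (1.0, 0.5, 2.0)]
    else:
        def model(x, log_tc50, hill):
            return four_param_logistic(x, 0.0, 100.0, log_tc50, hill)

        bounds = ([lo_x - 3.0, -20.0], [hi_x + 3.0, 20.0])
        starts = [(np.median(x), h) for h in (1.0, 0.5, 2.0)]

    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(model, x, resp, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(((model(x, *popt) - resp) ** 2).sum())
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return degenerate_result()
    if free_asymptotes:
        (bottom, span, log_tc50, hill), rss = best
        if span < 1e-6:
            return degenerate_result()
        top = bottom + span
    else:
        (log_tc50, hill), rss = best
        bottom, top = 0.0, 100.0
    return DoseResponseCurve(
        doses, resp, float(bottom), float(top), float(log_tc50), float(hill),
        float(10.0 ** log_tc50), converged=True, degenerate=False, rss=rss,
    )


# -------------------------------------------------------------------- qPCR
def relative_expression_ddct(records: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Per-group relative expression by the 2^-ddCt method.

    ``records`` needs columns group, sample, ct_target, ct_reference
    (technical replicates as extra rows are averaged per sample first).
    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the
    calibrator group's mean dCt, so the calibrator's relative quantity is
    exactly 1.
    """
    required = {"group", "sample", "ct_target", "ct_reference"}
    if not required.issubset(records.columns):
        raise DataError(f"qPCR records need columns {sorted(required)}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        raise DataError("missing Ct value in qPCR records")
    if (records[["ct_target", "ct_reference"]] <= 0).any().any():
        raise DataError("Ct values must be positive")
    if not (records["group"] == calibrator_group).any():
        raise DataError(f"calibrator group {calibrator_group!r} absent from records")

    per_sample = records.groupby(["group", "sample"], sort=False)[
        ["ct_target", "ct_reference"]
    ].mean()
    dct = per_sample["ct_target"] - per_sample["ct_reference"]
    mean_dct = dct.groupby(level="group", sort=False).mean()
    ddct = mean_dct - mean_dct[calibrator_group]
    out = pd.DataFrame(
        {
            "mean_dct": mean_dct,
            "ddct": ddct,
            "rel_expression": 2.0 ** (-ddct),
            "n_samples": dct.groupby(level="group", sort=False).size(),
        }
    )
    out.index.name = "group"
    return out


# ------------------------------------------------------------------ imaging
def mean_pixel_intensity(gray_value_sum: float, area: float) -> float:
    """Thresholded gray-value sum divided by area (intensity per unit area)."""
    if area <= 0:
        raise DataError("area must be positive")
    if gray_value_sum < 0:
        raise DataError("gray-value sum must be non-negative")
    return gray_value_sum / area


def mean_pixel_intensity_from_image(
    image, threshold: float = 10.0, area: float | None = None
) -> float:
    """Mean pixel intensity of an image, ignoring pixels below ``threshold``.

    ``area`` defaults to the number of supra-threshold pixels (the
    thresholded selection's area); pass an explicit area (e.g. the cell
    outline's) to normalize differently.
    """
    img = np.asarray(image, float)
    mask = img >= threshold
    if area is None:
        area = float(mask.sum())
    return mean_pixel_intensity(float(img[mask].sum()), area)


# ----------------------------------------------------------- grip / fibers
def percent_normal_force(
    pre_trials_g: Sequence[float], post_trials_g: Sequence[float], body_weight_g: float
) -> float:
    """100 * (mean post-treatment grip / mean pre-treatment grip) / body weight."""
    pre = np.asarray(pre_trials_g, float)
    post = np.asarray(post_trials_g, float)
    if np.any(pre < 0) or np.any(post < 0):
        raise DataError("grip trial forces must be non-negative")
    if body_weight_g <= 0:
        raise DataError("body weight must be positive")
    if pre.mean() <= 0:
        raise DataError("mean pre-treatment force must be positive")
    return 100.0 * (post.mean() / pre.mean()) / body_weight_g


def central_nuclei_percent(central_count: int, total_fibers: int) -> float:
    """Percentage of muscle fibers with centrally located nuclei."""
    if total_fibers <= 0:
        raise DataError("total fiber count must be positive")
    if central_count < 0 or central_count > total_fibers:
        raise DataError("central count must be between 0 and the total fiber count")
    return 100.0 * central_count / total_fibers
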