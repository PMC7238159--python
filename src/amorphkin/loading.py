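"""Monomolecular loading capacity of a drug on mesoporous silica.

Drug molecules adsorbed on the silica surface are immobilized: they no
longer contribute to the heat-capacity step dCp at the glass transition.
Measuring dCp for a series of drug/silica compositions and extrapolating
the linear dCp(w) dependence (w = wt.% drug) to dCp = 0 gives the
composition w* at which the entire drug fraction is surface-bound; the
monomolecular loading capacity is the corresponding silica fraction,
100 - w* wt.% (the Hempel construction).
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .exceptions import AnalysisError, ValidationError
from .types import CapacityDifference, CapacityResult, CpPoint

logger = logging.getLogger(__name__)


def fit_dcp_line(
    points: list[CpPoint],
    exclude_below_breakpoint: bool = True,
) -> CapacityResult:
    """Ordinary least squares dCp = slope*w + intercept and its zero crossing.

    Compositions with no detectable glass transition (dCp = 0, i.e. fully
    adsorbed drug) carry no information about the mobile fraction and are
    excluded by default.  A non-positive slope — dCp must grow with drug
    load — flags an invalid extrapolation.
    """
    pts = [p for p in points if p.delta_cp > 0] if exclude_below_breakpoint else list(points)
    loads = np.array([p.drug_load for p in pts], dtype=float)
    dcp = np.array([p.delta_cp for p in pts], dtype=float)
    if len(np.unique(loads)) < 2:
        raise ValidationError("need at least 2 distinct drug loads above the breakpoint")
    A = np.column_stack([loads, np.ones_like(loads)])
    coef, res, *_ = np.linalg.lstsq(A, dcp, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    if slope <= 0:
        raise AnalysisError(
            "non-positive dCp slope vs drug load: invalid extrapolation"
        )
    w0 = -intercept / slope
    slope_se = intercept_se = cap_se = float("nan")
    if len(loads) > 2:
        ssr = float(res[0]) if len(res) else float(np.sum((A @ coef - dcp) ** 2))
        cov = np.linalg.inv(A.T @ A) * ssr / (len(loads) - 2)
        slope_se = math.sqrt(max(cov[0, 0], 0.0))
        intercept_se = math.sqrt(max(cov[1, 1], 0.0))
        # delta method on w0 = -intercept/slope
        var_w0 = (
            cov[1, 1] + w0**2 * cov[0, 0] + 2 * w0 * cov[0, 1]
        ) / slope**2
        cap_se = math.sqrt(max(var_w0, 0.0))
    in_range = 0.0 <= w0 <= 100.0
    if not in_range:
        logger.warning("dCp zero crossing at %.1f wt.%% drug is outside [0, 100]", w0)
    return CapacityResult(
        slope=slope,
        intercept=intercept,
        drug_load_at_zero=w0,
        ms_capacity=100.0 - w0,
        slope_stderr=slope_se,
        intercept_stderr=intercept_se,
        capacity_stderr=cap_se,
        n_points=len(loads),
        in_range=in_range,
    )


def compare_capacities(a: CapacityResult, b: CapacityResult) -> CapacityDifference:
    """Difference of two loading capacities with quadrature-summed error."""
    for r in (a, b):
        if not r.in_range or not math.isfinite(r.ms_capacity):
            raise ValidationError("cannot compare an invalid capacity fit")
    se = [r.capacity_stderr for r in (a, b)]
    se = [0.0 if math.isnan(s) else s for s in se]
    return CapacityDifference(
        difference=a.ms_capacity - b.ms_capacity,
        stderr=math.hypot(se[0], se[1]),
    )
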