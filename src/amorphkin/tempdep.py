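"""Temperature dependence of relaxation times: VFT, Tg, fragility, Arrhenius.

The structural (alpha) relaxation of a supercooled liquid follows the
Vogel–Fulcher–Tammann law

    tau_alpha(T) = tau_inf * exp(D T0 / (T - T0)),

fitted here in log10 tau space (relaxation times span many decades) and
parameterized by (log10 tau_inf, DT0, T0) for conditioning — the product
DT0 is what is conventionally tabulated; the strength parameter D is
derived.  Two closed forms follow from the fit:

* the dielectric glass-transition temperature, defined as tau_alpha(Tg)
  = tau_g (100 s by convention):
      Tg = T0 + DT0 * log10(e) / (log10 tau_g - log10 tau_inf)
* the fragility (steepness) index
      m_p = d log10 tau / d(Tg/T) at T = Tg
          = DT0 * Tg / (ln 10 * (Tg - T0)^2).

Secondary (beta, gamma) relaxations in the glass are Arrhenius,
tau(T) = tau_inf exp(Ea / (R T)), fitted by linear regression of ln tau
on 1/T.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitError, ValidationError
from .types import (
    GAS_CONSTANT,
    ArrheniusResult,
    ProcessSeries,
    RelaxationMap,
    VFTResult,
)

logger = logging.getLogger(__name__)

_LOG10E = math.log10(math.e)


def vft_log10_tau(T, log10_tau_inf: float, DT0: float, T0: float) -> np.ndarray:
    """log10 tau(T) of the VFT law (T in kelvin, strictly above T0)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= T0):
        raise ValidationError("all temperatures must exceed T0")
    return log10_tau_inf + DT0 * _LOG10E / (T - T0)


def _tg_closed_form(
    log10_tau_inf: float, DT0: float, T0: float, tau_g: float = 100.0
) -> float:
    lg = math.log10(tau_g)
    if not lg > log10_tau_inf:
        raise ValidationError(
            "tau_g must exceed the high-temperature limit tau_inf of the VFT law"
        )
    return T0 + DT0 * _LOG10E / (lg - log10_tau_inf)


def _fragility_closed_form(
    log10_tau_inf: float, DT0: float, T0: float, Tg: float
) -> float:
    return DT0 * Tg / (math.log(10.0) * (Tg - T0) ** 2)


def tg_from_vft(v: VFTResult, tau_g: float = 100.0) -> float:
    """Glass-transition temperature (K) where the fitted tau_alpha = tau_g."""
    return _tg_closed_form(v.log10_tau_inf, v.DT0, v.T0, tau_g)


def fragility(v: VFTResult, tau_g: float = 100.0) -> float:
    """Fragility index m_p = d log10 tau / d(Tg/T) evaluated at T = Tg."""
    Tg = _tg_closed_form(v.log10_tau_inf, v.DT0, v.T0, tau_g)
    return _fragility_closed_form(v.log10_tau_inf, v.DT0, v.T0, Tg)


def fit_vft(
    temperature: np.ndarray,
    tau: np.ndarray,
    tau_g: float = 100.0,
) -> VFTResult:
    """Nonlinear least-squares VFT fit of a (T, tau_alpha) series.

    Deterministic initialization: T0 is scanned on a coarse grid (for a
    fixed T0 the model is linear in 1/(T - T0), solved by OLS), then the
    best candidate seeds a full 3-parameter refinement with the trust
    region reflective method.  Reports Tg(tau_g) and m_p alongside the
    parameters.
    """
    T = np.asarray(temperature, dtype=float)
    lt = np.log10(np.asarray(tau, dtype=float))
    if len(T) < 4:
        raise ValidationError("VFT fit needs at least 4 points")
    if np.any(np.asarray(tau) <= 0):
        raise ValidationError("relaxation times must be positive")

    t_min = float(T.min())
    best = (math.inf, None)
    for T0 in np.linspace(1.0, t_min - 2.0, 300):
        z = 1.0 / (T - T0)
        A = np.column_stack([np.ones_like(z), z])
        coef, res, *_ = np.linalg.lstsq(A, lt, rcond=None)
        ssr = float(res[0]) if len(res) else float(np.sum((A @ coef - lt) ** 2))
        if ssr < best[0] and coef[1] > 0:
            best = (ssr, (coef[0], coef[1] / _LOG10E, T0))
    if best[1] is None:
        raise FitError("VFT initialization failed: no admissible T0 found")
    lti0, DT00, T00 = best[1]

    def resid(theta):
        lti, DT0, T0 = theta
        return lti + DT0 * _LOG10E / (T - T0) - lt

    sol = least_squares(
        resid,
        x0=[lti0, DT00, T00],
        bounds=([-30.0, 1e-6, 1.0], [0.0, 1e5, t_min - 0.5]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not sol.success:
        raise FitError("VFT fit failed to converge", best_residual=float(sol.cost))
    lti, DT0, T0 = sol.x
    if T0 >= t_min:
        raise FitError(f"fitted T0={T0:.1f} K is not below the data range")
    dof = max(len(T) - 3, 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * 2 * sol.cost / dof
        stderr = {
            name: float(math.sqrt(max(cov[i, i], 0.0)))
            for i, name in enumerate(("log10_tau_inf", "DT0", "T0"))
        }
    except np.linalg.LinAlgError:
        cov, stderr = None, {}
    Tg = _tg_closed_form(lti, DT0, T0, tau_g)
    m_p = _fragility_closed_form(lti, DT0, T0, Tg)
    logger.info("VFT fit: log10 tau_inf=%.2f, T0=%.2f K, DT0=%.0f K, Tg=%.1f K, m_p=%.1f",
                lti, T0, DT0, Tg, m_p)
    return VFTResult(
        log10_tau_inf=float(lti), T0=float(T0), DT0=float(DT0),
        Tg=Tg, m_p=m_p, cov=cov, stderr=stderr,
    )


def fit_arrhenius(temperature: np.ndarray, tau: np.ndarray) -> ArrheniusResult:
    """Arrhenius fit of a secondary-relaxation (T, tau) series.

    Linear regression of ln tau on 1/T; the slope times the gas constant
    is the activation energy, reported in kJ/mol.  Invariant under the
    1/T <-> 1000/T reparameterization.
    """
    T = np.asarray(temperature, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if len(np.unique(T)) < 2:
        raise ValidationError("Arrhenius fit needs at least 2 distinct temperatures")
    if np.any(tau <= 0):
        raise ValidationError("relaxation times must be positive")
    x = 1.0 / T
    y = np.log(tau)
    A = np.column_stack([x, np.ones_like(x)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = coef
    if slope < 0:
        slope = max(slope, 0.0)  # Ea >= 0 by convention; negative slope clips to 0
    cov = None
    stderr = {}
    if len(T) > 2:
        ssr = float(res[0]) if len(res) else float(np.sum((A @ coef - y) ** 2))
        cov_lin = np.linalg.inv(A.T @ A) * ssr / (len(T) - 2)
        cov = cov_lin
        stderr = {
            "ea_kj_mol": float(math.sqrt(max(cov_lin[0, 0], 0.0)) * GAS_CONSTANT / 1e3),
            "log10_tau_inf": float(math.sqrt(max(cov_lin[1, 1], 0.0)) / math.log(10)),
        }
    return ArrheniusResult(
        log10_tau_inf=float(intercept / math.log(10.0)),
        ea_kj_mol=float(slope * GAS_CONSTANT / 1e3),
        cov=cov,
        stderr=stderr,
    )


def assemble_relaxation_map(
    series: list[ProcessSeries],
    model_points: int = 200,
) -> RelaxationMap:
    """Merge alpha + secondary process series into one relaxation map.

    Each series gets a dense model curve sampled from its attached fit
    (VFT for the alpha process, Arrhenius for secondaries).  Duplicate
    process labels are rejected; the alpha process must be present.
    """
    labels = [s.label for s in series]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"overlapping process labels: {labels}")
    if "alpha" not in labels:
        raise ValidationError("the alpha process is required")
    out = {}
    for s in series:
        if s.fit is not None and s.model_log10_tau is None:
            lo, hi = float(s.temperature.min()), float(s.temperature.max())
            if isinstance(s.fit, VFTResult):
                lo = max(lo, s.fit.T0 + 1.0)
                grid = np.linspace(lo, hi, model_points)
                model = vft_log10_tau(grid, s.fit.log10_tau_inf, s.fit.DT0, s.fit.T0)
            else:
                grid = np.linspace(lo, hi, model_points)
                model = (
                    s.fit.log10_tau_inf
                    + s.fit.ea_kj_mol * 1e3 / (GAS_CONSTANT * grid) * _LOG10E
                )
            s.model_temperature = grid
            s.model_log10_tau = model
        out[s.label] = s
    return RelaxationMap(series=out)
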