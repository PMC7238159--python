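"""Dielectric relaxation analysis: Havriliak–Negami fits, master plots, KWW.

The complex permittivity of a supercooled liquid is modelled as a sum of
Havriliak–Negami (HN) processes plus an ohmic dc-conductivity term,

    eps*(w) = eps_inf + sum_k d_eps_k / (1 + (i w tau_k)^a_k)^b_k
              + sigma_dc / (i eps_0 w),

with the sign convention eps* = eps' - i eps''.  The Cole–Cole form is the
b = 1 special case and Debye is a = b = 1.  The loss-peak relaxation time
of one HN process follows the standard peak formula

    tau_max = tau_HN [sin(pi a / (2 + 2b))]^(-1/a) [sin(pi a b / (2 + 2b))]^(1/a),

which is what the structural relaxation time tau_alpha reports.

Master plots implement time–temperature superposition: loss spectra are
shifted horizontally in log-frequency onto a reference spectrum, and the
shape of the merged alpha peak is summarized by the stretching exponent
beta_KWW of the one-sided Fourier transform of the KWW decay
phi(t) = exp(-(t/tau)^beta).
"""

from __future__ import annotations

import logging
import math

import numpy as np
from lmfit import Parameters, minimize as lmfit_minimize
from scipy.integrate import quad
from scipy.optimize import least_squares, minimize_scalar
from scipy.signal import find_peaks

from .exceptions import AnalysisError, FitError, ValidationError
from .types import (
    VACUUM_PERMITTIVITY,
    DielectricSpectrum,
    HNFit,
    HNProcess,
    KWWResult,
    MasterPlot,
    StudyConfig,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# HN model evaluation
# ---------------------------------------------------------------------------

def hn_eps(
    frequency: np.ndarray,
    delta_eps,
    tau_hn,
    a,
    b,
    eps_inf: float = 1.0,
    sigma_dc: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the HN sum for parameter arrays (one entry per process).

    Returns (eps', eps'') with the loss positive; the conductivity term
    contributes sigma_dc / (eps_0 w) to the loss only.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValidationError("frequencies must be positive")
    w = 2.0 * np.pi * f
    eps = np.full_like(f, eps_inf, dtype=complex)
    for de, tau, ai, bi in zip(
        np.atleast_1d(delta_eps), np.atleast_1d(tau_hn),
        np.atleast_1d(a), np.atleast_1d(b),
    ):
        eps = eps + de / (1.0 + (1j * w * tau) ** ai) ** bi
    loss = -eps.imag
    if sigma_dc > 0:
        loss = loss + sigma_dc / (VACUUM_PERMITTIVITY * w)
    return eps.real, loss


def hn_model(frequency: np.ndarray, fit: HNFit) -> tuple[np.ndarray, np.ndarray]:
    """Model eps', eps'' of a fitted spectrum on an arbitrary frequency grid."""
    return hn_eps(
        frequency,
        [p.delta_eps for p in fit.processes],
        [p.tau_hn for p in fit.processes],
        [p.a for p in fit.processes],
        [p.b for p in fit.processes],
        eps_inf=fit.eps_inf,
        sigma_dc=fit.sigma_dc,
    )


def tau_max_from_hn(p: HNProcess) -> float:
    """Loss-peak relaxation time of a single HN process.

    tau_max = tau_HN [sin(pi a/(2+2b))]^(-1/a) [sin(pi a b/(2+2b))]^(1/a).
    Reduces to tau_HN for b = 1 (Cole–Cole, symmetric peak) and hence for
    Debye.
    """
    arg = math.pi / (2.0 + 2.0 * p.b)
    return (
        p.tau_hn
        * math.sin(arg * p.a) ** (-1.0 / p.a)
        * math.sin(arg * p.a * p.b) ** (1.0 / p.a)
    )


def dielectric_strength(fit: HNFit, process: int = 0) -> float:
    """Dielectric strength d_eps of one fitted process (for, e.g., reporting
    the (beta_KWW, d_eps) anticorrelation pair)."""
    if not 0 <= process < len(fit.processes):
        raise ValidationError(f"process index {process} out of range")
    return fit.processes[process].delta_eps


# ---------------------------------------------------------------------------
# HN fitting
# ---------------------------------------------------------------------------

def _loss_peak_logf(spectrum: DielectricSpectrum, order: int = 1) -> list[float]:
    """Log10 frequencies of up to ``order`` interior loss maxima (largest first)."""
    logloss = np.log10(np.maximum(spectrum.eps_imag, 1e-300))
    idx, _ = find_peaks(logloss)
    idx = sorted(idx, key=lambda i: -logloss[i])[:order]
    return [float(np.log10(spectrum.frequency[i])) for i in idx]


def fit_hn(
    spectrum: DielectricSpectrum,
    n_processes: int = 1,
    include_conductivity: bool = True,
    include_real: bool = False,
    cole_cole: bool = False,
    init: dict | None = None,
    bounds: dict | None = None,
    config: StudyConfig | None = None,
    degenerate_threshold: float = 0.05,
) -> HNFit:
    """Fit a dielectric spectrum with ``n_processes`` HN terms (+ dc term).

    The objective is least squares on log10 eps'' over the measured grid
    (decades-spanning loss peaks), optionally joined by log10 eps'.  Eight
    randomized multi-starts (seeded from the configuration) guard against
    local minima; the best residual wins, ties broken by the smaller
    parameter-vector norm.  With ``cole_cole=True`` every asymmetry
    exponent b is fixed at 1.

    Returned processes are sorted slow-to-fast (descending tau_HN); a
    process whose peak loss contribution over the measured window falls
    below ``degenerate_threshold`` of the strongest process's peak, or
    whose loss peak coincides with a stronger process's, is flagged in
    ``degenerate`` — the model-selection guard against asking for more
    processes than the spectrum resolves (a redundant process collapses
    onto a ridge: negligible loss with arbitrary strength, or a duplicate
    sharing the stronger process's peak).
    """
    config = config or StudyConfig()
    init = init or {}
    bounds = dict(config.fit_bounds, **(bounds or {}))
    f = spectrum.frequency
    loss = spectrum.eps_imag
    if np.any(loss <= 0):
        raise AnalysisError("loss spectrum must be strictly positive to fit in log space")
    lf_min, lf_max = math.log10(f[0]), math.log10(f[-1])

    # data-driven base initialization
    peaks = _loss_peak_logf(spectrum, n_processes)
    while len(peaks) < n_processes:
        k = len(peaks)
        peaks.append(lf_min + (k + 1) * (lf_max - lf_min) / (n_processes + 1))
    peaks = sorted(peaks)  # ascending frequency = descending tau
    base = {}
    for k, lfpk in enumerate(peaks):
        height = float(np.interp(lfpk, np.log10(f), loss))
        base[f"de{k}"] = init.get(f"de{k}", max(2.0 * height, 1e-3))
        base[f"ltau{k}"] = init.get(f"ltau{k}", -lfpk - math.log10(2 * math.pi))
        base[f"a{k}"] = init.get(f"a{k}", 0.8)
        base[f"b{k}"] = init.get(f"b{k}", 1.0 if cole_cole else 0.8)
    eps_inf_data = float(np.min(spectrum.eps_real))
    sigma_init = init.get(
        "lsigma",
        math.log10(
            max(loss[0] * VACUUM_PERMITTIVITY * 2 * math.pi * f[0] * 0.5, 1e-15)
        ),
    )

    def make_params(rng: np.random.Generator | None) -> Parameters:
        params = Parameters()
        for k in range(n_processes):
            de, ltau = base[f"de{k}"], base[f"ltau{k}"]
            if rng is not None:
                de = de * math.exp(rng.normal(0, 0.3))
                ltau = ltau + rng.normal(0, 0.5)
            lo, hi = bounds.get(f"de{k}", (1e-6, 1e6))
            params.add(f"de{k}", value=min(max(de, lo), hi), min=lo, max=hi)
            lo, hi = bounds.get(f"ltau{k}", (-lf_max - 4, -lf_min + 4))
            params.add(f"ltau{k}", value=min(max(ltau, lo), hi), min=lo, max=hi)
            lo, hi = bounds.get(f"a{k}", (0.05, 1.0))
            params.add(f"a{k}", value=base[f"a{k}"], min=lo, max=hi)
            if cole_cole:
                params.add(f"b{k}", value=1.0, vary=False)
            else:
                lo, hi = bounds.get(f"b{k}", (0.05, 1.0))
                params.add(f"b{k}", value=base[f"b{k}"], min=lo, max=hi)
        params.add(
            "eps_inf",
            value=init.get("eps_inf", max(eps_inf_data, 1.0)),
            min=1.0,
            max=max(10.0 * eps_inf_data, 100.0),
            vary=include_real,
        )
        params.add("lsigma", value=sigma_init, min=-16.0, max=2.0,
                   vary=include_conductivity)
        return params

    def residual(params: Parameters) -> np.ndarray:
        de = [params[f"de{k}"].value for k in range(n_processes)]
        tau = [10.0 ** params[f"ltau{k}"].value for k in range(n_processes)]
        a = [params[f"a{k}"].value for k in range(n_processes)]
        b = [params[f"b{k}"].value for k in range(n_processes)]
        sig = 10.0 ** params["lsigma"].value if include_conductivity else 0.0
        er, ei = hn_eps(f, de, tau, a, b, eps_inf=params["eps_inf"].value, sigma_dc=sig)
        res = np.log10(np.maximum(ei, 1e-300)) - np.log10(loss)
        if include_real:
            res = np.concatenate([
                res,
                np.log10(np.maximum(er, 1e-300)) - np.log10(spectrum.eps_real),
            ])
        return res

    rng = np.random.default_rng(config.seed)
    best = None
    best_key = (math.inf, math.inf)
    for start in range(config.n_starts):
        params = make_params(None if start == 0 else rng)
        try:
            result = lmfit_minimize(residual, params, method="leastsq")
        except Exception:  # singular Jacobian etc. on a bad start
            continue
        chi = float(np.sum(result.residual**2))
        pnorm = float(np.linalg.norm([p.value for p in result.params.values()]))
        if (chi, pnorm) < best_key:
            best_key = (chi, pnorm)
            best = result
    if best is None:
        raise FitError("HN fit failed to converge from any start")

    p = best.params
    order = sorted(range(n_processes), key=lambda k: -p[f"ltau{k}"].value)
    processes = [
        HNProcess(
            delta_eps=p[f"de{k}"].value,
            tau_hn=10.0 ** p[f"ltau{k}"].value,
            a=p[f"a{k}"].value,
            b=p[f"b{k}"].value,
        )
        for k in order
    ]
    peak_contrib = [
        float(np.max(hn_eps(f, [pr.delta_eps], [pr.tau_hn], [pr.a], [pr.b])[1]))
        for pr in processes
    ]
    flagged = set(
        i for i, c in enumerate(peak_contrib)
        if c < degenerate_threshold * max(peak_contrib)
    )
    # a process sitting on top of a stronger one (same loss-peak position
    # within a third of a decade) is an unresolved duplicate, not a second
    # relaxation
    tmx = [tau_max_from_hn(pr) for pr in processes]
    for i in range(len(processes)):
        for j in range(len(processes)):
            if i != j and abs(math.log10(tmx[i] / tmx[j])) < 0.33:
                if peak_contrib[i] < peak_contrib[j]:
                    flagged.add(i)
    degenerate = tuple(sorted(flagged))
    if degenerate:
        logger.info("degenerate HN process(es) %s: strength below %.3g of largest",
                    degenerate, degenerate_threshold)
    stderr = {
        name: (p[name].stderr if p[name].stderr is not None else float("nan"))
        for name in p
        if p[name].vary
    }
    return HNFit(
        processes=processes,
        eps_inf=p["eps_inf"].value if include_real else max(eps_inf_data, 1.0),
        sigma_dc=10.0 ** p["lsigma"].value if include_conductivity else 0.0,
        tau_max=[tau_max_from_hn(pr) for pr in processes],
        residual_norm=math.sqrt(best_key[0]),
        stderr=stderr,
        degenerate=degenerate,
        temperature=spectrum.temperature,
        elapsed_time=spectrum.elapsed_time,
    )


def fit_secondary_cole_cole(
    spectrum: DielectricSpectrum,
    n_processes: int = 2,
    include_conductivity: bool = False,
    init: dict | None = None,
    bounds: dict | None = None,
    config: StudyConfig | None = None,
) -> HNFit:
    """Fit a sub-Tg spectrum with Cole–Cole processes (HN with b = 1).

    The default models the two secondary relaxations (beta and gamma) seen
    in glassy drugs; conductivity is off by default below Tg.  Output
    ordering is slow-to-fast, so process 0 is beta and process 1 is gamma.
    """
    return fit_hn(
        spectrum,
        n_processes=n_processes,
        include_conductivity=include_conductivity,
        cole_cole=True,
        init=init,
        bounds=bounds,
        config=config,
    )


# ---------------------------------------------------------------------------
# Master plots (time–temperature superposition)
# ---------------------------------------------------------------------------

def _peak_logf(logf: np.ndarray, logloss: np.ndarray) -> float:
    """Interior loss-peak position in log10 f, parabolic refinement."""
    i = int(np.argmax(logloss))
    if i == 0 or i == len(logloss) - 1:
        raise AnalysisError("loss maximum at the frequency-grid boundary")
    y0, y1, y2 = logloss[i - 1], logloss[i], logloss[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(logf[i])
    return float(logf[i] + 0.5 * (y0 - y2) / denom * (logf[i + 1] - logf[i]))


def build_master_plot(
    spectra: list[DielectricSpectrum],
    T_ref: float,
    min_overlap: int = 5,
) -> MasterPlot:
    """Superimpose a temperature series of loss spectra onto the reference.

    Each spectrum is shifted horizontally in log-frequency to minimize the
    mean-square log-loss mismatch with the reference over the overlapping
    support (linear interpolation in log-log space; 1-D bounded
    minimization per spectrum, walking outward from the temperature
    nearest the reference).  No vertical shift is fitted — raw loss
    amplitudes enter the mismatch; the merged curve is normalized by the
    reference peak value only.
    """
    if len(spectra) < 3:
        raise AnalysisError("master plot needs at least 3 spectra")
    ref = min(spectra, key=lambda s: abs(s.temperature - T_ref))
    if abs(ref.temperature - T_ref) > 0.5:
        raise AnalysisError(f"no spectrum at the reference temperature {T_ref} K")

    def logloss(sp: DielectricSpectrum) -> tuple[np.ndarray, np.ndarray]:
        return np.log10(sp.frequency), np.log10(np.maximum(sp.eps_imag, 1e-300))

    ref_logf, ref_ll = logloss(ref)
    ref_peak = _peak_logf(ref_logf, ref_ll)
    ref_peak_ll = float(np.interp(ref_peak, ref_logf, ref_ll))
    shifts: dict[float, float] = {ref.temperature: 0.0}
    merged_f = [ref_logf - ref_peak]
    merged_l = [ref_ll - ref_peak_ll]

    others = sorted(
        (s for s in spectra if s is not ref),
        key=lambda s: abs(s.temperature - ref.temperature),
    )
    for sp in others:
        logf, ll = logloss(sp)

        def mismatch(s: float) -> float:
            lf = logf + s
            ov = (lf >= ref_logf[0]) & (lf <= ref_logf[-1])
            if int(ov.sum()) < min_overlap:
                return 1e6
            return float(np.mean((ll[ov] - np.interp(lf[ov], ref_logf, ref_ll)) ** 2))

        try:
            guess = ref_peak - _peak_logf(logf, ll)
        except AnalysisError:
            # loss peak outside the measured window (spectra close to Tg):
            # coarse scan of the overlap residual seeds the refinement
            grid = np.arange(-8.0, 8.01, 0.25)
            guess = float(grid[int(np.argmin([mismatch(s) for s in grid]))])

        res = minimize_scalar(
            mismatch, bounds=(guess - 1.0, guess + 1.0), method="bounded",
            options={"xatol": 1e-5},
        )
        if mismatch(res.x) >= 1e6:
            raise AnalysisError(
                f"spectrum at {sp.temperature} K has no overlap with the reference "
                "after shifting"
            )
        shifts[sp.temperature] = float(res.x)
        merged_f.append(logf + res.x - ref_peak)
        merged_l.append(ll - ref_peak_ll)

    mf = np.concatenate(merged_f)
    ml = np.concatenate(merged_l)
    order = np.argsort(mf)
    # collapse duplicate reduced frequencies (same grid, integer-decade shifts)
    mf, ml = mf[order], ml[order]
    uniq = np.concatenate([[True], np.diff(mf) > 1e-12])
    return MasterPlot(
        reference_temperature=ref.temperature,
        shifts=shifts,
        freq_reduced=10.0 ** mf[uniq],
        loss_norm=10.0 ** ml[uniq],
        f_max_ref=10.0**ref_peak,
    )


# ---------------------------------------------------------------------------
# KWW transform
# ---------------------------------------------------------------------------

def _kww_loss_raw(x: float, beta: float) -> float:
    """Unnormalized KWW loss at x = omega * tau.

    eps''(x) propto int_0^inf beta u^(beta-1) exp(-u^beta) sin(x u) du
    (u = t/tau substitution).  Three-piece evaluation splitting at the
    first oscillation node u1 = 2 pi / x and at u = 1:

    * [0, u1]: substitution v = u^beta removes the integrable endpoint
      singularity; at most one oscillation, plain adaptive quadrature;
    * [u1, 1]: oscillatory-weighted (QAWO) rule, singularity excluded;
    * [1, inf): infinite-interval Fourier (QAWF) rule.

    Outside x in [1e-6, 1e6] the convergent low-frequency and asymptotic
    high-frequency expansions take over (relative error < 1e-6 at the
    crossover points).
    """
    from scipy.special import gamma as _gamma

    if x < 1e-6:  # eps'' ~ x * <u> - x^3 <u^3>/6, truncation error O(x^5)
        return x * _gamma(1.0 + 1.0 / beta) - x**3 * _gamma(1.0 + 3.0 / beta) / 6.0
    if x > 1e6:  # Watson-lemma asymptotic series in x^(-k beta)
        total, k = 0.0, 1
        prev = math.inf
        while k <= 10:
            term = ((-1) ** (k + 1) * _gamma(1.0 + k * beta)
                    * math.sin(math.pi * k * beta / 2.0)
                    / (math.factorial(k) * x ** (k * beta)))
            if abs(term) >= prev:  # divergent tail reached
                break
            total += term
            prev = abs(term)
            k += 1
        return total

    def amp(u: float) -> float:
        return beta * u ** (beta - 1.0) * math.exp(-(u**beta))

    u1 = min(2.0 * math.pi / x, 1.0)
    v1 = u1**beta
    part_a, _ = quad(
        lambda v: math.exp(-v) * math.sin(x * v ** (1.0 / beta)),
        0.0, v1, limit=200, epsabs=1e-12, epsrel=1e-10,
    )
    part_b = 0.0
    if u1 < 1.0:
        part_b, _ = quad(amp, u1, 1.0, weight="sin", wvar=x, limit=500,
                         epsabs=1e-12, epsrel=1e-10)
    # tail: the Fourier rule needs the integrand to decay within a few
    # oscillation cycles; when one cycle outlasts the decay range the
    # integrand is effectively non-oscillatory and the v = u^beta
    # substitution gives a smooth finite integral instead
    u_decay = 37.0 ** (1.0 / beta)  # exp(-u^beta) ~ 1e-16 beyond this
    if x * u_decay <= math.pi:
        part_c, _ = quad(
            lambda v: math.exp(-v) * math.sin(x * v ** (1.0 / beta)),
            1.0, 38.0, limit=200, epsabs=1e-14, epsrel=1e-10,
        )
    else:
        part_c, _ = quad(amp, 1.0, np.inf, weight="sin", wvar=x, limit=500,
                         epsabs=1e-12)
    return part_a + part_b + part_c


def _kww_peak_x(beta: float) -> tuple[float, float]:
    """Position and value of the KWW loss maximum in x = omega*tau."""
    res = minimize_scalar(
        lambda lx: -_kww_loss_raw(math.exp(lx), beta),
        bounds=(-3.0, 3.0), method="bounded", options={"xatol": 1e-8},
    )
    return math.exp(res.x), -res.fun


def kww_loss(omega: np.ndarray, tau_k: float, beta: float) -> np.ndarray:
    """Normalized KWW loss curve on an angular-frequency grid.

    The one-sided Fourier sine transform of -d/dt exp(-(t/tau)^beta),
    normalized to unit peak (true continuum peak, not the grid maximum).
    beta = 1 reproduces the Debye loss 2*x/(1+x^2) with x = omega*tau.
    """
    if not 0 < beta <= 1:
        raise ValidationError("beta must lie in (0, 1]")
    if not tau_k > 0:
        raise ValidationError("tau_k must be positive")
    omega = np.asarray(omega, dtype=float)
    values = np.array([_kww_loss_raw(x, beta) for x in omega * tau_k])
    _, peak = _kww_peak_x(beta)
    return values / peak


def fit_kww(
    master: MasterPlot,
    beta_init: float = 0.6,
    beta_bounds: tuple[float, float] = (0.2, 1.0),
    loss_floor: float = 1e-3,
) -> KWWResult:
    """Fit (beta_KWW, tau_KWW) to a master curve.

    Least squares on log10 of the peak-normalized loss; points below
    ``loss_floor`` (deep wings) are excluded.  The model curve is the KWW
    loss evaluated on a dense log grid in omega*tau and interpolated
    log-log onto the data, normalized the same way as the data (unit
    maximum over the fitted points).  tau_KWW is reported in seconds using
    the reference-spectrum peak frequency.
    """
    x = master.freq_reduced
    y = master.loss_norm
    keep = y >= loss_floor
    if int(keep.sum()) < 10:
        raise AnalysisError("master curve has too few points above the loss floor")
    x, y = x[keep], y[keep]
    logy = np.log10(y)

    def model_logy(theta: np.ndarray) -> np.ndarray:
        beta, ltau = theta
        u = 2.0 * np.pi * x * 10.0**ltau  # omega * tau in reduced units
        lu = np.log10(u)
        nodes = np.linspace(lu.min() - 0.05, lu.max() + 0.05,
                            max(int((lu.max() - lu.min()) * 12) + 2, 24))
        kn = np.log10([max(_kww_loss_raw(10.0**v, beta), 1e-300) for v in nodes])
        ly = np.interp(lu, nodes, kn)
        return ly - ly.max()

    def resid(theta: np.ndarray) -> np.ndarray:
        return model_logy(theta) - (logy - logy.max())

    # initial reduced tau: peak of the data sits near omega*tau = x_peak(beta)
    x0, _ = _kww_peak_x(beta_init)
    ltau0 = math.log10(x0 / (2.0 * math.pi))
    sol = least_squares(
        resid, x0=[beta_init, ltau0],
        bounds=([beta_bounds[0], ltau0 - 2], [beta_bounds[1], ltau0 + 2]),
        xtol=1e-10, ftol=1e-12,
    )
    if not sol.success:
        raise FitError("KWW fit failed to converge", best_residual=float(sol.cost))
    beta, ltau = sol.x
    # delta-method stderr on beta from the Jacobian
    beta_se = None
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(len(sol.fun) - 2, 1)
        cov = np.linalg.inv(jtj) * 2 * sol.cost / dof
        beta_se = float(math.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        pass
    tau_seconds = 10.0**ltau / master.f_max_ref
    return KWWResult(
        beta_kww=float(beta),
        tau_kww=float(tau_seconds),
        reference_temperature=master.reference_temperature,
        shift_factors=dict(master.shifts),
        beta_stderr=beta_se,
    )
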