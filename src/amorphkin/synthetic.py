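"""Synthetic-data generators with known ground truth.

Every downstream stage of the package is testable without instrument
exports: these generators emit DSC thermograms, dielectric spectra series
and dCp composition tables from known parameters, so analysis results can
be compared against the truth that produced them.

The kinetic ground truth is the Avrami law

    alpha(t) = 1 - exp(-((t - t0)/tau_cr)^n),  t > t0,

the unique sigmoid for which the Avramov constructions are exact: the
maximum of d(alpha)/d ln(t - t0) sits at t - t0 = tau_cr with value n/e,
and the tangent there spans exactly e/n on the ln-time axis.

Default parameter sets (`STUDY`) encode the reference study conditions
for amorphous simvastatin (SVT), neat and mixed with 9 wt.% of two
mesoporous-silica excipients (Syloid 244 and Syloid 3050), crystallized
isothermally at 363 K and probed dielectrically over 0.1 Hz – 1 MHz.

Every generator is a pure function of (truth, seed): the same inputs
yield a bit-identical output.  Noise models are additive Gaussian on
heat flow and multiplicative log-normal on permittivities (instrument-like
and positivity-preserving).
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError
from .relaxation import _kww_loss_raw, _kww_peak_x, hn_eps
from .types import (
    ArrheniusParams,
    CpPoint,
    DielectricSpectrum,
    HNProcess,
    KineticTruth,
    SpectralTruth,
    Thermogram,
    VFTParams,
)

#: Default broadband frequency grid: 8 points/decade over 0.1 Hz – 1 MHz.
DEFAULT_FREQ_GRID = np.logspace(-1, 6, 57)

#: Reference study conditions: isothermal crystallization truths (363 K),
#: VFT parameters of the structural relaxation, and silica loading
#: capacities, for neat SVT and its 9 wt.% silica mixtures.
STUDY = {
    "dsc_neat": KineticTruth(n=3.8, tau_cr_s=55 * 60.0, t0_s=8800.0),
    "dsc_syl3050": KineticTruth(n=1.8, tau_cr_s=107 * 60.0, t0_s=9150.0),
    "bds_neat": KineticTruth(n=2.34, tau_cr_s=201 * 60.0, t0_s=13600.0),
    "bds_syl3050": KineticTruth(n=1.026, tau_cr_s=737 * 60.0, t0_s=29750.0),
    "vft_neat": VFTParams(log10_tau_inf=-15.68, T0=244.01, DT0=2386.0),
    "vft_syl3050": VFTParams(log10_tau_inf=-15.23, T0=246.23, DT0=2240.0),
    "vft_syl244": VFTParams(log10_tau_inf=-15.18, T0=247.64, DT0=2183.0),
    "capacity_syl244": 84.3,  # wt.% MS
    "capacity_syl3050": 83.4,
    "delta_eps_alpha": 8.9,
    "beta_kww": 0.60,
}


def avrami_alpha(t, n: float, tau_cr_s: float, t0_s: float = 0.0) -> np.ndarray:
    """Avrami relative crystallinity alpha(t); 0 for t <= t0."""
    t = np.asarray(t, dtype=float)
    x = t - t0_s
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = 1.0 - np.exp(-((x[pos] / tau_cr_s) ** n))
    return out


def avrami_rate(t, n: float, tau_cr_s: float, t0_s: float = 0.0) -> np.ndarray:
    """d(alpha)/dt of the Avrami law; 0 for t <= t0 (singular there if n < 1)."""
    t = np.asarray(t, dtype=float)
    x = t - t0_s
    out = np.zeros_like(x)
    pos = x > 0
    z = (x[pos] / tau_cr_s) ** n
    out[pos] = (n / tau_cr_s) * (x[pos] / tau_cr_s) ** (n - 1.0) * np.exp(-z)
    return out


def gen_dsc_isothermal(
    truth: KineticTruth,
    sampling_dt: float,
    duration: float,
    seed: int = 0,
    temperature: float = 363.0,
) -> Thermogram:
    """Synthetic isothermal DSC thermogram of Avrami crystallization.

    heat_flow(t) = total_enthalpy * d(alpha)/dt + N(0, noise_sd); the
    noiseless exotherm integrates to the total enthalpy.  A duration of
    at least t0 + 5 tau_cr is recommended so the exotherm completes.
    """
    if sampling_dt <= 0:
        raise ValidationError("sampling_dt must be positive")
    t = np.arange(0.0, duration + sampling_dt / 2, sampling_dt)
    hf = truth.total_enthalpy_mj * avrami_rate(t, truth.n, truth.tau_cr_s, truth.t0_s)
    if truth.noise_sd_mw > 0:
        rng = np.random.default_rng(seed)
        hf = hf + rng.normal(0.0, truth.noise_sd_mw, size=hf.shape)
    return Thermogram(
        time=t, heat_flow=hf, temperature=temperature,
        label=f"synthetic Avrami n={truth.n} tau={truth.tau_cr_s:.0f}s",
    )


def _spectrum_from_params(
    freq, de, tau, a, b, eps_inf, sigma_dc, noise_sd, rng, **tags
) -> DielectricSpectrum:
    er, ei = hn_eps(freq, de, tau, a, b, eps_inf=eps_inf, sigma_dc=sigma_dc)
    if noise_sd > 0:
        er = er * np.exp(rng.normal(0.0, noise_sd, size=er.shape))
        ei = ei * np.exp(rng.normal(0.0, noise_sd, size=ei.shape))
    return DielectricSpectrum(frequency=freq, eps_real=er, eps_imag=ei, **tags)


def gen_bds_crystallization_series(
    truth: SpectralTruth,
    kinetic: KineticTruth,
    interval: float = 300.0,
    n_spectra: int = 289,
    seed: int = 0,
    freq: np.ndarray | None = None,
    temperature: float = 363.0,
) -> list[DielectricSpectrum]:
    """Dielectric spectra sampled every ``interval`` s during crystallization.

    The structural-process strength decays with the crystalline fraction,
    d_eps(t) = d_eps * (1 - alpha(t)); every other parameter stays fixed.
    The default cadence (300 s) and count (289 spectra = 24 h) mirror an
    overnight isothermal hold.
    """
    if interval <= 0:
        raise ValidationError("interval must be positive")
    if n_spectra < 2:
        raise ValidationError("need at least 2 spectra")
    freq = DEFAULT_FREQ_GRID if freq is None else np.asarray(freq, dtype=float)
    rng = np.random.default_rng(seed)
    times = np.arange(n_spectra) * interval
    alpha = avrami_alpha(times, kinetic.n, kinetic.tau_cr_s, kinetic.t0_s)
    out = []
    for t_k, a_k in zip(times, alpha):
        de = [max(truth.processes[0].delta_eps * (1.0 - a_k), 1e-12)]
        de += [p.delta_eps for p in truth.processes[1:]]
        out.append(
            _spectrum_from_params(
                freq,
                de,
                [p.tau_hn for p in truth.processes],
                [p.a for p in truth.processes],
                [p.b for p in truth.processes],
                truth.eps_inf, truth.sigma_dc, truth.noise_sd, rng,
                temperature=temperature, elapsed_time=float(t_k),
            )
        )
    return out


def gen_bds_temperature_series(
    truth: SpectralTruth,
    vft: VFTParams | None,
    temps: list[float],
    secondary: tuple[tuple[HNProcess, ArrheniusParams], ...] = (),
    seed: int = 0,
    freq: np.ndarray | None = None,
) -> list[DielectricSpectrum]:
    """Temperature series of dielectric spectra.

    The first process of ``truth`` is the structural (alpha) relaxation:
    its shape (d_eps, a, b) is kept while tau_HN(T) follows the VFT law.
    Optional secondary Cole–Cole processes follow Arrhenius laws with the
    given activation energies.  With ``vft=None`` only the secondary
    processes are generated (a sub-Tg series).
    """
    freq = DEFAULT_FREQ_GRID if freq is None else np.asarray(freq, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for T in temps:
        de, tau, a, b = [], [], [], []
        if vft is not None:
            p0 = truth.processes[0]
            de.append(p0.delta_eps)
            tau.append(float(vft.tau(T)))  # raises if T <= T0
            a.append(p0.a)
            b.append(p0.b)
        for proc, law in secondary:
            de.append(proc.delta_eps)
            tau.append(float(law.tau(T)))
            a.append(proc.a)
            b.append(proc.b)
        if not de:
            raise ValidationError("no processes to generate")
        out.append(
            _spectrum_from_params(
                freq, de, tau, a, b,
                truth.eps_inf, truth.sigma_dc, truth.noise_sd, rng,
                temperature=float(T),
            )
        )
    return out


def gen_kww_temperature_series(
    delta_eps: float,
    beta: float,
    vft: VFTParams,
    temps: list[float],
    seed: int = 0,
    freq: np.ndarray | None = None,
    eps_inf: float = 3.0,
    noise_sd: float = 0.0,
) -> list[DielectricSpectrum]:
    """Temperature series whose loss peak has an exact KWW shape.

    The loss is delta_eps times the unit-peak KWW loss evaluated at
    omega * tau(T), with tau(T) on the VFT law — i.e. a perfectly
    time–temperature-superposable series for master-plot and beta_KWW
    recovery studies.  eps' is filled with the flat eps_inf placeholder
    (the KWW chain only consumes the loss).
    """
    if not 0 < beta <= 1:
        raise ValidationError("beta must lie in (0, 1]")
    freq = DEFAULT_FREQ_GRID if freq is None else np.asarray(freq, dtype=float)
    rng = np.random.default_rng(seed)
    taus = vft.tau(np.asarray(temps, dtype=float))
    # one dense shape table in x = omega*tau, shared across temperatures
    x_lo = 2 * np.pi * freq[0] * taus.min()
    x_hi = 2 * np.pi * freq[-1] * taus.max()
    nodes = np.linspace(np.log10(x_lo) - 0.05, np.log10(x_hi) + 0.05,
                        int((np.log10(x_hi) - np.log10(x_lo)) * 16) + 2)
    table = np.log10([max(_kww_loss_raw(10.0**v, beta), 1e-300) for v in nodes])
    _, peak = _kww_peak_x(beta)
    out = []
    for T, tau in zip(temps, taus):
        lx = np.log10(2 * np.pi * freq * tau)
        loss = delta_eps * 10.0 ** np.interp(lx, nodes, table) / peak
        er = np.full_like(freq, eps_inf)
        if noise_sd > 0:
            loss = loss * np.exp(rng.normal(0.0, noise_sd, size=loss.shape))
        out.append(
            DielectricSpectrum(
                frequency=freq, eps_real=er, eps_imag=loss, temperature=float(T)
            )
        )
    return out


def gen_dcp_table(
    capacity_ms_wtpct: float,
    dcp_pure: float = 0.4,
    drug_loads: tuple[float, ...] = (50.0, 55.0, 64.0, 73.0, 82.0, 91.0, 100.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[CpPoint]:
    """Synthetic dCp-vs-composition table with an adsorbed immobile fraction.

    dCp(w) is linear in the drug load w, zero at the breakpoint
    w* = 100 - capacity (all drug adsorbed) and clipped at 0 below it;
    dCp(100) equals the neat-drug step ``dcp_pure``.  ``noise_sd`` is
    Gaussian, relative to the neat-drug step.
    """
    if not 0 < capacity_ms_wtpct < 100:
        if capacity_ms_wtpct == 100.0:
            pass  # no-adsorption limit: line through the origin
        else:
            raise ValidationError("capacity must lie in (0, 100] wt.%")
    if any(not 0 < w <= 100 for w in drug_loads):
        raise ValidationError("drug loads must lie in (0, 100] wt.%")
    rng = np.random.default_rng(seed)
    w_star = 100.0 - capacity_ms_wtpct
    points = []
    for w in drug_loads:
        dcp = dcp_pure * (w - w_star) / (100.0 - w_star) if w > w_star else 0.0
        if noise_sd > 0:
            dcp += rng.normal(0.0, noise_sd * dcp_pure)
        points.append(CpPoint(drug_load=float(w), delta_cp=max(dcp, 0.0)))
    return points
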