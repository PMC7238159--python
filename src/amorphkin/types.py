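"""Domain containers shared by every analysis stage.

The containers are plain dataclasses holding numpy arrays / floats with
invariant checks in ``__post_init__``.  Array fields are coerced to
contiguous float64 arrays on construction.  All internal units are SI
(seconds, kelvin, Hz, J); the characteristic crystallization time is
additionally reported in minutes because that is how the quantity is
conventionally tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .exceptions import ValidationError

GAS_CONSTANT = 8.314  # J/(mol K)
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

#: Conventional rounded factor n = alpha'_max / 0.368 (the exact value is 1/e).
AVRAMOV_DERIVATIVE_FACTOR = 0.368


def _as_array(x, name: str) -> np.ndarray:
    arr = np.ascontiguousarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def _check_equal_length(**arrays: np.ndarray) -> None:
    lengths = {k: len(v) for k, v in arrays.items()}
    if len(set(lengths.values())) > 1:
        raise ValidationError(f"array fields must have equal length, got {lengths}")


def _check_strictly_increasing(arr: np.ndarray, name: str) -> None:
    if len(arr) > 1 and not np.all(np.diff(arr) > 0):
        raise ValidationError(f"{name} must be strictly increasing")


@dataclass
class Thermogram:
    """Isothermal DSC trace: heat evolution rate vs time.

    Exothermic heat flow is stored positive, so the crystallization
    exotherm integrates to a positive enthalpy.
    """

    time: np.ndarray  # s, strictly increasing
    heat_flow: np.ndarray  # mW, exothermic positive
    temperature: float = 363.0  # K, constant for an isothermal run
    label: str = ""

    def __post_init__(self) -> None:
        self.time = _as_array(self.time, "time")
        self.heat_flow = _as_array(self.heat_flow, "heat_flow")
        _check_equal_length(time=self.time, heat_flow=self.heat_flow)
        _check_strictly_increasing(self.time, "time")
        if not self.temperature > 0:
            raise ValidationError("temperature must be positive (kelvin)")


@dataclass
class DielectricSpectrum:
    """One broadband dielectric spectrum: eps* = eps' - i eps'' on a frequency grid."""

    frequency: np.ndarray  # Hz, strictly increasing, > 0
    eps_real: np.ndarray
    eps_imag: np.ndarray  # loss, >= 0 by sign convention
    temperature: float = 363.0  # K
    elapsed_time: float | None = None  # s since start of isothermal hold

    def __post_init__(self) -> None:
        self.frequency = _as_array(self.frequency, "frequency")
        self.eps_real = _as_array(self.eps_real, "eps_real")
        self.eps_imag = _as_array(self.eps_imag, "eps_imag")
        _check_equal_length(
            frequency=self.frequency, eps_real=self.eps_real, eps_imag=self.eps_imag
        )
        _check_strictly_increasing(self.frequency, "frequency")
        if np.any(self.frequency <= 0):
            raise ValidationError("frequency must be positive")
        if not self.temperature > 0:
            raise ValidationError("temperature must be positive (kelvin)")


@dataclass
class KineticCurve:
    """Relative crystallinity alpha(t) from either the DSC or the BDS route."""

    time: np.ndarray  # s
    alpha: np.ndarray  # in [0, 1]
    t0: float = 0.0  # induction time, s (0 for a raw, uncorrected curve)
    source: Literal["DSC", "BDS"] = "DSC"

    def __post_init__(self) -> None:
        self.time = _as_array(self.time, "time")
        self.alpha = _as_array(self.alpha, "alpha")
        _check_equal_length(time=self.time, alpha=self.alpha)
        _check_strictly_increasing(self.time, "time")
        if np.any(self.alpha < -1e-9) or np.any(self.alpha > 1 + 1e-9):
            raise ValidationError("alpha must lie in [0, 1] (tolerance 1e-9)")
        self.alpha = np.clip(self.alpha, 0.0, 1.0)
        if self.t0 < 0:
            raise ValidationError("induction time t0 must be >= 0")
        if self.source not in ("DSC", "BDS"):
            raise ValidationError(f"source must be 'DSC' or 'BDS', got {self.source!r}")


@dataclass
class AvramovResult:
    """Full Avrami–Avramov characterization of one isothermal kinetic curve."""

    t0_s: float  # induction time
    tau_cr_s: float  # characteristic crystallization time
    tau_cr_min: float  # same, in minutes (conventional reporting unit)
    alpha_prime_max: float  # max of d(alpha)/d ln(t - t0)
    n_derivative: float  # n from the derivative maximum
    n_tangent: float  # n from the tangent construction
    ln_t1: float  # tangent intercept with alpha = 0 (ln seconds)
    ln_t2: float  # tangent intercept with alpha = 1 (ln seconds)
    source: Literal["DSC", "BDS"] = "DSC"

    def __post_init__(self) -> None:
        if not self.tau_cr_s > 0:
            raise ValidationError("tau_cr must be positive")
        if not self.ln_t2 > self.ln_t1:
            raise ValidationError("ln_t2 must exceed ln_t1")
        if not (self.n_derivative > 0 and self.n_tangent > 0):
            raise ValidationError("both n estimates must be positive")
        if self.t0_s < 0:
            raise ValidationError("t0 must be >= 0")


@dataclass
class NucleationScales:
    """Characteristic nucleation/growth scales of 3-D crystallization.

    For nucleation rate N (per volume per time) and linear growth rate V,
    t0_char = (N V^3)^(-1/4) and xi = (V/N)^(1/4).
    """

    nucleation_rate: float
    growth_rate: float
    t0_char: float
    xi: float

    def __post_init__(self) -> None:
        for name in ("nucleation_rate", "growth_rate", "t0_char", "xi"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")


@dataclass
class HNProcess:
    """One Havriliak–Negami relaxation process.

    a is the symmetric and b the asymmetric broadening exponent; b = 1
    reduces to the Cole–Cole form, a = b = 1 to Debye.
    """

    delta_eps: float
    tau_hn: float  # s
    a: float
    b: float = 1.0

    def __post_init__(self) -> None:
        if not self.delta_eps > 0:
            raise ValidationError("delta_eps must be positive")
        if not self.tau_hn > 0:
            raise ValidationError("tau_hn must be positive")
        if not 0 < self.a <= 1:
            raise ValidationError("a must lie in (0, 1]")
        if not 0 < self.b <= 1:
            raise ValidationError("b must lie in (0, 1]")

    @property
    def is_cole_cole(self) -> bool:
        return self.b == 1.0


@dataclass
class HNFit:
    """Result of fitting one dielectric spectrum with HN process(es) + dc term."""

    processes: list[HNProcess]
    eps_inf: float
    sigma_dc: float  # S/m
    tau_max: list[float] = field(default_factory=list)  # s, per process
    residual_norm: float = float("nan")
    stderr: dict = field(default_factory=dict)  # parameter name -> standard error
    degenerate: tuple[int, ...] = ()  # indices of processes with negligible strength
    temperature: float | None = None
    elapsed_time: float | None = None

    def __post_init__(self) -> None:
        if not self.eps_inf >= 1:
            raise ValidationError("eps_inf must be >= 1")
        if self.sigma_dc < 0:
            raise ValidationError("sigma_dc must be >= 0")
        self.degenerate = tuple(self.degenerate)
        if not self.tau_max:
            from .relaxation import tau_max_from_hn  # deferred: avoids import cycle

            self.tau_max = [tau_max_from_hn(p) for p in self.processes]


@dataclass
class MasterPlot:
    """Time–temperature superposition master curve of the structural loss peak."""

    reference_temperature: float  # K
    shifts: dict  # temperature (K) -> log10 frequency shift (decades)
    freq_reduced: np.ndarray  # f / f_max of the reference spectrum
    loss_norm: np.ndarray  # eps'' / eps''_max, merged over all spectra
    f_max_ref: float  # Hz, loss-peak frequency of the reference spectrum

    def __post_init__(self) -> None:
        self.freq_reduced = _as_array(self.freq_reduced, "freq_reduced")
        self.loss_norm = _as_array(self.loss_norm, "loss_norm")
        _check_equal_length(freq_reduced=self.freq_reduced, loss_norm=self.loss_norm)


@dataclass
class KWWResult:
    """Kohlrausch–Williams–Watts description of the master curve."""

    beta_kww: float
    tau_kww: float  # s
    reference_temperature: float  # K
    shift_factors: dict = field(default_factory=dict)  # K -> decades
    beta_stderr: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.beta_kww <= 1:
            raise ValidationError("beta_kww must lie in (0, 1]")
        if not self.tau_kww > 0:
            raise ValidationError("tau_kww must be positive")


@dataclass
class VFTResult:
    """Vogel–Fulcher–Tammann fit of the structural relaxation time.

    log10 tau(T) = log10_tau_inf + D*T0*log10(e) / (T - T0); the fit is
    parameterized by (log10_tau_inf, DT0, T0) for conditioning, with the
    strength parameter D derived as DT0/T0.
    """

    log10_tau_inf: float
    T0: float  # K, Vogel temperature
    DT0: float  # K, product D*T0 as conventionally tabulated
    D: float | None = None
    Tg: float | None = None  # K, where tau = tau_g (default 100 s)
    m_p: float | None = None  # fragility
    cov: np.ndarray | None = None  # covariance of (log10_tau_inf, DT0, T0)
    stderr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.T0 > 0:
            raise ValidationError("T0 must be positive")
        if not self.DT0 > 0:
            raise ValidationError("DT0 must be positive")
        if self.D is None:
            self.D = self.DT0 / self.T0
        if abs(self.DT0 - self.D * self.T0) > 1e-9 * max(1.0, abs(self.DT0)):
            raise ValidationError("DT0 must equal D*T0")
        if self.Tg is None or self.m_p is None:
            from .tempdep import _tg_closed_form, _fragility_closed_form

            self.Tg = _tg_closed_form(self.log10_tau_inf, self.DT0, self.T0)
            self.m_p = _fragility_closed_form(
                self.log10_tau_inf, self.DT0, self.T0, self.Tg
            )
        if not self.Tg > self.T0:
            raise ValidationError("Tg must exceed T0")
        if not self.m_p > 0:
            raise ValidationError("fragility must be positive")


@dataclass
class ArrheniusResult:
    """Arrhenius fit tau(T) = tau_inf * exp(Ea / (R T)) of a secondary process."""

    log10_tau_inf: float
    ea_kj_mol: float
    cov: np.ndarray | None = None
    stderr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ea_kj_mol < 0:
            raise ValidationError("activation energy must be >= 0")


@dataclass
class ProcessSeries:
    """One relaxation process on the relaxation map: tau(T) data + fitted law."""

    label: str  # "alpha", "beta", "gamma", ...
    temperature: np.ndarray  # K, sorted ascending
    tau: np.ndarray  # s
    fit: VFTResult | ArrheniusResult | None = None
    model_temperature: np.ndarray | None = None
    model_log10_tau: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.temperature = _as_array(self.temperature, "temperature")
        self.tau = _as_array(self.tau, "tau")
        _check_equal_length(temperature=self.temperature, tau=self.tau)
        order = np.argsort(self.temperature)
        self.temperature = self.temperature[order]
        self.tau = self.tau[order]
        if np.any(self.tau <= 0):
            raise ValidationError("relaxation times must be positive")


@dataclass
class RelaxationMap:
    """Relaxation map: alpha process (VFT) plus secondary processes (Arrhenius)."""

    series: dict = field(default_factory=dict)  # label -> ProcessSeries

    def __post_init__(self) -> None:
        for label, s in self.series.items():
            if s.label != label:
                raise ValidationError(f"series key {label!r} does not match label {s.label!r}")


@dataclass
class CpPoint:
    """Heat-capacity step at Tg for one drug/silica composition."""

    drug_load: float  # wt.% drug in the binary mixture
    delta_cp: float  # J/(g K)
    uncertainty: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.drug_load <= 100:
            raise ValidationError("drug_load must lie in (0, 100] wt.%")
        if self.delta_cp < 0:
            raise ValidationError("delta_cp must be >= 0")


@dataclass
class CapacityResult:
    """Monomolecular loading capacity from the linear ΔCp(w) extrapolation."""

    slope: float  # J/(g K) per wt.%
    intercept: float  # J/(g K)
    drug_load_at_zero: float  # wt.% drug where the line crosses ΔCp = 0
    ms_capacity: float  # wt.% silica = 100 - drug_load_at_zero
    slope_stderr: float = float("nan")
    intercept_stderr: float = float("nan")
    capacity_stderr: float = float("nan")
    n_points: int = 0
    in_range: bool = True  # False flags an extrapolation outside [0, 100] wt.%


@dataclass
class CapacityDifference:
    """Difference between two loading capacities with propagated uncertainty."""

    difference: float  # wt.% MS
    stderr: float


@dataclass
class KineticTruth:
    """Ground-truth Avrami parameters for the synthetic DSC/BDS generators."""

    n: float
    tau_cr_s: float
    t0_s: float = 0.0
    total_enthalpy_mj: float = 50.0
    noise_sd_mw: float = 0.0

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValidationError("Avrami exponent n must be positive")
        if not self.tau_cr_s > 0:
            raise ValidationError("tau_cr must be positive")
        if self.t0_s < 0:
            raise ValidationError("t0 must be >= 0")
        if self.noise_sd_mw < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class SpectralTruth:
    """Ground-truth HN parameters for the synthetic dielectric generators."""

    processes: tuple
    eps_inf: float = 3.0
    sigma_dc: float = 0.0  # S/m
    noise_sd: float = 0.0  # relative (multiplicative log-normal)

    def __post_init__(self) -> None:
        self.processes = tuple(self.processes)
        if not self.processes:
            raise ValidationError("at least one relaxation process required")
        if not self.eps_inf >= 1:
            raise ValidationError("eps_inf must be >= 1")
        if self.sigma_dc < 0:
            raise ValidationError("sigma_dc must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class VFTParams:
    """VFT law parameters used by generators: tau(T) = tau_inf exp(DT0/(T-T0))."""

    log10_tau_inf: float
    T0: float  # K
    DT0: float  # K

    def __post_init__(self) -> None:
        if not self.T0 > 0 or not self.DT0 > 0:
            raise ValidationError("T0 and DT0 must be positive")

    @property
    def D(self) -> float:
        return self.DT0 / self.T0

    def tau(self, temperature) -> np.ndarray:
        """Relaxation time (s) at the given temperature(s) (K)."""
        T = np.asarray(temperature, dtype=float)
        if np.any(T <= self.T0):
            raise ValidationError("temperature must exceed the Vogel temperature T0")
        return 10.0**self.log10_tau_inf * np.exp(self.DT0 / (T - self.T0))


@dataclass
class ArrheniusParams:
    """Arrhenius law parameters used by generators: tau = tau_inf exp(Ea/(R T))."""

    log10_tau_inf: float
    ea_kj_mol: float

    def __post_init__(self) -> None:
        if self.ea_kj_mol < 0:
            raise ValidationError("activation energy must be >= 0")

    def tau(self, temperature) -> np.ndarray:
        """Relaxation time (s) at the given temperature(s) (K)."""
        T = np.asarray(temperature, dtype=float)
        return 10.0**self.log10_tau_inf * np.exp(
            self.ea_kj_mol * 1e3 / (GAS_CONSTANT * T)
        )


@dataclass
class StudyConfig:
    """Tunable knobs of the analysis pipeline (mirrored by the CLI YAML config)."""

    smoothing_window: int = 21  # points, odd, >= 5 (local-polynomial derivative)
    smoothing_polyorder: int = 3
    inflection_tolerance: float = 0.005  # |alpha(inflection) - (1 - 1/e)| target
    tracking_frequency_hz: float = 10.0  # where eps'(t) is tracked for the BDS route
    resample_points: int = 400  # uniform ln-time grid size for derivatives
    seed: int = 0
    n_starts: int = 8  # multi-start count for HN fits
    fit_bounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.smoothing_window % 2 == 0 or self.smoothing_window < 5:
            raise ValidationError("smoothing_window must be odd and >= 5")
        if not 0 < self.inflection_tolerance < 0.1:
            raise ValidationError("inflection_tolerance must lie in (0, 0.1)")
        if self.smoothing_polyorder >= self.smoothing_window:
            raise ValidationError("polyorder must be smaller than the window")
        if not self.tracking_frequency_hz > 0:
            raise ValidationError("tracking frequency must be positive")
        if self.resample_points < 2 * self.smoothing_window:
            raise ValidationError("resample_points too small for the smoothing window")
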