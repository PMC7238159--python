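# Methods

`amorphkin` implements the quantitative workflow used to characterize the
physical stability of an amorphous drug — here parameterized for
simvastatin (SVT) stabilized on mesoporous silica (MS) — from isothermal
calorimetry (DSC) and broadband dielectric spectroscopy (BDS).  This note
records the models, the numerical choices behind them, and what the
synthetic-data studies do and do not demonstrate.

## Crystallization kinetics (Avrami–Avramov)

Both experimental routes reduce to a relative-crystallinity curve α(t):

* **DSC**: α(t) is the running fraction of the crystallization exotherm,
  α(t) = ∫_{t0}^{t} (dH/dt) dt / ∫_{t0}^{t∞} (dH/dt) dt, after optional
  linear baseline subtraction between the onset/completion anchors.
  Default anchors are the 0.1% / 99.9% quantiles of cumulative heat; we
  found that interior quantiles (e.g. 5%/95%) truncate the transform and
  bias the recovered exponents, so near-full-exotherm anchors are the
  default and explicit anchors are preferred when the onset is known.
* **BDS**: during isothermal crystallization the structural relaxation
  strength decays with the crystalline fraction, so the static
  permittivity drops; α(t) = ε′_N(t) = (ε′(0) − ε′(t))/(ε′(0) − ε′(∞)).
  ε′ is tracked at a fixed frequency (default 10 Hz — on the static
  plateau at the crystallization temperature, where a purely ohmic dc
  current does not touch ε′).  Plateau levels default to the mean of the
  first/last three time points.  A contrast below 0.1 permittivity units
  raises a *no crystallization detected* error — the behaviour of a fully
  stabilized sample, which is a result, not a failure.

The Avramov construction plots α against ln(t − t0):

* **Induction time t0** is defined as the offset that places the
  inflection of α(ln(t − t0)) at α = 1 − 1/e, found by bisection on t0
  over [0, t(α = 0.05)] with tolerance 0.005 on α.  Inside the bisection
  the inflection is located by fitting the universal Avrami peak shape
  A·exp(u − e^u), u = κ(ln x − ln x₀), to the derivative curve over the
  band above 50% of its maximum.  This locator is exact for Avrami input
  with any exponent and averages point noise over the whole band; a
  3-point parabola on a densely resampled smoothed curve carries almost
  no curvature signal and jitters by hundreds of seconds at realistic
  noise, while a plain wide-band parabola is biased by the peak's skew.
* **Characteristic time τ_cr** is the position of the maximum of
  dα/d ln(t − t0), refined by parabolic interpolation through the three
  points bracketing the discrete maximum.  For the Avrami law
  α = 1 − exp(−((t − t0)/τ)^n) the maximum sits exactly at t − t0 = τ.
* **Dimensionality n** comes from two estimators: the derivative maximum,
  n = α′_max/0.368 (0.368 being the conventional rounded 1/e — the
  rounded constant is used so reported exponents match the tabulated
  convention), and the tangent construction at τ_cr, whose intercepts
  with α = 0 and α = 1 give n = e/(ln t₂ − ln t₁).  Both are exact for
  Avrami input: the peak value is n/e and the tangent spans e/n.

**Derivative numerics.**  α is linearly resampled onto a 400-point
uniform grid in ln(t − t0) (the flat pre-onset stretch below α ≈ 0.5% is
dropped so grid resolution concentrates on the peak) and differentiated
with a Savitzky–Golay filter, default cubic polynomial over 21 points.
A quadratic window (the textbook choice) leaves a cubic-term bias of
~0.4% on the peak value — enough to shift τ_cr by ~1 min and t0 by ~50 s
at the reference conditions — which the cubic order removes; the wider
window buys noise averaging at no measurable bias (<0.1%).

**Precision at the reference conditions.**  With n = 3.8, τ_cr = 55 min,
t0 = 8800 s, 1 s sampling (a typical isothermal DSC logging rate) over
30 000 s and additive Gaussian noise of 2% of the peak heat flow, the
pipeline's Monte-Carlo precision is σ(t0) ≈ 36 s, σ(τ_cr) ≈ 0.45 min and
σ(n)/n ≈ 1%.  The conventional reporting bands (±100 s, ±1 min, 5%) are
therefore ~2σ statements about the estimate; the acceptance tests bound
the 20-seed sample mean by those bands and individual seeds by three
times them.

**Characteristic nucleation scales.**  For nucleation rate N (L⁻³ t⁻¹)
and growth rate V (L t⁻¹), t0_char = (N V³)^(−1/4) and ξ = (V/N)^(1/4).

## Dielectric relaxation

Spectra are modelled as ε*(ω) = ε∞ + Σ Δε/(1 + (iωτ_HN)^a)^b + σ_dc/(iε₀ω)
with the sign convention ε* = ε′ − iε″ (loss positive) and a purely ohmic
conductivity exponent (no fractional exponent).  The loss-peak time of
one process is the standard Havriliak–Negami peak formula

τ_max = τ_HN [sin(πa/(2+2b))]^(−1/a) [sin(πab/(2+2b))]^(1/a),

which reduces to τ_HN for Cole–Cole (b = 1) and Debye.  (A formula in
which both sine factors carry the argument πab/(2+2b) collapses to
τ_max = τ_HN for all shapes; the grid-argmax oracle test adjudicates in
favour of the form above.)

**Fitting.**  Least squares on log₁₀ ε″ over the measured grid (loss
peaks span decades), optionally joined by log₁₀ ε′ — the joint fit is
what constrains ε∞ and is used in the round-trip tests; with loss-only
fitting ε∞ is taken from the high-frequency ε′ minimum.  σ_dc and τ_HN
are fitted in log space.  Eight multi-starts (the first from data-driven
peak detection, the rest randomized around it with the config seed) guard
against local minima; best residual wins, exact ties broken by the
smaller parameter-vector norm.  Sub-T_g spectra are fitted with Cole–Cole
processes (b fixed at 1), two by default for the β and γ secondary
relaxations, conductivity off; output processes are ordered slow-to-fast
so process 0 is β.  A requested process that the spectrum does not
resolve collapses onto a ridge — negligible loss contribution with
arbitrary strength, or a duplicate sharing a stronger process's peak —
and is flagged as degenerate (threshold: 5% of the strongest peak
contribution, or peak positions within a third of a decade).

**Master plots.**  Time–temperature superposition: each spectrum of a
temperature series is shifted horizontally in log-frequency to minimize
the mean-square log-loss mismatch with the reference spectrum over the
overlapping support (linear interpolation in log-log space, bounded 1-D
minimization per spectrum, walking outward from the reference).  No
vertical shift is fitted; the merged curve is normalized by the reference
peak only.  Spectra whose loss peak has left the measured window (close
to T_g) are seeded by a coarse scan of the overlap residual instead of
peak alignment.

**KWW transform.**  The shape of the merged α-peak is summarized by the
stretching exponent β_KWW of the one-sided Fourier transform of
φ(t) = exp(−(t/τ)^β): ε″(ω) ∝ ∫₀^∞ (−dφ/dt) sin(ωt) dt.  With x = ωτ the
integral is evaluated in three pieces: [0, 2π/x] after the v = u^β
substitution (removes the integrable endpoint singularity; at most one
oscillation), [2π/x, 1] by the oscillatory-weighted (QAWO) rule, and
[1, ∞) by the infinite-interval Fourier (QAWF) rule — except that when a
single oscillation cycle outlasts the e^(−u^β) decay range the tail is
integrated as a smooth finite integral instead (the Fourier rule needs
cycles to sum).  Below x = 10⁻⁶ and above x = 10⁶ convergent low-x and
asymptotic high-x expansions take over; all regimes agree at the
crossovers to better than 10⁻⁹ and β = 1 reproduces the Debye loss
x/(1 + x²) to 10⁻¹⁰ over sixteen decades.  The KWW fit runs over
(β, log₁₀ τ) on the log of the peak-normalized master curve, excluding
points below 10⁻³ of the peak; the model curve is interpolated from a
12-points-per-decade table per iteration.

## Temperature dependence

τ_α(T) is fitted with the VFT law log₁₀ τ = log₁₀ τ∞ + DT₀·log₁₀e/(T − T₀),
parameterized by (log₁₀ τ∞, DT₀, T₀) — the product DT₀ is the quantity
conventionally tabulated and is much better conditioned than D alone; D
is derived.  Initialization is deterministic: T₀ is scanned on a coarse
grid (the model is linear in 1/(T − T₀) at fixed T₀), the best candidate
seeds a trust-region refinement.  Closed forms, both verified against
brute-force root finding / numerical differentiation to 10⁻⁶:

* T_g = T₀ + DT₀·log₁₀e/(log₁₀ τ_g − log₁₀ τ∞), with τ_g = 100 s by
  convention;
* fragility m_p = d log₁₀ τ / d(T_g/T) |_{T_g} = DT₀·T_g/(ln10·(T_g − T₀)²).
  In the Arrhenius limit (T₀ → 0) this degenerates to
  log₁₀ τ_g − log₁₀ τ∞ (16–17 for typical τ∞), the textbook minimal
  fragility.  Typical m_p of 50–100 is a report-level sanity note, never
  a constraint.

A caveat on uncertainties: with realistic temperature windows
(330–362 K here) the three VFT parameters are strongly correlated; at
0.05-decade scatter on log τ the information limit on DT₀ is several
hundred kelvin, an order of magnitude looser than the tens-of-kelvin
uncertainties conventionally tabulated (which correspond to few-millidecade
residual scatter).  The fit reports its own covariance-based errors.

Secondary relaxations are Arrhenius, τ(T) = τ∞ exp(E_a/RT), fitted by
linear regression of ln τ on 1/T (R = 8.314 J mol⁻¹ K⁻¹ fixed); E_a is
reported in kJ/mol.  `assemble_relaxation_map` merges the α (VFT) and
secondary (Arrhenius) series, with dense model curves, into one
serializable relaxation map.

## Loading capacity (Hempel ΔCp extrapolation)

Drug molecules adsorbed on the silica surface do not participate in the
glass transition, so the heat-capacity step ΔCp at T_g of a drug/silica
mixture falls below the ideal-mixing line.  Regressing ΔCp against drug
load w (wt.%) for compositions with a detectable glass transition
(points with ΔCp = 0 are excluded by default) and extrapolating to
ΔCp = 0 gives the composition w* at which all drug is surface-bound; the
monomolecular loading capacity is 100 − w* wt.% silica.  OLS with
standard linear-regression errors; the error on w* = −intercept/slope is
propagated by the delta method, and capacities of two silica grades are
compared with a quadrature-summed error.  A non-positive slope flags an
invalid extrapolation.  Note the leverage of the construction: with seven
compositions spanning 50–100 wt.% drug and the crossing near 16 wt.%,
a 2% relative scatter on ΔCp maps to ~2.3 wt.% scatter on the capacity —
the ±0.5 wt.% band conventionally quoted is a statement about the mean of
repeated determinations.

## Synthetic data: what it does and does not show

All generators are pure functions of (truth, seed) — same inputs, bit
identical output.  The kinetic ground truth is the Avrami law, the unique
sigmoid for which the Avramov constructions are exact, so recovery errors
measure the estimator, not model mismatch.  Noise models: additive
Gaussian on heat flow; multiplicative log-normal (relative sd) on ε′ and
ε″; Gaussian relative to the neat-drug step on ΔCp.  Default conditions
encode the reference study (`amorphkin.STUDY`): isothermal crystallization
truths at 363 K for neat SVT and the SVT + 9 wt.% MS mixture by both
routes, VFT parameters of the three samples, ΔCp capacities 84.3/83.4
wt.%, Δε_α = 8.9 and β_KWW = 0.60.  The dielectric frequency grid is
8 points/decade over 0.1 Hz–1 MHz; a spectra cadence of 300 s over 24 h
emulates an overnight hold.  The β/γ secondary-process defaults
(E_a ≈ 55 and 30 kJ/mol) are representative sub-T_g dynamics, not fitted
literature values.

What passing these studies does *not* show: real DSC baselines drift
nonlinearly and real crystallization is rarely exactly Avrami (surface
nucleation, impingement, thermal lag), real loss spectra carry electrode
polarization and conductivity with sub-ohmic exponents, and real master
plots superimpose only approximately when β_KWW drifts with temperature.
The package's guards (baseline anchors, degenerate-process flags, the
no-crystallization error) address the detectable versions of these, but
accuracy claims transfer to real data only to the extent the models hold.

A dedicated generator (`gen_kww_temperature_series`) produces a
temperature series whose loss is an exact unit-peak KWW shape scaled by
Δε and VFT-shifted in frequency — a perfectly superposable series for
master-plot and β_KWW recovery studies; the HN generator cannot produce
an exact KWW shape, so using it there would conflate shape mismatch with
estimator error.

## Known limitations

* The induction-time criterion is a point condition at the inflection;
  its precision is bounded by the local α noise (integrated instrument
  noise), ~35 s at the reference conditions.  A full-curve Avrami fit
  would be several times more precise but is deliberately not the
  reported estimator — the Avramov construction is the method under test.
* `fit_hn` assumes strictly positive loss (log-space objective); spectra
  with noise-driven non-positive loss values must be cleaned first.
* The master-plot shift optimizer assumes a single dominant loss peak per
  spectrum in the fitted window; strongly overlapping α + β spectra need
  explicit per-spectrum windows.
* VFT fits with T₀ close to or above min(T) − 0.5 K are rejected rather
  than extrapolated.
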