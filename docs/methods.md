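# Methods

`pcdsim` simulates the signal chain of an edge-on silicon strip detector
for photon-counting CT whose readout channel has an adjustable shaping
time. This note records the models, the parameters that matter, the
numerical choices, and the limits of what the simulations show.

## Channel model

The readout channel is a charge-sense amplifier (CSA), a pole-zero
cancellation stage, a shaper amplifier and two cascaded lossy Gm-C
integrators. Its response to the detector current is the rational transfer
function

    H(s) = (1/Cf)(Cpz/Cs) · τs/(1+sτs) · 2/(1+sτ1) · 2/(1+sτ2),  s = j2πf

with Cf = 200 fF, Cpz = 1600 fF, Cs = 200 fF. Two variants are modelled:

* **prototype** — the current ASIC: τs = 14 ns fixed, τ1 = Bτ0,
  τ2 = 2Bτ0 (the comparator load doubles the second Gm-C time constant).
  The selectable setting enters through B (long: B = 1; short:
  0.5 ≤ B < 1); the shaping time is τ = 2Bτ0.
* **ideal** — a proposed future channel with negligible comparator load:
  τs = τ1 = τ2 = τ0 and τ = 2τ0, so the shaper-amplifier corner tracks the
  filter.

The DC transimpedance is (1/Cf)(Cpz/Cs)·4τs. An alternative band-pass
numerator (sτs in place of τs) is selectable with `bandpass_numerator`;
the two forms differ only below the shaper corner and the DC-coupled form
is the default because it is the one whose noise counterpart (below) and
pulse shapes reproduce the validation surface. Shaping is applied in the
frequency domain (real FFT, multiply, inverse), with the window extended
to at least 20 shaping times and doubled until the response has decayed
below 1% of its peak — this keeps pulse-length measurements free of
wrap-around up to τ = 500 ns.

Pulse lengths are measured between the first upward and last downward
threshold crossing with linear interpolation between the 2-ns samples;
peaks are grid maxima without sub-sample refinement, matching the sampled
comparator registration.

## Charge transport

Photon interactions deposit point-like electron–hole clouds
(3.6 eV per pair) in a 500-µm wafer biased at 400 V with net doping
4.6·10¹¹ cm⁻³ (depletion voltage ≈ 89 V, well over-depleted). The 1-D
Poisson equation is solved by finite differences with φ = 0 at the
collecting strip and φ = 400 V at the backside; the solver is verified
against the closed-form over-depleted planar field
E(x) = V/d + (ρ/ε)(d/2 − x) to better than 0.1%.

Carriers drift at v = µE with constant low-field mobilities
(µe = 1350, µh = 480 cm²/Vs at 300 K; a velocity-saturation model is
available behind a flag but is off by default — at ≤ 10 kV/cm the
correction is a few percent). Diffusion adds independent Gaussian
displacements in x and y with variance 2D·dt per 2-ns step, D = kTµ/e,
resampled every step. Lateral positions reflect at the pixel boundary;
carriers reaching an electrode are absorbed. Each deposit is represented
by 1000 weighted macro-carriers per species, which keeps the induced
current smooth on the 2-ns grid at negligible cost.

Induced currents use the Shockley–Ramo theorem with a planar weighting
field E_w = 1/d. This is exact for a beam confined to the centre of one
pixel (no charge sharing), which is the measurement condition being
emulated; a strip weighting potential would only matter for edge
illumination, which is out of scope. Because the current is computed from
the realised displacement per step, the integrated current of a completed
trajectory equals the generated charge to machine precision.

Standard pulse ensembles (used for gains, kernels and fits) draw
interaction positions from a Gaussian of width 50 µm about the wafer
mid-plane (a collimated beam on the pixel centre), 20 pulses per energy,
seed 0. Gains are the linear-regression slope of mean peak voltage versus
energy over 40–80 keV; the ideal 40-ns channel gives ≈ 1.92 mV/keV.

## Electronic noise

Two input-referred white sources: a CSA current source amplified by the
detector capacitance (Gf = 5 mS, Cdet = 5 pF) reaching the output through
a band-pass weighted response (numerator |2πfτs|²), and a filter voltage
source seeing only the two Gm-C poles (16/|1+sτ1|²|1+sτ2|²). Source rms
levels (0.45 µA, 2.72 mV) are interpreted on the 2-ns sampling grid, i.e.
one-sided PSD = rms²/f_Nyquist.

Under this convention the printed source levels do not jointly reproduce
the stated reference point (σ = 2 keV at τ = 40 ns with a 4/5–1/5
CSA/filter power split): the filter source alone is consistent to ~1%,
the CSA source overshoots by ≈ 2.7× in variance (a unit-convention
ambiguity in the CSA prefactor). The source levels are therefore treated
as *defining* the reference: two renormalisation constants, computed once
against the reference configuration and logged, rescale the source powers
so the split and σ = 2 keV hold exactly at the ideal 40-ns channel. All
other configurations (including the prototype settings) inherit these
constants, so ratios between configurations are genuine model outputs.

Noise integrals use trapezoid quadrature on a 8192-point logarithmic grid
(1 kHz–1 GHz plus a DC anchor), which matches the closed-form rational
integrals to < 0.1% for τ between 20 and 500 ns. Time-domain realizations
propagate white Gaussian frames through the complex transfers by FFT and
agree with the integrated PSDs (Parseval) within Monte-Carlo error.

The ideal-channel σ(τ) used for thresholds and the power tradeoff is
expressed in keV with a single fixed calibration (the reference gain at
40 ns). Both noise components scale exactly as 1/τ for the ideal channel,
so σ(τ) = 2 keV · √(40 ns/τ). The published threshold table follows this
law at 100 ns (5.06 vs 5.2 keV printed) but its 400-ns row (1.9 keV)
falls well below the scaling-law value of ≈ 2.5 keV; no mechanism in the
channel equations produces that extra reduction, and the package reports
the scaling-law value. The alternative of recalibrating the keV scale
with a per-τ gain was rejected: ballistic deficit makes the gain *smaller*
at short τ, which moves σ(τ) in the wrong direction to explain the row.

## Counting and the E1/2 pulse-length method

Comparator outputs are sampled every clock cycle τc = 10 ns with a clock
phase drawn uniformly per frame; pulse arrivals carry an additional
uniform jitter over one clock cycle, since beam photons are asynchronous
to the clock. A super-threshold sample registers a count and opens a
deadtime (a multiple of τc); the count is binned by the highest threshold
the waveform exceeds inside the deadtime window (peak-hold), and the
first eligible sample after the window is at trigger + τd, so a pulse
still above threshold there is counted again. These semantics give the
measurement identity the whole method rests on: averaged over the clock
phase, the threshold E1/2 at which half the pulses double-count is the
point where the pulse length equals τd + τc/2. The package verifies the
identity to within ±5 ns across 40–80 keV and 40–100 ns deadtimes.

Threshold scans place well-separated pulses (2 µs apart) on a frame with
an additive noise realization, count at each threshold with a fresh
phase, and normalize by the number of pulses. Below ≈ 15 keV noise
triggering and triple counts push the normalized curve above 2; this
region is excluded from E1/2 extraction and curve fits (configurable
constant). E1/2 is the linear-interpolated crossing of 1.5.

Deadtime-vs-shaping-time operating points set the lowest threshold to
4σ(τ) (one noise count per 150 µs frame on average) and the deadtime to
the length of a 100-keV pulse at that threshold, rounded up to a clock
multiple: 140 ns at τ = 40 ns, 380 ns at τ = 100 ns.

## Calibration fits

Threshold-scan S-curves are fitted with the modified complementary error
function ½erfc((x−µ)/√2σ)(A1(x−µ)+A2) + A3(x−µ)+A4 by multi-start
least squares (data-driven centre guess plus typical noise widths; the
A1/A3 directions are shallow, hence the multi-start). Gain is the
regression slope of µ versus beam energy; σ in keV is the noise-only fit
width divided by the gain.

Shaper parameters (τ0, B_short) are recovered from E1/2 observations by
exhaustive grid search (τ0: 10–30 ns in 0.1-ns steps; B: 0.50–0.99 in
0.01 steps, ties toward smaller τ0). Predicted pulse lengths come from
one shared seeded pulse ensemble per energy, shaped per grid point with
the mean pulse peak normalised to the nominal energy — the pulse height
itself is not fitted. The grid search is deliberately brute-force (no
early exit), and round-trip tests recover random (τ0, B) pairs from fully
synthetic scans within one grid step.

## Spectra and dose efficiency

The tube spectrum is semi-empirical: Kramers bremsstrahlung (E0/E − 1)
attenuated inside the tungsten target over the Thomson–Whiddington mean
production depth (c_TW = 1.1·10⁶ keV²cm²/g, 10.5° takeoff), tungsten
Kα1/Kα2/Kβ lines at 8% of the inherently filtered fluence, then
Beer–Lambert filtration through 0.8 mm Be, 8.38 mm Al and 20–40 cm of
ICRU-44 soft tissue. After 20 cm of tissue the spectrum below ~30 keV is
extinguished, so the soft-tissue tables dominate the shape and the anode
details are second order.

Attenuation data are internal tabulations on a NIST-style grid
(1–150 keV, log-log interpolated) for Si, Al, Be, soft tissue and W. The
silicon interaction split uses the exact Klein–Nishina total cross
section for the incoherent part (the incoherent-scattering-function
correction is a few percent below ~30 keV where photoabsorption dominates
anyway) and obtains the photoelectric part by subtracting incoherent and
a small coherent estimate from the total; coherent scattering deposits no
energy and is excluded from the interaction cross section.

The detector response is a per-photon sampler, not a transport code:
attenuation in the 0.6-mm dead silicon at the pixel top, interaction over
the 30-mm edge-on active depth, then either a photoelectric full deposit
or a Klein–Nishina Compton electron deposit (scattered photon escapes;
no fluorescence — silicon K fluorescence is 1.74 keV and locally
reabsorbed — no Rayleigh deposit, no electron transport). Deposits are
histogrammed on the standard 0.5-keV grid from 1 to 120 keV; sub-keV
deposits fall outside the histogram and its normalization. Dose
efficiency is the fraction of the histogram above the threshold
(100% at 0 keV), i.e. the registered fraction of interacting photons for
a counting-only detector. With 10⁶ photons the 120 kVp / 20 cm spectrum
gives 68.0% above 8 keV, 84.3% above 4 keV and 79.2% above 5.2 keV, and
the 20/30/40 cm curves coincide within ~1 pp — the dose-efficiency curve
is essentially a property of the silicon response, not the patient
thickness. Prototyping showed that tracking one secondary interaction of
the scattered photon would shift these fractions up by only ~1.5 pp;
the single-interaction model was kept for simplicity.

## Power tradeoff

Preamplifier noise scales as σ ∝ 1/√P. The compensation curve solves
σ(P, τ*) = σ(P0, 40 ns) by bisection to 0.1 ns. Two scopes are reported:
`csa_only` (default — only the CSA component scales with power, the
literal reading of "power to the preamplifier") and `total`. Because both
noise components scale exactly as 1/τ, the factors have closed forms,
1 + 0.8(1/p − 1) and 1/p, and are independent of the reference shaping
time: 1.8 and 2.0 at p = ½. The published factors (1.875 at a 40-ns
reference, 2.5 at 200 ns) lie between/above these limits and differ from
each other, implying a σ(τ) that is not a pure power law; no such
behaviour follows from the channel's own noise equations, so the package
reports both scopes and documents the residual discrepancy rather than
adjusting the model (see also the 400-ns threshold row above, which
deviates in the *opposite* direction).

## What the synthetic data do and do not show

The synthetic threshold scans emulate the structure of the
characterisation campaign (beam energies, deadtime sets and counting
statistics per detector module) with the fitted time constants as ground
truth. They contain Poisson counting noise, electronic noise and clock
quantisation, but not ASIC fabrication spread, DAC nonlinearity,
temperature drift, charge sharing or pileup from beam structure. Passing
the round-trip tests therefore shows that the fitting pipeline is
unbiased and precise under the model's own assumptions — not that a real
ASIC's time constants would be recovered to the same precision.

## Problem sizes and numerical defaults

Pulse ensembles: 20 pulses × 1000 macro-carriers per species per energy.
Threshold scans: 600–1000 pulses, 0.5-keV threshold steps, 2-µs spacing.
Detector response: 10⁶ photons for headline dose-efficiency numbers,
3·10⁵ for curve-shape comparisons. Noise integrals: 8192-point log grid.
These sizes put every Monte-Carlo estimate's statistical error well below
the tolerance it is compared against (plateau noise ≲ 3%, efficiency
s.e. ≲ 0.05 pp) while keeping the full pipeline in the minutes range on
one core.

## Known limitations

* Planar weighting field only in the default path; charge sharing,
  cross-talk and anti-coincidence logic are out of scope.
* Attenuation tables are internal tabulations with percent-level accuracy;
  absolute dosimetry (Gy) is not attempted — all spectra are relative.
* The tube model is semi-empirical; its residual error is absorbed by the
  heavy filtration but would matter for lightly filtered beams.
* White noise sources only (no 1/f, no shot noise), constant mobilities,
  no trapping.
* The deposited spectrum carries no electronic-noise broadening; it is
  the pre-electronics deposit distribution.
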