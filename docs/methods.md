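# Methods

This note documents the models, conventions and numerical choices behind
`protoneuro`, and what the synthetic generators do and do not emulate.

## Units and containers

Canonical units are fixed at the scales the protocell literature reports:
seconds and millivolts for voltage traces, volts and microamperes for
voltammetry (hence μC charge and μA·V hysteresis areas), hertz and ohms for
impedance. Readers convert declared source units on input. The impedance
sign convention is capacitive ⇒ `z_im < 0`; Nyquist plots show −Z″.

## Cyclic voltammetry

Cycles are segmented at sweep reversals from the potential minimum; each
cycle holds one forward and one reverse sweep. Peaks are the raw current
extrema per sweep (anodic maximum on the forward sweep, cathodic minimum on
the reverse), with i_pa reported positive and i_pc negative; baseline
subtraction is off by default because the analyses this mirrors apply none.
Derived statistics:

* ΔE_p = E_pa − E_pc (V); η = |i_pa/i_pc| / ΔE_p (V⁻¹);
  ε = |i_pa·i_pc| / ΔE_p (μA²/V). The η and ε forms reproduce all the
  published per-system values they are checked against (η = 1.10/0.46,
  ε = 373.86 μA²/V, enhancements of ≈2200 % and ≈12 293 %).
* Q integrates |i| over time (dt = |dE|/ν), i.e. total charge passed,
  because the published per-cycle charge is positive and decaying; a
  `signed=True` option integrates the net current instead.
* The charge decay Q(n) = Q₀e^(−αn) is fitted unweighted in log space —
  the model is a pure exponential, so the log-linear problem is exact at
  zero noise and stable at the 100-cycle scale.
* The zero-crossing potential uses the first forward-sweep sign change
  (linear interpolation); I_zc is the reverse-sweep current interpolated at
  that same potential, which is generally nonzero when the loop has
  hysteresis. Multiple crossings tie-break to the first after the sweep
  minimum.
* Hysteresis area is the absolute shoelace area of the closed I–V polygon.

## Spike analysis

Detection is `scipy.signal.find_peaks` with a topographic-prominence
threshold and a minimum peak distance. Amplitude is defined as prominence
rather than absolute height because baselines drift across activity phases;
consequently detection is invariant under adding a constant to the trace.
Defaults (2 mV prominence, 60 s separation) suit minute-scale protocell
spiking; the separation must be lowered for trains with periods of seconds,
so both are mandatory, documented parameters. Two caveats follow from the
definition: an event whose decay is truncated by the end of the recording
exposes less than its full prominence, and events smaller than the
threshold are undetectable — validation fixtures therefore keep event
amplitudes above threshold and pad the recording tail.

Distribution summaries use type-7 (linear-interpolation) quartiles and
1/n central moments: skewness γ = μ₃/μ₂^{3/2} and Pearson (non-excess)
kurtosis κ = μ₄/μ₂², so near-normal data score κ ≈ 3, matching the
convention of the published spike tables. RMS phase segmentation computes
per-window V_rms of the mean-subtracted signal; automatic mode merges
contiguous windows falling in the same RMS band.

The source recordings report an average of 0.5 spikes/min for the pristine
system while its tabulated mean period (664.45 s) implies ≈0.09 /min; the
two are inconsistent and are left so. The pristine analog preset uses the
tabulated period, since the table is the quantitative record.

## Comparative statistics

The KS statistic is the exact supremum of |F̂₁ − F̂₂| over the pooled
sample; the p-value uses the asymptotic Kolmogorov distribution at
effective size n₁n₂/(n₁+n₂) (the published comparisons are all at large n
with p < 10⁻⁴, where the asymptotic form is adequate). Cohen's d uses the
equal-weight pooled SD √((σ₁²+σ₂²)/2), which reproduces the published
effect sizes (0.71 amplitude, −1.17 period) from the tabulated means and
SDs. No multiple-testing correction is applied.

## Impedance

The R(RC)(RC) ladder is fitted by complex nonlinear least squares with
modulus weighting, residual = (Z_obs − Z_model)/|Z_obs| stacked into real
and imaginary parts. Modulus weighting is essential because protocell
spectra span ~590 Ω to ~13 MΩ; unit weighting would let the megaohm arc
dominate. Parameters are optimized as logarithms, which enforces
positivity and conditions the nF-to-μF capacitance range. χ² is reported
as the weighted residual sum over (2·n_points − 5); because the weighting
convention of the published χ² = 0.0475 is unknown, fit quality is
validated by parameter recovery (noiseless round trip < 0.1 % per
parameter; median < 5 % per parameter at 1 % multiplicative noise) rather
than by matching that number. The default initial guess reads R₁ from the
high-frequency |Z| floor, the resistance total from the largest real part,
and capacitances from arc apex frequencies.

## Information metrics

Signals are binarized at their median (parameter-free, drift-robust; the
source analyses do not state their quantization). LZW complexity is the
number of phrases emitted by dictionary compression (alphabet {0,1})
divided by string length; the 8-symbol constant string hand-traces to 4
phrases, C = 0.5, frozen as a test oracle.

The PCI-style index is whole-minus-parts complexity. Because per-symbol
LZW complexity is length-dependent (a constant string of length n emits
~√(2n) phrases), subtracting window complexities from the whole-string
complexity would be biased by length alone and could not return 0 for a
constant trace. Both terms are therefore evaluated over the same windows:
the whole-signal term binarizes globally and the parts term binarizes each
window by its own threshold. Constant traces and concatenations of
identical windows score exactly 0.

The integration score averages the zero-lag Pearson correlation of
consecutive equal-length windows; Φ = H(X) − mean MI(Xᵢ, Xᵢ₊₁) with
entropies in bits over equal-width bins spanning [min v, max v] and the
same global edges on both axes of the joint histogram, making all four
metrics invariant under positive affine transforms of the potential.
Consecutive-window averages divide by the number of pairs (N−1) by
default; a `divisor="windows"` option divides by N instead, since the
source presentation is ambiguous on this point. Defaults n_windows = 10,
bins = 16; absolute metric values depend on these and on trace length, so
published magnitudes (e.g. Φ = 1.845–2.235) are not reproduction targets —
the cross-system orderings are.

## Synthetic generators

All generators are deterministic given (spec, seed).

**Spike traces.** Spike times follow a homogeneous Poisson process per
phase (optional rate-preserving dead time: with refractory r the hazard is
λ/(1−λr) so the mean rate stays λ); amplitudes are normal truncated at
zero, consistent with positive tabulated minima; the spike template is an
instantaneous rise with exponential decay (default τ = 30 s), since the
recordings show asymmetric spikes but no waveform equation. Baseline noise
is an Ornstein–Uhlenbeck process, not white noise: recorded baselines
wander over seconds-to-minutes, and median-binarized white noise would be
maximally LZW-complex regardless of amplitude, destroying the distinction
between "stable" and "rapidly fluctuating" systems. Phases can add a
linear baseline ramp and a slow sinusoidal component emulating the
large-scale potential oscillations the recordings show.

**System presets.** Three analogs encode the reported phenomenology at
desk scale (default 30 000 s, dt = 1 s, ≈1/6 of the recorded duration):
pristine P — sparse spikes at the tabulated period (≈0.09 /min), amplitude
7.62 ± 4.69 mV, quiet slowly-wandering baseline (OU σ = 0.75 mV,
τ = 120 s), small slow component; serotonin PS — 1.2 spikes/min, amplitude
14.87 ± 7.80 mV, rapid fluctuations (OU σ = 4 mV, τ = 2 s) and a large
18 mV slow oscillation (peaks reach ≈40–45 mV with spikes); PSP — three
phases with rates 0.2 → 0.9 → 1.8 /min, amplitude 10.84 ± 4.36 mV, and
fluctuation RMS growing from ~2 to ~9 mV split between OU noise and slow
oscillation. The slow-oscillation period is set to duration/10, the
default analysis window, so window-to-window correlation reflects each
system's oscillation strength. Under the default configuration these
presets reproduce the reported orderings: LZW complexity P < PSP < PS and
integration score highest for PS. The presets do **not** emulate bursts
clustering, inter-event correlations, amplitude-rate coupling, or
electrode-drift artifacts of real recordings, so passing orderings show
the metrics respond to activity structure as intended — not that real
recordings would yield the same absolute values.

**Burst traces.** A raised sinusoid at the specified frequency modulated
by a logistic envelope with time constant τ (bursts recur every 10τ),
honoring the published burst parameters (range ≈4–16 mV, τ = 200 s,
f = 1.8 min⁻¹ ⇒ period ≈33 s) without claiming the unpublished closed
form.

**Voltammograms.** Triangular sweeps with Gaussian anodic/cathodic peaks
(default width 0.05 V, 250 samples/sweep, peaks at 0.30/0.134 V) damped by
e^(−α(n−1)) on cycle n, so the per-cycle charge ratio is exactly e^(−α) at
zero noise.

**Spectra.** Log-spaced frequencies at a fixed density per decade
(11 decades × 12.3 points/decade ⇒ 136 points), circuit impedance from the
reference parameters, multiplicative complex Gaussian noise.

## Problem sizes and tolerances

Validation uses: 100-cycle voltammograms; 10⁴-s spike traces for
detection/rate recovery (Poisson 3σ bounds); 3×10⁴-s traces for
complexity orderings; 136-point spectra with 50 noise seeds for fit
recovery; 1000 replicate pairs (n = 500 each) for KS type-I calibration
(0.05 ± 0.02). Grid-resolution tolerances follow the generator's sampling
(e.g. ΔE_p within twice the 3.6 mV potential grid). Degenerate inputs:
constant traces give Φ = 0 and PCI = 0 (with a warning for the degenerate
histogram), zero-variance windows contribute zero correlation with a
warning, flat cycles raise a peaks-not-found signal, and non-positive
charges reject the log-linear decay fit.

## Known limitations

* Peak detection takes raw extrema; strongly sloped capacitive backgrounds
  would need the (off-by-default) linear baseline subtraction.
* The asymptotic KS p-value overstates significance slightly below
  n ≈ 20 per group; an exact small-sample method is out of scope.
* The equivalent-circuit model excludes constant-phase elements and
  diffusion (Warburg) impedance; spectra needing them will fit poorly.
* Absolute complexity metrics depend on sampling rate, duration and
  binning; only within-configuration comparisons are meaningful.
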