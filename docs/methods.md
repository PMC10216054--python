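# Methods

## The estimation problem

Solid tumors maintain an elevated interstitial fluid pressure (IFP), a
microenvironment marker that is normally measured by inserting a pressure
probe into the tissue. Ultrasound contrast microbubbles offer a noninvasive
route: a gas-filled, phospholipid-shelled microbubble driven near twice its
resonance frequency radiates a subharmonic component at half the transmit
frequency (f0/2), and the amplitude of that component falls approximately
linearly as the ambient hydrostatic pressure around the bubble rises.
Subharmonic-aided pressure estimation (SHAPE) turns this into a gauge: fit

    amp_dB = β0 + β1 · P            (P in mmHg, β1 < 0)

in a setting where the pressure is known, define the *pressure sensitivity*
as |β1| (dB/mmHg), and invert the line to read an unknown pressure off a
measured subharmonic amplitude.

The package implements the full chain as testable stages:

1. **Attenuation spectroscopy** (`shapeifp.attenuation`). Through-transmitted
   pulses through plain saline (reference) and the microbubble suspension
   (sample) give the attenuation coefficient over a path of z cm,

       α(f) = (8.686 / z) · (ln S_ref(f) − ln S_sample(f))   [dB/cm],

   with 8.686 = 20/ln 10 (amplitude-spectrum convention). The microbubble
   resonance is the argmax of α(f); the optimal subharmonic drive frequency
   is twice the resonance. Operand order is fixed so that attenuation is
   positive; bins where either spectrum sits more than 40 dB below its own
   peak are masked (the log of near-noise bins is meaningless), and argmax
   ties break toward the lower frequency so the output is deterministic.
   The resonance search band defaults to 2–6 MHz, inside the −6 dB band of
   a 3.5 MHz transducer with ~82% fractional bandwidth.

2. **Subharmonic extraction** (`shapeifp.extraction`). Per frame: take a
   rectangular ROI of the beamformed RF data, Hanning-window each scan line
   along the time axis, FFT with zero-padding to the next power of two ≥ 4×
   the window (so the 1 MHz band is localized with df ≪ 0.5 MHz), average
   per-line amplitude spectra linearly, and report 20·log10 of the band
   maximum in f0/2 ± 0.5 MHz. The measurement is the mean of per-frame dB
   values over 20 consecutive frames. Averaging across lines is done in
   linear amplitude (lines are one Welch-style spectral estimate); averaging
   across frames is done in dB (frames are repeated recordings of an
   amplitude). Spectra are normalized by 2/Σw so a tone of linear amplitude
   *a* reads back as *a*; all dB values then share one reference. The band
   statistic is the maximum (robust to small shifts of the subharmonic peak
   within the window); a per-bin dB mean is available as an option. Which 20
   frames enter the average is configurable (default: the first 20).

3. **Calibration and operating-point selection** (`shapeifp.calibration`).
   Ordinary least squares of amplitude on pressure; Pearson r with two-sided
   p from the t distribution on n−2 degrees of freedom (for n = 4 this is
   exactly p = 1 − |r|). Repeated acquisitions at the same pressure level
   are averaged before fitting by default, so 3 × 4 in vitro acquisitions
   enter as n = 4 — the convention under which the small-sample p values of
   the reference sweep reproduce. Across transmit pressures, the optimal
   operating point maximizes sensitivity **among entries significant at
   α = 0.05**: subharmonic generation passes through occurrence, growth
   (~0.3–0.6 MPa) and saturation stages, and a steep but non-significant fit
   is not a usable gauge. Mechanical index is PNP(MPa)/√f(MHz) — the
   square-root form is the one that reproduces the reference sweep's MI
   column. One-way tissue loss is coeff·depth·f (e.g. 0.48 dB/cm/MHz for
   fat: a 5 cm path at 8.5 MHz costs 20.4 dB), with a companion multiplier
   10^(loss/20) for restoring the in-situ pressure.

4. **Prediction and validation** (`shapeifp.validation`). IFP estimates are
   (amp − β0)/β1, never clipped (clipping would bias the error statistics
   near the range edges; implausible values are logged). Agreement is
   quantified by five repeats of a uniform random 20/10 model/validation
   split: fit on 20 tumors (per-tumor amplitude = mean of its three
   measurements), predict the held-out 10, report MAE, the sample SD and
   range of absolute errors, RMSE, and a two-sided paired t-test. Partition
   indices are recorded per repeat; each repeat uses its own spawned
   substream of the seed, so reports are bit-reproducible.

## What the synthetic generators emulate

No public RF data exist for this problem, so `shapeifp.synthetic` generates
every input with known truth at the study's own scale:

- **Amplitude datasets**: amp = β0 + β1·P + ε, ε ~ N(0, σ²) in dB
  (log-normal in linear amplitude — the analysis regresses dB). In vitro
  preset: β1 = −0.15 dB/mmHg over 10–40 mmHg in steps of 10, three repeats.
  In vivo presets: β1 = −1.019 (variant "abstract") or −1.015 ("discussion")
  — the two summaries published for the same experiment differ slightly, so
  both are exposed rather than silently resolved.
- **Noise calibration**: σ = |β1|·sd(P)·√(1/r² − 1) makes the population
  correlation equal a chosen target (0.966 in vitro; 0.853/0.848 in vivo
  against IFP ~ Uniform(3, 16) mmHg, sd 3.75). For the cohort, σ is defined
  at the *tumor level* (SD of the mean of the three injections); each raw
  measurement gets σ√3, so the calibrated correlation is the one seen when
  regressing per-tumor means — the quantity the study reports.
- **RF frame sets**: tones at f0/2, f0, 3f0/2 and 2f0 inside the ROI with
  programmed dB amplitudes (subharmonic from the pressure law), random
  phase per frame/line/tone, per-frame dB jitter (default σ = 0.5 dB, so
  20-frame averaging demonstrably reduces variance by ≈ √20), and white
  noise 60 dB below the weakest tone everywhere; outside the ROI, noise
  only. Tones rather than a Rayleigh–Plesset/Marmottant bubble ODE: no
  bubble model is part of the contract, and tones give the extraction chain
  an exact closed-form oracle. Consequently the synthetic spectra do **not**
  reproduce realistic subharmonic lineshapes, bubble destruction,
  concentration kinetics or depth-dependent attenuation — passing tests
  show the *processing chain* is correct and the statistical pipeline
  behaves as designed, not that a particular bubble physics holds.
- **Attenuation pulse pairs**: Gaussian-envelope broadband pulses; the
  sample arm is filtered by 10^(−α(f)z/20) with α a Gaussian bump (default
  peak 3 dB/cm at 4.2 MHz, SD 0.8 MHz, z = 5 cm). The filter is applied on
  a 16×-oversampled grid so the sample pulse's spectrum follows the
  intended curve below the analysis bin width. Default per-pulse noise is
  3·10⁻⁵ of the pulse peak: a Gaussian bump changes by only ~2·10⁻³ dB per
  12 kHz bin near its apex, so the noise must sit far below that for the
  argmax to stay at construction accuracy; the noise still exercises the
  50-pulse coherent-averaging path (~17 dB floor reduction).
- **Cohorts**: 30 tumors, IFP ~ Uniform(3, 16) mmHg, three measurements
  each; axes drawn log-normally (8% SD per axis) around the cube that gives
  the 200 mm³ volume threshold V = π/6·a·b·c.

Identical seeds give bit-identical outputs; RF frame sets embed their truth
in metadata.

## Numerical and design choices

- dB convention everywhere: 20·log10(linear) re 1.0. Ambient/IFP pressures
  in mmHg, acoustic pressures in kPa (MI computed from MPa), conversions via
  named helpers only.
- Indices 0-based and half-open; the time axis is always last.
- FFT zero-padding factor 4 in both the attenuation and extraction paths.
- Degenerate inputs fail loudly: all-equal pressures, sub-Nyquist sampling,
  empty frame sets, out-of-band extraction windows, no significant sweep
  entry. A zero band amplitude returns −inf dB with a warning rather than
  raising.
- Cross-validation SD column is the SD of *absolute* errors (it sits next
  to the MAE); this is an interpretive choice, as is averaging a tumor's
  three injections before fitting.

## Problem sizes

The test suite and the acceptance script use: 50-pulse ensembles of 1024
samples at 50 MHz for attenuation; 20-frame, 16-line, 512-sample frame sets
at 62.5 MHz (ROI 8 lines × 256 samples) for extraction; 3 × 4 acquisitions
for the in vitro fit; 30-tumor cohorts for calibration and validation, with
1000-seed coverage sweeps and 50-seed error-scale sweeps. These sizes
resolve every quantity the analysis reports while keeping the whole suite
in a few seconds.

## Known limitations

- Tone-based RF synthesis (above): no bubble physics, destruction,
  temperature or perfusion effects.
- The attenuation stage omits diffraction/transducer-response correction
  and treats time-resolved attenuation kinetics as separate static inputs.
- The calibration is strictly linear; sigmoidal or piecewise
  amplitude–pressure models and clinical MI compliance checks are out of
  scope.
- Predictions are extrapolations when amplitudes fall outside the fitted
  range; they are flagged, not clipped.
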