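# Methods

This note documents the models behind `photoblue`, the default parameters
and why they were chosen, the numerical choices that matter, and what the
synthetic data does and does not emulate.

## Photoconversion kinetics

Illumination drives a fluorophore population through three states with
continuous-time first-order kinetics,

    red --k_blue--> blue,   red --k_bleach_red--> dark,   blue --k_bleach_blue--> dark,

with one imaging frame as the unit dose (rates in frame⁻¹). The fractions
follow `exp(Q t) (1,0,0)` with `Q` the generator matrix, sampled at integer
frames; no direct blue→red back-conversion is modelled. The closed form is
verified against an explicit-Euler integrator to < 1e-6 in the tests.

Default rates — `k_blue = 0.03`, `k_bleach_red = 0.05`,
`k_bleach_blue = 0.01` per frame — are a *scenario preset*, not a
measurement: no rate constants are measurable from ensemble imaging alone.
They were chosen once so that ~20 % of the initial molecules are photoblued
after ten frames and roughly half the red pool has reacted, the regime in
which the artifact is clearly measurable. STED presets scale all rates up
(larger dose per frame); the oxygen-depletion preset multiplies `k_blue` by
0.1 (the conversion pathway is oxidative and is suppressed without oxygen;
the suppression factor is a free knob because no rate is measurable).
Whether oxygen depletion should also rescale the bleaching rates is left as
an independent knob for the same reason.

Exchangeable (PAINT-mode) probes bind their target transiently, so reacted
molecules are replaced from solution between frames. This is modelled as a
full pool reset — the trajectory reports (1, 0, 0) at every frame — and
partial-exchange rates are not modelled. The brightness of the photoblued
species relative to common green/orange dyes under blue excitation is the
tunable `brightness_ratio_blue` (default 0.02, i.e. 50× dimmer, inside the
observed 20–100× range).

## Emission spectra and unmixing

Spectra are generated and fitted with the asymmetric log-normal peak

    I(λ) = A · exp(−ln2 · [ln(1 + 2a(λ−λmax)/w) / a]²),   zero outside its support,

where `A` is the peak intensity, `λmax` the peak position, `w` the
approximate FWHM and `a` the asymmetry (Gaussian of FWHM `w` as a→0). The
asymmetry is frozen at 0.24 for dye emission. This parameterization is a
deliberate reimplementation choice: it is the standard asymmetric
log-normal peak expressed directly in the parameters of interest (λmax, w,
a).

Binned expected counts use the midpoint rule (`shape(center)·width`); the
12.5 nm channel width is small against the ≥ 40 nm line widths, and the
identical expression is used by generator and fitter so round trips are
exact. The default grid is 16 channels × 12.5 nm starting at 575 nm.

Fitting is weighted least squares with Poisson weights 1/√(counts+1)
(photon-counting detector). Background is a constant, estimated as the mean
of the two lowest-count bins among the two outermost bins on each side, and
subtracted with clipping at zero; the method is a choice, since only the
fact of background subtraction is standard, not its estimator. The
two-component unmixing freezes the shape (λmax, w, a) of the
pre-irradiation component and refits only its amplitude — "fixing the
parameters" of a known component is ambiguous between freezing and
re-scaling, and freezing the amplitude too would conflate bleaching with
unmixing. The blue component's peak is constrained below the red peak;
fitted shifts under 2 nm are flagged as non-detections.

The reported fraction of the photoblued species is its **area fraction**
over the recorded window (amplitude fractions are also computed); area is
chosen because it is insensitive to line-width differences between the
species.

## FCS simulation and analysis

The trace simulator places `n_molecules` 2D Brownian walkers in a periodic
box, detects them through a Gaussian profile `exp(−2r²/ω₀²)` centred in the
box, gates each molecule by a two-state bright/triplet Markov chain
(stationary dark fraction `T`, correlation time `τ_triplet`, exact one-bin
propagator), and draws per-bin photon counts Poisson. Theoretical values:
transit time `τ_D = ω₀²/4D` and amplitude `N_eff = n·πω₀²/L²` (2D Gaussian
effective area). Defaults: ω₀ = 240 nm (confocal), D = 1 µm²/s (lipid in a
supported bilayer), T = 0.15 with τ_triplet = 5 µs, 30 kHz peak emission per
molecule, 0.1 ms bins, 10 s acquisition (a typical point-FCS measurement;
recovery studies use 60 s).

Box size matters: in a periodic box the correlation tail is cut off at the
slowest diffusion mode `L²/4π²D`, and the fixed molecule number suppresses
the amplitude by ~`πω₀²/L²`. With the default `L = 3000 nm` the cutoff sits
at ~16 τ_D and both artifacts stay well below the recovery tolerances; a
2000 nm box produced a systematic −20 % τ_D bias and was rejected. For the
same reason the pipeline fits are restricted to lags ≤ 0.1 s (~7 τ_D), the
conventional "fit to where the curve has decayed" window.

The correlator is a multi-tau design: 16 lags per octave, pairwise bin
coarsening, symmetric normalization (each lag normalized by the means of
its two overlapping segments). Lag 0 is never reported and the first
correlator bin is excluded from fits (shot-noise/afterpulsing convention).
Per-lag standard errors come from splitting the trace into 10 equal blocks
and taking the across-block standard error; lags not resolvable within a
block carry no error estimate and are dropped from weighted fits. When a
trace's bin time exceeds τ_triplet the triplet gating coarse-grains into
uncorrelated per-bin noise — correct physics at those lags, but triplet
parameters are then not recoverable; resolving them requires bins ≲
τ_triplet/5.

Model fitting uses the 2D anomalous-diffusion model, optionally with the
triplet factor; any parameter can be frozen (e.g. τ_triplet to the
independently determined 5 µs, or α to 1 for free diffusion; α is otherwise
bounded to [0.3, 2]). Brightness is Q = mean rate / N; for the simulator's
Gaussian profile the expected Q is `counts_per_molecule/2 · (1−T)`.
Molecule percentages are `100·N(t)/N(0)` against the initial red-channel N.
The apparent STED spot follows `ω₀,STED = ω₀,conf·√(τ_D,STED/τ_D,conf)`.
In the pipeline, per-frame measurements average nothing across repeats;
with real repeated measurements the curves should be averaged before
fitting (parameter averaging is the documented alternative).

## GP imaging

Membrane pixels emit into a blue (580–630 nm) and a red (650–700 nm) band
such that per-pixel GP = (I_b−I_r)/(I_b+I_r) equals the prescribed truth;
photoblueing moves the fraction `f_blue/(f_red+f_blue)` of red-band
emission into the blue band (apparent GP = gp + φ(1−gp), strictly
increasing in φ), survival `f_red+f_blue` scales the intensity, and shot
noise/saturation are applied on demand. Masking keeps pixels with summed
intensity ≥ 20 % of the image maximum (the threshold is configurable; the
published analyses do not print theirs) and excludes saturated pixels. The
frame-0 mask is reused across the series so bleaching-driven mask shrinkage
cannot bias the time course. Pixels with zero summed intensity are masked,
not set to GP 0. The primary statistic is the mean of per-pixel GP values,
matching per-pixel ratiometric practice.

## FLIM

Antibodies carrying `n ≥ 2` dyes show mutual quenching: while ≥ 2 dyes
survive, each emits with reduced yield (default 0.3 of a lone dye) and the
quenched lifetime (default 2.3 ns); a lone survivor emits at full yield
with the unquenched lifetime (default 3.5 ns). Dyes bleach independently
per frame (default probability 0.12). This two-level yield/lifetime switch
reproduces the rise-then-fall intensity curve (quenched yield < ½) and the
> 1 ns ensemble lifetime rise; distance-dependent energy-transfer physics
is not modelled. The exact expectation (binomial survivor enumeration) is
computed alongside the Monte-Carlo ensemble and serves as its oracle.

Decays are exponential arrival times wrapped into a 25 ns period (40 MHz
pulsed excitation), optionally jittered by a Gaussian instrument response
and mixed with uniform background, histogrammed into 250 bins. Wrapping an
exponential into the period yields exactly the truncated exponential, so
the mean arrival time obeys ⟨t⟩ = τ − T·e^(−T/τ)/(1−e^(−T/τ)), which the
mean-arrival estimator inverts numerically (bracketing root search). The
correction matters at the percent level for τ ≈ T/5 and is negligible for
τ ≪ T. Background is auto-estimated from the last 10 % of the period,
iteratively corrected for the decay's own tail (the wrapped exponential
never vanishes there); a known background can be passed instead, and with
a fixed background the mean-arrival estimator is exactly linear in photon
mixtures. The mono-exponential fit is weighted least squares of
`A·e^(−t/τ)+B` from the peak bin (two bins later when the declared IRF
width exceeds half a bin). Estimators return flagged results — never
silent failures — on too few photons (< 100), absent decay signal, or
boundary-pinned fits. Frame series pool photons per frame and fit the
pooled decay; per-pixel fitting with IRF deconvolution, as commercial FLIM
software performs, is intentionally out of scope and the estimators here
are validated only against this package's own generator.

## Pipeline determinism and sizes

Every run derives per-stage random streams from one global seed
(`SeedSequence([seed, stage, k])`), so identical resolved configurations
reproduce every table bit-identically and stages do not perturb each other.
Default problem sizes — 60 s / 0.1 ms traces (600 000 bins), 64×64 image
stacks over 30 frames, 4000-antibody ensembles, 2×10⁵-count spectra — were
chosen so the full verification suite represents each measurement at
realistic signal levels while a complete run stays in the minutes range on
one CPU.

## What the synthetic data does not show

Passing tests demonstrate the *analysis* is correct against the *assumed*
photophysics. The generators do not model photochemical mechanism (singlet
oxygen, N-dealkylation), 3D point-spread functions or axial diffusion,
detector afterpulsing or dead time, STED depletion-pattern physics, spectral
instrument response, or partial dye exchange kinetics. Conclusions about
real samples inherit those assumptions; rate presets in particular are
qualitative regimes, not calibrated constants.
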