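# Methods

This note records the models implemented in `smfluor`, the defaults and why
they were chosen, what the synthetic-data layer does and does not emulate,
and the numerical decisions that shape the results.

## ALEX burst analysis

### Timing model

Excitation alternates with period 100 µs and a 40% duty cycle per laser.
The window placement within the period is a convention: donor excitation
occupies [0, 40) µs and acceptor excitation [50, 90) µs, leaving symmetric
10 µs guard gaps so that detector afterglow at window edges cannot mix
streams. Timestamps are integer microseconds and windows are half-open,
which makes stream splitting exact at boundaries. Photons falling in the
guard gaps are labelled `off_window`; they count toward the burst-search
rate (they are real detected photons) but not toward any stream.

### Burst search

Bursts are maximal runs of contiguous 1 ms windows whose all-photon rate
exceeds 3 kHz, kept when they contain at least 40 photons (the midpoint of
the conventional 35–50 range; both threshold and floor are parameters). A
binned-rate search was chosen over a sliding (Lee/Seidel-style) search
because the detection criterion being modelled is exactly a rate threshold
plus a photon floor; the binning granularity only matters within one
smoothing window of a burst's edges, and the photon floor dominates false
positive rejection. At default background rates (≤0.5 kHz total) the false
positive rate is negligible: a window must collect >3 background photons
*and* the run must reach 40 photons.

### Corrections

The correction chain follows the standard ALEX convention:

1. raw proximity ratio and stoichiometry from the four stream counts;
2. crosstalk subtraction, F_fret = F_DexAem − Lk·F_DexDem − Dir·F_AexAem,
   floored at zero;
3. γ-corrected efficiency E = F_fret/(F_fret + γ·F_DexDem).

Lk and Dir are medians of the per-burst ratios F_DexAem/F_DexDem over
donor-only bursts (S_raw > 0.85) and F_DexAem/F_AexAem over acceptor-only
bursts (S_raw < 0.15). Medians, not means: at ~100 photons per burst these
ratios are heavy-tailed and a single bright contaminant burst can drag a
mean far off. Each calibration subpopulation must contain at least 20
bursts, otherwise a `CalibrationError` instructs the caller to supply
external factors.

γ comes from two (or more) FRET standards of distinct mean efficiency
(ΔE ≥ 0.1 required). Each standard contributes one point at its population
mean — computed as ratios of summed counts, which is less biased than a mean
of per-burst ratios — and a straight line 1/S = Ω + Σ·E is fitted; then
γ = (Ω − 1)/(Ω + Σ − 1). Calibration uses crosstalk-corrected but
γ-uncorrected values; this is self-consistent because the accurate-E formula
applies γ only to the donor term. The convention was validated by
simulation: with the photon model below, the calibrated γ recovers the
generator's γ within ~2–3% at 2 standards × 2000 bursts, across the
0.75–1.2 range the method needs to cover.

Bursts with a zero denominator in any ratio are flagged `defined = False`
and excluded from histograms but retained in the table.

## The ALEX photon simulator

Per burst the generator draws a species, then detected-photon counts with
channel means

    Dex→Dem : B·(1−E)      Dex→Aem : B·γ·E      Aex→Aem : B_A

where B and B_A are the species' donor- and acceptor-excitation brightness.
This is the parameterisation under which (a) the accurate-FRET estimator is
centred on the true E, and (b) the calibration line 1/S = Ω + Σ·E is exactly
linear with Ω = 1 + B_A/B and Σ = (B_A/B)(1−γ)/γ — so γ recovery is a sharp
test, not an approximate one. Totals are drawn as a floored Poisson
(shifted-Poisson, default mean 100, floor 40) and split multinomially, which
preserves the channel ratios exactly; each species is rescaled to the same
mean total so that subpopulation counting statistics are comparable.

Distortions are applied in the inverse order of the corrections:
γ-weighted partition → leakage → direct excitation → background. Leakage
adds Poisson(Lk·F_DexDem) counts to the acceptor channel; it does not
remove them from the donor channel. This models spectral bleed-through —
donor emission appearing in the acceptor detection band does not change
what the donor bandpass collects — and it is the choice under which the
ratio estimator for Lk is centred on the true value and the calibrated γ
coincides with the instrument γ. (The alternative, *moving* photons between
channels, depletes the donor count and silently rescales the effective γ by
1 + Lk; the analysis chain remains self-consistent either way, but ground
truth and calibration then disagree by construction.) Direct excitation adds
Poisson(Dir·F_AexAem) to the Dex→Aem stream. Background photons arrive as a
homogeneous Poisson process per detector (default 0.2 kHz each).

Timestamps are placed on the integer-microsecond grid inside the correct
excitation windows, sampling slots without replacement so the stream is
strictly increasing by construction. Burst inter-arrival times are
exponential with mean 50 ms and bursts nominally span 1 ms, so bursts are
well separated at defaults. There is no diffusion-path or optics physics:
brightness is an effective per-burst quantity, and burst duration carries no
information. Consequences worth noting: the simulator cannot produce
within-burst dynamics, brightness–duration correlations, or shot-noise
artifacts of very short bursts, so passing recovery tests demonstrates the
correctness of the estimator algebra and calibration logic, not robustness
to those real-data features.

The scenario presets (`free-sigma54`, `holoenzyme`, `rpc`, `late-melted`,
`plus-pspf`, `plus-adp-alfx`, `plus-atp`) encode the σ54 state efficiencies
and population fractions as generator parameters, with 15% donor-only and
10% acceptor-only contaminants so self-calibration always has material to
work with. The instrument preset (γ = 0.9, Lk = 0.08, Dir = 0.06) sits in
the middle of the calibrated range. The trapped-intermediate preset's
low-FRET state is specified in the source material by a distance change
(~10 Å beyond the nucleotide-free complex) rather than an efficiency; the
preset uses E ≈ 0.14, the Förster inversion of that displacement at
R0 = 60 Å.

## TIRF donor-bleaching FRET

Background per channel is the mean of the last 30 frames (3 s at 100 ms
frames — "several seconds" after both dyes have bleached). Change points are
found per channel by binary segmentation minimizing within-segment squared
error, with a split accepted only when it reduces the cost by more than a
BIC-style penalty 2σ²·ln(n); σ is estimated robustly from the median
absolute deviation of first differences, so noiseless staircases are
segmented exactly and pure noise produces no splits. Minimum segment length
is 5 frames.

A trajectory is usable when the acceptor channel has exactly one downward
step, the donor channel exactly one downward step landing at background
(within noise), and the acceptor step precedes the donor step. Donor
blinking (two donor down-steps), donor-first bleaching (both channels drop
together) and non-single-step traces are returned `usable = False` rather
than raising. With a 50/50 bleach-order mix the detected usable fraction
tracks the simulated one to within a few percent.

The efficiency E = (I_d − I_da)/I_d uses at least 5 frames per averaging
region. It is intrinsically γ-free (both averages come from the same
detector channel) and no leakage correction is applied; it is exactly
invariant to a common additive offset because background subtraction
absorbs it. On noiseless traces the estimator returns the generator's E to
machine precision; averaging makes the per-molecule sd scale as the inverse
square root of the region length.

## Population decomposition

Histograms use bin width 0.025 over [−0.1, 1.1]; out-of-range values land in
the end bins so counts are conserved. The model is y0 + Σ areaᵢ·N(E; meanᵢ,
widthᵢ) with 1 or 2 components, fitted by bounded nonlinear least squares
(lmfit, trust-region `least_squares`; MINPACK `leastsq` stalls when a
parameter starts on a bound, so it is not used). Components are
parameterised by integrated area so fractions are direct area ratios.
Initialisation takes the n highest distinct local maxima of the
3-bin-smoothed histogram, with deterministic restarts (shifted means and a
quantile-based start) guarding against shoulder captures.

Model selection uses the least-squares AIC, N·ln(RSS/N) + 2k, k = 3n + 1,
ties to the simpler model; AICc is available behind a flag. Fits are
unweighted by default, matching common curve-fitting practice for these
histograms; Poisson weighting (1/√count) is available behind a flag. Two
degeneracy rules reject an n = 2 solution before it reaches the AIC
comparison: a component carrying less than about half an event, and a pair
of components whose means are closer than twice the larger width. The
latter matters: on unimodal counting data a second Gaussian inside the main
peak always absorbs some shot noise and the raw AIC rewards it; such a pair
is not two resolvable populations in any physical sense. With the rule in
place, Monte Carlo at the regimes of interest (one state at E = 0.75 vs two
states at 0.74/0.49 separated by ~4 widths) selects the correct n in ≥95%
of replicates, while two-state recovery keeps means within ±0.02 and the
major fraction within ±0.05.

## Distances

R = R0·(1/E − 1)^(1/6) with R0 a parameter, default 60.0 Å — the standard
literature value for the AF488/AF594 pair, validated here by the residual
bound over the σ54 state conversions (all printed (E, R) pairs reproduce
within 1.5 Å; E = 0.75 → 50.0 Å is exact). Efficiencies are required to be
strictly inside (0, 1); distances are reported to 0.1 Å. No κ² orientation
modelling and no dye-linker accessible-volume correction: reported R values
are relative inter-dye separations, which is what conformational *changes*
require.

## FCS

The single-component 3D Gaussian-focus model with the axial ratio κ fixed
at 6.0 (typical confocal value; fittable behind a flag). The lateral focal
radius w0 is a calibration input (default 250 nm), and temperature/viscosity
default to 30 °C water (η = 0.7972 mPa·s) to match the assay conditions.
Fits initialise from the curve itself (amplitude → N, half-amplitude lag →
τ_D) and warn when the lag grid does not extend past τ_D. No triplet or
multi-component models; the simulator produces curves directly rather than
correlating photon streams.

## Bulk assays

Anisotropy is r = (I_vv − G·I_vh)/(I_vv + 2G·I_vh), scale-invariant by
construction. Binding titrations are fitted with intensity = 1 −
amplitude·f_bound where f_bound is the exact single-site quadratic
(tight-binding) solution; this is the default rather than the hyperbola
because the regime of interest has the labelled species (10 nM) some 50-fold
above Kd (~0.2 nM), where ligand depletion makes the hyperbola badly biased.
The hyperbolic model is available and agrees with the quadratic to <1% in
the trace-labelled limit. ATPase rates come from the linear-regression slope
of A340 vs time divided by the NADH extinction coefficient (6220 M⁻¹cm⁻¹,
the standard value, a named constant) and the enzyme concentration;
non-decreasing traces are flagged rather than rejected. Michaelis–Menten
fits are plain least squares of v = Vmax·S/(KM + S).

## Problem sizes and numerical defaults

The recovery tests run at the sizes the claims refer to: 5000 bursts for the
two-state end-to-end chain, 2000 bursts per γ standard × 5 seeds × 3 γ
values, 200 molecules per TIRF ensemble, 40 Monte Carlo replicates per
model-selection regime, 2000–5000 events per histogram. All simulators take
explicit integer seeds (numpy `default_rng`); identical seeds are
bit-reproducible and results bundles serialize to byte-identical JSON.
Floors and tolerances: burst totals floored at the burst-search minimum so
simulated bursts are findable by construction; Gaussian widths bounded below
by half a bin; E_acc clipped to [−0.1, 1.1] for histogramming only, with the
raw value retained.

## Known limitations

- No within-burst dynamics, lifetime, polarization-resolved or
  burst-variance analysis; a molecule interconverting faster than its
  transit produces a single averaged E here.
- The burst search does not split merged events: two molecules closer than
  one smoothing window appear as one burst (at default occupancy this is
  ~2% of events).
- TIRF spot extraction is upstream: trajectories are inputs, and EMCCD gain,
  registration error and local background structure are not modelled.
- The mixture model caps at two components by design.
- FCS assumes one diffusing species and no photophysics; R_h is only as good
  as the w0 calibration.
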