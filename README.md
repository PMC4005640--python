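# smfluor

Single-molecule fluorescence analysis for mapping protein conformational
states: ALEX smFRET burst analysis with full crosstalk and γ calibration,
donor-bleaching FRET for immobilized complexes imaged by TIRF, Gaussian
population decomposition with AIC model selection, Förster-distance
conversion, FCS diffusion analysis with Stokes–Einstein hydrodynamics, and
the accompanying bulk assays (anisotropy, tight-binding titrations,
NADH-coupled ATPase kinetics).

The package was built around a concrete use case — resolving the
conformational states of the bacterial sigma factor σ54 as its
activator-binding domain (Region I) and DNA-binding domain (Region III)
rearrange during transcription activation — but every stage is generic.
Because raw instrument traces for such experiments are rarely deposited, the
package ships a first-class synthetic-data layer that forward-simulates
photon streams, bleaching trajectories, FCS decays and assay curves with
known ground truth, so the entire analysis chain is verifiable by parameter
recovery.

## The measurements and models

**ALEX burst analysis.** Alternating laser excitation interleaves donor and
acceptor excitation on a 100 µs period (40% duty cycle). Each photon is
classified by excitation window × detector into four streams; bursts from
single diffusing molecules are found with an all-photon rate threshold
(3 kHz) and a minimum photon count (40). Per burst,

    E_raw = F_DexAem / (F_DexAem + F_DexDem)
    S_raw = (F_DexAem + F_DexDem) / (F_DexAem + F_DexDem + F_AexAem)

Stoichiometry S separates donor-only (S ≈ 1) and acceptor-only (S ≈ 0)
molecules from dual-labelled ones, and those contaminant populations
calibrate the donor-leakage factor Lk and the direct-excitation factor Dir.
After crosstalk subtraction (F_fret = F_DexAem − Lk·F_DexDem − Dir·F_AexAem)
the detection-correction factor γ is fitted from two FRET standards of
distinct efficiency through the linear relation 1/S = Ω + Σ·E, with
γ = (Ω − 1)/(Ω + Σ − 1), giving the accurate efficiency

    E = F_fret / (F_fret + γ·F_DexDem)

**TIRF donor-bleaching FRET.** For surface-immobilized complexes recorded at
100 ms/frame, trajectories showing the useful bleaching sequence (acceptor
bleaches first, then the donor, each in a single step) yield a γ-free
per-molecule efficiency E = (I_d − I_da)/I_d from the donor intensity before
(I_da) and after (I_d) acceptor bleaching. Bleach steps are located by
binary-segmentation least-squares change-point detection.

**Populations and distances.** Efficiency histograms (bin 0.025) are fitted
with y0 plus one or two Gaussians parameterised by area, so population
fractions are area ratios; the component count is chosen by the
least-squares AIC, N·ln(RSS/N) + 2k with k = 3n + 1. Mean efficiencies map
to inter-dye distances through the Förster relation R = R0·(1/E − 1)^(1/6)
(R0 = 60 Å for the AF488/AF594 pair).

**FCS.** Autocorrelation curves are fitted with the single-component 3D
diffusion model G(τ) = (1/N)(1 + τ/τ_D)⁻¹(1 + τ/(κ²τ_D))^(−1/2); the
diffusion time converts to D = w0²/(4τ_D) and R_h = k_BT/(6πηD).

## Worked example

Simulate a two-state sample (states at E = 0.74 and 0.49, 73/27 mixing, with
donor-only/acceptor-only contaminants, γ = 0.9, Lk = 0.08, Dir = 0.06,
background) and run the complete analysis chain:

```python
from smfluor import alex, populations, presets, synthetic
from smfluor.distances import ForsterParams, distance_from_E

species = presets.preset_species("free-sigma54")
instrument = presets.preset_instrument("free-sigma54")
stream, _ = synthetic.simulate_alex_experiment(species, instrument, n_bursts=5000, seed=1)

standards = [
    alex.raw_es(alex.find_bursts(synthetic.simulate_fret_standard(E, instrument, seed=s)[0]))
    for E, s in ((0.3, 11), (0.8, 12))
]
table = alex.analyze_stream(stream, standard_tables=standards)
f = table.factors
print(f"Lk={f.Lk:.3f}  Dir={f.Dir:.3f}  gamma={f.gamma:.3f}")

dual = table.df.query("0.25 < S_corr < 0.8").dropna(subset=["E_acc"])
fit = populations.fit_populations(populations.fret_histogram(dual["E_acc_clip"]))
r0 = ForsterParams(R0=60.0)
print(f"{fit.n} population(s):")
for comp, frac in zip(fit.components, fit.fractions):
    print(f"  E = {comp.mean:.2f}  ({frac:.0%} of bursts)  ->  R = {distance_from_E(comp.mean, r0):.1f} A")
```

Output:

```
Lk=0.079  Dir=0.060  gamma=0.915
2 population(s):
  E = 0.74  (73% of bursts)  ->  R = 50.4 A
  E = 0.49  (27% of bursts)  ->  R = 60.6 A
```

The chain self-calibrates Lk and Dir from the contaminant populations,
recovers γ from the two simulated standards, selects two Gaussian
components by AIC, and returns the state means, their population fractions
and the corresponding inter-dye distances — all within tolerance of the
simulation's ground truth.

The same stages are scriptable from the shell:

```
smfluor simulate-alex --preset free-sigma54 --seed 1 --out run/
smfluor analyze-alex --photons run/photons.h5 --out run/
smfluor fit-populations --evalues run/bursts.csv --out run/populations.json
smfluor distances --evalues 0.74,0.49 --r0 60
```

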