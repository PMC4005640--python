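"""Generator presets encoding the σ54 experimental scenarios.

Each preset is a species list + instrument model whose FRET means and
population fractions are the values reported for that state of the σ54
transcription-activation cycle, so simulated runs double as regression
fixtures for the full pipeline.  Dual-labelled fractions are scaled to
leave room for donor-only (0.15) and acceptor-only (0.10) contaminants,
which every real sample contains and which the crosstalk calibration
requires.

The nucleotide-free +PspF low-FRET state is printed as E = 0.27; the
ADP·AlFx-trapped state is specified by its further ~10 Å separation
(E ≈ 0.14 at R0 = 60 Å).
"""

from __future__ import annotations

from .synthetic import InstrumentModel, SpeciesModel

DONOR_ONLY_FRACTION = 0.15
ACCEPTOR_ONLY_FRACTION = 0.10

#: (E, fraction-of-dual) pairs per scenario
_SCENARIOS: dict[str, list[tuple[float, float]]] = {
    "free-sigma54": [(0.74, 0.73), (0.49, 0.27)],
    "holoenzyme": [(0.71, 1.0)],
    "rpc": [(0.75, 1.0)],
    "late-melted": [(0.73, 0.57), (0.29, 0.43)],
    "plus-pspf": [(0.73, 0.22), (0.27, 0.78)],
    "plus-adp-alfx": [(0.73, 0.22), (0.14, 0.78)],
    "plus-atp": [(0.22, 1.0)],
}

#: instrument distortions typical of the calibrated range (γ within 0.75–1.2)
DEFAULT_INSTRUMENT = InstrumentModel(
    Lk_true=0.08, Dir_true=0.06, gamma_true=0.9,
    bg_rate_donor_kHz=0.2, bg_rate_acceptor_kHz=0.2,
)


def preset_names() -> list[str]:
    return sorted(_SCENARIOS)


def preset_species(name: str, with_contaminants: bool = True) -> list[SpeciesModel]:
    """Species list for a named scenario."""
    if name not in _SCENARIOS:
        raise KeyError(f"unknown preset {name!r}; choose from {preset_names()}")
    dual_total = 1.0 - (DONOR_ONLY_FRACTION + ACCEPTOR_ONLY_FRACTION) if with_contaminants else 1.0
    species = [
        SpeciesModel(true_E=E, label_state="dual", fraction=round(frac * dual_total, 12))
        for E, frac in _SCENARIOS[name]
    ]
    if with_contaminants:
        species.append(SpeciesModel(
            true_E=0.0, label_state="donor_only",
            fraction=DONOR_ONLY_FRACTION, brightness_Aex=0.0,
        ))
        species.append(SpeciesModel(
            true_E=0.0, label_state="acceptor_only", fraction=ACCEPTOR_ONLY_FRACTION,
        ))
    total = sum(s.fraction for s in species)
    if abs(total - 1.0) > 1e-9:  # absorb rounding into the first species
        first = species[0]
        species[0] = SpeciesModel(
            true_E=first.true_E, label_state=first.label_state,
            fraction=first.fraction + (1.0 - total),
            brightness_Dex=first.brightness_Dex, brightness_Aex=first.brightness_Aex,
        )
    return species


def preset_instrument(name: str) -> InstrumentModel:
    """Instrument model for a named scenario (shared across presets)."""
    if name not in _SCENARIOS:
        raise KeyError(f"unknown preset {name!r}; choose from {preset_names()}")
    return DEFAULT_INSTRUMENT
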