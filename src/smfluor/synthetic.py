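"""Forward simulation of every data type the analysis pipeline consumes.

Each simulator takes an explicit integer seed and returns ground truth next
to the data, so downstream stages (burst search, crosstalk/γ calibration,
donor-bleaching FRET, mixture fitting, FCS and assay fits) are all testable
by parameter recovery.

ALEX photon model
-----------------
A burst from a dual-labelled molecule with true efficiency E produces
detected photons with channel means

    Dex→Dem : B·(1−E)        Dex→Aem : B·γ·E        Aex→Aem : B_A

(B = ``brightness_Dex``, B_A = ``brightness_Aex``, γ the instrument's
detection-correction factor).  This is the parameterisation under which the
accurate-FRET estimator F_A/(F_A + γ·F_D) is centred on E and the
calibration line 1/S = Ω + Σ·E is exactly linear.  Distortions are applied
in the order γ-weighted partition → leakage → direct excitation →
background, the inverse of the correction order in the analysis.  Leakage adds
Poisson(Lk·F_DexDem) photons to the acceptor channel — donor emission
bleeding into the acceptor detection band, which does not deplete the
donor-channel count — so the ratio F_DexAem/F_DexDem is centred on Lk and
the calibrated γ coincides with the instrument's γ even under crosstalk;
direct excitation adds Poisson(Dir·F_AexAem) counts.  Photon totals are shifted-Poisson with a
floor; burst inter-arrival times are exponential (default 50 ms) so bursts
are well separated; timestamps are integer microseconds placed inside the
proper excitation windows.

The simulator has no diffusion-path or optics physics: brightness is an
effective per-burst quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alex import AlternationScheme, PhotonStream
from .assays import bound_fraction_quadratic, michaelis_menten
from .fcs import FcsCurve, fcs_model
from .tirf import Trajectory

LABEL_STATES = ("dual", "donor_only", "acceptor_only")


@dataclass(frozen=True)
class SpeciesModel:
    """One molecular species in an ALEX sample, with known ground truth."""

    true_E: float
    label_state: str
    fraction: float
    brightness_Dex: float = 100.0
    brightness_Aex: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_E <= 1.0:
            raise ValueError(f"true_E must be in [0, 1], got {self.true_E}")
        if self.label_state not in LABEL_STATES:
            raise ValueError(f"unknown label_state {self.label_state!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.brightness_Dex < 0 or self.brightness_Aex < 0:
            raise ValueError("brightness values must be non-negative")
        if self.label_state == "donor_only" and self.brightness_Aex != 0:
            object.__setattr__(self, "brightness_Aex", 0.0)


@dataclass(frozen=True)
class InstrumentModel:
    """True instrument distortions used to validate the calibration chain."""

    Lk_true: float = 0.0
    Dir_true: float = 0.0
    gamma_true: float = 1.0
    bg_rate_donor_kHz: float = 0.2
    bg_rate_acceptor_kHz: float = 0.2
    alternation: AlternationScheme = field(default_factory=AlternationScheme)

    def __post_init__(self) -> None:
        if self.Lk_true < 0 or self.Dir_true < 0:
            raise ValueError("crosstalk factors must be non-negative")
        if self.gamma_true <= 0:
            raise ValueError("gamma_true must be positive")
        if self.bg_rate_donor_kHz < 0 or self.bg_rate_acceptor_kHz < 0:
            raise ValueError("background rates must be non-negative")


@dataclass(frozen=True)
class TirfGroundTruth:
    """True levels and bleach times behind one simulated TIRF trajectory."""

    true_E: float
    Id_level: float = 1000.0     # donor counts/frame with no acceptor
    bg_d: float = 100.0
    bg_a: float = 80.0
    acceptor_bleach_frame: int = 150
    donor_bleach_frame: int = 350
    noise_sd: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_E <= 1.0:
            raise ValueError("true_E must be in [0, 1]")
        if self.acceptor_bleach_frame >= self.donor_bleach_frame:
            raise ValueError("acceptor must bleach before the donor")
        if min(self.Id_level, self.bg_d, self.bg_a, self.noise_sd) < 0:
            raise ValueError("levels must be non-negative")


def _validate_species(species: list[SpeciesModel]) -> None:
    if not species:
        raise ValueError("species list must not be empty")
    total = sum(s.fraction for s in species)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"species fractions sum to {total}, expected 1")


def _channel_means(s: SpeciesModel, gamma: float) -> np.ndarray:
    """Mean (DexDem, DexAem, AexAem) counts per burst for one species."""
    if s.label_state == "donor_only":
        return np.array([s.brightness_Dex, 0.0, 0.0])
    if s.label_state == "acceptor_only":
        return np.array([0.0, 0.0, s.brightness_Aex])
    E = s.true_E
    return np.array(
        [s.brightness_Dex * (1.0 - E), s.brightness_Dex * gamma * E, s.brightness_Aex]
    )


def _window_slots(scheme: AlternationScheme, window: tuple[float, float],
                  base_cycle: int, n_cycles: int) -> np.ndarray:
    """All integer-µs timestamps inside one excitation window over n cycles."""
    w0, w1 = int(window[0]), int(window[1])
    offsets = np.arange(w0, w1)
    cycles = (base_cycle + np.arange(n_cycles)) * int(scheme.period_us)
    return (cycles[:, None] + offsets[None, :]).ravel()


def simulate_alex_experiment(
    species: list[SpeciesModel],
    instrument: InstrumentModel,
    n_bursts: int,
    photons_per_burst_mean: float = 100.0,
    min_photons_floor: int = 40,
    mean_interarrival_ms: float = 50.0,
    burst_duration_ms: float = 1.0,
    seed: int = 0,
) -> tuple[PhotonStream, pd.DataFrame]:
    """Simulate a diffusing-molecule ALEX acquisition with known ground truth.

    Returns the photon stream and a per-burst ground-truth table holding the
    species, true efficiency, burst window, and the realised four-stream
    counts after leakage and direct excitation (background photons are
    timestamped separately and recorded per burst window).

    ``photons_per_burst_mean`` rescales every species' brightness so the mean
    *total* detected signal per burst is about that value; totals are drawn
    shifted-Poisson with floor ``min_photons_floor``.
    """
    _validate_species(species)
    if n_bursts < 0:
        raise ValueError("n_bursts must be non-negative")
    if photons_per_burst_mean <= 0 or burst_duration_ms <= 0 or mean_interarrival_ms <= 0:
        raise ValueError("photon and timing parameters must be positive")
    rng = np.random.default_rng(seed)
    scheme = instrument.alternation
    period = int(scheme.period_us)
    cycles_per_burst = max(int(burst_duration_ms * 1000.0 / period), 1)

    empty_truth = pd.DataFrame(
        columns=["burst_id", "species_index", "label_state", "true_E", "t_start",
                 "t_end", "n_signal", "F_Dex_Dem", "F_Dex_Aem", "F_Aex_Aem",
                 "F_Aex_Dem", "n_bg_donor", "n_bg_acceptor"]
    )
    if n_bursts == 0:
        return (
            PhotonStream(np.array([], dtype=np.int64), np.array([], dtype=np.int8), scheme),
            empty_truth,
        )

    fractions = np.array([s.fraction for s in species])
    means = [_channel_means(s, instrument.gamma_true) for s in species]
    # rescale each species so its mean total is photons_per_burst_mean; this
    # preserves all channel ratios (hence E and S) while keeping every
    # subpopulation's counting statistics comparable
    means = [m * (photons_per_burst_mean / float(np.sum(m))) for m in means]

    which = rng.choice(len(species), size=n_bursts, p=fractions)
    gaps_us = rng.exponential(mean_interarrival_ms * 1000.0, size=n_bursts)

    all_times: list[np.ndarray] = []
    all_dets: list[np.ndarray] = []
    records = []
    next_free_cycle = 0  # keeps consecutive bursts on disjoint alternation cycles
    for b in range(n_bursts):
        sp = int(which[b])
        m = means[sp]
        total_mean = float(np.sum(m))
        n_sig = min_photons_floor + rng.poisson(max(total_mean - min_photons_floor, 0.0))
        nD, nA, nAA = rng.multinomial(n_sig, m / total_mean)
        # leakage: donor emission bleeding into the acceptor detection band
        if instrument.Lk_true > 0 and nD > 0:
            nA += rng.poisson(instrument.Lk_true * nD)
        # direct excitation of the acceptor by the donor laser
        if instrument.Dir_true > 0 and nAA > 0:
            nA += rng.poisson(instrument.Dir_true * nAA)

        base = next_free_cycle + int(np.ceil(gaps_us[b] / period))
        n_cyc = cycles_per_burst
        dex_slots = _window_slots(scheme, scheme.dex_window, base, n_cyc)
        aex_slots = _window_slots(scheme, scheme.aex_window, base, n_cyc)
        while nD + nA > dex_slots.size or nAA > aex_slots.size:
            n_cyc *= 2
            dex_slots = _window_slots(scheme, scheme.dex_window, base, n_cyc)
            aex_slots = _window_slots(scheme, scheme.aex_window, base, n_cyc)
        dex_times = rng.choice(dex_slots, size=nD + nA, replace=False)
        aex_times = rng.choice(aex_slots, size=nAA, replace=False)
        dets = np.concatenate(
            [np.zeros(nD, dtype=np.int8), np.ones(nA, dtype=np.int8),
             np.ones(nAA, dtype=np.int8)]
        )
        times = np.concatenate([dex_times, aex_times])
        all_times.append(times)
        all_dets.append(dets)
        next_free_cycle = base + n_cyc + 1
        t0 = base * period
        t1 = (base + n_cyc) * period
        records.append({
            "burst_id": b, "species_index": sp,
            "label_state": species[sp].label_state, "true_E": species[sp].true_E,
            "t_start": t0, "t_end": t1, "n_signal": int(n_sig),
            "F_Dex_Dem": int(nD), "F_Dex_Aem": int(nA), "F_Aex_Aem": int(nAA),
            "F_Aex_Dem": 0, "n_bg_donor": 0, "n_bg_acceptor": 0,
        })

    sig_times = np.concatenate(all_times)
    sig_dets = np.concatenate(all_dets)
    t_total = float(sig_times.max()) + mean_interarrival_ms * 1000.0
    truth = pd.DataFrame(records)

    # homogeneous Poisson background on each detector, deduplicated against
    # signal photons so timestamps stay strictly increasing
    bg_times_list, bg_dets_list = [], []
    for det, rate in ((0, instrument.bg_rate_donor_kHz), (1, instrument.bg_rate_acceptor_kHz)):
        if rate <= 0:
            continue
        n_bg = rng.poisson(rate * 1e-3 * t_total)  # kHz * µs
        tt = np.unique(rng.integers(0, int(t_total), size=n_bg))
        tt = tt[~np.isin(tt, sig_times)]
        bg_times_list.append(tt)
        bg_dets_list.append(np.full(tt.size, det, dtype=np.int8))
        col = "n_bg_donor" if det == 0 else "n_bg_acceptor"
        lo = np.searchsorted(tt, truth["t_start"].to_numpy())
        hi = np.searchsorted(tt, truth["t_end"].to_numpy())
        truth[col] = hi - lo
    if bg_times_list:
        bg_times = np.concatenate(bg_times_list)
        bg_dets = np.concatenate(bg_dets_list)
        # collisions between the two background channels: drop later duplicates
        order = np.argsort(bg_times, kind="stable")
        bg_times, bg_dets = bg_times[order], bg_dets[order]
        keep = np.concatenate(([True], np.diff(bg_times) > 0))
        sig_times = np.concatenate([sig_times, bg_times[keep]])
        sig_dets = np.concatenate([sig_dets, bg_dets[keep]])

    order = np.argsort(sig_times, kind="stable")
    stream = PhotonStream(
        timestamps=sig_times[order].astype(np.int64),
        detectors=sig_dets[order], scheme=scheme,
    )
    return stream, truth


def simulate_fret_standard(
    true_E: float,
    instrument: InstrumentModel,
    n_bursts: int = 2000,
    photons_per_burst_mean: float = 100.0,
    seed: int = 0,
) -> tuple[PhotonStream, pd.DataFrame]:
    """Single dual-labelled species of known E — a polyproline-style standard."""
    species = [SpeciesModel(true_E=true_E, label_state="dual", fraction=1.0)]
    return simulate_alex_experiment(
        species, instrument, n_bursts,
        photons_per_burst_mean=photons_per_burst_mean, seed=seed,
    )


def simulate_tirf_trajectory(
    truth: TirfGroundTruth, n_frames: int, seed: int = 0,
    frame_period_ms: float = 100.0, molecule_id: str = "",
) -> Trajectory:
    """Two-channel trajectory with acceptor-then-donor single-step bleaching.

    Donor mean is Id·(1−E)+bg_d before the acceptor bleaches, Id+bg_d until
    the donor bleaches, bg_d after; the acceptor mirrors with Id·E+bg_a then
    background.  Gaussian frame noise of sd ``noise_sd`` on both channels.
    """
    if n_frames <= truth.donor_bleach_frame:
        raise ValueError("n_frames must exceed donor_bleach_frame")
    rng = np.random.default_rng(seed)
    a, d = truth.acceptor_bleach_frame, truth.donor_bleach_frame
    I_d = np.full(n_frames, truth.bg_d, dtype=float)
    I_a = np.full(n_frames, truth.bg_a, dtype=float)
    I_d[:a] += truth.Id_level * (1.0 - truth.true_E)
    I_d[a:d] += truth.Id_level
    I_a[:a] += truth.Id_level * truth.true_E
    if truth.noise_sd > 0:
        I_d += rng.normal(0.0, truth.noise_sd, size=n_frames)
        I_a += rng.normal(0.0, truth.noise_sd, size=n_frames)
    return Trajectory(I_d=I_d, I_a=I_a, frame_period_ms=frame_period_ms,
                      molecule_id=molecule_id)


def simulate_tirf_ensemble(
    true_E: float,
    n_molecules: int,
    n_frames: int = 450,
    useful_fraction: float = 0.5,
    Id_level: float = 1000.0,
    bg_d: float = 100.0,
    bg_a: float = 80.0,
    noise_sd: float = 30.0,
    seed: int = 0,
) -> tuple[list[Trajectory], list[bool]]:
    """Mixed ensemble of TIRF traces with and without the useful bleach order.

    A fraction ``useful_fraction`` of molecules bleach acceptor-first (the
    sequence the donor-bleaching method needs); the rest bleach donor-first,
    in which case FRET stops at the donor bleach and both channels drop on
    the same frame.  Returns the trajectories and the ground-truth
    usefulness flags.
    """
    rng = np.random.default_rng(seed)
    trajs: list[Trajectory] = []
    flags: list[bool] = []
    for i in range(n_molecules):
        useful = bool(rng.random() < useful_fraction)
        if useful:
            a = int(rng.integers(60, n_frames // 3))
            d = int(rng.integers(a + 60, n_frames - 40))
            truth = TirfGroundTruth(
                true_E=true_E, Id_level=Id_level, bg_d=bg_d, bg_a=bg_a,
                acceptor_bleach_frame=a, donor_bleach_frame=d, noise_sd=noise_sd)
            trajs.append(simulate_tirf_trajectory(
                truth, n_frames, seed=int(rng.integers(2**31)), molecule_id=f"mol{i}"))
        else:
            d = int(rng.integers(60, n_frames - 40))
            I_d = np.full(n_frames, bg_d, dtype=float)
            I_a = np.full(n_frames, bg_a, dtype=float)
            I_d[:d] += Id_level * (1.0 - true_E)
            I_a[:d] += Id_level * true_E
            sub = np.random.default_rng(int(rng.integers(2**31)))
            I_d += sub.normal(0.0, noise_sd, size=n_frames)
            I_a += sub.normal(0.0, noise_sd, size=n_frames)
            trajs.append(Trajectory(I_d=I_d, I_a=I_a, molecule_id=f"mol{i}"))
        flags.append(useful)
    return trajs, flags


def simulate_fcs_curve(
    n_particles: float, tau_D: float, kappa: float,
    lags=None, noise_sd: float = 0.0, seed: int = 0,
) -> FcsCurve:
    """FCS autocorrelation for a single 3D-diffusing species, with
    multiplicative Gaussian noise of relative sd ``noise_sd``."""
    if tau_D <= 0:
        raise ValueError("tau_D must be positive")
    if kappa <= 1:
        raise ValueError("kappa must exceed 1")
    if lags is None:
        lags = np.logspace(-6, 0, 120)  # 1 µs .. 1 s
    lags = np.asarray(lags, dtype=float)
    G = fcs_model(lags, n_particles, tau_D, kappa)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        G = G * (1.0 + noise_sd * rng.standard_normal(G.shape))
    return FcsCurve(lags=lags, G=G)


def simulate_assay_curves(
    mode: str, params: dict, x_grid, noise_sd: float = 0.0, seed: int = 0,
) -> pd.DataFrame:
    """Synthetic titration (``binding``) or rate (``michaelis_menten``) data.

    binding: normalized donor intensity 1 − amplitude·f_bound(L; Kd) with the
    exact tight-binding solution at ``labeled_total`` (nM); columns
    ligand_nM, intensity.  michaelis_menten: v = Vmax·S/(KM+S); columns
    atp_mM, rate.  Noise is multiplicative Gaussian with relative sd
    ``noise_sd``.
    """
    x = np.asarray(x_grid, dtype=float)
    rng = np.random.default_rng(seed)
    if mode == "binding":
        Kd = params["Kd"]
        if Kd <= 0:
            raise ValueError("Kd must be positive")
        labeled = params.get("labeled_total", 10.0)
        amp = params.get("amplitude", 0.5)
        y = 1.0 - amp * bound_fraction_quadratic(x, labeled, Kd)
        cols = ("ligand_nM", "intensity")
    elif mode == "michaelis_menten":
        KM, Vmax = params["KM"], params["Vmax"]
        if KM <= 0 or Vmax <= 0:
            raise ValueError("KM and Vmax must be positive")
        y = michaelis_menten(x, Vmax, KM)
        cols = ("atp_mM", "rate")
    else:
        raise ValueError(f"unknown assay mode {mode!r}")
    if noise_sd > 0:
        y = y * (1.0 + noise_sd * rng.standard_normal(y.shape))
    return pd.DataFrame({cols[0]: x, cols[1]: y})
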