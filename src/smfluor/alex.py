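"""ALEX smFRET burst analysis: stream splitting, burst search, corrections.

Alternating-laser excitation (ALEX) interleaves donor (Dex) and acceptor
(Aex) excitation on a microsecond period, so each detected photon is
classified by excitation window × detection channel into four streams:
Dex→Dem, Dex→Aem, Aex→Aem, Aex→Dem.  Per single-molecule burst the raw
proximity ratio and stoichiometry are

    E_raw = F_DexAem / (F_DexAem + F_DexDem)
    S_raw = (F_DexAem + F_DexDem) / (F_DexAem + F_DexDem + F_AexAem)

Stoichiometry separates donor-only (S ≈ 1), acceptor-only (S ≈ 0) and
dual-labelled (intermediate S) molecules; the contaminant populations
calibrate donor leakage (Lk) and acceptor direct excitation (Dir).  After
crosstalk subtraction, the detection-correction factor γ is obtained from
two FRET standards via the linear relation 1/S = Ω + Σ·E, from which
γ = (Ω − 1)/(Ω + Σ − 1), giving the accurate efficiency

    E_acc = F_fret / (F_fret + γ·F_DexDem).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STREAM_LABELS = ("Dex_Dem", "Dex_Aem", "Aex_Aem", "Aex_Dem", "off_window")
COUNT_COLUMNS = ("F_Dex_Dem", "F_Dex_Aem", "F_Aex_Aem", "F_Aex_Dem")

#: E_acc is clipped to this interval for histogramming (raw value retained)
E_CLIP_RANGE = (-0.1, 1.1)


class CalibrationError(RuntimeError):
    """Raised when a calibration subpopulation is empty or degenerate."""


@dataclass(frozen=True)
class AlternationScheme:
    """Laser alternation timing within one period (µs); windows half-open."""

    period_us: float = 100.0
    dex_window: tuple[float, float] = (0.0, 40.0)
    aex_window: tuple[float, float] = (50.0, 90.0)

    def __post_init__(self) -> None:
        d0, d1 = self.dex_window
        a0, a1 = self.aex_window
        if not (0 <= d0 < d1 <= self.period_us and 0 <= a0 < a1 <= self.period_us):
            raise ValueError("windows must lie within [0, period)")
        if max(d0, a0) < min(d1, a1):
            raise ValueError("excitation windows must be disjoint")

    @property
    def duty_fraction(self) -> float:
        return (self.dex_window[1] - self.dex_window[0]) / self.period_us


@dataclass
class PhotonStream:
    """Timestamped photon arrivals (µs, strictly increasing) on two detectors."""

    timestamps: np.ndarray
    detectors: np.ndarray  # 0 = donor, 1 = acceptor
    scheme: AlternationScheme = field(default_factory=AlternationScheme)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps)
        self.detectors = np.asarray(self.detectors, dtype=np.int8)
        if self.timestamps.shape != self.detectors.shape:
            raise ValueError("timestamps and detectors must have equal length")
        if self.timestamps.size and np.any(np.diff(self.timestamps) <= 0):
            bad = int(np.argmax(np.diff(self.timestamps) <= 0)) + 1
            raise ValueError(f"timestamps must be strictly increasing (row {bad})")
        if self.detectors.size and not np.isin(self.detectors, (0, 1)).all():
            raise ValueError("detector labels must be 0 (donor) or 1 (acceptor)")

    def __len__(self) -> int:
        return int(self.timestamps.size)


@dataclass
class CorrectionFactors:
    """Crosstalk and detection corrections applied to every burst."""

    Lk: float = 0.0
    Dir: float = 0.0
    Sigma: float = float("nan")
    Omega: float = float("nan")
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.Lk < 0 or self.Dir < 0:
            raise ValueError("Lk and Dir must be non-negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class BurstTable:
    """Per-burst records sharing one correction state.

    ``df`` columns: t_start, t_end, the four stream counts, and — once the
    corresponding stage has run — E_raw/S_raw, F_fret_corr/E_corr/S_corr and
    E_acc, with boolean ``defined`` marking bursts with valid ratios.
    """

    df: pd.DataFrame
    factors: CorrectionFactors | None = None

    def __len__(self) -> int:
        return len(self.df)


def split_streams(stream: PhotonStream) -> np.ndarray:
    """Label every photon as one of the four streams or off_window."""
    phase = np.mod(stream.timestamps, stream.scheme.period_us)
    d0, d1 = stream.scheme.dex_window
    a0, a1 = stream.scheme.aex_window
    in_dex = (phase >= d0) & (phase < d1)
    in_aex = (phase >= a0) & (phase < a1)
    labels = np.full(len(stream), "off_window", dtype=object)
    acc = stream.detectors == 1
    labels[in_dex & ~acc] = "Dex_Dem"
    labels[in_dex & acc] = "Dex_Aem"
    labels[in_aex & acc] = "Aex_Aem"
    labels[in_aex & ~acc] = "Aex_Dem"
    return labels


def find_bursts(
    stream: PhotonStream,
    rate_threshold_kHz: float = 3.0,
    min_photons: int = 40,
    smoothing_window_ms: float = 1.0,
) -> BurstTable:
    """Locate single-molecule bursts by an all-photon binned-rate threshold.

    The stream is binned into contiguous windows of ``smoothing_window_ms``;
    a burst is a maximal run of windows whose all-photon rate exceeds
    ``rate_threshold_kHz``, kept only if it contains at least ``min_photons``
    photons.  The four stream counts are accumulated per burst (off-window
    photons contribute to the rate but not to the counts).
    """
    if rate_threshold_kHz <= 0 or smoothing_window_ms <= 0:
        raise ValueError("threshold and smoothing window must be positive")
    cols = ["t_start", "t_end", *COUNT_COLUMNS]
    if len(stream) == 0:
        return BurstTable(df=pd.DataFrame(columns=cols))

    win_us = smoothing_window_ms * 1000.0
    t = np.asarray(stream.timestamps, dtype=float)
    win_idx = np.floor(t / win_us).astype(np.int64)
    n_win = int(win_idx[-1]) + 1
    counts = np.bincount(win_idx, minlength=n_win)
    # rate in kHz = photons per window / window length in ms
    hot = counts / smoothing_window_ms > rate_threshold_kHz

    # maximal runs of hot windows
    padded = np.concatenate(([False], hot, [False]))
    edges = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(edges == 1)
    run_ends = np.flatnonzero(edges == -1)  # exclusive

    labels = split_streams(stream)
    records = []
    for ws, we in zip(run_starts, run_ends):
        lo = np.searchsorted(win_idx, ws, side="left")
        hi = np.searchsorted(win_idx, we, side="left")
        if hi - lo < min_photons:
            continue
        burst_labels = labels[lo:hi]
        rec = {
            "t_start": float(t[lo]),
            "t_end": float(t[hi - 1]),
            "F_Dex_Dem": int(np.sum(burst_labels == "Dex_Dem")),
            "F_Dex_Aem": int(np.sum(burst_labels == "Dex_Aem")),
            "F_Aex_Aem": int(np.sum(burst_labels == "Aex_Aem")),
            "F_Aex_Dem": int(np.sum(burst_labels == "Aex_Dem")),
        }
        records.append(rec)
    return BurstTable(df=pd.DataFrame(records, columns=cols))


def raw_es(table: BurstTable) -> BurstTable:
    """Compute per-burst raw proximity ratio E_raw and stoichiometry S_raw.

    Bursts with a zero denominator are flagged ``defined == False`` and are
    excluded from histograms downstream, but stay in the table.
    """
    df = table.df.copy()
    A = df["F_Dex_Aem"].to_numpy(dtype=float)
    D = df["F_Dex_Dem"].to_numpy(dtype=float)
    AA = df["F_Aex_Aem"].to_numpy(dtype=float)
    dex_total = A + D
    all_total = dex_total + AA
    with np.errstate(divide="ignore", invalid="ignore"):
        df["E_raw"] = np.where(dex_total > 0, A / dex_total, np.nan)
        df["S_raw"] = np.where(all_total > 0, dex_total / all_total, np.nan)
    df["defined"] = (dex_total > 0) & (all_total > 0)
    return BurstTable(df=df, factors=table.factors)


def estimate_crosstalk(
    table: BurstTable,
    donor_only_S_min: float = 0.85,
    acceptor_only_S_max: float = 0.15,
    min_bursts: int = 20,
) -> tuple[float, float]:
    """Estimate (Lk, Dir) from the donor-only and acceptor-only populations.

    Lk is the median over donor-only bursts (S_raw above ``donor_only_S_min``)
    of F_DexAem/F_DexDem; Dir the median over acceptor-only bursts of
    F_DexAem/F_AexAem.  Medians are used because per-burst count ratios are
    heavy-tailed at low counts.
    """
    df = table.df
    if "S_raw" not in df:
        raise ValueError("run raw_es before estimate_crosstalk")
    donly = df[(df["S_raw"] > donor_only_S_min) & (df["F_Dex_Dem"] > 0)]
    aonly = df[(df["S_raw"] < acceptor_only_S_max) & (df["F_Aex_Aem"] > 0)]
    if len(donly) < min_bursts or len(aonly) < min_bursts:
        raise CalibrationError(
            f"calibration subpopulations too small (donor-only {len(donly)}, "
            f"acceptor-only {len(aonly)}; need {min_bursts} each) — supply "
            "correction factors from an external calibration instead"
        )
    Lk = float(np.median(donly["F_Dex_Aem"] / donly["F_Dex_Dem"]))
    Dir = float(np.median(aonly["F_Dex_Aem"] / aonly["F_Aex_Aem"]))
    return Lk, Dir


def correct_counts(table: BurstTable, factors: CorrectionFactors) -> BurstTable:
    """Subtract leakage and direct-excitation crosstalk from the FRET stream.

    F_fret = F_DexAem − Lk·F_DexDem − Dir·F_AexAem, floored at zero; E and S
    are recomputed with the corrected FRET count.
    """
    df = table.df.copy()
    A = df["F_Dex_Aem"].to_numpy(dtype=float)
    D = df["F_Dex_Dem"].to_numpy(dtype=float)
    AA = df["F_Aex_Aem"].to_numpy(dtype=float)
    F_fret = np.maximum(A - factors.Lk * D - factors.Dir * AA, 0.0)
    dex_total = F_fret + D
    all_total = dex_total + AA
    with np.errstate(divide="ignore", invalid="ignore"):
        df["F_fret_corr"] = F_fret
        df["E_corr"] = np.where(dex_total > 0, F_fret / dex_total, np.nan)
        df["S_corr"] = np.where(all_total > 0, dex_total / all_total, np.nan)
    df["defined"] = (dex_total > 0) & (all_total > 0)
    return BurstTable(df=df, factors=factors)


def _population_es(table: BurstTable) -> tuple[float, float]:
    """Population-level corrected (E, S) as ratios of summed counts."""
    df = table.df
    F = df["F_fret_corr"].sum()
    D = df["F_Dex_Dem"].sum()
    AA = df["F_Aex_Aem"].sum()
    return float(F / (F + D)), float((F + D) / (F + D + AA))


def calibrate_gamma(standard_tables: list[BurstTable]) -> tuple[float, float, float]:
    """Fit (Σ, Ω, γ) from crosstalk-corrected FRET standards.

    Each standard contributes one (E, 1/S) point at its population mean; a
    straight-line fit 1/S = Ω + Σ·E yields γ = (Ω − 1)/(Ω + Σ − 1).  The
    standards must differ in mean E by at least 0.1.
    """
    if len(standard_tables) < 2:
        raise CalibrationError("gamma calibration needs at least two FRET standards")
    points = [_population_es(t) for t in standard_tables]
    Es = np.array([p[0] for p in points])
    Ss = np.array([p[1] for p in points])
    if np.ptp(Es) < 0.1:
        raise CalibrationError(
            f"standards' mean E values span only {np.ptp(Es):.3f}; need >= 0.1"
        )
    Sigma, Omega = np.polyfit(Es, 1.0 / Ss, 1)
    gamma = (Omega - 1.0) / (Omega + Sigma - 1.0)
    if gamma <= 0:
        raise CalibrationError(f"calibration produced non-positive gamma ({gamma:.3f})")
    return float(Sigma), float(Omega), float(gamma)


def accurate_E(table: BurstTable, factors: CorrectionFactors) -> BurstTable:
    """γ-corrected accurate FRET efficiency per burst.

    E_acc = F_fret/(F_fret + γ·F_DexDem); a clipped copy (for histogramming)
    is stored in ``E_acc_clip``, the raw value in ``E_acc``.
    """
    if factors.gamma <= 0:
        raise ValueError("gamma must be positive")
    df = table.df.copy()
    if "F_fret_corr" not in df:
        raise ValueError("run correct_counts before accurate_E")
    F = df["F_fret_corr"].to_numpy(dtype=float)
    D = df["F_Dex_Dem"].to_numpy(dtype=float)
    denom = F + factors.gamma * D
    with np.errstate(divide="ignore", invalid="ignore"):
        df["E_acc"] = np.where(denom > 0, F / denom, np.nan)
    df["E_acc_clip"] = np.clip(df["E_acc"], *E_CLIP_RANGE)
    return BurstTable(df=df, factors=replace(factors))


def es_histogram_2d(
    table: BurstTable,
    bin_E: float = 0.025,
    bin_S: float = 0.025,
    e_col: str = "E_raw",
    s_col: str = "S_raw",
):
    """2D E–S histogram over bursts with defined ratios.

    Returns (counts, E_edges, S_edges); the grid total equals the number of
    defined bursts (values clipped into [0, 1]).
    """
    df = table.df
    if len(df) == 0:
        return np.zeros((0, 0)), np.array([]), np.array([])
    mask = df[e_col].notna() & df[s_col].notna()
    E = np.clip(df.loc[mask, e_col].to_numpy(dtype=float), 0.0, np.nextafter(1.0, 0.0))
    S = np.clip(df.loc[mask, s_col].to_numpy(dtype=float), 0.0, np.nextafter(1.0, 0.0))
    e_edges = np.arange(0.0, 1.0 + bin_E, bin_E)
    s_edges = np.arange(0.0, 1.0 + bin_S, bin_S)
    counts, _, _ = np.histogram2d(E, S, bins=(e_edges, s_edges))
    return counts, e_edges, s_edges


def analyze_stream(
    stream: PhotonStream,
    rate_threshold_kHz: float = 3.0,
    min_photons: int = 40,
    smoothing_window_ms: float = 1.0,
    factors: CorrectionFactors | None = None,
    standard_tables: list[BurstTable] | None = None,
) -> BurstTable:
    """Full chain: burst search → raw ratios → corrections → accurate E.

    If ``factors`` is None, Lk/Dir are estimated from the stream's own
    donor-only/acceptor-only populations; γ comes from ``standard_tables``
    (crosstalk-corrected here with the same Lk/Dir) when given, else 1.
    """
    table = raw_es(find_bursts(stream, rate_threshold_kHz, min_photons, smoothing_window_ms))
    if factors is None:
        Lk, Dir = estimate_crosstalk(table)
        factors = CorrectionFactors(Lk=Lk, Dir=Dir)
    table = correct_counts(table, factors)
    if np.isnan(factors.Sigma) and standard_tables is not None:
        corrected = [correct_counts(t, factors) for t in standard_tables]
        Sigma, Omega, gamma = calibrate_gamma(corrected)
        factors = CorrectionFactors(
            Lk=factors.Lk, Dir=factors.Dir, Sigma=Sigma, Omega=Omega, gamma=gamma
        )
        table = BurstTable(df=table.df, factors=factors)
    return accurate_E(table, factors)
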