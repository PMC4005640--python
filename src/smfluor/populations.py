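"""FRET-efficiency histograms and Gaussian population decomposition.

Single-molecule FRET histograms are decomposed into one or two Gaussian
populations by nonlinear least squares of

    y(E) = y0 + Σ_i area_i · N(E; mean_i, width_i)

against the binned counts, where each component is parameterised by its
integrated area (events × efficiency units) so that population fractions are
simply area_i / Σ area.  The number of components is chosen by the
least-squares Akaike information criterion, AIC = N·ln(RSS/N) + 2k with
k = 3n + 1 free parameters (ties favour the simpler model).

Fits are unweighted by default (matching common curve-fitting practice for
these histograms); Poisson weighting (residuals scaled by 1/√max(count, 1))
is available via ``weighting="poisson"``.  A two-component solution whose
means are closer than twice the larger component width does not describe
two resolvable populations — it merely absorbs shot noise around a single
peak — and is rejected as degenerate, which makes the AIC comparison select
a second component only for genuinely bimodal histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

DEFAULT_BIN_WIDTH = 0.025
DEFAULT_RANGE = (-0.1, 1.1)


class FitFailure(RuntimeError):
    """Raised when the mixture fit cannot produce non-degenerate components."""


@dataclass
class FretHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("bin_edges must have one more entry than counts")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_values(self) -> int:
        return int(self.counts.sum())


@dataclass
class GaussianComponent:
    mean: float
    width: float
    area: float


@dataclass
class MixtureFit:
    components: list[GaussianComponent]
    y0: float
    rss: float          # unweighted residual sum of squares
    aic: float          # computed from the minimised (possibly weighted) objective
    fractions: list[float] = field(default_factory=list)
    chi2: float = float("nan")  # weighted objective actually minimised

    @property
    def n(self) -> int:
        return len(self.components)


def fret_histogram(
    E_values,
    bin_width: float = DEFAULT_BIN_WIDTH,
    hist_range: tuple[float, float] = DEFAULT_RANGE,
) -> FretHistogram:
    """Histogram efficiencies on a uniform grid; out-of-range values go to end bins."""
    E = np.asarray(E_values, dtype=float)
    if E.size == 0:
        raise ValueError("no efficiency values supplied")
    if not np.all(np.isfinite(E)):
        raise ValueError("efficiency values must be finite")
    lo, hi = hist_range
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(np.clip(E, lo, np.nextafter(hi, lo)), bins=edges)
    return FretHistogram(bin_edges=edges, counts=counts)


def _gauss_area(x, mean, width, area):
    return area / (width * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * ((x - mean) / width) ** 2)


def _mixture_y(params: Parameters, x: np.ndarray, n: int) -> np.ndarray:
    y = np.full_like(x, params["y0"].value)
    for i in range(n):
        y = y + _gauss_area(
            x, params[f"mean{i}"].value, params[f"width{i}"].value, params[f"area{i}"].value
        )
    return y


def _peak_guesses(hist: FretHistogram, n: int) -> list[float]:
    """Centers of the n highest distinct local maxima of the smoothed histogram."""
    c = hist.counts.astype(float)
    smooth = np.convolve(c, np.ones(3) / 3.0, mode="same")
    interior = np.arange(1, smooth.size - 1)
    is_max = (smooth[interior] >= smooth[interior - 1]) & (smooth[interior] >= smooth[interior + 1])
    candidates = interior[is_max]
    if candidates.size == 0:
        candidates = np.argsort(c)[::-1]
    order = candidates[np.argsort(smooth[candidates])[::-1]]
    picks: list[int] = []
    min_sep = max(2, int(0.1 / hist.bin_width))  # peaks at least 0.1 E units apart
    for idx in order:
        if all(abs(idx - p) >= min_sep for p in picks):
            picks.append(int(idx))
        if len(picks) == n:
            break
    fallback = np.argsort(c)[::-1]
    for idx in fallback:
        if len(picks) == n:
            break
        if all(abs(idx - p) >= min_sep for p in picks):
            picks.append(int(idx))
    while len(picks) < n:
        picks.append(int(fallback[len(picks) % fallback.size]))
    return [float(hist.centers[p]) for p in picks]


def _quantile_guesses(hist: FretHistogram) -> list[float]:
    """Means at the 25%/75% quantiles of the binned distribution."""
    cum = np.cumsum(hist.counts)
    total = cum[-1]
    lo = int(np.searchsorted(cum, 0.25 * total))
    hi = int(np.searchsorted(cum, 0.75 * total))
    return [float(hist.centers[lo]), float(hist.centers[hi])]


def fit_mixture(
    hist: FretHistogram,
    n: int,
    init: list[float] | None = None,
    weighting: str = "none",
    aicc: bool = False,
) -> MixtureFit:
    """Fit a baseline-plus-n-Gaussian model to a FRET histogram (n in {1, 2}).

    Initialisation starts each component at one of the ``n`` highest distinct
    histogram peaks (or at ``init`` means if supplied); additional
    deterministic restarts jitter the starting means.  Degenerate results —
    components with vanishing area (less than about half an event) or an
    unresolved two-component pair (means closer than twice the larger
    width) — raise FitFailure.  ``aicc`` applies the small-sample AIC
    correction.
    """
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    if weighting not in ("poisson", "none"):
        raise ValueError("weighting must be 'poisson' or 'none'")
    occupied = int(np.count_nonzero(hist.counts))
    if occupied < (5 if n == 1 else 8):
        raise FitFailure(f"only {occupied} occupied bins; too few for n={n}")

    x, y = hist.centers, hist.counts
    w = 1.0 / np.sqrt(np.maximum(y, 1.0)) if weighting == "poisson" else np.ones_like(y)
    span = float(hist.bin_edges[-1] - hist.bin_edges[0])
    total_area = float(hist.counts.sum() * hist.bin_width)
    means0 = list(init) if init is not None else _peak_guesses(hist, n)

    starts = [means0]
    if n == 1:
        starts += [[means0[0] - 0.05], [means0[0] + 0.05]]
    else:
        m0, m1 = means0
        starts += [[m0 - 0.05, m1 + 0.05], [m0 + 0.05, m1 - 0.05],
                   [m0 - 0.1, m1], [m0, m1 + 0.1], _quantile_guesses(hist)]

    best = None
    for start in starts:
        params = Parameters()
        # y0 starts strictly inside its bound: MINPACK-style bound transforms
        # stall when a parameter begins exactly at a boundary
        params.add("y0", value=0.01, min=0.0)
        for i in range(n):
            params.add(f"mean{i}", value=float(np.clip(start[i], x[0], x[-1])),
                       min=float(hist.bin_edges[0]), max=float(hist.bin_edges[-1]))
            params.add(f"width{i}", value=0.05, min=hist.bin_width / 2.0, max=span)
            params.add(f"area{i}", value=total_area / n, min=0.0)
        try:
            out = minimize(lambda p: (_mixture_y(p, x, n) - y) * w, params,
                           method="least_squares", calc_covar=False)
        except Exception:
            continue
        chi2 = float(np.sum(out.residual**2))
        if best is None or chi2 < best[0]:
            best = (chi2, out.params)

    if best is None:
        raise FitFailure("mixture fit did not converge from any start")
    chi2, p = best
    comps = [
        GaussianComponent(
            mean=float(p[f"mean{i}"].value),
            width=float(p[f"width{i}"].value),
            area=float(p[f"area{i}"].value),
        )
        for i in range(n)
    ]
    comps.sort(key=lambda c: -c.area)
    total = sum(c.area for c in comps)
    # a component carrying less than ~half an event is structure-free
    if total <= 0.5 * hist.bin_width or min(c.area for c in comps) < 0.5 * hist.bin_width:
        raise FitFailure("degenerate fit: component area below half an event")
    if n == 2:
        sep = abs(comps[0].mean - comps[1].mean)
        if sep < 2.0 * max(c.width for c in comps):
            raise FitFailure(
                f"unresolved two-component fit: mean separation {sep:.3f} below "
                "twice the component width — not distinct populations"
            )
    rss = float(np.sum((_mixture_y(p, x, n) - y) ** 2))
    n_bins = x.size
    k = 3 * n + 1
    aic = n_bins * np.log(max(chi2, 1e-300) / n_bins) + 2 * k
    if aicc:
        aic += 2.0 * k * (k + 1) / max(n_bins - k - 1, 1)
    return MixtureFit(
        components=comps, y0=float(p["y0"].value), rss=rss, aic=float(aic),
        fractions=[c.area / total for c in comps], chi2=chi2,
    )


def select_model_aic(fit1: MixtureFit, fit2: MixtureFit) -> MixtureFit:
    """Pick the lower-AIC fit; ties go to the single-component model."""
    return fit2 if fit2.aic < fit1.aic else fit1


def fit_populations(
    hist: FretHistogram, max_n: int = 2, weighting: str = "none", aicc: bool = False,
) -> MixtureFit:
    """Fit n=1..max_n mixtures and return the AIC-selected model.

    A failed two-component fit (degenerate structure) falls back to the
    single-component model.
    """
    fit1 = fit_mixture(hist, 1, weighting=weighting, aicc=aicc)
    if max_n < 2:
        return fit1
    try:
        fit2 = fit_mixture(hist, 2, weighting=weighting, aicc=aicc)
    except FitFailure:
        return fit1
    return select_model_aic(fit1, fit2)


def population_fractions(fit: MixtureFit) -> list[float]:
    """Area-based population fractions, area_i / Σ area_j."""
    total = sum(c.area for c in fit.components)
    if total <= 0:
        raise ValueError("total component area is zero")
    return [c.area / total for c in fit.components]
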