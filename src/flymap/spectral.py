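"""Raman / stimulated-Raman spectral processing and quantification.

The processing chain mirrors standard vibrational-spectroscopy practice for
tissue lipid profiling: spectra are regridded to a uniform 1 cm^-1 axis,
background spectra recorded at the same focal plane are subtracted, an
asymmetric-least-squares baseline removes slow drift, and spectra are vector
normalized before group averaging.  Quantification covers

* band-intensity ratios — CD/CH 2140/2850 (newly synthesized lipids),
  D-lipid 2176/2850, unsaturation 3012/2850, lipid/protein 2850/2935 —
  computed on spectra that are regridded and background-subtracted but
  otherwise unprocessed (ratios are scale invariant, so normalization would
  not change them; baseline correction would),
* Gaussian decomposition of the CH-stretch region (2800-3050 cm^-1) with
  the A2885/A2850 area ratio as a lipid acyl-chain ordering measure,
* the half-height bandwidth of the 1295 cm^-1 CH2-twist band above a local
  linear baseline, a second ordering measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse
from scipy.sparse.linalg import spsolve

__all__ = [
    "RamanSpectrum",
    "PeakModel",
    "SpectralMetrics",
    "regrid",
    "subtract_background",
    "baseline_correct",
    "vector_normalize",
    "average_spectra",
    "band_intensity",
    "band_ratio",
    "fit_peaks",
    "area_ratio_2885_2850",
    "half_height_bandwidth",
    "compute_metrics",
    "CH_REGION",
    "CH_INITIAL_CENTERS",
]

_GAUSS_W = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: CH-stretch decomposition window and canonical initial band centers (cm^-1)
CH_REGION = (2800.0, 3050.0)
CH_INITIAL_CENTERS = (2850.0, 2871.0, 2885.0, 2927.0, 2958.0)


@dataclass
class RamanSpectrum:
    """A spectrum I(nu) on a strictly increasing wavenumber grid (cm^-1)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    processing_state: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must have equal length")
        if self.wavenumbers.ndim != 1 or self.wavenumbers.size < 2:
            raise ValueError("spectrum needs at least two samples")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")

    def _derive(self, intensities: np.ndarray, step_name: str) -> "RamanSpectrum":
        return RamanSpectrum(
            self.wavenumbers.copy(),
            np.asarray(intensities, float),
            [*self.processing_state, step_name],
        )

    def same_grid(self, other: "RamanSpectrum", atol: float = 1e-9) -> bool:
        return self.wavenumbers.shape == other.wavenumbers.shape and np.allclose(
            self.wavenumbers, other.wavenumbers, atol=atol
        )


def regrid(spectrum: RamanSpectrum, step: float = 1.0) -> RamanSpectrum:
    """Linearly interpolate onto a uniform grid covering the input range.

    The grid starts at the first input wavenumber and advances in ``step``
    increments up to the last one (included when the span is a multiple of
    the step, as it is for instrument exports).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    w = spectrum.wavenumbers
    n = int(np.floor((w[-1] - w[0]) / step + 1e-9)) + 1
    grid = w[0] + step * np.arange(n)
    interp = np.interp(grid, w, spectrum.intensities)
    return RamanSpectrum(grid, interp, [*spectrum.processing_state, f"regrid({step:g})"])


def subtract_background(spectrum: RamanSpectrum, background: RamanSpectrum) -> RamanSpectrum:
    """Pointwise subtraction of a background recorded on the same grid."""
    if not spectrum.same_grid(background):
        raise ValueError("spectrum and background must share an identical grid; regrid first")
    return spectrum._derive(spectrum.intensities - background.intensities, "subtract_background")


def baseline_correct(
    spectrum: RamanSpectrum,
    lam: float = 1e5,
    p: float = 0.01,
    n_iter: int = 10,
) -> RamanSpectrum:
    """Asymmetric-least-squares baseline removal (Eilers-Boelens).

    Minimizes sum(w_i (y_i - z_i)^2) + lam * sum((d2 z)^2) with asymmetric
    weights w = p above the baseline and 1 - p below, re-estimated
    ``n_iter`` times.  Positive peaks survive; slow drift is removed.
    """
    if lam <= 0 or not (0 < p < 1):
        raise ValueError("need lam > 0 and 0 < p < 1")
    y = spectrum.intensities
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    z = y
    for _ in range(max(1, n_iter)):
        a = sparse.diags(w) + dtd
        z = spsolve(a.tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return spectrum._derive(y - z, f"baseline_correct(lam={lam:g},p={p:g})")


def vector_normalize(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Scale intensities to unit Euclidean norm."""
    norm = float(np.linalg.norm(spectrum.intensities))
    if norm == 0.0:
        raise ValueError("cannot vector-normalize an all-zero spectrum")
    return spectrum._derive(spectrum.intensities / norm, "vector_normalize")


def average_spectra(spectra: list[RamanSpectrum]) -> RamanSpectrum:
    """Pointwise arithmetic mean of spectra on a common grid."""
    if not spectra:
        raise ValueError("need at least one spectrum to average")
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise ValueError("all spectra must share an identical grid")
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return RamanSpectrum(
        first.wavenumbers.copy(), mean, [*first.processing_state, f"average(n={len(spectra)})"]
    )


def _window_slice(spectrum: RamanSpectrum, lo: float, hi: float) -> slice:
    w = spectrum.wavenumbers
    if lo < w[0] - 1e-9 or hi > w[-1] + 1e-9:
        raise ValueError(
            f"window [{lo:g}, {hi:g}] cm^-1 lies outside the grid "
            f"[{w[0]:g}, {w[-1]:g}] cm^-1"
        )
    i0 = int(np.searchsorted(w, lo - 1e-9, side="left"))
    i1 = int(np.searchsorted(w, hi + 1e-9, side="right"))
    return slice(i0, i1)


def band_intensity(spectrum: RamanSpectrum, center: float, halfwidth: float = 2.0) -> float:
    """Mean intensity over ``center +- halfwidth`` (cm^-1)."""
    sl = _window_slice(spectrum, center - halfwidth, center + halfwidth)
    return float(spectrum.intensities[sl].mean())


def band_ratio(
    spectrum: RamanSpectrum,
    numerator_center: float,
    denominator_center: float,
    halfwidth: float = 2.0,
) -> float:
    """Windowed band-intensity ratio, e.g. CD/CH = I(2140)/I(2850)."""
    den = band_intensity(spectrum, denominator_center, halfwidth)
    if den <= 0:
        raise ValueError(
            f"denominator band at {denominator_center:g} cm^-1 has non-positive intensity"
        )
    return band_intensity(spectrum, numerator_center, halfwidth) / den


@dataclass(frozen=True)
class PeakModel:
    """A fitted Gaussian band."""

    center: float
    amplitude: float
    fwhm: float

    @property
    def sigma(self) -> float:
        return self.fwhm / _GAUSS_W

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * np.sqrt(2.0 * np.pi)


def _gaussian_sum(nu: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(nu, dtype=float)
    for amp, cen, sig in params.reshape(-1, 3):
        out += amp * np.exp(-0.5 * ((nu - cen) / sig) ** 2)
    return out


def fit_peaks(
    spectrum: RamanSpectrum,
    window: tuple[float, float],
    initial_centers: list[float],
    center_slack: float = 8.0,
    max_nfev: int = 20000,
) -> list[PeakModel]:
    """Bounded least-squares decomposition into a sum of Gaussians.

    Centers are constrained within ``+- center_slack`` cm^-1 of their
    initial values; amplitudes and widths are positive.  Returns one
    :class:`PeakModel` per initial center, in input order.
    """
    lo, hi = window
    sl = _window_slice(spectrum, lo, hi)
    nu = spectrum.wavenumbers[sl]
    y = spectrum.intensities[sl]
    centers = [c for c in initial_centers if lo <= c <= hi]
    if not centers:
        raise ValueError("no initial center inside the fit window")

    ymax = float(np.max(np.abs(y))) or 1.0
    x0, lb, ub = [], [], []
    for c in centers:
        amp0 = max(float(np.interp(c, nu, y)), 0.0)
        x0 += [amp0, c, 10.0 / _GAUSS_W]
        lb += [0.0, c - center_slack, 1.0 / _GAUSS_W]
        ub += [np.inf, c + center_slack, 120.0 / _GAUSS_W]

    res = optimize.least_squares(
        lambda p: _gaussian_sum(nu, p) - y,
        x0=np.array(x0),
        bounds=(np.array(lb), np.array(ub)),
        max_nfev=max_nfev,
    )
    if not res.success:
        raise RuntimeError(
            f"peak fit did not converge (residual norm {np.linalg.norm(res.fun):.3g})"
        )
    return [
        PeakModel(center=cen, amplitude=amp, fwhm=sig * _GAUSS_W)
        for amp, cen, sig in res.x.reshape(-1, 3)
    ]


def area_ratio_2885_2850(spectrum: RamanSpectrum) -> float:
    """A2885/A2850 lipid-ordering ratio from a joint five-Gaussian CH fit.

    The 2871 and 2885 cm^-1 bands overlap heavily, so areas come from a
    joint decomposition of the 2800-3050 cm^-1 region initialized at the
    canonical CH band positions, not from fixed integration windows.
    """
    peaks = fit_peaks(spectrum, CH_REGION, list(CH_INITIAL_CENTERS))
    by_init = dict(zip(CH_INITIAL_CENTERS, peaks))
    scale = max(p.amplitude for p in peaks)
    for band in (2885.0, 2850.0):
        if by_init[band].amplitude <= 1e-6 * max(scale, 1e-12):
            raise ValueError(f"no detectable band near {band:g} cm^-1")
    return by_init[2885.0].area / by_init[2850.0].area


def half_height_bandwidth(
    spectrum: RamanSpectrum,
    center: float,
    search_halfwidth: float = 15.0,
    baseline_halfwidth: float | None = None,
) -> float:
    """FWHM of the local peak nearest ``center``, above a local baseline.

    The peak maximum is searched within ``center +- search_halfwidth``.  The
    local baseline is the line through two anchors, one on each side of the
    peak: each anchor is the mean intensity over the outer fifth of the
    baseline window (default ``baseline_halfwidth`` = three search
    halfwidths, wide enough that band tails have decayed).  Averaging a
    flanking band instead of taking a single minimum keeps the anchor
    unbiased under noise.  Half-height crossings of the baseline-subtracted
    signal are located by linear interpolation between adjacent grid points.
    """
    w, y = spectrum.wavenumbers, spectrum.intensities
    if baseline_halfwidth is None:
        baseline_halfwidth = 3.0 * search_halfwidth
    s_lo = max(center - search_halfwidth, w[0])
    s_hi = min(center + search_halfwidth, w[-1])
    b_lo = max(center - baseline_halfwidth, w[0])
    b_hi = min(center + baseline_halfwidth, w[-1])
    ssl = _window_slice(spectrum, s_lo, s_hi)

    # local maxima in the search window; pick the one closest to `center`
    ys = y[ssl]
    inner = np.arange(1, ys.size - 1)
    is_max = (ys[inner] >= ys[inner - 1]) & (ys[inner] >= ys[inner + 1])
    cand = inner[is_max]
    if cand.size == 0:
        raise ValueError(f"no local maximum within {center:g} +- {search_halfwidth:g} cm^-1")
    ws = w[ssl]
    peak_i_local = cand[np.argmin(np.abs(ws[cand] - center))]
    peak_nu = ws[peak_i_local]
    peak_i = ssl.start + peak_i_local

    bsl = _window_slice(spectrum, b_lo, b_hi)
    band = max(3, (bsl.stop - bsl.start) // 10)  # outer fifth per side
    left_band = slice(bsl.start, min(bsl.start + band, peak_i))
    right_band = slice(max(bsl.stop - band, peak_i + 1), bsl.stop)
    if left_band.stop <= left_band.start or right_band.stop <= right_band.start:
        raise ValueError("degenerate baseline window around the peak")
    lx, ly = float(np.mean(w[left_band])), float(np.mean(y[left_band]))
    rx, ry = float(np.mean(w[right_band])), float(np.mean(y[right_band]))
    slope = (ry - ly) / (rx - lx)
    baseline = ly + slope * (w - lx)
    corr = y - baseline
    li, ri = left_band.start, right_band.stop - 1

    height = corr[peak_i]
    if height <= 0:
        raise ValueError(f"peak at {peak_nu:g} cm^-1 has non-positive height above baseline")
    half = height / 2.0

    def _crossing(idx_range, direction):
        prev = peak_i
        for i in idx_range:
            if corr[i] < half:
                # linear interpolation between grid points i and prev
                t = (half - corr[i]) / (corr[prev] - corr[i])
                return w[i] + t * (w[prev] - w[i])
            prev = i
        raise ValueError(
            f"half-height not reached on the {direction} side of the {peak_nu:g} cm^-1 peak"
        )

    left_x = _crossing(range(peak_i - 1, li - 1, -1), "low-wavenumber")
    right_x = _crossing(range(peak_i + 1, ri + 1), "high-wavenumber")
    return float(right_x - left_x)


@dataclass
class SpectralMetrics:
    """The named quantification panel for one (already background-handled) spectrum."""

    cd_ch_2140_2850: float
    dlipid_2176_2850: float
    unsat_3012_2850: float
    lipid_protein_2850_2935: float
    order_ratio_A2885_A2850: float | None = None
    hhbw_1295: float | None = None


def compute_metrics(
    spectrum: RamanSpectrum,
    background: RamanSpectrum | None = None,
    halfwidth: float = 2.0,
    order_ratio: bool = True,
    hhbw: bool = True,
) -> SpectralMetrics:
    """Regrid, subtract background, and compute the standard ratio panel.

    Ratios use the unnormalized, non-baseline-corrected spectrum; the
    half-height bandwidth tolerates slow baselines through its local linear
    baseline, and the CH decomposition absorbs offsets into the Gaussians'
    tails only weakly (flat backgrounds should be removed via
    ``background``).
    """
    spec = regrid(spectrum)
    if background is not None:
        spec = subtract_background(spec, regrid(background))
    metrics = SpectralMetrics(
        cd_ch_2140_2850=band_ratio(spec, 2140.0, 2850.0, halfwidth),
        dlipid_2176_2850=band_ratio(spec, 2176.0, 2850.0, halfwidth),
        unsat_3012_2850=band_ratio(spec, 3012.0, 2850.0, halfwidth),
        lipid_protein_2850_2935=band_ratio(spec, 2850.0, 2935.0, halfwidth),
    )
    if order_ratio:
        metrics.order_ratio_A2885_A2850 = area_ratio_2885_2850(spec)
    if hhbw:
        metrics.hhbw_1295 = half_height_bandwidth(spec, 1295.0)
    return metrics
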