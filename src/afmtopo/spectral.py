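"""Spatial roughness spectra of membrane nanosurfaces.

The membrane nanostructure is quantified by the 1-D spatial spectrum of
detrended height profiles: the spectral intensity S(nu) in nm^2 versus
spatial frequency nu = 1/L in 1/nm. The convention is one-sided
amplitude-squared: a cosine of amplitude A at an on-grid frequency yields
S = A^2 in its bin, so S reads directly as the square of the roughness
amplitude at that spatial period. The DC and Nyquist terms are excluded.

Two fixed period windows isolate the roughness scales of interest: the
first order, 600-1200 nm, captures large sponge-like membrane formations;
the second order, 50-300 nm, the fine ones. Per window the readout is the
triple (S_max, nu_max, L_max = 1/nu_max).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heightmap import HeightMap, Profile

__all__ = [
    "SpectralWindow", "SpatialSpectrum", "SpectralSummary",
    "ORDER_I", "ORDER_II",
    "detrend", "profile_spectrum", "spectral_summary",
    "period_from_frequency", "bandpass_surface", "cell_patch_spectrum",
]


@dataclass(frozen=True)
class SpectralWindow:
    """Period band (nm) selecting one roughness scale."""

    label: str
    period_min_nm: float
    period_max_nm: float

    def __post_init__(self):
        if not (0 < self.period_min_nm < self.period_max_nm):
            raise ValueError("need 0 < period_min < period_max")

    @property
    def nu_min(self) -> float:
        return 1.0 / self.period_max_nm

    @property
    def nu_max(self) -> float:
        return 1.0 / self.period_min_nm


#: large sponge-like formations
ORDER_I = SpectralWindow("order_I", 600.0, 1200.0)
#: fine-scale roughness
ORDER_II = SpectralWindow("order_II", 50.0, 300.0)


@dataclass
class SpatialSpectrum:
    """One-sided amplitude-squared spectrum of a height profile.

    ``frequencies`` are nu_k = k / (N * dx) for k = 1 .. ceil(N/2)-1 (DC and
    Nyquist excluded); ``intensities`` are S_k in nm^2.
    """

    frequencies: np.ndarray
    intensities: np.ndarray
    n_points: int
    pixel_size_nm: float

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.frequencies.shape != self.intensities.shape:
            raise ValueError("frequency/intensity length mismatch")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def power(self) -> float:
        """Sum S_k / 2 — the profile variance carried by the spectrum."""
        return float(np.sum(self.intensities) / 2.0)


@dataclass
class SpectralSummary:
    """Per-window readout: peak intensity and where it sits."""

    window: SpectralWindow
    S_max_nm2: float
    nu_max_per_nm: float

    @property
    def L_max_nm(self) -> float:
        return 1.0 / self.nu_max_per_nm


def _detrend_1d(h: np.ndarray) -> np.ndarray:
    n = len(h)
    if n < 3:
        raise ValueError("need at least 3 samples to detrend")
    x = np.arange(n, dtype=float)
    coeffs = np.polyfit(x, h, 1)
    return h - np.polyval(coeffs, x)


def _detrend_2d(h: np.ndarray) -> np.ndarray:
    rows, cols = h.shape
    if rows < 3 or cols < 3:
        raise ValueError("need at least 3 samples per dimension to detrend")
    y, x = np.mgrid[0:rows, 0:cols]
    A = np.column_stack([np.ones(h.size), x.ravel(), y.ravel()])
    coef, *_ = np.linalg.lstsq(A, h.ravel(), rcond=None)
    return h - (A @ coef).reshape(h.shape)


def detrend(obj):
    """Subtract the least-squares line (1-D) or plane (2-D).

    Accepts a ``Profile``, ``HeightMap`` or plain array and returns the same
    kind. The result has zero mean and zero linear trend; the operation is
    idempotent up to float tolerance.
    """
    if isinstance(obj, Profile):
        return Profile(obj.distances_nm.copy(), _detrend_1d(obj.heights_nm),
                       source=obj.source)
    if isinstance(obj, HeightMap):
        return HeightMap(_detrend_2d(obj.heights), obj.pixel_size_nm,
                         obj.origin_nm, dict(obj.metadata))
    arr = np.asarray(obj, dtype=float)
    return _detrend_1d(arr) if arr.ndim == 1 else _detrend_2d(arr)


def _spectrum_of_rows(rows: np.ndarray, pixel_size_nm: float) -> SpatialSpectrum:
    """Row-averaged one-sided spectrum of an array of detrended profiles."""
    n = rows.shape[-1]
    coeffs = np.fft.rfft(rows, axis=-1)
    s = np.abs(2.0 / n * coeffs) ** 2
    # drop DC; drop Nyquist bin when n is even (rfft length n//2 + 1)
    hi = n // 2 if n % 2 == 0 else n // 2 + 1
    s = s[..., 1:hi]
    if s.ndim == 2:
        s = s.mean(axis=0)
    freqs = np.arange(1, hi) / (n * pixel_size_nm)
    return SpatialSpectrum(freqs, s, n_points=n, pixel_size_nm=pixel_size_nm)


def profile_spectrum(profile) -> SpatialSpectrum:
    """One-sided amplitude-squared spectrum of a single profile.

    The profile is detrended internally. S_k = |(2/N) sum_n h_n
    exp(-2 pi i k n / N)|^2 for k = 1 .. ceil(N/2)-1, so a pure on-grid
    cosine of amplitude A gives S = A^2 in its bin and ~0 elsewhere.
    """
    if isinstance(profile, Profile):
        h, px = profile.heights_nm, profile.spacing_nm
    else:
        h, px = profile
        h = np.asarray(h, dtype=float)
    if len(h) < 8:
        raise ValueError("profile too short for a spectrum (need N >= 8)")
    return _spectrum_of_rows(_detrend_1d(h), px)


def spectral_summary(spectrum: SpatialSpectrum,
                     window: SpectralWindow) -> SpectralSummary:
    """Peak intensity within a period window (edges inclusive).

    Ties at equal S are broken toward the lowest frequency, i.e. the
    largest period.
    """
    sel = (spectrum.frequencies >= window.nu_min) & \
          (spectrum.frequencies <= window.nu_max)
    if not np.any(sel):
        raise ValueError(
            f"window {window.label} has no representable frequencies "
            f"(range {spectrum.frequencies[0]:.3g}..{spectrum.frequencies[-1]:.3g})")
    freqs = spectrum.frequencies[sel]
    vals = spectrum.intensities[sel]
    i = int(np.argmax(vals))  # argmax returns the first (lowest-nu) maximum
    return SpectralSummary(window, float(vals[i]), float(freqs[i]))


def period_from_frequency(nu_per_nm: float) -> float:
    """Spatial period L = 1/nu (nm) from spatial frequency (1/nm)."""
    if nu_per_nm <= 0:
        raise ValueError("spatial frequency must be positive")
    return 1.0 / nu_per_nm


def bandpass_surface(hmap: HeightMap, window: SpectralWindow) -> HeightMap:
    """Reconstruct the surface carried by one period window.

    The map is plane-detrended, transformed with a 2-D FFT, coefficients
    with radial frequency inside [1/period_max, 1/period_min] (inclusive)
    retained, and inverse-transformed. Roughness is treated as isotropic:
    the band is radial in frequency magnitude. The result is real and
    zero-mean, and its variance equals the in-band 2-D spectral power.
    """
    h = _detrend_2d(hmap.heights)
    rows, cols = h.shape
    fy = np.fft.fftfreq(rows, d=hmap.pixel_size_nm)
    fx = np.fft.fftfreq(cols, d=hmap.pixel_size_nm)
    nyq = 0.5 / hmap.pixel_size_nm
    if window.nu_min > nyq:
        raise ValueError(
            f"window {window.label} lies entirely above Nyquist ({nyq:.4g}/nm)")
    rad = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    mask = (rad >= window.nu_min) & (rad <= window.nu_max)
    spec = np.fft.fft2(h) * mask
    out = np.real(np.fft.ifft2(spec))
    return HeightMap(out, hmap.pixel_size_nm, hmap.origin_nm,
                     {**hmap.metadata, "bandpass": window.label})


def cell_patch_spectrum(hmap: HeightMap, cell_mask: np.ndarray | None,
                        patch_size_nm: float = 5000.0):
    """Roughness spectrum of a membrane patch centred on the cell apex.

    A square patch of ``patch_size_nm`` per side is taken around the highest
    pixel of the (masked) map; rows of the detrended patch are transformed
    individually and their spectra averaged, which stabilises S_max.
    Summaries are returned for every window whose band is representable on
    the patch grid.

    Returns
    -------
    (SpatialSpectrum, dict[str, SpectralSummary])
        The row-averaged spectrum and per-window summaries keyed by label.
    """
    h = hmap.heights
    if cell_mask is not None:
        if not np.any(cell_mask):
            raise ValueError("empty cell mask")
        masked = np.where(cell_mask, h, -np.inf)
    else:
        masked = h
    apex = np.unravel_index(np.argmax(masked), h.shape)
    half = int(round(patch_size_nm / hmap.pixel_size_nm)) // 2
    n = 2 * half
    if n < 8:
        raise ValueError("patch too small for a spectrum")
    r0, c0 = apex[0] - half, apex[1] - half
    # keep the patch on the grid; the apex stays inside it
    r0 = min(max(r0, 0), h.shape[0] - n)
    c0 = min(max(c0, 0), h.shape[1] - n)
    if r0 < 0 or c0 < 0:
        raise ValueError(
            f"map smaller than requested {patch_size_nm} nm patch")
    patch = h[r0:r0 + n, c0:c0 + n]
    if cell_mask is not None and not cell_mask[r0:r0 + n, c0:c0 + n].all():
        raise ValueError("cell too small: patch extends beyond the cell mask")
    rows = _detrend_2d(patch)
    rows = rows - rows.mean(axis=1, keepdims=True)  # per-row DC removal
    spectrum = _spectrum_of_rows(rows, hmap.pixel_size_nm)
    summaries = {}
    for window in (ORDER_I, ORDER_II):
        try:
            summaries[window.label] = spectral_summary(spectrum, window)
        except ValueError:
            summaries[window.label] = None
    return spectrum, summaries
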