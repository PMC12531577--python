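"""Shared 1-D profile measurement helpers (Gaussian fits, half-max widths)."""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

_FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


class FitError(RuntimeError):
    """A 1-D profile fit failed to converge or is ill-posed."""


class HalfMaxError(RuntimeError):
    """The half-maximum level is not crossed inside the sampled range."""


def _gauss(x, amp, mu, sigma, base):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + base


def fwhm_halfmax(x: np.ndarray, y: np.ndarray) -> float:
    """FWHM by linear interpolation of the half-maximum crossings.

    The baseline is the profile minimum; the half level is halfway between
    baseline and peak.  Raises :class:`HalfMaxError` if either flank never
    crosses the half level inside the sampled range.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    k = int(np.argmax(y))
    base = float(np.min(y))
    half = base + 0.5 * (y[k] - base)
    if y[k] <= base:
        raise HalfMaxError("profile is flat; no half-maximum exists")

    def cross(idx_range, reverse):
        seq = idx_range[::-1] if reverse else idx_range
        prev = k
        for i in seq:
            if y[i] < half:
                x0, x1 = x[i], x[prev]
                y0, y1 = y[i], y[prev]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = i
        raise HalfMaxError("half-maximum not crossed inside the sampled range")

    left = cross(np.arange(0, k), reverse=True)
    right = cross(np.arange(k + 1, len(y)), reverse=False)
    return float(right - left)


def fit_gaussian_1d(x: np.ndarray, y: np.ndarray, *,
                    window_fwhm: float | None = 1.5) -> tuple[float, float, float, float]:
    """Least-squares Gaussian-plus-baseline fit; returns (amp, mu, sigma, base).

    When ``window_fwhm`` is set, the fit is restricted to a window of
    ``window_fwhm`` half-max-widths on either side of the peak (estimated by
    half-max interpolation first), which keeps diffraction side lobes and
    far-defocus background out of the fit.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 5:
        raise FitError("need at least 5 samples to fit a Gaussian")
    k = int(np.argmax(y))
    base0 = float(np.min(y))
    amp0 = float(y[k] - base0)
    if amp0 <= 0:
        raise FitError("profile has no peak above baseline")
    try:
        w0 = fwhm_halfmax(x, y)
    except HalfMaxError:
        w0 = (x[-1] - x[0]) / 4.0
    sigma0 = max(w0 / _FWHM_SIGMA, 1e-6)
    if window_fwhm is not None:
        sel = np.abs(x - x[k]) <= window_fwhm * w0
        if sel.sum() < 5:
            order = np.argsort(np.abs(x - x[k]))
            sel = np.zeros(x.size, bool)
            sel[order[:min(7, x.size)]] = True
        xs, ys = x[sel], y[sel]
    else:
        xs, ys = x, y
    try:
        with warnings.catch_warnings():
            # flat-top profiles legitimately produce degenerate covariance
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gauss, xs, ys, p0=[amp0, x[k], sigma0, base0],
                maxfev=10000,
            )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    amp, mu, sigma, base = popt
    if not np.isfinite([amp, mu, sigma, base]).all() or amp <= 0:
        raise FitError("Gaussian fit returned a degenerate solution")
    return float(amp), float(mu), float(abs(sigma)), float(base)


def fwhm_gaussian(x: np.ndarray, y: np.ndarray, **kw) -> float:
    """FWHM = 2*sqrt(2*ln 2)*sigma from :func:`fit_gaussian_1d`."""
    _, _, sigma, _ = fit_gaussian_1d(x, y, **kw)
    return _FWHM_SIGMA * sigma
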