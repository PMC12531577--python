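"""Scalar Fourier-optics engine: pupils, defocus, and intensity PSFs.

The detection path of a high-NA widefield fluorescence microscope is modeled
with scalar diffraction.  The complex pupil is sampled on a square grid over
the normalized pupil radius ``rho = sin(theta)/sin(theta_max)`` (aperture edge
at ``rho = 1``, inclusive), defocus enters as the non-paraxial phase

    phi(rho; z) = (2*pi/lambda) * n * z * sqrt(1 - (NA*rho/n)**2),

and the intensity PSF at each axial position is the squared modulus of the
centered 2-D Fourier transform of the phase-modulated pupil.  With a pupil
grid of ``n`` samples across the diameter zero-padded by ``pad_factor``, the
natural lateral pitch of the transform is ``lambda / (2*NA*pad_factor)``.

All lengths are in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "SamplingError",
    "OpticalConfig",
    "PupilMask",
    "PSFVolume",
    "make_circular_pupil",
    "make_annular_pupil",
    "defocus_phase",
    "defocus_phase_values",
    "compute_intensity_psf",
    "axial_response",
    "psf_axial_profile",
    "psf_lateral_profile",
]


class SamplingError(ValueError):
    """A requested sampling grid violates a Nyquist or range constraint."""


@dataclass(frozen=True)
class OpticalConfig:
    """Physical and numerical parameters of the detection path.

    Defaults describe a 60x / NA 1.2 water-immersion objective with green
    emission (505/515 beads) and a sample-plane pixel size of 108 nm.
    """

    numerical_aperture: float = 1.2
    immersion_index: float = 1.33
    emission_wavelength: float = 0.515
    excitation_wavelength: float = 0.488  # metadata only
    magnification: float = 60.0
    pixel_size_sample: float = 0.108
    pupil_grid_n: int = 512
    pad_factor: int = 4
    z_step_fine: float = 0.05

    def __post_init__(self) -> None:
        if not self.numerical_aperture < self.immersion_index:
            raise ValueError(
                "numerical_aperture must be < immersion_index "
                f"(got NA={self.numerical_aperture}, n={self.immersion_index}); "
                "otherwise the defocus square root turns imaginary inside the pupil"
            )
        for name in ("numerical_aperture", "immersion_index", "emission_wavelength",
                     "excitation_wavelength", "magnification", "pixel_size_sample",
                     "z_step_fine"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pupil_grid_n < 16 or self.pupil_grid_n % 2:
            raise ValueError("pupil_grid_n must be an even integer >= 16")
        if self.pad_factor < 2:
            raise ValueError("pad_factor must be an integer >= 2")

    @property
    def fourier_pitch(self) -> float:
        """Lateral sample pitch of the padded pupil FFT, lambda/(2*NA*pad)."""
        return self.emission_wavelength / (2.0 * self.numerical_aperture * self.pad_factor)

    @property
    def nyquist_pitch(self) -> float:
        """Coarsest lateral pitch that still samples the PSF: lambda/(4*NA)."""
        return self.emission_wavelength / (4.0 * self.numerical_aperture)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown OpticalConfig fields: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "OpticalConfig":
        return replace(self, **kw)


@lru_cache(maxsize=8)
def _rho_grid(n: int) -> np.ndarray:
    """Normalized radius on an n x n grid spanning [-1, 1) with pitch 2/n."""
    axis = (np.arange(n) - n // 2) * (2.0 / n)
    xx, yy = np.meshgrid(axis, axis)
    return np.hypot(xx, yy)


@dataclass(frozen=True)
class PupilMask:
    """Complex pupil amplitude sampled over normalized radius rho in [-1, 1)."""

    amplitude: np.ndarray
    label: str = "pupil"

    def __post_init__(self) -> None:
        a = self.amplitude
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("pupil amplitude must be a square 2-D array")
        rho = _rho_grid(a.shape[0])
        if np.any(np.abs(a[rho > 1.0]) > 0):
            raise ValueError("pupil amplitude must vanish for rho > 1")
        if np.any(np.abs(a) > 1.0 + 1e-12):
            raise ValueError("pupil |amplitude| must be <= 1")

    @property
    def n(self) -> int:
        return self.amplitude.shape[0]

    @property
    def rho(self) -> np.ndarray:
        return _rho_grid(self.n)

    def energy(self) -> float:
        """Sum of |amplitude|^2 over the grid."""
        a = self.amplitude
        return float(np.sum(a.real ** 2 + a.imag ** 2))


@dataclass
class PSFVolume:
    """Sampled nonnegative 3-D intensity PSF on a regular raster.

    ``z_origin`` is the z of the first slice relative to nominal focus, so the
    axial coordinate of slice ``k`` is ``z_origin + k * axial_pitch``.
    """

    data: np.ndarray
    lateral_pitch: float
    axial_pitch: float
    z_origin: float
    normalization: str = "peak"  # "peak" | "energy" | "none"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("PSFVolume data must be (nz, ny, nx)")
        if np.any(self.data < 0):
            raise ValueError("PSF intensities must be >= 0")
        if self.lateral_pitch <= 0 or self.axial_pitch <= 0:
            raise ValueError("pitches must be > 0")

    @property
    def n_z(self) -> int:
        return self.data.shape[0]

    @property
    def z_values(self) -> np.ndarray:
        return self.z_origin + self.axial_pitch * np.arange(self.n_z)

    def lateral_halfwidth(self) -> float:
        """Half-extent of a slice in micrometres, measured from its center."""
        return (self.data.shape[-1] // 2) * self.lateral_pitch

    def save_tiff(self, path: str | Path) -> None:
        meta = {
            "lateral_pitch_um": self.lateral_pitch,
            "axial_pitch_um": self.axial_pitch,
            "z_origin_um": self.z_origin,
            "normalization": self.normalization,
            **self.meta,
        }
        tifffile.imwrite(path, self.data.astype(np.float32),
                         photometric="minisblack",
                         description=json.dumps(meta, sort_keys=True))

    @classmethod
    def load_tiff(cls, path: str | Path) -> "PSFVolume":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray().astype(np.float64)
            desc = tf.pages[0].tags["ImageDescription"].value
        meta = json.loads(desc)
        if data.ndim == 2:
            data = data[None]
        return cls(
            data=data,
            lateral_pitch=meta.pop("lateral_pitch_um"),
            axial_pitch=meta.pop("axial_pitch_um"),
            z_origin=meta.pop("z_origin_um"),
            normalization=meta.pop("normalization"),
            meta=meta,
        )


def make_circular_pupil(config: OpticalConfig) -> PupilMask:
    """Clear circular aperture: unit amplitude for rho <= 1, zero phase."""
    rho = _rho_grid(config.pupil_grid_n)
    amp = (rho <= 1.0).astype(np.complex128)
    return PupilMask(amplitude=amp, label="clear")


def make_annular_pupil(config: OpticalConfig, r_inner: float, r_outer: float,
                       *, outer_inclusive: bool = False, label: str | None = None) -> PupilMask:
    """Annular aperture r_inner <= rho < r_outer (or <= r_outer if inclusive).

    With ``r_inner=0, r_outer=1, outer_inclusive=True`` this reproduces the
    clear circular pupil exactly, sample for sample.
    """
    if not 0 <= r_inner < r_outer <= 1.0:
        raise ValueError("need 0 <= r_inner < r_outer <= 1")
    rho = _rho_grid(config.pupil_grid_n)
    if outer_inclusive:
        mask = (rho >= r_inner) & (rho <= r_outer)
    else:
        mask = (rho >= r_inner) & (rho < r_outer)
    return PupilMask(amplitude=mask.astype(np.complex128),
                     label=label or f"annulus[{r_inner:.4f},{r_outer:.4f}]")


def defocus_phase_values(config: OpticalConfig, defocus: float,
                         rho: np.ndarray | float) -> np.ndarray:
    """Unwrapped defocus phase phi(rho) in radians (closed form).

    phi = (2*pi/lambda) * n * z * sqrt(1 - (NA*rho/n)^2); strictly decreasing
    in rho for positive defocus.
    """
    rho = np.asarray(rho, dtype=float)
    na, n = config.numerical_aperture, config.immersion_index
    arg = np.clip(1.0 - (na * rho / n) ** 2, 0.0, None)
    return (2.0 * np.pi / config.emission_wavelength) * n * defocus * np.sqrt(arg)


def defocus_phase(config: OpticalConfig, defocus: float) -> PupilMask:
    """Phase-only pupil mask exp(i*phi(rho; defocus)) inside the aperture."""
    rho = _rho_grid(config.pupil_grid_n)
    inside = rho <= 1.0
    phi = defocus_phase_values(config, defocus, rho)
    amp = np.where(inside, np.exp(1j * phi), 0.0 + 0.0j)
    return PupilMask(amplitude=amp, label=f"defocus[{defocus:g}um]")


def _axial_pitch_of(z: np.ndarray, config: OpticalConfig) -> float:
    if z.size == 1:
        return config.z_step_fine
    dz = np.diff(z)
    if np.any(dz <= 0):
        raise ValueError("z_list must be strictly increasing")
    if not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-9):
        raise ValueError("z_list must be uniformly spaced for a PSFVolume raster")
    return float(dz[0])


def _normalize(data: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "none":
        return data
    if normalization == "peak":
        peak = data.max()
        return data / peak if peak > 0 else data
    if normalization == "energy":
        # peak per-slice energy -> 1, so values divided by the sample pitch^2
        # form a 2-D probability density for the best-covered slice
        e = data.sum(axis=(1, 2)).max()
        return data / e if e > 0 else data
    raise ValueError(f"unknown normalization {normalization!r}")


def compute_intensity_psf(pupil: PupilMask, config: OpticalConfig,
                          z_list: Sequence[float], *,
                          lateral_pitch: float | None = None,
                          crop_halfwidth: float | None = None,
                          normalization: str = "peak") -> PSFVolume:
    """Intensity PSF |FT{pupil * defocus_phase(z)}|^2 stacked over ``z_list``.

    Parameters
    ----------
    lateral_pitch
        Output lateral sample pitch in micrometres.  ``None`` keeps the native
        FFT pitch ``lambda/(2*NA*pad_factor)``.  Pitches coarser than the
        Nyquist bound ``lambda/(4*NA)`` are rejected.
    crop_halfwidth
        Keep only a centered lateral window of this half-width (micrometres).
        ``None`` keeps the full padded grid (needed for energy bookkeeping).
    normalization
        "peak" (default), "energy" (mean per-slice energy = 1) or "none"
        (raw |FFT|^2 values); recorded on the returned volume.
    """
    z = np.atleast_1d(np.asarray(z_list, dtype=float))
    if z.size == 0:
        raise ValueError("z_list must be nonempty")
    axial_pitch = _axial_pitch_of(z, config)

    native = config.fourier_pitch
    pitch = native if lateral_pitch is None else float(lateral_pitch)
    bound = config.nyquist_pitch
    if pitch > bound * (1 + 1e-9):
        raise SamplingError(
            f"lateral pitch {pitch:.4f} um is coarser than the Nyquist bound "
            f"lambda/(4*NA) = {bound:.4f} um"
        )

    n = pupil.n
    big = n * config.pad_factor
    rho = pupil.rho
    inside = rho <= 1.0
    na, nim = config.numerical_aperture, config.immersion_index
    chi = np.sqrt(np.clip(1.0 - (na * rho / nim) ** 2, 0.0, None))
    k = 2.0 * np.pi * nim / config.emission_wavelength

    lo = (big - n) // 2
    slices = []
    for zi in z:
        field_small = pupil.amplitude * np.where(inside, np.exp(1j * (k * zi) * chi), 0)
        emb = np.zeros((big, big), dtype=np.complex128)
        emb[lo:lo + n, lo:lo + n] = field_small
        f = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(emb)))
        intensity = f.real ** 2 + f.imag ** 2
        slices.append(_resample_slice(intensity, native, pitch, crop_halfwidth))
    data = _normalize(np.stack(slices), normalization)
    return PSFVolume(
        data=data,
        lateral_pitch=pitch,
        axial_pitch=axial_pitch,
        z_origin=float(z[0]),
        normalization=normalization,
        meta={"pupil": pupil.label, "config": json.loads(config.to_json())},
    )


def _resample_slice(intensity: np.ndarray, native: float, pitch: float,
                    crop_halfwidth: float | None) -> np.ndarray:
    big = intensity.shape[0]
    center = big // 2
    if crop_halfwidth is None and pitch == native:
        return intensity
    half_um = crop_halfwidth if crop_halfwidth is not None else (center - 1) * native
    if pitch == native:
        m = min(center - 1, int(round(half_um / native)))
        return intensity[center - m:center + m + 1, center - m:center + m + 1]
    m = int(np.floor(min(half_um, (center - 1) * native) / pitch))
    axis = np.arange(-m, m + 1) * (pitch / native) + center
    cc, rr = np.meshgrid(axis, axis)
    return ndimage.map_coordinates(intensity, [rr, cc], order=1, mode="constant")


def axial_response(pupil: PupilMask, config: OpticalConfig,
                   z_list: Sequence[float]) -> np.ndarray:
    """On-axis intensity PSF(0, 0, z) for each z, up to a fixed grid constant.

    The PSF value at the lateral origin is the squared modulus of the
    zero-frequency Fourier component, i.e. of the plain sum of the
    defocus-modulated pupil samples; no FFT is needed.  The returned values
    share the (unnormalized) scale of ``compute_intensity_psf(...,
    normalization="none")`` at the central pixel, so responses of different
    pupils on the same grid are directly comparable.
    """
    z = np.atleast_1d(np.asarray(z_list, dtype=float))
    rho = pupil.rho
    inside = (np.abs(pupil.amplitude) > 0)
    a = pupil.amplitude[inside]
    na, nim = config.numerical_aperture, config.immersion_index
    chi = np.sqrt(np.clip(1.0 - (na * rho[inside] / nim) ** 2, 0.0, None))
    k = 2.0 * np.pi * nim / config.emission_wavelength
    out = np.empty(z.size)
    for i, zi in enumerate(z):
        s = np.sum(a * np.exp(1j * (k * zi) * chi))
        out[i] = s.real ** 2 + s.imag ** 2
    return out


def psf_axial_profile(psf: PSFVolume) -> np.ndarray:
    """Per-slice peak intensity as a function of z (length n_z)."""
    if psf.n_z < 3:
        raise ValueError("axial profile needs at least 3 z slices")
    return psf.data.max(axis=(1, 2))


def psf_lateral_profile(psf: PSFVolume, z_index: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Lateral line profile through the peak of one slice.

    Returns ``(x_um, intensity)`` where x is measured from the slice center.
    ``z_index=None`` picks the slice containing the global peak.
    """
    if z_index is None:
        z_index = int(np.argmax(psf.data.max(axis=(1, 2))))
    sl = psf.data[z_index]
    r, _c = np.unravel_index(np.argmax(sl), sl.shape)
    prof = sl[r, :].astype(float)
    x = (np.arange(sl.shape[1]) - sl.shape[1] // 2) * psf.lateral_pitch
    return x, prof
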