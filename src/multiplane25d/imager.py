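"""Forward model: render scenes into camera frames with sCMOS noise.

Rendering is emitter-wise PSF lookup rather than per-slice convolution, so
emitters may sit at arbitrary continuous depths: each emitter contributes a
patch interpolated from the sampled PSF volume (linear blend between the two
bracketing z slices, spline interpolation laterally).  The photon image is
then pushed through a simple sCMOS model — quantum efficiency, Poisson shot
noise, Gaussian read noise, fixed offset, 16-bit quantization.

Brightness calibration: with an energy-normalized PSF a bead of brightness B
deposits ~B x path_transmission photons on the quadrant (minus whatever the
PSF crop discards at large defocus).  Exposure time is absorbed into the
brightness; there is no explicit time unit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .optics_core import OpticalConfig, PSFVolume
from .scene import Scene
from .splitter import SplitterConfig, flip_image

__all__ = [
    "NoiseModel",
    "CameraFrame",
    "DefocusRangeError",
    "render_plane",
    "render_quadframe",
    "render_quadframe_photons",
    "acquire_zstack",
    "plan_grid",
    "acquire_grid",
    "apply_camera_noise",
]


class DefocusRangeError(ValueError):
    """An emitter's defocus falls outside the sampled z range of the PSF."""


@dataclass(frozen=True)
class NoiseModel:
    """sCMOS camera model: counts = gain*(Poisson(QE*photons) + read) + offset."""

    quantum_efficiency: float = 0.82
    read_noise: float = 1.0      # electrons RMS
    offset: float = 100.0        # counts
    gain: float = 0.5            # counts / electron
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not 0 <= self.quantum_efficiency <= 1:
            raise ValueError("quantum_efficiency must lie in [0, 1]")
        for name in ("read_noise", "offset", "gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")

    @property
    def saturation(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass
class CameraFrame:
    """16-bit sensor raster plus acquisition metadata."""

    data: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.dtype != np.uint16:
            raise ValueError("CameraFrame data must be uint16 counts")

    def save_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.data, ome=True,
                         description=json.dumps(self.metadata, sort_keys=True,
                                                default=float))


def _config_digest(*objs) -> str:
    blob = "|".join(getattr(o, "to_json", lambda: json.dumps(repr(o)))()
                    for o in objs)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def apply_camera_noise(photon_image: np.ndarray, noise: NoiseModel,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Seeded sCMOS conversion of an expected-photon image to uint16 counts."""
    if np.any(photon_image < 0):
        raise ValueError("photon rates must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    electrons = rng.poisson(noise.quantum_efficiency * photon_image).astype(np.float64)
    counts = noise.gain * electrons
    counts += rng.normal(0.0, noise.read_noise, size=photon_image.shape) * noise.gain
    counts += noise.offset
    return np.clip(np.rint(counts), 0, noise.saturation).astype(np.uint16)


def render_plane(scene: Scene, psf: PSFVolume, focal_z: float,
                 config: OpticalConfig, *,
                 shape_px: tuple[int, int] = (512, 512),
                 origin_um: tuple[float, float] = (0.0, 0.0),
                 channel: int | None = None,
                 scale: float = 1.0,
                 include_background: bool = True,
                 out_of_range: str = "error",
                 interp_order: int = 1) -> np.ndarray:
    """Expected-photon image of the scene seen by a plane focused at ``focal_z``.

    Pixel (r, c) is centered at sample position
    ``(origin_x + (c + 0.5)*px, origin_y + (r + 0.5)*px)``.  Each emitter is
    looked up in the PSF volume at defocus ``z_e - focal_z`` (linear in z,
    spline of order ``interp_order`` laterally) and scaled so that brightness
    counts photons for an energy-normalized PSF.  ``out_of_range`` controls
    emitters whose defocus exceeds the PSF's sampled z range: "error" (the
    PSF is under-sampled for this scene), "skip" (omit their light).
    """
    if out_of_range not in ("error", "skip"):
        raise ValueError("out_of_range must be 'error' or 'skip'")
    h, w = shape_px
    px = config.pixel_size_sample
    img = np.zeros((h, w), dtype=np.float64)

    zvals = psf.z_values
    z_lo, z_hi = zvals[0], zvals[-1]
    pitch = psf.lateral_pitch
    ny, nx = psf.data.shape[1:]
    half_um = (min(nx, ny) // 2) * pitch
    photon_scale = (px / pitch) ** 2

    for e in scene.emitters:
        if channel is not None and e.channel != channel:
            continue
        dz = e.z - focal_z
        if dz < z_lo - 1e-9 or dz > z_hi + 1e-9:
            if out_of_range == "error":
                raise DefocusRangeError(
                    f"emitter defocus {dz:.2f} um outside PSF range "
                    f"[{z_lo:.2f}, {z_hi:.2f}] um")
            continue
        sx, sy = scene.channel_shift.get(e.channel, (0.0, 0.0))
        ex, ey = e.x + sx, e.y + sy

        c0 = max(int(np.floor((ex - half_um - origin_um[0]) / px - 0.5)), 0)
        c1 = min(int(np.ceil((ex + half_um - origin_um[0]) / px - 0.5)) + 1, w)
        r0 = max(int(np.floor((ey - half_um - origin_um[1]) / px - 0.5)), 0)
        r1 = min(int(np.ceil((ey + half_um - origin_um[1]) / px - 0.5)) + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue

        k = np.clip(np.searchsorted(zvals, dz) - 1, 0, len(zvals) - 2)
        t = np.clip((dz - zvals[k]) / (zvals[k + 1] - zvals[k]), 0.0, 1.0)

        xs = (origin_um[0] + (np.arange(c0, c1) + 0.5) * px - ex) / pitch + nx // 2
        ys = (origin_um[1] + (np.arange(r0, r1) + 0.5) * px - ey) / pitch + ny // 2
        cc, rr = np.meshgrid(xs, ys)
        coords = [rr, cc]
        patch = (1.0 - t) * ndimage.map_coordinates(
            psf.data[k], coords, order=interp_order, mode="constant")
        if t > 0:
            patch += t * ndimage.map_coordinates(
                psf.data[k + 1], coords, order=interp_order, mode="constant")
        np.clip(patch, 0.0, None, out=patch)
        img[r0:r1, c0:c1] += (e.brightness * photon_scale) * patch

    if include_background:
        img += scene.background_rate
    if scale != 1.0:
        img *= scale
    return img


def render_quadframe_photons(scene: Scene, splitter: SplitterConfig,
                             edof_psf: PSFVolume, config: OpticalConfig, *,
                             stage_xy: tuple[float, float] = (0.0, 0.0),
                             stage_z: float = 0.0,
                             channel: int | None = None,
                             out_of_range: str = "error",
                             interp_order: int = 1) -> np.ndarray:
    """Noise-free expected-photon sensor mosaic (float64, full sensor shape)."""
    sensor = np.zeros(splitter.sensor_shape_px, dtype=np.float64)
    h, w = splitter.quadrant_shape_rc
    px = config.pixel_size_sample
    for p in range(splitter.n_planes):
        dx, dy = splitter.injected_misregistration[p]
        sub = render_plane(
            scene, edof_psf, splitter.plane_centers[p] - stage_z, config,
            shape_px=(h, w),
            origin_um=(stage_xy[0] - dx * px, stage_xy[1] - dy * px),
            channel=channel,
            scale=splitter.path_transmissions[p],
            out_of_range=out_of_range,
            interp_order=interp_order,
        )
        r0, c0 = splitter.quadrant_origins_px[p]
        sensor[r0:r0 + h, c0:c0 + w] = flip_image(sub, splitter.flip_flags[p])
    return sensor


def render_quadframe(scene: Scene, splitter: SplitterConfig, edof_psf: PSFVolume,
                     config: OpticalConfig, noise: NoiseModel,
                     seed: int | np.random.Generator = 0, *,
                     stage_xy: tuple[float, float] = (0.0, 0.0),
                     stage_z: float = 0.0,
                     channel: int | None = None,
                     out_of_range: str = "error",
                     interp_order: int = 1) -> CameraFrame:
    """One multiplane exposure: four EDOF focal volumes on one sensor."""
    photons = render_quadframe_photons(
        scene, splitter, edof_psf, config, stage_xy=stage_xy, stage_z=stage_z,
        channel=channel, out_of_range=out_of_range, interp_order=interp_order)
    counts = apply_camera_noise(photons, noise, seed)
    meta = {
        "stage_x": stage_xy[0], "stage_y": stage_xy[1], "stage_z": stage_z,
        "channel": channel, "exposure": "absorbed-into-brightness",
        "config_digest": _config_digest(splitter, config),
    }
    return CameraFrame(data=counts, metadata=meta)


def acquire_zstack(scene: Scene, z_positions: Sequence[float], psf: PSFVolume,
                   config: OpticalConfig, noise: NoiseModel, seed: int = 0, *,
                   shape_px: tuple[int, int] = (512, 512),
                   origin_um: tuple[float, float] = (0.0, 0.0),
                   channel: int | None = None,
                   out_of_range: str = "error",
                   interp_order: int = 1) -> np.ndarray:
    """Serial z-scan: one widefield frame per focal position (piezo emulation).

    Returns a (n_z, h, w) uint16 stack.  Pass an EDOF PSF to emulate scanning
    with the layer cake installed.
    """
    z_positions = list(z_positions)
    if len(z_positions) == 0:
        raise ValueError("z_positions must be nonempty")
    if any(b <= a for a, b in zip(z_positions, z_positions[1:])):
        raise ValueError("z_positions must be sorted ascending")
    streams = np.random.SeedSequence(seed).spawn(len(z_positions))
    frames = []
    for z, ss in zip(z_positions, streams):
        photons = render_plane(scene, psf, z, config, shape_px=shape_px,
                               origin_um=origin_um, channel=channel,
                               out_of_range=out_of_range,
                               interp_order=interp_order)
        frames.append(apply_camera_noise(photons, noise, np.random.default_rng(ss)))
    return np.stack(frames)


def plan_grid(extent: tuple[float, float], fov: tuple[float, float],
              overlap_fraction: float, *,
              grid_shape: tuple[int, int] | None = None) -> pd.DataFrame:
    """Serpentine stop-and-snap stage plan covering ``extent``.

    Returns a table of nominal stage positions (um) ordered stage-efficiently:
    rows are scanned alternately left-to-right and right-to-left.
    """
    if not 0 <= overlap_fraction <= 0.5:
        raise ValueError("overlap_fraction must lie in [0, 0.5]")
    if fov[0] > extent[0] or fov[1] > extent[1]:
        raise ValueError("tile FOV larger than the scene extent")
    step = (fov[0] * (1 - overlap_fraction), fov[1] * (1 - overlap_fraction))
    if grid_shape is None:
        n_x = max(1, int(np.ceil((extent[0] - fov[0]) / step[0] - 1e-9)) + 1)
        n_y = max(1, int(np.ceil((extent[1] - fov[1]) / step[1] - 1e-9)) + 1)
    else:
        n_x, n_y = grid_shape
    rows = []
    order = 0
    for j in range(n_y):
        cols = range(n_x) if j % 2 == 0 else range(n_x - 1, -1, -1)
        for i in cols:
            rows.append((order, j, i, i * step[0], j * step[1]))
            order += 1
    return pd.DataFrame(rows, columns=["order", "grid_row", "grid_col",
                                       "nominal_x", "nominal_y"])


def acquire_grid(scene: Scene, splitter: SplitterConfig, edof_psf: PSFVolume,
                 config: OpticalConfig, noise: NoiseModel, seed: int = 0, *,
                 overlap_fraction: float = 0.1,
                 channels: Sequence[int | None] = (None,),
                 grid_shape: tuple[int, int] | None = None,
                 stage_jitter_px: float = 0.0,
                 out_of_range: str = "skip",
                 interp_order: int = 1) -> tuple[list[CameraFrame], pd.DataFrame]:
    """Tiled stop-and-snap acquisition of quad-plane frames.

    All channels are captured at each position before the stage moves
    (interleaved channel frames share identical stage positions).  With
    ``stage_jitter_px`` > 0 the true stage position deviates uniformly by up
    to that many pixels from nominal; the returned truth table records both,
    for stitching validation.
    """
    px = config.pixel_size_sample
    fov = (splitter.quadrant_shape_px[0] * px, splitter.quadrant_shape_px[1] * px)
    plan = plan_grid(scene.extent, fov, overlap_fraction, grid_shape=grid_shape)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    jitter = rng.uniform(-stage_jitter_px, stage_jitter_px, size=(len(plan), 2)) * px \
        if stage_jitter_px > 0 else np.zeros((len(plan), 2))
    streams = np.random.SeedSequence(seed).spawn(len(plan) * len(channels))

    frames: list[CameraFrame] = []
    truth_rows = []
    k = 0
    for (_, row), (jx, jy) in zip(plan.iterrows(), jitter):
        true_x = row.nominal_x + jx
        true_y = row.nominal_y + jy
        for ch in channels:
            frame = render_quadframe(
                scene, splitter, edof_psf, config, noise,
                np.random.default_rng(streams[k]),
                stage_xy=(true_x, true_y), channel=ch,
                out_of_range=out_of_range, interp_order=interp_order)
            frame.metadata.update(grid_row=int(row.grid_row),
                                  grid_col=int(row.grid_col),
                                  order=int(row.order), channel=ch)
            frames.append(frame)
            k += 1
        truth_rows.append((int(row.order), int(row.grid_row), int(row.grid_col),
                           row.nominal_x, row.nominal_y, true_x, true_y))
    truth = pd.DataFrame(truth_rows, columns=["order", "grid_row", "grid_col",
                                              "nominal_x", "nominal_y",
                                              "stage_x", "stage_y"])
    return frames, truth
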