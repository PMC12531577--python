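"""Analysis pipeline: quadrant splitting, registration, characterization,
projections, depth coding, stitching, and classical pre/post-processing.

The processing chain mirrors how multiplane quadrant data are handled in
practice: crop the sensor mosaic into four sub-images, undo the per-path
vertical flips so all planes share one orientation, register the planes to
the Z12-16 reference with bead calibration data, then feed the aligned
stack into measurement (spacing, FWHM, chromatic shift), projection, depth
coding or grid stitching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed
from scipy.spatial import cKDTree

from ._fit import FitError, HalfMaxError, fit_gaussian_1d, fwhm_gaussian, fwhm_halfmax
from .imager import CameraFrame
from .splitter import SplitterConfig, flip_image

__all__ = [
    "CalibrationError",
    "RegistrationMap",
    "StitchThresholds",
    "BeadZScan",
    "split_quadrants",
    "assemble_quadrants",
    "detect_beads",
    "calibrate_registration",
    "apply_registration",
    "measure_interplane_spacing",
    "measure_fwhm",
    "project",
    "grouped_aip",
    "depth_code",
    "DEFAULT_DEPTH_PALETTE",
    "stitch_grid",
    "bilateral_filter",
    "measure_chromatic_shift",
    "segment_nuclei_classical",
]


class CalibrationError(RuntimeError):
    """Bead-based calibration failed (too few beads, bad fits, ...)."""


# --------------------------------------------------------------------------
# quadrant handling

def split_quadrants(frame: CameraFrame | np.ndarray,
                    splitter: SplitterConfig) -> list[np.ndarray]:
    """Crop the sensor mosaic into per-plane sub-images, flips undone.

    Output order follows the plane labels (Z0-4, Z4-8, Z8-12, Z12-16)
    regardless of where each quadrant sits on the sensor; all four share one
    orientation afterwards.
    """
    data = frame.data if isinstance(frame, CameraFrame) else np.asarray(frame)
    if data.shape != tuple(splitter.sensor_shape_px):
        raise ValueError(
            f"frame shape {data.shape} does not match sensor "
            f"{splitter.sensor_shape_px}")
    h, w = splitter.quadrant_shape_rc
    subs = []
    for p in range(splitter.n_planes):
        r0, c0 = splitter.quadrant_origins_px[p]
        sub = data[r0:r0 + h, c0:c0 + w]
        subs.append(flip_image(sub, splitter.flip_flags[p]).copy())
    return subs


def assemble_quadrants(planes: Sequence[np.ndarray],
                       splitter: SplitterConfig,
                       fill: float = 0) -> np.ndarray:
    """Inverse of :func:`split_quadrants` (re-flip and paste); exact."""
    if len(planes) != splitter.n_planes:
        raise ValueError("need one sub-image per plane")
    out = np.full(splitter.sensor_shape_px, fill, dtype=planes[0].dtype)
    h, w = splitter.quadrant_shape_rc
    for p, sub in enumerate(planes):
        r0, c0 = splitter.quadrant_origins_px[p]
        out[r0:r0 + h, c0:c0 + w] = flip_image(sub, splitter.flip_flags[p])
    return out


# --------------------------------------------------------------------------
# bead detection and registration

def detect_beads(image: np.ndarray, *, threshold: float | None = None,
                 min_distance: int = 5, window: int = 7) -> pd.DataFrame:
    """Isolated-bead detection with sub-pixel center-of-mass refinement.

    Candidates are local maxima above ``threshold`` (default: image mean plus
    five robust standard deviations, 1.4826*MAD).  Each candidate is refined
    by the intensity center of mass in a ``window`` x ``window`` box after
    subtracting the box-edge median as local background.  Returns columns
    ``x_px``, ``y_px``, ``peak``.
    """
    img = np.asarray(image, dtype=np.float64)
    if threshold is None:
        med = np.median(img)
        mad = np.median(np.abs(img - med))
        threshold = img.mean() + 5.0 * 1.4826 * mad
    peaks = peak_local_max(img, min_distance=min_distance,
                           threshold_abs=threshold, exclude_border=window // 2)
    half = window // 2
    rows = []
    for r, c in peaks:
        box = img[r - half:r + half + 1, c - half:c + half + 1]
        edge = np.concatenate([box[0], box[-1], box[1:-1, 0], box[1:-1, -1]])
        sub = np.clip(box - np.median(edge), 0, None)
        total = sub.sum()
        if total <= 0:
            continue
        dy, dx = np.mgrid[-half:half + 1, -half:half + 1]
        rows.append((c + float((sub * dx).sum() / total),
                     r + float((sub * dy).sum() / total),
                     float(img[r, c])))
    return pd.DataFrame(rows, columns=["x_px", "y_px", "peak"])


@dataclass
class RegistrationMap:
    """Per-plane lateral shifts (px) relative to the reference plane."""

    reference: int = 3
    shifts: tuple[tuple[float, float], ...] = ((0.0, 0.0),) * 4
    residuals: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ref_shift = self.shifts[self.reference]
        if ref_shift != (0.0, 0.0):
            raise ValueError("reference plane shift must be (0, 0)")
        if not np.all(np.isfinite(np.asarray(self.shifts))):
            raise ValueError("shifts must be finite")


def calibrate_registration(plane_images: Sequence[np.ndarray], *,
                           reference: int = 3, gate_px: float = 5.0,
                           min_beads: int = 10,
                           threshold: float | None = None) -> RegistrationMap:
    """Estimate per-plane translations from a shared bead field.

    ``plane_images`` are per-plane bead images (2-D), or per-plane z-stacks
    (3-D, reduced by maximum projection first).  Beads are detected per
    plane, matched to the reference by nearest neighbour within ``gate_px``,
    and each plane's shift is the median matched displacement.  Raises
    :class:`CalibrationError` when fewer than ``min_beads`` matches survive.
    """
    imgs = [np.asarray(im, float) for im in plane_images]
    imgs = [im.max(axis=0) if im.ndim == 3 else im for im in imgs]
    dets = [detect_beads(im, threshold=threshold) for im in imgs]
    ref = dets[reference]
    if len(ref) < min_beads:
        raise CalibrationError(
            f"only {len(ref)} beads detected in the reference plane "
            f"(need >= {min_beads})")
    tree = cKDTree(ref[["x_px", "y_px"]].to_numpy())
    shifts = []
    residual_rows = []
    for p, det in enumerate(dets):
        if p == reference:
            shifts.append((0.0, 0.0))
            continue
        if len(det) == 0:
            raise CalibrationError(f"no beads detected in plane {p}")
        pts = det[["x_px", "y_px"]].to_numpy()
        dist, idx = tree.query(pts, distance_upper_bound=gate_px)
        ok = np.isfinite(dist)
        if ok.sum() < min_beads:
            raise CalibrationError(
                f"only {int(ok.sum())} matched beads between plane {p} and the "
                f"reference (need >= {min_beads})")
        disp = pts[ok] - tree.data[idx[ok]]
        dx, dy = np.median(disp, axis=0)
        shifts.append((float(dx), float(dy)))
        for (ddx, ddy) in disp:
            residual_rows.append((p, float(ddx), float(ddy),
                                  float(np.hypot(ddx - dx, ddy - dy))))
    residuals = pd.DataFrame(residual_rows,
                             columns=["plane", "dx_px", "dy_px", "residual_px"])
    return RegistrationMap(reference=reference, shifts=tuple(shifts),
                           residuals=residuals)


def apply_registration(sub_images: Sequence[np.ndarray], reg: RegistrationMap, *,
                       order: int = 3, fill: float = 0.0) -> np.ndarray:
    """Translate each plane by minus its shift; edges padded with ``fill``.

    Integer shifts reduce to exact pixel re-indexing (bit-identical in the
    interior); fractional shifts use spline interpolation of the given
    order (cubic by default, which keeps band-limited microscope images
    near-invertible under a shift and its negation).
    """
    if len(sub_images) != len(reg.shifts):
        raise ValueError("number of images must match the registration map")
    out = []
    for img, (dx, dy) in zip(sub_images, reg.shifts):
        arr = np.asarray(img, dtype=np.float64)
        if dx == 0.0 and dy == 0.0:
            out.append(arr.copy())
        elif float(dx).is_integer() and float(dy).is_integer():
            shifted = np.full_like(arr, fill)
            h, w = arr.shape
            r, c = -int(dy), -int(dx)
            r0, r1 = max(r, 0), min(h + r, h)
            c0, c1 = max(c, 0), min(w + c, w)
            shifted[r0:r1, c0:c1] = arr[r0 - r:r1 - r, c0 - c:c1 - c]
            out.append(shifted)
        else:
            # mirror boundary for the spline (a constant pad would ring far
            # into the interior through the prefilter); the strip that came
            # from outside the support is then overwritten with `fill`
            shifted = ndimage.shift(arr, (-dy, -dx), order=order, mode="mirror")
            h, w = arr.shape
            if dy > 0:
                shifted[h - int(np.ceil(dy)):, :] = fill
            elif dy < 0:
                shifted[:int(np.ceil(-dy)), :] = fill
            if dx > 0:
                shifted[:, w - int(np.ceil(dx)):] = fill
            elif dx < 0:
                shifted[:, :int(np.ceil(-dx))] = fill
            out.append(shifted)
    return np.stack(out)


# --------------------------------------------------------------------------
# characterization measurements

@dataclass
class BeadZScan:
    """Per-plane bead intensity versus stage z from an axial scan."""

    stage_z: np.ndarray
    intensities: tuple[np.ndarray, ...]   # one (n_beads, n_z) array per plane

    def __post_init__(self) -> None:
        for arr in self.intensities:
            if arr.ndim != 2 or arr.shape[1] != len(self.stage_z):
                raise ValueError("each plane needs an (n_beads, n_z) array")


def measure_interplane_spacing(zscan: BeadZScan, *,
                               fit_window_um: float = 3.0,
                               max_fail_fraction: float = 0.5) -> dict:
    """Plane spacings and peak-amplitude variation from a bead z-scan.

    Per plane and bead, a Gaussian with constant baseline is fitted to
    intensity versus stage z inside ``fit_window_um`` of the trace maximum;
    the plane's peak position and amplitude are the medians over beads.
    Returns a dict with ``peak_positions_um``, ``peak_amplitudes``,
    ``spacings_um``, ``mean_spacing_um`` and ``variation_percent`` =
    (max - min) / mean of the plane peak amplitudes x 100.
    """
    z = np.asarray(zscan.stage_z, float)
    if len(z) >= 2 and np.max(np.diff(z)) > 0.5 + 1e-9:
        raise ValueError("z-scan step must be <= 0.5 um to resolve the planes")
    positions, amplitudes = [], []
    for p, traces in enumerate(zscan.intensities):
        mus, amps = [], []
        n_fail = 0
        for trace in traces:
            k = int(np.argmax(trace))
            sel = np.abs(z - z[k]) <= fit_window_um
            try:
                amp, mu, _sigma, _base = fit_gaussian_1d(z[sel], trace[sel],
                                                         window_fwhm=None)
            except (FitError, ValueError):
                n_fail += 1
                continue
            mus.append(mu)
            amps.append(amp)
        if len(traces) == 0 or n_fail > max_fail_fraction * len(traces):
            raise CalibrationError(
                f"Gaussian fits diverged for {n_fail}/{len(traces)} beads in "
                f"plane {p}")
        positions.append(float(np.median(mus)))
        amplitudes.append(float(np.median(amps)))
    positions = np.asarray(positions)
    amplitudes = np.asarray(amplitudes)
    spacings = np.diff(positions)
    return {
        "peak_positions_um": positions.tolist(),
        "peak_amplitudes": amplitudes.tolist(),
        "spacings_um": spacings.tolist(),
        "mean_spacing_um": float(spacings.mean()) if spacings.size else float("nan"),
        "variation_percent": float(
            (amplitudes.max() - amplitudes.min()) / amplitudes.mean() * 100.0),
    }


def measure_fwhm(profile_or_image: np.ndarray, *,
                 coords: np.ndarray | None = None,
                 pitch: float | None = None,
                 axis: str = "lateral",
                 method: str = "gaussian_fit") -> dict:
    """Full width at half maximum of a 1-D profile or a 2-D image cut.

    For a 2-D image the profile is the row (axis="lateral") or column
    (axis="axial") through the brightest pixel.  Coordinates come from
    ``coords`` (same length as the profile) or ``pitch`` (uniform spacing);
    the result is in those units.

    ``gaussian_fit`` returns 2*sqrt(2 ln 2)*sigma of a least-squares Gaussian
    with constant baseline, fitted within +-1.5 half-max widths of the peak;
    ``halfmax_interp`` linearly interpolates the half-maximum crossings.
    Returns ``{"fwhm": ..., "method": ...}``.
    """
    arr = np.asarray(profile_or_image, dtype=float)
    if arr.ndim == 2:
        r, c = np.unravel_index(np.argmax(arr), arr.shape)
        prof = arr[r, :] if axis == "lateral" else arr[:, c]
    elif arr.ndim == 1:
        prof = arr
    else:
        raise ValueError("expected a 1-D profile or 2-D image")
    if coords is None:
        if pitch is None:
            raise ValueError("provide coords or pitch")
        coords = np.arange(prof.size) * pitch
    coords = np.asarray(coords, float)
    if coords.shape != prof.shape:
        raise ValueError("coords must match the profile length")
    if method == "gaussian_fit":
        value = fwhm_gaussian(coords, prof)
    elif method == "halfmax_interp":
        value = fwhm_halfmax(coords, prof)
    else:
        raise ValueError("method must be 'gaussian_fit' or 'halfmax_interp'")
    return {"fwhm": float(value), "method": method}


# --------------------------------------------------------------------------
# projections and depth coding

def project(stack: np.ndarray, method: str = "AIP") -> np.ndarray:
    """Average (AIP) or maximum (MIP) intensity projection over axis 0."""
    stack = np.asarray(stack)
    if stack.size == 0 or stack.ndim < 3:
        raise ValueError("stack must be a nonempty (n, h, w) array")
    if method == "AIP":
        return stack.mean(axis=0)
    if method == "MIP":
        return stack.max(axis=0)
    raise ValueError("method must be 'AIP' or 'MIP'")


def grouped_aip(stack: np.ndarray, group: int = 16) -> np.ndarray:
    """Average intensity projections of consecutive ``group``-slice blocks."""
    stack = np.asarray(stack)
    if stack.shape[0] % group:
        raise ValueError(f"stack depth {stack.shape[0]} not divisible by {group}")
    return stack.reshape(-1, group, *stack.shape[1:]).mean(axis=1)


DEFAULT_DEPTH_PALETTE = (
    (0.10, 0.30, 1.00),   # Z0-4  blue
    (0.10, 0.85, 0.25),   # Z4-8  green
    (1.00, 0.60, 0.05),   # Z8-12 orange
    (0.95, 0.10, 0.10),   # Z12-16 red
)


def depth_code(aligned_planes: Sequence[np.ndarray],
               palette: Sequence[tuple[float, float, float]] | None = None, *,
               labels: Sequence[str] | None = None) -> tuple[np.ndarray, dict]:
    """Color-coded depth composite: additive blend of normalized planes.

    Each plane is normalized to its own maximum (planes that are all zero
    stay zero) and multiplied by its palette color; the blended RGB image is
    clipped to [0, 1].  Returns ``(rgb, legend)`` where the legend maps plane
    label to color.
    """
    planes = [np.asarray(p, float) for p in aligned_planes]
    palette = tuple(palette) if palette is not None else DEFAULT_DEPTH_PALETTE
    if len(palette) != len(planes):
        raise ValueError(
            f"palette size {len(palette)} != plane count {len(planes)}")
    if labels is None:
        labels = [f"plane{i}" for i in range(len(planes))]
    rgb = np.zeros(planes[0].shape + (3,), dtype=np.float64)
    for img, color in zip(planes, palette):
        peak = img.max()
        norm = img / peak if peak > 0 else img
        rgb += norm[..., None] * np.asarray(color)
    legend = {lab: tuple(col) for lab, col in zip(labels, palette)}
    return np.clip(rgb, 0.0, 1.0), legend


# --------------------------------------------------------------------------
# grid stitching

@dataclass(frozen=True)
class StitchThresholds:
    """Pairwise-link acceptance gates for grid stitching.

    ``regression_threshold`` is the minimum normalized cross-correlation of
    an overlap after applying the measured shift; the displacement gates
    bound how far a measured pair offset may deviate from nominal, absolutely
    and relative to the average deviation of the accepted pairs.
    """

    regression_threshold: float = 0.3
    max_avg_displacement: float = 2.5
    absolute_displacement: float = 8.0

    def __post_init__(self) -> None:
        if min(self.regression_threshold, self.max_avg_displacement,
               self.absolute_displacement) < 0:
            raise ValueError("stitch thresholds must be >= 0")


def _overlap_slices(pos_a, pos_b, shape):
    """Half-open row/col slices of the overlap of two tiles at given positions."""
    h, w = shape
    r0 = max(pos_a[0], pos_b[0])
    r1 = min(pos_a[0] + h, pos_b[0] + h)
    c0 = max(pos_a[1], pos_b[1])
    c1 = min(pos_a[1] + w, pos_b[1] + w)
    if r1 - r0 < 8 or c1 - c0 < 8:
        return None
    def rel(pos):
        return (slice(int(round(r0 - pos[0])), int(round(r1 - pos[0]))),
                slice(int(round(c0 - pos[1])), int(round(c1 - pos[1]))))
    return rel(pos_a), rel(pos_b)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def stitch_grid(tiles: Sequence[np.ndarray], nominal_positions: np.ndarray,
                thresholds: StitchThresholds = StitchThresholds(), *,
                upsample_factor: int = 20) -> tuple[np.ndarray, pd.DataFrame]:
    """Phase-correlation grid stitching with FIJI-style displacement gates.

    Overlapping neighbours (from the nominal layout) are registered pairwise
    by phase correlation; a pair is accepted when its post-shift overlap
    correlation reaches ``regression_threshold``, its deviation from the
    nominal offset is at most ``absolute_displacement`` px, and at most
    ``max_avg_displacement`` times the average deviation of accepted pairs.
    Rejected pairs fall back to their nominal offsets.  Global tile
    positions solve the pair-offset least-squares problem anchored at tile
    0; overlaps are fused with linear (feathered) blending.

    ``nominal_positions`` are (row, col) pixel positions, one per tile.
    Returns ``(mosaic, table)`` with per-tile nominal and stitched positions.
    """
    tiles = [np.asarray(t, float) for t in tiles]
    shape = tiles[0].shape
    if any(t.shape != shape for t in tiles):
        raise ValueError("all tiles must share one shape")
    nominal = np.asarray(nominal_positions, float)
    n = len(tiles)
    if n == 1:
        table = pd.DataFrame({"tile": [0], "nominal_row": nominal[0, 0],
                              "nominal_col": nominal[0, 1],
                              "stitched_row": nominal[0, 0],
                              "stitched_col": nominal[0, 1]})
        return tiles[0].copy(), table

    # pairwise measurements on overlapping neighbours
    max_shift = int(np.ceil(thresholds.absolute_displacement)) + 2
    pairs = []   # (i, j, d_meas (row, col), quality, deviation)
    for i in range(n):
        for j in range(i + 1, n):
            ov = _overlap_slices(nominal[i], nominal[j], shape)
            if ov is None:
                continue
            (sa, sb) = ov
            a, b = tiles[i][sa], tiles[j][sb]
            shift, quality = _pair_offset(a, b, max_shift, upsample_factor)
            d_nominal = nominal[j] - nominal[i]
            d_meas = d_nominal + shift
            deviation = float(np.hypot(*(d_meas - d_nominal)))
            pairs.append([i, j, d_meas, quality, deviation])

    accepted = [p for p in pairs
                if p[3] >= thresholds.regression_threshold
                and p[4] <= thresholds.absolute_displacement]
    if accepted:
        mean_dev = float(np.mean([p[4] for p in accepted]))
        if mean_dev > 0:
            accepted = [p for p in accepted
                        if p[4] <= thresholds.max_avg_displacement * mean_dev
                        or p[4] <= 0.5]
    # rejected pairs fall back to their nominal offsets, but only where needed
    # to keep the tile graph connected (otherwise they would drag well-linked
    # tiles toward the nominal layout)
    used = {(p[0], p[1]) for p in accepted}
    links = list(accepted)
    comp = _components(n, links)
    for p in sorted((p for p in pairs if (p[0], p[1]) not in used),
                    key=lambda p: -p[3]):
        if comp[p[0]] != comp[p[1]]:
            links.append([p[0], p[1], nominal[p[1]] - nominal[p[0]], p[3], p[4]])
            old, new = comp[p[1]], comp[p[0]]
            comp = [new if c == old else c for c in comp]

    positions = _solve_positions(n, links, nominal)

    mosaic = _blend(tiles, positions)
    table = pd.DataFrame({
        "tile": np.arange(n),
        "nominal_row": nominal[:, 0], "nominal_col": nominal[:, 1],
        "stitched_row": positions[:, 0], "stitched_col": positions[:, 1],
    })
    fallback = np.zeros(n, bool)
    for i, j, *_ in links[len(accepted):]:
        fallback[i] = fallback[j] = True
    table["had_fallback_link"] = fallback
    return mosaic, table


def _pair_offset(a: np.ndarray, b: np.ndarray, max_shift: int,
                 upsample_factor: int) -> tuple[np.ndarray, float]:
    """Translation of b's content relative to a within a shared overlap.

    Exhaustive integer search over +-``max_shift`` maximizing the normalized
    cross-correlation of the shifted overlap (robust for the narrow strips a
    tile grid produces, where circular phase correlation aliases), followed
    by sub-pixel phase-correlation refinement of the residual.  Returns
    ``(shift_rc, quality)`` where quality is the best integer-shift NCC.
    """
    q_map = np.full((2 * max_shift + 1,) * 2, -2.0)
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            a2, b2 = _shifted_overlap(a, b, (dr, dc))
            if a2 is None:
                continue
            q_map[dr + max_shift, dc + max_shift] = _ncc(a2, b2)
    kr, kc = np.unravel_index(np.argmax(q_map), q_map.shape)
    best = (kr - max_shift, kc - max_shift)
    best_q = float(q_map[kr, kc])

    def _parabolic(m1, c0, p1):
        denom = m1 - 2 * c0 + p1
        return 0.5 * (m1 - p1) / denom if denom < 0 else 0.0

    # sub-pixel refinement by parabolic interpolation of the NCC surface
    resid = np.zeros(2)
    if 0 < kr < q_map.shape[0] - 1 and q_map[kr - 1, kc] > -2 and q_map[kr + 1, kc] > -2:
        resid[0] = _parabolic(q_map[kr - 1, kc], q_map[kr, kc], q_map[kr + 1, kc])
    if 0 < kc < q_map.shape[1] - 1 and q_map[kr, kc - 1] > -2 and q_map[kr, kc + 1] > -2:
        resid[1] = _parabolic(q_map[kr, kc - 1], q_map[kr, kc], q_map[kr, kc + 1])
    # b sampled at +best aligns with a, so b's content is displaced by -best
    return -(np.asarray(best, float) + resid), best_q


def _shifted_overlap(a, b, int_shift):
    dr, dc = int_shift
    h, w = a.shape
    r0a, r1a = max(0, -dr), min(h, h - dr)
    c0a, c1a = max(0, -dc), min(w, w - dc)
    if r1a - r0a < 4 or c1a - c0a < 4:
        return None, None
    return a[r0a:r1a, c0a:c1a], b[r0a + dr:r1a + dr, c0a + dc:c1a + dc]


def _components(n: int, links) -> list[int]:
    """Component id per tile under the given links (smallest member's index)."""
    adj = {i: set() for i in range(n)}
    for i, j, *_ in links:
        adj[i].add(j)
        adj[j].add(i)
    comp_id = [-1] * n
    for s in range(n):
        if comp_id[s] >= 0:
            continue
        stack = [s]
        while stack:
            v = stack.pop()
            if comp_id[v] >= 0:
                continue
            comp_id[v] = s
            stack.extend(u for u in adj[v] if comp_id[u] < 0)
    return comp_id


def _solve_positions(n, links, nominal):
    """Least-squares positions from pairwise offsets, anchored at tile 0.

    If the link graph is disconnected, every extra component is anchored at
    its own nominal position and a warning is emitted.
    """
    ids = _components(n, links)
    components = [{i for i in range(n) if ids[i] == c} for c in sorted(set(ids))]
    if len(components) > 1:
        warnings.warn("stitch graph is disconnected; extra components are "
                      "placed at their nominal positions", stacklevel=2)

    rows = []
    rhs = []
    anchors = {min(c) for c in components}
    for i, j, d, *_ in links:
        row = np.zeros(n)
        row[j] += 1.0
        row[i] -= 1.0
        rows.append(row)
        rhs.append(d)
    for a in anchors:
        row = np.zeros(n)
        row[a] = 1.0
        rows.append(row)
        rhs.append(nominal[a])
    A = np.asarray(rows)
    b = np.asarray(rhs)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol


def _blend(tiles, positions):
    shape = tiles[0].shape
    h, w = shape
    r_min = positions[:, 0].min()
    c_min = positions[:, 1].min()
    pos = positions - (r_min, c_min)
    H = int(np.ceil(pos[:, 0].max() + h))
    W = int(np.ceil(pos[:, 1].max() + w))
    acc = np.zeros((H, W))
    wacc = np.zeros((H, W))
    wy = 1.0 - np.abs(np.linspace(-1, 1, h, endpoint=True)) * (1 - 1.0 / h)
    wx = 1.0 - np.abs(np.linspace(-1, 1, w, endpoint=True)) * (1 - 1.0 / w)
    weight = np.outer(wy, wx)
    for tile, (pr, pc) in zip(tiles, pos):
        ir, ic = int(np.floor(pr)), int(np.floor(pc))
        fr, fc = pr - ir, pc - ic
        shifted = ndimage.shift(tile, (fr, fc), order=1, mode="nearest") \
            if (fr or fc) else tile
        acc[ir:ir + h, ic:ic + w] += shifted * weight
        wacc[ir:ir + h, ic:ic + w] += weight
    with np.errstate(invalid="ignore"):
        out = np.where(wacc > 0, acc / np.maximum(wacc, 1e-12), 0.0)
    return out


# --------------------------------------------------------------------------
# filtering, chromatic shift, segmentation harness

def bilateral_filter(image: np.ndarray, sigma_spatial: float,
                     sigma_range: float) -> np.ndarray:
    """Edge-preserving bilateral filter (spatial Gaussian x range Gaussian).

    Implemented by explicit window shifts so the large-``sigma_range`` limit
    is exactly the truncated (3 sigma) Gaussian blur with the same spatial
    kernel.  Borders use reflection.
    """
    if sigma_spatial <= 0 or sigma_range <= 0:
        raise ValueError("sigmas must be > 0")
    img = np.asarray(image, dtype=np.float64)
    radius = int(np.ceil(3.0 * sigma_spatial))
    pad = np.pad(img, radius, mode="symmetric")
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    inv_2ss = 1.0 / (2.0 * sigma_spatial ** 2)
    inv_2sr = 1.0 / (2.0 * sigma_range ** 2)
    h, w = img.shape
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            ws = np.exp(-(dx * dx + dy * dy) * inv_2ss)
            shifted = pad[radius + dy:radius + dy + h, radius + dx:radius + dx + w]
            wr = np.exp(-((shifted - img) ** 2) * inv_2sr)
            num += ws * wr * shifted
            den += ws * wr
    return num / den


def measure_chromatic_shift(planes_ch0: Sequence[np.ndarray],
                            planes_ch1: Sequence[np.ndarray], *,
                            pixel_size: float = 0.108, gate_px: float = 5.0,
                            min_beads: int = 10) -> pd.DataFrame:
    """Median cross-channel bead displacement per plane.

    Beads are detected independently in both channels of each plane and
    matched by nearest neighbour; the per-plane result is the median
    displacement (channel 1 minus channel 0).  Columns: plane, dx_um, dy_um,
    dx_px, dy_px, n_beads.
    """
    rows = []
    for p, (im0, im1) in enumerate(zip(planes_ch0, planes_ch1)):
        d0 = detect_beads(np.asarray(im0, float))
        d1 = detect_beads(np.asarray(im1, float))
        if len(d0) < min_beads or len(d1) < min_beads:
            raise CalibrationError(
                f"plane {p}: only {len(d0)}/{len(d1)} beads detected "
                f"(need >= {min_beads})")
        tree = cKDTree(d0[["x_px", "y_px"]].to_numpy())
        pts = d1[["x_px", "y_px"]].to_numpy()
        dist, idx = tree.query(pts, distance_upper_bound=gate_px)
        ok = np.isfinite(dist)
        if ok.sum() < min_beads:
            raise CalibrationError(
                f"plane {p}: only {int(ok.sum())} matched beads")
        disp = pts[ok] - tree.data[idx[ok]]
        dx, dy = np.median(disp, axis=0)
        rows.append((p, dx * pixel_size, dy * pixel_size, dx, dy, int(ok.sum())))
    return pd.DataFrame(rows, columns=["plane", "dx_um", "dy_um",
                                       "dx_px", "dy_px", "n_beads"])


def segment_nuclei_classical(image: np.ndarray, *, sigma_spatial: float = 2.0,
                             sigma_range: float | None = None,
                             min_size_px: int = 200,
                             split_touching: bool = True,
                             peak_min_distance: int = 15) -> tuple[np.ndarray, int]:
    """Bilateral prefilter + Otsu + watershed nucleus segmentation.

    A deliberately classical pipeline used as a closed-loop counting harness:
    bilateral denoising, Otsu thresholding, small-object removal, and an
    optional distance-transform watershed to split touching nuclei.  Returns
    ``(labels, count)``.
    """
    img = np.asarray(image, dtype=np.float64)
    if sigma_range is None:
        span = float(img.max() - img.min())
        sigma_range = max(0.1 * span, 1e-6)
    smooth = bilateral_filter(img, sigma_spatial, sigma_range)
    if smooth.max() <= smooth.min():
        return np.zeros(img.shape, dtype=np.int32), 0
    mask = smooth > threshold_otsu(smooth)
    mask = remove_small_objects(mask, max_size=min_size_px)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32), 0
    if not split_touching:
        labels = cc_label(mask)
        return labels.astype(np.int32), int(labels.max())
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=peak_min_distance, labels=mask,
                           exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    if markers.max() == 0:
        labels = cc_label(mask)
        return labels.astype(np.int32), int(labels.max())
    labels = watershed(-dist, markers, mask=mask)
    return labels.astype(np.int32), int(labels.max())
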