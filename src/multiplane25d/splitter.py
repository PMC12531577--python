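"""Quad-plane image splitter: geometry and radiometry.

Two cascaded 50:50 beam splitters plus folding mirrors create four detection
paths with staggered optical path lengths, so four focal volumes — 4 um thick
slabs centered at z = 2, 6, 10 and 14 um, labelled Z0-4 ... Z12-16 — land on
the four quadrants of a single sensor.  Two of the four paths contain an odd
number of mirrors and arrive vertically flipped (row-axis reversal).  With
ideal lossless components each path carries exactly 25% of the emitted
signal.

Pixel rectangles use row-major sensor coordinates with the origin at the
top-left and half-open extents.  Quadrant shape follows the published
(width, height) = (870, 750) px convention; the corresponding field of view
is 93.96 x 81.0 um at 108 nm/px.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SplitterConfig",
    "default_quadplane_config",
    "path_transmission",
    "transmissions_from_splits",
    "plane_for_depth",
    "quadrant_geometry",
    "flip_image",
]


def _default_origins(sensor: tuple[int, int], quad_rc: tuple[int, int],
                     gap: int = 0) -> tuple[tuple[int, int], ...]:
    """Four quadrant origins at the sensor corners with an optional guard gap."""
    h, w = quad_rc
    rows, cols = sensor
    return (
        (gap, gap),
        (gap, cols - w - gap),
        (rows - h - gap, gap),
        (rows - h - gap, cols - w - gap),
    )


@dataclass(frozen=True)
class SplitterConfig:
    """Quad-plane geometry, per-path radiometry and injected misregistration.

    ``quadrant_shape_px`` is (width, height); ``sensor_shape_px`` and
    ``quadrant_origins_px`` are (rows, cols).  ``injected_misregistration``
    holds per-plane sub-pixel (dx, dy) shifts in pixels used by the forward
    model to emulate imperfect alignment.
    """

    plane_centers: tuple[float, ...] = (2.0, 6.0, 10.0, 14.0)
    plane_span: float = 4.0
    plane_labels: tuple[str, ...] = ("Z0-4", "Z4-8", "Z8-12", "Z12-16")
    path_transmissions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    flip_flags: tuple[bool, ...] = (False, False, True, True)
    quadrant_shape_px: tuple[int, int] = (870, 750)  # (width, height)
    sensor_shape_px: tuple[int, int] = (2048, 2048)  # (rows, cols)
    quadrant_origins_px: tuple[tuple[int, int], ...] | None = None
    injected_misregistration: tuple[tuple[float, float], ...] = (
        (0.0, 0.0), (0.0, 0.0), (0.0, 0.0), (0.0, 0.0))
    guard_gap_px: int = 0

    def __post_init__(self) -> None:
        n = len(self.plane_centers)
        if n < 1:
            raise ValueError("need at least one plane")
        if not (len(self.plane_labels) == len(self.path_transmissions)
                == len(self.flip_flags) == len(self.injected_misregistration) == n):
            raise ValueError("per-plane field lengths must all match plane_centers")
        if self.plane_span <= 0:
            raise ValueError("plane_span must be > 0")
        centers = np.asarray(self.plane_centers, float)
        if n > 1 and not np.allclose(np.diff(centers), self.plane_span, atol=1e-9):
            raise ValueError("plane centers must be evenly spaced by plane_span")
        t = np.asarray(self.path_transmissions, float)
        if np.any(t < 0) or t.sum() > 1.0 + 1e-9:
            raise ValueError("path transmissions must be >= 0 and sum to <= 1")
        if self.quadrant_origins_px is None:
            object.__setattr__(
                self, "quadrant_origins_px",
                _default_origins(self.sensor_shape_px, self.quadrant_shape_rc,
                                 self.guard_gap_px)[:n])
        if len(self.quadrant_origins_px) != n:
            raise ValueError("need one quadrant origin per plane")
        self._validate_rectangles()

    @property
    def n_planes(self) -> int:
        return len(self.plane_centers)

    @property
    def quadrant_shape_rc(self) -> tuple[int, int]:
        """Quadrant shape as (rows, cols)."""
        w, h = self.quadrant_shape_px
        return (h, w)

    def _validate_rectangles(self) -> None:
        h, w = self.quadrant_shape_rc
        rows, cols = self.sensor_shape_px
        rects = []
        for r0, c0 in self.quadrant_origins_px:
            if r0 < 0 or c0 < 0 or r0 + h > rows or c0 + w > cols:
                raise ValueError(
                    f"quadrant at ({r0}, {c0}) of shape ({h}, {w}) exceeds the "
                    f"{rows}x{cols} sensor")
            rects.append((r0, c0, r0 + h, c0 + w))
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                a, b = rects[i], rects[j]
                if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
                    raise ValueError(f"quadrant rectangles {i} and {j} overlap")

    def depth_interval(self, plane_index: int) -> tuple[float, float]:
        c = self.plane_centers[plane_index]
        return (c - self.plane_span / 2.0, c + self.plane_span / 2.0)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SplitterConfig":
        d = json.loads(s)
        for key in ("plane_centers", "plane_labels", "path_transmissions",
                    "flip_flags"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("quadrant_shape_px", "sensor_shape_px"):
            if key in d:
                d[key] = tuple(d[key])
        for key in ("quadrant_origins_px", "injected_misregistration"):
            if key in d and d[key] is not None:
                d[key] = tuple(tuple(v) for v in d[key])
        return cls(**d)

    def replace(self, **kw) -> "SplitterConfig":
        return replace(self, **kw)


def default_quadplane_config(**overrides) -> SplitterConfig:
    """The published quad-plane geometry with all defaults."""
    return SplitterConfig(**overrides)


def transmissions_from_splits(
        first: tuple[float, float] = (0.5, 0.5),
        second_a: tuple[float, float] = (0.5, 0.5),
        second_b: tuple[float, float] = (0.5, 0.5)) -> tuple[float, ...]:
    """Per-plane transmissions as products of the two cascaded splits.

    Plane order: (first[0]*second_a[0], first[0]*second_a[1],
    first[1]*second_b[0], first[1]*second_b[1]).  Each split's two fractions
    must sum to <= 1 (equality means a lossless component).
    """
    for name, s in (("first", first), ("second_a", second_a), ("second_b", second_b)):
        if min(s) < 0 or sum(s) > 1.0 + 1e-12:
            raise ValueError(f"{name} split fractions must be >= 0 and sum to <= 1")
    return (first[0] * second_a[0], first[0] * second_a[1],
            first[1] * second_b[0], first[1] * second_b[1])


def path_transmission(config: SplitterConfig, plane_index: int) -> float:
    """Fraction of emitted signal reaching the given quadrant (0.25 ideal)."""
    if not 0 <= plane_index < config.n_planes:
        raise IndexError(f"plane_index {plane_index} out of range 0..{config.n_planes - 1}")
    return config.path_transmissions[plane_index]


def plane_for_depth(config: SplitterConfig, z: float) -> int | None:
    """Index of the plane whose half-open [lo, hi) depth interval contains z."""
    for i in range(config.n_planes):
        lo, hi = config.depth_interval(i)
        if lo <= z < hi:
            return i
    return None


def quadrant_geometry(config: SplitterConfig) -> list[dict]:
    """Pixel rectangles and physical FOV for all quadrants.

    Each entry has ``label``, ``row``, ``col``, ``height``, ``width`` (half-open
    pixel extents) and ``fov_um`` = (width_um, height_um) at the configured
    pixel size is left to the caller; here FOV uses 0.108 um unless a pixel
    size is supplied via :func:`quadrant_fov`.
    """
    config._validate_rectangles()
    h, w = config.quadrant_shape_rc
    return [
        {"label": config.plane_labels[i], "row": r0, "col": c0,
         "height": h, "width": w}
        for i, (r0, c0) in enumerate(config.quadrant_origins_px)
    ]


def quadrant_fov(config: SplitterConfig, pixel_size_sample: float) -> tuple[float, float]:
    """Physical quadrant field of view (width_um, height_um)."""
    w, h = config.quadrant_shape_px
    return (w * pixel_size_sample, h * pixel_size_sample)


def flip_image(image: np.ndarray, flag: bool) -> np.ndarray:
    """Vertical flip = reversal of the row axis; an involution."""
    return image[::-1] if flag else image
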