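"""Flat-detector geometry and resolution-shell bookkeeping.

The whole package works in terms of the diffraction vector length
``h = 1/d = 2 sin(theta) / lambda`` (Å⁻¹).  A pixel at radial distance
``r`` (mm) from the beam centre on a flat, orthogonal detector at
distance ``D`` subtends ``2*theta = atan(r / D)``.

Conventions: pixel coordinates are 0-based ``(fast, slow)`` with pixel
centres at integer coordinates; no tilt, parallax or per-panel gaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class DetectorGeometry:
    """Sample-detector geometry mapping pixels to reciprocal space.

    Parameters
    ----------
    distance_mm : sample-to-detector distance.
    pixel_mm : edge length of a (square) pixel.
    beam_center : beam position in pixels, ``(fast, slow)``; fractional allowed.
    wavelength_A : X-ray wavelength in Å.
    n_fast, n_slow : detector dimensions in pixels.
    """

    distance_mm: float
    pixel_mm: float
    beam_center: tuple[float, float]
    wavelength_A: float
    n_fast: int
    n_slow: int

    def __post_init__(self) -> None:
        if self.distance_mm <= 0:
            raise ValueError("distance_mm must be > 0")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be > 0")
        if self.wavelength_A <= 0:
            raise ValueError("wavelength_A must be > 0")
        cx, cy = self.beam_center
        # loose bound: an off-detector beam centre is legitimate in practice
        if not (-self.n_fast <= cx <= 2 * self.n_fast) or not (
            -self.n_slow <= cy <= 2 * self.n_slow
        ):
            raise ValueError("beam_center implausibly far outside the detector")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "distance_mm": self.distance_mm,
            "pixel_mm": self.pixel_mm,
            "beam_center_px": list(self.beam_center),
            "wavelength_A": self.wavelength_A,
            "shape": [self.n_fast, self.n_slow],
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DetectorGeometry":
        doc = json.loads(Path(path).read_text())
        return cls(
            distance_mm=doc["distance_mm"],
            pixel_mm=doc["pixel_mm"],
            beam_center=tuple(doc["beam_center_px"]),
            wavelength_A=doc["wavelength_A"],
            n_fast=doc["shape"][0],
            n_slow=doc["shape"][1],
        )


def pixel_resolution(geom: DetectorGeometry, px, py):
    """Diffraction vector length h (Å⁻¹) of pixel(s) ``(px, py)``.

    ``h = 2 sin(theta)/lambda`` with ``2 theta = atan(r/D)``; h = 0 at the
    beam centre and strictly increasing with radial distance.  Accepts
    scalars or arrays.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    r_mm = geom.pixel_mm * np.hypot(px - geom.beam_center[0], py - geom.beam_center[1])
    two_theta = np.arctan2(r_mm, geom.distance_mm)
    h = 2.0 * np.sin(two_theta / 2.0) / geom.wavelength_A
    return h if h.ndim else float(h)


def resolution_map(geom: DetectorGeometry) -> np.ndarray:
    """h at every pixel centre, as an ``(n_slow, n_fast)`` array."""
    px, py = np.meshgrid(np.arange(geom.n_fast), np.arange(geom.n_slow))
    return pixel_resolution(geom, px, py)


def max_resolution(geom: DetectorGeometry) -> float:
    """Largest h reachable at any detector corner."""
    corners_x = [0, geom.n_fast - 1]
    corners_y = [0, geom.n_slow - 1]
    return max(pixel_resolution(geom, x, y) for x in corners_x for y in corners_y)


@dataclass(frozen=True)
class ShellBinning:
    """Partition of (0, h_max] into resolution shells.

    ``edges`` has ``n_shells + 1`` strictly increasing entries from 0 to
    h_max; ``volumes[i]`` is the reciprocal-space volume
    ``(4π/3)(h_out³ − h_in³)`` of shell i.
    """

    edges: np.ndarray
    volumes: np.ndarray

    @property
    def n_shells(self) -> int:
        return len(self.volumes)

    @property
    def h_max(self) -> float:
        return float(self.edges[-1])

    def shell_index(self, h) -> np.ndarray:
        """Shell index of each h; -1 for h = 0 or h > h_max."""
        h = np.asarray(h, dtype=float)
        idx = np.searchsorted(self.edges, h, side="left") - 1
        idx = np.where((h <= 0) | (h > self.h_max), -1, np.clip(idx, 0, self.n_shells - 1))
        return idx

    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def make_shells(
    geom: DetectorGeometry,
    n_shells: int,
    d_min: float,
    policy: str = "volume",
) -> ShellBinning:
    """Build ``n_shells`` resolution shells out to ``d_min``.

    ``policy='volume'`` (default) makes shells of equal reciprocal volume
    (equal increments in h³), so the per-shell volume weights are uniform;
    ``policy='h'`` makes shells equal in h.
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    h_max = 1.0 / d_min
    h_edge = max_resolution(geom)
    if h_max > h_edge:
        raise ValueError(
            f"d_min={d_min} Å not reachable: detector corner reaches only "
            f"{1.0 / h_edge:.3f} Å"
        )
    if policy == "volume":
        edges = np.cbrt(np.linspace(0.0, h_max**3, n_shells + 1))
    elif policy == "h":
        edges = np.linspace(0.0, h_max, n_shells + 1)
    else:
        raise ValueError(f"unknown shell policy {policy!r}")
    volumes = (4.0 * np.pi / 3.0) * np.diff(edges**3)
    return ShellBinning(edges=edges, volumes=volumes)
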