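"""Seeded simulation of diffraction frames and whole mesh-scan stacks.

Each frame is a Poisson background with a smooth radial profile plus
Bragg spots rendered as 2-D Gaussians whose integrated intensities
follow the average-protein Wilson curve attenuated by ``exp(-2 B s²)``
and drawn from an exponential (acentric Wilson) distribution.  Optional
extras emulate the common nuisances of real mesh scans: sharp ice rings
and sparse, very strong salt spots with a flat resolution profile.

Spots are placed at random pixels, not on a consistent lattice: the
scoring stage never indexes, so lattice geometry is irrelevant to it.
There is no Ewald-sphere, mosaicity or detector-gap model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .detector import DetectorGeometry, pixel_resolution, resolution_map
from .wilson import standard_wilson_curve

__all__ = [
    "Frame",
    "FrameRecipe",
    "MeshSampleRecipe",
    "standard_wilson_curve",
    "render_frame",
    "render_mesh",
    "write_frame",
    "read_frame",
    "write_mesh",
    "read_mesh",
]


@dataclass
class Frame:
    """A 2-D count raster tied to a detector geometry.

    ``data`` is float64 ``(n_slow, n_fast)``; quantisation to 16-bit
    happens only on file output.
    """

    data: np.ndarray
    geom: DetectorGeometry


@dataclass(frozen=True)
class FrameRecipe:
    """Generative parameters for one simulated frame.

    background_level : Poisson mean (counts/pixel) at the beam centre.
    background_falloff : radial decay constant; mean background at
        diffraction vector length h is ``background_level * exp(-falloff h²)``.
    n_spots : number of Bragg spots to place.
    spot_scale : overall scale (counts) of spot integrated intensities.
    wilson_B : Debye–Waller B (Å²) of the simulated crystal.
    spot_sigma_px : Gaussian width of rendered spots.
    ice_rings : d-spacings (Å) at which to add sharp powder rings.
    salt_spots : number of very strong, resolution-flat salt spots.
    """

    background_level: float = 50.0
    background_falloff: float = 8.0
    n_spots: int = 0
    spot_scale: float = 1000.0
    wilson_B: float = 30.0
    spot_sigma_px: float = 1.5
    ice_rings: tuple[float, ...] = ()
    ice_strength: float = 60.0
    ice_width_px: float = 2.0
    salt_spots: int = 0
    salt_scale: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.n_spots < 0 or self.salt_spots < 0:
            raise ValueError("spot counts must be >= 0")
        if self.wilson_B < 0:
            raise ValueError("wilson_B must be >= 0")


# default ice rings of hexagonal ice, strongest first (d in Å)
ICE_RING_D = (3.90, 3.67, 3.44, 2.67, 2.25)


def _splat_gaussians(canvas, xs, ys, totals, sigma):
    """Add 2-D Gaussians of given integrated intensity to ``canvas`` in place.

    Returns the number of spots skipped because their window missed the
    detector entirely.
    """
    n_slow, n_fast = canvas.shape
    half = max(2, int(np.ceil(4.0 * sigma)))
    skipped = 0
    for x0, y0, total in zip(xs, ys, totals):
        ix, iy = int(round(x0)), int(round(y0))
        x_lo, x_hi = max(0, ix - half), min(n_fast, ix + half + 1)
        y_lo, y_hi = max(0, iy - half), min(n_slow, iy + half + 1)
        if x_lo >= x_hi or y_lo >= y_hi:
            skipped += 1
            continue
        gx = np.arange(x_lo, x_hi)
        gy = np.arange(y_lo, y_hi)
        wx = np.exp(-0.5 * ((gx - x0) / sigma) ** 2)
        wy = np.exp(-0.5 * ((gy - y0) / sigma) ** 2)
        prof = np.outer(wy, wx)
        prof *= total / (2.0 * np.pi * sigma**2)
        canvas[y_lo:y_hi, x_lo:x_hi] += prof
    return skipped


def render_frame(recipe: FrameRecipe, geom: DetectorGeometry) -> Frame:
    """Render one frame; bit-identical for identical recipe and seed.

    The Poisson background and the spot placement use independent child
    streams of the recipe seed, so changing ``spot_scale`` rescales the
    spot flux without re-rolling positions or intensity deviates.
    """
    ss = np.random.SeedSequence(recipe.seed)
    bg_rng, spot_rng, salt_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    hmap = resolution_map(geom)
    lam = recipe.background_level * np.exp(-recipe.background_falloff * hmap**2)

    # sharp ice rings: narrow radial Gaussian annuli of excess mean counts
    if recipe.ice_rings:
        # convert the ring width from pixels to h at the ring radius
        for d in recipe.ice_rings:
            h_ring = 1.0 / d
            dh = _h_per_pixel(geom, h_ring) * recipe.ice_width_px
            lam = lam + recipe.ice_strength * np.exp(
                -0.5 * ((hmap - h_ring) / dh) ** 2
            )

    canvas = bg_rng.poisson(lam).astype(float)

    if recipe.n_spots > 0:
        xs = spot_rng.uniform(0, geom.n_fast - 1, recipe.n_spots)
        ys = spot_rng.uniform(0, geom.n_slow - 1, recipe.n_spots)
        dev = spot_rng.exponential(1.0, recipe.n_spots)  # acentric Wilson stats
        h = pixel_resolution(geom, xs, ys)
        s = h / 2.0
        totals = (
            recipe.spot_scale
            * standard_wilson_curve(h)
            * np.exp(-2.0 * recipe.wilson_B * s**2)
            * dev
        )
        _splat_gaussians(canvas, xs, ys, totals, recipe.spot_sigma_px)

    if recipe.salt_spots > 0:
        scale = recipe.salt_scale if recipe.salt_scale is not None else 20.0 * recipe.spot_scale
        xs = salt_rng.uniform(0, geom.n_fast - 1, recipe.salt_spots)
        ys = salt_rng.uniform(0, geom.n_slow - 1, recipe.salt_spots)
        dev = salt_rng.exponential(1.0, recipe.salt_spots)
        # salt: no Wilson shape, no B attenuation, sharper profile
        _splat_gaussians(canvas, xs, ys, scale * dev, max(0.8, recipe.spot_sigma_px / 2))

    return Frame(data=canvas, geom=geom)


def _h_per_pixel(geom: DetectorGeometry, h: float) -> float:
    """Local dh per pixel step at diffraction vector length h."""
    theta = np.arcsin(np.clip(h * geom.wavelength_A / 2.0, 0, 1))
    r_mm = geom.distance_mm * np.tan(2.0 * theta)
    r_px = max(r_mm / geom.pixel_mm, 1.0)
    h1 = pixel_resolution(geom, geom.beam_center[0] + r_px + 1.0, geom.beam_center[1])
    h0 = pixel_resolution(geom, geom.beam_center[0] + r_px, geom.beam_center[1])
    return max(h1 - h0, 1e-9)


@dataclass
class MeshSampleRecipe:
    """A simulated sample holder: grid of positions, some holding crystals.

    ``crystal_mask`` is boolean ``(n_y, n_x)``; ``cluster_labels`` assigns an
    isomorphism-class label to each crystal position (used downstream when
    partial datasets are simulated per position).  ``overrides`` replaces
    the base crystal recipe at specific ``(iy, ix)`` positions.
    """

    grid: tuple[int, int]  # (n_x, n_y)
    crystal_mask: np.ndarray
    crystal_recipe: FrameRecipe = field(default_factory=lambda: FrameRecipe(n_spots=150))
    empty_recipe: FrameRecipe | None = None
    overrides: dict[tuple[int, int], FrameRecipe] = field(default_factory=dict)
    cluster_labels: dict[tuple[int, int], int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        n_x, n_y = self.grid
        self.crystal_mask = np.asarray(self.crystal_mask, dtype=bool)
        if self.crystal_mask.shape != (n_y, n_x):
            raise ValueError("crystal_mask shape must be (n_y, n_x)")


def _position_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % 2**31)


def render_mesh(
    sample: MeshSampleRecipe, geom: DetectorGeometry
) -> tuple[list[Frame], np.ndarray]:
    """Render one frame per grid point, row-major raster order.

    Raster order matches the heat-map axes: x runs along the fast
    (horizontal translation) axis, rows along y.  Returns the frame stack
    and the ground-truth crystal mask.
    """
    n_x, n_y = sample.grid
    empty = sample.empty_recipe or replace(
        sample.crystal_recipe, n_spots=0, salt_spots=0, ice_rings=()
    )
    stack: list[Frame] = []
    for iy in range(n_y):
        for ix in range(n_x):
            idx = iy * n_x + ix
            if sample.crystal_mask[iy, ix]:
                base = sample.overrides.get((iy, ix), sample.crystal_recipe)
            else:
                base = sample.overrides.get((iy, ix), empty)
            recipe = replace(base, seed=_position_seed(sample.seed, idx))
            stack.append(render_frame(recipe, geom))
    return stack, sample.crystal_mask.copy()


# ---------------------------------------------------------------------------
# file I/O: 16-bit grayscale TIFF + JSON sidecars


def write_frame(frame: Frame, path: str | Path) -> None:
    """Write as 16-bit TIFF (counts clipped to [0, 65535]) + geometry sidecar."""
    path = Path(path)
    data = np.clip(np.rint(frame.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    frame.geom.to_json(path.with_suffix(".json"))


def read_frame(path: str | Path) -> Frame:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    geom = DetectorGeometry.from_json(path.with_suffix(".json"))
    return Frame(data=data, geom=geom)


def write_mesh(
    stack: list[Frame], mask: np.ndarray, grid: tuple[int, int],
    out_dir: str | Path, seed: int = 0,
) -> None:
    """Write frame_0000.tif ... plus a manifest with grid shape and truth mask."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack):
        write_frame(frame, out_dir / f"frame_{i:04d}.tif")
    manifest = {
        "grid": list(grid),
        "seed": seed,
        "crystal_mask": np.asarray(mask, dtype=bool).tolist(),
        "n_frames": len(stack),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")


def read_mesh(in_dir: str | Path) -> tuple[list[Frame], dict]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    stack = [
        read_frame(in_dir / f"frame_{i:04d}.tif") for i in range(manifest["n_frames"])
    ]
    return stack, manifest
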