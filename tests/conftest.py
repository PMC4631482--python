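import numpy as np
import pytest

from meshmx.detector import DetectorGeometry, make_shells
from meshmx.frames import FrameRecipe, render_frame
from meshmx.scoring import ScoringParams


@pytest.fixture(scope="session")
def geom256():
    """Small flat detector reaching ~2.4 Å at the corner at 1 Å wavelength."""
    return DetectorGeometry(
        distance_mm=80.0, pixel_mm=0.3, beam_center=(127.5, 127.5),
        wavelength_A=1.0, n_fast=256, n_slow=256,
    )


@pytest.fixture(scope="session")
def shells20(geom256):
    return make_shells(geom256, 20, 3.0)


@pytest.fixture(scope="session")
def dense_params():
    """Scoring knobs for the densely spotted simulated frames used in tests:
    the component-size cap is lifted because overlapping Gaussian spots merge
    into large blobs that are still genuine Bragg signal."""
    return ScoringParams(max_spot_pixels=2000)


@pytest.fixture(scope="session")
def protein_recipe():
    """A strongly diffracting protein-like frame recipe."""
    return FrameRecipe(
        background_level=20.0, n_spots=1000, spot_scale=2.0e5,
        wilson_B=25.0, spot_sigma_px=1.0, seed=7,
    )


@pytest.fixture(scope="session")
def protein_frame(protein_recipe, geom256):
    return render_frame(protein_recipe, geom256)


def naive_average_linkage(dist: np.ndarray) -> list[float]:
    """O(n³) UPGMA agglomeration oracle; returns the sorted merge heights."""
    dist = dist.astype(float).copy()
    np.fill_diagonal(dist, np.inf)
    clusters = {i: [i] for i in range(dist.shape[0])}
    d = {frozenset((i, j)): dist[i, j]
         for i in range(dist.shape[0]) for j in range(i + 1, dist.shape[0])}
    heights = []
    next_id = dist.shape[0]
    while len(clusters) > 1:
        (a, b), h = min(
            ((pair, v) for pair, v in d.items()
             if all(k in clusters for k in pair)),
            key=lambda kv: kv[1],
        )
        pair = sorted((a, b))
        a, b = pair
        heights.append(h)
        merged = clusters[a] + clusters[b]
        na, nb = len(clusters[a]), len(clusters[b])
        del clusters[a], clusters[b]
        for c in list(clusters):
            dc = (na * d[frozenset((a, c))] + nb * d[frozenset((b, c))]) / (na + nb)
            d[frozenset((next_id, c))] = dc
        clusters[next_id] = merged
        next_id += 1
    return sorted(heights)
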