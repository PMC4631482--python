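"""Mesh-scan orchestration: heat maps, position ranking, end-to-end runs.

A mesh scan rasters the sample holder through the beam, one low-dose
frame per grid point.  Scoring every frame gives a heat map; positions
scoring above a contrast threshold are ranked and scheduled for partial
data collection (by default a 10° wedge of 100 images, i.e. ±5° around
the mesh orientation at 0.1°/image).  ``run_pipeline`` drives the whole
simulated workflow: mesh → score → select → simulate one partial dataset
per position → indexing-ambiguity resolution → correlation clustering →
merge of the main cluster → quality report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clustering, merging, scoring
from .detector import DetectorGeometry, make_shells
from .frames import FrameRecipe, MeshSampleRecipe, render_mesh
from .reflections import (
    WedgeParams,
    generate_ground_truth,
    preset_setting,
    simulate_partial_dataset,
)

__all__ = [
    "HeatMap",
    "CollectionPlan",
    "PipelineConfig",
    "grid_dimensions",
    "build_heat_map",
    "select_positions",
    "run_pipeline",
    "crystal_volume",
]


def grid_dimensions(area_w_um: float, area_h_um: float, beam_um: float) -> tuple[int, int]:
    """Mesh points per axis: ceiling of area over beam size."""
    if area_w_um <= 0 or area_h_um <= 0 or beam_um <= 0:
        raise ValueError("areas and beam size must be > 0")
    return math.ceil(area_w_um / beam_um), math.ceil(area_h_um / beam_um)


def crystal_volume(dims_um: tuple[float, float, float]) -> float:
    """Approximate crystal volume (µm³) from its average box dimensions."""
    a, b, c = dims_um
    return float(a * b * c)


@dataclass
class HeatMap:
    """Per-grid-point diffraction scores, x along the horizontal translation."""

    scores: np.ndarray           # (n_y, n_x), >= 0
    beam_um: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.scores, delimiter=",", fmt="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "HeatMap":
        return cls(scores=np.atleast_2d(np.loadtxt(path, delimiter=",")), **kw)


@dataclass
class WedgeSpec:
    total_range_deg: float = 10.0    # i.e. ±5° about the mesh orientation
    n_images: int = 100

    @property
    def oscillation_deg(self) -> float:
        return self.total_range_deg / self.n_images


@dataclass
class CollectionPlan:
    """Ranked collection positions with the wedge specification."""

    positions: list[tuple[int, int, float]]   # (x, y, score), score-descending
    wedge: WedgeSpec = field(default_factory=WedgeSpec)


def build_heat_map(stack_scores, grid: tuple[int, int], beam_um: float = 10.0) -> HeatMap:
    """Arrange per-frame scores (row-major raster order) into the mesh grid."""
    n_x, n_y = grid
    scores = np.asarray(stack_scores, dtype=float)
    if scores.size != n_x * n_y:
        raise ValueError(f"got {scores.size} scores for a {n_x}x{n_y} grid")
    return HeatMap(scores=scores.reshape(n_y, n_x), beam_um=beam_um)


def select_positions(
    heat_map: HeatMap, threshold: float = 0.0, max_positions: int | None = None,
    wedge: WedgeSpec | None = None,
) -> CollectionPlan:
    """Positions scoring above the contrast threshold, best first.

    Ties are broken by raster order.  ``max_positions`` optionally caps
    the list (the headless stand-in for interactive point picking).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n_y, n_x = heat_map.scores.shape
    entries = [
        (int(ix), int(iy), float(heat_map.scores[iy, ix]))
        for iy in range(n_y)
        for ix in range(n_x)
        if heat_map.scores[iy, ix] > threshold
    ]
    entries.sort(key=lambda e: (-e[2], e[1] * n_x + e[0]))
    if max_positions is not None:
        entries = entries[:max_positions]
    return CollectionPlan(positions=entries, wedge=wedge or WedgeSpec())


@dataclass
class PipelineConfig:
    """Study conditions of one simulated mesh-and-collect run."""

    grid: tuple[int, int] = (6, 5)
    n_crystals: int = 8
    n_outliers: int = 2               # crystals in the minority (non-isomorphous) class
    # frame simulation / scoring
    detector: DetectorGeometry = field(
        default_factory=lambda: DetectorGeometry(
            distance_mm=60.0, pixel_mm=0.3, beam_center=(63.5, 63.5),
            wavelength_A=1.0, n_fast=128, n_slow=128,
        )
    )
    frame_recipe: FrameRecipe = field(
        default_factory=lambda: FrameRecipe(
            background_level=20.0, n_spots=250, spot_scale=6.0e4,
            wilson_B=25.0, spot_sigma_px=1.0,
        )
    )
    scoring_params: scoring.ScoringParams = field(
        default_factory=lambda: scoring.ScoringParams(max_spot_pixels=400)
    )
    n_shells: int = 12
    d_min_frames: float = 3.0
    threshold: float = 0.0
    max_positions: int | None = None
    # reflection simulation / clustering / merging
    symmetry: str = "P4"
    d_min_reflections: float = 2.5
    fraction: float = 0.35
    noise_frac: float = 0.05
    class_shift: float = 0.35
    scale_spread: float = 0.2         # per-set k drawn log-uniform within ±spread
    b_rel_max: float = 4.0            # per-set relative B uniform in [0, max]
    ambiguity_fraction: float = 0.0   # fraction of sets planted with a flipped indexing
    cutoff: float = 0.15
    min_common: int = 30


def _derive_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % 2**31)


def run_pipeline(config: PipelineConfig, seed: int = 0) -> dict:
    """Run the full simulated workflow; deterministic for a fixed seed.

    Returns a JSON-serialisable report: heat map, collection plan,
    pairwise correlations, dendrogram (Newick), selected cluster, scaling
    model and merging statistics.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    n_x, n_y = config.grid

    # ---- plant crystals on the grid
    n_cells = n_x * n_y
    n_crystals = min(config.n_crystals, n_cells)
    cells = rng.choice(n_cells, size=n_crystals, replace=False)
    mask = np.zeros((n_y, n_x), dtype=bool)
    labels: dict[tuple[int, int], int] = {}
    for rank, cell in enumerate(sorted(cells.tolist())):
        iy, ix = divmod(cell, n_x)
        mask[iy, ix] = True
        labels[(iy, ix)] = 1 if rank >= n_crystals - config.n_outliers else 0

    sample = MeshSampleRecipe(
        grid=config.grid, crystal_mask=mask, crystal_recipe=config.frame_recipe,
        cluster_labels=labels, seed=_derive_seed(seed, 11),
    )

    # ---- mesh scan + scoring
    stack, _ = render_mesh(sample, config.detector)
    shells = make_shells(config.detector, config.n_shells, config.d_min_frames)
    results = [scoring.score_frame(f, shells, config.scoring_params) for f in stack]
    heat = build_heat_map([r.score for r in results], config.grid)
    plan = select_positions(heat, config.threshold, config.max_positions)

    report: dict = {
        "seed": seed,
        "grid": list(config.grid),
        "heat_map": np.round(heat.scores, 6).tolist(),
        "crystal_mask": mask.tolist(),
        "plan": {
            "positions": [[x, y, round(s, 6)] for x, y, s in plan.positions],
            "total_range_deg": plan.wedge.total_range_deg,
            "n_images": plan.wedge.n_images,
            "oscillation_deg": plan.wedge.oscillation_deg,
        },
    }
    if not plan.positions:
        report["merge"] = None
        return report

    # ---- one partial dataset per selected position
    setting = preset_setting(config.symmetry)
    truth = generate_ground_truth(
        setting, config.d_min_reflections, seed=_derive_seed(seed, 23)
    )
    sets = []
    planted_flips = []
    for rank, (x, y, _score) in enumerate(plan.positions):
        class_id = labels.get((y, x), 0)
        set_rng = np.random.default_rng(np.random.SeedSequence([seed, 31, rank]))
        flip = (
            bool(setting.ambiguity_ops)
            and rank > 0
            and set_rng.uniform() < config.ambiguity_fraction
        )
        planted_flips.append(flip)
        params = WedgeParams(
            fraction=config.fraction,
            scale_k=float(np.exp(set_rng.uniform(-config.scale_spread, config.scale_spread))),
            b_rel=float(set_rng.uniform(0.0, config.b_rel_max)),
            noise_frac=config.noise_frac,
            class_shift=config.class_shift if class_id != 0 else 0.0,
            class_id=class_id,
            reindex_op=setting.ambiguity_ops[0] if flip else None,
            seed=_derive_seed(seed, 41, rank),
        )
        sets.append(simulate_partial_dataset(truth, params, label=f"pos_{x}_{y}"))

    # ---- indexing resolution, clustering, merging
    sets, reindex_report = clustering.resolve_indexing(sets, setting, config.min_common)
    if len(sets) >= 2:
        ccm = clustering.pairwise_cc(sets, config.min_common)
        dist = clustering.cc_to_distance(ccm.cc)
        dend = clustering.hca(dist, labels=ccm.labels)
        sel = clustering.cut(dend, config.cutoff, dist=dist)
        main_idx = sel.main_cluster
        report["cc_matrix"] = np.round(np.where(np.isfinite(ccm.cc), ccm.cc, -2), 6).tolist()
        report["dendrogram_newick"] = dend.to_newick()
        report["main_cluster"] = [sets[i].label for i in main_idx]
        report["cluster_membership"] = sel.membership.tolist()
    else:
        main_idx = [0]
        report["main_cluster"] = [sets[0].label]
    report["reindexing"] = [
        {"label": s.label, "op_index": r["op_index"], "flagged": r["flagged"]}
        for s, r in zip(sets, reindex_report)
    ]

    chosen = [sets[i] for i in main_idx]
    scales = merging.fit_scales(chosen, reference=0, min_common=config.min_common)
    merged = merging.merge(chosen, scales)
    stats = merging.compute_stats(merged, n_possible=len(truth.hkl),
                                  cc_seed=_derive_seed(seed, 53))
    report["merge"] = {
        "n_sets_merged": len(chosen),
        "scales_k": [round(k, 6) if np.isfinite(k) else None for k in scales.scale_k],
        "b_rel": [round(b, 6) if np.isfinite(b) else None for b in scales.b_rel],
        "completeness": round(stats.completeness, 4),
        "multiplicity": round(stats.multiplicity, 4),
        "r_merge": round(stats.r_merge, 6) if stats.r_merge is not None else None,
        "r_pim": round(stats.r_pim, 6) if stats.r_pim is not None else None,
        "cc_half": round(stats.cc_half, 6) if stats.cc_half is not None else None,
        "mean_i_over_sigma": round(stats.mean_i_over_sigma, 4),
        "n_unique": stats.n_unique,
        "n_obs": stats.n_obs,
    }
    if setting.ambiguity_ops:
        twin = merging.h_test(merged, setting.ambiguity_ops[0])
        report["h_test"] = (
            {"mean_h": round(twin.mean_h, 6), "alpha": round(twin.alpha, 6),
             "n_pairs": twin.n_pairs}
            if twin is not None else None
        )
    return report


def report_to_json(report: dict) -> str:
    """Canonical JSON rendering (sorted keys) for byte-stable comparison."""
    return json.dumps(report, sort_keys=True, indent=1)
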