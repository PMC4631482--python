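"""Per-frame diffraction scoring.

The score of a frame is built in five steps:

1. a one-dimensional radial background function B(h) from iterative
   azimuthal averaging with sigma-clipping of outliers;
2. rejection of resolution shells where B(h) has a sharp peak — the
   signature of ice rings or salt powder diffraction;
3. Bragg-spot detection by Poisson thresholding and connected-component
   analysis with simple geometric plausibility checks;
4. the mean background-subtracted spot intensity per shell, Ī(h), fitted
   against the average-protein Wilson curve attenuated by an isotropic
   Debye–Waller factor, ``Ī(h) ≈ k · Σ_p(h) · exp(-2 B s²)`` with
   ``s = h/2``; the fit quality is CC_powder, the Pearson correlation
   between log Ī(h) and the fitted model;
5. score = max(CC_powder, 0) × Σ Ī(h)·V(h) over unflagged, spot-bearing
   shells, where V(h) is the reciprocal volume of the shell.  A frame
   with no accepted spots scores exactly zero.

CC_powder gates the score: strong but resolution-flat diffraction (salt)
correlates poorly with the protein curve and is suppressed even when no
explicit ring is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .detector import ShellBinning, pixel_resolution, resolution_map
from .frames import Frame
from .wilson import standard_wilson_curve

__all__ = [
    "ScoringParams",
    "BackgroundCurve",
    "Spot",
    "WilsonFit",
    "FrameScore",
    "estimate_background",
    "flag_sharp_rings",
    "find_spots",
    "mean_spot_intensity",
    "fit_wilson",
    "diffraction_score",
    "score_frame",
]


@dataclass(frozen=True)
class ScoringParams:
    """Tunable knobs of the scoring pipeline (all dimensionless or in px)."""

    k_reject: float = 3.0          # sigma-clip threshold in background estimation
    max_iter: int = 10
    min_shell_pixels: int = 50     # below this a shell is unusable
    ring_factor: float = 1.5       # B(h) > factor * smoothed B(h) flags a ring
    ring_window: int = 5           # moving-median window (shells)
    k_spot: float = 4.0            # spot threshold in Poisson sigmas
    min_spot_pixels: int = 2
    max_spot_pixels: int = 100
    ecc_max: float = 0.95


@dataclass
class BackgroundCurve:
    """Radial background B(h) with per-shell usability and ring flags."""

    shells: ShellBinning
    b_of_h: np.ndarray            # counts/pixel; NaN where unusable
    usable: np.ndarray            # bool per shell
    flagged: np.ndarray           # bool per shell: sharp ring, excluded downstream
    flag_reason: dict[int, str] = field(default_factory=dict)

    def good(self) -> np.ndarray:
        return self.usable & ~self.flagged


@dataclass
class Spot:
    """One accepted Bragg spot (8-connected pixel component)."""

    centroid: tuple[float, float]      # (fast, slow) px
    pixel_count: int
    integrated_intensity: float        # counts above background
    shell_index: int
    eccentricity: float
    pixels: np.ndarray = field(repr=False, default=None)  # (n, 2) [slow, fast]


@dataclass
class WilsonFit:
    scale_k: float
    b_iso: float                       # Å²
    cc_powder: float
    mean_spot_intensity: np.ndarray    # Ī(h) per shell, NaN where absent
    h_of_shell: np.ndarray             # abscissa used per shell


@dataclass
class FrameScore:
    """Scoring result for one frame; ``score == 0`` iff no accepted spots
    or the Wilson correlation is non-positive/absent."""

    score: float
    background: BackgroundCurve
    spots: list[Spot]
    fit: WilsonFit | None


def estimate_background(
    frame: Frame, shells: ShellBinning, params: ScoringParams = ScoringParams()
) -> BackgroundCurve:
    """Robust per-shell mean background by iterative sigma-clipping.

    Within each shell, pixels above ``mean + k_reject * sd`` are rejected
    and the mean recomputed until the rejection set is stable (or
    ``max_iter``).  Shells with fewer than ``min_shell_pixels`` pixels are
    marked unusable.
    """
    hmap = resolution_map(frame.geom)
    idx = shells.shell_index(hmap)
    n = shells.n_shells
    b = np.full(n, np.nan)
    usable = np.zeros(n, dtype=bool)
    flat = frame.data.ravel()
    flat_idx = idx.ravel()
    order = np.argsort(flat_idx, kind="stable")
    sorted_idx = flat_idx[order]
    bounds = np.searchsorted(sorted_idx, np.arange(-1, n + 1))
    for i in range(n):
        vals = flat[order[bounds[i + 1] : bounds[i + 2]]]
        if vals.size < params.min_shell_pixels:
            continue
        keep = np.ones(vals.size, dtype=bool)
        for _ in range(params.max_iter):
            m = vals[keep].mean()
            sd = vals[keep].std()
            new_keep = vals <= m + params.k_reject * sd
            if np.array_equal(new_keep, keep):
                break
            keep = new_keep
            if keep.sum() < params.min_shell_pixels:
                break
        if keep.sum() >= params.min_shell_pixels:
            b[i] = vals[keep].mean()
            usable[i] = True
    return BackgroundCurve(
        shells=shells, b_of_h=b, usable=usable, flagged=np.zeros(n, dtype=bool)
    )


def _moving_median(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def flag_sharp_rings(
    curve: BackgroundCurve, params: ScoringParams = ScoringParams()
) -> BackgroundCurve:
    """Flag shells whose background sticks out above a moving-median smooth.

    A sharp peak in B(h) indicates an ice ring or salt powder ring; the
    flagged shells are excluded from spot acceptance, the Wilson fit and
    the score.  Idempotent: flags are recomputed from the same B(h).
    """
    good = curve.usable
    if good.sum() < 5:
        return curve
    b = curve.b_of_h.copy()
    smooth = np.full_like(b, np.nan)
    smooth[good] = _moving_median(b[good], params.ring_window)
    flagged = np.zeros_like(curve.flagged)
    with np.errstate(invalid="ignore"):
        flagged[good] = b[good] > params.ring_factor * smooth[good]
    reasons = {int(i): "sharp ring (ice/salt)" for i in np.nonzero(flagged)[0]}
    return replace(curve, flagged=flagged, flag_reason=reasons)


def find_spots(
    frame: Frame, curve: BackgroundCurve, params: ScoringParams = ScoringParams()
) -> list[Spot]:
    """Detect Bragg spots above the local Poisson noise floor.

    Pixels exceeding ``B(h) + k_spot * sqrt(B(h))`` are grouped into
    8-connected components; components are accepted if their size lies in
    ``[min_spot_pixels, max_spot_pixels]``, their eccentricity is at most
    ``ecc_max`` (rejects streaks and panel artefacts) and their centroid
    is not on a flagged or unusable shell.
    """
    hmap = resolution_map(frame.geom)
    idx = curve.shells.shell_index(hmap)
    b_px = np.full(hmap.shape, np.inf)
    good = curve.usable
    valid = (idx >= 0) & good[np.clip(idx, 0, None)]
    b_px[valid] = curve.b_of_h[idx[valid]]
    # sqrt floor of 1 keeps the threshold meaningful on near-zero background
    thresh = b_px + params.k_spot * np.sqrt(np.maximum(b_px, 1.0))
    mask = frame.data > thresh
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    spots: list[Spot] = []
    if n_lab == 0:
        return spots
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        ys, xs = np.nonzero(labels[sl] == lab)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        npx = len(ys)
        if npx < params.min_spot_pixels or npx > params.max_spot_pixels:
            continue
        vals = frame.data[ys, xs] - curve.b_of_h[idx[ys, xs]]
        total = float(vals.sum())
        if total <= 0:
            continue
        cy = float(np.average(ys, weights=np.maximum(vals, 1e-12)))
        cx = float(np.average(xs, weights=np.maximum(vals, 1e-12)))
        ecc = _eccentricity(xs, ys)
        if ecc > params.ecc_max:
            continue
        si = int(curve.shells.shell_index(_h_at(frame, cx, cy)))
        if si < 0 or not curve.usable[si] or curve.flagged[si]:
            continue
        spots.append(
            Spot(
                centroid=(cx, cy),
                pixel_count=npx,
                integrated_intensity=total,
                shell_index=si,
                eccentricity=ecc,
                pixels=np.column_stack([ys, xs]),
            )
        )
    return spots


def _h_at(frame: Frame, cx: float, cy: float) -> float:
    return pixel_resolution(frame.geom, cx, cy)


def _eccentricity(xs: np.ndarray, ys: np.ndarray) -> float:
    """Eccentricity of the pixel cloud from its second moments (0 = round)."""
    if len(xs) < 3:
        return 1.0
    cov = np.cov(np.vstack([xs, ys]).astype(float))
    evals = np.linalg.eigvalsh(cov)
    lam_min, lam_max = max(evals[0], 0.0), max(evals[1], 0.0)
    if lam_max <= 0:
        return 0.0
    return float(np.sqrt(1.0 - lam_min / lam_max))


def mean_spot_intensity(
    frame: Frame, spots: list[Spot], curve: BackgroundCurve, dilate_px: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Mean Bragg intensity per detector pixel and shell, Ī(h).

    Ī(h) = (Σ over spot pixels of (I - B)) / N(h), with N(h) the number of
    detector pixels in shell h: the background-subtracted Bragg flux
    averaged over the whole shell, not just the thresholded pixels.
    (Averaging over thresholded pixels only would bias the curve: the
    above-threshold area of a Gaussian spot grows with the log of its
    total, flattening the apparent resolution falloff.)  The spot mask is
    dilated ``dilate_px`` pixels before summation to pick up the
    sub-threshold tails of weak spots.

    Shells without spot pixels (or flagged/unusable) get NaN.  Also
    returns the flux-weighted mean h of the spot pixels per shell, used
    as the fit abscissa.
    """
    shells = curve.shells
    hmap = resolution_map(frame.geom)
    idx = shells.shell_index(hmap)
    n = shells.n_shells

    mask = np.zeros(frame.data.shape, dtype=bool)
    for spot in spots:
        mask[spot.pixels[:, 0], spot.pixels[:, 1]] = True
    if dilate_px > 0:
        mask = ndimage.binary_dilation(
            mask, structure=np.ones((3, 3), bool), iterations=dilate_px
        )

    good_shell = curve.usable & ~curve.flagged
    valid = (idx >= 0) & good_shell[np.clip(idx, 0, None)]
    n_px = np.bincount(idx[valid], minlength=n)

    spot_sel = mask & valid
    si = idx[spot_sel]
    vals = frame.data[spot_sel] - curve.b_of_h[si]
    sums = np.bincount(si, weights=vals, minlength=n)
    spot_counts = np.bincount(si, minlength=n)
    h_sums = np.bincount(si, weights=hmap[spot_sel] * np.maximum(vals, 0), minlength=n)
    w_sums = np.bincount(si, weights=np.maximum(vals, 0), minlength=n)

    ibar = np.full(n, np.nan)
    h_of = shells.centers().copy()
    has = (spot_counts > 0) & (n_px > 0)
    ibar[has] = sums[has] / n_px[has]
    hw = has & (w_sums > 0)
    h_of[hw] = h_sums[hw] / w_sums[hw]
    return ibar, h_of


def fit_wilson(
    ibar: np.ndarray, h_of_shell: np.ndarray, std_curve=standard_wilson_curve
) -> WilsonFit | None:
    """Fit Ī(h) = k · Σ_p(h) · exp(-2 B s²) by linear least squares in logs.

    With y = log Ī − log Σ_p, the model is y = log k − 2 B s², linear in
    (log k, B).  CC_powder is the Pearson correlation between observed
    log Ī and the fitted model over the shells used.  Returns None when
    fewer than 4 shells carry a positive Ī.
    """
    use = np.isfinite(ibar) & (ibar > 0)
    if use.sum() < 4:
        return None
    h = h_of_shell[use]
    s2 = (h / 2.0) ** 2
    y = np.log(ibar[use]) - np.log(std_curve(h))
    A = np.column_stack([np.ones_like(s2), -2.0 * s2])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    log_k, b_iso = coef
    model = A @ coef + np.log(std_curve(h))
    obs = np.log(ibar[use])
    if np.std(obs) == 0 or np.std(model) == 0:
        cc = 1.0 if np.allclose(obs, model) else 0.0
    else:
        cc = float(np.corrcoef(obs, model)[0, 1])
    return WilsonFit(
        scale_k=float(np.exp(log_k)),
        b_iso=float(b_iso),
        cc_powder=cc,
        mean_spot_intensity=ibar.copy(),
        h_of_shell=h_of_shell.copy(),
    )


def diffraction_score(
    ibar: np.ndarray, curve: BackgroundCurve, fit: WilsonFit | None, has_spots: bool
) -> float:
    """score = max(CC_powder, 0) × Σ Ī(h)·V(h) over good, spot-bearing shells.

    Zero when no spots were accepted or the fit is absent/anticorrelated.
    """
    if not has_spots or fit is None:
        return 0.0
    cc = max(fit.cc_powder, 0.0)
    good = curve.good() & np.isfinite(ibar)
    total = float(np.nansum(ibar[good] * curve.shells.volumes[good]))
    return cc * max(total, 0.0)


def score_frame(
    frame: Frame, shells: ShellBinning, params: ScoringParams = ScoringParams()
) -> FrameScore:
    """Run the full scoring pipeline on one frame."""
    curve = estimate_background(frame, shells, params)
    curve = flag_sharp_rings(curve, params)
    spots = find_spots(frame, curve, params)
    if not spots:
        return FrameScore(score=0.0, background=curve, spots=[], fit=None)
    ibar, h_of = mean_spot_intensity(frame, spots, curve)
    fit = fit_wilson(ibar, h_of)
    score = diffraction_score(ibar, curve, fit, has_spots=True)
    return FrameScore(score=score, background=curve, spots=spots, fit=fit)
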