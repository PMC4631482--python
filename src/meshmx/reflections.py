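"""Reflection sets: symmetry, ASU reduction, simulation and file I/O.

A reflection set is a list of (h, k, l, I, σ) records under a unit cell
and a point-group operator list.  Only the point-group families relevant
to the workflow are shipped, as explicit operator lists (no general
space-group machinery): triclinic P1, monoclinic point group 2,
tetragonal point group 4, trigonal H3 and hexagonal P6 — the last three
with their merohedral indexing-ambiguity operators.

The partial-dataset simulator is the statistical test bed for the
clustering and merging stages: it draws a random subset of the unique
reflections of a seeded ground truth, applies a per-crystal linear scale
and relative B factor, Gaussian measurement noise, an optional
per-class non-isomorphism perturbation, and an optional alternative
indexing.  Wedge sampling is index-random rather than rotation-geometric:
the downstream statistics only need the overlap structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .wilson import standard_wilson_curve

__all__ = [
    "SymmetrySetting",
    "ReflectionSet",
    "GroundTruth",
    "WedgeParams",
    "preset_setting",
    "reduce_to_asu",
    "reduce_array_to_asu",
    "generate_ground_truth",
    "simulate_partial_dataset",
    "read_reflections",
    "write_reflections",
]

_I = np.eye(3, dtype=int)


def _ops_p2() -> list[np.ndarray]:
    return [_I, np.diag([-1, 1, -1])]


def _ops_p4() -> list[np.ndarray]:
    r4 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]])  # (h,k,l) -> (-k,h,l)
    return [_I, r4, r4 @ r4, r4 @ r4 @ r4]


def _ops_p3() -> list[np.ndarray]:
    # threefold about c in the hexagonal basis: (h,k,l) -> (k, -h-k, l)
    r3 = np.array([[0, 1, 0], [-1, -1, 0], [0, 0, 1]])
    return [_I, r3, r3 @ r3]


def _ops_p6() -> list[np.ndarray]:
    # sixfold about c: (h,k,l) -> (h+k, -h, l)
    r6 = np.array([[1, 1, 0], [-1, 0, 0], [0, 0, 1]])
    ops = [_I]
    m = _I
    for _ in range(5):
        m = m @ r6
        ops.append(m)
    return ops


# twofold perpendicular to c relating the two indexing choices in the
# merohedral tetragonal/trigonal/hexagonal cases: (h,k,l) -> (k,h,-l)
_SWAP_OP = np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]])

_PRESETS: dict[str, dict] = {
    "P1": dict(sg_number=1, ops=lambda: [_I], ambiguity=[],
               cell=(30.0, 40.0, 50.0, 85.0, 95.0, 100.0)),
    "P2": dict(sg_number=3, ops=_ops_p2, ambiguity=[],
               cell=(30.0, 40.0, 50.0, 90.0, 100.0, 90.0)),
    "P4": dict(sg_number=75, ops=_ops_p4, ambiguity=[_SWAP_OP],
               cell=(50.0, 50.0, 60.0, 90.0, 90.0, 90.0)),
    "H3": dict(sg_number=146, ops=_ops_p3, ambiguity=[_SWAP_OP],
               cell=(60.0, 60.0, 90.0, 90.0, 90.0, 120.0)),
    "P6": dict(sg_number=168, ops=_ops_p6, ambiguity=[_SWAP_OP],
               cell=(60.0, 60.0, 80.0, 90.0, 90.0, 120.0)),
}

_SG_TO_PRESET = {v["sg_number"]: k for k, v in _PRESETS.items()}


@dataclass(frozen=True)
class SymmetrySetting:
    """Unit cell plus explicit point-group and ambiguity operators."""

    name: str
    cell: tuple[float, float, float, float, float, float]  # a b c alpha beta gamma
    operators: tuple  # of 3x3 int ndarrays
    friedel: bool = True
    ambiguity_ops: tuple = ()
    sg_number: int = 1

    def __post_init__(self) -> None:
        ops = [np.asarray(m, dtype=int) for m in self.operators]
        keys = {m.tobytes() for m in ops}
        if _I.tobytes() not in keys:
            raise ValueError("operator list must contain the identity")
        for a in ops:
            for b in ops:
                if (a @ b).tobytes() not in keys:
                    raise ValueError("operator list not closed under composition")

    def reciprocal_metric(self) -> np.ndarray:
        a, b, c, al, be, ga = self.cell
        al, be, ga = np.radians([al, be, ga])
        g = np.array(
            [
                [a * a, a * b * np.cos(ga), a * c * np.cos(be)],
                [a * b * np.cos(ga), b * b, b * c * np.cos(al)],
                [a * c * np.cos(be), b * c * np.cos(al), c * c],
            ]
        )
        return np.linalg.inv(g)

    def d_spacing(self, hkl) -> np.ndarray:
        """Resolution d (Å) of Miller indices, general triclinic form."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        inv_d2 = np.einsum("ni,ij,nj->n", hkl, self.reciprocal_metric(), hkl)
        d = 1.0 / np.sqrt(inv_d2)
        return d if len(d) > 1 else float(d[0])


def preset_setting(name: str, cell=None, friedel: bool = True) -> SymmetrySetting:
    """One of the shipped symmetry families: P1, P2, P4, H3, P6."""
    if name not in _PRESETS:
        raise KeyError(f"unknown symmetry preset {name!r}; have {sorted(_PRESETS)}")
    p = _PRESETS[name]
    return SymmetrySetting(
        name=name,
        cell=tuple(cell) if cell is not None else p["cell"],
        operators=tuple(p["ops"]() if callable(p["ops"]) else p["ops"]),
        friedel=friedel,
        ambiguity_ops=tuple(p["ambiguity"]),
        sg_number=p["sg_number"],
    )


def reduce_to_asu(hkl, setting: SymmetrySetting) -> tuple[int, int, int]:
    """Canonical (lexicographically greatest) symmetry image of one index."""
    return tuple(reduce_array_to_asu(np.asarray(hkl, dtype=int).reshape(1, 3), setting)[0])


def reduce_array_to_asu(hkl: np.ndarray, setting: SymmetrySetting) -> np.ndarray:
    """Vectorised ASU reduction: lexicographic max over the full orbit.

    With Friedel symmetry on, the orbit includes the negated images, so
    (h,k,l) and (-h,-k,-l) always reduce identically.
    """
    hkl = np.asarray(hkl, dtype=int)
    images = [hkl @ np.asarray(op, dtype=int).T for op in setting.operators]
    if setting.friedel:
        images.extend([-im for im in images])
    stack = np.stack(images, axis=1)  # (n, n_ops, 3)
    # lexicographic argmax over (h, then k, then l)
    span = 1 + 2 * int(np.abs(stack).max(initial=1))
    rank = (stack[..., 0] * span + stack[..., 1]) * span + stack[..., 2]
    best = np.argmax(rank, axis=1)
    return stack[np.arange(len(hkl)), best]


@dataclass
class GroundTruth:
    """True intensities of every ASU-unique reflection out to d_min."""

    setting: SymmetrySetting
    d_min: float
    b_true: float
    seed: int
    hkl: np.ndarray          # (n, 3) int, ASU representatives, lexicographic order
    intensity: np.ndarray    # (n,) > 0

    def as_dict(self) -> dict[tuple[int, int, int], float]:
        return {tuple(r): float(i) for r, i in zip(self.hkl, self.intensity)}


def _enumerate_unique(setting: SymmetrySetting, d_min: float) -> np.ndarray:
    a, b, c = setting.cell[:3]
    hmax = int(np.ceil(a / d_min))
    kmax = int(np.ceil(b / d_min))
    lmax = int(np.ceil(c / d_min))
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = np.asarray(setting.d_spacing(hkl))
    hkl = hkl[d >= d_min]
    asu = reduce_array_to_asu(hkl, setting)
    uniq = np.unique(asu, axis=0)
    # lexicographic order (h, then k, then l), descending for a stable layout
    order = np.lexsort((uniq[:, 2], uniq[:, 1], uniq[:, 0]))
    return uniq[order]


def generate_ground_truth(
    setting: SymmetrySetting, d_min: float, b_true: float = 20.0, seed: int = 0
) -> GroundTruth:
    """Draw a seeded 'crystal': exponential intensities on the Wilson curve.

    Each unique reflection gets I ~ Exponential with mean proportional to
    ``Σ_p(h) · exp(-2 B_true s²)`` — acentric Wilson statistics on the
    average-protein curve.
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    uniq = _enumerate_unique(setting, d_min)
    d = np.asarray(setting.d_spacing(uniq))
    h = 1.0 / d
    s2 = (h / 2.0) ** 2
    mean = 1000.0 * standard_wilson_curve(h) * np.exp(-2.0 * b_true * s2)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    intensity = rng.exponential(mean)
    intensity = np.maximum(intensity, 1e-6 * mean.max())
    return GroundTruth(
        setting=setting, d_min=d_min, b_true=b_true, seed=seed,
        hkl=uniq, intensity=intensity,
    )


@dataclass
class ReflectionSet:
    """(h,k,l,I,σ) records under one symmetry setting.

    ``label`` identifies the source position; ``true_class`` carries the
    planted isomorphism class when the set is simulated.
    """

    hkl: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    setting: SymmetrySetting
    label: str = ""
    true_class: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("all sigmas must be > 0")

    def __len__(self) -> int:
        return len(self.intensity)

    def merged_by_unique(self) -> dict[tuple[int, int, int], tuple[float, float]]:
        """ASU-reduce and merge duplicates by inverse-variance weighted mean."""
        asu = reduce_array_to_asu(self.hkl, self.setting)
        out: dict[tuple[int, int, int], list] = {}
        for idx, i_obs, sig in zip(map(tuple, asu), self.intensity, self.sigma):
            out.setdefault(idx, []).append((i_obs, sig))
        merged = {}
        for idx, obs in out.items():
            w = np.array([1.0 / s**2 for _, s in obs])
            i_vals = np.array([i for i, _ in obs])
            merged[idx] = (float((w * i_vals).sum() / w.sum()), float(np.sqrt(1.0 / w.sum())))
        return merged


@dataclass(frozen=True)
class WedgeParams:
    """Generative parameters of one simulated partial dataset."""

    fraction: float = 0.35      # fraction of ASU uniques observed in the wedge
    scale_k: float = 1.0
    b_rel: float = 0.0          # Å², relative B vs the ground truth
    noise_frac: float = 0.08    # sd of the Gaussian noise as a fraction of I_true
    class_shift: float = 0.0    # non-isomorphism amplitude
    class_id: int = 0
    reindex_op: np.ndarray | None = None
    seed: int = 0


def _class_field(truth: GroundTruth, class_id: int) -> np.ndarray:
    """Fixed unit-variance perturbation field shared by a crystal class."""
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 7919, class_id]))
    return rng.standard_normal(len(truth.hkl))


def simulate_partial_dataset(
    truth: GroundTruth, params: WedgeParams, label: str = ""
) -> ReflectionSet:
    """One partial-wedge dataset drawn from the ground truth.

    I_obs = scale_k · exp(-2 b_rel s²) · I_true·(1 + class_shift·δ) + ε,
    with δ the per-class seeded perturbation field and
    ε ~ N(0, noise_frac·I_true).  Negative observations are kept; σ is
    noise_frac·I_true floored at 1% of the median true intensity.
    """
    if not (0 < params.fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(truth.hkl)
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 211]))
    n_take = max(1, int(round(params.fraction * n)))
    take = np.sort(rng.choice(n, size=n_take, replace=False))

    hkl = truth.hkl[take]
    i_true = truth.intensity[take]
    d = np.asarray(truth.setting.d_spacing(hkl))
    s2 = (0.5 / d) ** 2

    i_mod = i_true.copy()
    if params.class_shift != 0.0:
        delta = _class_field(truth, params.class_id)[take]
        i_mod = i_true * np.maximum(1.0 + params.class_shift * delta, 0.01)

    attn = params.scale_k * np.exp(-2.0 * params.b_rel * s2)
    eps = rng.normal(0.0, 1.0, n_take) * params.noise_frac * i_true
    i_obs = attn * i_mod + eps

    floor = 0.01 * float(np.median(truth.intensity))
    sigma = np.maximum(params.noise_frac * i_true, floor)

    if params.reindex_op is not None:
        hkl = hkl @ np.asarray(params.reindex_op, dtype=int).T
        hkl = reduce_array_to_asu(hkl, truth.setting)

    return ReflectionSet(
        hkl=hkl, intensity=i_obs, sigma=sigma, setting=truth.setting,
        label=label, true_class=params.class_id,
        meta={"params": params},
    )


# ---------------------------------------------------------------------------
# text I/O in an XDS-ASCII-style dialect


def write_reflections(rset: ReflectionSet, path: str | Path) -> None:
    """Write '!'-headed text: symmetry header then H K L IOBS SIGMA rows."""
    cell = " ".join(f"{v:10.4f}" for v in rset.setting.cell)
    lines = [
        "!FORMAT=XDS_ASCII    MERGE=FALSE    FRIEDEL'S_LAW="
        + ("TRUE" if rset.setting.friedel else "FALSE"),
        f"!SPACE_GROUP_NUMBER= {rset.setting.sg_number}",
        f"!UNIT_CELL_CONSTANTS= {cell}",
        "!WAVELENGTH= 1.0000",
        f"!DATA_SET_LABEL= {rset.label}" if rset.label else "!DATA_SET_LABEL= unnamed",
        "!NUMBER_OF_ITEMS_IN_EACH_DATA_RECORD=5",
        "!ITEM_H=1",
        "!ITEM_K=2",
        "!ITEM_L=3",
        "!ITEM_IOBS=4",
        "!ITEM_SIGMA(IOBS)=5",
        "!END_OF_HEADER",
    ]
    for (h, k, l), i_obs, sig in zip(rset.hkl, rset.intensity, rset.sigma):
        lines.append(f"{h:6d}{k:6d}{l:6d} {i_obs:14.6g} {sig:12.6g}")
    lines.append("!END_OF_DATA")
    Path(path).write_text("\n".join(lines) + "\n")


class ReflectionFileError(ValueError):
    pass


def read_reflections(path: str | Path) -> ReflectionSet:
    """Parse the dialect written by :func:`write_reflections`.

    Malformed header values or data rows raise with the line number; rows
    with σ ≤ 0 are rejected the same way.
    """
    path = Path(path)
    sg = None
    cell = None
    friedel = True
    label = ""
    rows: list[tuple[int, int, int, float, float]] = []
    in_data = False
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("!"):
            if "FRIEDEL'S_LAW=" in line:
                friedel = "FRIEDEL'S_LAW=TRUE" in line.replace(" ", "")
            elif line.startswith("!SPACE_GROUP_NUMBER="):
                sg = int(line.split("=", 1)[1])
            elif line.startswith("!UNIT_CELL_CONSTANTS="):
                vals = [float(v) for v in line.split("=", 1)[1].split()]
                if len(vals) != 6:
                    raise ReflectionFileError(f"{path}:{ln}: need 6 cell constants")
                cell = tuple(vals)
            elif line.startswith("!DATA_SET_LABEL="):
                label = line.split("=", 1)[1].strip()
            elif line.startswith("!END_OF_HEADER"):
                in_data = True
            elif line.startswith("!END_OF_DATA"):
                in_data = False
            continue
        if not in_data:
            raise ReflectionFileError(f"{path}:{ln}: data row before !END_OF_HEADER")
        parts = line.split()
        if len(parts) != 5:
            raise ReflectionFileError(f"{path}:{ln}: expected 5 columns, got {len(parts)}")
        try:
            h, k, l = (int(p) for p in parts[:3])
            i_obs, sig = float(parts[3]), float(parts[4])
        except ValueError as exc:
            raise ReflectionFileError(f"{path}:{ln}: unparsable row: {exc}") from exc
        if sig <= 0:
            raise ReflectionFileError(f"{path}:{ln}: sigma must be > 0 (got {sig})")
        rows.append((h, k, l, i_obs, sig))
    if sg is None or cell is None:
        raise ReflectionFileError(f"{path}: missing space group or cell in header")
    if sg not in _SG_TO_PRESET:
        raise ReflectionFileError(
            f"{path}: space group {sg} not among shipped presets {_SG_TO_PRESET}"
        )
    setting = preset_setting(_SG_TO_PRESET[sg], cell=cell, friedel=friedel)
    arr = np.array(rows, dtype=float) if rows else np.empty((0, 5))
    return ReflectionSet(
        hkl=arr[:, :3].astype(int), intensity=arr[:, 3], sigma=arr[:, 4],
        setting=setting, label=label,
    )
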