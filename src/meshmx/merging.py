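"""Relative scaling, merging and quality statistics for partial datasets.

Selected partial datasets are put on a common scale (per-set linear
scale k and relative isotropic B against a reference set), observations
are corrected by ``k · exp(-2 b_rel s²)`` and combined per unique
reflection by inverse-variance weighted mean.  Quality is summarised by
the standard multi-crystal merging statistics — completeness,
multiplicity, R_merge, the precision-indicating R_pim, the random-half
correlation CC_1/2 and mean I/σ — plus the twin-fraction estimate of the
intensity-ratio H-test and the Crick–Magdoff-style theoretical anomalous
diffraction ratio used to judge phasing feasibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reflections import ReflectionSet, reduce_array_to_asu, reduce_to_asu

__all__ = [
    "ScaleModel",
    "MergedDataset",
    "MergeStats",
    "TwinEstimate",
    "fit_scales",
    "merge",
    "compute_stats",
    "h_test",
    "anomalous_ratio",
]


@dataclass
class ScaleModel:
    """Per-set (k, b_rel) relative to the reference set (k=1, b=0)."""

    scale_k: list[float]
    b_rel: list[float]
    reference: int = 0
    dropped: list[int] = field(default_factory=list)


@dataclass
class MergedDataset:
    """Per-unique merged intensities with propagated sigmas."""

    hkl: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    n_obs: np.ndarray
    observations: dict[tuple[int, int, int], list[tuple[float, float]]]
    setting: object = None

    def as_dict(self) -> dict[tuple[int, int, int], tuple[float, float, int]]:
        return {
            tuple(r): (float(i), float(s), int(n))
            for r, i, s, n in zip(self.hkl, self.intensity, self.sigma, self.n_obs)
        }


@dataclass
class MergeStats:
    completeness: float          # percent of the reachable unique set
    multiplicity: float
    r_merge: float | None
    r_pim: float | None
    cc_half: float | None
    mean_i_over_sigma: float
    n_unique: int
    n_obs: int


@dataclass
class TwinEstimate:
    mean_h: float
    alpha: float                 # estimated twin fraction in [0, 0.5]
    n_pairs: int


def _s2(setting, hkl: np.ndarray) -> np.ndarray:
    d = np.asarray(setting.d_spacing(hkl))
    return (0.5 / d) ** 2


def fit_scales(
    sets: list[ReflectionSet], reference: int = 0, min_common: int = 30
) -> ScaleModel:
    """Weighted least-squares relative scaling against one reference set.

    Per set the model is ``log I_set = log k - 2 b_rel s² + log I_ref``
    over common uniques with positive intensities on both sides, with
    weights proportional to (I/σ)² of the set's observations.  Sets with
    fewer than ``min_common`` usable commons are dropped.
    """
    ref_merged = sets[reference].merged_by_unique()
    ks: list[float] = []
    bs: list[float] = []
    dropped: list[int] = []
    for i, s in enumerate(sets):
        if i == reference:
            ks.append(1.0)
            bs.append(0.0)
            continue
        merged = s.merged_by_unique()
        common = [k for k in merged.keys() & ref_merged.keys()
                  if merged[k][0] > 0 and ref_merged[k][0] > 0]
        if len(common) < min_common:
            dropped.append(i)
            ks.append(np.nan)
            bs.append(np.nan)
            continue
        hkl = np.array(common)
        s2 = _s2(s.setting, hkl)
        i_set = np.array([merged[k][0] for k in common])
        sig_set = np.array([merged[k][1] for k in common])
        i_ref = np.array([ref_merged[k][0] for k in common])
        y = np.log(i_set) - np.log(i_ref)
        w = (i_set / sig_set) ** 2
        A = np.column_stack([np.ones_like(s2), -2.0 * s2])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
        ks.append(float(np.exp(coef[0])))
        bs.append(float(coef[1]))
    return ScaleModel(scale_k=ks, b_rel=bs, reference=reference, dropped=dropped)


def merge(sets: list[ReflectionSet], scales: ScaleModel | None = None) -> MergedDataset:
    """Scale-correct every observation and merge per unique reflection.

    Correction divides each observation (and its σ) by the set's
    ``k · exp(-2 b_rel s²)``; merging is the inverse-variance weighted
    mean with ``σ_merged = sqrt(1/Σw)``.
    """
    if scales is None:
        scales = ScaleModel(scale_k=[1.0] * len(sets), b_rel=[0.0] * len(sets))
    obs: dict[tuple[int, int, int], list[tuple[float, float]]] = {}
    setting = sets[0].setting
    for s, k, b in zip(sets, scales.scale_k, scales.b_rel):
        if not np.isfinite(k):
            continue
        asu = reduce_array_to_asu(s.hkl, s.setting)
        corr = k * np.exp(-2.0 * b * _s2(s.setting, s.hkl))
        i_corr = s.intensity / corr
        sig_corr = s.sigma / corr
        for idx, i_c, s_c in zip(map(tuple, asu), i_corr, sig_corr):
            obs.setdefault(idx, []).append((float(i_c), float(s_c)))
    keys = sorted(obs.keys())
    hkl = np.array(keys, dtype=int).reshape(-1, 3)
    i_m = np.empty(len(keys))
    s_m = np.empty(len(keys))
    n_m = np.empty(len(keys), dtype=int)
    for j, key in enumerate(keys):
        vals = obs[key]
        w = np.array([1.0 / sg**2 for _, sg in vals])
        ii = np.array([iv for iv, _ in vals])
        i_m[j] = (w * ii).sum() / w.sum()
        s_m[j] = np.sqrt(1.0 / w.sum())
        n_m[j] = len(vals)
    return MergedDataset(hkl=hkl, intensity=i_m, sigma=s_m, n_obs=n_m,
                         observations=obs, setting=setting)


def compute_stats(
    merged: MergedDataset, n_possible: int, cc_seed: int = 0, n_splits: int = 10
) -> MergeStats:
    """Standard merging statistics against a reachable-unique count.

    R_merge = ΣΣ|I_i - Ī| / ΣΣ I_i over all multiply-observed uniques;
    R_pim additionally weights each unique by sqrt(1/(n-1)).  CC_1/2 is
    the Pearson correlation of two random half-averages per unique,
    averaged over ``n_splits`` seeded splits.
    """
    n_unique = len(merged.hkl)
    n_obs = int(merged.n_obs.sum())
    completeness = 100.0 * n_unique / n_possible if n_possible else 0.0
    multiplicity = n_obs / n_unique if n_unique else 0.0
    mean_ios = float(np.mean(merged.intensity / merged.sigma)) if n_unique else 0.0

    multi = {k: v for k, v in merged.observations.items() if len(v) >= 2}
    r_merge = r_pim = cc_half = None
    if multi:
        num_m = num_p = den = 0.0
        for vals in multi.values():
            ii = np.array([iv for iv, _ in vals])
            dev = np.abs(ii - ii.mean()).sum()
            num_m += dev
            num_p += np.sqrt(1.0 / (len(ii) - 1)) * dev
            den += ii.sum()
        if den > 0:
            r_merge = float(num_m / den)
            r_pim = float(num_p / den)
        ccs = []
        ss = np.random.SeedSequence([cc_seed, 977])
        for child in ss.spawn(n_splits):
            rng = np.random.default_rng(child)
            h1, h2 = [], []
            for vals in multi.values():
                ii = np.array([iv for iv, _ in vals])
                perm = rng.permutation(len(ii))
                half = len(ii) // 2
                if half == 0:
                    continue
                a = ii[perm[:half]].mean()
                b = ii[perm[half:]].mean()
                h1.append(a)
                h2.append(b)
            if len(h1) >= 2 and np.std(h1) > 0 and np.std(h2) > 0:
                ccs.append(np.corrcoef(h1, h2)[0, 1])
        if ccs:
            cc_half = float(np.mean(ccs))
    return MergeStats(
        completeness=completeness, multiplicity=multiplicity,
        r_merge=r_merge, r_pim=r_pim, cc_half=cc_half,
        mean_i_over_sigma=mean_ios, n_unique=n_unique, n_obs=n_obs,
    )


def h_test(
    merged: MergedDataset, twin_op: np.ndarray, min_pairs: int = 50
) -> TwinEstimate | None:
    """Intensity-ratio twin test over twin-related reflection pairs.

    H = |I₁ - I₂| / (I₁ + I₂) over pairs related by ``twin_op`` with both
    intensities positive.  For untwinned acentric data mean(H) → 1/2;
    for a twin fraction α, mean(H) = (1 - 2α)/2, so
    ``α = clamp(1/2 - mean(H), 0, 0.5)``.  Returns None below
    ``min_pairs`` pairs.
    """
    table = {tuple(r): i for r, i in zip(merged.hkl, merged.intensity)}
    op = np.asarray(twin_op, dtype=int)
    hs = []
    seen = set()
    setting = merged.setting
    for key, i1 in table.items():
        if key in seen:
            continue
        partner_raw = op @ np.asarray(key)
        partner = reduce_to_asu(partner_raw, setting) if setting is not None else tuple(partner_raw)
        if partner == key or partner not in table:
            continue
        i2 = table[partner]
        seen.add(key)
        seen.add(partner)
        if i1 <= 0 or i2 <= 0:
            continue
        hs.append(abs(i1 - i2) / (i1 + i2))
    if len(hs) < min_pairs:
        return None
    mean_h = float(np.mean(hs))
    alpha = float(np.clip(0.5 - mean_h, 0.0, 0.5))
    return TwinEstimate(mean_h=mean_h, alpha=alpha, n_pairs=len(hs))


# Crick–Magdoff-style constants: effective normal-scatterer Z and non-H
# atoms per residue for an average protein.
Z_EFF = 6.7
ATOMS_PER_RESIDUE = 7.7


def anomalous_ratio(n_residues: int, anom_atoms: list[tuple[float, float]]) -> float:
    """Theoretical anomalous diffraction ratio 〈ΔF/F〉 in percent.

    ``anom_atoms`` lists (count, f'' in electrons) per anomalous scatterer
    species at the intended wavelength.  The estimate is

        100 · √2 · sqrt(Σ count·f''²) / (Z_eff · sqrt(N_atoms)),

    with N_atoms = n_residues · 7.7 non-H atoms and Z_eff = 6.7.
    """
    if n_residues <= 0:
        raise ValueError("n_residues must be > 0")
    if not anom_atoms:
        return 0.0
    num = np.sqrt(2.0) * np.sqrt(sum(c * f * f for c, f in anom_atoms))
    den = Z_EFF * np.sqrt(n_residues * ATOMS_PER_RESIDUE)
    return float(100.0 * num / den)
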