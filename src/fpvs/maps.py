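"""Cohort-level spatial statistics over Talairach contact maps.

Voxel maps use overlapping 12 x 12 x 100 mm windows stepped by
3 x 3 x 100 mm (x: medial-lateral, y: posterior-anterior, z collapsed),
so an interior contact contributes to 16 (x, y) voxels. Postero-anterior
profiles use 12 mm windows stepped by 3 mm along y, hemispheres
collapsed. Inference on maps is by percentile bootstrap and permutation;
multiplicity by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

VOXEL_SIZE = (12.0, 12.0, 100.0)
VOXEL_STEP = (3.0, 3.0, 100.0)


def winsorized_mean(values, frac: float = 0.10) -> float:
    """Mean after clipping the most extreme ``frac`` of each tail.

    k = round(frac * n) values at each tail are replaced by the nearest
    retained value; k is forced to 0 for n < 5 so tiny samples are left
    untouched.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    k = int(round(frac * n)) if n >= 5 else 0
    if k > 0:
        v[:k] = v[k]
        v[n - k:] = v[n - k - 1]
    return float(v.mean())


def _window_centers(lo: float, hi: float, size: float,
                    step: float) -> np.ndarray:
    """Window centres on a step-grid anchored at 0 whose windows
    [c - size/2, c + size/2) intersect [lo, hi]."""
    first = np.floor((lo - size / 2) / step) * step + step
    return np.arange(first, hi + size / 2 + step / 2, step)


@dataclass
class VoxelGrid:
    """Windowed voxel summary of a contact map (overlapping voxels)."""

    table: pd.DataFrame  # cx, cy, cz, n_recorded, + mode columns
    size: tuple = VOXEL_SIZE
    step: tuple = VOXEL_STEP
    mode: str = "proportion"


def voxel_map(contacts: pd.DataFrame, values, mode: str = "proportion",
              size=VOXEL_SIZE, step=VOXEL_STEP,
              winsor_frac: float = 0.10) -> VoxelGrid:
    """Windowed voxel map over Talairach space.

    ``mode='proportion'``: ``values`` are significance flags; each voxel
    reports n_recorded, n_significant and their ratio. ``mode='amplitude'``:
    ``values`` are amplitudes; each voxel reports the winsorized mean.
    Voxels with no recorded contacts are omitted.
    """
    x = contacts["tal_x"].to_numpy(float)
    y = contacts["tal_y"].to_numpy(float)
    z = contacts["tal_z"].to_numpy(float)
    values = np.asarray(values)
    if len(values) != len(contacts):
        raise ValueError("values length must match contacts")
    if mode == "proportion":
        if values.dtype != bool and not np.isin(values, [0, 1]).all():
            raise ValueError("proportion mode requires boolean flags")
        values = values.astype(bool)
    elif mode != "amplitude":
        raise ValueError(f"unknown mode {mode!r}")

    cxs = _window_centers(x.min(), x.max(), size[0], step[0])
    cys = _window_centers(y.min(), y.max(), size[1], step[1])
    czs = _window_centers(z.min(), z.max(), size[2], step[2])
    rows = []
    for cz in czs:
        in_z = (z >= cz - size[2] / 2) & (z < cz + size[2] / 2)
        for cx in cxs:
            in_xz = in_z & (x >= cx - size[0] / 2) & (x < cx + size[0] / 2)
            if not in_xz.any():
                continue
            ys = y[in_xz]
            vs = values[in_xz]
            for cy in cys:
                sel = (ys >= cy - size[1] / 2) & (ys < cy + size[1] / 2)
                n = int(sel.sum())
                if n == 0:
                    continue
                row = {"cx": cx, "cy": cy, "cz": cz, "n_recorded": n}
                if mode == "proportion":
                    n_sig = int(vs[sel].sum())
                    row["n_significant"] = n_sig
                    row["proportion"] = n_sig / n
                else:
                    row["amplitude"] = winsorized_mean(vs[sel], winsor_frac)
                rows.append(row)
    return VoxelGrid(table=pd.DataFrame(rows), size=tuple(size),
                     step=tuple(step), mode=mode)


def bootstrap_proportion_p(flags, B: int = 2000, seed: int = 0) -> float:
    """p-value that a voxel's significant-proportion exceeds zero.

    Resamples the voxel's contacts with replacement B times; p is the
    fraction of bootstrap proportions equal to zero.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("empty voxel")
    if flags.all():
        return 0.0
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, flags.size, size=(B, flags.size))
    return float((flags[draws].sum(axis=1) == 0).mean())


@dataclass
class APProfile:
    """Windowed summary along the postero-anterior (Talairach y) axis."""

    y_centers: np.ndarray
    values: np.ndarray
    n_contacts: np.ndarray
    window: float = 12.0
    step: float = 3.0
    normalized: bool = False


def ap_profile(contacts: pd.DataFrame, values, normalize: bool = False,
               window: float = 12.0, step: float = 3.0,
               statistic: str = "mean") -> APProfile:
    """Postero-anterior profile: windowed mean of ``values`` along y.

    Hemispheres are collapsed (only y is used). Empty windows are
    skipped. With ``normalize=True`` the profile is z-scored across bins
    (mean 0, SD 1), which aligns profiles up to vertical translation and
    scale.
    """
    y = contacts["tal_y"].to_numpy(float)
    values = np.asarray(values, dtype=float)
    centers = _window_centers(y.min(), y.max(), window, step)
    ys, vals, ns = [], [], []
    for c in centers:
        sel = (y >= c - window / 2) & (y < c + window / 2)
        if not sel.any():
            continue
        ys.append(c)
        ns.append(int(sel.sum()))
        if statistic == "mean":
            vals.append(values[sel].mean())
        elif statistic == "winsorized_mean":
            vals.append(winsorized_mean(values[sel]))
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    vals = np.asarray(vals)
    if normalize:
        sd = vals.std()
        if sd == 0:
            raise ValueError("cannot normalize a constant profile")
        vals = (vals - vals.mean()) / sd
    return APProfile(y_centers=np.asarray(ys), values=vals,
                     n_contacts=np.asarray(ns), window=window, step=step,
                     normalized=normalize)


def proportion_contrast_index(p_lf: float, p_hf: float) -> float:
    """(p_lf - p_hf) / (p_lf + p_hf), in [-1, 1]; undefined at 0/0."""
    if p_lf < 0 or p_hf < 0:
        raise ValueError("proportions must be >= 0")
    s = p_lf + p_hf
    if s == 0:
        raise ValueError("contrast undefined when both proportions are 0")
    return (p_lf - p_hf) / s


def match_threshold(z_values, n_target: int) -> float:
    """Smallest threshold t with exactly ``n_target`` values above it.

    Returns the (n_target+1)-th largest value; with ties an exactly-N cut
    may not exist, in which case the nearest achievable count's threshold
    is returned (a warning attribute is exposed via the returned float's
    context — callers needing the achieved count should recount).
    """
    z = np.sort(np.asarray(z_values, dtype=float))[::-1]
    z = z[np.isfinite(z)]
    n = z.size
    if not 0 <= n_target <= n:
        raise ValueError("n_target out of range")
    if n_target == n:
        return float(np.nextafter(z[-1], -np.inf))
    t = float(z[n_target])
    achieved = int((z > t).sum())
    if achieved != n_target:
        import warnings
        warnings.warn(
            f"ties: {achieved} values exceed the threshold instead of "
            f"{n_target}", stacklevel=2)
    return t


def permutation_test(group_a, group_b, statistic=None, B: int = 10000,
                     seed: int = 0, paired: bool = False) -> float:
    """Two-tailed permutation p-value for a two-group difference.

    Default statistic: difference in means (== difference in proportions
    for 0/1 data). Unpaired: group labels are shuffled across the pooled
    sample. Paired: signs of within-pair differences are flipped.
    p = (1 + #{|stat*| >= |stat|}) / (B + 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    if statistic is None:
        statistic = lambda u, v: u.mean() - v.mean()
    obs = abs(statistic(a, b))
    count = 0
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal sizes")
        d = a - b
        for _ in range(B):
            signs = rng.choice([-1.0, 1.0], size=d.size)
            sd = signs * d
            count += abs(statistic(b + sd, b)) >= obs
    else:
        pooled = np.concatenate([a, b])
        na = a.size
        for _ in range(B):
            perm = rng.permutation(pooled)
            count += abs(statistic(perm[:na], perm[na:])) >= obs
    return (1 + count) / (B + 1)


def bh_fdr(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def bootstrap_ci(values, statistic=np.mean, B: int = 1000,
                 level: float = 0.99, seed: int = 0
                 ) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval of ``statistic``."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    stats = np.array([statistic(v[rng.integers(0, v.size, v.size)])
                      for _ in range(B)])
    tail = (1.0 - level) / 2.0 * 100.0
    return (float(np.percentile(stats, tail)),
            float(np.percentile(stats, 100.0 - tail)))


def split_half_profile_ci(contacts: pd.DataFrame, z_lf_col: str = "z_lf",
                          z_hf_col: str = "z_hf", B: int = 1000,
                          seed: int = 0, window: float = 12.0,
                          step: float = 3.0) -> dict:
    """Split-half correlations of postero-anterior Z profiles.

    Contacts are randomly split in half B times; each half yields an LF
    and an HF postero-anterior Z profile (restricted to y-bins populated
    in both halves). Pearson correlations within LF (half 1 vs half 2),
    within HF, and between signals (LF half 1 vs HF half 2) are collected
    and summarised by percentile 95% CIs.
    """
    rng = np.random.default_rng(seed)
    y = contacts["tal_y"].to_numpy(float)
    zlf = contacts[z_lf_col].to_numpy(float)
    zhf = contacts[z_hf_col].to_numpy(float)
    n = len(contacts)
    centers = _window_centers(y.min(), y.max(), window, step)

    def profile(idx, z):
        sums = []
        for c in centers:
            sel = (y[idx] >= c - window / 2) & (y[idx] < c + window / 2)
            sums.append(z[idx][sel].mean() if sel.any() else np.nan)
        return np.asarray(sums)

    r_lf, r_hf, r_between = [], [], []
    for _ in range(B):
        perm = rng.permutation(n)
        h1, h2 = perm[:n // 2], perm[n // 2:]
        p = [profile(h1, zlf), profile(h2, zlf),
             profile(h1, zhf), profile(h2, zhf)]
        ok = ~np.any([np.isnan(q) for q in p], axis=0)
        if ok.sum() < 3:
            continue
        lf1, lf2, hf1, hf2 = (q[ok] for q in p)
        if min(q.std() for q in (lf1, lf2, hf1, hf2)) == 0:
            continue  # constant profile: correlation undefined, skipped
        r_lf.append(np.corrcoef(lf1, lf2)[0, 1])
        r_hf.append(np.corrcoef(hf1, hf2)[0, 1])
        r_between.append(np.corrcoef(lf1, hf2)[0, 1])

    def ci(r):
        if len(r) < 2:
            return (np.nan, np.nan)
        return (float(np.percentile(r, 2.5)), float(np.percentile(r, 97.5)))

    return {
        "r_within_lf": np.asarray(r_lf),
        "r_within_hf": np.asarray(r_hf),
        "r_between": np.asarray(r_between),
        "ci_within_lf": ci(r_lf),
        "ci_within_hf": ci(r_hf),
        "ci_between": ci(r_between),
        "n_splits_used": len(r_lf),
    }
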