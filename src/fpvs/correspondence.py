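"""LF <-> HF functional correspondence: correlation, noise ceiling, FSI.

The maximum expected correlation (MEC) is the noise ceiling on the
between-signal amplitude correlation: each signal's reproducibility is
estimated by Monte-Carlo as the mean correlation between the measured
(log) amplitudes and simulated noisy re-measurements (measured + SD *
standard-normal draws, noise added on the linear scale), and the MEC is
the smaller of the two reproducibilities. The face-selectivity index
(FSI) is face / (face + base) amplitude, with amplitudes averaged across
the contact set before the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MECResult:
    reproducibility_lf: float
    reproducibility_hf: float
    mec: float
    observed_r: float
    ratio_to_mec: float
    ci_ratio: tuple[float, float]
    n_contacts: int
    n_excluded: int = 0


@dataclass
class FSIResult:
    fsi: float
    mean_face: float
    mean_base: float
    scope: str = ""
    n_contacts: int = 0
    clipped: bool = False


def _positive_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok], int((~ok).sum())


def log_pearson(x_amps, y_amps, B: int = 1000, seed: int = 0,
                ci_level: float = 0.95) -> dict:
    """Pearson correlation of log-transformed amplitude pairs.

    Amplitudes are right-skewed; the log transform normalises them.
    Pairs with a non-positive member are excluded (baseline-subtracted
    amplitudes can dip below zero on noise) and counted. CI by
    percentile bootstrap over pairs.
    """
    x, y, n_excluded = _positive_pairs(x_amps, y_amps)
    if x.size < 3:
        raise ValueError("need >= 3 usable pairs")
    lx, ly = np.log(x), np.log(y)
    r = float(np.corrcoef(lx, ly)[0, 1])
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(B):
        idx = rng.integers(0, x.size, x.size)
        if lx[idx].std() == 0 or ly[idx].std() == 0:
            continue
        rs.append(np.corrcoef(lx[idx], ly[idx])[0, 1])
    tail = (1 - ci_level) / 2 * 100
    ci = (float(np.percentile(rs, tail)),
          float(np.percentile(rs, 100 - tail)))
    return {"r": r, "ci": ci, "n": int(x.size), "n_excluded": n_excluded}


def _reproducibility(amps: np.ndarray, sds: np.ndarray, n_iter: int,
                     rng: np.random.Generator) -> float:
    """Mean over iterations of corr(log measured, log simulated)."""
    rs = []
    for _ in range(n_iter):
        sim = amps + sds * rng.standard_normal(amps.size)
        ok = (sim > 0) & (amps > 0)
        if ok.sum() < 3:
            continue
        rs.append(np.corrcoef(np.log(amps[ok]), np.log(sim[ok]))[0, 1])
    if not rs:
        raise ValueError("degenerate amplitudes: reproducibility undefined")
    return float(np.mean(rs))


def mec(amps_lf, amps_hf, sd_lf, sd_hf, n_iter: int = 2000,
        seed: int = 0, ci_level: float = 0.99) -> MECResult:
    """Maximum expected correlation between LF and HF amplitudes.

    ``sd_lf``/``sd_hf`` are the per-contact across-sequence amplitude
    SDs quantifying measurement noise. The ratio observed_r / MEC says
    what fraction of the attainable correlation is reached; its CI is a
    percentile bootstrap over contacts (both the observed correlation
    and a reduced-iteration MEC are recomputed per resample).
    """
    amps_lf = np.asarray(amps_lf, dtype=float)
    amps_hf = np.asarray(amps_hf, dtype=float)
    sd_lf = np.asarray(sd_lf, dtype=float)
    sd_hf = np.asarray(sd_hf, dtype=float)
    ok = (amps_lf > 0) & (amps_hf > 0)
    n_excluded = int((~ok).sum())
    amps_lf, amps_hf = amps_lf[ok], amps_hf[ok]
    sd_lf, sd_hf = sd_lf[ok], sd_hf[ok]
    if amps_lf.size < 3:
        raise ValueError("need >= 3 contacts with positive amplitudes")
    if np.ptp(amps_lf) == 0 or np.ptp(amps_hf) == 0:
        raise ValueError("zero-variance amplitudes: MEC degenerate")

    rng = np.random.default_rng(seed)
    rep_lf = _reproducibility(amps_lf, sd_lf, n_iter, rng)
    rep_hf = _reproducibility(amps_hf, sd_hf, n_iter, rng)
    m = min(rep_lf, rep_hf)
    observed = float(np.corrcoef(np.log(amps_lf), np.log(amps_hf))[0, 1])
    ratio = observed / m if m > 0 else np.nan

    # bootstrap the ratio over contacts (reduced inner iterations)
    inner = max(50, n_iter // 10)
    ratios = []
    for _ in range(200):
        idx = rng.integers(0, amps_lf.size, amps_lf.size)
        al, ah = amps_lf[idx], amps_hf[idx]
        if np.ptp(al) == 0 or np.ptp(ah) == 0:
            continue
        try:
            mb = min(_reproducibility(al, sd_lf[idx], inner, rng),
                     _reproducibility(ah, sd_hf[idx], inner, rng))
        except ValueError:
            continue
        if mb <= 0:
            continue
        rb = np.corrcoef(np.log(al), np.log(ah))[0, 1]
        ratios.append(rb / mb)
    tail = (1 - ci_level) / 2 * 100
    ci = ((float(np.percentile(ratios, tail)),
           float(np.percentile(ratios, 100 - tail)))
          if len(ratios) >= 10 else (np.nan, np.nan))
    return MECResult(
        reproducibility_lf=rep_lf, reproducibility_hf=rep_hf, mec=m,
        observed_r=observed, ratio_to_mec=ratio, ci_ratio=ci,
        n_contacts=int(amps_lf.size), n_excluded=n_excluded)


def fsi(face_amps, base_amps, scope: str = "") -> FSIResult:
    """Face-selectivity index of a contact set.

    Amplitudes are averaged across contacts before the ratio
    face / (face + base), keeping the index in [0, 1] when the means are
    non-negative; negative means clip the index with a flag.
    """
    face = np.asarray(face_amps, dtype=float)
    base = np.asarray(base_amps, dtype=float)
    if face.size == 0 or face.size != base.size:
        raise ValueError("need matched, non-empty amplitude sets")
    mf, mb = float(face.mean()), float(base.mean())
    denom = mf + mb
    if denom <= 0:
        raise ValueError("FSI undefined: mean face + base amplitude <= 0")
    raw = mf / denom
    clipped = not 0.0 <= raw <= 1.0
    return FSIResult(fsi=float(np.clip(raw, 0.0, 1.0)), mean_face=mf,
                     mean_base=mb, scope=scope, n_contacts=int(face.size),
                     clipped=clipped)
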