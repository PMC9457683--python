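"""Cohort summary tables: counts, shares and hemisphere proportions.

Percentages are rounded half-away-from-zero at one decimal (banker's
rounding would bias printed shares).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .data_model import REGIONS, StimulusProtocol
from .envelope import HFConfig
from .spectral import Z_THRESHOLD


@dataclass
class RunConfig:
    """Everything that determines a reproducible end-to-end run."""

    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    hf_config: HFConfig = field(default_factory=HFConfig)
    z_threshold: float = Z_THRESHOLD
    seed: int = 0
    n_bootstrap: int = 2000
    n_permutation: int = 10000
    round_decimals: int = 1


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (2.25 -> 2.3, -2.25 -> -2.3)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def classification_shares(n_lf_only: int, n_both: int,
                          n_hf_only: int) -> dict:
    """Shares of the three face-selective classes and overlap rates.

    Returns percentages rounded half-away-from-zero at one decimal
    (share_lf_only additionally as an integer, matching the convention
    of printing whole-percent LF-only shares).
    """
    total = n_lf_only + n_both + n_hf_only
    if total == 0:
        return {"total": 0}
    n_lf = n_lf_only + n_both
    n_hf = n_hf_only + n_both
    return {
        "total": total,
        "share_lf_only_pct": round_half_away(100 * n_lf_only / total),
        "share_lf_only_pct_int": int(round_half_away(
            100 * n_lf_only / total, 0)),
        "share_both_pct": round_half_away(100 * n_both / total),
        "share_hf_only_pct": round_half_away(100 * n_hf_only / total),
        "overlap_from_hf_pct": round_half_away(100 * n_both / n_hf),
        "overlap_from_lf_pct": round_half_away(100 * n_both / n_lf),
        "n_lf_plus": n_lf,
        "n_hf_plus": n_hf,
    }


def region_count_table(contacts: pd.DataFrame,
                       z_threshold: float = Z_THRESHOLD) -> pd.DataFrame:
    """Region x hemisphere counts of LF+ and HF+ contacts, with totals.

    Expects columns region, hemisphere, z_lf, z_hf. LF+ means z_lf >
    threshold regardless of HF, and vice versa (the two columns
    overlap on LF+HF+ contacts).
    """
    df = contacts.copy()
    df["LF+"] = df["z_lf"] > z_threshold
    df["HF+"] = df["z_hf"] > z_threshold
    rows = []
    for region in REGIONS:
        sub = df[df["region"] == region]
        rows.append({
            "region": region,
            "LF+_L": int(sub[sub.hemisphere == "L"]["LF+"].sum()),
            "LF+_R": int(sub[sub.hemisphere == "R"]["LF+"].sum()),
            "HF+_L": int(sub[sub.hemisphere == "L"]["HF+"].sum()),
            "HF+_R": int(sub[sub.hemisphere == "R"]["HF+"].sum()),
        })
    table = pd.DataFrame(rows)
    totals = {"region": "Total"}
    for c in ("LF+_L", "LF+_R", "HF+_L", "HF+_R"):
        totals[c] = int(table[c].sum())
    return pd.concat([table, pd.DataFrame([totals])], ignore_index=True)


def hemisphere_proportions(contacts: pd.DataFrame,
                           z_threshold: float = Z_THRESHOLD) -> dict:
    """Per-hemisphere proportions of significant contacts (percent)."""
    out = {}
    for sig, z_col in (("lf", "z_lf"), ("hf", "z_hf")):
        for hemi in ("L", "R"):
            sub = contacts[contacts.hemisphere == hemi]
            if len(sub) == 0:
                continue
            n_sig = int((sub[z_col] > z_threshold).sum())
            out[f"{sig}_{hemi}_pct"] = round_half_away(
                100 * n_sig / len(sub))
            out[f"{sig}_{hemi}_n"] = n_sig
            out[f"{sig}_{hemi}_recorded"] = len(sub)
    return out


def run_report(contacts: pd.DataFrame,
               config: RunConfig = RunConfig()) -> dict:
    """Publication-style cohort report from a quantified contact table.

    Returns the region x hemisphere count table, classification shares
    and hemisphere proportions. Empty cohorts yield empty tables.
    """
    if len(contacts) == 0:
        return {"region_table": pd.DataFrame(), "shares": {"total": 0},
                "hemispheres": {}}
    thr = config.z_threshold
    lf = contacts["z_lf"] > thr
    hf = contacts["z_hf"] > thr
    shares = classification_shares(
        int((lf & ~hf).sum()), int((lf & hf).sum()), int((~lf & hf).sum()))
    return {
        "region_table": region_count_table(contacts, thr),
        "shares": shares,
        "hemispheres": hemisphere_proportions(contacts, thr),
    }
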