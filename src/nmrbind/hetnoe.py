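"""Steady-state heteronuclear 15N-{1H} NOE profiling.

The het-NOE ratio I_NOE/I_ref per backbone amide reports ps-ns backbone
mobility: ~0.8 for a rigid structured core, low or negative for flexible
linkers and tails.  Errors are propagated from a single global spectral
noise estimate; negative ratios are real (flexible tails) and not clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class IntensityTable:
    """Paired NOE / reference peak intensities with a global noise estimate."""

    data: pd.DataFrame  # columns: residue_number, I_noe, I_ref
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        required = {"residue_number", "I_noe", "I_ref"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"intensity table must have columns {sorted(required)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path, noise_sd: float = 0.0) -> "IntensityTable":
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        return cls(data=df, noise_sd=noise_sd)


def hetnoe_profile(table: IntensityTable) -> pd.DataFrame:
    """Per-residue het-NOE ratio I_NOE/I_ref with propagated error.

    error = |ratio| * sqrt((noise/I_noe)^2 + (noise/I_ref)^2).  Residues with
    I_ref == 0 are skipped with a warning (ratio undefined).
    """
    if table.data.empty:
        raise ValueError("empty intensity table")
    df = table.data.copy()
    zero_ref = df["I_ref"] == 0
    if zero_ref.any():
        skipped = df.loc[zero_ref, "residue_number"].tolist()
        warnings.warn(f"skipping residues with zero reference intensity: {skipped}")
        df = df[~zero_ref]
    ratio = df["I_noe"] / df["I_ref"]
    noise = table.noise_sd
    with np.errstate(divide="ignore"):
        rel = np.sqrt((noise / df["I_noe"]) ** 2 + (noise / df["I_ref"]) ** 2)
    error = np.abs(ratio) * rel
    error = error.replace([np.inf], np.nan).fillna(0.0) if noise == 0 else error
    return pd.DataFrame(
        {
            "residue_number": df["residue_number"].to_numpy(),
            "ratio": ratio.to_numpy(),
            "ratio_error": np.asarray(error, dtype=float),
        }
    )


def region_average(
    profile: pd.DataFrame, regions: dict[str, tuple[int, int]]
) -> pd.DataFrame:
    """Mean +/- SD of the het-NOE ratio over named residue ranges.

    A region with no observed residues is reported with NaN mean/SD and
    n = 0 rather than raised as an error, so partial assignments do not
    abort a multi-region summary.
    """
    if not regions:
        raise ValueError("no regions given")
    rows = []
    for name, (lo, hi) in regions.items():
        if hi < lo:
            raise ValueError(f"region {name!r}: end {hi} before start {lo}")
        sel = profile[
            (profile["residue_number"] >= lo) & (profile["residue_number"] <= hi)
        ]
        if sel.empty:
            rows.append((name, lo, hi, np.nan, np.nan, 0))
        else:
            vals = sel["ratio"].to_numpy()
            sd = float(np.std(vals, ddof=0)) if len(vals) > 1 else 0.0
            rows.append((name, lo, hi, float(np.mean(vals)), sd, len(vals)))
    return pd.DataFrame(
        rows, columns=["region", "start", "end", "mean_ratio", "sd_ratio", "n"]
    )
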