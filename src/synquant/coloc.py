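"""Per-cell intensity and colocalization quantification.

For each segmented cell the pipeline reports the mean fluorescence intensity
(MFI) of every channel and the pairwise Pearson correlation coefficient
(PCC) between channels, both evaluated over the pixels of the cell mask —
the synaptic interface as seen by TIRF.  PCC ranges from 1 (perfect
colocalization) through 0 (no linear relation) to -1 (anticorrelation).
Records are aggregated per group as median and interquartile range with
per-experiment means, matching superplot-style reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CellQuantRecord", "mfi", "pcc", "aggregate"]


@dataclass
class CellQuantRecord:
    """Quantification of one cell at one timepoint in one experiment."""

    cell_id: int
    timepoint: str = ""
    experiment: str = ""
    condition: str = ""
    mfi: dict[str, float] = field(default_factory=dict)
    pcc: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in self.mfi.values():
            if v < 0:
                raise ValueError("MFI must be nonnegative")
        for v in self.pcc.values():
            if not np.isnan(v) and not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError("PCC must lie in [-1, 1]")

    def to_row(self) -> dict:
        row: dict = {
            "cell_id": self.cell_id,
            "timepoint": self.timepoint,
            "experiment": self.experiment,
            "condition": self.condition,
        }
        for ch, v in self.mfi.items():
            row[f"mfi_{ch}"] = v
        for (a, b), v in self.pcc.items():
            row[f"pcc_{a}_{b}"] = v
        return row


def mfi(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean intensity of ``image`` over the pixels of a boolean ``mask``.

    Background handling is the caller's concern: pass a background-subtracted
    image to report background-corrected MFI.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(image[mask].mean())


def pcc(image_a: np.ndarray, image_b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation of two channels over the mask pixels.

    Returns ``nan`` (a flagged missing value, deliberately not 0) when either
    channel is constant over the mask, where the correlation is undefined.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    x = a[mask]
    y = b[mask]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    r = float(stats.pearsonr(x, y).statistic)
    # perfectly (anti)correlated channels accumulate ~1 ulp of rounding in
    # the dot products; snap to the exact limit inside that band
    if abs(r) > 1.0 - 1e-12:
        r = float(np.sign(r))
    return float(np.clip(r, -1.0, 1.0))


def aggregate(
    records: pd.DataFrame,
    group_by: str | list[str],
    value_columns: list[str] | None = None,
    experiment_by: str = "experiment",
) -> pd.DataFrame:
    """Summarise per-cell measurements per group.

    For every group and value column: n, median, 25th/75th percentiles
    (linear-interpolation percentile convention), and the per-experiment
    means (one column per experiment, superplot-style).
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    for col in group_by:
        if col not in records.columns:
            raise KeyError(f"unknown group label {col!r}")
    if value_columns is None:
        value_columns = [
            c
            for c in records.columns
            if c.startswith(("mfi_", "pcc_")) or records[c].dtype.kind == "f"
        ]
        value_columns = list(dict.fromkeys(value_columns))
    has_exp = experiment_by in records.columns

    rows = []
    for keys, sub in records.groupby(group_by, sort=True, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for col in value_columns:
            vals = sub[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            row = dict(zip(group_by, keys))
            row.update(
                {
                    "value": col,
                    "n": int(vals.size),
                    "median": float(np.median(vals)),
                    "q25": float(np.percentile(vals, 25)),
                    "q75": float(np.percentile(vals, 75)),
                }
            )
            if has_exp:
                exp_means = sub.groupby(experiment_by)[col].mean()
                row["n_experiments"] = int(exp_means.size)
                for exp, m in exp_means.items():
                    row[f"exp_mean_{exp}"] = float(m)
            rows.append(row)
    return pd.DataFrame(rows)
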