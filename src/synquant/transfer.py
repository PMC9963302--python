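"""Bead-supported-lipid-bilayer transfer statistic and dose-curve comparison.

T cells release receptor-loaded vesicles onto antigen-coated beads; flow
cytometry then measures fluorescence on the bead and cell populations.  The
transfer statistic is the bead MFI relative to the summed bead and cell MFI,

    f = MFI_bead / (MFI_bead + MFI_cell),

computed per experiment and averaged with SEM across experiments.  Dose
responses over ligand density are compared between two conditions with an
extra-sum-of-squares F test: one curve fitted to the pooled data versus one
curve per condition, with F = [(SS_shared - SS_separate)/Δdf] /
[SS_separate/df_separate].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["TransferResult", "DoseCurveComparison", "transfer_fraction", "compare_dose_curves"]

REQUIRED_COLUMNS = {"population", "fluorescence"}


@dataclass
class TransferResult:
    fraction: float
    sem: float
    n_experiments: int
    per_experiment: dict[str, float]


@dataclass
class DoseCurveComparison:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    ss_shared: float
    ss_separate: float
    params_shared: np.ndarray
    params_by_condition: dict[str, np.ndarray]
    model: str


def _select(table: pd.DataFrame, condition, density) -> pd.DataFrame:
    sub = table
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if density is not None:
        sub = sub[np.isclose(sub["ligand_density"], density)]
    return sub


def _population_mfi(sub: pd.DataFrame, robust: bool) -> tuple[float, float]:
    stat = np.median if robust else np.mean
    bead = sub[sub["population"] == "bead"]["fluorescence"]
    cell = sub[sub["population"] == "cell"]["fluorescence"]
    if bead.empty or cell.empty:
        raise ValueError("both bead and cell populations are required")
    return float(stat(bead)), float(stat(cell))


def transfer_fraction(
    table: pd.DataFrame,
    condition: str | None = None,
    density: float | None = None,
    robust: bool = False,
) -> TransferResult:
    """Bead MFI relative to the summed bead and cell MFI.

    If an ``experiment`` column is present the ratio is computed per
    experiment and reported as mean +/- SEM across experiments; otherwise a
    single ratio with SEM 0.  Returns ``nan`` (flagged missing) when both
    MFIs are zero.  ``robust=True`` switches the population statistic from
    the mean to the median.
    """
    if not REQUIRED_COLUMNS <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(REQUIRED_COLUMNS)}")
    sub = _select(table, condition, density)
    if sub.empty:
        raise ValueError("no events for the requested condition/density")

    groups = (
        [(e, g) for e, g in sub.groupby("experiment")]
        if "experiment" in sub.columns
        else [("all", sub)]
    )
    per_exp: dict[str, float] = {}
    for exp, g in groups:
        bead, cell = _population_mfi(g, robust)
        per_exp[str(exp)] = bead / (bead + cell) if bead + cell > 0 else float("nan")
    vals = np.array(list(per_exp.values()), dtype=float)
    ok = vals[~np.isnan(vals)]
    if ok.size == 0:
        return TransferResult(float("nan"), float("nan"), len(per_exp), per_exp)
    sem = float(ok.std(ddof=1) / np.sqrt(ok.size)) if ok.size > 1 else 0.0
    return TransferResult(float(ok.mean()), sem, len(per_exp), per_exp)


def _fractions_by_density(table: pd.DataFrame, condition: str) -> pd.DataFrame:
    """One transfer-fraction observation per (density, experiment)."""
    sub = table[table["condition"] == condition]
    if "ligand_density" not in sub.columns:
        raise ValueError("table must have a ligand_density column")
    rows = []
    for dens, g in sub.groupby("ligand_density"):
        groups = (
            [(e, gg) for e, gg in g.groupby("experiment")]
            if "experiment" in g.columns
            else [("all", g)]
        )
        for exp, gg in groups:
            bead, cell = _population_mfi(gg, robust=False)
            if bead + cell > 0:
                rows.append(
                    {"density": float(dens), "experiment": exp, "fraction": bead / (bead + cell)}
                )
    return pd.DataFrame(rows)


def _fit_linear_logdensity(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lx = np.log10(x)
    coef = np.polyfit(lx, y, deg=1)
    resid = y - np.polyval(coef, lx)
    return coef, resid


def _fit_hyperbolic(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    def model(x, top, k):
        return top * x / (k + x)

    p0 = (max(y.max(), 1e-6), np.median(x))
    popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    return np.asarray(popt), y - model(x, *popt)


_MODELS = {"linear_logdensity": _fit_linear_logdensity, "hyperbolic": _fit_hyperbolic}


def compare_dose_curves(
    table: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    model: str = "linear_logdensity",
) -> DoseCurveComparison:
    """Extra-sum-of-squares F test between two conditions' dose curves.

    Transfer fractions per (density, experiment) are fitted with either one
    shared curve over both conditions or one curve per condition; the F test
    asks whether the separate fits reduce the residual sum of squares more
    than expected by chance.  Default curve family: straight line of
    transfer fraction against log10 ligand density (``hyperbolic`` — a
    saturating binding curve in density — is selectable).
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(_MODELS)}")
    fit = _MODELS[model]
    obs = {c: _fractions_by_density(table, c) for c in (condition_a, condition_b)}
    for c, df in obs.items():
        if df["density"].nunique() < 3:
            raise ValueError(f"condition {c!r} needs >= 3 ligand densities")
        if model == "linear_logdensity" and (df["density"] <= 0).any():
            raise ValueError("log-density model requires strictly positive densities")

    params_sep: dict[str, np.ndarray] = {}
    ss_sep = 0.0
    n_total = 0
    for c, df in obs.items():
        coef, resid = fit(df["density"].to_numpy(), df["fraction"].to_numpy())
        params_sep[c] = coef
        ss_sep += float(np.sum(resid**2))
        n_total += len(df)

    pooled = pd.concat(list(obs.values()), ignore_index=True)
    coef_shared, resid_shared = fit(pooled["density"].to_numpy(), pooled["fraction"].to_numpy())
    ss_shared = float(np.sum(resid_shared**2))

    k = len(coef_shared)  # parameters per curve
    df_num = k
    df_den = n_total - 2 * k
    if df_den <= 0:
        raise ValueError("degenerate fit: no residual degrees of freedom")
    if ss_sep == 0.0:
        # noise-free data: identical conditions give F = 0, different ones
        # give infinite evidence for separate curves
        if ss_shared <= 1e-30:
            return DoseCurveComparison(0.0, df_num, df_den, 1.0, ss_shared, ss_sep,
                                       coef_shared, params_sep, model)
        return DoseCurveComparison(float("inf"), df_num, df_den, 0.0, ss_shared, ss_sep,
                                   coef_shared, params_sep, model)
    f = ((ss_shared - ss_sep) / df_num) / (ss_sep / df_den)
    f = max(f, 0.0)
    p = float(stats.f.sf(f, df_num, df_den))
    return DoseCurveComparison(float(f), df_num, df_den, p, ss_shared, ss_sep,
                               coef_shared, params_sep, model)
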