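"""Trait-trait correlation matrices and index-trait linear screens.

The screening stage mirrors the classic reporting layout of ripening
studies: a symmetric Pearson correlation matrix over the measured traits,
and a grid of simple linear regressions of every candidate index (RGB or
spectral) against every trait, each summarised by its coefficient of
determination and a significance star.

Significance is assessed from the t distribution of the OLS slope; stars
mark P <= 0.05 (*), P <= 0.01 (**) and P <= 0.001 (***).  No
multiple-testing correction is applied to the stars themselves, but a
Bonferroni-adjusted p-value column is emitted for transparency.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["pearson_matrix", "linreg_screen", "significance_star", "screen_pivot"]


def significance_star(p_value: float) -> str:
    """Star label for a two-sided p-value: ns / * / ** / ***."""
    if not np.isfinite(p_value):
        return "ns"
    if p_value <= 0.001:
        return "***"
    if p_value <= 0.01:
        return "**"
    if p_value <= 0.05:
        return "*"
    return "ns"


def pearson_matrix(traits: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of the numeric columns.

    Constant columns get a missing row/column (with a warning); the
    diagonal is 1 and the matrix is symmetric.
    """
    num = traits.select_dtypes(include=[np.number])
    constant = [c for c in num.columns if num[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(
            f"constant column(s) {constant} have undefined correlations; "
            "reported as missing",
            UserWarning,
            stacklevel=2,
        )
    return num.corr(method="pearson", min_periods=min_periods)


def _fit_one(x: np.ndarray, y: np.ndarray, index_name: str, trait_name: str) -> dict:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    base = {"index": index_name, "trait": trait_name, "n": n}
    if n < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        base.update(slope=np.nan, intercept=np.nan, r2=np.nan, p_value=np.nan,
                    star="ns", missing=True)
        return base
    fit = stats.linregress(x[ok], y[ok])
    base.update(
        slope=fit.slope,
        intercept=fit.intercept,
        r2=fit.rvalue ** 2,
        p_value=fit.pvalue,
        star=significance_star(fit.pvalue),
        missing=False,
    )
    return base


def linreg_screen(index_df: pd.DataFrame, trait_df: pd.DataFrame) -> pd.DataFrame:
    """One simple OLS fit per (index, trait) pair.

    Parameters
    ----------
    index_df : DataFrame
        Candidate predictor columns (RGB or spectral indices), one row per
        sample.
    trait_df : DataFrame
        Measured trait columns, aligned to the same samples (index_df and
        trait_df must share their row index).

    Returns a tidy DataFrame with slope, intercept, R2, the two-sided
    p-value of the slope, sample count, the significance star and a
    Bonferroni-adjusted p-value over all fits in this screen.  Pairs where
    the index (or trait) is constant are flagged ``missing``.
    """
    if not index_df.index.equals(trait_df.index):
        raise ValueError("index table and trait table must be aligned on the same samples")
    trait_num = trait_df.select_dtypes(include=[np.number])
    rows = []
    for ic in index_df.columns:
        x = index_df[ic].to_numpy(dtype=float)
        for tc in trait_num.columns:
            rows.append(_fit_one(x, trait_num[tc].to_numpy(dtype=float), str(ic), str(tc)))
    out = pd.DataFrame(rows)
    m = int(out["p_value"].notna().sum())
    out["p_bonferroni"] = np.minimum(out["p_value"] * max(m, 1), 1.0)
    return out


def screen_pivot(screen: pd.DataFrame, value: str = "r2", stars: bool = True) -> pd.DataFrame:
    """Reshape a tidy screen into a report table: rows = indices, columns = traits.

    With ``stars=True`` cells are strings like ``"0.91***"``; otherwise the
    raw numeric values are returned.
    """
    if stars:
        cells = screen.assign(
            cell=lambda d: d.apply(
                lambda r: "" if not np.isfinite(r[value])
                else f"{r[value]:.2f}{r['star'] if r['star'] != 'ns' else ''}",
                axis=1,
            )
        )
        return cells.pivot(index="index", columns="trait", values="cell")
    return screen.pivot(index="index", columns="trait", values=value)
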