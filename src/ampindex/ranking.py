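"""Rankings of units per index and the Spearman correlation matrix.

Units are ranked by descending score (rank 1 = best); ties share the average
rank.  Cross-index association is measured with Spearman's rank correlation
on average ranks; two-tailed p-values use the t-approximation
t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom, and cells are
flagged at the 0.05 (*) and 0.01 (**) levels.  An exact permutation p-value
is available behind a flag for small samples (n <= 10).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

logger = logging.getLogger("ampindex")

EXACT_P_MAX_N = 10


def rank_units(scores: pd.Series, name: str = "score") -> pd.DataFrame:
    """Rank units by descending score; tied units share the average rank.

    Display order is non-increasing in score with ties broken
    alphabetically by unit label, so output is stable across runs.
    """
    if len(scores) < 1:
        raise ValidationError("cannot rank an empty score column")
    s = scores.astype(float)
    ranks = pd.Series(
        stats.rankdata(-s.to_numpy(), method="average"), index=s.index
    )
    out = pd.DataFrame({"unit": s.index.astype(str), name: s.to_numpy()})
    out["rank"] = ranks.to_numpy()
    out = out.sort_values(
        [name, "unit"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


@dataclass(frozen=True)
class CorrelationMatrix:
    """Spearman rho with two-tailed p-values and significance flags.

    ``flags`` holds "**" (p < 0.01), "*" (p < 0.05), "" (not significant) or
    "NA" (rho undefined, e.g. a constant column)."""

    rho: pd.DataFrame
    p_value: pd.DataFrame
    flags: pd.DataFrame
    n: int


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-tailed exact permutation p-value for Spearman rho, tie-free case.

    Enumerates all n! pairings of the rank vectors and counts |rho| at least
    as extreme as observed.  With integer ranks this reduces to comparing
    sums of squared rank differences, so it is exact, but it is only
    feasible for small n."""
    rx = stats.rankdata(x).astype(int)
    ry = stats.rankdata(y).astype(int)
    n = len(rx)
    # with no ties rho is a decreasing affine function of S = sum d^2;
    # |rho| >= |rho_obs| <=> S <= S_lo or S >= S_hi
    s_obs = float(np.sum((rx - ry) ** 2))
    s_mid = n * (n * n - 1) / 6.0  # S at rho = 0
    dev = abs(s_mid - s_obs)
    count = 0
    total = 0
    base = np.sort(ry)
    for perm in itertools.permutations(base):
        s = float(np.sum((rx - np.asarray(perm)) ** 2))
        if abs(s_mid - s) >= dev - 1e-9:
            count += 1
        total += 1
    return count / total


def spearman_matrix(
    score_columns: pd.DataFrame | Mapping[str, pd.Series],
    exact_p: bool = False,
) -> CorrelationMatrix:
    """Pairwise Spearman correlation across index score columns.

    All columns must share the same unit set (n >= 3).  A constant column
    has undefined rho against everything; those cells are reported as NA
    rather than raising.  ``exact_p`` switches to the exact permutation
    p-value, allowed only for n <= 10 and tie-free columns.
    """
    df = pd.DataFrame(score_columns)
    if df.isna().to_numpy().any():
        raise ValidationError(
            "score columns do not share a common unit set (missing values "
            "after alignment)"
        )
    n = len(df)
    if n < 3:
        raise ValidationError(f"need >= 3 units for correlation, got {n}")
    names = list(df.columns)
    k = len(names)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    constant = {c for c in names if df[c].nunique() <= 1}
    if exact_p and n > EXACT_P_MAX_N:
        raise ValidationError(
            f"exact permutation p-value is limited to n <= {EXACT_P_MAX_N}, got {n}"
        )
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            if a in constant or b in constant:
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                continue
            res = stats.spearmanr(df[a], df[b])
            r, p = float(res.statistic), float(res.pvalue)
            if exact_p:
                x, y = df[a].to_numpy(), df[b].to_numpy()
                if len(np.unique(x)) < n or len(np.unique(y)) < n:
                    logger.warning(
                        "ties in %s/%s: falling back to the t-approximation", a, b
                    )
                else:
                    p = _exact_spearman_p(x, y, r)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    for c in constant:
        i = names.index(c)
        rho[i, i] = np.nan
        pval[i, i] = np.nan
    rho_df = pd.DataFrame(rho, index=names, columns=names)
    p_df = pd.DataFrame(pval, index=names, columns=names)
    flags = p_df.map(_flag)
    flags[rho_df.isna()] = "NA"
    np.fill_diagonal(p_df.to_numpy(), 0.0)
    return CorrelationMatrix(rho=rho_df, p_value=p_df, flags=flags, n=n)


def _flag(p: float) -> str:
    if not math.isfinite(p):
        return "NA"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _fmt_cell(r: float, flag: str) -> str:
    if not math.isfinite(r):
        return "NA"
    # publication style: 3 decimals, no leading zero, minus sign preserved
    txt = f"{r:.3f}"
    txt = txt.replace("-0.", "−.").replace("0.", ".", 1) if abs(r) < 1 else txt
    if txt.startswith("-"):
        txt = "−" + txt[1:]
    return txt + ("" if flag == "NA" else flag)


def render_correlation_report(matrix: CorrelationMatrix) -> str:
    """Human-readable wide table: 3-dp coefficients with star flags.

    Diagonal cells render as 1.000; off-diagonal cells carry * / ** flags
    for two-tailed significance at 0.05 / 0.01.  Machine consumers should
    use :func:`correlation_long` instead (full-precision floats).
    """
    names = list(matrix.rho.columns)
    width = max(max(len(n) for n in names), 8) + 2
    cell_w = max(len(n) for n in names) + 2
    cell_w = max(cell_w, 10)
    lines = ["".ljust(width) + "".join(n.rjust(cell_w) for n in names)]
    for a in names:
        cells = []
        for b in names:
            if a == b and math.isfinite(matrix.rho.loc[a, b]):
                cells.append("1.000".rjust(cell_w))
            else:
                cells.append(
                    _fmt_cell(
                        float(matrix.rho.loc[a, b]), str(matrix.flags.loc[a, b])
                    ).rjust(cell_w)
                )
        lines.append(a.ljust(width) + "".join(cells))
    lines.append("* p < 0.05 (2-tailed)   ** p < 0.01 (2-tailed)")
    return "\n".join(lines)


def correlation_long(matrix: CorrelationMatrix) -> pd.DataFrame:
    """Long-format machine twin: one row per unordered pair, full precision."""
    names = list(matrix.rho.columns)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rows.append(
                {
                    "index_a": a,
                    "index_b": b,
                    "rho": float(matrix.rho.loc[a, b]),
                    "p_value": float(matrix.p_value.loc[a, b]),
                    "flag": str(matrix.flags.loc[a, b]),
                }
            )
    return pd.DataFrame(rows, columns=["index_a", "index_b", "rho", "p_value", "flag"])
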