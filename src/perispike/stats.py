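"""Shared statistical primitives and population-level tests.

Houses the single MAD implementation used by every gate in the package,
the chi-square test with adjusted standardized residuals, GMM/BIC
modality selection, and thin wrappers over standard factorial ANOVA,
rank-sum and distribution-comparison procedures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


def mad(values: Sequence[float]) -> float:
    """Median absolute deviation about the median (unscaled)."""
    v = np.asarray(values, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


@dataclass
class ContingencyResult:
    chi2: float
    dof: int
    p: float
    std_residuals: np.ndarray   # adjusted (Haberman) residuals, r x c
    flagged_cells: List[Tuple[int, int]]


def contingency_with_residuals(table: Sequence[Sequence[float]],
                               alpha: float = 0.05) -> ContingencyResult:
    """Pearson chi-square with per-cell adjusted standardized residuals.

    The adjusted residual for cell (i, j) is
    (O - E) / sqrt(E * (1 - row_i/N) * (1 - col_j/N)); cells are flagged
    when |residual| exceeds the two-sided normal quantile at
    alpha / (r*c) (Bonferroni over cells).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of nonnegative counts")
    n = obs.sum()
    if n <= 0:
        raise ValueError("empty table")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = (obs - expected) / np.sqrt(
            expected * (1 - row[:, None] / n) * (1 - col[None, :] / n))
    r, c = obs.shape
    crit = sps.norm.ppf(1 - alpha / (2 * r * c))
    flagged = [(i, j) for i in range(r) for j in range(c)
               if abs(adj[i, j]) > crit]
    return ContingencyResult(chi2=float(chi2), dof=int(dof), p=float(p),
                             std_residuals=adj, flagged_cells=flagged)


def modality_bic(values: Sequence[float], max_components: int = 4,
                 seed: int = 0) -> int:
    """Number of modes of a distribution selected by Gaussian-mixture BIC.

    Mixtures with 1..max_components components are fitted with several
    restarts; the component count with the smallest BIC wins.
    """
    from sklearn.mixture import GaussianMixture

    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if v.shape[0] < 20:
        raise ValueError("need at least 20 values for modality selection")
    bics = []
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, n_init=5, random_state=seed)
        gm.fit(v)
        bics.append(gm.bic(v))
    return int(np.argmin(bics)) + 1


def group_comparisons(data: pd.DataFrame, value: str,
                      factors: Sequence[str],
                      mode: str = "anova") -> pd.DataFrame:
    """Thin wrapper over standard group-comparison procedures.

    mode="anova": full-factorial ANOVA (all main effects + interactions)
    via statsmodels OLS, returning F and p per term, plus Tukey HSD
    pairwise p-values for each single factor.
    mode="ranksum": two-level single factor Wilcoxon rank-sum.
    mode="ks": two-level single factor two-sample Kolmogorov-Smirnov.
    """
    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    if mode in ("ranksum", "ks"):
        if len(factors) != 1:
            raise ValueError(f"{mode} mode takes exactly one factor")
        levels = sorted(data[factors[0]].unique())
        if len(levels) != 2:
            raise ValueError(f"{mode} mode needs exactly two levels")
        a = data.loc[data[factors[0]] == levels[0], value]
        b = data.loc[data[factors[0]] == levels[1], value]
        if mode == "ranksum":
            stat, p = sps.ranksums(a, b)
        else:
            stat, p = sps.ks_2samp(a, b)
        return pd.DataFrame([dict(term=factors[0], statistic=float(stat),
                                  p=float(p), kind=mode)])

    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = data.rename(columns={value: "_y"}).copy()
    rhs = " * ".join(f"C({f})" for f in factors)
    model = ols(f"_y ~ {rhs}", data=df).fit()
    try:
        anova = sm.stats.anova_lm(model, typ=2)
    except ValueError:
        # empty cells in a full factorial: fall back to type-I sums
        anova = sm.stats.anova_lm(model, typ=1)
    rows = [dict(term=str(idx), statistic=float(r["F"]),
                 p=float(r["PR(>F)"]), kind="anova")
            for idx, r in anova.iterrows() if np.isfinite(r.get("F", np.nan))]
    # Tukey post-hoc per single factor
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    for f in factors:
        if df[f].nunique() >= 2:
            tk = pairwise_tukeyhsd(df["_y"], df[f])
            for row in tk.summary().data[1:]:
                rows.append(dict(term=f"tukey:{f}:{row[0]}-{row[1]}",
                                 statistic=float(row[2]), p=float(row[3]),
                                 kind="tukey"))
    return pd.DataFrame(rows)
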