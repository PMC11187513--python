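"""Power analysis and group-comparison statistics.

Sample-size planning for the omnibus fixed-effects one-way ANOVA F test
uses the noncentral F distribution: with k groups, total N and Cohen's
effect size f, the test statistic under the alternative is distributed
F'(k-1, N-k, lambda) with noncentrality lambda = f^2 * N, and

    power = P( F' > F_crit(k-1, N-k, alpha) ).

``required_balanced_n`` searches balanced designs (N a multiple of k,
at least 2 per group) for the smallest N attaining the target power.
A thin standardized-OLS reporter covers the multivariable regression
step (standardized betas, SEs, p values, adjusted R^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PowerSpec",
    "GroupSummary",
    "cohens_f",
    "power_oneway_ncF",
    "required_balanced_n",
    "standardized_regression",
]


@dataclass
class PowerSpec:
    """Design of a balanced k-group omnibus one-way ANOVA F test."""

    k_groups: int
    effect_size_f: float
    alpha: float = 0.05
    target_power: float = 0.90

    def __post_init__(self) -> None:
        if self.k_groups < 2:
            raise ValueError("need at least 2 groups")
        if self.effect_size_f < 0:
            raise ValueError("effect size f must be nonnegative")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.target_power < 1):
            raise ValueError("target power must be in (0, 1)")


@dataclass
class GroupSummary:
    """Per-group n, mean, SD of one variable."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd <= 0:
            raise ValueError("group SD must be positive")


def cohens_f(groups: Sequence[GroupSummary]) -> float:
    """Cohen's f: between-group SD over pooled within-group SD.

    f = sqrt( sum_g n_g (m_g - m.)^2 / N ) / s_pooled, with m. the
    n-weighted grand mean and s_pooled^2 = sum (n_g - 1) sd_g^2 / (N - k).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups])
    sd = np.array([g.sd for g in groups])
    N = n.sum()
    grand = float(np.sum(n * m) / N)
    between = float(np.sqrt(np.sum(n * (m - grand) ** 2) / N))
    pooled_var = float(np.sum((n - 1) * sd**2) / (N - len(groups)))
    if pooled_var <= 0:
        raise ValueError("pooled within-group SD is zero")
    return between / float(np.sqrt(pooled_var))


def power_oneway_ncF(n_total: int, spec: PowerSpec) -> float:
    """Power of the omnibus one-way ANOVA F test at total sample size N.

    Noncentrality lambda = f^2 * N; exact for f = 0, where the
    noncentral F reduces to the central F and power equals alpha.
    """
    if n_total < spec.k_groups + 1:
        raise ValueError("N must exceed the number of groups")
    df1 = spec.k_groups - 1
    df2 = n_total - spec.k_groups
    f_crit = sps.f.isf(spec.alpha, df1, df2)
    lam = spec.effect_size_f**2 * n_total
    if lam == 0.0:
        return float(sps.f.sf(f_crit, df1, df2))
    return float(sps.ncf.sf(f_crit, df1, df2, lam))


def required_balanced_n(spec: PowerSpec, n_cap: int = 100_000) -> int:
    """Smallest balanced total N reaching the target power.

    Balanced means equal allocation: N a multiple of k_groups with at
    least 2 per group.  Raises if the target is unreachable below
    ``n_cap``.
    """
    if spec.effect_size_f <= 0:
        raise ValueError("effect size f must be positive for sample-size search")
    k = spec.k_groups
    n = 2 * k
    while n <= n_cap:
        if power_oneway_ncF(n, spec) >= spec.target_power:
            return n
        n += k
    raise ValueError(
        f"target power {spec.target_power} unreachable with f="
        f"{spec.effect_size_f} below N={n_cap}"
    )


# ---------------------------------------------------------------------------
# Standardized multivariable regression reporter


def standardized_regression(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
):
    """OLS on z-scored response and predictors.

    Complete-case rows only.  Returns (coef_table, adjusted_r2) where
    coef_table has one row per predictor with the standardized beta, its
    SE and two-sided p value.  Raises on rank-deficient designs, naming
    the collinear columns.
    """
    import statsmodels.api as sm

    cols = [response, *predictors]
    data = table[cols].dropna()
    if len(data) < len(predictors) + 2:
        raise ValueError(
            f"need at least {len(predictors) + 2} complete-case rows, "
            f"got {len(data)}"
        )
    z = (data - data.mean()) / data.std(ddof=1)
    if z.isna().any().any():
        bad = [c for c in cols if z[c].isna().any()]
        raise ValueError(f"zero-variance columns: {bad}")

    X = z[list(predictors)].to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < len(predictors):
        involved = [
            p
            for i, p in enumerate(predictors)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {involved}")

    model = sm.OLS(z[response].to_numpy(), sm.add_constant(X))
    fit = model.fit()
    coef = pd.DataFrame(
        {
            "beta": fit.params[1:],
            "se": fit.bse[1:],
            "p": fit.pvalues[1:],
        },
        index=list(predictors),
    )
    return coef, float(fit.rsquared_adj)
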