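"""Equivalence and non-inferiority analysis of two-arm screening outcomes.

The primary safety comparison is the difference in attendance proportions
D = p_I - p_C between the individualised and control arms.  Single-arm
proportions get Wilson score intervals; the difference gets the Newcombe
square-and-add interval built from the two Wilson intervals (no continuity
correction, which reproduces published bounds).  Equivalence requires the
whole CI to lie strictly inside (-delta_eq, +delta_eq) with delta_eq = 0.05;
non-inferiority of disease detection requires the CI lower bound to exceed
-delta_NI with delta_NI = 0.015.

Risk-group subgroup analyses combine per-group Newcombe intervals with a
binomial GLM (logit link) in arm, risk group and their interaction.
Missing outcomes are handled by multiple imputation from a logistic model
on baseline characteristics, pooled by Rubin's rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, t as t_dist

__all__ = [
    "ProportionDiff",
    "Margin",
    "Verdict",
    "wilson_ci",
    "newcombe_diff_ci",
    "equivalence_verdict",
    "noninferiority_verdict",
    "subgroup_analysis",
    "impute_missing",
    "rubin_pool",
    "simple_imputation",
]


@dataclass(frozen=True)
class ProportionDiff:
    """Two-arm counts with the implied difference in proportions."""

    x1: int  # individualised events
    n1: int
    x2: int  # control events
    n2: int
    level: float = 0.95

    def __post_init__(self) -> None:
        for x, n in ((self.x1, self.n1), (self.x2, self.n2)):
            if not 0 <= x <= n:
                raise ValueError("need 0 <= x <= n")
        if not 0 < self.level < 1:
            raise ValueError("confidence level must lie in (0, 1)")

    @property
    def p1(self) -> float:
        return self.x1 / self.n1

    @property
    def p2(self) -> float:
        return self.x2 / self.n2

    @property
    def diff(self) -> float:
        return self.p1 - self.p2


@dataclass(frozen=True)
class Margin:
    """Prespecified margins: equivalence 5%, non-inferiority 1.5%."""

    equivalence: float = 0.05
    noninferiority: float = 0.015

    def __post_init__(self) -> None:
        if self.equivalence <= 0 or self.noninferiority <= 0:
            raise ValueError("margins must be positive")


@dataclass(frozen=True)
class Verdict:
    label: str           # "equivalent" / "non-inferior" / "not-established"
    ci: tuple[float, float]
    margin: float

    @property
    def established(self) -> bool:
        return self.label != "not-established"


def wilson_ci(x, n, level: float = 0.95) -> tuple:
    """Wilson score interval for a binomial proportion (vectorised).

    Centre ``(p + z^2/2n) / (1 + z^2/n)``, half-width
    ``z sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n)``; bounds always in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("n must be positive")
    if np.any((x < 0) | (x > n)):
        raise ValueError("need 0 <= x <= n")
    z = norm.ppf(0.5 + level / 2)
    p = x / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    lower = np.where(x == 0, 0.0, np.clip(centre - half, 0.0, 1.0))
    upper = np.where(x == n, 1.0, np.clip(centre + half, 0.0, 1.0))
    if lower.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def newcombe_diff_ci(pd_: ProportionDiff) -> tuple[float, float, float]:
    """Newcombe square-and-add CI for a difference of two proportions.

    With Wilson bounds (l1, u1) and (l2, u2) for the two arms:
    ``lower = D - sqrt((p1-l1)^2 + (u2-p2)^2)`` and
    ``upper = D + sqrt((u1-p1)^2 + (p2-l2)^2)``.
    Returns ``(D, lower, upper)``.
    """
    l1, u1 = wilson_ci(pd_.x1, pd_.n1, pd_.level)
    l2, u2 = wilson_ci(pd_.x2, pd_.n2, pd_.level)
    d = pd_.diff
    lower = d - np.sqrt((pd_.p1 - l1) ** 2 + (u2 - pd_.p2) ** 2)
    upper = d + np.sqrt((u1 - pd_.p1) ** 2 + (pd_.p2 - l2) ** 2)
    return d, float(lower), float(upper)


def newcombe_diff_ci_arrays(x1, n1, x2, n2, level: float = 0.95):
    """Vectorised Newcombe intervals for stacks of 2x2 tables."""
    x1, n1, x2, n2 = (np.asarray(a, dtype=float) for a in (x1, n1, x2, n2))
    l1, u1 = wilson_ci(x1, n1, level)
    l2, u2 = wilson_ci(x2, n2, level)
    p1, p2 = x1 / n1, x2 / n2
    d = p1 - p2
    lower = d - np.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    upper = d + np.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    return d, lower, upper


def equivalence_verdict(ci: tuple[float, float], m: Margin = Margin()) -> Verdict:
    """Equivalent iff the CI lies strictly inside (-delta_eq, +delta_eq)."""
    lower, upper = ci
    if lower > upper:
        raise ValueError("malformed interval")
    ok = -m.equivalence < lower and upper < m.equivalence
    return Verdict("equivalent" if ok else "not-established", (lower, upper), m.equivalence)


def noninferiority_verdict(ci: tuple[float, float], m: Margin = Margin()) -> Verdict:
    """Non-inferior iff the CI lower bound exceeds -delta_NI (strict)."""
    lower, upper = ci
    if lower > upper:
        raise ValueError("malformed interval")
    ok = lower > -m.noninferiority
    return Verdict(
        "non-inferior" if ok else "not-established", (lower, upper), m.noninferiority
    )


@dataclass
class SubgroupResult:
    per_group: dict                      # group -> (D, lower, upper)
    glm_params: pd.Series
    glm_pvalues: pd.Series
    glm_fitted_props: pd.DataFrame       # (arm, group) -> fitted proportion


def subgroup_analysis(tables: dict, level: float = 0.95) -> SubgroupResult:
    """Per-risk-group Newcombe intervals plus an arm x group interaction GLM.

    ``tables`` maps group label -> ``(x_individualised, n_individualised,
    x_control, n_control)``.  Control participants carry baseline risk-group
    labels from their recorded engine risks.  The GLM is binomial with logit
    link and arm, group and arm:group factors (saturated for the 2 x G
    layout, so fitted proportions reproduce the observed ones exactly).
    Empty groups are skipped with a warning.
    """
    per_group = {}
    rows = []
    for group, (x1, n1, x2, n2) in tables.items():
        if n1 == 0 or n2 == 0:
            warnings.warn(f"risk group {group!r} empty in one arm; skipped", RuntimeWarning)
            continue
        per_group[group] = newcombe_diff_ci(ProportionDiff(x1, n1, x2, n2, level))
        rows.append({"arm": 1, "group": group, "x": x1, "n": n1})
        rows.append({"arm": 0, "group": group, "x": x2, "n": n2})
    df = pd.DataFrame(rows)
    groups = sorted(df["group"].unique())
    X_cols = {"const": np.ones(len(df)), "arm": df["arm"].to_numpy(dtype=float)}
    for g in groups[1:]:
        ind = (df["group"] == g).astype(float).to_numpy()
        X_cols[f"group[{g}]"] = ind
        X_cols[f"arm:group[{g}]"] = ind * df["arm"].to_numpy(dtype=float)
    X = pd.DataFrame(X_cols)
    endog = np.column_stack([df["x"], df["n"] - df["x"]])
    fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    fitted = df[["arm", "group"]].copy()
    fitted["fitted_prop"] = fit.predict(X)
    fitted["observed_prop"] = df["x"] / df["n"]
    return SubgroupResult(
        per_group=per_group,
        glm_params=fit.params,
        glm_pvalues=fit.pvalues,
        glm_fitted_props=fitted,
    )


def impute_missing(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    m: int = 20,
    seed: int | None = None,
) -> list[pd.DataFrame]:
    """Multiple imputation of a binary outcome from baseline characteristics.

    A logistic GLM is fitted on complete cases; for each of the ``m``
    imputations, coefficients are drawn from the approximate normal
    posterior and missing outcomes from the implied Bernoulli (proper
    imputation).  Baseline predictors must be complete.
    """
    if data[predictors].isna().any().any():
        raise ValueError("baseline predictors must be complete")
    rng = np.random.default_rng(seed)
    missing = data[outcome].isna()
    complete = data[~missing]
    X = sm.add_constant(complete[predictors].astype(float), has_constant="add")
    y = complete[outcome].astype(float)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    Xmis = sm.add_constant(
        data.loc[missing, predictors].astype(float), has_constant="add"
    )
    L = np.linalg.cholesky(np.asarray(fit.cov_params()))
    out = []
    for _ in range(m):
        beta = np.asarray(fit.params) + L @ rng.standard_normal(len(fit.params))
        p = 1.0 / (1.0 + np.exp(-(Xmis.to_numpy(dtype=float) @ beta)))
        filled = data.copy()
        filled.loc[missing, outcome] = (rng.random(int(missing.sum())) < p).astype(float)
        out.append(filled)
    return out


def simple_imputation(data: pd.DataFrame, outcome: str, fill: str) -> pd.DataFrame:
    """Deterministic best/worst-case fill-in: ``fill`` is 'all' or 'none'."""
    if fill not in ("all", "none"):
        raise ValueError("fill must be 'all' or 'none'")
    filled = data.copy()
    filled[outcome] = filled[outcome].fillna(1.0 if fill == "all" else 0.0)
    return filled


@dataclass(frozen=True)
class PooledEstimate:
    estimate: float
    variance: float
    within: float
    between: float
    df: float
    ci: tuple[float, float]
    m: int


def rubin_pool(
    estimates, variances, level: float = 0.95
) -> PooledEstimate:
    """Rubin's rules: pooled estimate, total variance W + (1 + 1/m)B, t CI.

    Degrees of freedom follow the classical formula
    ``(m - 1) (1 + W / ((1 + 1/m) B))^2`` (infinite when B = 0).
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = est.size
    if m < 2:
        raise ValueError("pooling needs at least two imputations (B undefined)")
    qbar = float(est.mean())
    W = float(var.mean())
    B = float(est.var(ddof=1))
    total = W + (1 + 1 / m) * B
    if B > 0:
        df = (m - 1) * (1 + W / ((1 + 1 / m) * B)) ** 2
        tq = t_dist.ppf(0.5 + level / 2, df)
    else:
        df = np.inf
        tq = norm.ppf(0.5 + level / 2)
    half = tq * np.sqrt(total)
    return PooledEstimate(
        estimate=qbar,
        variance=total,
        within=W,
        between=B,
        df=float(df),
        ci=(qbar - half, qbar + half),
        m=m,
    )
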