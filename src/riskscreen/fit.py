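"""Maximum-likelihood fitting of the multi-state risk model to panel data.

Screening data are interval-censored panel observations: each participant is
seen at a sequence of visit times and only the state at each visit is
recorded, not the exact transition times.  The likelihood of a consecutive
observation pair (s_i at t_i, s_{i+1} at t_{i+1}) is the transition
probability P[s_i -> s_{i+1}](t_{i+1} - t_i; z_i) from the matrix
exponential of the covariate-specific intensity matrix, and the panel
log-likelihood is the sum of these log-probabilities over all pairs.

Covariate selection uses the small-sample corrected Akaike information
criterion AICc = -2 l + 2k + 2k(k+1)/(n - k - 1), with k the number of free
parameters and n the number of participants, by forward selection from the
empty covariate set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .model import INTENSITY_FLOOR_LOG, MultiStateModel, expm_batch

__all__ = [
    "PanelPairs",
    "FitResult",
    "panel_pairs",
    "panel_loglik",
    "fit_multistate_model",
    "aicc",
    "aicc_select",
]

_LOG_FLOOR = 1e-300


class FitError(RuntimeError):
    """Raised when a fit cannot be set up (not for non-convergence)."""


@dataclass
class PanelPairs:
    """Consecutive-observation pairs extracted from a panel data frame."""

    from_idx: np.ndarray
    to_idx: np.ndarray
    dt: np.ndarray
    Z: np.ndarray            # covariate rows at the pair's first observation
    n_participants: int
    # grouping of identical (dt, Z) rows so each group needs one expm
    group_inverse: np.ndarray = field(default=None)
    group_dt: np.ndarray = field(default=None)
    group_Z: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.group_inverse is None:
            key = np.column_stack([self.dt, self.Z])
            uniq, inv = np.unique(key, axis=0, return_inverse=True)
            self.group_inverse = inv
            self.group_dt = uniq[:, 0]
            self.group_Z = uniq[:, 1:]


def panel_pairs(
    data: pd.DataFrame,
    states: tuple[str, ...],
    covariates: tuple[str, ...] = (),
    id_col: str = "id",
    time_col: str = "time",
    state_col: str = "state",
) -> PanelPairs:
    """Extract consecutive observation pairs from long-format panel data.

    ``data`` holds one row per screening observation with participant id,
    observation time (months), observed state and covariate columns.  Times
    must be strictly increasing within participant.
    """
    df = data.sort_values([id_col, time_col], kind="stable")
    state_code = {s: i for i, s in enumerate(states)}
    codes = df[state_col].map(state_code)
    if codes.isna().any():
        bad = df.loc[codes.isna(), state_col].unique()
        raise FitError(f"unknown state label(s) {list(bad)}")
    ids = df[id_col].to_numpy()
    times = df[time_col].to_numpy(dtype=float)
    codes = codes.to_numpy(dtype=int)
    same = ids[1:] == ids[:-1]
    dt = times[1:] - times[:-1]
    if np.any(same & (dt <= 0)):
        raise FitError("observation times must be strictly increasing within participant")
    Z = (
        df[list(covariates)].to_numpy(dtype=float)
        if covariates
        else np.zeros((len(df), 0))
    )
    keep = same
    if not keep.any():
        raise FitError("need at least two observations for at least one participant")
    return PanelPairs(
        from_idx=codes[:-1][keep],
        to_idx=codes[1:][keep],
        dt=dt[keep],
        Z=Z[:-1][keep],
        n_participants=int(pd.unique(ids).size),
    )


def _log_probabilities(
    params: np.ndarray,
    pairs: PanelPairs,
    trans_idx: np.ndarray,
    n_states: int,
    n_cov: int,
    centering: np.ndarray,
) -> np.ndarray:
    """Per-pair log transition probabilities at parameter vector ``params``."""
    n_trans = trans_idx.shape[0]
    log_q0 = params[:n_trans]
    betas = params[n_trans:].reshape(n_trans, n_cov) if n_cov else np.zeros((n_trans, 0))
    Zc = pairs.group_Z - centering
    log_rates = log_q0[None, :] + Zc @ betas.T
    rates = np.exp(np.clip(log_rates, -700, 50))
    g = rates.shape[0]
    Q = np.zeros((g, n_states, n_states))
    Q[:, trans_idx[:, 0], trans_idx[:, 1]] = rates
    rows = np.arange(n_states)
    Q[:, rows, rows] -= Q.sum(axis=2)
    P = expm_batch(Q, pairs.group_dt)
    p = P[pairs.group_inverse, pairs.from_idx, pairs.to_idx]
    return np.log(np.maximum(p, _LOG_FLOOR))


def panel_loglik(
    params: np.ndarray,
    pairs: PanelPairs,
    trans_idx: np.ndarray,
    n_states: int,
    n_cov: int,
    centering: np.ndarray,
) -> float:
    return float(
        _log_probabilities(params, pairs, trans_idx, n_states, n_cov, centering).sum()
    )


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = x.size
    H = np.zeros((k, k))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return H


@dataclass
class FitResult:
    """A fitted multi-state model with inference byproducts."""

    model: MultiStateModel
    loglik: float
    params: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    param_names: tuple[str, ...]
    n_participants: int
    n_pairs: int
    converged: bool
    message: str
    pinned: tuple[str, ...] = ()

    @property
    def n_params(self) -> int:
        return self.params.size

    def wald_intervals(self, level: float = 0.95) -> pd.DataFrame:
        """Per-parameter Wald confidence intervals on the working scale."""
        z = norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.se,
                "lower": self.params - z * self.se,
                "upper": self.params + z * self.se,
            },
            index=list(self.param_names),
        )

    def aicc(self) -> float:
        return aicc(self.loglik, self.n_params, self.n_participants)


def fit_multistate_model(
    data: pd.DataFrame,
    transitions: tuple[tuple[str, str], ...],
    covariates: tuple[str, ...] = (),
    states: tuple[str, ...] | None = None,
    start_log_intensity: float = -3.0,
    gtol: float = 1e-6,
    max_iter: int = 500,
    compute_se: bool = True,
    **panel_kwargs,
) -> FitResult:
    """Fit the covariate-dependent multi-state model to panel data.

    Optimisation is quasi-Newton (L-BFGS-B) from log-intensity ``-3``
    (about 0.05/month) and zero covariate coefficients, with log-intensities
    bounded below at the floor ``-12``.  An allowed transition with no
    directly observed occurrences is reported as pinned (estimate at the
    floor) with a warning; non-convergence is reported explicitly in the
    returned status, never silently.
    """
    from .model import STATES

    states = tuple(states) if states is not None else STATES
    transitions = tuple((a, b) for a, b in transitions)
    covariates = tuple(covariates)
    pairs = panel_pairs(data, states, covariates, **panel_kwargs)
    state_ix = {s: i for i, s in enumerate(states)}
    trans_idx = np.array([(state_ix[a], state_ix[b]) for a, b in transitions])
    n_states, n_trans, n_cov = len(states), len(transitions), len(covariates)
    centering = pairs.Z.mean(axis=0) if n_cov else np.zeros(0)

    x0 = np.concatenate(
        [np.full(n_trans, start_log_intensity), np.zeros(n_trans * n_cov)]
    )
    bounds = [(INTENSITY_FLOOR_LOG, 8.0)] * n_trans + [(-50.0, 50.0)] * (n_trans * n_cov)

    def nll(x):
        return -panel_loglik(x, pairs, trans_idx, n_states, n_cov, centering)

    res = minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    params = res.x
    loglik = -float(res.fun)
    if not res.success:
        warnings.warn(f"multi-state fit did not converge: {res.message}", RuntimeWarning)

    # transitions never directly observed end up pinned at the floor
    observed = set(zip(pairs.from_idx.tolist(), pairs.to_idx.tolist()))
    pinned = []
    for t, (a, b) in enumerate(transitions):
        if (state_ix[a], state_ix[b]) not in observed or params[t] <= INTENSITY_FLOOR_LOG + 0.1:
            if (state_ix[a], state_ix[b]) not in observed:
                params[t] = INTENSITY_FLOOR_LOG
                pinned.append(f"{a}->{b}")
    if pinned:
        warnings.warn(
            f"no observed transitions for {', '.join(pinned)}; "
            "log-intensity pinned at the floor",
            RuntimeWarning,
        )

    names = [f"logq({a}->{b})" for a, b in transitions] + [
        f"beta({a}->{b}:{c})" for a, b in transitions for c in covariates
    ]
    k = params.size
    if compute_se:
        H = _numeric_hessian(nll, params)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        diag = np.diag(cov).copy()
        diag[diag < 0] = np.nan
        se = np.sqrt(diag)
    else:
        cov = np.full((k, k), np.nan)
        se = np.full(k, np.nan)

    model = MultiStateModel(
        transitions=transitions,
        log_baseline=params[:n_trans].copy(),
        covariates=covariates,
        betas=params[n_trans:].reshape(n_trans, n_cov).copy() if n_cov else None,
        centering=centering.copy() if n_cov else None,
        states=states,
    )
    return FitResult(
        model=model,
        loglik=loglik,
        params=params,
        se=se,
        cov=cov,
        param_names=tuple(names),
        n_participants=pairs.n_participants,
        n_pairs=pairs.dt.size,
        converged=bool(res.success),
        message=str(res.message),
        pinned=tuple(pinned),
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``-2l + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_select(
    data: pd.DataFrame,
    candidates: tuple[str, ...],
    transitions: tuple[tuple[str, str], ...],
    states: tuple[str, ...] | None = None,
    **fit_kwargs,
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Forward covariate selection by AICc.

    Starting from the covariate-free model, the candidate whose addition
    most lowers AICc is added; selection stops when no addition improves.
    Returns the chosen subset and the full audit table of every model
    visited (covariates, k, log-likelihood, AICc).  Candidate models with
    too few participants for AICc are skipped with a warning.
    """
    if not candidates:
        raise ValueError("candidate covariate set must be non-empty")
    fit_kwargs.setdefault("compute_se", False)
    rows = []

    def try_fit(covs: tuple[str, ...]) -> float | None:
        fr = fit_multistate_model(
            data, transitions, covariates=covs, states=states, **fit_kwargs
        )
        try:
            crit = aicc(fr.loglik, fr.n_params, fr.n_participants)
        except ValueError:
            warnings.warn(
                f"model with covariates {covs} skipped: n <= k + 1", RuntimeWarning
            )
            return None
        rows.append(
            {
                "covariates": ",".join(covs) or "(none)",
                "k": fr.n_params,
                "loglik": fr.loglik,
                "aicc": crit,
            }
        )
        return crit

    chosen: tuple[str, ...] = ()
    best = try_fit(chosen)
    if best is None:
        raise FitError("baseline model has too few participants for AICc")
    remaining = list(candidates)
    while remaining:
        scores = []
        for c in remaining:
            crit = try_fit(chosen + (c,))
            if crit is not None:
                scores.append((crit, c))
        if not scores:
            break
        crit, c = min(scores)
        if crit < best:
            best = crit
            chosen = chosen + (c,)
            remaining.remove(c)
        else:
            break
    return chosen, pd.DataFrame(rows)
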