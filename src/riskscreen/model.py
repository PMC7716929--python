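"""Covariate-dependent continuous-time Markov model for screening risk.

The state space describes two-eye retinopathy grading at a screening episode:
``R0R0`` (no retinopathy in either eye), ``R1R0`` (background retinopathy in
one eye), ``R1R1`` (background retinopathy in both eyes) and the absorbing
``SP`` (screen-positive: referable retinopathy/maculopathy, ungradable images
or other significant eye disease).  Transitions between the observable grades
may run in both directions (background retinopathy can regress); once a
person is screen-positive they leave routine recall, so ``SP`` admits no
outgoing transitions.

Each allowed transition r -> s carries an intensity

    q_rs(z) = exp(log q0_rs + beta_rs . (z - c))

where ``z`` is the participant's covariate vector (age, diabetes duration,
HbA1c, systolic BP, total cholesterol, prior-retinopathy flag, ...) and ``c``
a vector of centering constants fixed at model-fitting time.  Transition
probabilities over an interval come from the matrix exponential of the
intensity matrix, and the risk of becoming screen-positive within a horizon
is the corresponding entry of that matrix.

The recall-interval allocation rule compares cumulative screen-positive risk
over 12 and 24 months with a threshold (default 2.5%): a person whose
24-month risk is below the threshold is recalled at 24 months (low risk),
one whose 12-month risk is below it at 12 months (medium risk), and anyone
else at 6 months (high risk).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm as _scipy_expm

__all__ = [
    "STATES",
    "SP",
    "DEFAULT_TRANSITIONS",
    "MultiStateModel",
    "RiskProfile",
    "RiskGroup",
    "intensity_matrix",
    "transition_probabilities",
    "expm_batch",
    "screen_positive_risk",
    "allocate_interval",
    "simple_stratification",
    "default_truth_model",
]

R0R0 = "R0R0"
R1R0 = "R1R0"
R1R1 = "R1R1"
SP = "SP"

STATES: tuple[str, ...] = (R0R0, R1R0, R1R1, SP)

#: Default allowed transition structure: regression between observable
#: grades is permitted ("mixed" Markov structure) and every observable grade
#: has a direct edge into SP (maculopathy can arise without prior background
#: retinopathy in the fellow eye).
DEFAULT_TRANSITIONS: tuple[tuple[str, str], ...] = (
    (R0R0, R1R0),
    (R1R0, R0R0),
    (R1R0, R1R1),
    (R1R1, R1R0),
    (R0R0, SP),
    (R1R0, SP),
    (R1R1, SP),
)

INTENSITY_FLOOR_LOG = -12.0  # log-intensity floor for unobserved transitions


class ModelError(ValueError):
    """Raised for structurally invalid multi-state models."""


@dataclass
class MultiStateModel:
    """A covariate-dependent CTMC over retinopathy states.

    Parameters
    ----------
    transitions
        Ordered allowed transitions ``(from_state, to_state)``.  ``SP`` (the
        last state) must have no outgoing transitions.
    log_baseline
        Baseline log-intensities, one per allowed transition, on the
        per-month scale.
    covariates
        Names of covariates entering the intensities (may be empty).
    betas
        Array of shape ``(n_transitions, n_covariates)`` with log-linear
        covariate effects per transition.
    centering
        Covariate centering constants, shape ``(n_covariates,)``.
    states
        Ordered state labels; the absorbing screen-positive state must be
        last.
    """

    transitions: tuple[tuple[str, str], ...]
    log_baseline: np.ndarray
    covariates: tuple[str, ...] = ()
    betas: np.ndarray | None = None
    centering: np.ndarray | None = None
    states: tuple[str, ...] = STATES

    def __post_init__(self) -> None:
        self.transitions = tuple((a, b) for a, b in self.transitions)
        self.log_baseline = np.asarray(self.log_baseline, dtype=float)
        self.covariates = tuple(self.covariates)
        k = len(self.covariates)
        if self.betas is None:
            self.betas = np.zeros((len(self.transitions), k))
        self.betas = np.asarray(self.betas, dtype=float).reshape(
            len(self.transitions), k
        )
        if self.centering is None:
            self.centering = np.zeros(k)
        self.centering = np.asarray(self.centering, dtype=float).reshape(k)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def absorbing_state(self) -> str:
        return self.states[-1]

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ModelError(f"unknown state {state!r}") from None

    def transition_indices(self) -> np.ndarray:
        """Integer ``(from, to)`` index pairs, shape (n_transitions, 2)."""
        return np.array(
            [(self.state_index(a), self.state_index(b)) for a, b in self.transitions],
            dtype=int,
        ).reshape(len(self.transitions), 2)

    def validate(self) -> None:
        if self.log_baseline.shape != (len(self.transitions),):
            raise ModelError("one baseline log-intensity required per transition")
        absorbing = self.absorbing_state
        for a, b in self.transitions:
            if a == b:
                raise ModelError(f"self-transition {a}->{b} not allowed")
            if a == absorbing:
                raise ModelError(
                    f"absorbing state {absorbing} admits no outgoing transitions"
                )
            self.state_index(a), self.state_index(b)
        if not np.all(np.isfinite(self.betas)):
            raise ModelError("non-finite covariate coefficient")

    # -- evaluation --------------------------------------------------------
    def covariate_row(self, z) -> np.ndarray:
        """Coerce a mapping / Series / sequence to an ordered covariate row."""
        if not self.covariates:
            return np.zeros(0)
        if hasattr(z, "keys") or hasattr(z, "get"):
            row = np.array([float(z[name]) for name in self.covariates])
        else:
            row = np.asarray(z, dtype=float).reshape(len(self.covariates))
        if not np.all(np.isfinite(row)):
            raise ValueError("non-finite covariate value")
        return row

    def intensity_matrix(self, z=None) -> np.ndarray:
        return intensity_matrix(self, z)

    def intensity_matrices(self, Z: np.ndarray) -> np.ndarray:
        """Batch intensity matrices for covariate rows ``Z`` (n, n_cov)."""
        Z = np.asarray(Z, dtype=float).reshape(-1, len(self.covariates))
        if not np.all(np.isfinite(Z)):
            raise ValueError("non-finite covariate value")
        zc = Z - self.centering
        log_rates = self.log_baseline[None, :] + zc @ self.betas.T
        rates = np.exp(log_rates)
        n, m = Z.shape[0], self.n_states
        Q = np.zeros((n, m, m))
        idx = self.transition_indices()
        Q[:, idx[:, 0], idx[:, 1]] = rates
        rows = np.arange(m)
        Q[:, rows, rows] -= Q.sum(axis=2)
        return Q

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "transitions": [list(t) for t in self.transitions],
            "log_baseline": self.log_baseline.tolist(),
            "covariates": list(self.covariates),
            "betas": self.betas.tolist(),
            "centering": self.centering.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "MultiStateModel":
        return cls(
            transitions=tuple(tuple(t) for t in d["transitions"]),
            log_baseline=np.asarray(d["log_baseline"], dtype=float),
            covariates=tuple(d.get("covariates", ())),
            betas=np.asarray(d.get("betas", []), dtype=float)
            if d.get("covariates")
            else None,
            centering=np.asarray(d.get("centering", []), dtype=float)
            if d.get("covariates")
            else None,
            states=tuple(d.get("states", STATES)),
        )

    @classmethod
    def from_json(cls, path) -> "MultiStateModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def intensity_matrix(model: MultiStateModel, z=None) -> np.ndarray:
    """Intensity (rate) matrix Q at covariate vector ``z``.

    Off-diagonal entries are nonzero only on allowed transitions; each row
    sums to zero and the absorbing-state row is all zeros.
    """
    if model.covariates:
        row = model.covariate_row(z if z is not None else {})
        return model.intensity_matrices(row[None, :])[0]
    m = model.n_states
    Q = np.zeros((m, m))
    idx = model.transition_indices()
    Q[idx[:, 0], idx[:, 1]] = np.exp(model.log_baseline)
    rows = np.arange(m)
    Q[rows, rows] -= Q.sum(axis=1)
    return Q


def expm_batch(Qs: np.ndarray, ts: np.ndarray | float) -> np.ndarray:
    """Matrix exponentials ``exp(Q_i * t_i)`` for a stack of rate matrices.

    Uses a batched eigendecomposition (rate matrices are generically
    diagonalisable); any matrix whose reconstructed probability rows fail to
    sum to one (defective or ill-conditioned cases) falls back to
    ``scipy.linalg.expm``.
    """
    Qs = np.asarray(Qs, dtype=float)
    single = Qs.ndim == 2
    if single:
        Qs = Qs[None]
    ts = np.broadcast_to(np.asarray(ts, dtype=float), (Qs.shape[0],))
    if np.any(ts < 0):
        raise ValueError("time must be non-negative")
    A = Qs * ts[:, None, None]
    try:
        w, V = np.linalg.eig(A)
        P = (V * np.exp(w)[:, None, :]) @ np.linalg.inv(V)
        P = P.real
    except np.linalg.LinAlgError:
        P = np.full_like(A, np.nan)
    rowsum_err = np.abs(P.sum(axis=2) - 1.0).max(axis=1)
    bad = ~np.isfinite(rowsum_err) | (rowsum_err > 1e-9) | (P.min(axis=(1, 2)) < -1e-9)
    for i in np.nonzero(bad)[0]:
        P[i] = _scipy_expm(A[i])
    np.clip(P, 0.0, 1.0, out=P)
    return P[0] if single else P


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """Row-stochastic transition probability matrix ``P(t) = exp(Qt)``."""
    if t < 0:
        raise ValueError("time must be non-negative")
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    return expm_batch(Q, float(t))


def screen_positive_risk(
    model: MultiStateModel, state: str, z=None, horizon: float = 24.0
) -> float:
    """Probability of reaching the absorbing screen-positive state.

    Parameters
    ----------
    state
        Current (non-absorbing) retinopathy state.
    horizon
        Risk horizon in months (6, 12 and 24 in routine use).
    """
    if state == model.absorbing_state:
        raise ValueError("risk undefined from the absorbing screen-positive state")
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if horizon == 0:
        return 0.0
    Q = intensity_matrix(model, z)
    P = transition_probabilities(Q, horizon)
    return float(P[model.state_index(state), model.n_states - 1])


@dataclass(frozen=True)
class RiskProfile:
    """Cumulative screen-positive risks over the 6/12/24-month horizons."""

    risk6: float
    risk12: float
    risk24: float

    def __post_init__(self) -> None:
        r = (self.risk6, self.risk12, self.risk24)
        if not all(np.isfinite(r)):
            raise ValueError("non-finite risk")
        if min(r) < -1e-12 or max(r) > 1 + 1e-12:
            raise ValueError("risks must lie in [0, 1]")
        if self.risk6 > self.risk12 + 1e-9 or self.risk12 > self.risk24 + 1e-9:
            raise ValueError("risks must be non-decreasing in horizon (SP absorbing)")


_GROUP_INTERVALS = {"high": 6, "medium": 12, "low": 24}


@dataclass(frozen=True)
class RiskGroup:
    """Risk-group label with its recall interval (high/6, medium/12, low/24)."""

    label: str
    interval_months: int

    def __post_init__(self) -> None:
        if _GROUP_INTERVALS.get(self.label) != self.interval_months:
            raise ValueError("label and interval must correspond (high/6, medium/12, low/24)")


def allocate_interval(rp: RiskProfile, tau: float = 0.025) -> RiskGroup:
    """Allocate a risk group / recall interval against threshold ``tau``.

    The longest horizon whose cumulative risk is strictly below the
    threshold wins: 24 months if ``risk24 < tau``, else 12 months if
    ``risk12 < tau``, else 6 months.  A risk exactly equal to the threshold
    does not qualify for the longer interval.
    """
    if rp.risk24 < tau:
        return RiskGroup("low", 24)
    if rp.risk12 < tau:
        return RiskGroup("medium", 12)
    return RiskGroup("high", 6)


def simple_stratification(previous_state: str, current_state: str) -> int:
    """Two-screen stratification rule used as a comparator.

    Recall at 24 months only when neither of the two most recent screens
    showed any retinopathy in either eye; otherwise recall at 12 months.
    """
    return 24 if previous_state == R0R0 and current_state == R0R0 else 12


def default_truth_model() -> MultiStateModel:
    """A plausible generating model for synthetic screening populations.

    Baseline per-month intensities give roughly: slow incidence of
    background retinopathy from R0R0, regression at a comparable rate,
    medium-risk 24-month screen-positive risk just above the 2.5% threshold
    from R1R0, and a 12-month risk above threshold from R1R1.  Log-linear
    effects of diabetes duration and HbA1c on progression edges induce the
    covariate/risk-group correlation seen in screening populations.
    """
    covs = ("age", "duration", "hba1c", "sbp", "chol")
    trans = DEFAULT_TRANSITIONS
    log_q0 = np.log([0.0045, 0.0040, 0.0030, 0.0025, 0.0002, 0.0015, 0.0040])
    betas = np.zeros((len(trans), len(covs)))
    progression = [0, 2, 4, 5, 6]  # edges toward worse states / SP
    for e in progression:
        betas[e, 1] = 0.030   # per year of diabetes duration
        betas[e, 2] = 0.012   # per mmol/mol HbA1c
        betas[e, 3] = 0.004   # per mmHg systolic BP
        betas[e, 4] = 0.050   # per mmol/l total cholesterol
    betas[:, 0] = -0.002      # slight attenuation with age
    centering = np.array([63.1, 7.0, 51.0, 130.0, 4.0])
    return MultiStateModel(
        transitions=trans,
        log_baseline=log_q0,
        covariates=covs,
        betas=betas,
        centering=centering,
    )
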