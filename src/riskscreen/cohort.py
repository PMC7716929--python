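"""Synthetic screening cohorts: baseline covariates, disease paths, attendance.

No individual-level screening data are publicly deposited for programmes of
this kind, so every downstream stage runs on synthetic participants whose
statistical structure matches what a mature English screening population
looks like: about 81% with no retinopathy in either eye, right-skewed
diabetes duration and HbA1c, roughly 88% type 2 diabetes, and per-arm,
per-risk-group attendance probabilities in the mid 0.7s to mid 0.8s.

Continuous covariates are sampled from truncated-normal or log-normal
families parameterised to reproduce published medians and interquartile
ranges; true disease trajectories are simulated from a covariate-dependent
continuous-time Markov model (exponential holding times, categorical
destination by relative intensity, screen-positive absorbing); attendance
at an invitation is a Bernoulli draw with the arm x risk-group probability,
attended visits occurring uniformly within the 90-day (3-month) window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .model import SP, STATES, MultiStateModel

__all__ = [
    "CovariateSpec",
    "CohortProfile",
    "StatePath",
    "generate_baseline_cohort",
    "sample_progression_path",
    "state_at",
    "sample_attendance",
    "sample_panel",
]

#: Half-width of the attendance window, months (90 days).
ATTENDANCE_WINDOW = 3.0

_IQR_Z = 1.3489795003921634  # 2 * Phi^{-1}(0.75)


class ProfileError(ValueError):
    """Raised for invalid cohort profile configuration."""


@dataclass
class CovariateSpec:
    """Marginal distribution of one continuous covariate.

    ``truncnorm`` uses mean = median and sd = IQR / 1.349 truncated to
    ``[lo, hi]``; ``lognormal`` uses mu = log median and
    sigma = log(q3/q1) / 1.349, clipped to ``[lo, hi]``.
    """

    family: str
    median: float
    q1: float
    q3: float
    lo: float
    hi: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "truncnorm":
            sd = (self.q3 - self.q1) / _IQR_Z
            a = (self.lo - self.median) / sd
            b = (self.hi - self.median) / sd
            return truncnorm.rvs(
                a, b, loc=self.median, scale=sd, size=n, random_state=rng
            )
        if self.family == "lognormal":
            mu = np.log(self.median)
            sigma = np.log(self.q3 / self.q1) / _IQR_Z
            return np.clip(rng.lognormal(mu, sigma, size=n), self.lo, self.hi)
        raise ProfileError(f"unknown covariate family {self.family!r}")


def _default_covariates() -> dict:
    return {
        "age": CovariateSpec("truncnorm", 63.1, 54.9, 70.7, 14.0, 100.0),
        "duration": CovariateSpec("lognormal", 7.0, 4.2, 11.0, 0.25, 70.0),
        "hba1c": CovariateSpec("lognormal", 51.0, 44.0, 62.0, 20.0, 160.0),
        "sbp": CovariateSpec("truncnorm", 130.0, 122.0, 138.0, 80.0, 220.0),
        "chol": CovariateSpec("truncnorm", 4.0, 3.4, 4.7, 1.0, 10.0),
    }


def _default_attendance() -> dict:
    # per (arm, baseline risk group) first-follow-up attendance probabilities
    return {
        ("control", "high"): 0.773,
        ("control", "medium"): 0.817,
        ("control", "low"): 0.857,
        ("individualised", "high"): 0.723,
        ("individualised", "medium"): 0.822,
        ("individualised", "low"): 0.851,
    }


@dataclass
class CohortProfile:
    """Target joint structure of a synthetic screening cohort."""

    state_probs: dict = field(
        default_factory=lambda: {"R0R0": 0.812, "R1R0": 0.124, "R1R1": 0.063}
    )
    covariates: dict = field(default_factory=_default_covariates)
    dm_type_probs: dict = field(
        default_factory=lambda: {"type1": 0.040, "type2": 0.885, "unknown": 0.075}
    )
    attendance: dict = field(default_factory=_default_attendance)
    withdrawal_per_annum: float = 0.06
    prior_retinopathy_given_r0: float = 0.05
    child_fraction: float = 0.002  # aged under 16 at randomisation
    n_clinics: int = 8

    def __post_init__(self) -> None:
        self.validate()
        total = sum(self.state_probs.values())
        self.state_probs = {k: v / total for k, v in self.state_probs.items()}

    def validate(self) -> None:
        probs = list(self.state_probs.values()) + list(self.attendance.values())
        probs += list(self.dm_type_probs.values())
        probs += [self.prior_retinopathy_given_r0, self.child_fraction]
        if any((p < 0) or (p > 1) for p in probs):
            raise ProfileError("probabilities must lie in [0, 1]")
        total = sum(self.state_probs.values())
        if not 0.97 <= total <= 1.03:
            raise ProfileError(f"state probabilities sum to {total:.3f}, not 1")
        if not 0 <= self.withdrawal_per_annum < 1:
            raise ProfileError("withdrawal rate must lie in [0, 1)")

    # monthly hazard such that the per-annum loss fraction is as configured
    @property
    def withdrawal_hazard_monthly(self) -> float:
        return -np.log1p(-self.withdrawal_per_annum) / 12.0

    def attendance_prob(self, arm: str, group: str) -> float:
        try:
            return self.attendance[(arm, group)]
        except KeyError:
            raise ProfileError(f"no attendance probability for {(arm, group)}") from None

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["covariates"] = {k: asdict(v) for k, v in self.covariates.items()}
        d["attendance"] = {f"{a}:{g}": p for (a, g), p in self.attendance.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortProfile":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["covariates"] = {k: CovariateSpec(**v) for k, v in d["covariates"].items()}
        d["attendance"] = {
            tuple(k.split(":")): p for k, p in d["attendance"].items()
        }
        return cls(**d)


def generate_baseline_cohort(
    n: int, profile: CohortProfile | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Generate ``n`` synthetic participants at their baseline screen.

    Returns one row per participant with columns ``id, age, duration,
    hba1c, sbp, chol, dm_type, prior_ret, state0, clinic, age_band``.
    Deterministic given ``seed``; covariate marginals converge to the
    profile targets as ``n`` grows.
    """
    profile = profile or CohortProfile()
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    cols = {"id": np.arange(n)}
    for name, spec in profile.covariates.items():
        cols[name] = spec.sample(n, rng)
    dm_labels = list(profile.dm_type_probs)
    cols["dm_type"] = rng.choice(
        dm_labels, size=n, p=[profile.dm_type_probs[k] for k in dm_labels]
    )
    state_labels = list(profile.state_probs)
    cols["state0"] = rng.choice(
        state_labels, size=n, p=[profile.state_probs[k] for k in state_labels]
    )
    prior = np.where(
        cols["state0"] == "R0R0",
        rng.random(n) < profile.prior_retinopathy_given_r0,
        True,
    )
    cols["prior_ret"] = prior.astype(int)
    cols["clinic"] = rng.integers(0, profile.n_clinics, size=n)
    # a tiny fraction of participants are children (randomised in blocks of 2)
    child = rng.random(n) < profile.child_fraction
    if "age" in cols:
        cols["age"] = np.where(child, rng.uniform(12.0, 15.9, size=n), cols["age"])
    cols["age_band"] = np.where(child, "<16", ">=16")
    df = pd.DataFrame(cols)
    return df


@dataclass(frozen=True)
class StatePath:
    """Right-continuous piecewise-constant trajectory: jump times and states."""

    times: tuple[float, ...]
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states) or not self.times:
            raise ValueError("times and states must align and be non-empty")
        if self.times[0] != 0.0:
            raise ValueError("path must start at time 0")

    def state_at(self, t: float) -> str:
        return state_at(self, t)

    @property
    def sp_time(self) -> float | None:
        """Time of absorption into SP, if reached."""
        for t, s in zip(self.times, self.states):
            if s == SP:
                return t
        return None


def state_at(path: StatePath, t: float) -> str:
    """State occupied at time ``t`` (right-continuous)."""
    i = int(np.searchsorted(np.asarray(path.times), t, side="right")) - 1
    return path.states[max(i, 0)]


def sample_progression_path(
    participant,
    model: MultiStateModel,
    horizon: float,
    rng: np.random.Generator | int | None = None,
) -> StatePath:
    """Simulate one true disease trajectory from the generating model.

    Standard continuous-time simulation: from the current state, the
    holding time is exponential with the total exit rate and the
    destination categorical with probabilities proportional to the
    individual transition intensities; the screen-positive state is
    absorbing.  ``participant`` is a mapping/Series carrying ``state0`` and
    the model's covariate columns.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    state = participant["state0"] if "state0" in participant else participant["state"]
    Q = model.intensity_matrix(participant if model.covariates else None)
    if np.any(Q[np.triu_indices_from(Q, 1)] < 0) or np.any(
        Q[np.tril_indices_from(Q, -1)] < 0
    ):
        raise ValueError("negative transition intensity")
    times = [0.0]
    states = [state]
    t = 0.0
    i = model.state_index(state)
    while True:
        exit_rate = -Q[i, i]
        if exit_rate <= 0:
            break
        t += rng.exponential(1.0 / exit_rate)
        if t >= horizon:
            break
        probs = Q[i].copy()
        probs[i] = 0.0
        probs = probs / exit_rate
        i = rng.choice(model.n_states, p=probs)
        times.append(t)
        states.append(model.states[i])
        if model.states[i] == model.absorbing_state:
            break
    return StatePath(tuple(times), tuple(states))


@dataclass(frozen=True)
class Attendance:
    attended: bool
    actual_time: float | None


def sample_attendance(
    arm: str,
    risk_group: str,
    invitation_time: float,
    profile: CohortProfile,
    rng: np.random.Generator,
) -> Attendance:
    """Bernoulli attendance at an invitation with the arm x group probability.

    Attended visits occur at a uniform time within the 90-day (3-month)
    window after the invitation.
    """
    if invitation_time < 0:
        raise ValueError("invitation time must be non-negative")
    p = profile.attendance_prob(arm, risk_group)
    if rng.random() < p:
        return Attendance(True, invitation_time + rng.uniform(0.0, ATTENDANCE_WINDOW))
    return Attendance(False, None)


def sample_utilities(
    ids,
    times: tuple[float, ...] = (0.0, 12.0, 24.0),
    seed: int | None = None,
    mean: float = 0.82,
    concentration: float = 10.0,
    followup_sd: float = 0.06,
    allow_negative: bool = False,
) -> pd.DataFrame:
    """Synthetic already-valued utility index series (one row per time).

    Baseline utilities are beta-distributed with most mass near full
    health, as preference-based indices (EQ-5D, HUI3) look in screening
    populations; follow-up values are the baseline plus small Gaussian
    perturbations (baseline-correlated), clipped to the instrument range.
    ``allow_negative`` permits states valued worse than dead (HUI3-like).
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(ids)
    a = mean * concentration
    b = (1 - mean) * concentration
    u0 = rng.beta(a, b, size=ids.size)
    lo = -0.36 if allow_negative else 0.0
    rows = []
    for i, pid in enumerate(ids):
        for t in times:
            u = u0[i] if t == 0 else np.clip(u0[i] + rng.normal(0, followup_sd), lo, 1.0)
            rows.append((pid, float(t), float(u)))
    return pd.DataFrame(rows, columns=["id", "time_months", "utility"])


def sample_panel(
    cohort: pd.DataFrame,
    model: MultiStateModel,
    times: tuple[float, ...],
    seed: int | None = None,
) -> pd.DataFrame:
    """Observe simulated true trajectories at fixed visit times.

    Each participant's continuous-time path is simulated from ``model`` and
    read off at the scheduled ``times``, producing the long-format panel
    consumed by :func:`riskscreen.fit.fit_multistate_model`.  Observation
    stops once the absorbing state has been recorded.
    """
    rng = np.random.default_rng(seed)
    times = tuple(float(t) for t in times)
    horizon = max(times) + 1e-9
    cov_cols = list(model.covariates)
    rows = []
    for _, part in cohort.iterrows():
        path = sample_progression_path(part, model, horizon, rng)
        for t in times:
            s = path.state_at(t)
            rows.append((part["id"], t, s, *(part[c] for c in cov_cols)))
            if s == model.absorbing_state:
                break
    return pd.DataFrame(rows, columns=["id", "time", "state", *cov_cols])
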