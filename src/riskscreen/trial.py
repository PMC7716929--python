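"""Two-arm screening-trial simulation.

Participants are randomised 1:1 between annual-recall screening (control)
and individualised variable-interval screening, using stratified permuted
blocks (clinic x age band; random blocks of four and six for adults, two
for children).  The control arm is invited at 12 and 24 months; the
individualised arm is invited at the interval allocated by the risk engine,
recomputed at every attended visit from the observed state and covariates.
Attendance at an invitation is resolved within a 90-day window; true
screen-positive status is read off the simulated disease path at the
attended time; a configured fraction of screen-positive results is
confirmed as sight-threatening retinopathy on clinical examination, and
false positives re-enter the trial.  Withdrawals (consent withdrawal and
loss to follow-up) truncate all later visits.

The simulator emits per-protocol and intention-to-treat analysis sets for
first-follow-up attendance and for confirmed disease within 24 months plus
the window, the inputs of the safety analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import (
    ATTENDANCE_WINDOW,
    CohortProfile,
    sample_progression_path,
)
from .model import MultiStateModel, RiskProfile, allocate_interval, expm_batch

__all__ = [
    "CONTROL",
    "INDIVIDUALISED",
    "RandomisationScheme",
    "TrialConfig",
    "TrialDataset",
    "CountTable",
    "randomise",
    "run_trial",
    "build_analysis_sets",
]

CONTROL = "control"
INDIVIDUALISED = "individualised"

_INTERVAL_TO_GROUP = {6: "high", 12: "medium", 24: "low"}


@dataclass
class RandomisationScheme:
    """Stratified permuted-block randomisation (1:1 allocation).

    Strata are clinic x age band; adults (>=16) use random blocks of four
    and six, children (<16) blocks of two, so that within every completed
    block the arms are exactly balanced.
    """

    block_sizes_adult: tuple[int, ...] = (4, 6)
    block_sizes_child: tuple[int, ...] = (2,)
    seed: int | None = None

    def __post_init__(self) -> None:
        for s in (*self.block_sizes_adult, *self.block_sizes_child):
            if s % 2:
                raise ValueError("block sizes must be even for 1:1 allocation")


def randomise(cohort: pd.DataFrame, scheme: RandomisationScheme) -> pd.Series:
    """Assign arms by stratified permuted blocks; deterministic given seed."""
    for col in ("clinic", "age_band"):
        if col not in cohort.columns:
            raise ValueError(f"cohort must carry a {col!r} stratum column")
    if cohort[["clinic", "age_band"]].isna().any().any():
        raise ValueError("unknown stratum (missing clinic/age band)")
    rng = np.random.default_rng(scheme.seed)
    arms = pd.Series(index=cohort.index, dtype=object)
    # iterate strata in a deterministic order
    strata = cohort.groupby(["clinic", "age_band"], sort=True).indices
    for (clinic, band), idx in strata.items():
        sizes = (
            scheme.block_sizes_child if band == "<16" else scheme.block_sizes_adult
        )
        assigned = []
        while len(assigned) < len(idx):
            size = int(rng.choice(sizes))
            block = [CONTROL] * (size // 2) + [INDIVIDUALISED] * (size // 2)
            rng.shuffle(block)
            assigned.extend(block)
        arms.iloc[idx] = assigned[: len(idx)]
    return arms


@dataclass
class TrialConfig:
    """Tunable parameters of the simulated trial."""

    follow_up_months: float = 24.0
    window_months: float = ATTENDANCE_WINDOW
    econ_extra_window_months: float = ATTENDANCE_WINDOW  # compounding-lag allowance
    tau: float = 0.025
    stdr_confirm_prob: float = 0.8     # P(confirmed STDR | true-path screen-positive)
    false_positive_rate: float = 0.035  # per attended screen, other eye disease
    deviation_rate: float = 0.0         # wrong-interval protocol deviations
    consent_withdrawal_prob: float = 0.006
    withdrawals: bool = True
    itt_missing_as_nonattend: bool = True
    group_probs_override: dict | None = None  # {"high": p, "medium": p, "low": p}

    @property
    def horizon(self) -> float:
        return self.follow_up_months + self.window_months + self.econ_extra_window_months


@dataclass
class TrialDataset:
    """Simulated trial output: participant summaries plus the visit log."""

    participants: pd.DataFrame
    visits: pd.DataFrame
    config: TrialConfig

    def to_csv(self, participants_path, visits_path, manifest_path=None) -> None:
        self.participants.to_csv(participants_path, index=False)
        self.visits.to_csv(visits_path, index=False)
        if manifest_path is not None:
            d = asdict(self.config)
            with open(manifest_path, "w") as fh:
                json.dump(d, fh, indent=2)


def _interval_lookup(
    rce: MultiStateModel, cohort: pd.DataFrame, tau: float
) -> dict[str, np.ndarray]:
    """Recall interval per participant for each possible non-absorbing state.

    Covariates are frozen at baseline, so the 12- and 24-month risk from
    every observable state can be precomputed with two batched matrix
    exponentials per cohort.
    """
    n = len(cohort)
    if rce.covariates:
        Z = cohort[list(rce.covariates)].to_numpy(dtype=float)
        Qs = rce.intensity_matrices(Z)
    else:
        Qs = np.repeat(rce.intensity_matrix()[None], n, axis=0)
    sp = rce.n_states - 1
    P12 = expm_batch(Qs, 12.0)
    P24 = expm_batch(Qs, 24.0)
    out = {}
    for s in rce.states[:-1]:
        i = rce.state_index(s)
        r12, r24 = P12[:, i, sp], P24[:, i, sp]
        interval = np.where(r24 < tau, 24, np.where(r12 < tau, 12, 6))
        out[s] = interval.astype(int)
    return out


def _wrong_interval(correct: int) -> int:
    # deviations observed in practice: longer-interval participants recalled
    # early, one high-risk participant recalled late
    return 12 if correct in (6, 24) else 6


def run_trial(
    cohort: pd.DataFrame,
    assignments: pd.Series,
    rce: MultiStateModel | None,
    truth: MultiStateModel,
    profile: CohortProfile | None = None,
    config: TrialConfig | None = None,
    seed: int | None = None,
) -> TrialDataset:
    """Simulate the trial for an assigned cohort.

    ``rce`` drives interval allocation in the individualised arm (and risk
    recording for controls); ``truth`` generates the underlying disease
    paths.  With ``config.group_probs_override`` set, baseline risk groups
    are drawn from the given probabilities instead of the risk engine and
    remain fixed (calibration mode); otherwise ``rce`` is required.
    """
    profile = profile or CohortProfile()
    config = config or TrialConfig()
    rng = np.random.default_rng(seed)
    if config.group_probs_override is None and rce is None:
        raise ValueError("an rce model is required unless group probabilities are overridden")

    lookup = (
        _interval_lookup(rce, cohort, config.tau) if rce is not None else None
    )
    override = config.group_probs_override
    if override is not None:
        labels = list(override)
        baseline_groups = rng.choice(
            labels, size=len(cohort), p=[override[k] for k in labels]
        )

    hazard = profile.withdrawal_hazard_monthly if config.withdrawals else 0.0
    follow_up = config.follow_up_months
    window = config.window_months
    stdr_cutoff = follow_up + window

    part_rows = []
    visit_rows = []
    for pos, (_, part) in enumerate(cohort.iterrows()):
        pid = part["id"]
        arm = assignments.iloc[pos]
        consent_withdrawn = (
            config.withdrawals and rng.random() < config.consent_withdrawal_prob
        )
        consent_time = rng.uniform(0.0, follow_up) if consent_withdrawn else np.inf
        loss_time = rng.exponential(1.0 / hazard) if hazard > 0 else np.inf
        withdrawal_time = min(consent_time, loss_time)

        path = sample_progression_path(part, truth, config.horizon, rng)
        if override is not None:
            group0 = baseline_groups[pos]
            interval0 = {"high": 6, "medium": 12, "low": 24}[group0]
        else:
            interval0 = int(lookup[part["state0"]][pos])
            group0 = _INTERVAL_TO_GROUP[interval0]

        group = group0
        interval = interval0
        deviation = False
        exited = False
        stdr_time = np.inf
        n_invited = n_attended = 0
        first_attended: float | bool = np.nan  # NaN = unresolved (withdrawn first)
        reset_state: str | None = None  # pre-absorption state after false positive
        reset_time = 0.0

        t_inv = 12.0 if arm == CONTROL else float(interval)
        first = True
        while t_inv <= follow_up + 1e-9 and not exited:
            if withdrawal_time <= t_inv:
                break
            n_invited += 1
            att_group = group0 if arm == CONTROL else group
            p_att = profile.attendance_prob(arm, att_group)
            attended = rng.random() < p_att
            actual = t_inv + rng.uniform(0.0, window) if attended else np.nan
            obs_state = None
            screen_positive = False
            stdr = False
            next_interval = interval
            if attended:
                n_attended += 1
                if reset_state is not None and actual >= reset_time:
                    true_state = reset_state
                else:
                    true_state = path.state_at(actual)
                if true_state == truth.absorbing_state:
                    screen_positive = True
                    pre = next(
                        s for t, s in zip(path.times[::-1], path.states[::-1])
                        if s != truth.absorbing_state
                    )
                    if rng.random() < config.stdr_confirm_prob:
                        stdr = True
                        stdr_time = min(stdr_time, actual)
                        exited = True
                    else:
                        # false positive on clinical examination: re-entered,
                        # truth reset to the pre-absorption state
                        reset_state = pre
                        reset_time = actual
                    obs_state = pre
                else:
                    obs_state = true_state
                    if rng.random() < config.false_positive_rate:
                        screen_positive = True  # other eye disease; re-entered
                if not exited and arm == INDIVIDUALISED:
                    if override is not None:
                        next_interval = interval
                    else:
                        next_interval = int(lookup[obs_state][pos])
                    if config.deviation_rate > 0 and rng.random() < config.deviation_rate:
                        next_interval = _wrong_interval(next_interval)
                        deviation = True
                    group = _INTERVAL_TO_GROUP[next_interval]
            if first:
                first_attended = bool(attended)
                first = False
            visit_rows.append(
                (
                    pid,
                    arm,
                    att_group,
                    round(t_inv, 6),
                    attended,
                    round(actual, 6) if attended else np.nan,
                    obs_state,
                    screen_positive,
                    stdr,
                    next_interval,
                )
            )
            interval = next_interval
            if arm == CONTROL:
                t_inv += 12.0
            else:
                t_inv += float(interval)

        stdr_24 = stdr_time <= stdr_cutoff
        followed_24 = withdrawal_time > stdr_cutoff
        part_rows.append(
            (
                pid,
                arm,
                group0,
                group,
                consent_withdrawn,
                None if not np.isfinite(withdrawal_time) else round(withdrawal_time, 6),
                deviation,
                first_attended,
                stdr_24,
                followed_24,
                n_invited,
                n_attended,
            )
        )

    participants = pd.DataFrame(
        part_rows,
        columns=[
            "id",
            "arm",
            "baseline_group",
            "final_group",
            "consent_withdrawn",
            "withdrawal_time",
            "deviation",
            "first_followup_attended",
            "stdr_within_24m",
            "followed_24m",
            "n_invited",
            "n_attended",
        ],
    )
    visits = pd.DataFrame(
        visit_rows,
        columns=[
            "id",
            "arm",
            "group_at_invitation",
            "invitation_time",
            "attended",
            "actual_time",
            "observed_state",
            "screen_positive",
            "stdr_confirmed",
            "next_interval",
        ],
    )
    # ITT membership: everyone except consent withdrawals; PP additionally
    # excludes protocol deviations and participants whose first follow-up
    # was never resolved (withdrawn before the first invitation)
    participants["itt"] = ~participants["consent_withdrawn"]
    participants["per_protocol"] = (
        participants["itt"]
        & ~participants["deviation"]
        & participants["first_followup_attended"].notna()
    )
    return TrialDataset(participants=participants, visits=visits, config=config)


@dataclass(frozen=True)
class CountTable:
    """Two-by-two events/denominator counts (individualised vs control)."""

    x_individualised: int
    n_individualised: int
    x_control: int
    n_control: int


@dataclass
class AnalysisSets:
    """Per-protocol and intention-to-treat count tables for safety outcomes."""

    attendance: dict = field(default_factory=dict)  # (approach, scope) -> CountTable
    stdr: dict = field(default_factory=dict)

    def table(self, outcome: str, approach: str, scope: str = "overall") -> CountTable:
        store = self.attendance if outcome == "attendance" else self.stdr
        return store[(approach, scope)]


def _counts(df: pd.DataFrame, flag: str) -> tuple[int, int]:
    return int(df[flag].sum()), int(len(df))


def build_analysis_sets(trial: TrialDataset) -> AnalysisSets:
    """Derive the 2x2 count tables consumed by the safety analysis.

    Attendance is assessed at the first follow-up invitation; confirmed
    disease within 24 months plus the 90-day window.  Per-protocol excludes
    protocol deviations and participants withdrawn before their outcome
    could be observed; intention-to-treat keeps every participant who did
    not withdraw consent (unresolved attendance counted as non-attendance
    by default).
    """
    parts = trial.participants
    out = AnalysisSets()
    scopes = {"overall": None, "high": "high", "medium": "medium", "low": "low"}

    for scope, grp in scopes.items():
        base = parts if grp is None else parts[parts["baseline_group"] == grp]

        pp = base[base["per_protocol"]]
        att = pp[pp["first_followup_attended"].notna()].copy()
        att["attended"] = att["first_followup_attended"].astype(bool)
        xi, ni = _counts(att[att["arm"] == INDIVIDUALISED], "attended")
        xc, nc = _counts(att[att["arm"] == CONTROL], "attended")
        out.attendance[("per_protocol", scope)] = CountTable(xi, ni, xc, nc)

        itt = base[base["itt"]].copy()
        if trial.config.itt_missing_as_nonattend:
            itt["attended"] = (itt["first_followup_attended"] == True)  # noqa: E712 (NaN -> False)
        else:
            itt = itt[itt["first_followup_attended"].notna()].copy()
            itt["attended"] = itt["first_followup_attended"].astype(bool)
        xi, ni = _counts(itt[itt["arm"] == INDIVIDUALISED], "attended")
        xc, nc = _counts(itt[itt["arm"] == CONTROL], "attended")
        out.attendance[("itt", scope)] = CountTable(xi, ni, xc, nc)

        pp_stdr = base[
            base["per_protocol"] & (base["followed_24m"] | base["stdr_within_24m"])
        ]
        xi, ni = _counts(pp_stdr[pp_stdr["arm"] == INDIVIDUALISED], "stdr_within_24m")
        xc, nc = _counts(pp_stdr[pp_stdr["arm"] == CONTROL], "stdr_within_24m")
        out.stdr[("per_protocol", scope)] = CountTable(xi, ni, xc, nc)

        itt_stdr = base[base["itt"]]
        xi, ni = _counts(itt_stdr[itt_stdr["arm"] == INDIVIDUALISED], "stdr_within_24m")
        xc, nc = _counts(itt_stdr[itt_stdr["arm"] == CONTROL], "stdr_within_24m")
        out.stdr[("itt", scope)] = CountTable(xi, ni, xc, nc)
    return out
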