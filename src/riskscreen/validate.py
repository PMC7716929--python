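"""Discrimination metrics and optimism correction for the risk engine.

Predicted screen-positive risks are compared with observed outcomes over
each horizon: AUC by rank comparison (ties counted one half), sensitivity
and specificity from the two-by-two table at the allocation threshold, and
a concordance index over all usable pairs.  Optimism correction follows the
standard bootstrap recipe: refit on a resample, evaluate on the original
data, and average the apparent-minus-test difference over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index
from scipy.stats import rankdata

from .fit import fit_multistate_model
from .model import MultiStateModel, expm_batch

__all__ = [
    "ValidationReport",
    "auc_rank",
    "sens_spec",
    "predicted_risks",
    "outcome_table",
    "validate_model",
]


def auc_rank(risks: np.ndarray, outcomes: np.ndarray) -> float:
    """Mann-Whitney AUC: rank comparison of risks between outcome groups.

    Returns NaN when all outcomes are identical (AUC undefined).
    """
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    n1 = int(outcomes.sum())
    n0 = outcomes.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(risks)
    return float((ranks[outcomes].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def sens_spec(risks: np.ndarray, outcomes: np.ndarray, tau: float) -> tuple[float, float]:
    """Sensitivity and specificity of the rule ``risk >= tau``."""
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    positive = risks >= tau
    tp = int((positive & outcomes).sum())
    fn = int((~positive & outcomes).sum())
    tn = int((~positive & ~outcomes).sum())
    fp = int((positive & ~outcomes).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def predicted_risks(
    model: MultiStateModel, states: np.ndarray, Z: np.ndarray, horizon: float
) -> np.ndarray:
    """Batch screen-positive risks for baseline states and covariate rows."""
    Qs = (
        model.intensity_matrices(Z)
        if model.covariates
        else np.repeat(model.intensity_matrix()[None], len(states), axis=0)
    )
    P = expm_batch(Qs, float(horizon))
    state_idx = np.array([model.state_index(s) for s in states])
    return P[np.arange(len(states)), state_idx, model.n_states - 1]


def outcome_table(
    data: pd.DataFrame,
    model: MultiStateModel,
    id_col: str = "id",
    time_col: str = "time",
    state_col: str = "state",
) -> pd.DataFrame:
    """Per-participant baseline state/covariates and screen-positive timing.

    The event time is the first observation in the absorbing state; without
    such an observation the participant is censored at the last visit.
    """
    df = data.sort_values([id_col, time_col], kind="stable")
    absorbing = model.absorbing_state
    first = df.groupby(id_col, sort=False).first()
    last_time = df.groupby(id_col, sort=False)[time_col].max()
    sp = df[df[state_col] == absorbing].groupby(id_col, sort=False)[time_col].min()
    out = first.copy()
    out["event"] = out.index.isin(sp.index)
    out["event_time"] = last_time
    out.loc[sp.index, "event_time"] = sp
    return out.reset_index()


@dataclass
class ValidationReport:
    """Discrimination metrics at each horizon, optionally optimism-corrected."""

    horizons: tuple[float, ...]
    tau: float
    auc: dict = field(default_factory=dict)
    sensitivity: dict = field(default_factory=dict)
    specificity: dict = field(default_factory=dict)
    c_index: float = float("nan")
    auc_corrected: dict = field(default_factory=dict)
    c_index_corrected: float = float("nan")
    n_bootstrap: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.horizons:
            rows.append(
                {
                    "horizon": h,
                    "auc": self.auc.get(h),
                    "sensitivity": self.sensitivity.get(h),
                    "specificity": self.specificity.get(h),
                    "auc_corrected": self.auc_corrected.get(h),
                }
            )
        return pd.DataFrame(rows)


def _apparent_metrics(
    model: MultiStateModel, table: pd.DataFrame, horizons, tau
) -> tuple[dict, dict, dict, float]:
    Z = (
        table[list(model.covariates)].to_numpy(dtype=float)
        if model.covariates
        else np.zeros((len(table), 0))
    )
    states = table["state"].to_numpy()
    aucs, sens, specs = {}, {}, {}
    risk24 = None
    for h in horizons:
        risks = predicted_risks(model, states, Z, h)
        # outcome within horizon is ascertainable: event before h, or
        # followed beyond h without an event
        event_in = table["event"].to_numpy() & (table["event_time"].to_numpy() <= h)
        usable = event_in | (table["event_time"].to_numpy() >= h)
        aucs[h] = auc_rank(risks[usable], event_in[usable])
        s, sp_ = sens_spec(risks[usable], event_in[usable], tau)
        sens[h], specs[h] = s, sp_
        if h == max(horizons):
            risk24 = risks
    cidx = concordance_index(
        table["event_time"].to_numpy(),
        -risk24,
        table["event"].to_numpy().astype(int),
    )
    return aucs, sens, specs, float(cidx)


def validate_model(
    model: MultiStateModel,
    data: pd.DataFrame,
    horizons: tuple[float, ...] = (6.0, 12.0, 24.0),
    tau: float = 0.025,
    n_bootstrap: int = 0,
    transitions: tuple[tuple[str, str], ...] | None = None,
    seed: int | None = None,
    id_col: str = "id",
    **fit_kwargs,
) -> ValidationReport:
    """Validate predicted screen-positive risks against panel outcomes.

    With ``n_bootstrap > 0`` (and the ``transitions`` used to fit the
    model), optimism-corrected AUC and concordance are estimated by
    refitting on bootstrap resamples of participants and averaging the
    apparent-minus-original metric difference.
    """
    table = outcome_table(data, model, id_col=id_col)
    report = ValidationReport(horizons=tuple(horizons), tau=tau)
    aucs, sens, specs, cidx = _apparent_metrics(model, table, horizons, tau)
    report.auc, report.sensitivity, report.specificity = aucs, sens, specs
    report.c_index = cidx

    if n_bootstrap > 0:
        if transitions is None:
            raise ValueError("optimism correction needs the fitting transitions")
        rng = np.random.default_rng(seed)
        ids = data[id_col].unique()
        opt_auc = {h: [] for h in horizons}
        opt_c = []
        for _ in range(n_bootstrap):
            take = rng.choice(ids, size=ids.size, replace=True)
            parts = []
            for j, pid in enumerate(take):
                sub = data[data[id_col] == pid].copy()
                sub[id_col] = j
                parts.append(sub)
            boot = pd.concat(parts, ignore_index=True)
            fr = fit_multistate_model(
                boot,
                transitions,
                covariates=model.covariates,
                states=model.states,
                compute_se=False,
                **fit_kwargs,
            )
            bt = outcome_table(boot, fr.model, id_col=id_col)
            a_b, _, _, c_b = _apparent_metrics(fr.model, bt, horizons, tau)
            a_o, _, _, c_o = _apparent_metrics(fr.model, table, horizons, tau)
            for h in horizons:
                opt_auc[h].append(a_b[h] - a_o[h])
            opt_c.append(c_b - c_o)
        report.auc_corrected = {
            h: aucs[h] - float(np.nanmean(opt_auc[h])) for h in horizons
        }
        report.c_index_corrected = cidx - float(np.mean(opt_c))
        report.n_bootstrap = n_bootstrap
    return report
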