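"""Validation battery for the winning utility model.

Mirrors the three checks run on the study's winning model:

* predictive accuracy — simulate each participant's decisions from their
  fitted parameters (50 sets by default), score the fraction matching the
  observed decisions, and test the group mean against the 9% chance level
  (1/11 options) with a one-sample t test;
* parameter recovery — simulate from a set of generating parameters, refit,
  and correlate generating against recovered values across participants,
  set by set; reported as the mean Pearson r over sets with a percentile CI.
  With synthetic cohorts the generating values are the true parameters,
  which is a stricter, self-contained version of the original
  real-vs-refitted design;
* parameter independence — Pearson correlation between fitted kappa and eta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import DesignSpec, chance_accuracy
from .models import ParamSet, UtilityModelSpec, get_model, utility_matrix, _log_softmax
from .fitting import DegenerateDataError, fit_participant

__all__ = [
    "AccuracyReport",
    "RecoveryReport",
    "ValidationReport",
    "simulate_from_params",
    "predictive_accuracy",
    "parameter_recovery",
    "parameter_independence",
    "validate_winning_model",
    "plot_effects",
]


def _self_error(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials
    if "condition" in t.columns:
        t = t[t["condition"] == "self_error"]
    return t.dropna(subset=["harm", "wrongdoers"])


def _params_row(params: pd.DataFrame, pid) -> ParamSet:
    r = params.loc[pid]
    return ParamSet(
        kappa=float(r.get("kappa", 0.0)),
        eta=float(r.get("eta", 0.0)),
        theta=float(r.get("theta", 0.0)),
        lam=float(r.get("lam", 0.0)),
    )


def simulate_from_params(
    model: str | UtilityModelSpec,
    params: pd.DataFrame,
    trials: pd.DataFrame,
    n_sets: int = 1,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulated decisions for every (participant, trial, set).

    Returns a long DataFrame: participant_id, trial_index, set, harm,
    wrongdoers, responsibility, decision.
    """
    spec = get_model(model)
    rng = np.random.default_rng(seed)
    out = []
    t = _self_error(trials)
    for pid, block in t.groupby("participant_id", sort=False):
        if pid not in params.index:
            continue
        p = _params_row(params, pid)
        H = block["harm"].to_numpy(dtype=float)
        W = block["wrongdoers"].to_numpy(dtype=float)
        P = np.exp(_log_softmax(p.lam, utility_matrix(spec, p.kappa, p.eta, p.theta, H, W)))
        u = rng.random((n_sets, len(H), 1))
        draws = (P[None, :, :].cumsum(axis=2) < u).sum(axis=2)
        for s in range(n_sets):
            out.append(
                pd.DataFrame(
                    dict(
                        participant_id=pid,
                        trial_index=block["trial_index"].to_numpy()
                        if "trial_index" in block
                        else np.arange(1, len(H) + 1),
                        set=s + 1,
                        harm=H.astype(int),
                        wrongdoers=W.astype(int),
                        responsibility=5 - W.astype(int),
                        decision=draws[s],
                    )
                )
            )
    return pd.concat(out, ignore_index=True)


@dataclass
class AccuracyReport:
    per_participant: pd.Series  # accuracy in [0, 1]
    mean: float
    ci: tuple[float, float]  # t-interval across participants
    chance: float
    t_stat: float
    p_value: float
    n_sets: int

    def __repr__(self) -> str:
        return (
            f"<AccuracyReport mean={self.mean:.3f} "
            f"CI=[{self.ci[0]:.3f}, {self.ci[1]:.3f}] chance={self.chance:.3f} "
            f"p={self.p_value:.2g}>"
        )


def predictive_accuracy(
    results, trials: pd.DataFrame, n_sets: int = 50, seed=0, chance: float | None = None
) -> AccuracyReport:
    """Fraction of simulated decisions matching the observed ones.

    ``results`` is a CompensationChoiceResults (or any object with ``spec``
    and ``params``).  Accuracy per participant pools all trial x set draws.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    spec, params = results.spec, results.params
    t = _self_error(trials).dropna(subset=["decision"])
    rng = np.random.default_rng(seed)
    acc = {}
    for pid, block in t.groupby("participant_id", sort=False):
        if pid not in params.index:
            continue
        p = _params_row(params, pid)
        H = block["harm"].to_numpy(dtype=float)
        W = block["wrongdoers"].to_numpy(dtype=float)
        D = block["decision"].to_numpy(dtype=int)
        P = np.exp(_log_softmax(p.lam, utility_matrix(spec, p.kappa, p.eta, p.theta, H, W)))
        u = rng.random((n_sets, len(H), 1))
        draws = (P[None, :, :].cumsum(axis=2) < u).sum(axis=2)
        acc[pid] = float((draws == D[None, :]).mean())
    acc = pd.Series(acc, name="accuracy")
    if chance is None:
        chance = chance_accuracy(DesignSpec())
    n = len(acc)
    mean = float(acc.mean())
    if n > 1:
        sem = acc.std(ddof=1) / np.sqrt(n)
        half = sps.t.ppf(0.975, n - 1) * sem
        tt = sps.ttest_1samp(acc, chance)
        t_stat, p = float(tt.statistic), float(tt.pvalue)
    else:
        half, t_stat, p = np.nan, np.nan, np.nan
    return AccuracyReport(acc, mean, (mean - half, mean + half), chance, t_stat, p, n_sets)


@dataclass
class RecoveryReport:
    r_kappa: float  # mean Pearson r over simulation sets
    r_eta: float
    ci_kappa: tuple[float, float]  # 2.5/97.5 percentile over sets
    ci_eta: tuple[float, float]
    per_set: pd.DataFrame  # set, r_kappa, r_eta
    n_sets: int
    n_failed: int  # participant refits that failed and were dropped

    def __repr__(self) -> str:
        return (
            f"<RecoveryReport r_kappa={self.r_kappa:.3f} "
            f"r_eta={self.r_eta:.3f} sets={self.n_sets}>"
        )


def parameter_recovery(
    model: str | UtilityModelSpec,
    params: pd.DataFrame,
    trials: pd.DataFrame,
    n_sets: int = 50,
    seed=0,
    bounds=None,
    grid_points: int = 5,
) -> RecoveryReport:
    """Simulate from ``params``, refit, and correlate generating vs recovered.

    One Pearson r per simulation set (across participants), summarised as
    the mean over sets with a 95% percentile interval.  Per-set seeds are
    spawned from the master seed.
    """
    spec = get_model(model)
    pids = [p for p in params.index]
    if len(pids) < 3:
        raise ValueError("parameter recovery needs at least 3 participants")
    t = _self_error(trials)
    blocks = {
        pid: (
            block["harm"].to_numpy(dtype=float),
            block["wrongdoers"].to_numpy(dtype=float),
        )
        for pid, block in t.groupby("participant_id", sort=False)
        if pid in params.index
    }
    streams = np.random.SeedSequence(seed).spawn(n_sets)
    rows = []
    n_failed = 0
    for s, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        true_k, true_e, rec_k, rec_e = [], [], [], []
        for pid in pids:
            H, W = blocks[pid]
            p = _params_row(params, pid)
            P = np.exp(
                _log_softmax(p.lam, utility_matrix(spec, p.kappa, p.eta, p.theta, H, W))
            )
            u = rng.random((len(H), 1))
            D = (P.cumsum(axis=1) < u).sum(axis=1)
            try:
                fit = fit_participant(
                    spec, (H, W, D), bounds=bounds, grid_points=grid_points,
                    participant_id=str(pid),
                )
            except DegenerateDataError:
                n_failed += 1
                continue
            true_k.append(p.kappa)
            true_e.append(p.eta)
            rec_k.append(fit.params.kappa)
            rec_e.append(fit.params.eta)
        rk = sps.pearsonr(true_k, rec_k).statistic if len(true_k) >= 3 else np.nan
        re_ = sps.pearsonr(true_e, rec_e).statistic if spec.baseline and len(true_e) >= 3 else np.nan
        rows.append(dict(set=s, r_kappa=rk, r_eta=re_))
    per_set = pd.DataFrame(rows)
    rk = per_set["r_kappa"].to_numpy(dtype=float)
    re_ = per_set["r_eta"].to_numpy(dtype=float)
    return RecoveryReport(
        r_kappa=float(np.nanmean(rk)),
        r_eta=float(np.nanmean(re_)) if spec.baseline else np.nan,
        ci_kappa=tuple(np.nanpercentile(rk, [2.5, 97.5])),
        ci_eta=tuple(np.nanpercentile(re_, [2.5, 97.5])) if spec.baseline else (np.nan, np.nan),
        per_set=per_set,
        n_sets=n_sets,
        n_failed=n_failed,
    )


def parameter_independence(params: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (and two-sided p) between fitted kappa and eta."""
    k = params["kappa"].to_numpy(dtype=float)
    e = params["eta"].to_numpy(dtype=float)
    if len(k) < 3:
        raise ValueError("need at least 3 participants")
    if np.ptp(k) == 0 or np.ptp(e) == 0:
        raise ValueError("correlation undefined for a constant parameter vector")
    r = sps.pearsonr(k, e)
    return float(r.statistic), float(r.pvalue)


@dataclass
class ValidationReport:
    model: str
    accuracy: AccuracyReport
    recovery: RecoveryReport
    independence_r: float
    independence_p: float
    n_simulation_sets: int
    seed: int | None = None

    def to_dict(self) -> dict:
        a, r = self.accuracy, self.recovery
        return dict(
            model=self.model,
            n_simulation_sets=self.n_simulation_sets,
            seed=self.seed,
            accuracy=dict(
                per_participant=a.per_participant.to_dict(),
                mean=a.mean,
                ci=list(a.ci),
                chance=a.chance,
                t_stat=a.t_stat,
                p_value=a.p_value,
            ),
            recovery=dict(
                r_kappa=r.r_kappa,
                r_eta=r.r_eta,
                ci_kappa=list(r.ci_kappa),
                ci_eta=list(r.ci_eta),
                n_failed=r.n_failed,
            ),
            independence=dict(r=self.independence_r, p=self.independence_p),
        )


def validate_winning_model(results, trials, n_sets: int = 50, seed: int = 0) -> ValidationReport:
    """Run the full battery on fitted results for one model."""
    acc = predictive_accuracy(results, trials, n_sets=n_sets, seed=seed)
    rec = parameter_recovery(
        results.spec, results.params, trials, n_sets=n_sets, seed=seed + 1
    )
    try:
        r, p = parameter_independence(results.params)
    except ValueError:
        r, p = np.nan, np.nan
    return ValidationReport(results.spec.id, acc, rec, r, p, n_sets, seed)


def plot_effects(results, seed=0, ax=None):
    """Observed vs simulated mean compensation by harm and by responsibility."""
    import matplotlib.pyplot as plt

    trials = _self_error(results.model.trials).dropna(subset=["decision"])
    sim = simulate_from_params(results.spec, results.params, trials, n_sets=10, seed=seed)
    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(8, 3), sharey=True)
    for a, factor in zip(ax, ("harm", "responsibility")):
        obs = trials.groupby(factor)["decision"].mean()
        pred = sim.groupby(factor)["decision"].mean()
        a.plot(obs.index, obs.values, "o-", label="observed")
        a.plot(pred.index, pred.values, "s--", label="simulated")
        a.set_xlabel(f"{factor} level")
        a.set_ylabel("mean tokens")
        a.legend()
    return ax
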