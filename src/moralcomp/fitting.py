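"""Per-participant maximum-likelihood estimation and BIC model comparison.

The main entry point is the statsmodels-style pair

    model = CompensationChoiceModel(trials, "1.3")
    res = model.fit()
    print(res.summary())

``trials`` is a TrialRecord DataFrame (one or many participants); ``fit``
estimates each participant's free parameters by maximising the softmax
log-likelihood, starting a bounded quasi-Newton (L-BFGS-B) search from the
best point of a coarse lattice over the parameter box.  ``compare_models``
fits all eight model variants and selects the winner by summed BIC across
participants (ties broken toward fewer free parameters).

Participants whose decisions are all zero are excluded from fitting: a
constant-zero allocation makes the sensitivity and baseline parameters
unidentifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import (
    MODEL_IDS,
    ParamSet,
    UtilityModelSpec,
    _trial_arrays,
    default_bounds,
    get_model,
    log_likelihood,
    log_likelihood_grid,
)

__all__ = [
    "FitResult",
    "DegenerateDataError",
    "fit_participant",
    "CompensationChoiceModel",
    "CompensationChoiceResults",
    "ComparisonTable",
    "compare_models",
    "select_winner",
    "FITS_COLUMNS",
]

FITS_COLUMNS = [
    "participant_id",
    "model",
    "kappa",
    "eta",
    "theta",
    "lam",
    "loglik",
    "n_trials",
    "bic",
    "converged",
]


class DegenerateDataError(ValueError):
    """Decisions carry no information about the model parameters."""


@dataclass
class FitResult:
    participant_id: str
    model: str
    params: ParamSet
    log_likelihood: float
    n_trials: int
    converged: bool
    start: ParamSet

    @property
    def bic(self) -> float:
        k = get_model(self.model).k
        return k * np.log(self.n_trials) - 2.0 * self.log_likelihood

    def as_row(self) -> dict:
        p = self.params
        return dict(
            participant_id=self.participant_id,
            model=self.model,
            kappa=p.kappa,
            eta=p.eta,
            theta=p.theta,
            lam=p.lam,
            loglik=self.log_likelihood,
            n_trials=self.n_trials,
            bic=self.bic,
            converged=self.converged,
        )


def _param_grid(spec: UtilityModelSpec, bounds, grid_points: int):
    """Coarse lattice: ``grid_points`` even points per free parameter, with a
    log-spaced lambda axis (plus 0) since likelihood curvature in lambda is
    multiplicative."""
    axes = []
    for name in spec.free_params:
        lo, hi = bounds[name]
        if name == "lam":
            axes.append(np.concatenate([[0.0], np.geomspace(max(lo, 0.1), hi, grid_points)]))
        else:
            axes.append(np.linspace(lo, hi, grid_points))
    mesh = np.meshgrid(*axes, indexing="ij")
    return {n: m.ravel() for n, m in zip(spec.free_params, mesh)}


def fit_participant(
    model: str | UtilityModelSpec,
    trials,
    bounds: dict | None = None,
    grid_points: int = 5,
    tol: float = 1e-6,
    participant_id: str = "",
) -> FitResult:
    """MLE for one participant: coarse-grid initialisation + bounded L-BFGS-B.

    The returned log-likelihood is never below the best grid point's (the
    local search falls back to the grid optimum if it fails to improve).
    """
    spec = get_model(model)
    H, W, D = _trial_arrays(trials)
    if np.all(D == 0):
        raise DegenerateDataError(
            "all decisions are 0; model parameters cannot be reliably estimated"
        )
    bounds = bounds or default_bounds(spec)

    grid = _param_grid(spec, bounds, grid_points)
    ll = log_likelihood_grid(
        spec,
        grid.get("theta", np.zeros_like(grid["kappa"])),
        grid["kappa"],
        grid.get("eta", np.zeros_like(grid["kappa"])),
        grid["lam"],
        H,
        W,
        D,
    )
    best = int(np.argmax(ll))
    x0 = np.array([grid[name][best] for name in spec.free_params])
    ll0 = float(ll[best])
    start = ParamSet.from_array(spec, x0)

    lo = np.array([bounds[n][0] for n in spec.free_params])
    hi = np.array([bounds[n][1] for n in spec.free_params])

    def nll(x):
        return -log_likelihood(spec, ParamSet.from_array(spec, np.clip(x, lo, hi)), (H, W, D))

    box = list(zip(lo, hi))
    res = minimize(nll, x0, method="L-BFGS-B", bounds=box,
                   options={"ftol": tol, "maxiter": 500})
    # the |ideal - D| terms put kinks in the objective; a simplex polish from
    # the quasi-Newton solution cleans up stalls at non-differentiable points
    x1 = np.clip(res.x, lo, hi) if np.isfinite(res.fun) else x0
    polish = minimize(nll, x1, method="Nelder-Mead",
                      options={"xatol": 1e-6, "fatol": tol, "maxiter": 2000})
    cands = [(ll0, x0, True)]
    if np.isfinite(res.fun):
        cands.append((-float(res.fun), np.clip(res.x, lo, hi), bool(res.success)))
    if np.isfinite(polish.fun):
        cands.append((-float(polish.fun), np.clip(polish.x, lo, hi), bool(polish.success)))
    llf, xbest, converged = max(cands, key=lambda c: c[0])
    if llf <= ll0 and len(cands) > 1 and xbest is x0:
        converged = False  # local search never improved on the grid optimum
    params = ParamSet.from_array(spec, xbest)
    return FitResult(
        participant_id=participant_id,
        model=spec.id,
        params=params,
        log_likelihood=llf,
        n_trials=len(D),
        converged=converged,
        start=start,
    )


class CompensationChoiceModel:
    """Softmax utility model of compensation decisions for a cohort.

    Parameters
    ----------
    trials : DataFrame
        TrialRecord layout; only self-error rows with decisions are used.
    model : str or UtilityModelSpec
        One of the eight variants, e.g. ``"1.3"``.
    bounds, grid_points, tol
        Fitting configuration (box bounds, coarse-grid resolution, and the
        objective convergence tolerance of the local search).
    """

    def __init__(self, trials: pd.DataFrame, model="1.3", bounds=None,
                 grid_points: int = 5, tol: float = 1e-6):
        self.spec = get_model(model)
        self.trials = trials
        self.bounds = bounds or default_bounds(self.spec)
        self.grid_points = grid_points
        self.tol = tol

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model="1.3", **kw) -> "CompensationChoiceModel":
        return cls(df, model=model, **kw)

    def _participant_blocks(self):
        t = self.trials
        if "condition" in t.columns:
            t = t[t["condition"] == "self_error"]
        t = t.dropna(subset=["decision"])
        for pid, block in t.groupby("participant_id", sort=False):
            yield pid, block

    def fit(self) -> "CompensationChoiceResults":
        fits, excluded = [], []
        for pid, block in self._participant_blocks():
            try:
                fits.append(
                    fit_participant(
                        self.spec, block, self.bounds, self.grid_points, self.tol,
                        participant_id=str(pid),
                    )
                )
            except DegenerateDataError:
                excluded.append(str(pid))
        if not fits:
            raise DegenerateDataError("no participant could be fitted")
        return CompensationChoiceResults(self, fits, excluded)

    def loglike(self, params: ParamSet, participant_id=None) -> float:
        t = self.trials
        if participant_id is not None:
            t = t[t["participant_id"] == participant_id]
        return log_likelihood(self.spec, params, t)


class CompensationChoiceResults:
    """Fit results for one model over a cohort.

    Attributes
    ----------
    params : DataFrame
        Per-participant estimates (kappa, eta, theta, lam) plus loglik,
        n_trials, bic, converged.
    excluded : list of str
        Participants dropped because every decision was zero.
    """

    def __init__(self, model: CompensationChoiceModel, fits: list[FitResult], excluded):
        self.model = model
        self.spec = model.spec
        self.fits = fits
        self.excluded = list(excluded)
        self.params = (
            pd.DataFrame([f.as_row() for f in fits]).set_index("participant_id")
        )

    @property
    def llf(self) -> float:
        return float(self.params["loglik"].sum())

    @property
    def bic(self) -> float:
        return float(self.params["bic"].sum())

    @property
    def n_participants(self) -> int:
        return len(self.fits)

    def paramset(self, participant_id) -> ParamSet:
        r = self.params.loc[participant_id]
        return ParamSet(kappa=r["kappa"], eta=r["eta"], theta=r["theta"], lam=r["lam"])

    # validation conveniences (implemented in moralcomp.validation)

    def simulate(self, n_sets: int = 1, seed: int | np.random.Generator = 0) -> pd.DataFrame:
        from .validation import simulate_from_params

        return simulate_from_params(
            self.spec, self.params, self.model.trials, n_sets=n_sets, seed=seed
        )

    def predictive_accuracy(self, n_sets: int = 50, seed=0):
        from .validation import predictive_accuracy

        return predictive_accuracy(self, self.model.trials, n_sets=n_sets, seed=seed)

    def parameter_recovery(self, n_sets: int = 50, seed=0):
        from .validation import parameter_recovery

        return parameter_recovery(
            self.spec, self.params, self.model.trials, n_sets=n_sets, seed=seed,
            bounds=self.model.bounds, grid_points=self.model.grid_points,
        )

    def parameter_independence(self):
        from .validation import parameter_independence

        return parameter_independence(self.params)

    def plot_effects(self, seed=0, ax=None):
        from .validation import plot_effects

        return plot_effects(self, seed=seed, ax=ax)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Compensation choice model results",
            "=" * 46,
            f"model id:          {self.spec.id} ({self.spec.family})",
            f"free parameters:   {', '.join(self.spec.free_params)} (k={self.spec.k})",
            f"participants:      {self.n_participants}"
            + (f"  (excluded: {len(self.excluded)})" if self.excluded else ""),
            f"total log-lik:     {self.llf:.2f}",
            f"summed BIC:        {self.bic:.2f}",
            "-" * 46,
            "parameter    mean      sd       min      max",
        ]
        for name in self.spec.free_params:
            col = {"lam": "lam"}.get(name, name)
            v = p[col]
            lines.append(
                f"{name:<10} {v.mean():>7.3f} {v.std():>8.3f} {v.min():>8.3f} {v.max():>8.3f}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<CompensationChoiceResults model={self.spec.id} "
            f"n={self.n_participants} BIC={self.bic:.1f}>"
        )


@dataclass
class ComparisonTable:
    """Group-level BIC comparison across model variants."""

    bic_matrix: pd.DataFrame  # participants x models
    summed_bic: pd.Series
    winner: str
    results: dict[str, CompensationChoiceResults] = field(default_factory=dict)

    @property
    def delta_bic(self) -> pd.Series:
        return self.summed_bic - self.summed_bic.min()

    def summary(self) -> str:
        lines = [
            "Model comparison (summed BIC across participants)",
            "=" * 50,
            f"winner: {self.winner}",
            "-" * 50,
            "model     k   summed BIC     delta BIC",
        ]
        for mid in self.summed_bic.index:
            k = get_model(mid).k
            lines.append(
                f"{mid:<8} {k:>2} {self.summed_bic[mid]:>12.2f} {self.delta_bic[mid]:>12.2f}"
            )
        return "\n".join(lines)


def compare_models(
    trials: pd.DataFrame,
    models=MODEL_IDS,
    bounds=None,
    grid_points: int = 5,
    tol: float = 1e-6,
) -> ComparisonTable:
    """Fit every candidate model and pick the summed-BIC minimiser.

    Ties (within 1e-9) are broken toward the model with fewer free
    parameters.  Raises if any model is missing fits for a participant that
    another model fitted.
    """
    results: dict[str, CompensationChoiceResults] = {}
    for mid in models:
        m = CompensationChoiceModel(trials, mid, bounds=bounds,
                                    grid_points=grid_points, tol=tol)
        results[get_model(mid).id] = m.fit()

    bic_cols = {mid: r.params["bic"] for mid, r in results.items()}
    bic_matrix = pd.DataFrame(bic_cols)
    if bic_matrix.isna().any().any():
        gaps = [
            f"{mid}: {bic_matrix.index[bic_matrix[mid].isna()].tolist()}"
            for mid in bic_matrix.columns
            if bic_matrix[mid].isna().any()
        ]
        raise ValueError("missing fits — " + "; ".join(gaps))
    summed = bic_matrix.sum(axis=0)
    return ComparisonTable(bic_matrix, summed, select_winner(summed), results)


def select_winner(summed_bic: pd.Series) -> str:
    """Summed-BIC minimiser; ties (within 1e-9) go to fewer free parameters."""
    lowest = summed_bic.min()
    tied = [mid for mid in summed_bic.index if summed_bic[mid] <= lowest + 1e-9]
    return min(tied, key=lambda mid: (get_model(mid).k, mid))
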