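"""Softmax utility models of compensatory decision-making.

Eight candidate utilities U(D) for allocating D of 10 tokens to a harmed
receiver, organised in two families that differ in how harm H (1-4) and the
number of wrongdoers W (1-4) are integrated:

* diffusion family (1.x): the attributed harm is the per-wrongdoer share
  H/W — responsibility is diluted across wrongdoers;
* amplification family (2.x): responsibility R = 5 - W multiplies harm, H*R.

Within each family the variants toggle a self-interest (greed) term and a
compensatory baseline:

    x.1:  U(D) = theta*(10 - D) - (1 - theta)*|kappa*A + eta - D|
    x.2:  U(D) = theta*(10 - D) - (1 - theta)*|kappa*A - D|
    x.3:  U(D) = -|kappa*A + eta - D|
    x.4:  U(D) = -|kappa*A - D|

with A = H/W (family 1) or H*R (family 2).  kappa is compensatory
sensitivity (tokens per unit attributed harm), eta the compensatory baseline
(tokens), theta the greed weight in [0, 1].  Choices follow a softmax over
the 11 options with inverse temperature lambda >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UtilityModelSpec",
    "ParamSet",
    "MODELS",
    "MODEL_IDS",
    "get_model",
    "default_bounds",
    "utility",
    "choice_probabilities",
    "log_likelihood",
    "N_OPTIONS",
    "OPTIONS",
]

OPTIONS = np.arange(11)
N_OPTIONS = 11

_PARAM_ORDER = ("theta", "kappa", "eta", "lam")


@dataclass(frozen=True)
class UtilityModelSpec:
    """One of the eight model variants."""

    id: str
    family: str  # "diffusion" or "amplification"
    self_interest: bool
    baseline: bool

    @property
    def free_params(self) -> tuple[str, ...]:
        names = []
        if self.self_interest:
            names.append("theta")
        names.append("kappa")
        if self.baseline:
            names.append("eta")
        names.append("lam")
        return tuple(names)

    @property
    def k(self) -> int:
        """Number of free parameters (lambda always counted)."""
        return len(self.free_params)


def _registry() -> dict[str, UtilityModelSpec]:
    out = {}
    for fam_idx, family in (("1", "diffusion"), ("2", "amplification")):
        for var, (self_int, base) in {
            "1": (True, True),
            "2": (True, False),
            "3": (False, True),
            "4": (False, False),
        }.items():
            mid = f"{fam_idx}.{var}"
            out[mid] = UtilityModelSpec(mid, family, self_int, base)
    return out


MODELS: dict[str, UtilityModelSpec] = _registry()
MODEL_IDS: tuple[str, ...] = tuple(MODELS)


def get_model(model: str | UtilityModelSpec) -> UtilityModelSpec:
    if isinstance(model, UtilityModelSpec):
        return model
    try:
        return MODELS[str(model)]
    except KeyError:
        raise KeyError(f"unknown model id {model!r}; choose from {MODEL_IDS}") from None


def default_bounds(spec: UtilityModelSpec) -> dict[str, tuple[float, float]]:
    """Box bounds keeping the ideal point kappa*A + eta near the 0-10 range.

    The amplification family's attributed harm H*R reaches 16, so its kappa
    bound is scaled down accordingly.
    """
    kappa_hi = 10.0 if spec.family == "diffusion" else 2.5
    return {
        "theta": (0.0, 1.0),
        "kappa": (0.0, kappa_hi),
        "eta": (0.0, 10.0),
        "lam": (0.0, 20.0),
    }


@dataclass(frozen=True)
class ParamSet:
    """Participant-level parameters; unused ones stay at their neutral value."""

    kappa: float
    lam: float
    eta: float = 0.0
    theta: float = 0.0

    def as_array(self, spec: UtilityModelSpec) -> np.ndarray:
        return np.array([getattr(self, name) for name in spec.free_params])

    @classmethod
    def from_array(cls, spec: UtilityModelSpec, values) -> "ParamSet":
        kw = dict(zip(spec.free_params, np.asarray(values, dtype=float)))
        return cls(
            kappa=kw["kappa"],
            lam=kw["lam"],
            eta=kw.get("eta", 0.0),
            theta=kw.get("theta", 0.0),
        )

    def validate(self, spec: UtilityModelSpec, bounds=None) -> None:
        bounds = bounds or default_bounds(spec)
        for name in spec.free_params:
            lo, hi = bounds[name]
            v = getattr(self, name)
            if name == "lam" and np.isinf(v) and v > 0:
                continue  # lam = inf is the documented deterministic limit
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")


def attributed_harm(spec: UtilityModelSpec, H, W):
    """H/W for the diffusion family, H*(5 - W) for the amplification family."""
    H = np.asarray(H, dtype=float)
    W = np.asarray(W, dtype=float)
    if spec.family == "diffusion":
        return H / W
    return H * (5.0 - W)


def utility_matrix(spec, kappa, eta, theta, H, W, options=OPTIONS):
    """U(D) over all options; broadcasts over trials and parameter arrays.

    Shapes: ``kappa``/``eta``/``theta`` broadcast against ``H``/``W``; one
    option axis is appended, giving ``(..., n_trials, n_options)``.
    """
    A = attributed_harm(spec, H, W)
    ideal = np.asarray(kappa)[..., None] * A + np.asarray(eta)[..., None]
    D = np.asarray(options, dtype=float)
    aversion = -np.abs(ideal[..., None] - D)
    if spec.self_interest:
        theta = np.asarray(theta)[..., None, None]
        return theta * (10.0 - D) + (1.0 - theta) * aversion
    return aversion


def utility(
    model: str | UtilityModelSpec, params: ParamSet, H, W, D=None, options=OPTIONS
):
    """U(D) for one (H, W); over all options when ``D`` is None."""
    spec = get_model(model)
    U = utility_matrix(
        spec, params.kappa, params.eta, params.theta, np.atleast_1d(H), np.atleast_1d(W), options
    )[0]
    if D is None:
        return U
    D = int(D)
    opts = list(np.asarray(options))
    if D not in opts:
        raise ValueError(f"decision {D} outside the option set {opts[0]}..{opts[-1]}")
    return float(U[opts.index(D)])


def _log_softmax(lam, U):
    lam_arr = np.asarray(lam, dtype=float)
    if lam_arr.ndim == 0 and np.isinf(lam_arr):
        # deterministic limit: the softmax converges to the uniform
        # distribution over the argmax set (exact utility ties split evenly)
        best = U.max(axis=-1, keepdims=True)
        mask = U >= best - 1e-12
        with np.errstate(divide="ignore"):
            return np.log(mask / mask.sum(axis=-1, keepdims=True))
    z = lam_arr[..., None, None] * U
    z = z - z.max(axis=-1, keepdims=True)  # overflow-safe for large lam*U
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def choice_probabilities(
    model: str | UtilityModelSpec, params: ParamSet, H, W, options=OPTIONS
) -> np.ndarray:
    """Softmax choice distribution P(D) over the option set at one (H, W)."""
    spec = get_model(model)
    U = utility_matrix(
        spec, params.kappa, params.eta, params.theta, np.atleast_1d(H), np.atleast_1d(W), options
    )
    return np.exp(_log_softmax(params.lam, U))[0]


def _trial_arrays(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        t = trials
        if "condition" in t.columns:
            t = t[t["condition"] == "self_error"]
        t = t.dropna(subset=["decision"])
        H = t["harm"].to_numpy(dtype=float)
        W = t["wrongdoers"].to_numpy(dtype=float)
        D = t["decision"].to_numpy(dtype=int)
    else:
        H, W, D = (np.asarray(a) for a in trials)
    if len(H) == 0:
        raise ValueError("no self-error trials with decisions")
    return H, W, D


def log_likelihood(
    model: str | UtilityModelSpec, params: ParamSet, trials, options=OPTIONS
) -> float:
    """Summed log P(D_t) of the observed decisions under the softmax rule.

    ``trials`` is either a TrialRecord DataFrame (self-error rows with
    decisions are selected) or an ``(H, W, D)`` triple of arrays.
    """
    spec = get_model(model)
    H, W, D = _trial_arrays(trials)
    U = utility_matrix(spec, params.kappa, params.eta, params.theta, H, W, options)
    logp = _log_softmax(params.lam, U)
    return float(logp[np.arange(len(D)), D].sum())


def log_likelihood_grid(
    spec: UtilityModelSpec, theta_grid, kappa_grid, eta_grid, lam_grid, H, W, D,
    options=OPTIONS,
) -> np.ndarray:
    """Log-likelihood at every point of a parameter lattice (vectorised).

    ``*_grid`` are 1-D arrays of equal length G (already expanded to the
    cartesian product by the caller); returns shape (G,).
    """
    U = utility_matrix(spec, np.asarray(kappa_grid), np.asarray(eta_grid),
                       np.asarray(theta_grid), H, W, options)
    logp = _log_softmax(np.asarray(lam_grid), U)
    return logp[..., np.arange(len(D)), D].sum(axis=-1)
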