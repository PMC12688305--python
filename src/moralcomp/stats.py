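"""Behavioral statistics: manipulation checks, emotion and compensation
mixed-effects regressions, sensitivity extraction, dependent-correlation
tests, bootstrap mediation, and trait correlations.

Mixed models are linear mixed-effects regressions (statsmodels MixedLM,
fitted by ML) with participant-specific random intercepts and random slopes
for each fixed effect.  If the full correlated random structure does not
converge the fit falls back to independent (diagonal) random slopes, then to
a random intercept only, and — for noise-free degenerate data with zero
residual variance — to plain OLS; the fallback used is recorded on the
result.  Fixed-effect tests use the normal approximation for p-values.

Emotion type is coded guilt=1, shame=0 throughout, so a predictor-by-type
interaction coefficient equals the guilt slope minus the shame slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "PairedComparison",
    "manipulation_check",
    "emotions_to_long",
    "merge_emotions",
    "EmotionRegressionResult",
    "emotion_regression",
    "CompensationRegressionResult",
    "compensation_regression",
    "extract_sensitivities",
    "dependent_correlation_test",
    "MediationResult",
    "bootstrap_mediation",
    "trait_correlations",
]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA (pairwise, paired-differences formulation)


@dataclass
class PairedComparison:
    level_a: object
    level_b: object
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


def manipulation_check(
    ratings: pd.DataFrame,
    level_col: str,
    value_col: str = "rating",
    comparisons: list[tuple] | None = None,
) -> pd.DataFrame:
    """Pairwise repeated-measures ANOVA across rating levels.

    For a two-level within-subject comparison the ANOVA F equals the squared
    paired t, so each row is computed from the paired differences:
    F = t^2 with (1, n-1) df and partial eta^2 = F / (F + df2).

    ``comparisons`` defaults to adjacent level pairs in sorted order.
    Missing cells raise with the offending participant ids.
    """
    wide = ratings.pivot_table(
        index="participant_id", columns=level_col, values=value_col, aggfunc="mean"
    )
    if comparisons is None:
        levels = sorted(wide.columns, key=str)
        comparisons = list(zip(levels, levels[1:]))
    rows = []
    for a, b in comparisons:
        pair = wide[[a, b]]
        missing = pair.index[pair.isna().any(axis=1)].tolist()
        if missing:
            raise ValueError(f"missing ratings for comparison {a} vs {b}: {missing}")
        d = (pair[b] - pair[a]).to_numpy(dtype=float)
        n = len(d)
        df2 = n - 1
        sd = d.std(ddof=1)
        if sd == 0:
            F = 0.0 if np.allclose(d, 0) else np.inf
        else:
            t = d.mean() / (sd / np.sqrt(n))
            F = t * t
        p = float(sps.f.sf(F, 1, df2)) if np.isfinite(F) else 0.0
        peta = float(F / (F + df2)) if np.isfinite(F) else 1.0
        rows.append(PairedComparison(a, b, float(F), 1, df2, p, peta))
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# data reshaping


def emotions_to_long(emotions: pd.DataFrame) -> pd.DataFrame:
    """Per-cell guilt/shame ratings to long format with etype guilt=1, shame=0."""
    long = emotions.melt(
        id_vars=["participant_id", "harm", "responsibility"],
        value_vars=["guilt", "shame"],
        var_name="emotion",
        value_name="rating",
    )
    long["etype"] = (long["emotion"] == "guilt").astype(float)
    return long


def merge_emotions(trials: pd.DataFrame, emotions: pd.DataFrame) -> pd.DataFrame:
    """Broadcast each (harm, responsibility) cell's survey ratings onto the
    self-error trials of that cell."""
    t = trials[trials["condition"] == "self_error"].dropna(subset=["decision"]).copy()
    for c in ("harm", "responsibility", "decision"):
        t[c] = t[c].astype(int)
    return t.merge(emotions, on=["participant_id", "harm", "responsibility"], how="left")


# ---------------------------------------------------------------------------
# mixed-model machinery


def _ols_degenerate(formula: str, df: pd.DataFrame):
    """OLS fit; returns the result when residual variance is ~0 (noise-free
    data, where a mixed model is singular), else None."""
    res = smf.ols(formula, data=df).fit()
    if res.resid.std() < 1e-8:
        return res
    return None


def _fit_mixed(formula: str, df: pd.DataFrame, re_cols: list[str]):
    """Fit MixedLM (ML) with a fallback chain on the random structure.

    Returns (result, fallback_label) with labels 'full', 'diagonal',
    'intercept', 'ols'.
    """
    ols = _ols_degenerate(formula, df)
    if ols is not None:
        return ols, "ols"

    attempts = [
        ("full", dict(re_formula="~" + " + ".join(re_cols))),
        (
            "diagonal",
            dict(re_formula="1", vc_formula={c: f"0 + {c}" for c in re_cols}),
        ),
        ("intercept", dict(re_formula="1")),
    ]
    if not re_cols:
        attempts = attempts[-1:]
    last_err = None
    for label, kw in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = smf.mixedlm(formula, data=df, groups=df["participant_id"], **kw)
                res = mod.fit(reml=False, method="lbfgs", maxiter=200)
            if res.converged and np.isfinite(res.params).all():
                return res, label
        except Exception as err:  # singular/LinAlg problems -> next structure
            last_err = err
    # last resort: plain OLS, flagged
    ols = smf.ols(formula, data=df).fit()
    if last_err is not None and not np.isfinite(ols.params).all():
        raise last_err
    return ols, "ols"


def _coef_table(res) -> pd.DataFrame:
    names = list(res.fe_params.index) if hasattr(res, "fe_params") else list(res.params.index)
    est = res.fe_params if hasattr(res, "fe_params") else res.params
    cov = res.cov_params().loc[names, names]
    se = np.sqrt(np.diag(cov))
    z = est.to_numpy() / se
    p = 2 * sps.norm.sf(np.abs(z))
    return pd.DataFrame({"estimate": est.to_numpy(), "se": se, "z": z, "p": p}, index=names)


def _contrast(res, weights: dict[str, float]) -> tuple[float, float]:
    """Estimate and SE of a linear contrast of fixed effects."""
    names = list(res.fe_params.index) if hasattr(res, "fe_params") else list(res.params.index)
    est = res.fe_params if hasattr(res, "fe_params") else res.params
    cov = res.cov_params().loc[names, names].to_numpy()
    c = np.array([weights.get(n, 0.0) for n in names])
    val = float(c @ est.to_numpy())
    se = float(np.sqrt(c @ cov @ c))
    return val, se


# ---------------------------------------------------------------------------
# emotion regressions


@dataclass
class EmotionRegressionResult:
    predictor: str
    coefficients: pd.DataFrame  # fixed effects: estimate, se, z, p
    interaction: dict  # estimate (beta_guilt - beta_shame), se, z, p
    simple_slopes: pd.DataFrame  # per emotion type: slope, se, z, p
    fallback: str
    result: object = field(repr=False)  # underlying statsmodels result
    data: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"Emotion mixed regression — rating ~ {self.predictor} * type "
            f"(random structure: {self.fallback})",
            self.coefficients.round(4).to_string(),
            f"interaction (guilt - shame slope): "
            f"{self.interaction['estimate']:.4f} "
            f"(se {self.interaction['se']:.4f}, p {self.interaction['p']:.4g})",
            "simple slopes:",
            self.simple_slopes.round(4).to_string(),
        ]
        return "\n".join(lines)


def emotion_regression(
    emotions: pd.DataFrame, predictor: str = "harm"
) -> EmotionRegressionResult:
    """Regress emotion ratings on a level predictor, emotion type, and their
    interaction (random intercept + slopes per participant).

    ``predictor`` is ``"harm"``, ``"responsibility"``, or ``"full"`` (harm,
    responsibility, type, and all interactions).  Levels enter numerically
    (1-4), and with guilt coded 1 the interaction coefficient equals the
    guilt slope minus the shame slope; simple slopes per type come from the
    same fit.
    """
    long = emotions_to_long(emotions) if "rating" not in emotions.columns else emotions.copy()
    if predictor == "full":
        long["hr"] = long["harm"] * long["responsibility"]
        long["he"] = long["harm"] * long["etype"]
        long["re_"] = long["responsibility"] * long["etype"]
        long["hre"] = long["harm"] * long["responsibility"] * long["etype"]
        fixed = ["harm", "responsibility", "etype", "hr", "he", "re_", "hre"]
        formula = "rating ~ " + " + ".join(fixed)
        res, fb = _fit_mixed(formula, long, fixed)
        coef = _coef_table(res)
        inter_rows = {}
        for term, label in (("he", "harm_x_type"), ("re_", "responsibility_x_type")):
            est, se = _contrast(res, {term: 1.0})
            z = est / se if se > 0 else np.inf * np.sign(est)
            inter_rows[label] = dict(estimate=est, se=se, z=z, p=2 * sps.norm.sf(abs(z)))
        slopes = []
        for x, term in (("harm", "he"), ("responsibility", "re_")):
            for emo, w in (("guilt", 1.0), ("shame", 0.0)):
                est, se = _contrast(res, {x: 1.0, term: w})
                z = est / se if se > 0 else np.inf * np.sign(est)
                slopes.append(dict(predictor=x, emotion=emo, slope=est, se=se, z=z,
                                   p=2 * sps.norm.sf(abs(z))))
        return EmotionRegressionResult(
            "full", coef, inter_rows, pd.DataFrame(slopes), fb, res, long
        )

    if predictor not in ("harm", "responsibility"):
        raise ValueError("predictor must be 'harm', 'responsibility' or 'full'")
    long["x_etype"] = long[predictor] * long["etype"]
    fixed = [predictor, "etype", "x_etype"]
    formula = "rating ~ " + " + ".join(fixed)
    res, fb = _fit_mixed(formula, long, fixed)
    coef = _coef_table(res)
    est, se = _contrast(res, {"x_etype": 1.0})
    z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
    interaction = dict(estimate=est, se=se, z=z, p=2 * sps.norm.sf(abs(z)) if se > 0 else 0.0)
    slopes = []
    for emo, w in (("guilt", 1.0), ("shame", 0.0)):
        s, s_se = _contrast(res, {predictor: 1.0, "x_etype": w})
        sz = s / s_se if s_se > 0 else np.inf * np.sign(s)
        slopes.append(dict(emotion=emo, slope=s, se=s_se, z=sz,
                           p=2 * sps.norm.sf(abs(sz)) if s_se > 0 else 0.0))
    return EmotionRegressionResult(
        predictor, coef, interaction, pd.DataFrame(slopes).set_index("emotion"), fb, res, long
    )


# ---------------------------------------------------------------------------
# compensation regressions (models I-IV)


COMP_MODELS = {
    "I": ["guilt"],
    "II": ["shame"],
    "III": ["guilt", "shame"],
    "IV": ["guilt", "shame", "guilt_shame"],
}


def _mixed_bic(res, n_obs: int) -> float:
    """BIC = k ln N - 2 llf with k = fixed + covariance parameters (ML fit)."""
    k = len(res.params) + 1  # + residual variance (profiled out of params)
    return float(k * np.log(n_obs) - 2.0 * res.llf)


@dataclass
class CompensationRegressionResult:
    bic: pd.Series  # per model I..IV
    winner: str
    coefficients: pd.DataFrame  # winner's fixed effects
    wald_chi2: float  # 1-df test of guilt == shame coefficient (model III)
    wald_p: float
    fallbacks: dict[str, str]
    results: dict[str, object] = field(repr=False)
    data: pd.DataFrame = field(repr=False, default=None)

    def summary(self) -> str:
        return "\n".join(
            [
                "Compensation mixed regressions (BIC, ML)",
                self.bic.round(2).to_string(),
                f"winner: {self.winner}",
                self.coefficients.round(4).to_string(),
                f"Wald chi2(1) guilt vs shame: {self.wald_chi2:.3f} (p {self.wald_p:.4g})",
            ]
        )


def compensation_regression(data: pd.DataFrame) -> CompensationRegressionResult:
    """Fit the four candidate mixed models of compensation and select by BIC.

    ``data`` carries one row per self-error trial with that trial's cell
    guilt and shame ratings (see :func:`merge_emotions`).  All models share
    the outcome (tokens given) and the random structure (participant
    intercept + slopes for each fixed effect); they differ only in fixed
    effects: I guilt; II shame; III guilt + shame; IV adds the interaction.
    The guilt-vs-shame coefficient comparison is a 1-df Wald chi-square on
    the contrast of the two coefficients in the model containing both.
    """
    df = data.copy()
    df["decision"] = df["decision"].astype(float)
    df["guilt_shame"] = df["guilt"] * df["shame"]
    results, fallbacks, bics = {}, {}, {}
    for mid, fixed in COMP_MODELS.items():
        formula = "decision ~ " + " + ".join(fixed)
        res, fb = _fit_mixed(formula, df, fixed)
        results[mid] = res
        fallbacks[mid] = fb
        bics[mid] = _mixed_bic(res, len(df))
    bic = pd.Series(bics)
    winner = bic.idxmin()
    coef = _coef_table(results[winner])
    est, se = _contrast(results["III"], {"guilt": 1.0, "shame": -1.0})
    if se > 1e-10:
        chi2 = (est / se) ** 2
    else:  # exchangeable/degenerate columns: no evidence of a difference
        chi2 = 0.0 if abs(est) < 1e-8 else np.inf
    p = float(sps.chi2.sf(chi2, 1))
    return CompensationRegressionResult(bic, winner, coef, float(chi2), p, fallbacks, results, df)


# ---------------------------------------------------------------------------
# per-participant sensitivities


def _participant_slopes_mixed(res, fallback, data, outcome, terms, extract=None):
    """Per-participant coefficient for each term in ``extract`` (default all
    of ``terms``): fixed effect + BLUP when the full random structure was
    fitted, else per-participant OLS over the complete fixed design
    (flagged by the caller through ``fallback``)."""
    extract = list(extract or terms)
    pids = data["participant_id"].unique()
    if fallback == "full":
        fe = res.fe_params
        re = res.random_effects
        out = {}
        for pid in pids:
            b = re[pid]
            out[pid] = {t: float(fe[t] + b.get(t, 0.0)) for t in extract}
        return pd.DataFrame(out).T
    # OLS per participant, always with the full fixed-effect design so
    # correlated terms (e.g. type and type-by-predictor) are not confounded
    rows = {}
    for pid, block in data.groupby("participant_id"):
        X = np.column_stack(
            [np.ones(len(block))] + [block[t].to_numpy(dtype=float) for t in terms]
        )
        y = block[outcome].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        coef = dict(zip(terms, beta[1:]))
        rows[pid] = {t: coef[t] for t in extract}
    return pd.DataFrame(rows).T


def extract_sensitivities(
    harm_model: EmotionRegressionResult,
    resp_model: EmotionRegressionResult,
    comp_model: CompensationRegressionResult,
) -> pd.DataFrame:
    """Participant-level sensitivities from the fitted mixed models.

    Emotion sensitivities (rating units per level) come from the
    predictor-by-type regressions: the guilt slope for participant i is the
    fixed simple slope plus the participant's predicted random deviations on
    the predictor and interaction terms.  Compensatory sensitivities (tokens
    per rating unit) come from the guilt+shame compensation model.  When a
    model fell back to a structure without random slopes, per-participant
    OLS slopes are substituted (recorded in ``DataFrame.attrs['fallbacks']``).
    """
    out = {}
    for label, er in (("harm", harm_model), ("resp", resp_model)):
        x = er.predictor
        sl = _participant_slopes_mixed(
            er.result, er.fallback, er.data, "rating",
            terms=[x, "etype", "x_etype"], extract=[x, "x_etype"],
        )
        out[f"{label}_guilt"] = sl[x] + sl["x_etype"]
        out[f"{label}_shame"] = sl[x]
    comp_res = comp_model.results["III"]
    comp_fb = comp_model.fallbacks["III"]
    sl = _participant_slopes_mixed(comp_res, comp_fb, comp_model.data, "decision", ["guilt", "shame"])
    out["guilt_comp"] = sl["guilt"]
    out["shame_comp"] = sl["shame"]
    df = pd.DataFrame(out)
    df.index.name = "participant_id"
    df.attrs["fallbacks"] = {
        "harm": harm_model.fallback,
        "responsibility": resp_model.fallback,
        "compensation": comp_fb,
    }
    return df


# ---------------------------------------------------------------------------
# dependent correlations (Pearson-Filon) and mediation


def dependent_correlation_test(r_jk: float, r_jh: float, r_kh: float, n: int):
    """Pearson-Filon Z for two overlapping dependent correlations.

    Tests r_jk == r_jh where both correlations share variable j and r_kh is
    the correlation between the non-shared variables.  Two-sided p from the
    standard normal.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r_jk, r_jh, r_kh):
        if abs(r) >= 1:
            raise ValueError("degenerate input: |r| must be < 1")
    k = r_kh * (1 - r_jk**2 - r_jh**2) - 0.5 * r_jk * r_jh * (
        1 - r_jk**2 - r_jh**2 - r_kh**2
    )
    denom = np.sqrt((1 - r_jk**2) ** 2 + (1 - r_jh**2) ** 2 - 2 * k)
    z = np.sqrt(n) * (r_jk - r_jh) / denom
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class MediationResult:
    a: float  # X -> M
    b: float  # M -> Y controlling X
    c_total: float  # X -> Y
    c_prime: float  # X -> Y controlling M
    indirect: float  # a * b (point estimate)
    ci: tuple[float, float]  # percentile bootstrap CI of a*b
    significant: bool
    n_boot: int
    boots: np.ndarray = field(repr=False, default=None)


def bootstrap_mediation(x, m, y, n_boot: int = 5000, seed=0) -> MediationResult:
    """Percentile-bootstrap test of the indirect effect X -> M -> Y.

    Paths a (M ~ X) and b (Y ~ X + M) are OLS slopes recomputed on each of
    ``n_boot`` resamples (observations drawn with replacement); the indirect
    effect a*b is summarised by its 95% percentile interval and called
    significant when the interval excludes zero.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not (len(m) == len(y) == n):
        raise ValueError("x, m, y must have equal length")
    if n < 10:
        raise ValueError("need n >= 10")
    if x.std() == 0 or m.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")

    def paths(X, M, Y):
        # row-wise OLS via centered cross-products
        Xc = X - X.mean(axis=-1, keepdims=True)
        Mc = M - M.mean(axis=-1, keepdims=True)
        Yc = Y - Y.mean(axis=-1, keepdims=True)
        sxx = (Xc * Xc).sum(axis=-1)
        sxm = (Xc * Mc).sum(axis=-1)
        smm = (Mc * Mc).sum(axis=-1)
        sxy = (Xc * Yc).sum(axis=-1)
        smy = (Mc * Yc).sum(axis=-1)
        a = sxm / sxx
        det = sxx * smm - sxm**2
        # collinear limit (M carries all of X's variance): attribute the
        # shared path to the mediator, so the indirect effect equals the total
        singular = det <= 1e-12 * sxx * smm
        safe_det = np.where(singular, 1.0, det)
        b = np.where(singular, smy / smm, (sxx * smy - sxm * sxy) / safe_det)
        c_prime = np.where(singular, 0.0, (smm * sxy - sxm * smy) / safe_det)
        c_total = sxy / sxx
        return a, b, c_total, c_prime

    a, b, c_total, c_prime = paths(x, m, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ab, bb, *_ = paths(x[idx], m[idx], y[idx])
    boots = ab * bb
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return MediationResult(
        float(a), float(b), float(c_total), float(c_prime), float(a * b),
        (float(lo), float(hi)), bool(lo > 0 or hi < 0), n_boot, boots,
    )


# ---------------------------------------------------------------------------
# trait correlations


def trait_correlations(traits: pd.DataFrame, compensation: pd.Series) -> pd.DataFrame:
    """Pearson r (two-sided p) between each trait column and mean compensation."""
    comp = compensation.reindex(traits.index).to_numpy(dtype=float)
    if len(comp) < 3:
        raise ValueError("need at least 3 participants")
    rows = {}
    for col in traits.columns:
        v = traits[col].to_numpy(dtype=float)
        if np.ptp(v) == 0 or np.ptp(comp) == 0:
            rows[col] = dict(r=np.nan, p=np.nan, defined=False)
        else:
            r = sps.pearsonr(v, comp)
            rows[col] = dict(r=float(r.statistic), p=float(r.pvalue), defined=True)
    return pd.DataFrame(rows).T
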