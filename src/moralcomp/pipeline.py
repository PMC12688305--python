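"""Configuration and the end-to-end pipeline: simulate -> fit -> compare ->
validate -> stats, with every artifact stamped by config hash and seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .design import DesignSpec
from .fitting import FITS_COLUMNS, compare_models
from .models import MODEL_IDS
from .simulate import CohortSpec, EmotionGenSpec, generate_dataset, write_dataset
from .stats import (
    compensation_regression,
    emotion_regression,
    extract_sensitivities,
    manipulation_check,
    merge_emotions,
    trait_correlations,
)
from .validation import validate_winning_model

__all__ = ["PipelineConfig", "run_pipeline", "load_trials", "write_fits", "read_fits"]

log = logging.getLogger("moralcomp")


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips through YAML unchanged."""

    n_participants: int = 40
    model: str = "1.3"
    seed: int = 0
    n_validation_sets: int = 50
    emotion_mediated: bool = False
    grid_points: int = 5
    models: tuple[str, ...] = MODEL_IDS
    design: DesignSpec = field(default_factory=DesignSpec)
    cohort: CohortSpec | None = None
    emotion_spec: EmotionGenSpec = field(default_factory=EmotionGenSpec)
    outdir: str = "moralcomp_run"

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["design"] = asdict(self.design)
        d["emotion_spec"] = asdict(self.emotion_spec)
        d["cohort"] = asdict(self.cohort) if self.cohort else None
        d["models"] = list(self.models)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src: str | Path) -> "PipelineConfig":
        is_path = isinstance(src, Path) or (
            isinstance(src, str) and "\n" not in src and Path(src).exists()
        )
        text = Path(src).read_text() if is_path else str(src)
        d = yaml.safe_load(text)
        d["design"] = DesignSpec(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in d["design"].items()})
        d["emotion_spec"] = EmotionGenSpec(**d["emotion_spec"])
        if d.get("cohort"):
            c = d["cohort"]
            for k in ("kappa_range", "eta_range", "theta_range"):
                c[k] = tuple(c[k])
            d["cohort"] = CohortSpec(**c)
        d["models"] = tuple(d["models"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def load_trials(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a trials CSV; ``column_map`` renames external columns onto the
    TrialRecord fields so foreign deposits can be ingested unchanged."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    for col in ("harm", "wrongdoers", "responsibility", "decision"):
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    if "responsibility" not in df.columns and "wrongdoers" in df.columns:
        df["responsibility"] = 5 - df["wrongdoers"]
    if "wrongdoers" not in df.columns and "responsibility" in df.columns:
        df["wrongdoers"] = 5 - df["responsibility"]
    if "condition" not in df.columns:
        df["condition"] = "self_error"
    return df


def write_fits(results, path: str | Path) -> None:
    results.params.reset_index()[FITS_COLUMNS].to_csv(path, index=False)


def read_fits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"model": str}).set_index("participant_id")


def _stats_stage(ds, min_n: int = 3) -> dict:
    """Behavioral statistics on a dataset bundle; small cohorts complete with
    insufficient-n warnings instead of failing."""
    out: dict = {"warnings": []}
    n = ds.trials["participant_id"].nunique()
    pain = manipulation_check(ds.checks.pain, level_col="harm")
    resp_levels = ["1", "2", "3", "4"]
    comparisons = list(zip(resp_levels, resp_levels[1:])) + [
        ("correct", lvl) for lvl in resp_levels
    ]
    resp = manipulation_check(
        ds.checks.responsibility, level_col="level", comparisons=comparisons
    )
    out["manipulation_checks"] = {
        "pain": pain.to_dict(orient="records"),
        "responsibility": resp.to_dict(orient="records"),
    }
    harm_er = emotion_regression(ds.emotions, "harm")
    resp_er = emotion_regression(ds.emotions, "responsibility")
    out["emotion_regression"] = {
        "harm": {
            "interaction": harm_er.interaction,
            "simple_slopes": harm_er.simple_slopes.to_dict(orient="index"),
            "fallback": harm_er.fallback,
        },
        "responsibility": {
            "interaction": resp_er.interaction,
            "simple_slopes": resp_er.simple_slopes.to_dict(orient="index"),
            "fallback": resp_er.fallback,
        },
    }
    comp = compensation_regression(merge_emotions(ds.trials, ds.emotions))
    out["compensation_regression"] = {
        "bic": comp.bic.to_dict(),
        "winner": comp.winner,
        "coefficients": comp.coefficients.to_dict(orient="index"),
        "wald_chi2": comp.wald_chi2,
        "wald_p": comp.wald_p,
        "fallbacks": comp.fallbacks,
    }
    sens = extract_sensitivities(harm_er, resp_er, comp)
    out["sensitivities"] = sens.reset_index().to_dict(orient="list")
    mean_comp = (
        ds.trials[ds.trials["condition"] == "self_error"]
        .groupby("participant_id")["decision"]
        .mean()
    )
    if n >= min_n:
        out["trait_correlations"] = trait_correlations(ds.traits, mean_comp).to_dict(
            orient="index"
        )
    else:
        out["warnings"].append(
            f"trait correlations skipped: n={n} participants is insufficient"
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write the artifact bundle to outdir.

    Returns a manifest dict of stage outputs.  Any stage failure raises with
    the stage name; partial outputs written so far are left in place.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = {"config_hash": config.config_hash, "seed": config.seed, "stages": {}}
    stage = "simulate"
    try:
        log.info("run start: hash=%s seed=%d", config.config_hash, config.seed)
        config.to_yaml(out / "config.yaml")

        ds = generate_dataset(
            n_participants=config.n_participants,
            model=config.model,
            seed=config.seed,
            design=config.design,
            cohort=config.cohort,
            emotion_spec=config.emotion_spec,
            emotion_mediated=config.emotion_mediated,
        )
        write_dataset(ds, out / "dataset")
        manifest["stages"]["simulate"] = str(out / "dataset")
        log.info("simulate: %d participants", config.n_participants)

        stage = "fit"
        comparison = compare_models(
            ds.trials, models=config.models, grid_points=config.grid_points
        )
        win_res = comparison.results[comparison.winner]
        write_fits(win_res, out / "fits.csv")
        comparison.bic_matrix.to_csv(out / "bic_matrix.csv")
        (out / "comparison.txt").write_text(comparison.summary() + "\n")
        manifest["stages"]["fit"] = str(out / "fits.csv")
        manifest["winner"] = comparison.winner
        log.info("fit/compare: winner %s", comparison.winner)

        stage = "validate"
        try:
            report = validate_winning_model(
                win_res, ds.trials, n_sets=config.n_validation_sets, seed=config.seed
            )
            payload = report.to_dict()
            log.info(
                "validate: accuracy %.3f (chance %.3f), r_kappa %.3f, r_eta %.3f",
                report.accuracy.mean, report.accuracy.chance,
                report.recovery.r_kappa, report.recovery.r_eta,
            )
        except ValueError as err:  # e.g. too few participants for recovery
            payload = {"warning": f"validation incomplete: {err}"}
            log.warning("validate skipped: %s", err)
        (out / "validation.json").write_text(
            json.dumps(payload, indent=2, default=float)
        )
        manifest["stages"]["validate"] = str(out / "validation.json")

        stage = "stats"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stats_out = _stats_stage(ds)
        (out / "stats.json").write_text(json.dumps(stats_out, indent=2, default=float))
        manifest["stages"]["stats"] = str(out / "stats.json")
        for w in stats_out["warnings"]:
            log.warning("%s", w)

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.info("run complete")
        return manifest
    except Exception as err:
        log.error("stage %r failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()
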