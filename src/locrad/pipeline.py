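"""One-command orchestration: generate, extract, select, train, evaluate.

A single master seed fans out deterministically to every stochastic stage
(cohort generation, LASSO folds, CV repetitions, bootstrap intervals) via
``numpy.random.SeedSequence`` spawning, so one integer reproduces a run
bit-exactly. The zero-effect cohort is an expected degenerate case: when no
feature couple survives the multiple-testing correction the run records an
"expected-null" outcome instead of failing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import (
    ConfigurationError,
    LocradError,
    NoSignificantCoupleError,
    NoUncorrelatedPairError,
    PipelineError,
)
from .evaluation import EvaluationReport, evaluate_scores, render_report
from .feature_selection import SelectionResult, select_features
from .io import CohortTable, save_json, write_feature_table
from .local_radiomics import FEATURE_NAMES, extract_cohort_features, extract_features
from .svm_workflow import (
    DEFAULT_TRAIN_SIZES,
    FittedModel,
    SplitPlan,
    build_training_set,
    train_model,
)
from .synthetic_cohort import CohortConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

STAGE_SEEDS = ("cohort", "lasso", "folds", "boot_train", "boot_test")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    cohort: CohortConfig = CohortConfig()
    seed: int = 0
    window_side: int | None = None
    alpha: float = 0.05
    rho_max: float = 0.15
    train_sizes: tuple[int, int] = DEFAULT_TRAIN_SIZES
    n_reps: int = 100
    n_folds: int = 3
    lasso_folds: int = 10
    n_lambda: int = 100
    n_boot: int = 2000
    make_plots: bool = False

    def validate(self) -> None:
        self.cohort.validate()
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0 < self.rho_max <= 1:
            raise ConfigurationError("rho_max must lie in (0, 1]")
        if self.window_side is not None and (self.window_side < 3 or self.window_side % 2 == 0):
            raise ConfigurationError("window_side override must be odd and >= 3")
        for name in ("n_reps", "n_folds", "lasso_folds", "n_lambda", "n_boot"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if min(self.train_sizes) < self.n_folds:
            raise ConfigurationError("each class needs at least n_folds training members")

    def stage_seeds(self) -> dict[str, int]:
        """Named per-stage integer seeds derived from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(STAGE_SEEDS))
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(STAGE_SEEDS, children)
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = asdict(self.cohort)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            cohort = {
                k: tuple(v) if isinstance(v, list) else v for k, v in cohort.items()
            }
            cohort = CohortConfig(**cohort)
        if "train_sizes" in d and isinstance(d["train_sizes"], list):
            d["train_sizes"] = tuple(d["train_sizes"])
        return cls(cohort=cohort, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: expected a mapping at the top level")
        try:
            config = cls.from_dict(raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc
        config.validate()
        return config


@dataclass
class StudyResult:
    """In-memory result of one full analysis."""

    status: str  # "ok" or "expected-null"
    table: CohortTable
    plan: SplitPlan | None = None
    selection: SelectionResult | None = None
    model: FittedModel | None = None
    report_train: EvaluationReport | None = None
    report_test: EvaluationReport | None = None
    detail: str = ""
    seeds: dict[str, int] = field(default_factory=dict)
    #: per-patient planted ground truth (synthetic runs only)
    planted: pd.DataFrame | None = None


def analyze_cohort(table: CohortTable, config: RunConfig) -> StudyResult:
    """Split, select, train and evaluate an extracted feature table."""
    seeds = config.stage_seeds()

    plan = build_training_set(table.X(), table.y(), table.ids(), config.train_sizes)
    part = table.with_partition(plan.train_ids)

    try:
        selection = select_features(
            part,
            rho_max=config.rho_max,
            alpha=config.alpha,
            seed=seeds["lasso"],
            n_folds=config.lasso_folds,
            n_lambda=config.n_lambda,
        )
    except (NoSignificantCoupleError, NoUncorrelatedPairError) as exc:
        logger.info("selection found no couple (expected under a null cohort): %s", exc)
        return StudyResult(
            status="expected-null", table=part, plan=plan, detail=str(exc), seeds=seeds
        )

    model = train_model(
        part,
        selection,
        n_reps=config.n_reps,
        n_folds=config.n_folds,
        seed=seeds["folds"],
    )

    reports = {}
    for name, boot_seed in (("train", seeds["boot_train"]), ("test", seeds["boot_test"])):
        scores = model.scores_for(part, name)
        reports[name] = evaluate_scores(
            scores.to_numpy(),
            part.y(name),
            patient_ids=scores.index,
            n_boot=config.n_boot,
            seed=boot_seed,
        )

    return StudyResult(
        status="ok",
        table=part,
        plan=plan,
        selection=selection,
        model=model,
        report_train=reports["train"],
        report_test=reports["test"],
        seeds=seeds,
    )


def run_study(config: RunConfig) -> StudyResult:
    """Full in-memory pipeline: phantom cohort, extraction, analysis."""
    config.validate()
    seeds = config.stage_seeds()
    cohort_cfg = replace(config.cohort, seed=seeds["cohort"])
    patients = generate_cohort(cohort_cfg)
    records = []
    for p in patients:
        fv = extract_features(p.volume, p.mask, window_side=config.window_side)
        rec = {"patient_id": p.patient_id, "label": p.label}
        rec.update(dict(zip(fv.names, fv.values)))
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=["patient_id", "label", *FEATURE_NAMES])
    result = analyze_cohort(CohortTable(df, FEATURE_NAMES), config)
    result.planted = pd.DataFrame({
        "patient_id": [p.patient_id for p in patients],
        "label": [p.label for p in patients],
        "heterogeneity": [p.planted_heterogeneity for p in patients],
        "asymmetry": [p.planted_asymmetry for p in patients],
    }).set_index("patient_id")
    return result


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Disk-backed pipeline writing every intermediate artifact.

    Layout under ``outdir``: ``cohort/`` (NIfTI volumes + manifest),
    ``features.csv``, ``selection.json``, ``model.json``,
    ``report_train.json`` / ``report_test.json`` (plus plots when enabled),
    ``provenance.json`` and ``status.json``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (NoSignificantCoupleError, NoUncorrelatedPairError):
                raise
            except LocradError as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrap

    cohort_cfg = replace(config.cohort, seed=seeds["cohort"])
    patients = stage("simulate")(generate_cohort, cohort_cfg)
    manifest = stage("simulate")(write_cohort, patients, outdir / "cohort")

    table = stage("extract")(extract_cohort_features, manifest, config.window_side)
    write_feature_table(table, outdir / "features.csv")

    plan = stage("split")(
        build_training_set, table.X(), table.y(), table.ids(), config.train_sizes
    )
    part = table.with_partition(plan.train_ids)
    write_feature_table(part, outdir / "features.csv")
    save_json(plan.to_dict(), outdir / "split.json")

    provenance = {
        "locrad_version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stage_seeds": seeds,
        "numpy_version": np.__version__,
    }
    save_json(provenance, outdir / "provenance.json")

    try:
        selection = stage("select")(
            select_features,
            part,
            rho_max=config.rho_max,
            alpha=config.alpha,
            seed=seeds["lasso"],
            n_folds=config.lasso_folds,
            n_lambda=config.n_lambda,
        )
    except (NoSignificantCoupleError, NoUncorrelatedPairError) as exc:
        save_json(
            {"status": "expected-null", "stage": "select", "detail": str(exc)},
            outdir / "status.json",
        )
        logger.info("run aborted at selection (expected-null): %s", exc)
        return outdir

    save_json(selection.to_dict(), outdir / "selection.json")

    model = stage("train")(
        train_model,
        part,
        selection,
        n_reps=config.n_reps,
        n_folds=config.n_folds,
        seed=seeds["folds"],
    )
    save_json(model.to_dict(), outdir / "model.json")

    for name, boot_seed in (("train", seeds["boot_train"]), ("test", seeds["boot_test"])):
        scores = model.scores_for(part, name)
        report = stage("evaluate")(
            evaluate_scores,
            scores.to_numpy(),
            part.y(name),
            patient_ids=scores.index,
            n_boot=config.n_boot,
            seed=boot_seed,
        )
        plots = (outdir / f"plots_{name}") if config.make_plots else None
        render_report(report, outdir / f"report_{name}.json", plots_dir=plots)

    save_json({"status": "ok"}, outdir / "status.json")
    return outdir
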