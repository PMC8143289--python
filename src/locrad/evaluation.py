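"""ROC/AUC evaluation, Youden cutoff, confusion metrics and report artifacts.

Metrics follow the usual screening conventions: sensitivity and specificity
are read at the Youden cutoff (the threshold maximizing
sensitivity + specificity - 1, the maximum being the informedness I);
positive predictive value (PPV) and false discovery rate (FDR = 1 - PPV)
describe the predicted-positive group; F2 is the F-beta score with beta = 2,
weighting recall four times precision. AUC confidence intervals use a
stratified percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import EvaluationError, ValidationError
from .feature_selection import wilcoxon_rank_sum
from .io import save_json

REPORT_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# ROC and cutoff
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """Empirical ROC points and AUC.

    Returns ``(points, auc)`` where ``points`` is an (n_thresholds, 3) array
    of ``(fpr, tpr, threshold)`` rows (a row predicts positive when
    score >= threshold) and the AUC equals the Mann-Whitney rank statistic
    (ties counted half).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("both classes must be present to compute a ROC")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr, thr]), auc


def youden_cutoff(roc_points: np.ndarray) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are resolved toward the highest specificity (lowest false-positive
    rate), then toward the higher threshold.
    """
    pts = np.asarray(roc_points, dtype=float)
    if pts.size == 0:
        raise ValidationError("empty ROC")
    fpr, tpr, thr = pts[:, 0], pts[:, 1], pts[:, 2]
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    best = best[fpr[best] == fpr[best].min()]
    return float(thr[best[np.argmax(thr[best])]])


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @classmethod
    def from_predictions(cls, labels, predicted) -> "ConfusionCounts":
        labels = np.asarray(labels, dtype=int)
        predicted = np.asarray(predicted, dtype=int)
        return cls(
            tp=int(np.sum((labels == 1) & (predicted == 1))),
            fp=int(np.sum((labels == 0) & (predicted == 1))),
            fn=int(np.sum((labels == 1) & (predicted == 0))),
            tn=int(np.sum((labels == 0) & (predicted == 0))),
        )


@dataclass(frozen=True)
class ConfusionMetrics:
    """Derived rates; a ``None`` entry marks an undefined metric, never 0."""

    sensitivity: float | None
    specificity: float | None
    informedness: float | None
    ppv: float | None
    fdr: float | None
    f2: float | None

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "informedness": self.informedness,
            "ppv": self.ppv,
            "fdr": self.fdr,
            "f2": self.f2,
        }


def confusion_metrics(c: ConfusionCounts) -> ConfusionMetrics:
    """Exact rational computation of the derived rates.

    Undefined metrics (no positives, no negatives, or no predicted
    positives) come back as ``None``.
    """
    se = Fraction(c.tp, c.positives) if c.positives > 0 else None
    sp = Fraction(c.tn, c.negatives) if c.negatives > 0 else None
    informedness = se + sp - 1 if (se is not None and sp is not None) else None
    predicted_pos = c.tp + c.fp
    ppv = Fraction(c.tp, predicted_pos) if predicted_pos > 0 else None
    fdr = 1 - ppv if ppv is not None else None
    if ppv is not None and se is not None and (4 * ppv + se) > 0:
        f2 = 5 * ppv * se / (4 * ppv + se)
    else:
        f2 = None
    as_float = lambda v: float(v) if v is not None else None
    return ConfusionMetrics(
        sensitivity=as_float(se),
        specificity=as_float(sp),
        informedness=as_float(informedness),
        ppv=as_float(ppv),
        fdr=as_float(fdr),
        f2=as_float(f2),
    )


# ---------------------------------------------------------------------------
# bootstrap CI and group separation
# ---------------------------------------------------------------------------

def auc_bootstrap_ci(
    scores, labels, n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for the AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("both classes must be present")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(pos, size=pos.size, replace=True),
            rng.choice(neg, size=neg.size, replace=True),
        ])
        aucs[b] = roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.quantile(aucs, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def group_separation(scores, labels) -> tuple[float, float, float]:
    """Group medians of the score and the two-sided rank-sum p-value.

    Returns ``(median_class0, median_class1, p)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    s0, s1 = scores[labels == 0], scores[labels == 1]
    if s0.size == 0 or s1.size == 0:
        raise EvaluationError("both groups must be nonempty")
    return float(np.median(s0)), float(np.median(s1)), wilcoxon_rank_sum(s0, s1)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Everything reported for one evaluated patient set."""

    roc_points: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    youden_cutoff: float
    confusion: ConfusionCounts
    metrics: ConfusionMetrics
    patient_ids: tuple[str, ...]
    scores: np.ndarray
    labels: np.ndarray
    median_ncs: float
    median_cs: float
    separation_p: float

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "roc_points": np.asarray(self.roc_points).tolist(),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "youden_cutoff": self.youden_cutoff,
            "confusion": {
                "tp": self.confusion.tp, "fp": self.confusion.fp,
                "fn": self.confusion.fn, "tn": self.confusion.tn,
            },
            "metrics": self.metrics.to_dict(),
            "waterfall": [
                {"patient_id": pid, "score": float(s), "label": int(l)}
                for pid, s, l in zip(self.patient_ids, self.scores, self.labels)
            ],
            "boxplot": {
                "median_ncs": self.median_ncs,
                "median_cs": self.median_cs,
                "separation_p": self.separation_p,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        wf = d["waterfall"]
        metrics = d["metrics"]
        return cls(
            roc_points=np.asarray(d["roc_points"], dtype=float),
            auc=float(d["auc"]),
            auc_ci=tuple(d["auc_ci"]),
            youden_cutoff=float(d["youden_cutoff"]),
            confusion=ConfusionCounts(**{k: int(v) for k, v in d["confusion"].items()}),
            metrics=ConfusionMetrics(**metrics),
            patient_ids=tuple(e["patient_id"] for e in wf),
            scores=np.array([e["score"] for e in wf]),
            labels=np.array([e["label"] for e in wf], dtype=int),
            median_ncs=float(d["boxplot"]["median_ncs"]),
            median_cs=float(d["boxplot"]["median_cs"]),
            separation_p=float(d["boxplot"]["separation_p"]),
        )


def evaluate_scores(
    scores,
    labels,
    patient_ids=None,
    n_boot: int = 2000,
    seed: int = 0,
    cutoff: float | None = None,
) -> EvaluationReport:
    """Full evaluation of per-patient scores against binary labels.

    The decision threshold defaults to the Youden cutoff of these scores;
    pass ``cutoff`` to reuse a threshold chosen elsewhere.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if patient_ids is None:
        patient_ids = tuple(f"p{i:03d}" for i in range(len(scores)))
    points, auc = roc_auc(scores, labels)
    ci = auc_bootstrap_ci(scores, labels, n_boot=n_boot, seed=seed)
    if cutoff is None:
        cutoff = youden_cutoff(points)
    predicted = (scores >= cutoff).astype(int)
    confusion = ConfusionCounts.from_predictions(labels, predicted)
    med0, med1, p = group_separation(scores, labels)
    return EvaluationReport(
        roc_points=points,
        auc=auc,
        auc_ci=ci,
        youden_cutoff=float(cutoff),
        confusion=confusion,
        metrics=confusion_metrics(confusion),
        patient_ids=tuple(str(p) for p in patient_ids),
        scores=scores,
        labels=labels,
        median_ncs=med0,
        median_cs=med1,
        separation_p=p,
    )


def render_report(
    report: EvaluationReport, path: str | Path, plots_dir: str | Path | None = None
) -> list[Path]:
    """Serialize a report to JSON, optionally with ROC/waterfall/boxplot PNGs."""
    path = Path(path)
    written = [save_json(report.to_dict(), path)]
    if plots_dir is not None:
        written.extend(_render_plots(report, Path(plots_dir)))
    return written


def _render_plots(report: EvaluationReport, plots_dir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots_dir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.roc_points[:, 0], report.roc_points[:, 1], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC (AUC = {report.auc:.2f})")
    fig.tight_layout()
    p = plots_dir / "roc.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    order = np.argsort(-report.scores)
    colors = np.where(report.labels[order] == 1, "#1f3b73", "#7bc47b")
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(np.arange(len(order)), report.scores[order] - report.youden_cutoff,
           color=colors, width=0.8)
    ax.axhline(0.0, c="k", lw=0.8)
    ax.set_ylabel("score - cutoff")
    ax.set_title("Radiomic score waterfall")
    fig.tight_layout()
    p = plots_dir / "waterfall.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(3, 4))
    groups = [report.scores[report.labels == 0], report.scores[report.labels == 1]]
    ax.boxplot(groups, tick_labels=["ncsPCa", "csPCa"])
    ax.set_ylabel("radiomic score")
    ax.set_title(f"Separation (p = {report.separation_p:.2g})")
    fig.tight_layout()
    p = plots_dir / "boxplot.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
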