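"""Sequential two-model classification strategies and their evaluation.

Three quality grades are resolved by two binary PLS-DA stages applied in
order.  Strategy S1 first separates EVOO from everything else, then routes
the non-EVOO samples to a VOO-vs-LOO stage; strategy S2 first isolates LOO
(the grade that is not edible unrefined, so conceptually the more cautious
sequence) and then splits the remainder into VOO vs EVOO.

Evaluation mirrors standard chemometric reporting: per-stage per-class
correct-classification tables for cross-validation (per-fold refits over the
calibration set, with scaling and threshold re-estimated inside every fold
and the latent-variable count held fixed) and for the untouched external
set, ROC curves and AUC per stage, per-sample class probabilities, and a
triage list of samples whose assigned-class probability falls below a chosen
probability level — those are the ones a laboratory would forward to the
sensory panel.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .core import Category, OliveGradeError, SampleManifest
from .plsda import (
    PLSDAConfig,
    PLSDAModel,
    SplitResult,
    bayes_threshold,
    choose_n_lv,
    fit_pls,
    predict_proba,
    venetian_blinds_folds,
)
from .preprocess import FingerprintMatrix, autoscale_fit

__all__ = [
    "Strategy",
    "CascadeModel",
    "CascadePrediction",
    "StageTable",
    "EvaluationReport",
    "fit_cascade",
    "predict_cascade",
    "evaluate",
    "roc_curve",
]


class Strategy(str, enum.Enum):
    """S1: EVOO vs no-EVOO, then VOO vs LOO.  S2: LOO vs no-LOO, then VOO vs
    EVOO."""

    S1 = "S1"
    S2 = "S2"

    @property
    def stage1_target(self) -> Category:
        return Category.EVOO if self is Strategy.S1 else Category.LOO

    @property
    def stage1_labels(self) -> tuple[str, str]:
        t = self.stage1_target.value
        return (f"no-{t}", t)  # (class0, class1)

    @property
    def stage2_pair(self) -> tuple[Category, Category]:
        # (class0, class1)
        if self is Strategy.S1:
            return (Category.LOO, Category.VOO)
        return (Category.EVOO, Category.VOO)

    @property
    def stage2_labels(self) -> tuple[str, str]:
        c0, c1 = self.stage2_pair
        return (c0.value, c1.value)


@dataclasses.dataclass
class CascadeModel:
    strategy: Strategy
    stage1: PLSDAModel
    stage2: PLSDAModel
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.stage1.class_labels) != self.strategy.stage1_labels:
            raise OliveGradeError("stage1 labels do not match the strategy")
        if tuple(self.stage2.class_labels) != self.strategy.stage2_labels:
            raise OliveGradeError("stage2 labels do not match the strategy")

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy.value,
            "stage1": self.stage1.to_dict(),
            "stage2": self.stage2.to_dict(),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeModel":
        return cls(
            strategy=Strategy(d["strategy"]),
            stage1=PLSDAModel.from_dict(d["stage1"]),
            stage2=PLSDAModel.from_dict(d["stage2"]),
            provenance=d.get("provenance", {}),
        )


def _binary_y(categories: list[Category], positive: Category) -> np.ndarray:
    return np.array([1.0 if c == positive else 0.0 for c in categories])


def fit_cascade(
    strategy: Strategy,
    fingerprints: FingerprintMatrix,
    manifest: SampleManifest,
    split: SplitResult,
    config: PLSDAConfig = PLSDAConfig(),
) -> CascadeModel:
    """Fit both stages on the calibration split.

    Stage 1 trains on every calibration sample with one-vs-rest relabeling;
    stage 2 only on the calibration samples of its two grades.  Each stage's
    latent-variable count is chosen independently by venetian-blinds CV over
    its own training block (calibration samples in manifest order).
    """
    strategy = Strategy(strategy)
    cats = manifest.categories()
    order = manifest.order()
    cal_ids = sorted(split.calibration_ids, key=order.__getitem__)
    Fcal = fingerprints.rows(cal_ids)
    cal_cats = [cats[s] for s in cal_ids]

    y1 = _binary_y(cal_cats, strategy.stage1_target)
    for frac, name in ((y1.sum(), "positive"), (len(y1) - y1.sum(), "negative")):
        if frac < config.n_blinds:
            raise OliveGradeError(
                f"stage 1 has fewer {name} calibration samples than folds"
            )
    n_lv1, cv_err1 = choose_n_lv(Fcal.X, y1, config.max_lv, config.n_blinds, config.priors)
    stage1 = fit_pls(
        Fcal.X, y1, n_lv1, class_labels=strategy.stage1_labels, priors=config.priors
    )
    stage1.cv_errors = cv_err1

    c0, c1 = strategy.stage2_pair
    pair_ids = [s for s in cal_ids if cats[s] in (c0, c1)]
    pair_cats = [cats[s] for s in pair_ids]
    if min(pair_cats.count(c0), pair_cats.count(c1)) < config.n_blinds:
        raise OliveGradeError("stage 2 has a class with fewer calibration samples than folds")
    F2 = fingerprints.rows(pair_ids)
    y2 = _binary_y(pair_cats, c1)
    n_lv2, cv_err2 = choose_n_lv(F2.X, y2, config.max_lv, config.n_blinds, config.priors)
    stage2 = fit_pls(F2.X, y2, n_lv2, class_labels=strategy.stage2_labels, priors=config.priors)
    stage2.cv_errors = cv_err2

    return CascadeModel(
        strategy=strategy,
        stage1=stage1,
        stage2=stage2,
        provenance={
            "n_calibration": len(cal_ids),
            "n_stage2_calibration": len(pair_ids),
            "n_lv": [n_lv1, n_lv2],
            "split_method": split.method,
        },
    )


@dataclasses.dataclass
class CascadePrediction:
    sample_id: str
    label: Category
    path: list[str]  # stage-wise assigned labels, e.g. ["no-EVOO", "VOO"]
    probability: float  # P(assigned class) at the deciding stage
    stage_probabilities: dict[str, float]


def predict_cascade(
    model: CascadeModel, X: np.ndarray, sample_ids: list[str] | None = None
) -> list[CascadePrediction]:
    """Route every row through the two stages; each sample receives exactly
    one final grade, with the deciding stage's assigned-class probability."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if sample_ids is None:
        sample_ids = [str(i) for i in range(X.shape[0])]
    proba1 = predict_proba(model.stage1, X)
    proba2 = predict_proba(model.stage2, X)
    target = model.strategy.stage1_target
    out = []
    for i, sid in enumerate(sample_ids):
        p0, p1, yhat1 = proba1[i]
        stage_probs = {"stage1_p_target": float(p1)}
        if yhat1 > model.stage1.threshold:
            label, path, prob = target, [target.value], float(p1)
        else:
            q0, q1, yhat2 = proba2[i]
            c0, c1 = model.strategy.stage2_pair
            stage_probs["stage2_p_class1"] = float(q1)
            if yhat2 > model.stage2.threshold:
                label, prob = c1, float(q1)
            else:
                label, prob = c0, float(q0)
            path = [f"no-{target.value}", label.value]
        out.append(
            CascadePrediction(
                sample_id=sid,
                label=label,
                path=path,
                probability=prob,
                stage_probabilities=stage_probs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep over the unique scores (ties grouped into one
    step) and AUC by the trapezoid rule.

    Returns (fpr, tpr, auc); the curve starts at (0, 0) and ends at (1, 1).
    AUC equals the Mann–Whitney U statistic divided by n0·n1 (ties counted
    half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = int(labels.size - n1)
    if n0 == 0 or n1 == 0:
        raise OliveGradeError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = labels[order].astype(float)
    # group tied scores into a single step
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    last = np.concatenate([distinct, [s.size - 1]])
    tp = np.cumsum(pos)[last]
    fp = (last + 1) - tp
    tpr = np.concatenate([[0.0], tp / n1])
    fpr = np.concatenate([[0.0], fp / n0])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


# ---------------------------------------------------------------------------
# Evaluation report
# ---------------------------------------------------------------------------


def _pct(correct: int, total: int) -> int:
    if total == 0:
        return 0
    ratio = Decimal(correct) * 100 / Decimal(total)
    return int(ratio.quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class StageTable:
    """Per-class and overall correct/total counts, printed-style integer
    percentages (half-up) and raw fractions."""

    per_class: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for label, (correct, total) in self.per_class.items():
            if correct > total:
                raise OliveGradeError(f"{label}: correct > total")

    @property
    def overall(self) -> tuple[int, int]:
        correct = sum(c for c, _ in self.per_class.values())
        total = sum(t for _, t in self.per_class.values())
        return correct, total

    def to_dict(self) -> dict:
        out = {}
        for label, (correct, total) in self.per_class.items():
            out[label] = {
                "correct": correct,
                "total": total,
                "percent": _pct(correct, total),
                "fraction": correct / total if total else None,
            }
        c, t = self.overall
        out["TOTAL"] = {
            "correct": c,
            "total": t,
            "percent": _pct(c, t),
            "fraction": c / t if t else None,
        }
        return out


def _stage_table(true01: np.ndarray, pred01: np.ndarray, labels: tuple[str, str]) -> StageTable:
    per = {}
    for code, label in ((1.0, labels[1]), (0.0, labels[0])):
        mask = true01 == code
        per[label] = (int(((pred01 == code) & mask).sum()), int(mask.sum()))
    return StageTable(per_class=per)


@dataclasses.dataclass
class EvaluationReport:
    strategy: Strategy
    stages: dict  # stage name -> set name -> table/roc/auc
    probabilities: dict  # set name -> sample_id -> P(correct class)
    triage: list[str]
    probability_level: float
    external_cascade: StageTable | None = None

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, StageTable):
                return obj.to_dict()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "strategy": self.strategy.value,
            "stages": conv(self.stages),
            "probabilities": conv(self.probabilities),
            "triage": list(self.triage),
            "probability_level": self.probability_level,
            "external_cascade": conv(self.external_cascade),
        }


def _cv_stage(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    labels: tuple[str, str],
    config: PLSDAConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out scores and binary predictions from venetian-blinds per-fold
    refits (scaling + threshold per fold, LV count fixed)."""
    n = X.shape[0]
    folds = venetian_blinds_folds(n, config.n_blinds)
    scores = np.empty(n)
    preds = np.empty(n)
    for test_idx in folds:
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        if np.unique(y[train]).size < 2:
            raise OliveGradeError("a CV fold lost one class; reduce n_blinds")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_pls(X[train], y[train], n_lv, class_labels=labels, priors=config.priors)
            yhat = model.decision_function(X[test_idx])
        scores[test_idx] = yhat
        preds[test_idx] = (yhat > model.threshold).astype(float)
    return scores, preds


def evaluate(
    model: CascadeModel,
    fingerprints: FingerprintMatrix,
    manifest: SampleManifest,
    split: SplitResult,
    probability_level: float = 0.5,
    config: PLSDAConfig = PLSDAConfig(),
) -> EvaluationReport:
    """Full evaluation of a fitted cascade: per-stage tables for
    cross-validation and external validation, ROC/AUC, per-sample correct-
    class probabilities and the sub-``probability_level`` triage list."""
    if not 0.0 < probability_level <= 1.0:
        raise OliveGradeError("probability_level must lie in (0, 1]")
    cats = manifest.categories()
    order = manifest.order()
    cal_ids = sorted(split.calibration_ids, key=order.__getitem__)
    ext_ids = sorted(split.external_ids, key=order.__getitem__)
    strategy = model.strategy
    stages: dict[str, dict] = {"stage1": {}, "stage2": {}}
    probabilities: dict[str, dict[str, float]] = {"cross_validation": {}, "external": {}}

    # ---- stage definitions -------------------------------------------------
    target = strategy.stage1_target
    c0, c1 = strategy.stage2_pair
    stage_defs = [
        ("stage1", model.stage1, strategy.stage1_labels, cal_ids, ext_ids, target),
        (
            "stage2",
            model.stage2,
            strategy.stage2_labels,
            [s for s in cal_ids if cats[s] in (c0, c1)],
            [s for s in ext_ids if cats[s] in (c0, c1)],
            c1,
        ),
    ]

    for name, stage, labels, stage_cal, stage_ext, positive in stage_defs:
        ycal = _binary_y([cats[s] for s in stage_cal], positive)
        Xcal = fingerprints.rows(stage_cal).X
        cv_scores, cv_preds = _cv_stage(Xcal, ycal, stage.n_lv, labels, config)
        fpr_cv, tpr_cv, auc_cv = roc_curve(cv_scores, ycal == 1.0)
        yext = _binary_y([cats[s] for s in stage_ext], positive)
        Xext = fingerprints.rows(stage_ext).X
        proba = predict_proba(stage, Xext)
        ext_preds = (proba[:, 2] > stage.threshold).astype(float)
        fpr_ex, tpr_ex, auc_ex = roc_curve(proba[:, 2], yext == 1.0)
        stages[name] = {
            "cross_validation": {
                "table": _stage_table(ycal, cv_preds, labels),
                "roc": {"fpr": fpr_cv, "tpr": tpr_cv},
                "auc": auc_cv,
            },
            "external": {
                "table": _stage_table(yext, ext_preds, labels),
                "roc": {"fpr": fpr_ex, "tpr": tpr_ex},
                "auc": auc_ex,
            },
        }
        # P(correct class) per sample (external: from the fitted stage;
        # CV: from the two-Gaussian posterior of the fold scores' stage fit)
        for sid, row, truth in zip(stage_ext, proba, yext):
            p_correct = row[1] if truth == 1.0 else row[0]
            probabilities["external"].setdefault(sid, float(p_correct))
        cv_proba = _scores_to_proba(stage, cv_scores)
        for sid, p1, truth in zip(stage_cal, cv_proba, ycal):
            p_correct = p1 if truth == 1.0 else 1.0 - p1
            probabilities["cross_validation"].setdefault(sid, float(p_correct))

    # ---- cascade-level external three-class table and triage ---------------
    Fext = fingerprints.rows(ext_ids)
    predictions = predict_cascade(model, Fext.X, ext_ids)
    per_class: dict[str, tuple[int, int]] = {}
    for cat in (Category.EVOO, Category.VOO, Category.LOO):
        ids = [p for p, s in zip(predictions, ext_ids) if cats[s] == cat]
        per_class[cat.value] = (sum(p.label == cat for p in ids), len(ids))
    triage = [p.sample_id for p in predictions if p.probability < probability_level]

    return EvaluationReport(
        strategy=strategy,
        stages=stages,
        probabilities=probabilities,
        triage=triage,
        probability_level=probability_level,
        external_cascade=StageTable(per_class=per_class),
    )


def _scores_to_proba(stage: PLSDAModel, scores: np.ndarray) -> np.ndarray:
    """P(class1) for raw decision scores under the stage's fitted posterior."""
    from scipy.stats import norm

    mu0, sd0 = stage.class_score_stats[stage.class_labels[0]]
    mu1, sd1 = stage.class_score_stats[stage.class_labels[1]]
    log0 = np.log(stage.priors[0]) + norm.logpdf(scores, mu0, sd0)
    log1 = np.log(stage.priors[1]) + norm.logpdf(scores, mu1, sd1)
    top = np.maximum(log0, log1)
    w0, w1 = np.exp(log0 - top), np.exp(log1 - top)
    return np.clip(w1 / (w0 + w1), 1e-12, 1.0 - 1e-12)
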