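"""Two-class PLS-DA built from scratch: NIPALS fitting, Kennard–Stone
calibration/external splitting, venetian-blinds cross-validation for the
latent-variable count, and a Bayes-rule probabilistic class threshold.

The classifier is PLS1 regression of a centered {0,1} class dummy on the
autoscaled fingerprint, with the decision cut on the predicted response ŷ
placed where the posterior probability of the two classes is equal.  Class-
conditional densities are Gaussians fitted to the calibration ŷ of each
class; with equal priors and equal spreads the threshold reduces to the
midpoint of the class means.

Everything is arranged for wide matrices (hundreds of samples × ~10⁴
points): per-component cost is O(n·p) and nothing ever materializes a p×p
object.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import norm

from .core import OliveGradeError
from .preprocess import ScalingParams, autoscale_fit

__all__ = [
    "PLSDAModel",
    "SplitResult",
    "PLSDAConfig",
    "kennard_stone_split",
    "fit_pls",
    "choose_n_lv",
    "bayes_threshold",
    "predict_proba",
]

_PROB_EPS = 1e-12  # posterior probabilities are clipped away from 0 and 1


@dataclasses.dataclass(frozen=True)
class PLSDAConfig:
    max_lv: int = 20
    n_blinds: int = 10
    priors: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.max_lv < 1 or self.n_blinds < 2:
            raise OliveGradeError("max_lv >= 1 and n_blinds >= 2 required")
        if abs(sum(self.priors) - 1.0) > 1e-9 or min(self.priors) <= 0:
            raise OliveGradeError("priors must be positive and sum to 1")


# ---------------------------------------------------------------------------
# Kennard-Stone split
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SplitResult:
    calibration_ids: list[str]
    external_ids: list[str]
    method: str = "kennard_stone"
    fraction_external: float = 0.25
    #: calibration ids in the order the greedy algorithm picked them
    selection_order: list[str] | None = None

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.external_ids):
            raise OliveGradeError("calibration and external sets overlap")


def kennard_stone_split(
    X: np.ndarray,
    fraction_external: float = 0.25,
    sample_ids: list[str] | None = None,
) -> SplitResult:
    """Deterministic Kennard–Stone selection of the calibration subset.

    Starts from the two mutually most distant samples (Euclidean) and
    greedily adds the sample maximizing its minimum distance to the
    selected set; the remainder becomes the external validation set.  Ties
    break toward the smallest row index.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise OliveGradeError("Kennard-Stone needs at least 3 samples")
    if not 0.0 < fraction_external < 1.0:
        raise OliveGradeError("fraction_external must lie in (0, 1)")
    if not np.all(np.isfinite(X)):
        raise OliveGradeError("X must be finite")
    n_external = int(np.floor(fraction_external * n + 0.5))
    n_cal = n - n_external
    if n_cal < 2 or n_external < 1:
        raise OliveGradeError("split leaves an empty set")

    sq = np.einsum("ij,ij->i", X, X)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)

    start = np.unravel_index(np.argmax(d2), d2.shape)  # first max in row-major order
    selected = [min(start), max(start)]
    min_d2 = np.minimum(d2[selected[0]], d2[selected[1]])
    min_d2[selected] = -np.inf
    while len(selected) < n_cal:
        nxt = int(np.argmax(min_d2))  # argmax returns the first (smallest) index on ties
        selected.append(nxt)
        np.minimum(min_d2, d2[nxt], out=min_d2)
        min_d2[nxt] = -np.inf
    cal = sorted(selected)
    ext = [i for i in range(n) if i not in set(cal)]
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    return SplitResult(
        calibration_ids=[sample_ids[i] for i in cal],
        external_ids=[sample_ids[i] for i in ext],
        fraction_external=fraction_external,
        selection_order=[sample_ids[i] for i in selected],
    )


# ---------------------------------------------------------------------------
# Bayes threshold
# ---------------------------------------------------------------------------


def _class_stats(scores: np.ndarray) -> tuple[float, float]:
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise OliveGradeError("need at least two calibration scores per class")
    sd = float(np.std(scores, ddof=1))
    return float(np.mean(scores)), max(sd, 1e-12)


def bayes_threshold(
    scores0: np.ndarray,
    scores1: np.ndarray,
    priors: tuple[float, float] = (0.5, 0.5),
) -> float:
    """Decision value on ŷ where the two prior-weighted Gaussian class
    densities cross between the class means (posterior = 0.5).

    With equal priors and equal SDs this is exactly the midpoint of the
    class means.  If no crossing lies between the means (pathological
    spread combinations) the midpoint is returned with a warning.
    """
    mu0, sd0 = _class_stats(scores0)
    mu1, sd1 = _class_stats(scores1)
    pi0, pi1 = priors
    if pi0 <= 0 or pi1 <= 0 or abs(pi0 + pi1 - 1.0) > 1e-9:
        raise OliveGradeError("priors must be positive and sum to 1")
    midpoint = 0.5 * (mu0 + mu1)
    if np.isclose(mu0, mu1):
        warnings.warn("class means coincide; falling back to midpoint threshold")
        return midpoint

    lo, hi = min(mu0, mu1), max(mu0, mu1)
    if np.isclose(sd0, sd1, rtol=1e-9, atol=0.0):
        root = midpoint + sd0 * sd0 * np.log(pi0 / pi1) / (mu1 - mu0)
        if lo < root < hi:
            return float(root)
        warnings.warn("no posterior crossing between the class means; using midpoint")
        return midpoint

    # pi0 N(y; mu0, sd0) = pi1 N(y; mu1, sd1)  ->  quadratic in y
    a = 1.0 / (2.0 * sd1 * sd1) - 1.0 / (2.0 * sd0 * sd0)
    b = mu0 / (sd0 * sd0) - mu1 / (sd1 * sd1)
    c = (
        mu1 * mu1 / (2.0 * sd1 * sd1)
        - mu0 * mu0 / (2.0 * sd0 * sd0)
        + np.log((pi0 * sd1) / (pi1 * sd0))
    )
    disc = b * b - 4.0 * a * c
    if disc >= 0:
        roots = [(-b + s * np.sqrt(disc)) / (2.0 * a) for s in (+1.0, -1.0)]
        inside = [r for r in roots if lo < r < hi]
        if inside:
            return float(min(inside, key=lambda r: abs(r - midpoint)))
    warnings.warn("no posterior crossing between the class means; using midpoint")
    return midpoint


# ---------------------------------------------------------------------------
# NIPALS PLS1
# ---------------------------------------------------------------------------


class RankExhaustedError(OliveGradeError):
    def __init__(self, achievable: int, requested: int):
        self.achievable = achievable
        super().__init__(
            f"requested {requested} latent variables but the data supports at most {achievable}"
        )


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int, tol: float = 1e-12):
    """NIPALS PLS1 on centered/scaled data.

    Returns weights W, loadings P, y-loadings q and, per component count k,
    the accumulated regression vector b_k (computed incrementally via
    R = W (PᵀW)⁻¹ without forming the inverse).
    """
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    R = np.zeros((p, n_lv))
    B = np.zeros((p, n_lv))
    scores = np.zeros((n, n_lv))
    x_scale = float(np.sqrt((Xc * Xc).sum())) or 1.0
    for k in range(n_lv):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn <= tol * x_scale:
            return W[:, :k], P[:, :k], q[:k], B[:, :k], scores[:, :k], k
        w /= wn
        t = X @ w
        tt = float(t @ t)
        if tt <= (tol * x_scale) ** 2:
            return W[:, :k], P[:, :k], q[:k], B[:, :k], scores[:, :k], k
        pk = (X.T @ t) / tt
        qk = float(y @ t) / tt
        X -= np.outer(t, pk)
        y = y - qk * t
        W[:, k], P[:, k], q[k], scores[:, k] = w, pk, qk, t
        r = w - R[:, :k] @ (P[:, :k].T @ w)
        R[:, k] = r
        B[:, k] = (B[:, k - 1] if k else 0.0) + r * qk
    return W, P, q, B, scores, n_lv


@dataclasses.dataclass
class PLSDAModel:
    """A fitted two-class PLS-DA stage.

    ``class_labels`` orders the pair as (class0, class1); the response dummy
    codes class1 as 1.  ``class_score_stats`` holds the Gaussian fitted to
    each class's calibration ŷ, which together with ``priors`` defines both
    the threshold and the posterior probabilities.
    """

    n_lv: int
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    b: np.ndarray  # regression vector for the scaled data
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    class_labels: tuple[str, str]
    class_score_stats: dict[str, tuple[float, float]]
    priors: tuple[float, float]
    threshold: float
    cv_errors: list[float] | None = None

    @property
    def n_points(self) -> int:
        return int(self.b.size)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """ŷ for raw (unscaled) rows with the training scaling applied."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_points:
            raise OliveGradeError(
                f"fingerprint width {X.shape[1]} does not match model ({self.n_points})"
            )
        return self.y_mean + ((X - self.x_mean) / self.x_sd) @ self.b

    def predict(self, X: np.ndarray) -> list[str]:
        yhat = self.decision_function(X)
        return [self.class_labels[1] if v > self.threshold else self.class_labels[0] for v in yhat]

    def to_dict(self) -> dict:
        return {
            "n_lv": self.n_lv,
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "b": self.b.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "class_labels": list(self.class_labels),
            "class_score_stats": {k: list(v) for k, v in self.class_score_stats.items()},
            "priors": list(self.priors),
            "threshold": self.threshold,
            "cv_errors": self.cv_errors,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSDAModel":
        return cls(
            n_lv=int(d["n_lv"]),
            W=np.asarray(d["W"], dtype=float),
            P=np.asarray(d["P"], dtype=float),
            q=np.asarray(d["q"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            y_mean=float(d["y_mean"]),
            class_labels=tuple(d["class_labels"]),
            class_score_stats={k: tuple(v) for k, v in d["class_score_stats"].items()},
            priors=tuple(d["priors"]),
            threshold=float(d["threshold"]),
            cv_errors=d.get("cv_errors"),
        )


def _prepare_y(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise OliveGradeError("y must be coded {0, 1}")
    if np.unique(y).size < 2:
        raise OliveGradeError("y has zero variance (single class)")
    return y


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    class_labels: tuple[str, str] = ("class0", "class1"),
    priors: tuple[float, float] = (0.5, 0.5),
    scaling: ScalingParams | None = None,
) -> PLSDAModel:
    """Fit a two-class PLS-DA with ``n_lv`` latent variables.

    ``X`` is the raw calibration block; autoscaling (mean 0 / SD 1, n−1
    denominator, fitted on these rows unless ``scaling`` is supplied) and
    the centered dummy coding of ``y`` happen internally, and the scaling
    constants are stored in the model so prediction accepts raw rows.
    """
    X = np.asarray(X, dtype=float)
    y = _prepare_y(y)
    if X.shape[0] != y.size:
        raise OliveGradeError("X and y disagree on the number of samples")
    if n_lv < 1:
        raise OliveGradeError("n_lv must be >= 1")
    if scaling is None:
        scaling = autoscale_fit(X)
    Xc = (X - scaling.mean) / scaling.sd
    y_mean = float(y.mean())
    W, P, q, B, scores, got = _nipals(Xc, y - y_mean, n_lv)
    if got < n_lv:
        raise RankExhaustedError(got, n_lv)
    b = B[:, n_lv - 1]
    yhat = y_mean + Xc @ b
    s0, s1 = yhat[y == 0.0], yhat[y == 1.0]
    stats = {class_labels[0]: _class_stats(s0), class_labels[1]: _class_stats(s1)}
    threshold = bayes_threshold(s0, s1, priors)
    return PLSDAModel(
        n_lv=n_lv,
        W=W,
        P=P,
        q=q,
        b=b,
        x_mean=scaling.mean,
        x_sd=scaling.sd,
        y_mean=y_mean,
        class_labels=class_labels,
        class_score_stats=stats,
        priors=priors,
        threshold=threshold,
    )


def predict_proba(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """Per-sample (P(class0), P(class1), ŷ) from the fitted two-Gaussian
    posterior.  Probabilities sum to 1 and are clipped away from {0, 1}."""
    yhat = model.decision_function(X)
    mu0, sd0 = model.class_score_stats[model.class_labels[0]]
    mu1, sd1 = model.class_score_stats[model.class_labels[1]]
    log0 = np.log(model.priors[0]) + norm.logpdf(yhat, mu0, sd0)
    log1 = np.log(model.priors[1]) + norm.logpdf(yhat, mu1, sd1)
    top = np.maximum(log0, log1)
    w0 = np.exp(log0 - top)
    w1 = np.exp(log1 - top)
    p1 = np.clip(w1 / (w0 + w1), _PROB_EPS, 1.0 - _PROB_EPS)
    return np.column_stack([1.0 - p1, p1, yhat])


# ---------------------------------------------------------------------------
# Venetian-blinds selection of the latent-variable count
# ---------------------------------------------------------------------------


def venetian_blinds_folds(n: int, n_blinds: int) -> list[np.ndarray]:
    """Fold f holds samples i with i mod n_blinds == f, in given order."""
    if n_blinds < 2 or n_blinds > n:
        raise OliveGradeError("need 2 <= n_blinds <= n")
    index = np.arange(n)
    return [index[index % n_blinds == f] for f in range(n_blinds)]


def choose_n_lv(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int = 20,
    n_blinds: int = 10,
    priors: tuple[float, float] = (0.5, 0.5),
) -> tuple[int, list[float]]:
    """Pick the LV count minimizing venetian-blinds CV misclassification.

    Scaling, the NIPALS fit and the Bayes threshold are re-fit inside every
    fold; all candidate counts are scored from a single incremental NIPALS
    pass per fold.  Ties go to the smaller count.  ``max_lv`` is further
    capped at min(n − n_blinds, 50) and by the rank actually available in
    every fold.
    """
    X = np.asarray(X, dtype=float)
    y = _prepare_y(y)
    n = X.shape[0]
    cap = min(max_lv, n - n_blinds, 50, X.shape[1])
    if cap < 1:
        raise OliveGradeError("too few samples for cross-validation")
    folds = venetian_blinds_folds(n, n_blinds)
    errors = np.zeros(cap)
    achievable = cap
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = X[train_mask], y[train_mask]
        Xte, yte = X[test_idx], y[test_idx]
        if np.unique(ytr).size < 2:
            raise OliveGradeError("a CV fold lost one class entirely; reduce n_blinds")
        scaling = autoscale_fit(Xtr)
        Xc = (Xtr - scaling.mean) / scaling.sd
        y_mean = float(ytr.mean())
        _, _, _, B, _, got = _nipals(Xc, ytr - y_mean, cap)
        achievable = min(achievable, got) if got else achievable
        if got == 0:
            raise OliveGradeError("no usable latent variable in a CV fold")
        Xte_c = (Xte - scaling.mean) / scaling.sd
        fit_c = Xc @ B[:, :got] + y_mean  # calibration yhat per component count
        pred_c = Xte_c @ B[:, :got] + y_mean
        for k in range(got):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                thr = bayes_threshold(fit_c[ytr == 0.0, k], fit_c[ytr == 1.0, k], priors)
            errors[k] += np.sum((pred_c[:, k] > thr) != (yte == 1.0))
    errors = errors[:achievable]
    best = int(np.argmin(errors)) + 1  # first minimum -> fewest LVs on ties
    return best, (errors / n).tolist()
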