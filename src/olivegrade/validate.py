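"""Untargeted method validation: pointwise RSD repeatability, the
Horwitz-style intensity trend, and standard-solution signal-to-noise.

Fingerprinting methods cannot be validated per-analyte, so repeatability is
judged on the chromatogram itself: QC-pool replicates are COW-aligned and
region-selected, then the relative standard deviation (RSD% = 100·SD/mean,
n−1 SD) of every retained data point across replicates is tabulated into
frequency classes and checked against acceptance rules — intra-day: more
than 90% of points with RSD < 15% and more than 95% with RSD < 20%;
inter-day (within-lab reproducibility): more than 85% and more than 90%
respectively.  Consistency with the Horwitz-style trend (higher RSD at
lower intensity) is tested as a negative Spearman correlation between log
point intensity and RSD%, since in fingerprint mode no concentrations exist
to evaluate the numeric Horwitz curve on.

RSD is computed on aligned *raw* intensities, never autoscaled ones — the
RSD of a mean-centered variable is undefined — and points whose replicate
mean sits below the noise floor are excluded so that baseline points do not
contribute meaningless ratios.

Sensitivity is a targeted spot check: for a compound spiked into refined
oil, S is the baseline-subtracted peak apex near its retention time and N
the mean absolute baseline-subtracted intensity in the 43–50 s blank
window; the system passes if S/N > 3 (strictly).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .core import Chromatogram, CompoundSpec, OliveGradeError
from .preprocess import NOISE_WINDOW, FingerprintMatrix, noise_sd

__all__ = [
    "PointwiseRSD",
    "RSDFrequencyTable",
    "RepeatabilityResult",
    "HorwitzTrend",
    "SNResult",
    "pointwise_rsd",
    "qc_noise_floor",
    "rsd_frequency_table",
    "check_repeatability",
    "horwitz_trend_check",
    "signal_to_noise",
    "REPEATABILITY_RULES",
]

#: RSD%-class upper bounds, matching the reporting layout used for
#: fingerprint repeatability tables.
RSD_CLASS_BOUNDS = (10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)

#: (rsd_threshold %, minimum cumulative % of points) per mode.
REPEATABILITY_RULES = {
    "intra_day": ((15.0, 90.0), (20.0, 95.0)),
    "inter_day": ((15.0, 85.0), (20.0, 90.0)),
}


@dataclasses.dataclass
class PointwiseRSD:
    """RSD% per retained point, with the mask and means that produced it."""

    rsd: np.ndarray
    means: np.ndarray
    kept: np.ndarray  # boolean mask over the input points

    def __post_init__(self) -> None:
        if np.any(self.rsd < 0):
            raise OliveGradeError("RSD must be >= 0")


def qc_noise_floor(F: FingerprintMatrix, reference: Chromatogram, k: float = 10.0) -> np.ndarray:
    """Per-point absolute intensity floor: blank-window baseline of the
    reference plus ``k`` × blank-window noise SD, per instrument column."""
    floor = np.empty(F.n_points)
    t = reference.time_axis
    window = (t >= NOISE_WINDOW[0]) & (t <= NOISE_WINDOW[1])
    for column in ("nonpolar", "polar"):
        block = F.block_mask(column)
        baseline = float(np.median(reference.trace(column)[window]))
        floor[block] = baseline + k * noise_sd(reference, column)
    return floor


def pointwise_rsd(
    F: FingerprintMatrix | np.ndarray,
    noise_floor: float | np.ndarray | None = None,
) -> PointwiseRSD:
    """RSD% of every data point across aligned, unscaled QC replicates.

    Points whose replicate mean falls below ``noise_floor`` are excluded.
    Requires at least two replicates and positive means on the retained
    points.
    """
    if isinstance(F, FingerprintMatrix):
        if F.autoscaled:
            raise OliveGradeError("RSD is undefined on autoscaled data")
        X = F.X
    else:
        X = np.asarray(F, dtype=float)
    if X.shape[0] < 2:
        raise OliveGradeError("pointwise RSD needs at least two replicates")
    means = X.mean(axis=0)
    if noise_floor is None:
        kept = np.ones(X.shape[1], dtype=bool)
    else:
        kept = means >= np.asarray(noise_floor)
    if not kept.any():
        raise OliveGradeError("no points above the noise floor")
    if np.any(means[kept] <= 0):
        raise OliveGradeError("non-positive replicate mean above the noise floor")
    Xk = X[:, kept]
    sd = Xk.std(axis=0, ddof=1)
    sd[Xk.max(axis=0) == Xk.min(axis=0)] = 0.0  # identical replicates: exactly 0
    return PointwiseRSD(rsd=100.0 * sd / means[kept], means=means[kept], kept=kept)


@dataclasses.dataclass
class RSDFrequencyTable:
    """Disjoint RSD% bands (≤10, 10–15, …, 90–100, >100) with counts and
    percentages; counts always conserve the number of retained points."""

    bounds: tuple[float, ...]
    counts: np.ndarray
    mode: str | None = None

    @property
    def n_points(self) -> int:
        return int(self.counts.sum())

    @property
    def percents(self) -> np.ndarray:
        return 100.0 * self.counts / self.n_points

    def cumulative_percent_below(self, threshold: float) -> float:
        """Percent of points with RSD <= threshold (threshold must be a
        class bound)."""
        if threshold not in self.bounds:
            raise OliveGradeError(f"{threshold} is not a class bound")
        idx = self.bounds.index(threshold)
        return float(100.0 * self.counts[: idx + 1].sum() / self.n_points)

    def as_rows(self) -> list[dict]:
        rows = []
        for i, bound in enumerate(self.bounds):
            rows.append(
                {
                    "class": bound,
                    "count": int(self.counts[i]),
                    "percent": float(self.percents[i]),
                }
            )
        if self.counts[len(self.bounds) :].sum() > 0:
            rows.append(
                {
                    "class": "overflow",
                    "count": int(self.counts[len(self.bounds)]),
                    "percent": float(self.percents[len(self.bounds)]),
                }
            )
        return rows


def rsd_frequency_table(rsd: np.ndarray, mode: str | None = None) -> RSDFrequencyTable:
    rsd = np.asarray(rsd, dtype=float)
    if rsd.size == 0:
        raise OliveGradeError("empty RSD vector")
    if np.any(rsd < 0):
        raise OliveGradeError("RSD must be >= 0")
    edges = np.concatenate([[-np.inf], RSD_CLASS_BOUNDS, [np.inf]])
    counts, _ = np.histogram(rsd, bins=edges)
    return RSDFrequencyTable(bounds=RSD_CLASS_BOUNDS, counts=counts, mode=mode)


@dataclasses.dataclass
class RepeatabilityResult:
    mode: str
    passed: bool
    criteria_detail: list[dict]

    def __bool__(self) -> bool:
        return self.passed


def check_repeatability(
    table: RSDFrequencyTable,
    mode: str,
    horwitz_consistent: bool | None = None,
) -> RepeatabilityResult:
    """Evaluate the cumulative-RSD acceptance rules for the given mode; an
    optional Horwitz-trend verdict is AND-ed into the overall pass."""
    if mode not in REPEATABILITY_RULES:
        raise OliveGradeError(f"unknown repeatability mode {mode!r}")
    detail = []
    passed = True
    for threshold, required in REPEATABILITY_RULES[mode]:
        achieved = table.cumulative_percent_below(threshold)
        ok = achieved > required
        passed &= ok
        detail.append(
            {
                "rule": f"RSD<{threshold:g}%",
                "required_percent": required,
                "achieved_percent": achieved,
                "pass": ok,
            }
        )
    if horwitz_consistent is not None:
        passed &= horwitz_consistent
        detail.append(
            {
                "rule": "horwitz_trend",
                "required_percent": None,
                "achieved_percent": None,
                "pass": bool(horwitz_consistent),
            }
        )
    return RepeatabilityResult(mode=mode, passed=bool(passed), criteria_detail=detail)


@dataclasses.dataclass
class HorwitzTrend:
    consistent: bool
    rho: float
    p_value: float

    def __bool__(self) -> bool:
        return self.consistent


def horwitz_trend_check(means: np.ndarray, rsd: np.ndarray) -> HorwitzTrend:
    """Spearman correlation between log point intensity and RSD%: the trend
    is consistent when the correlation is negative with p < 0.05."""
    means = np.asarray(means, dtype=float)
    rsd = np.asarray(rsd, dtype=float)
    if means.size != rsd.size or means.size < 3:
        raise OliveGradeError("need matching mean/RSD vectors of length >= 3")
    if np.any(means <= 0):
        raise OliveGradeError("means must be positive for the log-intensity trend")
    rho, p = stats.spearmanr(np.log(means), rsd)
    if np.isnan(rho):  # constant input on either side
        return HorwitzTrend(consistent=False, rho=0.0, p_value=1.0)
    return HorwitzTrend(consistent=bool(rho < 0 and p < 0.05), rho=float(rho), p_value=float(p))


def horwitz_curve(concentration_mass_fraction: np.ndarray) -> np.ndarray:
    """Classical Horwitz RSD% curve, 2^(1 − 0.5·log10 C); plotted in reports
    for orientation only, never gated on (fingerprint points have no
    concentration scale)."""
    c = np.asarray(concentration_mass_fraction, dtype=float)
    return 2.0 ** (1.0 - 0.5 * np.log10(c))


# ---------------------------------------------------------------------------
# Signal-to-noise
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SNResult:
    compound: str
    peak_time: float
    S: float
    N: float
    passed: bool

    @property
    def ratio(self) -> float:
        return self.S / self.N


def signal_to_noise(
    c: Chromatogram, compound: CompoundSpec, column: str = "nonpolar"
) -> SNResult:
    """S/N of a spiked standard: apex (baseline-subtracted, within ±3σ of
    the compound's retention time) over the mean absolute noise in the
    43–50 s blank window.  Passes only if the ratio strictly exceeds 3."""
    rt = compound.rt(column)
    if NOISE_WINDOW[0] <= rt <= NOISE_WINDOW[1]:
        raise OliveGradeError(
            f"{compound.name}: retention time {rt} s lies inside the noise window"
        )
    t = c.time_axis
    trace = c.trace(column)
    window = (t >= NOISE_WINDOW[0]) & (t <= NOISE_WINDOW[1])
    if not window.any():
        raise OliveGradeError("trace does not cover the noise window")
    baseline = float(np.median(trace[window]))
    noise = float(np.mean(np.abs(trace[window] - baseline)))
    if noise <= 0:
        raise OliveGradeError("zero noise in the blank window; S/N undefined")
    region = (t >= rt - 3.0 * compound.width) & (t <= rt + 3.0 * compound.width)
    if not region.any():
        raise OliveGradeError("trace does not cover the compound window")
    # apex from a lightly smoothed trace (boxcar ~ sigma/2) so that white
    # noise cannot masquerade as a peak on a blank injection
    dt = float(t[1] - t[0])
    w = max(1, int(round(compound.width / (2.0 * dt))))
    smoothed = np.convolve(trace, np.ones(w) / w, mode="same")
    apex_idx = int(np.argmax(smoothed[region]))
    S = float(smoothed[region][apex_idx] - baseline)
    peak_time = float(t[region][apex_idx])
    ratio = S / noise
    return SNResult(compound=compound.name, peak_time=peak_time, S=S, N=noise, passed=bool(ratio > 3.0))
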