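"""Chromatogram preprocessing: COW alignment, fingerprint assembly,
signal-region selection and autoscaling.

The pipeline mirrors standard chemometric practice for untargeted GC
fingerprints: every trace is warped onto a reference with correlation
optimized warping (COW) to undo retention-time drift, the two column traces
are concatenated into one wide row per sample, uninformative edge points are
trimmed, the contiguous region between the first and last real peak is
retained, and — for classification only — each retained variable is
autoscaled using statistics of the calibration rows alone.

COW divides the reference into consecutive segments of ``segment_length``
points and searches, per segment, over source segments whose length may
deviate by up to ``slack`` points; each candidate is linearly interpolated
to the reference segment length and scored by Pearson correlation, and the
dynamic program returns the boundary placement maximizing the summed
correlation with both signal ends pinned.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._cow import _cow_dp
from .core import Chromatogram, OliveGradeError

__all__ = [
    "CowParams",
    "WarpingResult",
    "FingerprintMatrix",
    "ScalingParams",
    "cow_align",
    "warp_feasible_range",
    "build_fingerprints",
    "select_signal_region",
    "autoscale_fit",
    "autoscale_apply",
    "choose_reference",
]

#: Blank region of the run (seconds) used for noise estimation: baseline
#: noise is measured between 43 and 50 s, where no compound elutes.
NOISE_WINDOW = (43.0, 50.0)


@dataclasses.dataclass(frozen=True)
class CowParams:
    """COW configuration.

    ``segment_length`` and ``slack`` are in grid points (100 points = 1 s at
    the 0.01 s sampling step).  ``band`` optionally bounds each boundary's
    absolute displacement from its reference position; ``None`` allows the
    full slack-accumulating search.  The default band of 40 points (0.4 s)
    is far above realistic retention-time drift on this instrument class and
    exists purely to keep the dynamic program fast on 10,000-point traces.
    """

    segment_length: int = 100
    slack: int = 15
    band: int | None = 40

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise OliveGradeError("segment_length must be >= 2")
        if not 1 <= self.slack < self.segment_length:
            raise OliveGradeError("slack must satisfy 1 <= slack < segment_length")
        if self.band is not None and self.band < self.slack:
            raise OliveGradeError("band must be >= slack (or None)")


@dataclasses.dataclass
class WarpingResult:
    warped: np.ndarray
    boundary_map: list[tuple[int, int]]  # (reference boundary, source boundary)
    objective: float
    parameters: tuple[int, int]  # (segment_length, slack)

    @property
    def n_segments(self) -> int:
        return len(self.boundary_map) - 1

    @property
    def is_identity(self) -> bool:
        return all(r == s for r, s in self.boundary_map)


def _reference_boundaries(n_ref: int, m: int) -> np.ndarray:
    bounds = list(range(0, n_ref - 1, m))
    bounds.append(n_ref - 1)
    return np.asarray(bounds, dtype=np.int64)


def warp_feasible_range(
    n_ref: int, n_sig: int, segment_length: int, slack: int, band: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boundary grid and per-boundary feasible source-position intervals.

    Shared by the dynamic program and by the exhaustive-enumeration oracle in
    the test suite, so both search exactly the same space.
    """
    boundaries = _reference_boundaries(n_ref, segment_length)
    k = len(boundaries) - 1
    seg_len = np.diff(boundaries)
    lo = np.empty(k + 1, dtype=np.int64)
    hi = np.empty(k + 1, dtype=np.int64)
    lo[0] = hi[0] = 0
    for i in range(k):  # forward reachability
        lo[i + 1] = lo[i] + max(1, seg_len[i] - slack)
        hi[i + 1] = hi[i] + seg_len[i] + slack
    if lo[k] > n_sig - 1 or hi[k] < n_sig - 1:
        raise OliveGradeError(
            f"slack {slack} cannot map a {n_sig}-point signal onto a {n_ref}-point reference"
        )
    lo[k] = hi[k] = n_sig - 1
    for i in range(k, 0, -1):  # backward reachability
        lo[i - 1] = max(lo[i - 1], lo[i] - (seg_len[i - 1] + slack))
        hi[i - 1] = min(hi[i - 1], hi[i] - max(1, seg_len[i - 1] - slack))
    if band is not None:
        scale = (n_sig - 1) / (n_ref - 1)
        for i in range(1, k):
            center = int(round(boundaries[i] * scale))
            lo[i] = max(lo[i], center - band)
            hi[i] = min(hi[i], center + band)
            if lo[i] > hi[i]:
                raise OliveGradeError("warp band leaves no feasible boundary position")
    return boundaries, lo, hi


def _compose_warp(signal: np.ndarray, boundaries: np.ndarray, positions: np.ndarray) -> np.ndarray:
    warped = np.empty(boundaries[-1] + 1, dtype=float)
    for i in range(len(boundaries) - 1):
        b0, b1 = boundaries[i], boundaries[i + 1]
        x0, x1 = positions[i], positions[i + 1]
        coords = np.linspace(x0, x1, b1 - b0 + 1)
        warped[b0 : b1 + 1] = np.interp(coords, np.arange(x0, x1 + 1), signal[x0 : x1 + 1])
    return warped


def cow_align(
    signal: np.ndarray,
    reference: np.ndarray,
    segment_length: int,
    slack: int,
    band: int | None = None,
) -> WarpingResult:
    """Align ``signal`` onto ``reference`` by correlation optimized warping.

    Returns the warped signal (reference length), the optimal boundary map,
    and the summed per-segment Pearson correlation.  Zero-variance segments
    contribute a correlation of 0.  Endpoints are pinned.
    """
    signal = np.ascontiguousarray(signal, dtype=float)
    reference = np.ascontiguousarray(reference, dtype=float)
    if signal.ndim != 1 or reference.ndim != 1:
        raise OliveGradeError("cow_align expects 1-D intensity vectors")
    if not 1 <= slack < segment_length:
        raise OliveGradeError("slack must satisfy 1 <= slack < segment_length")
    if len(reference) < 2 * segment_length or len(signal) < 2 * segment_length:
        raise OliveGradeError("signals must be at least two segments long")
    boundaries, lo, hi = warp_feasible_range(
        len(reference), len(signal), segment_length, slack, band
    )
    objective, positions = _cow_dp(signal, reference, boundaries, lo, hi, slack)
    if objective < -1e29 or positions[0] != 0:
        raise OliveGradeError("no feasible warping path")
    warped = _compose_warp(signal, boundaries, positions)
    return WarpingResult(
        warped=warped,
        boundary_map=list(zip(boundaries.tolist(), positions.tolist())),
        objective=float(objective),
        parameters=(segment_length, slack),
    )


# ---------------------------------------------------------------------------
# Fingerprint matrix
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ScalingParams:
    mean: np.ndarray
    sd: np.ndarray  # n-1 denominator; zero-variance columns hold sd = 1
    zero_variance: np.ndarray  # bool flag per column

    @property
    def n_points(self) -> int:
        return int(self.mean.size)


@dataclasses.dataclass
class FingerprintMatrix:
    """Samples × retained-points matrix with provenance.

    ``point_source``/``point_time`` record, for every retained column, which
    instrument column it came from and its retention time on the reference
    grid.
    """

    X: np.ndarray
    sample_ids: list[str]
    point_source: np.ndarray  # str array: "nonpolar" | "polar"
    point_time: np.ndarray  # seconds on the reference grid
    aligned: bool = False
    autoscaled: bool = False
    scaling_params: ScalingParams | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise OliveGradeError("fingerprint matrix must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise OliveGradeError("fingerprint matrix contains non-finite values")
        if len(self.sample_ids) != self.X.shape[0]:
            raise OliveGradeError("sample_ids length mismatch")
        if self.point_source.size != self.X.shape[1] or self.point_time.size != self.X.shape[1]:
            raise OliveGradeError("point index length mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_points(self) -> int:
        return self.X.shape[1]

    def rows(self, ids: Sequence[str]) -> "FingerprintMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        sel = [index[s] for s in ids]
        return dataclasses.replace(
            self, X=self.X[sel], sample_ids=list(ids), scaling_params=self.scaling_params
        )

    def block_mask(self, column: str) -> np.ndarray:
        return self.point_source == column


def choose_reference(samples: Sequence[Chromatogram]) -> Chromatogram:
    """Medoid reference: the sample whose raw concatenated trace has the
    highest mean Pearson correlation with all the others."""
    if not samples:
        raise OliveGradeError("no samples")
    if len(samples) == 1:
        return samples[0]
    raw = np.stack(
        [np.concatenate([c.trace_nonpolar, c.trace_polar]) for c in samples]
    )
    corr = np.corrcoef(raw)
    mean_corr = (corr.sum(axis=1) - 1.0) / (len(samples) - 1)
    return samples[int(np.argmax(mean_corr))]


def build_fingerprints(
    samples: Sequence[Chromatogram],
    reference: Chromatogram,
    cow: CowParams = CowParams(),
    trim: int = 50,
    align: bool = True,
) -> FingerprintMatrix:
    """Align every sample's two traces to the reference and concatenate them.

    ``trim`` trailing points are dropped from each aligned column trace
    before concatenation (2 × (10,000 − 50) = 19,900 points on a full run).
    Set ``align=False`` to concatenate raw traces (used to quantify how much
    alignment buys).
    """
    n = reference.n_points
    for c in samples:
        if c.n_points != n or abs(c.dt - reference.dt) > 1e-12:
            raise OliveGradeError(f"sample {c.sample_id}: time grid differs from reference")
    if trim < 0 or 2 * trim >= n:
        raise OliveGradeError("bad trim length")
    keep = n - trim
    rows = []
    for c in samples:
        parts = []
        for column in ("nonpolar", "polar"):
            trace = c.trace(column)
            if align and c.sample_id != reference.sample_id:
                trace = cow_align(
                    trace, reference.trace(column), cow.segment_length, cow.slack, cow.band
                ).warped
            parts.append(trace[:keep])
        rows.append(np.concatenate(parts))
    point_source = np.array(["nonpolar"] * keep + ["polar"] * keep)
    point_time = np.concatenate([reference.time_axis[:keep]] * 2)
    return FingerprintMatrix(
        X=np.stack(rows),
        sample_ids=[c.sample_id for c in samples],
        point_source=point_source,
        point_time=point_time,
        aligned=align,
    )


def noise_sd(reference: Chromatogram, column: str) -> float:
    """Detector noise SD from the blank window of the reference trace,
    after removing the window median (local baseline)."""
    t = reference.time_axis
    window = (t >= NOISE_WINDOW[0]) & (t <= NOISE_WINDOW[1])
    values = reference.trace(column)[window]
    if values.size < 10:
        raise OliveGradeError("blank window not covered by the reference trace")
    return float(np.std(values - np.median(values), ddof=1))


def select_signal_region(
    F: FingerprintMatrix, reference: Chromatogram, k: float = 10.0
) -> FingerprintMatrix:
    """Retain, per instrument column, the contiguous point run between the
    first and last index where the cross-sample maximum of
    baseline-subtracted intensity exceeds ``k`` × the blank-window noise SD.

    The per-sample baseline is the median of that sample's own blank-window
    intensities in the same block.
    """
    if F.autoscaled:
        raise OliveGradeError("select_signal_region expects an unscaled matrix")
    keep_masks = []
    for column in ("nonpolar", "polar"):
        block = F.block_mask(column)
        if not block.any():
            raise OliveGradeError(f"no {column} block in matrix")
        times = F.point_time[block]
        Xb = F.X[:, block]
        window = (times >= NOISE_WINDOW[0]) & (times <= NOISE_WINDOW[1])
        if not window.any():
            raise OliveGradeError("blank window missing from fingerprint")
        baselines = np.median(Xb[:, window], axis=1, keepdims=True)
        sd = noise_sd(reference, column)
        above = (Xb - baselines).max(axis=0) > k * sd
        if not above.any():
            raise OliveGradeError("no signal region detected")
        first = int(np.argmax(above))
        last = int(len(above) - 1 - np.argmax(above[::-1]))
        mask = np.zeros(block.sum(), dtype=bool)
        mask[first : last + 1] = True
        keep_masks.append(mask)
    keep = np.zeros(F.n_points, dtype=bool)
    keep[F.block_mask("nonpolar")] = keep_masks[0]
    keep[F.block_mask("polar")] = keep_masks[1]
    return dataclasses.replace(
        F,
        X=F.X[:, keep],
        point_source=F.point_source[keep],
        point_time=F.point_time[keep],
    )


# ---------------------------------------------------------------------------
# Autoscaling (split-aware)
# ---------------------------------------------------------------------------


def autoscale_fit(F: FingerprintMatrix | np.ndarray) -> ScalingParams:
    """Column means and SDs (n−1 denominator) from the fitting rows only.

    Fit this on calibration rows and apply everywhere; fitting on the full
    matrix would leak external-set information into the model.
    """
    X = F.X if isinstance(F, FingerprintMatrix) else np.asarray(F, dtype=float)
    if X.shape[0] < 2:
        raise OliveGradeError("autoscaling needs at least two rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd <= 0
    sd = np.where(zero, 1.0, sd)
    return ScalingParams(mean=mean, sd=sd, zero_variance=zero)


def autoscale_apply(F: FingerprintMatrix, params: ScalingParams) -> FingerprintMatrix:
    if params.n_points != F.n_points:
        raise OliveGradeError(
            f"scaling params cover {params.n_points} points, matrix has {F.n_points}"
        )
    X = (F.X - params.mean) / params.sd
    return dataclasses.replace(F, X=X, autoscaled=True, scaling_params=params)
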