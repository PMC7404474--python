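"""Numba inner loops for correlation-optimized warping.

The dynamic program lives here so the hot loops (per-segment candidate
scoring with on-the-fly linear interpolation) compile to machine code; the
public API and all validation live in :mod:`olivegrade.preprocess`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _segment_corr(signal, x_prev, ln, rcent, rnorm):
    """Pearson correlation between a reference segment and the source slice
    ``signal[x_prev : x_prev + ln]`` linearly interpolated to the reference
    segment length.

    ``rcent`` is the centered reference segment, ``rnorm`` its Euclidean
    norm; a zero-variance segment on either side contributes 0.
    """
    npts = rcent.shape[0]  # reference segment length in points
    if rnorm <= 0.0:
        return 0.0
    sz = 0.0
    szz = 0.0
    szr = 0.0
    scale = ln / (npts - 1.0)  # map j in [0, npts-1] onto [0, ln]
    for j in range(npts):
        g = j * scale
        k = int(g)
        if k >= ln:
            k = ln - 1
        f = g - k
        z = signal[x_prev + k] * (1.0 - f) + signal[x_prev + k + 1] * f
        sz += z
        szz += z * z
        szr += z * rcent[j]
    var = szz - sz * sz / npts
    # near-constant candidates lose the variance to cancellation; treat a
    # coefficient of variation below ~1e-7 as degenerate (correlation 0)
    if var <= 1e-300 or (szz > 0.0 and var < 1e-14 * szz):
        return 0.0
    # szr needs no centering of z: sum((z-zbar)*rcent) == szr since sum(rcent)=0
    corr = szr / (np.sqrt(var) * rnorm)
    if corr > 1.0:
        corr = 1.0
    elif corr < -1.0:
        corr = -1.0
    return corr


@njit(cache=True, fastmath=False)
def _cow_dp(signal, reference, boundaries, lo, hi, slack):
    """Dynamic program over segment boundary positions.

    boundaries : reference boundary indices b_0..b_K (b_0 = 0, b_K = N-1)
    lo, hi     : feasible source-position interval per boundary (inclusive)
    Returns (objective, positions) where positions are the optimal source
    boundary indices; ties resolved toward the smallest predecessor.
    """
    n_seg = boundaries.shape[0] - 1
    width = 0
    for i in range(n_seg + 1):
        w = hi[i] - lo[i] + 1
        if w > width:
            width = w
    NEG = -1e30
    dp = np.full((n_seg + 1, width), NEG)
    parent = np.full((n_seg + 1, width), -1, dtype=np.int64)
    dp[0, 0] = 0.0

    for i in range(n_seg):
        b0 = boundaries[i]
        b1 = boundaries[i + 1]
        m_i = b1 - b0  # reference segment length in intervals
        refseg = reference[b0 : b1 + 1]
        rmean = 0.0
        for j in range(refseg.shape[0]):
            rmean += refseg[j]
        rmean /= refseg.shape[0]
        rcent = refseg - rmean
        rss = 0.0
        raw_ss = 0.0
        for j in range(rcent.shape[0]):
            rss += rcent[j] * rcent[j]
            raw_ss += refseg[j] * refseg[j]
        # same relative-degeneracy rule as for candidate segments
        rnorm = 0.0 if (raw_ss > 0.0 and rss < 1e-14 * raw_ss) else np.sqrt(rss)

        for x_next in range(lo[i + 1], hi[i + 1] + 1):
            best = NEG
            arg = -1
            # iterate ln descending => x_prev ascending => smallest-prev tie-break
            for ln in range(m_i + slack, m_i - slack - 1, -1):
                if ln < 1:
                    continue
                x_prev = x_next - ln
                if x_prev < lo[i] or x_prev > hi[i]:
                    continue
                prev = dp[i, x_prev - lo[i]]
                if prev <= NEG / 2:
                    continue
                corr = _segment_corr(signal, x_prev, ln, rcent, rnorm)
                cand = prev + corr
                if cand > best:
                    best = cand
                    arg = x_prev
            dp[i + 1, x_next - lo[i + 1]] = best
            parent[i + 1, x_next - lo[i + 1]] = arg

    positions = np.empty(n_seg + 1, dtype=np.int64)
    positions[n_seg] = hi[n_seg]  # == lo[n_seg] == L-1 (pinned endpoint)
    objective = dp[n_seg, positions[n_seg] - lo[n_seg]]
    for i in range(n_seg, 0, -1):
        positions[i - 1] = parent[i, positions[i] - lo[i]]
    return objective, positions
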