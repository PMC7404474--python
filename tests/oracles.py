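"""Independent reference implementations used only to check the package.

Everything here is deliberately brute-force or library-based (np.interp,
np.corrcoef, lstsq, exhaustive enumeration) and shares no code with the
implementation paths it validates, except the feasibility helper that
defines the common search space for warping.
"""

from __future__ import annotations

import itertools

import numpy as np

from olivegrade.preprocess import warp_feasible_range


def brute_force_cow(signal, reference, segment_length, slack, band=None):
    """Exhaustive enumeration over all feasible boundary sequences.

    Returns (objective, boundary positions); first maximum wins on exact
    ties, matching the dynamic program's smallest-predecessor rule.
    """
    signal = np.asarray(signal, dtype=float)
    reference = np.asarray(reference, dtype=float)
    boundaries, lo, hi = warp_feasible_range(
        len(reference), len(signal), segment_length, slack, band
    )
    k = len(boundaries) - 1
    best_obj, best_seq = -np.inf, None
    for seq in itertools.product(*(range(lo[i], hi[i] + 1) for i in range(k + 1))):
        total = 0.0
        feasible = True
        for i in range(k):
            ln = seq[i + 1] - seq[i]
            m_i = boundaries[i + 1] - boundaries[i]
            if not max(1, m_i - slack) <= ln <= m_i + slack:
                feasible = False
                break
            ref_seg = reference[boundaries[i] : boundaries[i + 1] + 1]
            src = signal[seq[i] : seq[i + 1] + 1]
            z = np.interp(np.linspace(0.0, ln, m_i + 1), np.arange(ln + 1), src)
            if np.std(ref_seg) == 0.0 or np.std(z) == 0.0:
                corr = 0.0
            else:
                corr = float(np.corrcoef(ref_seg, z)[0, 1])
            total += corr
        if feasible and total > best_obj:
            best_obj, best_seq = total, seq
    return best_obj, best_seq


def identity_warp_objective(signal, reference, segment_length):
    """Summed per-segment correlation of the *unwarped* signal."""
    boundaries, _, _ = warp_feasible_range(
        len(reference), len(signal), segment_length, 1, None
    )
    total = 0.0
    for i in range(len(boundaries) - 1):
        a, b = boundaries[i], boundaries[i + 1]
        r, s = reference[a : b + 1], signal[a : b + 1]
        if np.std(r) == 0.0 or np.std(s) == 0.0:
            continue
        total += float(np.corrcoef(r, s)[0, 1])
    return total


def bayes_threshold_grid(mu0, sd0, mu1, sd1, priors=(0.5, 0.5), resolution=1e-6):
    """Dense-grid root of the prior-weighted two-Gaussian posterior between
    the class means."""
    from scipy.stats import norm

    lo, hi = sorted((mu0, mu1))
    grid = np.arange(lo, hi, resolution)
    diff = priors[0] * norm.pdf(grid, mu0, sd0) - priors[1] * norm.pdf(grid, mu1, sd1)
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    assert sign_change.size > 0, "no crossing on the grid"
    i = sign_change[0]
    return 0.5 * (grid[i] + grid[i + 1])


def mann_whitney_auc(scores, labels):
    """AUC as the normalized Mann-Whitney U statistic (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


def kennard_stone_greedy_check(X, calibration_indices):
    """Verify each greedy step of a Kennard-Stone selection: after the
    mutually most distant start pair, every added sample must attain the
    max-min distance to the already-selected set."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    sel = list(calibration_indices[:2])
    assert d[sel[0], sel[1]] == d.max(), "start pair is not the most distant"
    for step in range(2, len(calibration_indices)):
        remaining = [i for i in range(n) if i not in sel]
        min_d = {i: min(d[i, j] for j in sel) for i in remaining}
        chosen = calibration_indices[step]
        assert np.isclose(min_d[chosen], max(min_d.values())), (
            f"step {step}: chose {chosen} with min-dist {min_d[chosen]}, "
            f"best was {max(min_d.values())}"
        )
        sel.append(chosen)
    return True
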