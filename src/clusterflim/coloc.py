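"""Manders' colocalization coefficients with Costes automatic thresholding.

M1 is the fraction of channel A's above-threshold intensity that lies on
pixels where channel B is above its threshold; M2 swaps the roles.  Both
lie in [0, 1].  The thresholds come from a Costes-style search: an
orthogonal (total least squares) regression B ~ a*A + b is walked down
from the top of channel A's intensity range until the Pearson correlation
of the pixels below both thresholds drops to zero or below — the
remaining above-threshold pixels then carry all the correlated signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ColocResult", "costes_threshold", "manders", "coloc_auto"]


@dataclass
class ColocResult:
    """Manders' coefficients and the thresholds they were computed at."""

    M1: float
    M2: float
    thresholds: tuple  # (T_A, T_B)
    pearson_below: float  # correlation of sub-threshold pixels


def _orthogonal_regression(a: np.ndarray, b: np.ndarray) -> tuple:
    """Total-least-squares line b = slope*a + intercept (first PC)."""
    cov = np.cov(a, b)
    if cov[0, 0] == 0 and cov[1, 1] == 0:
        raise ValueError("both channels are constant; regression undefined")
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, np.argmax(evals)]
    if direction[0] == 0:
        raise ValueError("channel A is constant; regression undefined")
    slope = direction[1] / direction[0]
    intercept = b.mean() - slope * a.mean()
    return float(slope), float(intercept)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def costes_threshold(imgA, imgB, n_steps: int = 200) -> tuple:
    """Automatic (T_A, T_B) threshold pair along the regression line.

    Candidate T_A values step down through intensity quantiles of channel
    A; T_B follows the orthogonal regression.  The first pair for which
    the below-both-thresholds Pearson correlation is <= 0 (or undefined)
    is accepted; if none is reached, the lowest candidate is returned.
    """
    a = np.asarray(imgA, dtype=float).ravel()
    b = np.asarray(imgB, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("channel images must have equal shapes")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("intensities must be non-negative")
    slope, intercept = _orthogonal_regression(a, b)
    # quantile ladder from the top of A's range downward
    qs = np.linspace(1.0, 0.0, n_steps + 1)
    candidates = np.unique(np.quantile(a, qs))[::-1]
    t_a = candidates[0]
    t_b = slope * t_a + intercept
    for t_a in candidates:
        t_b = slope * t_a + intercept
        below = (a < t_a) & (b < t_b)
        if below.sum() < 2:
            continue
        r = _pearson(a[below], b[below])
        if np.isnan(r) or r <= 0:
            break
    t_a = float(np.clip(t_a, a.min(), a.max()))
    t_b = float(np.clip(t_b, b.min(), b.max()))
    return t_a, t_b


def manders(imgA, imgB, T_A: float, T_B: float) -> ColocResult:
    """Thresholded Manders' M1/M2 at the given thresholds.

    Mask convention: channel A's measured signal is its above-threshold
    pixels (A > T_A); of that signal, the colocalized part is gated by the
    partner channel's threshold (B > T_B).  So
    ``M1 = sum A[A > T_A and B > T_B] / sum A[A > T_A]`` and M2 swaps the
    roles, which keeps both coefficients in [0, 1] by construction.
    """
    a = np.asarray(imgA, dtype=float)
    b = np.asarray(imgB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel images must have equal shapes")
    above_a = a > T_A
    above_b = b > T_B
    denom_a = a[above_a].sum()
    denom_b = b[above_b].sum()
    if denom_a <= 0 or denom_b <= 0:
        raise ValueError(
            "no above-threshold signal in one channel; Manders undefined"
        )
    both = above_a & above_b
    m1 = float(a[both].sum() / denom_a)
    m2 = float(b[both].sum() / denom_b)
    below = ~above_a & ~above_b
    r_below = _pearson(a[below].ravel(), b[below].ravel()) if below.sum() >= 2 else np.nan
    return ColocResult(
        M1=m1, M2=m2,
        thresholds=(float(T_A), float(T_B)),
        pearson_below=r_below,
    )


def coloc_auto(imgA, imgB) -> ColocResult:
    """Costes threshold search followed by Manders' coefficients."""
    t_a, t_b = costes_threshold(imgA, imgB)
    return manders(imgA, imgB, t_a, t_b)
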