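"""Independent minimal EMD used only as a cross-check oracle in tests.

Intentionally written with different primitives and policies than the
package implementation so that agreement between the two is evidence of
correctness rather than shared code: extrema come from
``scipy.signal.argrelextrema``, envelope knots are clamped to the signal
endpoints instead of mirrored, and the sift runs a fixed number of
iterations (S-number style) with no Cauchy or envelope test.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    n = x.size
    # clamp: include both endpoints as knots
    knots = np.concatenate([[0], idx, [n - 1]])
    knots = np.unique(knots)
    return CubicSpline(knots, x[knots])(np.arange(n))


def reference_sift(x: np.ndarray, n_iters: int = 3) -> np.ndarray | None:
    # A small fixed iteration count: the clamped-endpoint knots make each
    # extra sift pass accumulate boundary error on slow modes, so the
    # reference deliberately under- rather than over-sifts.
    d = x.astype(float).copy()
    for _ in range(n_iters):
        mx = argrelextrema(d, np.greater)[0]
        mn = argrelextrema(d, np.less)[0]
        if mx.size < 2 or mn.size < 2:
            return None
        m = 0.5 * (_envelope(d, mx) + _envelope(d, mn))
        d = d - m
    return d


def reference_emd(x: np.ndarray, n_imfs: int = 3) -> list[np.ndarray]:
    """Up to ``n_imfs`` modes from the fixed-iteration reference sifter."""
    imfs: list[np.ndarray] = []
    residual = np.asarray(x, dtype=float).copy()
    for _ in range(n_imfs):
        d = reference_sift(residual)
        if d is None:
            break
        imfs.append(d)
        residual = residual - d
    return imfs
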