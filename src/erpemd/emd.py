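"""Empirical mode decomposition by sifting with cubic-spline envelopes.

A signal is decomposed into intrinsic mode functions (IMFs) and a residual:

    x(t) = sum_i imf_i(t) + r_n(t)

Each IMF must (a) have extrema and zero-crossing counts differing by at
most one and (b) have a near-zero mean envelope everywhere.  Sifting
repeatedly subtracts the mean of the upper and lower cubic-spline
envelopes until the candidate satisfies the IMF criteria, a Cauchy-type
convergence criterion fires, or an iteration cap is hit.  End effects are
controlled by mirroring the two extrema nearest each edge about the edge
before spline fitting.

Only the first few IMFs are of interest for event-related potentials:
they carry the high-frequency (beta/gamma-range) oscillatory content,
while later modes are smooth slow trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SiftConfig",
    "IMFDecomposition",
    "InsufficientExtremaError",
    "find_extrema",
    "zero_crossings",
    "build_envelopes",
    "mean_envelope",
    "is_imf",
    "sift_one_imf",
    "emd_decompose",
]


class InsufficientExtremaError(ValueError):
    """Raised when a signal has too few extrema to build spline envelopes.

    Signals a monotone (or near-monotone) residual: decomposition stops.
    """


@dataclass(frozen=True)
class SiftConfig:
    """Sifting parameters.

    ``sd_threshold`` is the Cauchy stopping bound on
    ``sum((d_prev - d)**2) / sum(d_prev**2)`` between successive sift
    iterates; ``envelope_tolerance`` bounds the residual mean envelope
    relative to the candidate's peak-to-peak amplitude in the IMF test.
    """

    n_imfs: int = 3
    max_sift_iters: int = 50
    sd_threshold: float = 0.2
    envelope_tolerance: float = 0.05
    boundary_mode: str = "mirror"

    def __post_init__(self) -> None:
        if self.n_imfs < 1:
            raise ValueError("n_imfs must be >= 1")
        if self.max_sift_iters < 1:
            raise ValueError("max_sift_iters must be >= 1")
        if self.sd_threshold <= 0 or self.envelope_tolerance <= 0:
            raise ValueError("thresholds must be > 0")
        if self.boundary_mode != "mirror":
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")


@dataclass
class IMFDecomposition:
    """Ordered IMFs plus residual for one channel waveform."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_length: int
    sift_counts: list[int] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out = out + imf
        return out


# ----------------------------------------------------------------------
# extrema and zero crossings
# ----------------------------------------------------------------------

def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima and minima indices, sorted, disjoint.

    A flat run bounded by a rise and a fall (or fall and rise) counts as a
    single extremum at its midpoint.  Signals shorter than 3 samples have
    no extrema.
    """
    x = np.asarray(signal, dtype=float)
    empty = np.array([], dtype=int)
    if x.size < 3:
        return empty, empty
    dx = np.diff(x)
    nz = np.nonzero(dx)[0]
    if nz.size < 2:
        return empty, empty  # constant or monotone-with-plateaus
    maxima: list[int] = []
    minima: list[int] = []
    prev = nz[0]
    for cur in nz[1:]:
        if dx[prev] > 0 and dx[cur] < 0:
            maxima.append((prev + 1 + cur) // 2)
        elif dx[prev] < 0 and dx[cur] > 0:
            minima.append((prev + 1 + cur) // 2)
        prev = cur
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def zero_crossings(signal: np.ndarray) -> int:
    """Number of sign changes; an exact-zero sample counts once."""
    x = np.asarray(signal, dtype=float)
    s = x[x != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[:-1] * s[1:] < 0))


# ----------------------------------------------------------------------
# envelopes
# ----------------------------------------------------------------------

def _mirror_knots(
    idx: np.ndarray, val: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror the two extrema nearest each edge about that edge."""
    left_t = -idx[:2][::-1]
    left_v = val[:2][::-1]
    right_t = 2 * (n - 1) - idx[-2:][::-1]
    right_v = val[-2:][::-1]
    t = np.concatenate([left_t, idx, right_t]).astype(float)
    v = np.concatenate([left_v, val, right_v])
    # mirrored knots can coincide with originals when an extremum sits on
    # the edge; keep strictly increasing knots
    keep = np.concatenate([[True], np.diff(t) > 0])
    return t[keep], v[keep]


def build_envelopes(
    signal: np.ndarray,
    maxima: np.ndarray,
    minima: np.ndarray,
    boundary_mode: str = "mirror",
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline lower and upper envelopes evaluated at every sample.

    Returns ``(e_min, e_max)``.  Raises :class:`InsufficientExtremaError`
    if either extremum family has fewer than 2 members (monotone residual).
    """
    if boundary_mode != "mirror":
        raise ValueError(f"unknown boundary_mode {boundary_mode!r}")
    x = np.asarray(signal, dtype=float)
    if len(maxima) < 2 or len(minima) < 2:
        raise InsufficientExtremaError(
            f"need >= 2 maxima and >= 2 minima, got {len(maxima)}/{len(minima)}"
        )
    n = x.size
    t = np.arange(n)
    t_max, v_max = _mirror_knots(np.asarray(maxima), x[maxima], n)
    t_min, v_min = _mirror_knots(np.asarray(minima), x[minima], n)
    e_max = CubicSpline(t_max, v_max)(t)
    e_min = CubicSpline(t_min, v_min)(t)
    return e_min, e_max


def mean_envelope(e_min: np.ndarray, e_max: np.ndarray) -> np.ndarray:
    """Pointwise mean of the lower and upper envelopes."""
    e_min = np.asarray(e_min, dtype=float)
    e_max = np.asarray(e_max, dtype=float)
    if e_min.shape != e_max.shape:
        raise ValueError(
            f"envelope length mismatch: {e_min.shape} vs {e_max.shape}"
        )
    return 0.5 * (e_min + e_max)


# ----------------------------------------------------------------------
# IMF test and sifting
# ----------------------------------------------------------------------

def is_imf(
    signal: np.ndarray,
    envelope_tolerance: float = 0.05,
    boundary_mode: str = "mirror",
) -> tuple[bool, dict]:
    """Test the two IMF criteria.

    True iff |#extrema − #zero-crossings| <= 1 and the maximum absolute
    mean envelope is at most ``envelope_tolerance`` times the signal's
    peak-to-peak range.  The zero signal is an IMF by convention.
    Diagnostics report the counts and the envelope magnitude.
    """
    x = np.asarray(signal, dtype=float)
    maxima, minima = find_extrema(x)
    n_ext = len(maxima) + len(minima)
    n_zc = zero_crossings(x)
    ptp = float(np.ptp(x))
    if len(maxima) < 2 or len(minima) < 2:
        # envelopes undefined; accept only if there is nothing oscillatory
        # left to balance (zero or near-flat signal)
        mean_env_max = 0.0
    else:
        e_min, e_max = build_envelopes(x, maxima, minima, boundary_mode)
        mean_env_max = float(np.max(np.abs(mean_envelope(e_min, e_max))))
    counts_ok = abs(n_ext - n_zc) <= 1
    env_ok = ptp == 0.0 or mean_env_max <= envelope_tolerance * ptp
    diagnostics = {
        "n_extrema": n_ext,
        "n_zero_crossings": n_zc,
        "mean_envelope_max": mean_env_max,
        "peak_to_peak": ptp,
    }
    return bool(counts_ok and env_ok), diagnostics


def _is_monotone(x: np.ndarray) -> bool:
    maxima, minima = find_extrema(x)
    return len(maxima) == 0 and len(minima) == 0


def sift_one_imf(
    signal: np.ndarray, config: SiftConfig = SiftConfig()
) -> tuple[Optional[np.ndarray], np.ndarray, int]:
    """Extract one IMF from ``signal`` by iterated envelope-mean removal.

    Returns ``(imf, residual, iterations)``; for a monotone input the IMF
    is None, the residual is the input and the count 0.  ``imf + residual``
    reconstructs the input exactly (the residual is computed by
    subtraction).
    """
    x = np.asarray(signal, dtype=float)
    if _is_monotone(x):
        return None, x.copy(), 0
    d = x.copy()
    k = 0
    for _ in range(config.max_sift_iters):
        maxima, minima = find_extrema(d)
        try:
            e_min, e_max = build_envelopes(d, maxima, minima, config.boundary_mode)
        except InsufficientExtremaError:
            break
        m = mean_envelope(e_min, e_max)
        d_new = d - m
        k += 1
        ok, diag = is_imf(d_new, config.envelope_tolerance, config.boundary_mode)
        if ok:
            d = d_new
            break
        denom = float(np.sum(d * d))
        sd = float(np.sum((d - d_new) ** 2)) / denom if denom > 0 else 0.0
        d = d_new
        # accept the Cauchy stop only once the extrema/zero-crossing count
        # criterion holds, so returned modes are bona fide IMFs
        counts_ok = abs(diag["n_extrema"] - diag["n_zero_crossings"]) <= 1
        if sd < config.sd_threshold and counts_ok:
            break
    return d, x - d, k


def emd_decompose(
    signal: np.ndarray, config: SiftConfig = SiftConfig()
) -> IMFDecomposition:
    """Decompose ``signal`` into up to ``config.n_imfs`` IMFs plus residual.

    Each extracted IMF is sifted from the running residual; extraction
    stops early when the residual is monotone or lacks two maxima/minima.
    The additive reconstruction ``sum(imfs) + residual == signal`` holds to
    floating-point accuracy by construction.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd_decompose expects a 1-D signal")
    if x.size < 8:
        raise ValueError(f"signal too short for EMD: {x.size} < 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    residual = x.copy()
    for _ in range(config.n_imfs):
        maxima, minima = find_extrema(residual)
        if len(maxima) < 2 or len(minima) < 2:
            break
        imf, residual, k = sift_one_imf(residual, config)
        if imf is None:
            break
        imfs.append(imf)
        counts.append(k)
    return IMFDecomposition(
        imfs=imfs, residual=residual, source_length=x.size, sift_counts=counts
    )


def decompose_to_n(
    signal: np.ndarray, config: SiftConfig = SiftConfig()
) -> list[np.ndarray]:
    """Exactly ``config.n_imfs`` mode waveforms, zero-padding missing ones.

    Convenience for feature assembly, which needs a fixed number of modes
    per channel even when extraction stops early on a smooth signal.
    """
    dec = emd_decompose(signal, config)
    out = list(dec.imfs)
    while len(out) < config.n_imfs:
        out.append(np.zeros(dec.source_length))
    return out
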