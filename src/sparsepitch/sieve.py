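"""Gaussian harmonic sieve: sparse coefficients -> pitch probability density.

Every row i of the sieve matrix G scores one candidate pitch f_i: it is a sum
of Gaussians centered on the harmonics n*f_i (n = 1, 2, ... while
n*f_i <= f_max) with standard deviation

    sigma_i = 0.2 * ERB(f_i) = 0.2 * 24.7 * (4.37 * f_i / 1000 + 1)   [Hz]

so template width tracks cochlear bandwidth.  The coefficient vector h
(length M, on the dictionary frequency axis) is linearly interpolated onto a
dense candidate grid (P = 15 M points), multiplied by G, and L1-normalized
into a genuine unit-sum density.  The pitch estimate is the density argmax,
optionally restricted to a +-0.5 octave interval as in psychoacoustic
readouts; salience is the height ratio of the two tallest local maxima
within one octave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .periphery import erb, erb_space

GRID_OVERSAMPLE = 15  # dense grid points per dictionary atom


def pitch_grid(n_points: int, f_min: float = 125.0, f_max: float = 20000.0) -> np.ndarray:
    """Dense candidate-pitch grid, ERB-number spaced."""
    return erb_space(f_min, f_max, n_points)


@dataclass
class SieveMatrix:
    grid: np.ndarray  # (P,) ascending candidate pitches
    weights: np.ndarray  # (P, P), rows = candidate pitch templates
    sigmas: np.ndarray  # (P,)


@dataclass
class PitchPDF:
    grid: np.ndarray
    probs: np.ndarray  # nonnegative, unit sum
    no_pitch: bool = False


def build_sieve(grid: np.ndarray, f_max: float = 20000.0) -> SieveMatrix:
    """Assemble the P x P harmonic-template matrix for a candidate grid."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly ascending")
    P = len(grid)
    sigmas = 0.2 * erb(grid)
    G = np.zeros((P, P), dtype=np.float32)
    for i in range(P):
        fi, si = grid[i], sigmas[i]
        for n in range(1, int(f_max // fi) + 1):
            center = n * fi
            lo = np.searchsorted(grid, center - 8 * si)
            hi = np.searchsorted(grid, center + 8 * si)
            if hi > lo:
                d = grid[lo:hi] - center
                G[i, lo:hi] += np.exp(-(d * d) / (2 * si * si))
    return SieveMatrix(grid=grid, weights=G, sigmas=sigmas)


_SIEVE_CACHE: dict[tuple, SieveMatrix] = {}


def sieve_for(n_points: int, f_min: float = 125.0, f_max: float = 20000.0) -> SieveMatrix:
    """Cached sieve for a standard grid (built once per geometry)."""
    key = (n_points, round(f_min, 6), round(f_max, 6))
    if key not in _SIEVE_CACHE:
        _SIEVE_CACHE[key] = build_sieve(pitch_grid(n_points, f_min, f_max), f_max)
    return _SIEVE_CACHE[key]


def interpolate_coefficients(
    h: np.ndarray, dict_freqs: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Linear interpolation of h from the atom frequencies onto the dense grid."""
    if len(grid) < len(h):
        raise ValueError("dense grid shorter than coefficient vector")
    ht = np.interp(grid, dict_freqs, np.asarray(h, dtype=float), left=0.0, right=0.0)
    return np.maximum(ht, 0.0)


def compute_pdf(h_tilde: np.ndarray, sieve: SieveMatrix) -> PitchPDF:
    """p = G . h_tilde, L1-normalized to a unit-sum density.

    An all-zero input carries no pitch cue; a uniform density is returned
    with the ``no_pitch`` flag set.
    """
    h_tilde = np.asarray(h_tilde, dtype=float)
    if np.any(h_tilde < 0):
        raise ValueError("h_tilde must be nonnegative")
    p = sieve.weights.astype(float) @ h_tilde
    total = p.sum()
    if total <= 0:
        n = len(sieve.grid)
        return PitchPDF(sieve.grid, np.full(n, 1.0 / n), no_pitch=True)
    return PitchPDF(sieve.grid, p / total)


def octave_interval(center: float) -> tuple[float, float]:
    """The +-0.5 octave (geometric) interval around ``center``."""
    return center / np.sqrt(2.0), center * np.sqrt(2.0)


def _local_maxima(p: np.ndarray) -> np.ndarray:
    """Indices of strict 3-point local maxima; plateaus take their left edge."""
    idx, props = find_peaks(p, plateau_size=1)
    return props["left_edges"] if len(idx) else idx


@dataclass
class PitchEstimate:
    f_hat: float
    peaks: np.ndarray  # (k, 2) [frequency, height], sorted by height desc


def estimate_pitch(
    pdf: PitchPDF, restrict: tuple[float, float] | None = None
) -> PitchEstimate:
    """Argmax pitch plus ranked local maxima, optionally within an interval."""
    grid, p = pdf.grid, pdf.probs
    if restrict is not None:
        lo, hi = restrict
        mask = (grid >= lo) & (grid <= hi)
        if not mask.any():
            raise ValueError("restriction interval contains no grid points")
    else:
        mask = np.ones(len(grid), dtype=bool)
    sub = np.where(mask, p, -np.inf)
    # np.argmax returns the first (= lowest-frequency) point of a tie
    best = int(np.argmax(sub))
    peaks_idx = _local_maxima(p)
    peaks_idx = peaks_idx[mask[peaks_idx]]
    order = np.argsort(p[peaks_idx])[::-1]
    peaks = np.column_stack([grid[peaks_idx][order], p[peaks_idx][order]]) \
        if len(peaks_idx) else np.empty((0, 2))
    return PitchEstimate(f_hat=float(grid[best]), peaks=peaks)


def salience(pdf: PitchPDF, interval: tuple[float, float]) -> float:
    """Ratio of the two tallest local maxima within a one-octave interval.

    Returns ``inf`` when fewer than two local maxima fall inside (a single
    unambiguous peak: maximally salient).
    """
    est = estimate_pitch(pdf, restrict=interval)
    if len(est.peaks) < 2:
        return float("inf")
    return float(est.peaks[0, 1] / est.peaks[1, 1])
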