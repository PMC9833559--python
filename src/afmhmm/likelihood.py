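"""Per-frame image likelihoods for rigid-body fitting.

Three scores between a reference (observed) image and a pseudo-AFM template:

* the full Gaussian likelihood, whose maximum coincides with the minimum
  pixel-RMSD at fixed noise width λ;
* the marginalized likelihood, in which the unknown height-scale β, stage
  offset dz and noise width λ are integrated out analytically (Gaussian
  integrals for β and dz, a saddle-point approximation for λ), leaving a
  score that depends only on five pixel sums

      Co = Σ I_ref,  Cc = Σ I_pseudo,  Coo = Σ I_ref²,
      Ccc = Σ I_pseudo²,  Coc = Σ I_ref·I_pseudo;

* an FFT translation search that evaluates the marginalized likelihood at
  every cyclic integer-pixel shift of the template (only Coc depends on the
  shift) and takes the slice at the maximizing shift.

All marginalized values are computed in log space; nothing is exponentiated,
so the score is stable at N_pixel = 4800 and beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .afm_imaging import AFMImage, _heights

__all__ = [
    "SimilarityStats",
    "NoiseModel",
    "AffineCalibration",
    "DegenerateImageError",
    "similarity_stats",
    "pixel_rmsd",
    "full_log_likelihood",
    "marginal_log_likelihood",
    "translation_loglik_map",
    "best_translation",
]

# Relative floor applied to the residual bracket of the marginalized
# likelihood: a numerically perfect template match would otherwise send the
# log-likelihood to +inf (zero residual corresponds to λ -> 0).
_B1_RELATIVE_FLOOR = 1e-15


class DegenerateImageError(ValueError):
    """Raised when the marginalized likelihood is undefined (e.g. a constant
    pseudo-image, for which the height scale β cannot be resolved)."""


@dataclass(frozen=True)
class SimilarityStats:
    """The five pixel sums entering the marginalized likelihood (nm units)."""

    co: float
    cc: float
    coo: float
    ccc: float
    coc: float


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian pixel-noise model; ``lam`` is the standard deviation (nm)."""

    lam: float

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("noise standard deviation must be positive")


@dataclass(frozen=True)
class AffineCalibration:
    """Height calibration (scale β, stage offset dz).  The fitting pipeline
    never estimates these — they are marginalized out — but the type is used
    by the brute-force marginalization cross-checks."""

    beta: float = 1.0
    dz_offset: float = 0.0

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("height scale beta must be positive")


def _pair(iref, ipseudo):
    a, b = _heights(iref), _heights(ipseudo)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def similarity_stats(iref, ipseudo) -> SimilarityStats:
    """The five sums Co, Cc, Coo, Ccc, Coc over all pixels."""
    a, b = _pair(iref, ipseudo)
    return SimilarityStats(
        co=float(a.sum()),
        cc=float(b.sum()),
        coo=float((a * a).sum()),
        ccc=float((b * b).sum()),
        coc=float((a * b).sum()),
    )


def pixel_rmsd(iref, ipseudo) -> float:
    """Root mean squared pixel-height difference (nm)."""
    a, b = _pair(iref, ipseudo)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def full_log_likelihood(iref, ipseudo, noise: NoiseModel) -> float:
    """Log of the full Gaussian image likelihood.

    Per-pixel normalizer (2πλ²)^(−1/2) with λ the noise standard deviation;
    at fixed λ the ranking over templates equals the ascending pixel-RMSD
    ranking.
    """
    a, b = _pair(iref, ipseudo)
    lam = noise.lam
    n = a.size
    return float(-0.5 * n * np.log(2.0 * np.pi * lam * lam)
                 - ((a - b) ** 2).sum() / (2.0 * lam * lam))


def _marginal_arrays(co, cc, coo, ccc, coc, n):
    """Broadcasted log marginalized likelihood (no degeneracy checks).

    The two bracket terms are the translation-dependent residual bracket B1
    and the template-variance bracket B2; the constant prefactor
    √π·(2πe)^(1−N/2) is the exact Gaussian-integral constant, so absolute
    values agree with brute-force marginalization of the full likelihood up
    to the λ saddle-point error.
    """
    n = float(n)
    b2 = (n - 2.0) * (n * ccc - cc * cc)
    b1 = n * (ccc * coo - coc**2) + 2.0 * co * coc * cc - ccc * co**2 - coo * cc**2
    floor = _B1_RELATIVE_FLOOR * np.maximum(n * ccc * coo, np.finfo(float).tiny)
    b1 = np.clip(b1, floor, None)
    return (
        0.5 * np.log(np.pi)
        + (1.0 - n / 2.0) * np.log(2.0 * np.pi * np.e)
        + (1.5 - n / 2.0) * np.log(b1)
        + (n / 2.0 - 2.0) * np.log(b2)
    )


def _marginal_core(co, cc, coo, ccc, coc, n):
    """Log marginalized likelihood; ``coc`` may be an array (per-shift map)."""
    if (n - 2.0) * (n * ccc - cc * cc) <= 0.0:
        raise DegenerateImageError(
            "degenerate pseudo-image: zero height variance (constant image), "
            "the height scale cannot be marginalized"
        )
    out = _marginal_arrays(co, cc, coo, ccc, np.asarray(coc, dtype=float), n)
    return out if out.shape else float(out)


def marginal_log_likelihood(stats: SimilarityStats, n_pixel: int) -> float:
    """Log of the marginalized likelihood given the five similarity sums.

    Invariant to adding a constant to the pseudo-image (dz marginalized) and
    shifts by exactly −log a when the pseudo-image is scaled by a > 0 (β
    marginalized).  Requires ``n_pixel >= 5`` so both bracket exponents are
    meaningful; a constant pseudo-image raises :class:`DegenerateImageError`.
    """
    if n_pixel < 5:
        raise ValueError(f"n_pixel must be >= 5, got {n_pixel}")
    return _marginal_core(stats.co, stats.cc, stats.coo, stats.ccc, stats.coc, n_pixel)


def translation_loglik_map(iref, template) -> np.ndarray:
    """Log marginalized likelihood at every cyclic integer-pixel shift.

    Entry ``[dy, dx]`` scores the template cyclically shifted down by ``dy``
    rows and right by ``dx`` columns.  Only Coc varies with the shift; it is
    computed for all shifts at once by FFT cross-correlation.
    """
    a, b = _pair(iref, template)
    if a.size < 5:
        raise ValueError("images must have at least 5 pixels")
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    coc_map = np.fft.irfft2(fa * np.conj(fb), s=a.shape)
    return _marginal_core(
        float(a.sum()), float(b.sum()), float((a * a).sum()), float((b * b).sum()),
        coc_map, a.size,
    )


def best_translation(iref, template):
    """Maximize the marginalized likelihood over cyclic integer shifts.

    Returns ``(dx, dy, log_marginal)``; ties are broken by the smallest
    (dy, dx) lexicographically.
    """
    ll = translation_loglik_map(iref, template)
    flat = int(np.argmax(ll))  # first occurrence in row-major order = smallest (dy, dx)
    dy, dx = np.unravel_index(flat, ll.shape)
    return int(dx), int(dy), float(ll[dy, dx])
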