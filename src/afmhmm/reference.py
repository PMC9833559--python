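"""Independent brute-force reference implementations.

These deliberately avoid the optimized code paths (closed-form tip contact,
FFT correlation, forward-backward/Viterbi recursions, saddle-point
marginalization) and recompute the same quantities by direct enumeration,
dense sampling, or numerical quadrature.  They are slow and exist to
cross-check the production implementations on small inputs.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.special import logsumexp

from . import orientations
from .afm_imaging import AFMImage, ImageGrid, Structure, TipModel, pixel_centers, _heights

__all__ = [
    "tip_profile",
    "synthesize_image_dilation",
    "correlation_map_direct",
    "marginal_loglik_quadrature",
    "evidence_enumerate",
    "viterbi_enumerate",
]


def tip_profile(s, tip: TipModel):
    """Height of the tip's lower surface above its lowest point, at lateral
    distance ``s`` from the axis (hemisphere blended into a cone flank)."""
    s = np.asarray(s, dtype=float)
    r = tip.apex_radius
    theta = np.deg2rad(tip.half_angle_deg)
    switch = r * np.cos(theta)
    apex = r - np.sqrt(np.clip(r * r - s * s, 0.0, None))
    flank = (r - r * np.sin(theta)) + (s - switch) / np.tan(theta)
    return np.where(s <= switch, apex, flank)


def synthesize_image_dilation(structure: Structure, q, dx: float, dy: float,
                              tip: TipModel, grid: ImageGrid,
                              n_samples: int = 2000) -> AFMImage:
    """Pseudo-AFM image as a morphological dilation of densely sampled bead
    surfaces by the tip profile.

    For each pixel the height is the maximum over sampled bead-surface
    points p of ``z_p − profile(lateral distance from p to the tip axis)``,
    clipped at the stage — the definition of grayscale dilation by the
    (reflected) tip.  By symmetry the maximizing surface point lies in the
    plane containing the bead centre and the tip axis, so each bead reduces
    to a dense 1-D scan over its cross-section circle.
    """
    if len(structure) == 0:
        return AFMImage(np.zeros(grid.shape), grid)
    rotated = orientations.rotate(structure, q)
    coords = rotated.coords.copy()
    coords[:, 2] -= coords[:, 2].min()
    coords[:, 0] += dx
    coords[:, 1] += dy

    xs, ys = pixel_centers(grid)
    t = np.linspace(0.0, np.pi, n_samples)
    sin_t, cos_t = np.sin(t), np.cos(t)

    heights = np.zeros(grid.shape)
    for (bx, by, bz), radius in zip(coords, structure.radii):
        d = np.sqrt((xs[None, :] - bx) ** 2 + (ys[:, None] - by) ** 2)  # (ny, nx)
        # surface point at angle t: lateral offset radius*sin(t) toward/away
        # from the axis, height bz + radius*cos(t)
        lateral = np.abs(d[:, :, None] - radius * sin_t[None, None, :])
        cand = bz + radius * cos_t[None, None, :] - tip_profile(lateral, tip)
        heights = np.maximum(heights, cand.max(axis=2))
    return AFMImage(np.clip(heights, 0.0, None), grid)


def correlation_map_direct(iref, template) -> np.ndarray:
    """Cyclic cross-correlation Coc(dy, dx) by an explicit double loop."""
    a, b = _heights(iref), _heights(template)
    ny, nx = a.shape
    out = np.empty((ny, nx))
    for sy in range(ny):
        for sx in range(nx):
            out[sy, sx] = float((a * np.roll(b, (sy, sx), axis=(0, 1))).sum())
    return out


def marginal_loglik_quadrature(iref, ipseudo) -> float:
    """Marginalization of the full Gaussian likelihood by direct integration.

    β and dz are integrated analytically (Gaussian integrals); the noise
    width λ is integrated numerically with a flat prior.  Serves as the
    oracle for the saddle-point marginalized likelihood.
    """
    a, b = _heights(iref), _heights(ipseudo)
    if a.shape != b.shape:
        raise ValueError("image shapes differ")
    n = a.size
    co, cc = float(a.sum()), float(b.sum())
    coo, ccc = float((a * a).sum()), float((b * b).sum())
    coc = float((a * b).sum())

    det = n * ccc - cc * cc
    if det <= 0:
        raise ValueError("degenerate (constant) pseudo-image")
    s_min = (n * (ccc * coo - coc**2) + 2.0 * co * coc * cc
             - ccc * co**2 - coo * cc**2) / det
    if s_min <= 0:
        raise ValueError("zero residual; marginal diverges")

    # after the beta/dz Gaussian integrals the integrand over lambda is
    #   (2*pi*lam^2)^(-n/2) * 2*pi*lam^2 / sqrt(det) * exp(-s_min/(2 lam^2))
    const = -0.5 * n * np.log(2.0 * np.pi) + np.log(2.0 * np.pi) - 0.5 * np.log(det)
    lam_star = np.sqrt(s_min / (n - 2.0))  # mode of the lambda integrand

    def log_integrand(lam):
        return const + (2.0 - n) * np.log(lam) - s_min / (2.0 * lam * lam)

    peak = log_integrand(lam_star)
    value, _ = quad(lambda lam: np.exp(log_integrand(lam) - peak),
                    0.0, np.inf, limit=200)
    return float(peak + np.log(value))


def _path_logprob(path, loglik, log_T, log_pi):
    lp = log_pi[path[0]] + loglik[0, path[0]]
    for t in range(1, len(path)):
        lp += log_T[path[t - 1], path[t]] + loglik[t, path[t]]
    return lp


def _log_params(model):
    with np.errstate(divide="ignore"):
        return np.log(model.transition), np.log(model.initial)


def evidence_enumerate(loglik: np.ndarray, model) -> float:
    """Time-series evidence by explicit summation over all M^T state paths."""
    loglik = np.asarray(loglik, dtype=float)
    n_t, n_s = loglik.shape
    log_T, log_pi = _log_params(model)
    scores = [_path_logprob(path, loglik, log_T, log_pi)
              for path in itertools.product(range(n_s), repeat=n_t)]
    return float(logsumexp(scores))


def viterbi_enumerate(loglik: np.ndarray, model):
    """Maximum-likelihood path by explicit enumeration (ties -> first path
    in lexicographic order, matching the lowest-state-index tie-break)."""
    loglik = np.asarray(loglik, dtype=float)
    n_t, n_s = loglik.shape
    log_T, log_pi = _log_params(model)
    best_path, best_score = None, -np.inf
    for path in itertools.product(range(n_s), repeat=n_t):
        score = _path_logprob(path, loglik, log_T, log_pi)
        if score > best_score:
            best_path, best_score = path, score
    return np.asarray(best_path, dtype=int), float(best_score)
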