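"""Frame-by-frame rigid-body fitting.

Scans every candidate structure x orientation state against each frame:
synthesizes the pseudo-AFM template once per state at zero shift (the
molecule geometry does not depend on the frame), then evaluates the
marginalized likelihood at every cyclic integer-pixel translation via FFT
cross-correlation and keeps the maximum slice.  The per-(frame, state) log
likelihoods form the emission table consumed by the hidden Markov stage; the
per-frame argmax is the classical frame-by-frame maximum-likelihood estimate.

The height scale β and stage offset dz are never explicit parameters here —
they are marginalized inside the likelihood, so imperfect height calibration
does not bias the fit.  The tip radius is fixed during a fit;
:func:`scan_tip_radius` repeats the fit independently per radius.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .afm_imaging import AFMImage, ImageGrid, ImageSeries, TipModel, synthesize_image, _heights
from .likelihood import _marginal_core, DegenerateImageError

__all__ = [
    "EmissionTable",
    "make_state_space",
    "synthesize_templates",
    "compute_emissions",
    "fit_frame",
    "fit_series",
    "scan_tip_radius",
    "save_emissions",
    "load_emissions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmissionTable:
    """Per-frame log marginal likelihood over (structure, orientation) states.

    ``loglik`` is (T, M); ``dx``/``dy`` record the maximizing integer-pixel
    translation per (frame, state).  ``states`` is an (M, 2) array of
    (structure index, orientation index) pairs.  ``log_offset`` (length T)
    is an additive per-frame offset: absolute log-likelihoods are
    ``loglik + log_offset[:, None]`` (all zeros unless a table has been
    rescaled).
    """

    loglik: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    states: np.ndarray
    tip_radius: float | None = None
    log_offset: np.ndarray | None = None

    def __post_init__(self):
        ll = np.asarray(self.loglik, dtype=float)
        object.__setattr__(self, "loglik", ll)
        object.__setattr__(self, "dx", np.asarray(self.dx, dtype=int))
        object.__setattr__(self, "dy", np.asarray(self.dy, dtype=int))
        object.__setattr__(self, "states", np.asarray(self.states, dtype=int))
        offset = self.log_offset
        if offset is None:
            offset = np.zeros(ll.shape[0])
        object.__setattr__(self, "log_offset", np.asarray(offset, dtype=float))

    @property
    def n_frames(self) -> int:
        return self.loglik.shape[0]

    @property
    def n_states(self) -> int:
        return self.loglik.shape[1]

    def argmax_states(self) -> np.ndarray:
        """Per-frame argmax state index (ties -> lowest state index)."""
        return np.argmax(self.loglik, axis=1)


def make_state_space(n_structures: int, n_orientations: int) -> np.ndarray:
    """(M, 2) array of (structure, orientation) pairs, structure-major order."""
    m, o = np.meshgrid(np.arange(n_structures), np.arange(n_orientations), indexing="ij")
    return np.stack([m.ravel(), o.ravel()], axis=1)


def synthesize_templates(ensemble, grid_q: np.ndarray, tip: TipModel,
                         image_grid: ImageGrid) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one zero-shift template per (structure, orientation) state.

    Returns ``(templates, states)`` with templates of shape (M, ny, nx).
    """
    states = make_state_space(len(ensemble), len(grid_q))
    templates = np.empty((len(states),) + image_grid.shape)
    for s, (m, o) in enumerate(states):
        templates[s] = synthesize_image(ensemble[m], grid_q[o], 0.0, 0.0, tip,
                                        image_grid).heights
    return templates, states


def _emissions_for_frames(frames: np.ndarray, templates: np.ndarray,
                          states: np.ndarray, tip_radius=None) -> EmissionTable:
    n_pix = frames.shape[1] * frames.shape[2]
    n_states = len(templates)
    shape = frames.shape[1:]

    cc = templates.sum(axis=(1, 2))
    ccc = (templates**2).sum(axis=(1, 2))
    ft_conj = np.conj(np.fft.rfft2(templates, axes=(-2, -1)))
    b2 = (n_pix - 2.0) * (n_pix * ccc - cc * cc)
    degenerate = b2 <= 0
    if degenerate.any():
        logger.warning(
            "%d state(s) have degenerate (constant) templates; their "
            "log-likelihood is set to -inf", int(degenerate.sum()),
        )

    n_frames = len(frames)
    loglik = np.full((n_frames, n_states), -np.inf)
    best_dx = np.zeros((n_frames, n_states), dtype=int)
    best_dy = np.zeros((n_frames, n_states), dtype=int)
    ok = ~degenerate
    from .likelihood import _marginal_arrays

    for t, frame in enumerate(frames):
        fa = np.fft.rfft2(frame)
        coc_maps = np.fft.irfft2(fa[None, :, :] * ft_conj, s=shape)  # (M, ny, nx)
        co = float(frame.sum())
        coo = float((frame * frame).sum())
        ll_maps = _marginal_arrays(co, cc[ok, None, None], coo,
                                   ccc[ok, None, None], coc_maps[ok], n_pix)
        flat = ll_maps.reshape(ok.sum(), -1)
        best = np.argmax(flat, axis=1)  # first max = smallest (dy, dx)
        dys, dxs = np.unravel_index(best, shape)
        loglik[t, ok] = flat[np.arange(len(best)), best]
        best_dx[t, ok] = dxs
        best_dy[t, ok] = dys
    return EmissionTable(loglik, best_dx, best_dy, states, tip_radius=tip_radius)


def compute_emissions(series: ImageSeries, ensemble, grid_q: np.ndarray,
                      tip: TipModel, image_grid: ImageGrid | None = None) -> EmissionTable:
    """Emission table for a whole series: log marginal likelihood and best
    translation for every (frame, structure, orientation)."""
    image_grid = image_grid or series.grid
    templates, states = synthesize_templates(ensemble, grid_q, tip, image_grid)
    return _emissions_for_frames(series.frames, templates, states, tip.apex_radius)


def _argmax_row(table: EmissionTable, t: int):
    s = int(np.argmax(table.loglik[t]))
    return s, (int(table.states[s, 0]), int(table.states[s, 1]),
               int(table.dx[t, s]), int(table.dy[t, s]), float(table.loglik[t, s]))


def fit_frame(iref: AFMImage, ensemble, grid_q: np.ndarray, tip: TipModel,
              image_grid: ImageGrid | None = None):
    """Fit a single frame; returns ``(emission_row_table, best)`` where best
    is ``(m, orientation, dx, dy, loglik)`` under the deterministic
    (state index, dy, dx) tie-break."""
    image_grid = image_grid or iref.grid
    series = ImageSeries(_heights(iref)[None, :, :], image_grid)
    table = compute_emissions(series, ensemble, grid_q, tip, image_grid)
    _, best = _argmax_row(table, 0)
    return table, best


def fit_series(series: ImageSeries, ensemble, grid_q: np.ndarray, tip: TipModel,
               image_grid: ImageGrid | None = None):
    """Fit every frame of a series.

    Returns ``(EmissionTable, DataFrame)`` with one row per frame:
    frame, structure, orientation, dx, dy, loglik.
    """
    table = compute_emissions(series, ensemble, grid_q, tip, image_grid)
    rows = []
    for t in range(table.n_frames):
        _, (m, o, dx, dy, ll) = _argmax_row(table, t)
        rows.append((t, m, o, dx, dy, ll))
    result = pd.DataFrame(rows, columns=["frame", "structure", "orientation",
                                         "dx", "dy", "loglik"])
    return table, result


def scan_tip_radius(series: ImageSeries, ensemble, grid_q: np.ndarray,
                    radii, half_angle_deg: float = 10.0,
                    image_grid: ImageGrid | None = None) -> dict:
    """Independent fits of the same series at each tip apex radius.

    The radius is fixed within each fit; entries do not interact.
    Returns ``{radius: (EmissionTable, DataFrame)}``.
    """
    results = {}
    for r in radii:
        if r <= 0:
            raise ValueError(f"tip radius must be positive, got {r}")
        tip = TipModel(apex_radius=float(r), half_angle_deg=half_angle_deg)
        results[float(r)] = fit_series(series, ensemble, grid_q, tip, image_grid)
    return results


def save_emissions(table: EmissionTable, path) -> None:
    """Write an emission table to HDF5 with a JSON metadata sidecar."""
    import h5py

    path = str(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("loglik", data=table.loglik)
        fh.create_dataset("dx", data=table.dx)
        fh.create_dataset("dy", data=table.dy)
        fh.create_dataset("states", data=table.states)
        fh.create_dataset("log_offset", data=table.log_offset)
    meta = {"n_frames": int(table.n_frames), "n_states": int(table.n_states),
            "tip_radius": table.tip_radius}
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_emissions(path) -> EmissionTable:
    import h5py

    path = str(path)
    tip_radius = None
    try:
        with open(path + ".json") as fh:
            tip_radius = json.load(fh).get("tip_radius")
    except FileNotFoundError:
        pass
    with h5py.File(path, "r") as fh:
        return EmissionTable(fh["loglik"][...], fh["dx"][...], fh["dy"][...],
                             fh["states"][...], tip_radius=tip_radius,
                             log_offset=fh["log_offset"][...])
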