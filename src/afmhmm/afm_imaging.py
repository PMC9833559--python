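"""Pseudo-AFM image synthesis by tip-molecule collision detection, plus I/O.

A molecule is a set of beads (Cα atoms with per-residue effective radii, in
nm).  The probe tip is modelled as a hemispherical apex of radius ``r``
blended tangent-continuously into a conical frustum whose flank makes
``half_angle`` degrees with the vertical tip axis.  For each pixel the image
height is the lowest tip position at which the tip, descending perpendicular
to the stage, first touches any bead:

* apex contact (lateral bead distance ``d <= (r+R)·cosθ``):
  ``h = z − r + sqrt((r+R)² − d²)``
* flank contact (larger ``d``):
  ``h = z − r + (R + r − d·cosθ)/sinθ``

where ``z`` is the bead centre height and ``R`` its effective radius.  The
two regimes join where the cone is tangent to the apex hemisphere.  Heights
are clipped below at the stage (0 nm).

Coordinate convention: x maps to image columns (nx), y to rows (ny); pixel
centres are measured from the image centre, so a structure whose lateral
centroid is at the origin appears mid-image.  Before imaging the molecule is
rotated about its centroid, dropped so its minimum bead-centre z is 0, then
shifted laterally by continuous offsets (dx, dy).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from . import orientations

__all__ = [
    "Structure",
    "TipModel",
    "ImageGrid",
    "AFMImage",
    "ImageSeries",
    "DEFAULT_BEAD_RADIUS",
    "synthesize_image",
    "add_gaussian_noise",
    "read_structure",
    "read_image_series",
    "write_image_series",
    "pixel_centers",
]

#: Uniform fallback effective Cα radius (nm) used when no per-residue table is given.
DEFAULT_BEAD_RADIUS = 0.4


@dataclass(frozen=True)
class Structure:
    """Bead model of a molecule: coordinates (N, 3) in nm plus effective radii."""

    coords: np.ndarray
    radii: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if len(radii) != len(coords):
            raise ValueError("coords and radii must have matching lengths")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if len(radii) and (not np.all(np.isfinite(radii)) or np.any(radii <= 0)):
            raise ValueError("bead radii must be positive and finite")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class TipModel:
    """Probe tip: hemispherical apex of radius ``apex_radius`` (nm) blended
    into a cone whose flank makes ``half_angle_deg`` with the tip axis."""

    apex_radius: float = 2.5
    half_angle_deg: float = 10.0

    def __post_init__(self):
        if self.apex_radius <= 0:
            raise ValueError("tip apex radius must be positive")
        if not (0.0 < self.half_angle_deg < 90.0):
            raise ValueError("tip half angle must lie strictly between 0 and 90 degrees")


@dataclass(frozen=True)
class ImageGrid:
    """Raster geometry of the height map (pixel size in nm)."""

    pixel_size: float = 0.625
    nx: int = 80
    ny: int = 60

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("image must have at least one pixel per axis")

    @property
    def n_pixel(self) -> int:
        return self.nx * self.ny

    @property
    def shape(self) -> tuple:
        return (self.ny, self.nx)


@dataclass(frozen=True)
class AFMImage:
    """A single ny x nx height map (nm) on an :class:`ImageGrid`."""

    heights: np.ndarray
    grid: ImageGrid = field(default_factory=ImageGrid)

    def __post_init__(self):
        h = np.asarray(self.heights, dtype=float)
        if h.shape != self.grid.shape:
            raise ValueError(f"heights shape {h.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite")
        object.__setattr__(self, "heights", h)


@dataclass(frozen=True)
class ImageSeries:
    """Ordered stack of frames (T, ny, nx) sharing one grid."""

    frames: np.ndarray
    grid: ImageGrid = field(default_factory=ImageGrid)

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3 or f.shape[1:] != self.grid.shape:
            raise ValueError(f"frames must have shape (T, {self.grid.ny}, {self.grid.nx})")
        object.__setattr__(self, "frames", f)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, t) -> AFMImage:
        return AFMImage(self.frames[t], self.grid)


def pixel_centers(grid: ImageGrid):
    """Pixel-centre coordinates (nm) measured from the image centre."""
    xs = (np.arange(grid.nx) + 0.5) * grid.pixel_size - grid.nx * grid.pixel_size / 2.0
    ys = (np.arange(grid.ny) + 0.5) * grid.pixel_size - grid.ny * grid.pixel_size / 2.0
    return xs, ys


def _heights(image) -> np.ndarray:
    return image.heights if isinstance(image, AFMImage) else np.asarray(image, dtype=float)


def synthesize_image(
    structure: Structure,
    q=orientations.IDENTITY,
    dx: float = 0.0,
    dy: float = 0.0,
    tip: TipModel = TipModel(),
    grid: ImageGrid = ImageGrid(),
) -> AFMImage:
    """Noiseless pseudo-AFM image of a structure in pose (q, dx, dy).

    An empty structure yields an all-zero image.  (dx, dy) are continuous
    lateral shifts in nm applied after rotation and stage alignment.
    """
    if len(structure) == 0:
        return AFMImage(np.zeros(grid.shape), grid)

    rotated = orientations.rotate(structure, q)
    coords = rotated.coords.copy()
    coords[:, 2] -= coords[:, 2].min()
    coords[:, 0] += dx
    coords[:, 1] += dy

    xs, ys = pixel_centers(grid)
    theta = np.deg2rad(tip.half_angle_deg)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    r = tip.apex_radius

    bx = coords[:, 0][:, None, None]
    by = coords[:, 1][:, None, None]
    bz = coords[:, 2][:, None, None]
    br = structure.radii[:, None, None]
    d = np.sqrt((xs[None, None, :] - bx) ** 2 + (ys[None, :, None] - by) ** 2)

    reff = r + br
    apex = bz - r + np.sqrt(np.clip(reff**2 - d**2, 0.0, None))
    flank = bz - r + (br + r - d * cos_t) / sin_t
    contact = np.where(d <= reff * cos_t, apex, flank)
    return AFMImage(np.clip(contact.max(axis=0), 0.0, None), grid)


def add_gaussian_noise(image: AFMImage, sigma: float, seed) -> AFMImage:
    """Add i.i.d. Gaussian pixel noise of standard deviation ``sigma`` (nm).

    ``seed`` may be an int or a :class:`numpy.random.Generator`; identical
    seeds reproduce the same noise field.
    """
    if sigma < 0:
        raise ValueError(f"noise standard deviation must be >= 0, got {sigma}")
    if sigma == 0:
        return image
    rng = np.random.default_rng(seed)
    return AFMImage(image.heights + rng.normal(0.0, sigma, size=image.heights.shape), image.grid)


def read_structure(path, radius_table=None, default_radius: float = DEFAULT_BEAD_RADIUS,
                   center: bool = True) -> Structure:
    """Read Cα beads from a PDB file (HETATM ignored), coordinates in nm.

    ``radius_table`` maps residue names to effective radii (nm).  When given,
    any residue absent from the table is an error naming the residue; when
    None every bead gets ``default_radius``.  With ``center=True`` (default)
    the coordinates are translated so the centroid is at the origin, which
    places the molecule mid-image under the imaging convention.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        model = next(parser.get_structure("s", str(path)).get_models())
    except PDBConstructionException as err:
        raise ValueError(f"failed to parse PDB file {path}: {err}") from err
    except StopIteration:
        raise ValueError(f"failed to parse PDB file {path}: no models found") from None

    coords, labels = [], []
    for chain in model:
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag.strip():
                continue  # skip HETATM / waters
            if "CA" in residue:
                coords.append(residue["CA"].coord / 10.0)  # Angstrom -> nm
                labels.append(residue.get_resname().strip())

    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if radius_table is not None:
        missing = sorted({name for name in labels if name not in radius_table})
        if missing:
            raise ValueError(
                "residue(s) missing from effective-radius table: " + ", ".join(missing)
            )
        radii = np.array([radius_table[name] for name in labels], dtype=float)
    else:
        radii = np.full(len(coords), default_radius)
    if center and len(coords):
        coords = coords - coords.mean(axis=0)
    return Structure(coords, radii, tuple(labels))


_HEADER_RE = re.compile(
    r"#\s*nx=(\d+)\s+ny=(\d+)\s+pixel=([0-9.eE+-]+)\s+frames=(\d+)\s*$"
)


def write_image_series(series: ImageSeries, path) -> None:
    """Write an image series; plain text by default, HDF5 for .h5/.hdf5 paths.

    Text layout: header ``# nx=.. ny=.. pixel=.. frames=..`` then per frame a
    blank-line-separated ny x nx whitespace-delimited matrix of heights (nm).
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset("frames", data=series.frames)
            dset.attrs["nx"] = series.grid.nx
            dset.attrs["ny"] = series.grid.ny
            dset.attrs["pixel"] = series.grid.pixel_size
        return
    g = series.grid
    with open(path, "w") as fh:
        fh.write(f"# nx={g.nx} ny={g.ny} pixel={g.pixel_size:.9g} frames={len(series)}\n")
        for t, frame in enumerate(series.frames):
            if t:
                fh.write("\n")
            for row in frame:
                fh.write(" ".join(f"{v:.8e}" for v in row) + "\n")


def read_image_series(path) -> ImageSeries:
    """Read an image series written by :func:`write_image_series`."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            dset = fh["frames"]
            grid = ImageGrid(float(dset.attrs["pixel"]), int(dset.attrs["nx"]),
                             int(dset.attrs["ny"]))
            return ImageSeries(dset[...], grid)

    with open(path) as fh:
        header = fh.readline()
        match = _HEADER_RE.match(header.strip())
        if match is None:
            raise ValueError(f"{path}:1: malformed header line: {header.strip()!r}")
        nx, ny, pixel, n_frames = (int(match[1]), int(match[2]), float(match[3]),
                                   int(match[4]))
        values = []
        for lineno, line in enumerate(fh, start=2):
            text = line.strip()
            if not text:
                continue
            try:
                row = [float(v) for v in text.split()]
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
            if len(row) != nx:
                raise ValueError(f"{path}:{lineno}: expected {nx} values, got {len(row)}")
            values.append(row)
    data = np.asarray(values, dtype=float)
    if data.shape[0] != n_frames * ny:
        raise ValueError(
            f"{path}: expected {n_frames}x{ny} rows, got {data.shape[0]}"
        )
    return ImageSeries(data.reshape(n_frames, ny, nx), ImageGrid(pixel, nx, ny))
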