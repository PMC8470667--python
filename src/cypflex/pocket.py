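"""Grid-based binding-pocket volume (POVME-style).

The pocket is the part of a user-defined inclusion region (a union of
spheres) that is not occluded by van-der-Waals-padded protein atoms.  A
cubic lattice at ``grid_spacing`` is laid over the inclusion region,
anchored at the first sphere centre; every lattice point within
``vdw(element) + padding`` of any atom is removed; optionally only the
6-connected component containing the lattice point nearest a seed point
is kept.  The volume is the count of surviving points times the voxel
volume.

The inclusion region is fixed in space: for a trajectory it does not
follow the protein, so frames must be aligned first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigError, NotAlignedError, PocketSeedError
from .structure import StructureModel, Trajectory

logger = logging.getLogger(__name__)

#: Bondi-style van der Waals radii (A) by element; unknown elements use "other".
DEFAULT_VDW = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "other": 1.70,
}
DEFAULT_PADDING = 1.09  # water-probe-like, A


@dataclass
class PocketGridConfig:
    """Inclusion region and lattice parameters for pocket-volume runs."""

    inclusion_spheres: list[tuple[tuple[float, float, float], float]]
    grid_spacing: float = 1.0
    padding: float = DEFAULT_PADDING
    contiguity: bool = True
    seed_point: tuple[float, float, float] | None = None  # default: first centre
    vdw_table: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW))

    def __post_init__(self):
        if not self.inclusion_spheres:
            raise ConfigError("at least one inclusion sphere is required")
        if self.grid_spacing <= 0:
            raise ConfigError("grid_spacing must be positive")
        if any(r <= 0 for _, r in self.inclusion_spheres):
            raise ConfigError("inclusion sphere radii must be positive")
        if self.padding < 0:
            raise ConfigError("padding must be >= 0")
        if self.seed_point is None:
            self.seed_point = tuple(self.inclusion_spheres[0][0])
        seed = np.asarray(self.seed_point, float)
        inside = any(
            np.linalg.norm(seed - np.asarray(c)) <= r
            for c, r in self.inclusion_spheres
        )
        if not inside:
            raise ConfigError("seed point lies outside every inclusion sphere")

    def radius_for(self, element: str) -> float:
        return self.vdw_table.get(element, self.vdw_table.get("other", 1.70))


@dataclass
class PocketVolumeSeries:
    """Per-frame pocket volumes (A^3) with mean and sample-sd fluctuation."""

    volumes: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.volumes))

    @property
    def rms_fluctuation(self) -> float:
        if self.volumes.size < 2 or np.ptp(self.volumes) == 0:
            return 0.0
        return float(np.std(self.volumes, ddof=1))


def _build_lattice(config: PocketGridConfig):
    """Lattice points inside the union of inclusion spheres.

    Returns (points (M, 3), integer offsets (M, 3) from the lattice
    origin).  The lattice is anchored at the first sphere centre, so
    translating atoms and config jointly by a lattice vector is exact.
    """
    anchor = np.asarray(config.inclusion_spheres[0][0], float)
    h = config.grid_spacing
    centers = np.array([c for c, _ in config.inclusion_spheres], float)
    radii = np.array([r for _, r in config.inclusion_spheres], float)
    lo = np.floor((centers - radii[:, None] - anchor).min(axis=0) / h).astype(int)
    hi = np.ceil((centers + radii[:, None] - anchor).max(axis=0) / h).astype(int)
    axes = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
    ijk = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    pts = anchor + ijk * h
    inside = np.zeros(len(pts), bool)
    for c, r in zip(centers, radii):
        inside |= np.sum((pts - c) ** 2, axis=1) <= r * r
    if not inside.any():
        raise ConfigError("inclusion region generated no lattice points")
    return pts[inside], ijk[inside]


def _contiguous_component(ijk, kept, seed_offset):
    """Restrict ``kept`` to the 6-connected component holding the seed voxel."""
    lo = ijk.min(axis=0)
    shape = ijk.max(axis=0) - lo + 1
    vol = np.zeros(shape, bool)
    kept_ijk = ijk[kept] - lo
    vol[kept_ijk[:, 0], kept_ijk[:, 1], kept_ijk[:, 2]] = True
    labels, _ = ndimage.label(vol, structure=ndimage.generate_binary_structure(3, 1))
    seed_lab = labels[tuple(seed_offset - lo)]
    out = np.zeros_like(kept)
    sel = labels[ijk[kept, 0] - lo[0], ijk[kept, 1] - lo[1], ijk[kept, 2] - lo[2]]
    out[np.flatnonzero(kept)[sel == seed_lab]] = True
    return out


class _Lattice:
    """Frame-fixed lattice over the inclusion region, reusable across frames."""

    def __init__(self, config: PocketGridConfig):
        self.config = config
        self.pts, self.ijk = _build_lattice(config)
        self.tree = cKDTree(self.pts)
        seed = np.asarray(config.seed_point, float)
        self.seed_idx = int(np.argmin(np.sum((self.pts - seed) ** 2, axis=1)))

    def volume(self, coords, elements, return_points=False):
        kept = np.ones(len(self.pts), bool)
        coords = np.asarray(coords, float)
        if len(coords):
            elements = np.asarray(elements, dtype=object)
            for elem in dict.fromkeys(elements):
                radius = self.config.radius_for(str(elem)) + self.config.padding
                hits = self.tree.query_ball_point(coords[elements == elem], radius)
                for lst in hits:
                    kept[lst] = False
        if self.config.contiguity:
            if not kept[self.seed_idx]:
                raise PocketSeedError(
                    "the lattice point nearest the seed is occluded by an atom; "
                    "move seed_point into open pocket space"
                )
            kept = _contiguous_component(self.ijk, kept, self.ijk[self.seed_idx])
        volume = float(kept.sum()) * self.config.grid_spacing**3
        if return_points:
            return volume, self.pts[kept]
        return volume


def pocket_volume_frame(
    coords: np.ndarray,
    elements,
    config: PocketGridConfig,
    return_points: bool = False,
):
    """Pocket volume (A^3) of one coordinate frame.

    ``coords`` are atom positions (N, 3); ``elements`` their element
    symbols (vdW lookup).  With ``return_points`` the surviving lattice
    points are returned too (e.g. for a pseudo-atom PDB dump).
    """
    return _Lattice(config).volume(coords, elements, return_points=return_points)


def pocket_volume_series(
    traj: Trajectory,
    config: PocketGridConfig,
    require_aligned: bool = True,
) -> PocketVolumeSeries:
    """Per-frame pocket volumes over a trajectory with a frame-fixed grid.

    The inclusion region does not move with the protein, so the
    trajectory must have global motion removed (``require_aligned``
    guards this; pass False for inputs that are rigid by construction).
    """
    if require_aligned and not traj.aligned:
        raise NotAlignedError(
            "pocket_volume_series needs an aligned trajectory "
            "(or require_aligned=False for rigid inputs)"
        )
    elements = traj.topology.element
    lattice = _Lattice(config)
    volumes = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        try:
            volumes[f] = lattice.volume(traj.frames[f], elements)
        except PocketSeedError as exc:
            raise PocketSeedError(f"frame {f}: {exc}") from exc
    return PocketVolumeSeries(volumes=volumes)


def write_pocket_points_pdb(points: np.ndarray, path) -> None:
    """Dump kept lattice points as pseudo-atoms for visual inspection."""
    from .structure import StructureModel, write_pdb

    n = len(points)
    model = StructureModel(
        atom_name=["PT"] * n,
        element=["He"] * n,  # inert placeholder element
        residue_name=["PKT"] * n,
        residue_seq=np.ones(n, int),
        chain_id=["Z"] * n,
        hetero=[True] * n,
        coords=np.asarray(points, float),
    )
    write_pdb(model, path)
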