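"""Synthetic structures, trajectories, families and elastic scans.

Every generator has exactly known ground truth, so each pipeline stage
can be verified at desk scale without external data:

* toy proteins -- an extended C-alpha chain (3.8 A spacing) with
  pseudo side-chain charged atoms carrying correct PDB atom names;
* Gaussian trajectories -- i.i.d. per-axis normal displacements of
  known sigma around the reference (RMSF = sigma * sqrt(3), MSD plateau
  = 6 sigma^2), optionally AR(1)-correlated;
* bridged trajectories -- each programmed salt bridge is formed per
  frame by an independent Bernoulli draw with known occupancy; member
  atoms are placed so the minimum O--N distance is exactly the formed
  (2.8 A) or broken (6.0 A) distance;
* synthetic families -- proteins whose mean RMSF is linearly and
  negatively coupled to salt-bridge density with additive noise;
* elastic scans -- the exact inverse of the quartic-corrected Gaussian
  fit model, with multiplicative log-normal noise.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .neutron import ElasticScan
from .pocket import PocketGridConfig
from .saltbridge import ACIDIC_MEMBER_ATOMS, BASIC_MEMBER_ATOMS
from .structure import StructureModel, Trajectory, write_pdb

CA_SPACING = 3.8  # A, extended-chain C-alpha spacing

# pseudo side-chain offsets (A) from the residue C-alpha, by atom name
_SIDE_CHAIN_OFFSETS = {
    "ASP": {"OD1": (0.0, 1.5, 0.0), "OD2": (2.2, 1.5, 0.0)},
    "GLU": {"OE1": (0.0, 1.5, 0.0), "OE2": (2.2, 1.5, 0.0)},
    "LYS": {"NZ": (0.0, 1.5, 0.0)},
    "ARG": {"NE": (0.0, 1.5, 0.0), "NH1": (0.8, 2.5, 0.0), "NH2": (-0.8, 2.5, 0.0)},
    "HIS": {"ND1": (0.5, 1.5, 0.0), "NE2": (-0.5, 1.5, 0.0)},
}


@dataclass(frozen=True)
class BridgeSpec:
    """One programmed salt bridge: partner residues and target occupancy."""

    acidic_seq: int
    basic_seq: int
    occupancy: float
    formed_distance: float = 2.8
    broken_distance: float = 6.0

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ConfigError("occupancy must be in [0, 1]")
        if not self.formed_distance < 3.2 < self.broken_distance:
            raise ConfigError("need formed < 3.2 A < broken")


@dataclass
class ToyProteinSpec:
    """A toy protein: chain length, charged placements, bridges, noise.

    ``placements`` maps 1-based residue numbers to charged residue types
    (ASP/GLU/LYS/ARG/HIS); other residues are glycines with a single
    C-alpha.  ``sigma`` is the per-axis Gaussian fluctuation amplitude
    in A, scalar or one value per residue.
    """

    n_residues: int
    placements: tuple[tuple[int, str], ...] = ()
    bridges: tuple[BridgeSpec, ...] = ()
    sigma: float | np.ndarray = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 1:
            raise ConfigError("n_residues must be >= 1")
        seqs = [seq for seq, _ in self.placements]
        if len(seqs) != len(set(seqs)):
            raise ConfigError("duplicate placement residue index")
        for seq, name in self.placements:
            if not 1 <= seq <= self.n_residues:
                raise ConfigError(f"placement residue {seq} out of range")
            if name not in _SIDE_CHAIN_OFFSETS:
                raise ConfigError(f"unsupported charged residue type {name}")
        placed = dict(self.placements)
        for b in self.bridges:
            if placed.get(b.acidic_seq) not in ACIDIC_MEMBER_ATOMS:
                raise ConfigError(f"bridge acidic residue {b.acidic_seq} not placed")
            if placed.get(b.basic_seq) not in BASIC_MEMBER_ATOMS:
                raise ConfigError(f"bridge basic residue {b.basic_seq} not placed")
        basics = [b.basic_seq for b in self.bridges]
        if len(basics) != len(set(basics)):
            raise ConfigError("two bridge specs control the same basic residue")
        sig = np.atleast_1d(np.asarray(self.sigma, float))
        if np.any(sig < 0):
            raise ConfigError("sigma must be >= 0")
        if sig.size not in (1, self.n_residues):
            raise ConfigError("sigma must be scalar or one value per residue")

    def sigma_per_residue(self) -> np.ndarray:
        sig = np.atleast_1d(np.asarray(self.sigma, float))
        if sig.size == 1:
            return np.full(self.n_residues, sig[0])
        return sig.copy()


def make_toy_structure(spec: ToyProteinSpec) -> StructureModel:
    """Build the reference structure of a toy protein.

    Extended chain along x, one C-alpha per residue, pseudo side-chain
    charged atoms with correct PDB atom names; writable as valid PDB.
    """
    placed = dict(spec.placements)
    names, elements, res_names, res_seq, coords = [], [], [], [], []
    for seq in range(1, spec.n_residues + 1):
        res = placed.get(seq, "GLY")
        ca = np.array([(seq - 1) * CA_SPACING, 0.0, 0.0])
        names.append("CA")
        elements.append("C")
        res_names.append(res)
        res_seq.append(seq)
        coords.append(ca)
        for atom, offset in _SIDE_CHAIN_OFFSETS.get(res, {}).items():
            names.append(atom)
            elements.append(atom[0])  # O or N
            res_names.append(res)
            res_seq.append(seq)
            coords.append(ca + offset)
    return StructureModel(
        atom_name=names,
        element=elements,
        residue_name=res_names,
        residue_seq=res_seq,
        chain_id=["A"] * len(names),
        coords=np.asarray(coords),
    )


def _residue_sigma_per_atom(structure: StructureModel, sigma_res: np.ndarray):
    seq = structure.residue_seq  # toy chains are numbered 1..n
    return sigma_res[seq - 1]


def _apply_bridges(structure, frames, bridges, rng):
    """Overwrite bridge member atoms frame by frame.

    Member atoms of both partners are pinned to the reference geometry
    (no thermal noise) and the basic nitrogens are placed along +y from
    the first carboxylate oxygen so that the minimum O--N cross distance
    is exactly the formed or broken distance of the frame's Bernoulli
    draw.  Returns the realized formed series per bridge.
    """
    realized: dict[tuple[int, int], np.ndarray] = {}
    n_frames = frames.shape[0]
    for b in bridges:
        formed = rng.random(n_frames) < b.occupancy
        realized[(b.acidic_seq, b.basic_seq)] = formed
        acid_key = ("A", b.acidic_seq, "")
        base_key = ("A", b.basic_seq, "")
        acid_idx = structure.residue_index[acid_key]
        acid_name = structure.residue_name[acid_idx[0]]
        member_order = ACIDIC_MEMBER_ATOMS[acid_name]
        o_atoms = [
            int(i) for name in member_order
            for i in acid_idx if structure.atom_name[i] == name
        ]
        base_idx = structure.residue_index[base_key]
        base_name = structure.residue_name[base_idx[0]]
        n_atoms = [
            int(i) for name in BASIC_MEMBER_ATOMS[base_name]
            for i in base_idx if structure.atom_name[i] == name
        ]
        # pin acidic oxygens to the reference (exact geometry)
        for i in o_atoms:
            frames[:, i] = structure.coords[i]
        dist = np.where(formed, b.formed_distance, b.broken_distance)
        o1 = structure.coords[o_atoms[0]]
        for k, i in enumerate(n_atoms):
            # first N sits exactly at the target distance; the rest behind it
            offset = np.array([0.4 * k, 1.0 * (k > 0) + 0.3 * k, 0.0])
            frames[:, i, 0] = o1[0] + offset[0]
            frames[:, i, 1] = o1[1] + dist + offset[1]
            frames[:, i, 2] = o1[2]
    return realized


def make_gaussian_trajectory(
    structure: StructureModel,
    sigma,
    n_frames: int,
    dt: float = 10.0,
    seed: int = 0,
    ar1: float = 0.0,
) -> Trajectory:
    """Reference + i.i.d. per-axis Gaussian displacements.

    ``sigma`` is scalar or per-residue (A).  With ``ar1`` in (0, 1) the
    displacement process is AR(1) with that lag-one autocorrelation and
    the same stationary sigma, for MSD-shape tests.
    """
    if n_frames < 2:
        raise ConfigError("n_frames must be >= 2")
    sig = np.atleast_1d(np.asarray(sigma, float))
    if np.any(sig < 0):
        raise ConfigError("sigma must be >= 0")
    n_res = int(structure.residue_seq.max())
    sigma_res = np.full(n_res, sig[0]) if sig.size == 1 else sig
    sigma_atom = _residue_sigma_per_atom(structure, sigma_res)
    rng = np.random.default_rng(seed)
    if ar1 > 0:
        innov_sd = np.sqrt(1.0 - ar1**2)
        noise = np.empty((n_frames, structure.n_atoms, 3))
        noise[0] = rng.standard_normal((structure.n_atoms, 3))
        for f in range(1, n_frames):
            noise[f] = ar1 * noise[f - 1] + innov_sd * rng.standard_normal(
                (structure.n_atoms, 3)
            )
        noise *= sigma_atom[None, :, None]
    else:
        noise = rng.standard_normal((n_frames, structure.n_atoms, 3))
        noise *= sigma_atom[None, :, None]
    frames = structure.coords[None] + noise
    return Trajectory(topology=structure, frames=frames, dt=dt)


def make_bridged_trajectory(
    structure: StructureModel,
    bridges: tuple[BridgeSpec, ...],
    n_frames: int,
    dt: float = 10.0,
    seed: int = 0,
    sigma=0.0,
):
    """Trajectory with programmed Bernoulli salt bridges.

    Returns (trajectory, realized) where ``realized`` maps
    (acidic_seq, basic_seq) to the per-frame formed series actually
    drawn -- the exact ground truth for lifetime recovery.
    """
    traj = make_gaussian_trajectory(structure, sigma, n_frames, dt=dt, seed=seed)
    rng = np.random.default_rng([seed, 1])  # separate stream from the noise
    realized = _apply_bridges(structure, traj.frames, bridges, rng)
    return traj, realized


def make_toy_trajectory(spec: ToyProteinSpec, n_frames: int, dt: float = 10.0):
    """Structure + trajectory from one spec (noise plus bridges)."""
    structure = make_toy_structure(spec)
    return structure, *make_bridged_trajectory(
        structure, spec.bridges, n_frames, dt=dt, seed=spec.seed,
        sigma=spec.sigma_per_residue(),
    )


# --------------------------------------------------------------------------
# Synthetic family
# --------------------------------------------------------------------------

@dataclass
class SyntheticFamilySpec:
    """A family of toy proteins with density-coupled flexibility.

    Salt-bridge densities are drawn uniformly from ``density_range``
    (bridges per 100 residues); the mean RMSF of each protein is set to
    ``intercept + slope * density + Normal(0, noise_sd)`` (slope
    strictly negative).  With the defaults the population Pearson
    correlation between density and RMSF is -0.45.  Each protein is a
    20 ns trajectory (frame spacing ``dt`` ps) of which the second half
    is the analysis window, mirroring a short equilibrated production
    run.  Proteins in the denser half of the range are labelled
    Bacteria, the rest Animalia.
    """

    n_proteins: int = 146
    n_residues: int = 100
    density_range: tuple[float, float] = (2.0, 8.0)
    intercept: float = 2.0  # A, mean RMSF at zero density
    slope: float = -0.1  # A per (bridge / 100 residues)
    noise_sd: float = 0.3437  # A; gives population r = -0.45 for the defaults
    n_frames: int = 500
    dt: float = 40.0  # ps -> 20 ns total, 10 ns analysis window
    min_rmsf: float = 0.05  # A, floor keeping sigma positive
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 3:
            raise ConfigError("n_proteins must be >= 3")
        if self.slope >= 0:
            raise ConfigError("slope must be strictly negative")
        lo, hi = self.density_range
        if not 0 <= lo <= hi:
            raise ConfigError("invalid density range")
        max_bridges = self.n_residues // 4
        if np.ceil(hi * self.n_residues / 100.0) > max_bridges:
            raise ConfigError(
                "infeasible density: more bridges than placeable pairs "
                f"(max {max_bridges} for {self.n_residues} residues)"
            )

    @property
    def window_ns(self) -> tuple[float, float]:
        total = self.n_frames * self.dt / 1000.0
        return (total / 2.0, total)


@dataclass
class FamilyProtein:
    """One generated family member with everything needed to summarise it."""

    protein_id: str
    category: str
    bacteria_like: bool
    structure: StructureModel
    trajectory: Trajectory
    gate: tuple[tuple[str, int], tuple[str, int]]
    pocket: PocketGridConfig


@dataclass
class FamilyData:
    spec: SyntheticFamilySpec
    proteins: list[FamilyProtein]
    truth: pd.DataFrame


def _family_protein_spec(spec, k, density, rmsf_target, rng):
    """Build one member's ToyProteinSpec realising the target density."""
    n_bridges_full = int(np.floor(density * spec.n_residues / 100.0))
    frac = density * spec.n_residues / 100.0 - n_bridges_full
    placements, bridges = [], []
    kinds_acid = ("ASP", "GLU")
    kinds_base = ("LYS", "ARG", "HIS")
    total = n_bridges_full + (1 if frac > 1e-9 else 0)
    for m in range(total):
        acid_seq = 4 * m + 1
        base_seq = 4 * m + 2
        placements.append((acid_seq, kinds_acid[m % 2]))
        placements.append((base_seq, kinds_base[m % 3]))
        occ = 1.0 if m < n_bridges_full else frac
        bridges.append(BridgeSpec(acid_seq, base_seq, occupancy=occ))
    sigma = max(rmsf_target, spec.min_rmsf) / np.sqrt(3.0)
    return ToyProteinSpec(
        n_residues=spec.n_residues,
        placements=tuple(placements),
        bridges=tuple(bridges),
        sigma=sigma,
        seed=int(rng.integers(2**31 - 1)),
    )


def make_family(spec: SyntheticFamilySpec | None = None) -> FamilyData:
    """Generate a synthetic protein family with known coupling.

    The ground-truth table carries, per protein, the programmed density,
    the per-axis sigma, the expected mean RMSF (sigma * sqrt(3)) and the
    category label.  Gate residues sit in the uncharged tail of each
    chain; the pocket inclusion sphere floats above the chain midpoint.
    """
    spec = spec or SyntheticFamilySpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.density_range
    densities = rng.uniform(lo, hi, size=spec.n_proteins)
    rmsf_noise = rng.normal(0.0, spec.noise_sd, size=spec.n_proteins)
    midpoint = (lo + hi) / 2.0

    proteins: list[FamilyProtein] = []
    truth_rows = []
    for k in range(spec.n_proteins):
        density = float(densities[k])
        rmsf_target = spec.intercept + spec.slope * density + float(rmsf_noise[k])
        rmsf_target = max(rmsf_target, spec.min_rmsf)
        pspec = _family_protein_spec(spec, k, density, rmsf_target, rng)
        structure = make_toy_structure(pspec)
        traj, _ = make_bridged_trajectory(
            structure, pspec.bridges, spec.n_frames, dt=spec.dt,
            seed=pspec.seed, sigma=pspec.sigma_per_residue(),
        )
        category = "Bacteria" if density >= midpoint else "Animalia"
        gate_a = ("A", spec.n_residues - 12)
        gate_b = ("A", spec.n_residues - 4)
        mid_x = (spec.n_residues - 1) * CA_SPACING / 2.0
        pocket = PocketGridConfig(
            inclusion_spheres=[((mid_x, 8.0, 0.0), 6.0)],
            grid_spacing=1.0,
        )
        proteins.append(
            FamilyProtein(
                protein_id=f"SYN{k:03d}",
                category=category,
                bacteria_like=False,
                structure=structure,
                trajectory=traj,
                gate=(gate_a, gate_b),
                pocket=pocket,
            )
        )
        truth_rows.append(
            {
                "protein_id": f"SYN{k:03d}",
                "category": category,
                "density_programmed": density,
                "sigma": float(pspec.sigma_per_residue()[0]),
                "expected_rmsf": max(rmsf_target, spec.min_rmsf),
                "n_bridges": len(pspec.bridges),
            }
        )
    return FamilyData(spec=spec, proteins=proteins, truth=pd.DataFrame(truth_rows))


def write_family(data: FamilyData, outdir) -> Path:
    """Write trajectories (multi-model PDB), a manifest and the truth table.

    Returns the manifest path; the manifest is consumable by the
    family-correlation stage (``cypflex summarize/correlate``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    start_ns, end_ns = data.spec.window_ns
    rows = []
    for p in data.proteins:
        traj_path = outdir / f"{p.protein_id}.pdb"
        write_pdb(p.trajectory, traj_path)
        center, radius = p.pocket.inclusion_spheres[0]
        rows.append(
            {
                "protein_id": p.protein_id,
                "category": p.category,
                "bacteria_like": p.bacteria_like,
                "trajectory": traj_path.name,
                "format": "pdb",
                "dt_ps": p.trajectory.dt,
                "window_start_ns": start_ns,
                "window_end_ns": end_ns,
                "gate_chain": p.gate[0][0],
                "gate_res_a": p.gate[0][1],
                "gate_res_b": p.gate[1][1],
                "pocket_x": center[0],
                "pocket_y": center[1],
                "pocket_z": center[2],
                "pocket_radius": radius,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    data.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return manifest


# --------------------------------------------------------------------------
# Elastic scans
# --------------------------------------------------------------------------

def make_elastic_scan(
    msd_true: float,
    q: np.ndarray | None = None,
    amplitude: float = 2.0,
    quartic: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
    temperature: float = 300.0,
) -> ElasticScan:
    """Elastic scan generated from a known MSD.

    I(q) = exp(amplitude - (msd_true / 6) q^2 + quartic * q^4), times
    multiplicative log-normal noise of the given relative level.
    """
    if msd_true < 0:
        raise ConfigError("msd_true must be >= 0")
    if q is None:
        q = np.linspace(0.2, 1.8, 33)
    q = np.asarray(q, float)
    log_i = amplitude - (msd_true / 6.0) * q**2 + quartic * q**4
    intensity = np.exp(log_i)
    if noise > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * np.exp(rng.normal(0.0, noise, size=q.size))
    return ElasticScan(temperature=temperature, q=q, intensity=intensity)
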