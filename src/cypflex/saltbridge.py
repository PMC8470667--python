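"""Salt-bridge detection, lifetimes and densities.

A salt bridge is a residue-level contact between a carboxylate oxygen of
an acidic residue (Asp OD1/OD2, Glu OE1/OE2) and a charged-group
nitrogen of a basic residue (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2).  A
pair counts as formed in a frame when the minimum O--N distance over the
member-atom cross pairs is within the cutoff (default 3.2 A, inclusive).
The lifetime (occupancy) of a pair is the fraction of frames in which it
is formed; pairs formed in at least one frame enter the inventory.

Lifetime categories follow the 2% / 20% boundaries: short < 2%,
medium 2--20% (both ends inclusive), long > 20%.

Salt-bridge density is the number of bridges per 100 amino-acid
residues; the distinct-pair variant counts inventory entries, the
per-frame variant counts bridges formed in each frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError
from .structure import ResidueKey, StructureModel, Trajectory

logger = logging.getLogger(__name__)

ACIDIC_MEMBER_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_MEMBER_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
#: His protonation-state aliases map onto HIS member atoms
_HIS_ALIASES = ("HIS", "HID", "HIE", "HIP", "HSD", "HSE", "HSP")

DEFAULT_CUTOFF = 3.2
DEFAULT_BOUNDARIES = (0.02, 0.20)


@dataclass(frozen=True)
class ChargedGroup:
    """The titratable group of one residue: its O (acidic) or N (basic) atoms."""

    residue: ResidueKey
    residue_name: str
    sign: str  # "acidic" | "basic"
    member_atoms: tuple[int, ...]  # atom positions in the topology

    def __post_init__(self):
        if self.sign not in ("acidic", "basic"):
            raise ValueError("sign must be 'acidic' or 'basic'")
        if not self.member_atoms:
            raise ValueError("member_atoms must be non-empty")


@dataclass
class SaltBridgeRecord:
    """One acidic-basic residue pair with its per-frame formed series."""

    acidic: ResidueKey
    basic: ResidueKey
    acidic_name: str
    basic_name: str
    formed: np.ndarray  # per-frame bool
    total_time_ns: float

    @property
    def lifetime(self) -> float:
        """Occupancy: fraction of frames in which the bridge is formed."""
        return float(np.mean(self.formed))

    @property
    def lifetime_ns(self) -> float:
        return self.lifetime * self.total_time_ns

    def category(self, boundaries: tuple[float, float] = DEFAULT_BOUNDARIES) -> str:
        lo, hi = boundaries
        s = self.lifetime
        if s < lo:
            return "short"
        if s <= hi:
            return "medium"
        return "long"

    def label(self) -> str:
        """Paper-style pair label, e.g. ASP251-LYS178."""
        return (
            f"{self.acidic_name}{self.acidic[1]}{self.acidic[2]}"
            f"-{self.basic_name}{self.basic[1]}{self.basic[2]}"
        )


@dataclass
class SaltBridgeSummary:
    """Inventory of the bridges of one trajectory plus its densities."""

    records: list[SaltBridgeRecord]
    n_residues: int
    n_frames: int
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES
    density_series: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_distinct(self) -> int:
        return len(self.records)

    @property
    def density_distinct(self) -> float:
        """Distinct pairs per 100 residues (unrounded)."""
        return 100.0 * self.n_distinct / self.n_residues

    @property
    def density_mean(self) -> float:
        """Time-average of the per-frame density."""
        return float(np.mean(self.density_series)) if self.density_series.size else 0.0

    @property
    def counts_by_category(self) -> dict[str, int]:
        counts = {"short": 0, "medium": 0, "long": 0}
        for rec in self.records:
            counts[rec.category(self.boundaries)] += 1
        return counts


def enumerate_charged_groups(
    structure: StructureModel,
    include_his: bool = True,
    include_termini: bool = False,
) -> list[ChargedGroup]:
    """One :class:`ChargedGroup` per titratable residue with resolved member atoms.

    Residues whose member atoms are all missing from the coordinates are
    skipped with a logged warning.  ``include_termini`` adds the chain
    N-terminal amine nitrogen and C-terminal OXT as extra groups.
    """
    if structure.n_residues == 0:
        raise ConfigError("structure has no protein residues")
    groups: list[ChargedGroup] = []
    mask = structure.protein_mask
    for key in structure.residue_keys(protein_only=True):
        atom_idx = structure.residue_index[key]
        atom_idx = atom_idx[mask[atom_idx]]
        if atom_idx.size == 0:
            continue
        res_name = str(structure.residue_name[atom_idx[0]])
        canonical = "HIS" if res_name in _HIS_ALIASES else res_name
        if canonical in ACIDIC_MEMBER_ATOMS:
            wanted, sign = ACIDIC_MEMBER_ATOMS[canonical], "acidic"
        elif canonical in BASIC_MEMBER_ATOMS:
            if canonical == "HIS" and not include_his:
                continue
            wanted, sign = BASIC_MEMBER_ATOMS[canonical], "basic"
        else:
            continue
        members = tuple(
            int(i) for i in atom_idx if structure.atom_name[i] in wanted
        )
        if not members:
            logger.warning(
                "charged residue %s %s:%s has no %s member atoms; skipped",
                res_name, key[0], key[1], sign,
            )
            continue
        groups.append(ChargedGroup(key, canonical, sign, members))

    if include_termini:
        groups.extend(_terminal_groups(structure))
    return groups


def _terminal_groups(structure: StructureModel) -> list[ChargedGroup]:
    groups = []
    mask = structure.protein_mask
    for chain in dict.fromkeys(structure.chain_id[mask]):
        chain_atoms = np.flatnonzero(mask & (structure.chain_id == chain))
        keys = [
            (chain, int(structure.residue_seq[i]), structure.insertion_code[i])
            for i in chain_atoms
        ]
        first_key, last_key = keys[0], keys[-1]
        n_idx = [
            int(i)
            for i in structure.residue_index[first_key]
            if structure.atom_name[i] == "N"
        ]
        if n_idx:
            name = str(structure.residue_name[n_idx[0]])
            groups.append(ChargedGroup(first_key, name, "basic", tuple(n_idx)))
        oxt_idx = [
            int(i)
            for i in structure.residue_index[last_key]
            if structure.atom_name[i] in ("OXT",)
        ]
        if oxt_idx:
            name = str(structure.residue_name[oxt_idx[0]])
            groups.append(ChargedGroup(last_key, name, "acidic", tuple(oxt_idx)))
    return groups


def _split_groups(groups):
    acidic = [g for g in groups if g.sign == "acidic"]
    basic = [g for g in groups if g.sign == "basic"]
    return acidic, basic


def _member_table(groups):
    """Flatten member atoms: (atom_indices, owning-group index per atom)."""
    atom_idx = np.concatenate([np.asarray(g.member_atoms, int) for g in groups])
    owner = np.concatenate(
        [np.full(len(g.member_atoms), k, int) for k, g in enumerate(groups)]
    )
    return atom_idx, owner


def detect_bridges_frame(
    coords: np.ndarray,
    groups: list[ChargedGroup],
    cutoff: float = DEFAULT_CUTOFF,
) -> set[tuple[ResidueKey, ResidueKey]]:
    """Residue pairs bridged in one frame.

    A pair (acidic, basic) is present iff the minimum Euclidean distance
    over its O x N member-atom cross pairs is <= ``cutoff``.  Multiple
    simultaneous atom contacts count once.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    acidic, basic = _split_groups(groups)
    if not acidic or not basic:
        return set()
    formed = _formed_matrix(coords[None], acidic, basic, cutoff)[0]
    ai, bi = np.nonzero(formed)
    return {(acidic[a].residue, basic[b].residue) for a, b in zip(ai, bi)}


def _formed_matrix(frames, acidic, basic, cutoff):
    """(n_frames, n_acidic, n_basic) bool: pair formed per frame.

    Works on the O x N atom distance matrix per frame and reduces over
    each group's member atoms (min distance <= cutoff).
    """
    a_atoms, a_owner = _member_table(acidic)
    b_atoms, b_owner = _member_table(basic)
    n_frames = frames.shape[0]
    out = np.zeros((n_frames, len(acidic), len(basic)), bool)
    for f in range(n_frames):
        d = cdist(frames[f, a_atoms], frames[f, b_atoms])
        contact = d <= cutoff
        if contact.any():
            ii, jj = np.nonzero(contact)
            out[f, a_owner[ii], b_owner[jj]] = True
    return out


def compute_records(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES,
    include_his: bool = True,
    include_termini: bool = False,
    n_residues_override: int | None = None,
) -> SaltBridgeSummary:
    """Full salt-bridge inventory of a trajectory.

    One record per residue pair formed in at least one frame, with its
    per-frame formed series, lifetime and category.  Densities use the
    count of resolved protein residues in the topology unless
    ``n_residues_override`` supplies an explicit denominator (e.g. the
    full construct length).
    """
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    n_residues = n_residues_override or traj.topology.n_residues
    if n_residues == 0:
        raise ConfigError("topology has zero protein residues")
    _warn_if_broken_chain(traj)

    groups = enumerate_charged_groups(
        traj.topology, include_his=include_his, include_termini=include_termini
    )
    acidic, basic = _split_groups(groups)
    records: list[SaltBridgeRecord] = []
    if acidic and basic:
        formed = _formed_matrix(traj.frames, acidic, basic, cutoff)
        ever = formed.any(axis=0)
        per_frame_count = formed.sum(axis=(1, 2))
        for a, b in zip(*np.nonzero(ever)):
            records.append(
                SaltBridgeRecord(
                    acidic=acidic[a].residue,
                    basic=basic[b].residue,
                    acidic_name=acidic[a].residue_name,
                    basic_name=basic[b].residue_name,
                    formed=formed[:, a, b].copy(),
                    total_time_ns=traj.total_time_ns,
                )
            )
    else:
        per_frame_count = np.zeros(traj.n_frames)

    return SaltBridgeSummary(
        records=records,
        n_residues=n_residues,
        n_frames=traj.n_frames,
        boundaries=boundaries,
        density_series=100.0 * per_frame_count / n_residues,
    )


def _warn_if_broken_chain(traj: Trajectory, threshold: float = 5.0) -> None:
    """Unwrapped-input guard: consecutive CA-CA distances should stay < 5 A."""
    topo = traj.topology
    ca = np.flatnonzero(topo.protein_mask & (topo.atom_name == "CA"))
    if ca.size < 2:
        return
    same_chain = topo.chain_id[ca[:-1]] == topo.chain_id[ca[1:]]
    gaps = np.linalg.norm(traj.frames[0, ca[1:]] - traj.frames[0, ca[:-1]], axis=1)
    if np.any(same_chain & (gaps > threshold)):
        logger.warning(
            "consecutive CA-CA distance exceeds %.1f A; trajectory may be "
            "wrapped across periodic boundaries", threshold,
        )


def density_distinct(n_distinct: int, n_residues: int) -> float:
    """Distinct bridges per 100 residues, reported to one decimal."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    return round(100.0 * n_distinct / n_residues, 1)


def filter_region(
    summary: SaltBridgeSummary, regions: list[tuple[int, int]]
) -> SaltBridgeSummary:
    """Restrict the inventory to bridges touching any residue range.

    Ranges are inclusive, in author numbering.  A record is kept iff at
    least one partner residue lies in some range.  Densities are
    recomputed over the filtered records with an unchanged denominator.
    """
    for start, end in regions:
        if start > end:
            raise ConfigError(f"malformed residue range {start}-{end}")

    def in_any(key: ResidueKey) -> bool:
        return any(start <= key[1] <= end for start, end in regions)

    kept = [r for r in summary.records if in_any(r.acidic) or in_any(r.basic)]
    if kept:
        per_frame = np.sum([r.formed for r in kept], axis=0)
    else:
        per_frame = np.zeros(summary.n_frames)
    return SaltBridgeSummary(
        records=kept,
        n_residues=summary.n_residues,
        n_frames=summary.n_frames,
        boundaries=summary.boundaries,
        density_series=100.0 * per_frame / summary.n_residues,
    )


def records_table(summary: SaltBridgeSummary):
    """Per-pair table: labels, lifetime %, lifetime ns, category."""
    import pandas as pd

    rows = [
        {
            "acidic": f"{r.acidic_name}{r.acidic[1]}{r.acidic[2]}",
            "basic": f"{r.basic_name}{r.basic[1]}{r.basic[2]}",
            "chain_acidic": r.acidic[0],
            "chain_basic": r.basic[0],
            "lifetime_pct": 100.0 * r.lifetime,
            "lifetime_ns": r.lifetime_ns,
            "category": r.category(summary.boundaries),
        }
        for r in summary.records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "acidic", "basic", "chain_acidic", "chain_basic",
            "lifetime_pct", "lifetime_ns", "category",
        ],
    )
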