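"""Flexibility descriptors: superposition, RMSF, MSD and gate distances.

Global rigid-body motion is removed by least-squares (Kabsch)
superposition before any fluctuation is measured.  Alignment uses a
two-pass scheme: frames are first fitted to frame 0 on the selection
atoms, the mean structure of the fitted frames is computed, and all
frames are re-fitted to that mean.

RMSF is per residue: the root of the time-mean squared displacement of
the residue's selected atom(s) about their time-mean position (squared
displacements are averaged over atoms before the root).  The MSD curve
averages squared displacements over selected atoms and strided time
origins for each lag.  Fluctuations of scalar series (gate distance)
use the sample (n-1) standard deviation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, NotAlignedError, SelectionError
from .structure import ResidueKey, ResidueSelector, Trajectory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SuperpositionResult:
    """Proper rotation + translation minimizing weighted RMSD, and that RMSD."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,), A
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _kabsch_batch(mobile: np.ndarray, reference: np.ndarray,
                  weights: np.ndarray | None = None):
    """Vectorised Kabsch fit of a stack of point sets onto references.

    mobile: (F, N, 3); reference: (N, 3) or (F, N, 3).
    Returns rotations (F, 3, 3), translations (F, 3), rmsd (F,).
    Reflections are prevented (det = +1 always).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if reference.ndim == 2:
        reference = np.broadcast_to(reference, mobile.shape)
    n = mobile.shape[1]
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()
    mob_c = np.einsum("n,fni->fi", w, mobile)
    ref_c = np.einsum("n,fni->fi", w, reference)
    p = mobile - mob_c[:, None]
    q = reference - ref_c[:, None]
    h = np.einsum("fni,n,fnj->fij", p, w, q)  # weighted cross-covariance P^T W Q
    u, _, vt = np.linalg.svd(h)
    d = np.ones((mobile.shape[0], 3))
    d[:, 2] = np.sign(np.linalg.det(u @ vt))  # prevent reflections
    r_row = np.einsum("fij,fj,fjk->fik", u, d, vt)  # fitted rows = p @ r_row
    rot = r_row.transpose(0, 2, 1)  # column-vector convention: x' = R x
    trans = ref_c - np.einsum("fij,fj->fi", rot, mob_c)
    fitted = np.einsum("fnj,fjk->fnk", p, r_row) + ref_c[:, None]
    rmsd = np.sqrt(np.einsum("n,fn->f", w, np.sum((fitted - reference) ** 2, axis=2)))
    return rot, trans, rmsd


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Both are (N, 3) with N >= 3 non-collinear points.  Returns the
    proper rotation R and translation t such that ``coords @ R.T + t``
    minimises the (weighted) RMSD to the reference.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise AlignmentError("mobile and reference must both be (N, 3)")
    if mobile.shape[0] < 3:
        raise AlignmentError("superposition needs at least 3 points")
    centred = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-10) < 2:
        raise AlignmentError("reference points are collinear or coincident")
    rot, trans, rmsd = _kabsch_batch(mobile[None], reference, weights)
    return SuperpositionResult(rotation=rot[0], translation=trans[0], rmsd=float(rmsd[0]))


def align_trajectory(traj: Trajectory, selector: ResidueSelector | None = None) -> Trajectory:
    """Remove global rigid-body motion (two-pass mean-structure scheme).

    Pass 1 fits every frame to frame 0 on the selector atoms (default:
    all C-alpha); pass 2 re-fits to the mean structure of the fitted
    frames.  All atoms are transformed; only selector atoms define the fit.
    """
    selector = selector or ResidueSelector(mode="calpha")
    idx = selector.resolve(traj.topology)
    if idx.size < 3:
        raise AlignmentError("alignment selection must contain >= 3 atoms")
    if np.ptp(traj.frames, axis=0).max() == 0.0:
        # frozen ensemble: identity is the exact fixed point
        return Trajectory(topology=traj.topology, frames=traj.frames.copy(),
                          dt=traj.dt, aligned=True, t0_ps=traj.t0_ps)

    def _fit_all(frames, reference_sel):
        rot, trans, _ = _kabsch_batch(frames[:, idx], reference_sel)
        return np.einsum("fij,fnj->fni", rot, frames) + trans[:, None]

    pass1 = _fit_all(traj.frames, traj.frames[0, idx])
    mean_sel = pass1[:, idx].mean(axis=0)
    pass2 = _fit_all(pass1, mean_sel)
    return Trajectory(topology=traj.topology, frames=pass2, dt=traj.dt,
                      aligned=True, t0_ps=traj.t0_ps)


# --------------------------------------------------------------------------
# RMSF
# --------------------------------------------------------------------------

@dataclass
class FlexibilityProfile:
    """Per-residue RMSF (A) in topology order."""

    residues: list[ResidueKey]
    rmsf: np.ndarray

    @property
    def mean_rmsf(self) -> float:
        """Arithmetic mean over all profiled residues."""
        return float(np.mean(self.rmsf))

    def as_dict(self) -> dict[ResidueKey, float]:
        return dict(zip(self.residues, self.rmsf))


def rmsf(traj: Trajectory, selector: ResidueSelector | None = None) -> FlexibilityProfile:
    """Per-residue RMSF of an aligned trajectory.

    For each residue, the squared displacement of its selected atoms from
    their time-mean positions is averaged over frames and atoms, then
    rooted.  The default selection is one C-alpha per residue.
    """
    if not traj.aligned:
        raise NotAlignedError("rmsf needs an aligned trajectory (align_trajectory)")
    selector = selector or ResidueSelector(mode="calpha")
    idx = selector.resolve(traj.topology)
    coords = traj.frames[:, idx]
    msd_per_atom = np.mean(
        np.sum((coords - coords.mean(axis=0)) ** 2, axis=2), axis=0
    )
    # atoms that never move fluctuate exactly 0 (no mean-rounding residue)
    msd_per_atom[np.ptp(coords, axis=0).max(axis=1) == 0.0] = 0.0
    topo = traj.topology
    residues: list[ResidueKey] = []
    values: list[float] = []
    per_res: dict[ResidueKey, list[float]] = {}
    order: list[ResidueKey] = []
    for pos, i in enumerate(idx):
        key = (topo.chain_id[i], int(topo.residue_seq[i]), topo.insertion_code[i])
        if key not in per_res:
            per_res[key] = []
            order.append(key)
        per_res[key].append(msd_per_atom[pos])
    for key in order:
        residues.append(key)
        values.append(float(np.sqrt(np.mean(per_res[key]))))
    return FlexibilityProfile(residues=residues, rmsf=np.asarray(values))


SSEMap = dict[str, tuple[int, int]]
"""Named secondary-structure elements -> inclusive author-numbered ranges."""


def rmsf_by_sse(profile: FlexibilityProfile, sse: SSEMap):
    """Mean RMSF inside each secondary-structure element, in map order.

    Overlapping elements are both computed, with a warning.  An element
    covering no profiled residue raises, naming the element.
    """
    import pandas as pd

    items = list(sse.items())
    for (name_a, (a0, a1)), (name_b, (b0, b1)) in zip(items, items[1:]):
        if max(a0, b0) <= min(a1, b1):
            warnings.warn(f"SSE ranges {name_a} and {name_b} overlap")
    rows = []
    for name, (start, end) in items:
        if start > end:
            raise SelectionError(f"SSE {name}: malformed range {start}-{end}")
        mask = np.array([start <= key[1] <= end for key in profile.residues])
        if not mask.any():
            raise SelectionError(f"SSE {name} contains no profiled residues")
        rows.append({"sse": name, "start": start, "end": end,
                     "mean_rmsf": float(profile.rmsf[mask].mean()),
                     "n_residues": int(mask.sum())})
    return pd.DataFrame(rows, columns=["sse", "start", "end", "mean_rmsf", "n_residues"])


# --------------------------------------------------------------------------
# MSD
# --------------------------------------------------------------------------

@dataclass
class MSDCurve:
    """Mean-squared displacement (A^2) on a grid of lag times (ps)."""

    lags_ps: np.ndarray
    msd: np.ndarray


def default_lag_grid(total_time_ps: float, per_decade: int = 20,
                     lo_ps: float = 10.0, hi_ps: float = 1e4) -> np.ndarray:
    """Log-spaced lags, ``per_decade`` per decade over [lo, hi] ps,
    truncated to lags shorter than the trajectory."""
    n_dec = np.log10(hi_ps / lo_ps)
    grid = np.logspace(np.log10(lo_ps), np.log10(hi_ps),
                       int(round(n_dec * per_decade)) + 1)
    return grid[grid < total_time_ps]


def msd_curve(
    traj: Trajectory,
    selector: ResidueSelector | None = None,
    lags_ps: np.ndarray | None = None,
    max_origins: int = 1000,
) -> MSDCurve:
    """Time-origin-averaged MSD over selected atoms.

    MSD(tau) = < |r(t + tau) - r(t)|^2 > over atoms and strided origins
    (at most ``max_origins`` per lag).  Lags that are not multiples of
    dt are rounded to the nearest frame with a warning.  Lag 0 is always
    included and is exactly 0.
    """
    if not traj.aligned:
        raise NotAlignedError("msd_curve needs an aligned trajectory")
    selector = selector or ResidueSelector(mode="heavy")
    idx = selector.resolve(traj.topology)
    coords = traj.frames[:, idx]
    total_ps = traj.n_frames * traj.dt
    if lags_ps is None:
        lags_ps = default_lag_grid(total_ps)
    lags_ps = np.asarray(lags_ps, float)
    if lags_ps.size and lags_ps.max() >= total_ps:
        raise ValueError("maximum lag must be shorter than the trajectory")

    out_lags = [0.0]
    out_msd = [0.0]
    warned = False
    for lag in lags_ps:
        if lag == 0:
            continue
        frames_lag = int(round(lag / traj.dt)) if traj.dt > 0 else 0
        if traj.dt > 0 and abs(frames_lag * traj.dt - lag) > 1e-9 and not warned:
            warnings.warn("lag grid is not commensurate with dt; lags rounded "
                          "to the nearest frame")
            warned = True
        frames_lag = max(frames_lag, 1)
        if frames_lag >= traj.n_frames:
            continue
        n_origins = traj.n_frames - frames_lag
        stride = max(1, n_origins // max_origins)
        origins = np.arange(0, n_origins, stride)
        disp = coords[origins + frames_lag] - coords[origins]
        out_lags.append(frames_lag * traj.dt)
        out_msd.append(float(np.mean(np.sum(disp**2, axis=2))))
    return MSDCurve(lags_ps=np.asarray(out_lags), msd=np.asarray(out_msd))


# --------------------------------------------------------------------------
# Ligand-gate distance
# --------------------------------------------------------------------------

@dataclass
class GateSeries:
    """Per-frame gate distance (A) with mean and sample-sd fluctuation."""

    distances: np.ndarray
    residue_a: ResidueKey
    residue_b: ResidueKey

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def rms_fluctuation(self) -> float:
        """Sample (n-1) standard deviation; exactly 0 for a constant series."""
        if self.distances.size < 2 or np.ptp(self.distances) == 0:
            return 0.0
        return float(np.std(self.distances, ddof=1))


def gate_distance_series(
    traj: Trajectory,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
    atom_a: str = "CA",
    atom_b: str = "CA",
) -> GateSeries:
    """Per-frame distance between two named atoms (default C-alpha).

    Residues are (chain_id, residue_seq) in author numbering, e.g. the
    F/G-loop Ser and B'-helix Pro that frame the substrate access channel.
    """
    topo = traj.topology
    ia = topo.find_atom(residue_a[0], residue_a[1], atom_a)
    ib = topo.find_atom(residue_b[0], residue_b[1], atom_b)
    d = np.linalg.norm(traj.frames[:, ia] - traj.frames[:, ib], axis=1)
    return GateSeries(
        distances=d,
        residue_a=(residue_a[0], residue_a[1], ""),
        residue_b=(residue_b[0], residue_b[1], ""),
    )
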