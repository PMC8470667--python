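"""Cross-protein descriptor summaries and family-wide correlations.

One :class:`ProteinSummary` per protein collects the salt-bridge density
and the flexibility descriptors (mean RMSF, gate-distance fluctuation,
pocket-volume fluctuation) from one trajectory, after the standard
preprocessing chain: strip non-protein atoms, slice the analysis
window, align.  :func:`correlate_family` then computes the Pearson
correlation of salt-bridge density with each descriptor across the
family, with pairwise deletion of missing descriptors, plus
per-biological-category means.

Two density definitions are supported: the time-averaged per-frame
count (default, matching how a family of short trajectories is
summarised) and the distinct-pair inventory count; both are carried in
the summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, CorrelationError
from .flexibility import align_trajectory, gate_distance_series, rmsf
from .pocket import PocketGridConfig, pocket_volume_series
from .saltbridge import DEFAULT_BOUNDARIES, DEFAULT_CUTOFF, compute_records
from .structure import ResidueSelector, Trajectory, slice_time, strip_nonprotein

logger = logging.getLogger(__name__)

CATEGORIES = ("Fungi", "Archaea", "Bacteria", "Protista", "Animalia", "Plantae",
              "Unknown")


@dataclass
class ProteinSummary:
    """One protein's salt-bridge density and flexibility descriptors."""

    protein_id: str
    category: str = "Unknown"
    bacteria_like: bool = False
    salt_bridge_density: float = 0.0  # per 100 residues (configured definition)
    density_distinct: float = 0.0  # distinct-pair variant, always carried
    mean_rmsf: float | None = None  # A
    gate_fluctuation: float | None = None  # A
    pocket_fluctuation: float | None = None  # A^3

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ConfigError(
                f"category {self.category!r} not in {CATEGORIES}"
            )
        for name in ("salt_bridge_density", "mean_rmsf", "gate_fluctuation",
                     "pocket_fluctuation"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CorrelationResult:
    """Pearson r between two named descriptors over n proteins."""

    pair: str
    pearson_r: float
    n: int


@dataclass
class SummaryConfig:
    """What to compute per protein and with which parameters.

    ``window_ns`` is the analysis window (e.g. the second half of an
    equilibrated run); ``gate`` is ((chain, resseq), (chain, resseq))
    for the ligand-gate distance and ``pocket`` a grid config; either
    may be None to omit that descriptor.  ``density_definition`` is
    ``per_frame`` (time-averaged instantaneous count) or ``distinct``.
    """

    window_ns: tuple[float, float] | None = None
    cutoff: float = DEFAULT_CUTOFF
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES
    density_definition: str = "per_frame"
    rmsf_selector: ResidueSelector = field(
        default_factory=lambda: ResidueSelector(mode="calpha")
    )
    align_selector: ResidueSelector = field(
        default_factory=lambda: ResidueSelector(mode="calpha")
    )
    gate: tuple[tuple[str, int], tuple[str, int]] | None = None
    pocket: PocketGridConfig | None = None
    n_residues_override: int | None = None

    def __post_init__(self):
        if self.density_definition not in ("per_frame", "distinct"):
            raise ConfigError("density_definition must be 'per_frame' or 'distinct'")


def summarize_protein(
    traj: Trajectory,
    config: SummaryConfig,
    protein_id: str = "protein",
    category: str = "Unknown",
    bacteria_like: bool = False,
) -> ProteinSummary:
    """Run the full descriptor chain on one trajectory.

    strip non-protein -> slice window -> align -> salt-bridge densities
    -> mean RMSF -> gate fluctuation -> pocket fluctuation.  Stage
    failures propagate with the stage named.
    """

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{protein_id}:{name}] {exc}") from exc

    traj = _stage("strip_nonprotein", strip_nonprotein, traj)
    if config.window_ns is not None:
        traj = _stage("slice_time", slice_time, traj, *config.window_ns)
    traj = _stage("align", align_trajectory, traj, config.align_selector)

    sb = _stage(
        "saltbridge", compute_records, traj,
        cutoff=config.cutoff, boundaries=config.boundaries,
        n_residues_override=config.n_residues_override,
    )
    density = (
        sb.density_mean if config.density_definition == "per_frame"
        else sb.density_distinct
    )
    profile = _stage("rmsf", rmsf, traj, config.rmsf_selector)

    gate_fluct = None
    if config.gate is not None:
        (res_a, res_b) = config.gate
        series = _stage("gate", gate_distance_series, traj, res_a, res_b)
        gate_fluct = series.rms_fluctuation
    pocket_fluct = None
    if config.pocket is not None:
        series = _stage("pocket", pocket_volume_series, traj, config.pocket)
        pocket_fluct = series.rms_fluctuation

    return ProteinSummary(
        protein_id=protein_id,
        category=category,
        bacteria_like=bacteria_like,
        salt_bridge_density=density,
        density_distinct=sb.density_distinct,
        mean_rmsf=profile.mean_rmsf,
        gate_fluctuation=gate_fluct,
        pocket_fluctuation=pocket_fluct,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient.

    Requires equal lengths, n >= 3 and non-constant inputs.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise CorrelationError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CorrelationError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


_DESCRIPTORS = (
    ("mean_rmsf", "density_vs_mean_rmsf"),
    ("pocket_fluctuation", "density_vs_pocket_fluctuation"),
    ("gate_fluctuation", "density_vs_gate_fluctuation"),
)


def correlate_family(
    summaries: Sequence[ProteinSummary],
) -> tuple[list[CorrelationResult], pd.DataFrame]:
    """Family-wide Pearson correlations and per-category statistics.

    Returns (correlations, grouped table).  Each correlation pairs the
    salt-bridge density with one flexibility descriptor over the
    proteins carrying both values (pairwise deletion, counts logged);
    descriptors with fewer than 3 complete pairs are skipped with a
    warning.  Constant inputs raise :class:`CorrelationError`.
    """
    if len(summaries) < 3:
        raise CorrelationError("need at least 3 protein summaries")
    results: list[CorrelationResult] = []
    for attr, name in _DESCRIPTORS:
        pairs = [
            (s.salt_bridge_density, getattr(s, attr))
            for s in summaries
            if getattr(s, attr) is not None
        ]
        dropped = len(summaries) - len(pairs)
        if dropped:
            logger.info("%s: %d proteins lack %s; excluded pairwise",
                        name, dropped, attr)
        if len(pairs) < 3:
            logger.warning("%s: fewer than 3 complete pairs; skipped", name)
            continue
        x, y = map(np.asarray, zip(*pairs))
        results.append(CorrelationResult(pair=name, pearson_r=pearson(x, y),
                                         n=len(pairs)))

    df = summaries_table(summaries)
    grouped = (
        df.groupby("category", sort=True)
        .agg(
            n=("protein_id", "size"),
            density_mean=("salt_bridge_density", "mean"),
            rmsf_mean=("mean_rmsf", "mean"),
            gate_fluct_mean=("gate_fluctuation", "mean"),
            pocket_fluct_mean=("pocket_fluctuation", "mean"),
        )
        .reset_index()
    )
    return results, grouped


def summaries_table(summaries: Sequence[ProteinSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": s.protein_id,
                "category": s.category,
                "bacteria_like": s.bacteria_like,
                "salt_bridge_density": s.salt_bridge_density,
                "density_distinct": s.density_distinct,
                "mean_rmsf": s.mean_rmsf,
                "gate_fluctuation": s.gate_fluctuation,
                "pocket_fluctuation": s.pocket_fluctuation,
            }
            for s in summaries
        ]
    )


def correlations_table(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"pair": r.pair, "pearson_r": r.pearson_r, "n": r.n} for r in results],
        columns=["pair", "pearson_r", "n"],
    )


def plot_family(summaries: Sequence[ProteinSummary], path) -> None:
    """Three-panel scatter of density against each flexibility descriptor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"Fungi": "c", "Archaea": "b", "Bacteria": "k", "Protista": "grey",
              "Animalia": "r", "Plantae": "g", "Unknown": "m"}
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    labels = {"mean_rmsf": "mean RMSF (A)",
              "pocket_fluctuation": "pocket volume fluctuation (A^3)",
              "gate_fluctuation": "gate distance fluctuation (A)"}
    for ax, (attr, _) in zip(axes, _DESCRIPTORS):
        for s in summaries:
            v = getattr(s, attr)
            if v is None:
                continue
            face = "none" if s.bacteria_like else colors[s.category]
            ax.scatter(s.salt_bridge_density, v,
                       edgecolors=colors[s.category], facecolors=face, s=18)
        ax.set_xlabel("salt bridges per 100 residues")
        ax.set_ylabel(labels[attr])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
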