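"""Mean-squared displacements from elastic incoherent neutron scans.

An elastic scan is the elastic peak intensity S(q, dt) of the dynamic
structure factor measured on a q grid at one temperature, at fixed
instrument resolution dt (here ~1 ns).  In the Gaussian approximation
with a leading non-Gaussian correction, the intensity follows

    ln I(q) = a - (MSD / 6) q^2 + c q^4

so the MSD is -6 times the q^2 coefficient of an ordinary least-squares
fit of ln I on (1, q^2, q^4) over a configurable q window (default
0.25--1.75 1/A).  A convention switch reports the variance
<u^2> = -3 b (the ``ln I = a - <u^2> q^2 / 3`` convention, i.e. MSD/2)
instead; see ``convention`` in :func:`fit_msd_q4`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitError


@dataclass
class ElasticScan:
    """One temperature point of an elastic scan.

    q in 1/A (strictly increasing, positive), intensity in arbitrary
    units (positive), optional per-point uncertainties, instrument
    resolution time in ns and hydration level (g water / g protein) as
    metadata.
    """

    temperature: float
    q: np.ndarray
    intensity: np.ndarray
    error: np.ndarray | None = None
    resolution_time: float = 1.0
    hydration: float = 0.4

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must be equal-length 1-D arrays")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be positive")
        if self.error is not None:
            self.error = np.asarray(self.error, float)


@dataclass
class MSDResult:
    """Fitted MSD (A^2) at one temperature with fit diagnostics."""

    temperature: float
    msd: float
    stderr: float
    residual_norm: float
    n_points: int


def fit_msd_q4(
    scan: ElasticScan,
    qmin: float = 0.25,
    qmax: float = 1.75,
    convention: str = "msd",
    weighted: bool = False,
) -> MSDResult:
    """Quartic-corrected Gaussian fit of one elastic scan.

    OLS of ln I on (1, q^2, q^4) over [qmin, qmax]; MSD = -6 b where b
    is the q^2 coefficient.  ``convention="u2"`` reports the
    displacement variance <u^2> = -3 b instead.  With ``weighted`` and
    per-point uncertainties, inverse-variance weights on ln I are used.
    """
    if convention not in ("msd", "u2"):
        raise ValueError("convention must be 'msd' or 'u2'")
    mask = (scan.q >= qmin) & (scan.q <= qmax)
    if mask.sum() < 4:
        raise FitError(
            f"need >= 4 points in [{qmin}, {qmax}] 1/A, got {int(mask.sum())}"
        )
    q = scan.q[mask]
    intensity = scan.intensity[mask]
    if np.any(intensity <= 0):
        raise FitError("non-positive intensity inside the fit window")
    y = np.log(intensity)
    design = np.column_stack([np.ones_like(q), q**2, q**4])
    if weighted and scan.error is not None:
        # var(ln I) ~ (dI / I)^2
        w = (intensity / scan.error[mask]) ** 2
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        resid = (y - design @ coef) * sw
    else:
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
    n, p = len(q), 3
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    factor = 6.0 if convention == "msd" else 3.0
    return MSDResult(
        temperature=scan.temperature,
        msd=float(-factor * coef[1]),
        stderr=float(factor * np.sqrt(cov[1, 1])),
        residual_norm=float(np.linalg.norm(resid)),
        n_points=n,
    )


def msd_vs_temperature(
    scans: list[ElasticScan],
    qmin: float = 0.25,
    qmax: float = 1.75,
    normalize_lowest: bool = False,
    convention: str = "msd",
) -> pd.DataFrame:
    """Fit every scan and tabulate MSD against temperature.

    With ``normalize_lowest`` every scan is divided by the
    lowest-temperature scan (point-wise, on a shared q grid) before
    fitting, removing the static structure factor.
    """
    if not scans:
        raise ValueError("no scans supplied")
    scans = sorted(scans, key=lambda s: s.temperature)
    temps = [s.temperature for s in scans]
    if len(set(temps)) != len(temps):
        import warnings

        warnings.warn("duplicate temperatures in scan list; all kept")
    if normalize_lowest:
        ref = scans[0]
        fitted_scans = []
        for s in scans:
            if s.q.shape != ref.q.shape or not np.allclose(s.q, ref.q):
                raise FitError("normalization requires a shared q grid")
            fitted_scans.append(
                ElasticScan(
                    temperature=s.temperature,
                    q=s.q,
                    intensity=s.intensity / ref.intensity,
                    resolution_time=s.resolution_time,
                    hydration=s.hydration,
                )
            )
        scans = fitted_scans
    rows = []
    for s in scans:
        r = fit_msd_q4(s, qmin=qmin, qmax=qmax, convention=convention)
        rows.append(
            {
                "temperature_K": r.temperature,
                "msd_A2": r.msd,
                "stderr_A2": r.stderr,
                "residual_norm": r.residual_norm,
                "n_points": r.n_points,
            }
        )
    return pd.DataFrame(rows)


def read_elastic_scans(path, sep: str | None = None) -> list[ElasticScan]:
    """Read elastic scans from delimited text.

    Accepts a long-format table with columns ``temperature``, ``q``,
    ``intensity`` (optional ``error``), or a two/three-column file
    (q, intensity[, error]) representing a single scan at an unknown
    temperature (recorded as NaN).  Lines starting with '#' are comments.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+|,|\t",
                     engine="python", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "temperature" in cols and "q" in cols:
        scans = []
        for temp, sub in df.groupby(cols["temperature"], sort=True):
            sub = sub.sort_values(cols["q"])
            err = sub[cols["error"]].to_numpy() if "error" in cols else None
            scans.append(
                ElasticScan(
                    temperature=float(temp),
                    q=sub[cols["q"]].to_numpy(),
                    intensity=sub[cols["intensity"]].to_numpy(),
                    error=err,
                )
            )
        return scans
    arr = df.to_numpy(float)
    err = arr[:, 2] if arr.shape[1] > 2 else None
    return [ElasticScan(temperature=float("nan"), q=arr[:, 0],
                        intensity=arr[:, 1], error=err)]
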