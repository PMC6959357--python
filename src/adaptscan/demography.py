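"""Divergence times from PSMC-style effective-population-size trajectories.

For a pseudo-diploid built from two selfing individuals, the inferred Ne
trajectory rises abruptly at the time the two lineages stopped exchanging
genes; reading the curve against a fixed cutoff N* (default 5e4) gives a
divergence-time estimate.  Only the post-processing is implemented here:
parsing the PSMC output (RS records of the final round, or a two-column
scaled TSV), rescaling to years with a per-year mutation rate, and the
cutoff read-off.

Scaling: with theta per site (from the PSMC TR record), per-year mutation
rate mu and generation time g (years), N0 = theta / (4 mu g), time in years
= 2 N0 g t_scaled = theta t_scaled / (2 mu), and Ne = lambda_k N0.  The
year axis is therefore independent of g; g enters only the Ne scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "NeTrajectory",
    "DivergenceEstimate",
    "parse_trajectory",
    "divergence_time",
    "divergence_matrix",
    "DEFAULT_MU",
    "DEFAULT_CUTOFF",
]

DEFAULT_MU = 6.5e-9  # per site per year
DEFAULT_CUTOFF = 5e4


@dataclass
class NeTrajectory:
    """Step function of Ne over time, years before present, present first."""

    t_start: np.ndarray  # years, increasing into the past
    t_end: np.ndarray    # t_end[i] = t_start[i+1]; last is +inf
    ne: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.t_start = np.asarray(self.t_start, dtype=np.float64)
        self.t_end = np.asarray(self.t_end, dtype=np.float64)
        self.ne = np.asarray(self.ne, dtype=np.float64)
        if not (len(self.t_start) == len(self.t_end) == len(self.ne)):
            raise DataError("trajectory arrays must have equal length")
        if len(self.t_start) == 0:
            raise DataError("empty trajectory")
        if np.any(np.diff(self.t_start) <= 0):
            raise DataError("trajectory times must be strictly increasing")
        if np.any(self.t_start < 0) or np.any(self.ne <= 0):
            raise DataError("negative times or non-positive Ne")
        if not np.allclose(self.t_end[:-1], self.t_start[1:]):
            raise DataError("trajectory intervals must be contiguous")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_start_years": self.t_start, "t_end_years": self.t_end, "ne": self.ne}
        )


@dataclass
class DivergenceEstimate:
    label: str
    divergence_years: float | None
    cutoff: float


def _read_rs_block(text: str):
    """(t_scaled, lambda) steps and theta from the final PSMC round."""
    rounds = []
    cur_rs, cur_theta = [], None
    for line in text.splitlines():
        parts = line.split("\t")
        if parts[0] == "TR":
            if cur_rs:
                rounds.append((cur_theta, cur_rs))
                cur_rs = []
            cur_theta = float(parts[1])
        elif parts[0] == "RS":
            cur_rs.append((float(parts[2]), float(parts[3])))
    if cur_rs:
        rounds.append((cur_theta, cur_rs))
    if not rounds:
        raise DataError("no RS records found in PSMC output")
    theta, rs = rounds[-1]
    if theta is None:
        raise DataError("PSMC output lacks a TR (theta) record")
    t = np.array([r[0] for r in rs])
    lam = np.array([r[1] for r in rs])
    return t, lam, theta


def parse_trajectory(
    source,
    mu: float = DEFAULT_MU,
    gen_time: float = 1.0,
    theta: float | None = None,
    label: str = "",
) -> NeTrajectory:
    """Parse PSMC main output (RS records) or a 2-column scaled TSV.

    ``source`` is a path or raw text.  The TSV dialect has two tab-separated
    columns (scaled time, scaled Ne lambda) with an optional ``#theta=<v>``
    header line; for RS input theta comes from the final TR record.  Times
    are rescaled to years via theta*t/(2*mu); Ne = lambda * theta/(4*mu*g).
    """
    if mu <= 0 or gen_time <= 0:
        raise DataError("mu and gen_time must be positive")
    text = source
    p = Path(str(source))
    if len(str(source)) < 4096 and p.is_file():
        text = p.read_text()
    text = text.strip()
    if not text:
        raise DataError("empty trajectory input")
    if "RS\t" in text or text.startswith("RS"):
        t, lam, theta_eff = _read_rs_block(text)
    else:
        rows = []
        theta_eff = theta
        for ln, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("#theta="):
                    theta_eff = float(line.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"line {ln}: expected 2 tab-separated columns")
            rows.append((float(parts[0]), float(parts[1])))
        if not rows:
            raise DataError("no data rows in trajectory input")
        t = np.array([r[0] for r in rows])
        lam = np.array([r[1] for r in rows])
    if theta is not None:
        theta_eff = theta
    if theta_eff is None:
        raise DataError("theta required to scale the trajectory")
    if np.any(np.diff(t) <= 0) or np.any(t < 0) or np.any(lam <= 0):
        raise DataError("non-monotone times or non-positive Ne in input")
    n0 = theta_eff / (4.0 * mu * gen_time)
    t_years = theta_eff * t / (2.0 * mu)
    ne = lam * n0
    t_end = np.append(t_years[1:], np.inf)
    return NeTrajectory(t_years, t_end, ne, label=label)


def divergence_time(
    traj: NeTrajectory, cutoff: float = DEFAULT_CUTOFF, interpolate: bool = False
) -> DivergenceEstimate:
    """First time, scanning from the present, at which Ne reaches the cutoff.

    Default is the start of the first interval with Ne >= cutoff (reading a
    step plot); ``interpolate=True`` instead places the crossing by
    log-linear interpolation between the previous interval's start and the
    crossing interval's start.  Undefined when the cutoff is never reached.
    """
    idx = np.flatnonzero(traj.ne >= cutoff)
    if len(idx) == 0:
        return DivergenceEstimate(traj.label, None, cutoff)
    i = int(idx[0])
    t = float(traj.t_start[i])
    if interpolate and i > 0 and traj.ne[i] > traj.ne[i - 1]:
        t0, t1 = traj.t_start[i - 1], traj.t_start[i]
        n0, n1 = traj.ne[i - 1], traj.ne[i]
        frac = (np.log(cutoff) - np.log(n0)) / (np.log(n1) - np.log(n0))
        frac = float(np.clip(frac, 0.0, 1.0))
        t = float(t0 + frac * (t1 - t0))
    return DivergenceEstimate(traj.label, t, cutoff)


def divergence_matrix(trajectories: dict, cutoff: float = DEFAULT_CUTOFF, **kw) -> pd.DataFrame:
    """Symmetric accession x accession divergence-time table.

    ``trajectories`` maps (acc_a, acc_b) pairs to NeTrajectory; undefined
    estimates stay NaN (flagged, not zero).  Accession order follows first
    appearance in the pair keys.
    """
    keys = list(trajectories)
    if len(set(keys)) != len(keys):
        raise DataError("duplicate pair labels")
    seen = []
    for a, b in keys:
        for x in (a, b):
            if x not in seen:
                seen.append(x)
    out = pd.DataFrame(np.nan, index=seen, columns=seen)
    for (a, b), traj in trajectories.items():
        est = divergence_time(traj, cutoff=cutoff, **kw)
        val = est.divergence_years if est.divergence_years is not None else np.nan
        out.loc[a, b] = val
        out.loc[b, a] = val
    return out
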