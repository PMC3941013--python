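"""Departure of a hexameric pore assembly from six-fold symmetry.

Six structurally equivalent alpha carbons (one per protomer) define a
hexagon; its three main diagonals connect opposite vertices.  The
eccentricity coefficient E = D_max/d_min (longest over shortest diagonal)
equals 1 for perfect six-fold symmetry and grows as the pore mouth
deforms.  Interior angles of the same hexagon track the dynamics of
individual protomers.  Distributions of these observables between two
conditions are compared with the Mann-Whitney U test, which makes no
normality assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class HexFrameSeries:
    """Per-frame alpha-carbon coordinates of a six-protomer assembly.

    coords has shape (n_frames, 6, n_residues, 3), in nm.  Protomer order
    is the cyclic adjacency around the pore; residue order follows
    ``residue_ids``.
    """

    coords: np.ndarray
    residue_ids: list[int]
    protomer_labels: list[str] = field(default_factory=lambda: list("ABCDEF"))
    times: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[1] != 6 or self.coords.shape[3] != 3:
            raise ValueError(
                "coords must have shape (n_frames, 6, n_residues, 3), "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[2] != len(self.residue_ids):
            raise ValueError("residue axis does not match residue_ids")
        if len(self.protomer_labels) != 6:
            raise ValueError("exactly 6 protomer labels required")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def residue_index(self, residue: int) -> int:
        try:
            return self.residue_ids.index(residue)
        except ValueError:
            raise KeyError(f"residue {residue} not in trajectory") from None

    def vertices(self, frame: int, residue: int) -> np.ndarray:
        """(6, 3) alpha-carbon positions of one residue ring in one frame."""
        return self.coords[frame, :, self.residue_index(residue), :]


@dataclass
class EccentricityResult:
    """Diameters, eccentricity and interior angles of one hexagon."""

    D_max: float          # nm
    d_min: float          # nm
    E: float              # dimensionless, >= 1
    angles_deg: np.ndarray  # 6 interior angles


@dataclass
class MWUResult:
    U: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" or "normal_approx"


def _project_to_plane(vertices: np.ndarray) -> np.ndarray:
    """Project 6 points onto their least-squares plane, returning (6, 2).

    2-D input is used as-is.  For 3-D input the plane is found by SVD of
    the centred coordinates; the in-plane basis is orthonormal, so all
    distances and angles within the plane are preserved.
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape == (6, 2):
        return v
    if v.shape != (6, 3):
        raise ValueError(f"expected 6 vertices in 2-D or 3-D, got shape {v.shape}")
    centred = v - v.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return centred @ vt[:2].T


def hexagon_metrics(vertices: np.ndarray) -> EccentricityResult:
    """Eccentricity and interior angles of a hexagon given its 6 vertices.

    Vertices are ordered around the ring (protomer adjacency).  The three
    diameters are the opposite-vertex distances (i, i+3); edges and short
    diagonals are not diameters.  Interior angle at vertex i is the angle
    between the edges to vertices i-1 and i+1, computed in the projection
    plane; convex hexagons are assumed (angles sum to 720 deg).
    """
    v = np.asarray(vertices, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("vertices must be finite")
    p2 = _project_to_plane(v)
    edges = np.roll(p2, -1, axis=0) - p2
    edge_len = np.linalg.norm(edges, axis=1)
    if np.any(edge_len < 1e-12):
        raise ValueError("coincident adjacent vertices")
    diams = np.linalg.norm(p2[3:6] - p2[0:3], axis=1)
    d_min = float(diams.min())
    if d_min < 1e-12:
        raise ValueError("degenerate hexagon: a main diagonal has zero length")
    D_max = float(diams.max())
    # interior angle at i: between vectors to the two neighbours
    prev_vec = np.roll(p2, 1, axis=0) - p2
    next_vec = np.roll(p2, -1, axis=0) - p2
    cosang = np.einsum("ij,ij->i", prev_vec, next_vec) / (
        np.linalg.norm(prev_vec, axis=1) * np.linalg.norm(next_vec, axis=1)
    )
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return EccentricityResult(D_max=D_max, d_min=d_min, E=D_max / d_min, angles_deg=angles)


def eccentricity_noiseless(a: float) -> float:
    """Eccentricity of a regular hexagon stretched by ``a`` along one axis.

    Vertices at 0, 60, ..., 300 deg on the unit circle with x scaled by a
    have diameters 2a and 2*sqrt(a^2/4 + 3/4), giving
    E = a / sqrt(a^2/4 + 3/4) for a >= 1.
    """
    if a < 1:
        raise ValueError("anisotropy a must be >= 1")
    return a / np.sqrt(0.25 * a**2 + 0.75)


def anisotropy_from_eccentricity(E: float) -> float:
    """Invert :func:`eccentricity_noiseless`: a = sqrt(3 E^2 / (4 - E^2))."""
    if not 1.0 <= E < 2.0:
        raise ValueError("E must lie in [1, 2) for a single-axis stretch")
    return float(np.sqrt(3.0 * E**2 / (4.0 - E**2)))


def select_frames(
    traj: HexFrameSeries, n_frames: int | None = None, last_ns: float | None = None
) -> np.ndarray:
    """Indices of ``n_frames`` equally spaced frames, optionally restricted
    to the trailing ``last_ns`` of the trajectory (requires frame times)."""
    idx = np.arange(traj.n_frames)
    if last_ns is not None:
        if traj.times is None:
            raise ValueError("trajectory has no frame times; cannot select by time")
        t_end = traj.times[-1]
        idx = idx[traj.times >= t_end - last_ns]
    if len(idx) == 0:
        raise ValueError("empty frame selection")
    if n_frames is not None:
        if n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        pick = np.unique(np.round(np.linspace(0, len(idx) - 1, min(n_frames, len(idx)))).astype(int))
        idx = idx[pick]
    return idx


def eccentricity_series(
    traj: HexFrameSeries,
    residues: Sequence[int],
    frames: np.ndarray | None = None,
    aggregate: str = "frame_mean",
) -> dict:
    """Eccentricity over (residue, frame) pairs with summary statistics.

    aggregate="frame_mean" (default): average E over residues within each
    frame first, then report mean and s.e.m. over the frame means
    (n = n_frames).  aggregate="pooled": mean and s.e.m. over all
    (residue, frame) values (n = n_residues * n_frames).

    Returns a dict with a tidy ``table`` (frame, residue, E, D_max, d_min),
    ``mean``, ``sem`` and ``n``.
    """
    residues = list(residues)
    if not residues:
        raise ValueError("empty residue selection")
    if frames is None:
        frames = np.arange(traj.n_frames)
    frames = np.asarray(frames, dtype=int)
    if len(frames) == 0:
        raise ValueError("empty frame selection")
    rows = []
    for fi in frames:
        for rid in residues:
            m = hexagon_metrics(traj.vertices(fi, rid))
            rows.append((int(fi), rid, m.E, m.D_max, m.d_min))
    table = pd.DataFrame(rows, columns=["frame", "residue", "E", "D_max", "d_min"])
    if aggregate == "frame_mean":
        per_frame = table.groupby("frame")["E"].mean()
        values = per_frame.to_numpy()
    elif aggregate == "pooled":
        values = table["E"].to_numpy()
    else:
        raise ValueError(f"unknown aggregation {aggregate!r}")
    n = len(values)
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {"table": table, "values": values, "mean": mean, "sem": sem, "n": n}


def angle_series(traj: HexFrameSeries, residue: int, frames: np.ndarray | None = None) -> pd.DataFrame:
    """Interior angles of one residue ring, per frame.

    Returns a DataFrame with columns frame, angle_1..angle_6 (degrees).
    ``pooled_angles`` of the result is simply the 6 columns flattened.
    """
    if frames is None:
        frames = np.arange(traj.n_frames)
    rows = []
    for fi in np.asarray(frames, dtype=int):
        m = hexagon_metrics(traj.vertices(fi, residue))
        rows.append([int(fi), *m.angles_deg])
    return pd.DataFrame(rows, columns=["frame"] + [f"angle_{i+1}" for i in range(6)])


def pooled_angles(angle_table: pd.DataFrame) -> np.ndarray:
    """Flatten the six per-vertex angle series into one distribution."""
    return angle_table[[c for c in angle_table.columns if c.startswith("angle_")]].to_numpy().ravel()


def mann_whitney_u(sample_a, sample_b, mode: str = "auto") -> MWUResult:
    """Two-sided Mann-Whitney U test.

    mode="auto" uses the exact null distribution when n1+n2 <= 12 and the
    samples are tie-free, and the tie-corrected normal approximation
    otherwise; "exact" and "normal_approx" force the choice.  U is the
    statistic of the first sample (number of (a, b) pairs with a > b,
    ties counting one half).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if mode == "auto":
        use_exact = (len(a) + len(b) <= 12) and not has_ties
    elif mode == "exact":
        use_exact = True
    elif mode == "normal_approx":
        use_exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MWUResult(
        U=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=len(a),
        n2=len(b),
        method="exact" if use_exact else "normal_approx",
    )
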