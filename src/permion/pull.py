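"""Detachment-force estimation from constant-velocity force-ramp traces.

A helix anchored to the pore wall is pulled through a spring whose free
end moves at constant velocity v: the force rises linearly with slope k*v
until the anchoring interaction breaks, then drops abruptly.  Two
estimators are provided for the detachment force: a per-trace drop
detector, and the divergence point of the mean traces of two conditions
(the reading used when one condition ruptures early and the other late).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PullTraceSet:
    """Force-vs-time traces for a set of pulled helices.

    traces: list of (t, F) pairs of 1-D arrays; t in ns, F in kJ/mol/nm.
    k (kJ/mol/nm^2) and v (nm/ns) give the nominal ramp slope k*v.
    """

    traces: list[tuple[np.ndarray, np.ndarray]]
    k: float
    v: float
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = []
        for t, f in self.traces:
            t = np.asarray(t, dtype=float)
            f = np.asarray(f, dtype=float)
            if t.shape != f.shape or t.ndim != 1 or len(t) < 2:
                raise ValueError("each trace must be two equal-length 1-D arrays")
            clean.append((t, f))
        self.traces = clean

    @property
    def ramp_slope(self) -> float:
        """Nominal loading rate k*v, kJ mol^-1 nm^-1 per ns."""
        return self.k * self.v


@dataclass
class MeanTrace:
    """Pointwise mean of several traces on a common grid, with spread."""

    t: np.ndarray
    f_mean: np.ndarray
    f_sd: np.ndarray
    n: int


@dataclass
class DetachmentEstimate:
    """Detachment (rupture) force estimate.

    ``detected`` is False when no qualifying event exists, in which case
    f_detach and t_detach are NaN — a valid outcome for a helix that stays
    attached for the whole ramp.
    """

    f_detach: float  # kJ/mol/nm
    t_detach: float  # ns
    method: str      # "per_trace_drop" or "mean_trace_divergence"
    uncertainty: float = float("nan")
    detected: bool = True

    def as_dict(self) -> dict:
        return {
            "f_detach": float(self.f_detach),
            "t_detach": float(self.t_detach),
            "method": self.method,
            "uncertainty": float(self.uncertainty),
            "detected": bool(self.detected),
        }


def mean_pull_trace(trace_set: PullTraceSet) -> MeanTrace:
    """Pointwise mean and sd of the traces on a common time grid.

    The grid spans the overlap of all time supports at the coarsest native
    spacing; traces are linearly interpolated onto it.
    """
    if len(trace_set.traces) < 2:
        raise ValueError("need at least 2 traces to average")
    t0 = max(t[0] for t, _ in trace_set.traces)
    t1 = min(t[-1] for t, _ in trace_set.traces)
    if t1 <= t0:
        raise ValueError("traces have disjoint time supports")
    dt = max(np.median(np.diff(t)) for t, _ in trace_set.traces)
    grid = np.arange(t0, t1 + 0.5 * dt, dt)
    grid = grid[grid <= t1 + 1e-12]
    stack = np.vstack([np.interp(grid, t, f) for t, f in trace_set.traces])
    return MeanTrace(
        t=grid,
        f_mean=stack.mean(axis=0),
        f_sd=stack.std(axis=0, ddof=1),
        n=stack.shape[0],
    )


def running_average(t: np.ndarray, f: np.ndarray, window: float) -> np.ndarray:
    """Centred moving mean over a time window, shrinking at the edges.

    ``window`` in ns; output on the input grid.  Assumes uniform sampling
    (the window is converted to an odd sample count).
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    if len(t) < 2:
        raise ValueError("trace too short")
    dt = float(np.median(np.diff(t)))
    if window <= 0:
        raise ValueError("window must be positive")
    if window < dt:
        return f.copy()  # sub-sample window: the box filter is an identity
    if window > t[-1] - t[0]:
        raise ValueError("window exceeds trace span")
    m = max(1, int(round(window / dt)))
    if m % 2 == 0:
        m += 1
    return (
        pd.Series(f).rolling(window=m, center=True, min_periods=1).mean().to_numpy()
    )


def _sustained(mask: np.ndarray, t: np.ndarray, dwell: float) -> int | None:
    """First index opening a True run that lasts at least ``dwell`` ns
    (runs touching the end of the trace qualify)."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return None
    # split into runs of consecutive indices
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], splits + 1])
    ends = np.concatenate([splits, [len(idx) - 1]])
    for s, e in zip(starts, ends):
        i0, i1 = idx[s], idx[e]
        if t[i1] - t[i0] >= dwell or i1 == len(t) - 1:
            return int(i0)
    return None


def detachment_force(
    t: np.ndarray,
    f: np.ndarray,
    drop_fraction: float = 0.3,
    dwell: float = 0.1,
) -> DetachmentEstimate:
    """Per-trace rupture: force at the last maximum before the first
    sustained drop.

    A drop qualifies when the force stays below (1 - drop_fraction) of the
    running peak for at least ``dwell`` ns.  The estimate is the running
    peak value at drop onset and the time it was reached.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    peak = np.maximum.accumulate(f)
    mask = f < (1.0 - drop_fraction) * peak
    i0 = _sustained(mask, t, dwell)
    if i0 is None:
        return DetachmentEstimate(
            f_detach=float("nan"), t_detach=float("nan"),
            method="per_trace_drop", detected=False,
        )
    f_rupt = peak[i0]
    i_peak = int(np.flatnonzero(f[: i0 + 1] == f_rupt)[-1])
    return DetachmentEstimate(
        f_detach=float(f_rupt), t_detach=float(t[i_peak]), method="per_trace_drop"
    )


def divergence_force(
    mean_a: MeanTrace,
    mean_b: MeanTrace,
    n_sd: float = 2.0,
    dwell: float = 0.1,
    smooth_window: float | None = None,
    reference: str = "ramp",
) -> DetachmentEstimate:
    """Detachment force read off the divergence point of two mean traces.

    The traces diverge at the first time their difference exceeds ``n_sd``
    pooled pointwise standard deviations for at least ``dwell`` ns.  The
    force reported is read at that onset on the chosen reference:
    "ramp" (default) reads the larger of the two traces there — the
    condition still loading, i.e. the shared ramp both followed until the
    weaker one let go — and is symmetric under swapping the conditions;
    "common" averages the two; "a"/"b" read a single trace.
    """
    grid = mean_a.t
    fb = np.interp(grid, mean_b.t, mean_b.f_mean)
    sb = np.interp(grid, mean_b.t, mean_b.f_sd)
    fa, sa = mean_a.f_mean, mean_a.f_sd
    if smooth_window is not None:
        fa = running_average(grid, fa, smooth_window)
        fb = running_average(grid, fb, smooth_window)
    pooled = np.sqrt(0.5 * (sa**2 + sb**2))
    floor = 1e-9 * max(np.abs(fa).max(), np.abs(fb).max(), 1.0)
    mask = np.abs(fa - fb) > n_sd * np.maximum(pooled, floor)
    i0 = _sustained(mask, grid, dwell)
    if i0 is None:
        return DetachmentEstimate(
            f_detach=float("nan"), t_detach=float("nan"),
            method="mean_trace_divergence", detected=False,
        )
    if reference == "ramp":
        f_read = max(fa[i0], fb[i0])
    elif reference == "common":
        f_read = 0.5 * (fa[i0] + fb[i0])
    elif reference == "a":
        f_read = fa[i0]
    elif reference == "b":
        f_read = fb[i0]
    else:
        raise ValueError(
            f"reference must be 'ramp', 'common', 'a' or 'b', got {reference!r}"
        )
    return DetachmentEstimate(
        f_detach=float(f_read),
        t_detach=float(grid[i0]),
        method="mean_trace_divergence",
        uncertainty=float(pooled[i0]),
    )


def prerupture_slope(t: np.ndarray, f: np.ndarray, est: DetachmentEstimate | None = None) -> float:
    """Least-squares loading rate over the pre-rupture ramp, (kJ/mol/nm)/ns."""
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    if est is not None and est.detected:
        sel = t <= est.t_detach
        t, f = t[sel], f[sel]
    if len(t) < 2:
        raise ValueError("not enough pre-rupture samples")
    return float(np.polyfit(t, f, 1)[0])
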