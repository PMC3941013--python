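"""Potential of mean force from steered-pulling force logs.

A steered run drags a tagged ion along the pore axis z with a stiff moving
harmonic spring; the time-averaged spring force, integrated along z, is the
work profile W(z) — the potential of mean force (PMF) for single-ion
permeation through the hemichannel.  A full gap-junction-channel profile is
obtained by reflecting the hemichannel profile about its extracellular end,
where two docked hemichannels meet.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .constants import kBT

Tag = Literal["hemichannel", "full_channel", "tilted"]


@dataclass
class SMDLog:
    """Record of a constant-velocity steered pull along the pore axis.

    Attributes
    ----------
    t : array, ns
    z_trap : array, nm — position of the moving end of the spring
    z_ion : array, nm — position of the pulled ion
    f_spring : array, kJ mol^-1 nm^-1 — recorded spring force k*(z_trap - z_ion)
    k : spring constant, kJ mol^-1 nm^-2
    v : pull velocity, nm/ns
    """

    t: np.ndarray
    z_trap: np.ndarray
    z_ion: np.ndarray
    f_spring: np.ndarray
    k: float
    v: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z_trap = np.asarray(self.z_trap, dtype=float)
        self.z_ion = np.asarray(self.z_ion, dtype=float)
        self.f_spring = np.asarray(self.f_spring, dtype=float)
        n = len(self.t)
        if not (len(self.z_trap) == len(self.z_ion) == len(self.f_spring) == n):
            raise ValueError("SMDLog arrays must have equal length")
        if n and np.any(np.diff(self.t) < 0):
            raise ValueError("SMDLog times must be sorted")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class PMFProfile:
    """Free-energy profile W(z) on a strictly increasing z grid.

    z in nm, W in kJ/mol.  Hemichannel profiles are anchored W(z[0]) = 0;
    the absolute offset is physically irrelevant (gauge freedom) and never
    enters conductance.
    """

    z: np.ndarray
    w: np.ndarray
    tag: Tag = "hemichannel"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.z.shape != self.w.shape or self.z.ndim != 1:
            raise ValueError("z and W must be 1-D arrays of equal length")
        if len(self.z) >= 2 and not np.all(np.diff(self.z) > 0):
            raise ValueError("z grid must be strictly increasing")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("W must be finite everywhere")

    @property
    def length(self) -> float:
        """Span of the profile along z, nm."""
        return float(self.z[-1] - self.z[0])

    def shifted(self, dw: float) -> "PMFProfile":
        """Return the profile with a constant added to W (gauge shift)."""
        return replace(self, w=self.w + dw)


def window_average_force(
    log: SMDLog, window: float, bin_by: str = "trap"
) -> tuple[np.ndarray, np.ndarray]:
    """Block-average the recorded spring force over fixed time windows.

    Parameters
    ----------
    log : SMDLog
    window : window duration in ns (e.g. 0.04 for 40 ps)
    bin_by : "trap" (default) or "ion" — which position defines the z
        centre of each window.  The trap is the controlled variable.

    Returns
    -------
    (z_centers, f_mean) : one pair per complete window; the trailing
    incomplete window is dropped.
    """
    if len(log) == 0:
        raise ValueError("empty log")
    if bin_by not in ("trap", "ion"):
        raise ValueError(f"bin_by must be 'trap' or 'ion', got {bin_by!r}")
    t = log.t - log.t[0]
    span = t[-1]
    if window > span:
        raise ValueError(
            f"window {window} ns exceeds log span {span:.6g} ns"
        )
    idx = np.floor(t / window + 1e-12).astype(np.int64)
    # a window is complete when the log extends past its right edge
    n_complete = int(np.floor(span / window + 1e-9))
    if n_complete < 1:
        raise ValueError("window longer than log")
    keep = idx < n_complete
    idx = idx[keep]
    counts = np.bincount(idx, minlength=n_complete)
    if np.any(counts < 2):
        raise ValueError("window must contain at least 2 samples")
    zpos = log.z_trap if bin_by == "trap" else log.z_ion
    z_centers = np.bincount(idx, weights=zpos[keep], minlength=n_complete) / counts
    f_mean = np.bincount(idx, weights=log.f_spring[keep], minlength=n_complete) / counts
    return z_centers, f_mean


def integrate_pmf(
    z: np.ndarray, f: np.ndarray, tag: Tag = "hemichannel"
) -> PMFProfile:
    """Cumulative trapezoidal integral of the mean force along z.

    W(z) = ∫ F dz with W anchored to zero at the first grid point
    (cytoplasmic entry).
    """
    from scipy.integrate import cumulative_trapezoid

    z = np.asarray(z, dtype=float)
    f = np.asarray(f, dtype=float)
    if len(z) < 2:
        raise ValueError("need at least 2 force points to integrate")
    if not np.all(np.diff(z) > 0):
        raise ValueError("z must be strictly increasing")
    w = cumulative_trapezoid(f, z, initial=0.0)
    return PMFProfile(z=z, w=w, tag=tag)


def differentiate_pmf(profile: PMFProfile) -> tuple[np.ndarray, np.ndarray]:
    """Return the force profile F(z) = dW/dz (central differences).

    Round-trip partner of :func:`integrate_pmf`: the recorded spring force
    opposes the channel's mean force, so its integral is W and its value is
    the W gradient.
    """
    return profile.z, np.gradient(profile.w, profile.z)


def reflect_pmf(profile: PMFProfile, z_mirror: float, tol: float | None = None) -> PMFProfile:
    """Extend a hemichannel PMF to a full channel by mirror symmetry.

    The profile is reflected about the vertical axis through ``z_mirror``,
    the extracellular end of the hemichannel where the second (docked)
    hemichannel begins.  ``z_mirror`` must coincide with the last grid
    point within ``tol`` (default: one grid spacing, since window-centre
    grids end up to half a window short of the nominal span).  The mirror
    point is not duplicated.
    """
    z, w = profile.z, profile.w
    if len(z) < 2:
        raise ValueError("cannot reflect a profile with fewer than 2 points")
    if tol is None:
        tol = float(np.max(np.diff(z)))
    if abs(z_mirror - z[-1]) > tol:
        raise ValueError(
            f"z_mirror={z_mirror} must coincide with the last grid point "
            f"{z[-1]:.6g} (within {tol:.3g} nm)"
        )
    z_ref = 2.0 * z_mirror - z[::-1]
    w_ref = w[::-1]
    if z_ref[0] - z[-1] < 1e-12 * max(1.0, abs(z_mirror)):
        z_ref, w_ref = z_ref[1:], w_ref[1:]
    z_out = np.concatenate([z, z_ref])
    w_out = np.concatenate([w, w_ref])
    return PMFProfile(z=z_out, w=w_out, tag="full_channel", meta=dict(profile.meta))


def pmf_from_log(
    log: SMDLog,
    window: float = 0.04,
    bin_by: str = "trap",
    friction_correction: bool = False,
    D: float | None = None,
    T: float = 300.0,
) -> PMFProfile:
    """Full pipeline: window-average the force, optionally subtract the
    steady-state Stokes drag gamma_f*v (gamma_f = kBT/D), and integrate.

    The drag correction is off by default; at the slow pull speeds used for
    production profiles the bias is below thermal noise.
    """
    z, f = window_average_force(log, window, bin_by=bin_by)
    if friction_correction:
        if D is None:
            raise ValueError("friction correction requires the diffusion coefficient D")
        f = f - (kBT(T) / D) * log.v
    return integrate_pmf(z, f)
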