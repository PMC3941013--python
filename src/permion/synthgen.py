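"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of molecular-dynamics
outputs — steered-pulling force logs, hexamer ring trajectories, and
force-ramp rupture traces — so each downstream estimator can be validated
against a prescribed truth (PMF shape, ring anisotropy, rupture force)
without running any simulation software.

Steered pulling is modelled as overdamped (Brownian) motion of a single
ion along the pore axis z in a prescribed free-energy profile W(z), towed
by a harmonic trap moving at constant velocity:

    dz = (D/kBT) * F_total * dt + sqrt(2 D dt) * eta,    eta ~ N(0, 1)

with F_total = -W'(z) + k*(z_trap - z) and the recorded observable the
spring force k*(z_trap - z).  The friction is set by the Einstein relation
gamma_f = kBT/D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import kBT
from .hexgeometry import HexFrameSeries
from .pmf import SMDLog
from .pull import PullTraceSet


# ---------------------------------------------------------------------------
# PMF shapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PMFSpec:
    """Prescribed free-energy profile W(z), the generator's ground truth.

    kind: "flat", "linear" (slope, kJ/mol/nm), "gaussian_barrier" (height
    kJ/mol, center nm, width nm), or "tabulated" (explicit z/W table,
    interpolated linearly).
    """

    kind: str = "flat"
    z_range: tuple[float, float] = (0.0, 8.6)
    height: float = 20.0
    center: float = 4.3
    width: float = 0.5
    slope: float = 10.0
    table_z: tuple | None = None
    table_w: tuple | None = None

    def __post_init__(self) -> None:
        z0, z1 = self.z_range
        if not z1 > z0:
            raise ValueError("z_range must satisfy z_max > z_min")
        if self.kind == "gaussian_barrier" and self.width <= 0:
            raise ValueError("gaussian width must be positive")
        if self.kind == "tabulated":
            if self.table_z is None or self.table_w is None:
                raise ValueError("tabulated PMF needs table_z and table_w")
        elif self.kind not in ("flat", "linear", "gaussian_barrier"):
            raise ValueError(f"unknown PMF kind {self.kind!r}")

    def w(self, z):
        """Evaluate W(z), kJ/mol."""
        z = np.asarray(z, dtype=float)
        if self.kind == "flat":
            out = np.zeros_like(z)
        elif self.kind == "linear":
            out = self.slope * (z - self.z_range[0])
        elif self.kind == "gaussian_barrier":
            out = self.height * np.exp(-((z - self.center) ** 2) / (2 * self.width**2))
        else:
            out = np.interp(z, np.asarray(self.table_z), np.asarray(self.table_w))
        if not np.all(np.isfinite(out)):
            raise ValueError("PMF evaluated to a non-finite value")
        return out

    def dw(self, z: float) -> float:
        """Gradient W'(z), kJ/mol/nm."""
        if self.kind == "flat":
            return 0.0
        if self.kind == "linear":
            return self.slope
        if self.kind == "gaussian_barrier":
            d = z - self.center
            return -self.height * d / self.width**2 * math.exp(-(d * d) / (2 * self.width**2))
        h = 1e-4
        return float((self.w(z + h) - self.w(z - h)) / (2 * h))


@dataclass(frozen=True)
class LangevinParams:
    """Parameters of the overdamped steered-pulling integrator.

    k: trap spring constant, kJ/mol/nm^2 (production pulls use 2000);
    v: trap velocity, nm/ns (0.5 for production, slower for recovery);
    dt: time step, ns (None picks 0.05*kBT/(k*D), half the stability bound);
    T: temperature, K; D: ion diffusion coefficient, nm^2/ns;
    thermal_noise: False gives the deterministic T->0 drift limit.
    """

    k: float = 2000.0
    v: float = 0.5
    dt: float | None = None
    T: float = 300.0
    D: float = 1.957
    seed: int = 0
    thermal_noise: bool = True
    output_stride: int = 10

    def __post_init__(self) -> None:
        for name in ("k", "T", "D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.output_stride < 1:
            raise ValueError("output_stride must be >= 1")

    def resolved_dt(self) -> float:
        if self.dt is not None:
            return self.dt
        return 0.05 * kBT(self.T) / (self.k * self.D)


def gen_smd_log(pmf: PMFSpec, lp: LangevinParams) -> SMDLog:
    """Steered-pulling force log over the profile's full z range.

    The trap starts at z_min and moves at exactly v*t; the ion starts in
    the trap.  Euler-Maruyama steps; the recorded spring force is
    k*(z_trap - z_ion) at every ``output_stride``-th step.  Raises when
    the step size violates the stability contract k*dt*D/kBT < 0.1.
    """
    dt = lp.resolved_dt()
    kbt = kBT(lp.T)
    mobility = lp.D / kbt
    if lp.k * dt * lp.D / kbt >= 0.1:
        raise ValueError(
            f"unstable step: k*dt*D/kBT = {lp.k * dt * lp.D / kbt:.3g} >= 0.1; "
            "reduce dt"
        )
    z0, z1 = pmf.z_range
    if lp.v > 0:
        n_steps = int(math.ceil((z1 - z0) / (lp.v * dt)))
    else:
        n_steps = int(math.ceil(1.0 / dt))  # 1 ns of stationary sampling
    rng = np.random.default_rng(lp.seed)
    noise_sd = math.sqrt(2.0 * lp.D * dt) if lp.thermal_noise else 0.0
    n_out = n_steps // lp.output_stride + 1 + (1 if n_steps % lp.output_stride else 0)
    t_rec = np.empty(n_out)
    ztr_rec = np.empty(n_out)
    zion_rec = np.empty(n_out)

    z = z0
    j = 0
    drift = mobility * dt
    stride = lp.output_stride
    dw = pmf.dw
    for i in range(n_steps + 1):
        t = i * dt
        z_trap = z0 + lp.v * t
        if (i % stride == 0 or i == n_steps) and j < n_out:
            t_rec[j] = t
            ztr_rec[j] = z_trap
            zion_rec[j] = z
            j += 1
        if i == n_steps:
            break
        f_total = -dw(z) + lp.k * (z_trap - z)
        z = z + drift * f_total
        if noise_sd:
            z += noise_sd * rng.standard_normal()
    t_rec, ztr_rec, zion_rec = t_rec[:j], ztr_rec[:j], zion_rec[:j]
    return SMDLog(
        t=t_rec,
        z_trap=ztr_rec,
        z_ion=zion_rec,
        f_spring=lp.k * (ztr_rec - zion_rec),
        k=lp.k,
        v=lp.v,
        meta={
            "generator": "gen_smd_log",
            "pmf_kind": pmf.kind,
            "dt_ns": dt,
            "T_K": lp.T,
            "D_nm2_ns": lp.D,
            "seed": lp.seed,
        },
    )


# ---------------------------------------------------------------------------
# Hexamer ring trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HexSynthSpec:
    """Synthetic six-protomer ring trajectory.

    Vertices sit at 0, 60, ..., 300 degrees on a circle of the per-residue
    radius, the x axis is stretched by the anisotropy factor ``a`` >= 1,
    and i.i.d. Gaussian noise of ``noise_sd`` nm is added per coordinate
    per frame.  Each residue ring is offset along z by ``z_spacing`` so
    the assembly has helical depth.
    """

    n_frames: int = 100
    residue_ids: tuple = tuple(range(2, 15))
    radius: float = 1.0
    a: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    z_spacing: float = 0.15
    frame_dt: float = 0.18  # ns between stored frames

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.a < 1:
            raise ValueError("anisotropy a must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not self.residue_ids:
            raise ValueError("need at least one residue id")


def gen_hex_traj(spec: HexSynthSpec) -> HexFrameSeries:
    """Generate a hexamer ring trajectory with known anisotropy."""
    rng = np.random.default_rng(spec.seed)
    angles = np.radians(np.arange(6) * 60.0)
    n_res = len(spec.residue_ids)
    base = np.empty((6, n_res, 3))
    base[:, :, 0] = (spec.a * spec.radius * np.cos(angles))[:, None]
    base[:, :, 1] = (spec.radius * np.sin(angles))[:, None]
    base[:, :, 2] = (np.arange(n_res) * spec.z_spacing)[None, :]
    coords = np.broadcast_to(base, (spec.n_frames, 6, n_res, 3)).copy()
    if spec.noise_sd > 0:
        coords += rng.normal(0.0, spec.noise_sd, size=coords.shape)
    times = np.arange(spec.n_frames) * spec.frame_dt
    return HexFrameSeries(
        coords=coords,
        residue_ids=list(spec.residue_ids),
        times=times,
        meta={
            "generator": "gen_hex_traj",
            "a": spec.a,
            "radius": spec.radius,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
    )


# ---------------------------------------------------------------------------
# Force-ramp rupture traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PullSynthSpec:
    """Synthetic force-ramp traces with a single rupture per trace.

    The force rises at the nominal loading rate k*v until a per-trace
    rupture force drawn from N(rupture_mean, rupture_sd), then relaxes
    exponentially (time constant ``relax_tau``) to ``residual``; additive
    Gaussian noise of ``noise_sd`` throughout.  Units: force kJ/mol/nm,
    time ns.
    """

    n_traces: int = 6
    k: float = 100.0
    v: float = 1.0
    rupture_mean: float = 105.0
    rupture_sd: float = 0.0
    residual: float = 0.0
    noise_sd: float = 0.0
    dt: float = 0.001
    t_max: float = 3.0
    relax_tau: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rupture_mean <= 0:
            raise ValueError("rupture mean must be positive")
        if self.n_traces < 1:
            raise ValueError("need at least one trace")
        if self.dt <= 0 or self.t_max <= self.dt:
            raise ValueError("invalid time grid")
        if self.t_max * self.k * self.v <= self.rupture_mean:
            raise ValueError(
                "rupture unreachable: t_max*k*v = "
                f"{self.t_max * self.k * self.v:.6g} <= rupture mean "
                f"{self.rupture_mean:.6g}"
            )


def gen_pull_traces(spec: PullSynthSpec) -> tuple[PullTraceSet, np.ndarray]:
    """Generate rupture traces; returns (trace set, true rupture forces).

    Individual rupture draws are clipped to 98% of the maximum reachable
    ramp force so that every trace contains exactly one rupture event.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.t_max + 0.5 * spec.dt, spec.dt)
    slope = spec.k * spec.v
    f_max = 0.98 * spec.t_max * slope
    ruptures = rng.normal(spec.rupture_mean, spec.rupture_sd, size=spec.n_traces)
    ruptures = np.clip(ruptures, 1e-6, f_max)
    traces = []
    for fr in ruptures:
        t_rupt = fr / slope
        f = np.where(
            t <= t_rupt,
            slope * t,
            spec.residual + (fr - spec.residual) * np.exp(-(t - t_rupt) / spec.relax_tau),
        )
        if spec.noise_sd > 0:
            f = f + rng.normal(0.0, spec.noise_sd, size=f.shape)
        traces.append((t.copy(), f))
    trace_set = PullTraceSet(
        traces=traces,
        k=spec.k,
        v=spec.v,
        meta={
            "generator": "gen_pull_traces",
            "rupture_mean": spec.rupture_mean,
            "rupture_sd": spec.rupture_sd,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
    )
    return trace_set, ruptures
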