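"""Run configuration: channel defaults, window sizes, seeds, aggregation.

A flat key-value document (YAML on disk).  Unknown keys are rejected so a
typo cannot silently fall back to a default; every stage logs its fully
resolved configuration.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields

import yaml

from .conductance import DEFAULT_VOLTAGES_MV

log = logging.getLogger("permion")


@dataclass
class RunConfig:
    # channel physics
    temperature_K: float = 300.0
    concentration_M: float = 0.15
    diffusion_m2_s: float = 1.957e-9
    channel_length_nm: float = 17.2
    ion_charge_e: float = 1.0
    eps_r: float = 78.4
    # analysis windows
    force_window_ns: float = 0.04
    running_average_ns: float = 0.0002
    # sweeps and aggregation
    voltages_mV: tuple = DEFAULT_VOLTAGES_MV
    eccentricity_aggregate: str = "frame_mean"
    ion_count_rounding: str = "none"
    # randomness
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "voltages_mV" in doc:
            doc["voltages_mV"] = tuple(doc["voltages_mV"])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["voltages_mV"] = list(doc["voltages_mV"])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def channel_params(self):
        from .conductance import ChannelParams

        return ChannelParams(
            T=self.temperature_K,
            c=self.concentration_M,
            D=self.diffusion_m2_s,
            L=self.channel_length_nm,
            q=self.ion_charge_e,
            eps_r=self.eps_r,
        )

    def log_resolved(self, stage: str) -> None:
        log.info("stage=%s config=%s", stage, asdict(self))
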