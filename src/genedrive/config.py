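"""Run-configuration loading and validation.

Configurations are flat-keyed YAML with three optional sections —
``drive``, ``lifecycle``, ``release``, ``mcmc`` — plus top-level
``architecture``, ``loci`` and ``preset`` keys.  Unknown keys are rejected
and every probability is range-checked at load time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields

import yaml

from .field import LifecycleParams, ReleaseSchedule
from .genetics import ARCHITECTURES, LOCI_CONFIGS, DriveParams
from .presets import preset_parameters

__all__ = ["MCMCConfig", "RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class MCMCConfig:
    iterations: int = 50_000
    burn_in: int = 10_000
    proposal_scale: float = 0.25

    def __post_init__(self):
        if self.iterations < 0 or self.burn_in < 0:
            raise ValueError("iterations and burn_in must be non-negative")
        if self.burn_in > self.iterations:
            raise ValueError("burn_in exceeds iterations")
        if self.proposal_scale <= 0:
            raise ValueError("proposal_scale must be positive")


@dataclass(frozen=True)
class RunConfig:
    architecture: str = "homer"
    loci: str = "one_locus"
    drive: DriveParams = DriveParams()
    lifecycle: LifecycleParams = LifecycleParams()
    release: ReleaseSchedule = ReleaseSchedule()
    mcmc: MCMCConfig = MCMCConfig()

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.loci not in LOCI_CONFIGS:
            raise ValueError(f"unknown loci config {self.loci!r}")


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid '{name}' section: {e}") from e


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    A ``preset`` key seeds the drive parameters from a named bundle; any
    keys in the ``drive`` section override individual preset values.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    allowed_top = {"architecture", "loci", "preset", "drive", "lifecycle", "release", "mcmc"}
    unknown = set(raw) - allowed_top
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")

    drive_section = dict(raw.get("drive") or {})
    if "preset" in raw:
        base = preset_parameters(raw["preset"])
        allowed = {f.name for f in fields(DriveParams)}
        unknown = set(drive_section) - allowed
        if unknown:
            raise ValueError(f"unknown key(s) in 'drive': {sorted(unknown)}")
        drive = base.with_(**drive_section)
    else:
        drive = _build(DriveParams, drive_section, "drive")

    release_section = dict(raw.get("release") or {})
    if "days" in release_section:
        release_section["days"] = tuple(release_section["days"])
    return RunConfig(
        architecture=raw.get("architecture", "homer"),
        loci=raw.get("loci", "one_locus"),
        drive=drive,
        lifecycle=_build(LifecycleParams, dict(raw.get("lifecycle") or {}), "lifecycle"),
        release=_build(ReleaseSchedule, release_section, "release"),
        mcmc=_build(MCMCConfig, dict(raw.get("mcmc") or {}), "mcmc"),
    )


def config_hash(path) -> str:
    """Stable short hash of the parsed configuration content."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    canon = yaml.safe_dump(raw, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
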