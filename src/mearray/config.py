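"""Run configuration: a flat, documented YAML mapping.

Every field has a default; a config file may set any subset.  The
structure round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    """All knobs of a simulation run.

    Units are SI: meters, A/m, A*m, Hz.
    """

    # excitation
    excitation: str = "homogeneous"          # homogeneous | dipole
    H0: List[float] = field(default_factory=lambda: [1.0, 0.0, 0.0])   # A/m
    dipole_moment: List[float] = field(default_factory=lambda: [0.0, 1e-3, 0.0])  # A*m
    dipole_position: List[float] = field(default_factory=lambda: [30e-3, -20e-3, 30e-3])
    frequency: float = 848.0
    secondary_dipole: bool = False
    # array
    rows: int = 3
    cols: int = 5
    spacings: List[float] = field(default_factory=lambda: [5e-3, 10e-3, 20e-3, 50e-3])
    standoff: float = 15e-3
    spacing_convention: str = "edge"         # edge | center
    # head
    head_outer_radius: float = 0.100
    skull_thickness: float = 0.003
    head_inner_radius: Optional[float] = None
    # materials
    mu_r_ms: float = 1000.0
    loss_factor: float = 0.01
    # solver
    grid: List[int] = field(default_factory=lambda: [24, 6, 1])
    solver_method: str = "direct"            # direct | fixed_point
    solver_tol: float = 1e-8
    dipole_cutoff: Optional[float] = None
    # output
    output_dir: str = "results"
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if self.excitation not in ("homogeneous", "dipole"):
            raise ValueError(
                f"unknown excitation kind {self.excitation!r}; valid kinds: "
                "homogeneous, dipole"
            )
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if len(self.grid) != 3 or min(self.grid) < 1:
            raise ValueError("grid must be three positive integers")
        if not self.spacings:
            raise ValueError("at least one spacing is required")
        return self


def load_config(path) -> RunConfig:
    """Read a YAML config, rejecting unknown keys exhaustively."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(
            f"unknown config keys: {sorted(unknown)}; valid keys: {sorted(known)}"
        )
    return RunConfig(**raw).validate()


def dump_config(config: RunConfig, path=None) -> str:
    text = yaml.safe_dump(asdict(config), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
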