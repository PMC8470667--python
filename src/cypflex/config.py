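"""Structured run configuration: schema, defaults, YAML loading.

One nested YAML document configures an end-to-end run; unknown keys are
rejected before any computation.  Defaults follow the standard analysis
parameters: 3.2 A salt-bridge cutoff, 2% / 20% lifetime boundaries,
0.25--1.75 1/A neutron fit window.  Command-line flags override config
values, which override defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError
from .pocket import DEFAULT_PADDING, DEFAULT_VDW, PocketGridConfig
from .structure import ResidueSelector


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class InputConfig(_Strict):
    topology: str | None = None
    trajectory: str | None = None
    format: Literal["pdb", "dcd", "xtc"] = "pdb"
    dt_ps: float | None = None


class SaltBridgeConfig(_Strict):
    cutoff: float = 3.2
    boundaries: tuple[float, float] = (0.02, 0.20)
    include_his: bool = True
    include_termini: bool = False
    n_residues_override: int | None = None
    regions: list[tuple[int, int]] = Field(default_factory=list)


class SelectorConfig(_Strict):
    mode: Literal["all", "calpha", "heavy", "backbone",
                  "name-list", "residue-range"] = "calpha"
    names: list[str] = Field(default_factory=list)
    ranges: list[tuple[int, int]] = Field(default_factory=list)
    chain: str | None = None

    def build(self) -> ResidueSelector:
        return ResidueSelector(
            mode=self.mode, names=tuple(self.names),
            ranges=tuple(tuple(r) for r in self.ranges), chain=self.chain,
        )


class FlexibilityConfig(_Strict):
    rmsf_selector: SelectorConfig = Field(default_factory=SelectorConfig)
    msd_selector: SelectorConfig = Field(
        default_factory=lambda: SelectorConfig(mode="heavy")
    )
    align_selector: SelectorConfig = Field(default_factory=SelectorConfig)
    sse: dict[str, tuple[int, int]] = Field(default_factory=dict)


class GateConfig(_Strict):
    chain: str = "A"
    residue_a: int
    residue_b: int
    atom_a: str = "CA"
    atom_b: str = "CA"


class SphereConfig(_Strict):
    center: tuple[float, float, float]
    radius: float


class PocketConfig(_Strict):
    spheres: list[SphereConfig]
    grid_spacing: float = 1.0
    padding: float = DEFAULT_PADDING
    contiguity: bool = True
    seed_point: tuple[float, float, float] | None = None
    vdw_table: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_VDW))

    def build(self) -> PocketGridConfig:
        return PocketGridConfig(
            inclusion_spheres=[(tuple(s.center), s.radius) for s in self.spheres],
            grid_spacing=self.grid_spacing,
            padding=self.padding,
            contiguity=self.contiguity,
            seed_point=tuple(self.seed_point) if self.seed_point else None,
            vdw_table=dict(self.vdw_table),
        )


class NeutronConfig(_Strict):
    qmin: float = 0.25
    qmax: float = 1.75
    convention: Literal["msd", "u2"] = "msd"
    normalize_lowest: bool = False


class FamilyConfig(_Strict):
    manifest: str | None = None
    density_definition: Literal["per_frame", "distinct"] = "per_frame"


class SynthFamilyConfig(_Strict):
    n_proteins: int = 146
    n_residues: int = 100
    density_range: tuple[float, float] = (2.0, 8.0)
    intercept: float = 2.0
    slope: float = -0.1
    noise_sd: float = 0.3437
    n_frames: int = 500
    dt_ps: float = 40.0


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "cypflex_out"
    window_ns: tuple[float, float] | None = None
    inputs: InputConfig = Field(default_factory=InputConfig)
    saltbridge: SaltBridgeConfig = Field(default_factory=SaltBridgeConfig)
    flexibility: FlexibilityConfig = Field(default_factory=FlexibilityConfig)
    gate: GateConfig | None = None
    pocket: PocketConfig | None = None
    neutron: NeutronConfig = Field(default_factory=NeutronConfig)
    family: FamilyConfig = Field(default_factory=FamilyConfig)
    synth: SynthFamilyConfig = Field(default_factory=SynthFamilyConfig)

    @model_validator(mode="after")
    def _check_window(self):
        if self.window_ns is not None and not self.window_ns[0] < self.window_ns[1]:
            raise ValueError("window_ns must satisfy start < end")
        return self


def load_config(path: str | Path | None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; apply flag overrides on top."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"config root of {path} must be a mapping")
            data = loaded
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        section = data
        *parents, leaf = key.split(".")
        for p in parents:
            section = section.setdefault(p, {})
        section[leaf] = value
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
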