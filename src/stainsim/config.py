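"""Experiment configuration: YAML round-trip and object construction.

A config file fully determines an experiment: the optical system, the stain
set, the unmixing plane and solver, the concentration grids and the scene.
Unknown keys are rejected so typos fail loudly, and serialisation round-trips
losslessly, which together with mandatory seeds makes every run repeatable
bit for bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import InvalidInputError
from .forward import (
    OpticalSystem,
    StainDefinition,
    catalogue_stain,
    monochromatic_system,
    sequential_led_system,
    wideband_system,
)
from .spectra import WavelengthGrid, read_spectrum_csv, \
    standard_spectrum, surrogate_catalogue

_SYSTEM_BUILDERS = {
    "wideband": wideband_system,
    "led": sequential_led_system,
    "monochromatic": monochromatic_system,
}


@dataclass
class SceneConfig:
    type: str = "cells"  # cells | selfsimilar
    width: int = 128
    height: int = 128
    n_cells: int = 12
    c_range: list = field(default_factory=lambda: [[0.5, 4.0], [0.5, 4.0]])
    levels: int = 2
    c_values: list = field(default_factory=lambda: [1.0, 2.0, 4.0])
    tile_px: int = 40

    def __post_init__(self) -> None:
        if self.type not in ("cells", "selfsimilar"):
            raise InvalidInputError(f"unknown scene type {self.type!r}")


@dataclass
class ExperimentConfig:
    """Complete, serialisable description of one experiment."""

    system: Any = "wideband"
    compare_system: str | None = None
    stains: list = field(default_factory=lambda: ["DAB", "HTX"])
    channels: list = field(default_factory=lambda: ["B", "G"])
    solver: str = "lsq"
    grid_values: list = field(default_factory=lambda: [0.1, 1.0, 2.0, 4.0, 8.0])
    sweep_concentrations: list = field(default_factory=lambda: [1, 2, 3, 4, 5])
    grid: dict = field(default_factory=lambda: {
        "start_nm": 405.0, "stop_nm": 700.0, "step_nm": 5.0})
    scene: SceneConfig = field(default_factory=SceneConfig)
    quantise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.scene, Mapping):
            self.scene = SceneConfig(**self.scene)
        if self.solver not in ("exact", "lsq"):
            raise InvalidInputError(f"unknown solver {self.solver!r}")

    # -- serialisation ----------------------------------------------------
    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ExperimentConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise InvalidInputError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- object construction ---------------------------------------------
    def build_grid(self) -> WavelengthGrid:
        return WavelengthGrid(**self.grid)

    def build_system(self, name: Any = None) -> OpticalSystem:
        """Build the configured system, or a named comparison system.

        ``system`` is either one of the predefined names (wideband, led,
        monochromatic) or a mapping with per-channel spectrum specs, each
        spec being ``surrogate:NAME``, ``standard:NAME`` or a CSV path.
        """
        spec = self.system if name is None else name
        grid = self.build_grid()
        if isinstance(spec, str):
            if spec not in _SYSTEM_BUILDERS:
                raise InvalidInputError(
                    f"unknown system {spec!r}; expected one of "
                    f"{sorted(_SYSTEM_BUILDERS)} or a mapping"
                )
            return _SYSTEM_BUILDERS[spec](grid=grid)
        if not isinstance(spec, Mapping):
            raise InvalidInputError("system must be a name or a mapping")
        channels = tuple(spec.get("channels", ("R", "G", "B")))
        illumination = {
            ch: self._spectrum(spec["illumination"][ch], "illumination", grid)
            for ch in channels
        }
        sensitivity = {
            ch: self._spectrum(spec["sensitivity"][ch], "sensitivity", grid)
            for ch in channels
        }
        return OpticalSystem(illumination=illumination, sensitivity=sensitivity,
                             channels=channels, name=str(spec.get("name", "custom")))

    @staticmethod
    def _spectrum(spec: str, role: str, grid: WavelengthGrid):
        if spec.startswith("surrogate:"):
            return surrogate_catalogue(spec.removeprefix("surrogate:"), grid)
        if spec.startswith("standard:"):
            return standard_spectrum(spec.removeprefix("standard:"), grid)
        return read_spectrum_csv(spec, role, grid)

    def build_stains(self) -> list[StainDefinition]:
        grid = self.build_grid()
        stains = []
        for entry in self.stains:
            if isinstance(entry, str):
                stains.append(catalogue_stain(entry, grid))
            else:  # {"name": ..., "csv": path}
                od = read_spectrum_csv(entry["csv"], "optical_density", grid)
                stains.append(StainDefinition(entry["name"], od))
        return stains

    def build_scene(self):
        from .imaging import make_cell_scene, make_selfsimilar_scene

        names = tuple(
            e if isinstance(e, str) else e["name"] for e in self.stains
        )
        sc = self.scene
        if sc.type == "cells":
            return make_cell_scene(
                sc.width, sc.height, sc.n_cells,
                [tuple(r) for r in sc.c_range], self.seed, names,
            )
        return make_selfsimilar_scene(sc.levels, sc.c_values, sc.tile_px, names)
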