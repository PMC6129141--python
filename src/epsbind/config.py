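"""Run configuration: a single YAML file wiring selections, cutoffs and paths.

All scalar defaults equal the field-standard analysis parameters: 2.7 Å and
30° for hydrogen bonds, 4.5 Å for repulsive contacts, 2.6 Å / 3.5 Å for Mg²⁺
coordination spheres, 0.95 for sequence redundancy.  Anything structural
(named selections, helix ranges, file paths per variant) lives in the config
file; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .core import SelectionSpec
from .hbonds import ESPINOSA_A_KJ_MOL, ESPINOSA_B_PER_A, HBondCriteria

__all__ = ["RunConfig", "load_config", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "equilibration_fraction": 0.0,
    "criteria": {"d_max": 2.7, "angle_max": 30.0,
                 "angle_convention": "deviation", "energy_distance": "H-A"},
    "espinosa": {"A": ESPINOSA_A_KJ_MOL, "B": ESPINOSA_B_PER_A},
    "contact_cutoff": 4.5,
    "first_sphere_cutoff": 2.6,
    "water_bridge_cutoff": 3.5,
    "redundancy_threshold": 0.95,
    "identity_denominator": "mutual",
    "selections": {},
    "helix_a": None,
    "helix_b": None,
    "mass_convention": "unit",
    "reference_distances": {},
    "reference_source": "",
    "variants": {},
    "ti_tables": {},
    "alignment": {},
    "reference_label": "WT",
    "reference_kd": {},
    "out_dir": "epsbind_out",
}


@dataclass
class RunConfig:
    """Validated configuration for the end-to-end pipeline."""

    values: dict[str, Any] = field(default_factory=lambda: dict(DEFAULTS))

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {**DEFAULTS, **self.values}
        for key in ("criteria", "espinosa"):
            merged[key] = {**DEFAULTS[key], **(merged.get(key) or {})}
            extra = set(merged[key]) - set(DEFAULTS[key])
            if extra:
                raise ValueError(f"unknown {key} keys: {sorted(extra)}")
        self.values = merged
        if not (0.0 <= self["equilibration_fraction"] < 1.0):
            raise ValueError("equilibration_fraction must be in [0, 1)")
        self.criteria()  # validates cutoffs

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def criteria(self) -> HBondCriteria:
        c = self["criteria"]
        return HBondCriteria(d_max=float(c["d_max"]), angle_max=float(c["angle_max"]),
                             angle_convention=c["angle_convention"],
                             energy_distance=c["energy_distance"])

    def selection(self, name: str) -> SelectionSpec:
        try:
            raw = self["selections"][name]
        except KeyError as exc:
            raise KeyError(f"selection {name!r} not defined in config") from exc
        return SelectionSpec(
            name=name,
            residue_ids=frozenset(int(r) for r in raw.get("residue_ids", [])),
            atom_names=frozenset(raw.get("atom_names", [])),
            residue_names=frozenset(raw.get("residue_names", [])),
        )

    def provenance(self) -> list[str]:
        """Which parameters are at their defaults vs overridden, for logging."""
        lines = []
        for key in ("equilibration_fraction", "contact_cutoff",
                    "first_sphere_cutoff", "water_bridge_cutoff",
                    "redundancy_threshold"):
            tag = "default" if self.values[key] == DEFAULTS[key] else "override"
            lines.append(f"{key} = {self.values[key]} ({tag})")
        c, dc = self["criteria"], DEFAULTS["criteria"]
        for key in dc:
            tag = "default" if c[key] == dc[key] else "override"
            lines.append(f"criteria.{key} = {c[key]} ({tag})")
        return lines


def load_config(path: str | None) -> RunConfig:
    """Load a YAML config file; ``None`` gives pure defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig(values=data)
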