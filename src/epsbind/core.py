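"""Core domain types shared by all analysis stages.

The central container is the :class:`Ensemble`: replicate runs of frames of
named atoms, standing in for an MD trajectory of the ATP-synthase ε subunit
with bound Mg²⁺·ATP.  Protein residues are numbered in the thermophilic
*Bacillus* PS3 crystal convention (1-based) throughout; mutants such as R103A
are represented by their topology (an alanine at position 103), never by a
flag, so selections naming a mutated arginine simply resolve empty.

Frames carry no physical time axis: equilibration discard is expressed as a
fraction of leading frames, and per-run statistics are reduced over replicate
run means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Ensemble",
    "SelectionSpec",
    "SummaryStat",
    "SelectionError",
    "TopologyError",
    "resolve_selection",
    "run_statistics",
    "discard_equilibration",
]


class SelectionError(ValueError):
    """A selection could not be resolved against a frame's topology."""


class TopologyError(ValueError):
    """Frames within an ensemble do not share atom naming/ordering."""


@dataclass(frozen=True)
class AtomRecord:
    """One named atom with Cartesian coordinates in Å."""

    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str
    element: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite position for atom {self.atom_name}")

    @property
    def key(self) -> tuple[str, str, int, str]:
        """Topology identity of the atom (everything except coordinates)."""
        return (self.atom_name, self.residue_name, self.residue_id, self.chain_id)


class Frame:
    """An ordered list of atoms with a frame index.

    Coordinates are also exposed as an (n_atoms, 3) float array for vectorised
    geometry; the array is built once at construction.
    """

    __slots__ = ("atoms", "frame_index", "coords", "_topology_key")

    def __init__(self, atoms: Sequence[AtomRecord], frame_index: int = 0):
        if frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self.frame_index = frame_index
        self.coords = np.array([a.position for a in self.atoms], dtype=float)
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        self._topology_key = tuple(a.key for a in self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def topology_key(self) -> tuple:
        return self._topology_key

    def with_coords(self, coords: np.ndarray, frame_index: int | None = None) -> "Frame":
        """New frame with the same topology but replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [
            AtomRecord(a.atom_name, a.residue_name, a.residue_id, a.chain_id,
                       a.element, tuple(float(x) for x in xyz))
            for a, xyz in zip(self.atoms, coords)
        ]
        return Frame(atoms, self.frame_index if frame_index is None else frame_index)


class Ensemble:
    """Replicate runs of frames sharing one topology.

    Parameters
    ----------
    runs
        One ordered frame list per replicate run.  Every frame in every run
        must share identical atom naming and ordering; a violation raises
        :class:`TopologyError` at construction.
    equilibration_fraction
        Fraction ``f`` in [0, 1) of leading frames per run discarded before
        any statistic is computed (``floor(f * n_frames)`` frames dropped).
    label
        Variant / condition tag, e.g. ``"WT"``, ``"R103A"``, or a Mg²⁺
        coordination tag such as ``"Oα/Oβ"``.
    """

    def __init__(self, runs: Sequence[Sequence[Frame]],
                 equilibration_fraction: float = 0.0, label: str = ""):
        if not runs or any(len(run) == 0 for run in runs):
            raise ValueError("ensemble needs >= 1 run and every run non-empty")
        if not (0.0 <= equilibration_fraction < 1.0):
            raise ValueError("equilibration_fraction must be in [0, 1)")
        ref_key = runs[0][0].topology_key
        for i_run, run in enumerate(runs):
            for frame in run:
                if frame.topology_key != ref_key:
                    raise TopologyError(
                        f"run {i_run}, frame {frame.frame_index}: atom "
                        f"naming/ordering differs from run 0, frame 0"
                    )
        for i_run, run in enumerate(runs):
            if len(run) - n_discarded(equilibration_fraction, len(run)) < 1:
                raise ValueError(
                    f"equilibration_fraction={equilibration_fraction} leaves no "
                    f"analysis frames in run {i_run}"
                )
        self.runs: tuple[tuple[Frame, ...], ...] = tuple(tuple(run) for run in runs)
        self.equilibration_fraction = float(equilibration_fraction)
        self.label = label

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def topology(self) -> Frame:
        return self.runs[0][0]

    def analysis_runs(self) -> list[tuple[Frame, ...]]:
        """Runs with the equilibration prefix removed."""
        out = []
        for run in self.runs:
            k = n_discarded(self.equilibration_fraction, len(run))
            out.append(run[k:])
        return out

    def iter_analysis_frames(self) -> Iterable[Frame]:
        for run in self.analysis_runs():
            yield from run


def n_discarded(fraction: float, n_frames: int) -> int:
    """Number of leading frames dropped: exactly ``floor(fraction * n_frames)``."""
    return int(math.floor(fraction * n_frames))


@dataclass(frozen=True)
class SelectionSpec:
    """A named set of residue ids and/or atom names.

    Matching semantics: an atom matches if its residue_id is in
    ``residue_ids`` (or residue_ids is empty, meaning "any residue") AND its
    atom_name is in ``atom_names`` (or atom_names is empty, meaning "any
    atom").  ``residue_names`` further restricts by residue name when given.
    At least one of the three filters must be non-empty.
    """

    name: str
    residue_ids: frozenset[int] = frozenset()
    atom_names: frozenset[str] = frozenset()
    residue_names: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_ids", frozenset(self.residue_ids))
        object.__setattr__(self, "atom_names", frozenset(self.atom_names))
        object.__setattr__(self, "residue_names", frozenset(self.residue_names))
        if not (self.residue_ids or self.atom_names or self.residue_names):
            raise ValueError(f"selection {self.name!r} is empty")

    def matches(self, atom: AtomRecord) -> bool:
        if self.residue_ids and atom.residue_id not in self.residue_ids:
            return False
        if self.atom_names and atom.atom_name not in self.atom_names:
            return False
        if self.residue_names and atom.residue_name not in self.residue_names:
            return False
        return True


def resolve_selection(spec: SelectionSpec, frame: Frame,
                      strict: bool = False) -> list[int]:
    """Atom indices in ``frame`` matched by ``spec``, in ascending order.

    With ``strict=True`` an empty resolution raises :class:`SelectionError`
    naming the selector; otherwise an empty list is returned (the convention
    used for mutated-away arginines).
    """
    idx = [i for i, a in enumerate(frame.atoms) if spec.matches(a)]
    if strict and not idx:
        raise SelectionError(
            f"selection {spec.name!r} (residues={sorted(spec.residue_ids)}, "
            f"atoms={sorted(spec.atom_names)}) matched no atoms"
        )
    return idx


@dataclass(frozen=True)
class SummaryStat:
    """Replicate-level summary: mean and SD of per-run means."""

    mean: float
    sd: float
    n_runs: int

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_runs == 1 and self.sd != 0:
            raise ValueError("sd must be 0 for a single run")

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f}"


def run_statistics(per_frame_values: Sequence[Sequence[float]],
                   equilibration_fraction: float = 0.0) -> SummaryStat:
    """Reduce per-frame values to a replicate-level :class:`SummaryStat`.

    Each run's values are first truncated by the equilibration fraction, then
    averaged; the reported mean is the mean of run means and the SD is the
    sample SD (n−1 denominator) of the run means, zero for a single run.
    """
    if not per_frame_values:
        raise ValueError("need >= 1 run")
    run_means = []
    for i, values in enumerate(per_frame_values):
        k = n_discarded(equilibration_fraction, len(values))
        kept = list(values)[k:]
        if not kept:
            raise ValueError(f"equilibration discard leaves no frames in run {i}")
        run_means.append(float(np.mean(kept)))
    n = len(run_means)
    mean = float(np.mean(run_means))
    sd = float(np.std(run_means, ddof=1)) if n > 1 else 0.0
    return SummaryStat(mean=mean, sd=sd, n_runs=n)
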