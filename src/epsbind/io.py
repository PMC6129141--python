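"""File I/O: multi-model PDB ensembles and thermodynamic-integration tables.

This is the only module that interprets file dialects.  Structural ensembles
are exchanged as multi-model PDB files (one file per replicate run, MODEL /
ENDMDL blocks delimiting frames) — desk-scale and dependency-light; binary
trajectory formats are out of scope.  PDB parsing and writing go through
biotite, so fixed-width v3 columns, 3-decimal coordinates and element columns
follow the library's conventions; occupancy/B-factor are ignored on read and
written as 1.00/0.00.

ATP phosphate-oxygen naming defaults to PDB chemical-component conventions
(O1A/O2A/O3A = α set, O1B/O2B/O3B = β, O1G/O2G/O3G = γ); remap via config
when your ensembles use other names.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import AtomRecord, Ensemble, Frame, TopologyError

__all__ = [
    "EnsembleFileSet",
    "TIWindowTable",
    "read_ensemble",
    "write_ensemble",
    "read_ti_table",
    "HETERO_RESIDUES",
]

# Residue names written as HETATM records.
HETERO_RESIDUES = frozenset({"ATP", "ADP", "MG", "HOH", "WAT"})


@dataclass(frozen=True)
class EnsembleFileSet:
    """Ordered multi-model PDB paths, one per replicate run."""

    paths: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.paths:
            raise ValueError("EnsembleFileSet needs >= 1 path")
        object.__setattr__(self, "paths", tuple(self.paths))


def _stack_to_frames(stack: struc.AtomArrayStack, path: str) -> list[Frame]:
    frames = []
    n_models = stack.stack_depth()
    for m in range(n_models):
        arr = stack[m]
        atoms = []
        for i in range(arr.array_length()):
            res_id = int(arr.res_id[i])
            if res_id < 1:
                raise ValueError(
                    f"{path}, model {m + 1}: residue id {res_id} < 1 "
                    f"(1-based PS3 numbering expected)"
                )
            atoms.append(AtomRecord(
                atom_name=str(arr.atom_name[i]),
                residue_name=str(arr.res_name[i]),
                residue_id=res_id,
                chain_id=str(arr.chain_id[i]) or "A",
                element=str(arr.element[i]),
                position=tuple(float(x) for x in arr.coord[i]),
            ))
        frames.append(Frame(atoms, frame_index=m))
    return frames


def read_ensemble(files: EnsembleFileSet | Sequence[str],
                  equilibration_fraction: float = 0.0,
                  label: str | None = None) -> Ensemble:
    """Read one multi-model PDB per replicate run into an :class:`Ensemble`.

    Frames are ordered by MODEL number; atom order is preserved.  Topology
    constancy is enforced across models within a file and across files;
    violations raise :class:`TopologyError` naming the offending file.
    """
    if not isinstance(files, EnsembleFileSet):
        files = EnsembleFileSet(paths=tuple(files), label=label or "")
    runs = []
    for path in files.paths:
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        pdb = PDBFile.read(path)
        try:
            stack = pdb.get_structure()
        except Exception as exc:  # biotite raises on ragged models
            raise TopologyError(
                f"{path}: inconsistent models ({exc})"
            ) from exc
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        runs.append(_stack_to_frames(stack, path))
    ens_label = label if label is not None else files.label
    try:
        return Ensemble(runs, equilibration_fraction, ens_label)
    except TopologyError as exc:
        raise TopologyError(f"across files {list(files.paths)}: {exc}") from exc


def _frames_to_stack(frames: Sequence[Frame]) -> struc.AtomArrayStack:
    n_atoms = len(frames[0])
    template = struc.AtomArray(n_atoms)
    for i, a in enumerate(frames[0].atoms):
        template.chain_id[i] = a.chain_id
        template.res_id[i] = a.residue_id
        template.res_name[i] = a.residue_name
        template.atom_name[i] = a.atom_name
        template.element[i] = a.element
        template.hetero[i] = a.residue_name in HETERO_RESIDUES
    stack = struc.AtomArrayStack(len(frames), n_atoms)
    for cat in ("chain_id", "res_id", "res_name", "atom_name", "element", "hetero"):
        stack.set_annotation(cat, template.get_annotation(cat))
    for m, frame in enumerate(frames):
        stack.coord[m] = frame.coords
    return stack


def write_ensemble(ensemble: Ensemble, path_prefix: str) -> list[str]:
    """Write one multi-model PDB per run; returns the written paths.

    Files are named ``{prefix}_run1.pdb``, ``{prefix}_run2.pdb``, …
    """
    out_dir = os.path.dirname(path_prefix)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, run in enumerate(ensemble.runs, start=1):
        stack = _frames_to_stack(run)
        pdb = PDBFile()
        pdb.set_structure(stack)
        # single-frame runs must still carry MODEL/ENDMDL delimiters
        if not any(line.startswith("MODEL") for line in pdb.lines):
            pdb.lines = ["MODEL        1", *pdb.lines, "ENDMDL"]
        path = f"{path_prefix}_run{i}.pdb"
        pdb.write(path)
        paths.append(path)
    return paths


@dataclass(frozen=True)
class TIWindowTable:
    """λ-grid of window-averaged ∂H/∂λ values (kcal/mol) for one direction.

    Any per-window equilibration discard (e.g. the first 100 ps of a 500 ps
    window) is applied upstream by whoever produced the averages; only the
    declared fraction is recorded here as metadata.
    """

    lambdas: tuple[float, ...]
    dhdl: tuple[float, ...]
    direction: str  # "forward" | "backward"
    discard_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"direction must be forward|backward, got {self.direction!r}")
        if len(self.lambdas) != len(self.dhdl):
            raise ValueError("lambda and dH/dlambda columns differ in length")
        if len(self.lambdas) < 2:
            raise ValueError("TI table needs >= 2 windows")
        lams = np.asarray(self.lambdas, dtype=float)
        if np.any(lams < 0) or np.any(lams > 1):
            raise ValueError("lambda values must lie in [0, 1]")
        if np.any(np.diff(lams) <= 0):
            raise ValueError("lambda values must be strictly increasing (duplicates?)")
        if not (0.0 <= self.discard_fraction < 1.0):
            raise ValueError("discard_fraction must be in [0, 1)")

    @property
    def n_windows(self) -> int:
        return len(self.lambdas)


def read_ti_table(path: str, direction: str,
                  discard_fraction: float = 0.0) -> TIWindowTable:
    """Read a two-column (λ, ⟨∂H/∂λ⟩) text table.

    Whitespace- or comma-delimited; lines starting with ``#`` are comments;
    blank lines and trailing whitespace are ignored.  Rows are sorted by λ;
    duplicate λ values are an error.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two numeric columns")
            try:
                lam, val = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable number") from exc
            rows.append((lam, val))
    if len(rows) < 2:
        raise ValueError(f"{path}: TI table needs >= 2 rows, got {len(rows)}")
    rows.sort(key=lambda r: r[0])
    lams = [r[0] for r in rows]
    if len(set(lams)) != len(lams):
        dups = sorted({l for l in lams if lams.count(l) > 1})
        raise ValueError(f"{path}: duplicate lambda values {dups}")
    return TIWindowTable(
        lambdas=tuple(lams),
        dhdl=tuple(r[1] for r in rows),
        direction=direction,
        discard_fraction=discard_fraction,
    )


def write_ti_table(table: TIWindowTable, path: str) -> None:
    """Write a TI table in the same two-column text format read back in."""
    with open(path, "w") as fh:
        fh.write(f"# lambda  dH/dlambda (kcal/mol)  direction={table.direction}\n")
        for lam, val in zip(table.lambdas, table.dhdl):
            fh.write(f"{lam:.10g} {val:.10g}\n")
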