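"""Repulsive electrostatic contacts and Mg²⁺ coordination-state classification.

Repulsive contacts are co-locations (minimum inter-atom distance ≤ 4.5 Å by
default) of positively charged binding-site moieties: the guanidinium
nitrogens (NE/NH1/NH2) of arginines 92, 99, 103, 115, 122 and 126 present in
the variant, and the Mg²⁺ ion.  Counting is pair-level — each unordered group
pair contributes at most one contact per frame regardless of how many atom
pairs lie inside the cutoff — consistent with the ~1–2 contacts typical of
the ε-subunit binding site.  In mutant topologies the substituted arginine
resolves to no atoms and simply drops out of the pair set.

Mg²⁺–ATP coordination is classified per frame: first-sphere Oα/Oβ or Oβ/Oγ
when at least one oxygen of each phosphate group lies within the first-sphere
cutoff (default 2.6 Å, standard Mg–O coordination geometry); FIRST_SPHERE_OTHER
for any other direct phosphate contact pattern; SECOND_SPHERE when no
phosphate oxygen is direct but a water oxygen bridges (within the first-sphere
cutoff of Mg and within the bridge cutoff, default 3.5 Å, of a phosphate
oxygen); otherwise UNBOUND.
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Ensemble, Frame, SelectionSpec, SummaryStat, resolve_selection, run_statistics

__all__ = [
    "RepulsiveContactSpec",
    "CoordinationState",
    "PhosphateNaming",
    "DEFAULT_PHOSPHATE_NAMING",
    "default_repulsive_groups",
    "count_repulsive_contacts",
    "ensemble_contact_stats",
    "classify_mg_coordination",
    "coordination_occupancy",
]

BASIC_RESIDUE_IDS = (92, 99, 103, 115, 122, 126)
ARG_N_ATOMS = frozenset({"NE", "NH1", "NH2"})


def default_repulsive_groups() -> list[SelectionSpec]:
    """Guanidinium-N groups of the six binding-site arginines plus Mg²⁺."""
    groups = [
        SelectionSpec(name=f"R{rid}", residue_ids=frozenset({rid}),
                      atom_names=ARG_N_ATOMS, residue_names=frozenset({"ARG"}))
        for rid in BASIC_RESIDUE_IDS
    ]
    groups.append(SelectionSpec(name="MG", residue_names=frozenset({"MG"}),
                                atom_names=frozenset({"MG"})))
    return groups


@dataclass(frozen=True)
class RepulsiveContactSpec:
    cutoff: float = 4.5
    groups: tuple[SelectionSpec, ...] = field(default_factory=lambda: tuple(default_repulsive_groups()))

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if len(self.groups) < 2:
            raise ValueError("need >= 2 groups")
        object.__setattr__(self, "groups", tuple(self.groups))


class CoordinationState(enum.Enum):
    FIRST_SPHERE_OA_OB = "Oα/Oβ"
    FIRST_SPHERE_OB_OG = "Oβ/Oγ"
    FIRST_SPHERE_OTHER = "other first sphere"
    SECOND_SPHERE = "second sphere"
    UNBOUND = "unbound"


@dataclass(frozen=True)
class PhosphateNaming:
    """ATP phosphate-oxygen atom names per Greek group (remappable)."""

    alpha: frozenset[str] = frozenset({"O1A", "O2A", "O3A"})
    beta: frozenset[str] = frozenset({"O1B", "O2B", "O3B"})
    gamma: frozenset[str] = frozenset({"O1G", "O2G", "O3G"})


DEFAULT_PHOSPHATE_NAMING = PhosphateNaming()


def count_repulsive_contacts(frame: Frame, spec: RepulsiveContactSpec = RepulsiveContactSpec(),
                             ) -> tuple[int, list[tuple[str, str]]]:
    """Pair-level repulsive-contact count for one frame.

    Returns ``(count, pairs)`` where ``pairs`` names the contacting group
    pairs.  A pair contacts when the minimum distance between any atom of one
    group and any atom of the other is ≤ the cutoff.  Groups resolving to no
    atoms (mutated residues) are skipped; with fewer than two non-empty
    groups the count is 0 with a warning.
    """
    resolved = [(g.name, resolve_selection(g, frame)) for g in spec.groups]
    resolved = [(name, idx) for name, idx in resolved if idx]
    if len(resolved) < 2:
        warnings.warn("fewer than 2 non-empty repulsive groups; count is 0",
                      stacklevel=2)
        return 0, []
    coords = frame.coords
    pairs = []
    for i in range(len(resolved)):
        name_i, idx_i = resolved[i]
        xyz_i = coords[idx_i]
        for j in range(i + 1, len(resolved)):
            name_j, idx_j = resolved[j]
            d = np.linalg.norm(xyz_i[:, None, :] - coords[idx_j][None, :, :], axis=-1)
            if float(d.min()) <= spec.cutoff:
                pairs.append((name_i, name_j))
    return len(pairs), pairs


def ensemble_contact_stats(ensemble: Ensemble,
                           spec: RepulsiveContactSpec = RepulsiveContactSpec(),
                           ) -> SummaryStat:
    """Replicate-level statistics of the per-frame repulsive-contact count."""
    per_run = []
    for run in ensemble.analysis_runs():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_run.append([float(count_repulsive_contacts(f, spec)[0]) for f in run])
    return run_statistics(per_run)


def _mg_index(frame: Frame) -> int:
    idx = [i for i, a in enumerate(frame.atoms)
           if a.residue_name == "MG" or a.atom_name == "MG"]
    if len(idx) != 1:
        raise ValueError(f"expected exactly one Mg2+ ion, found {len(idx)}")
    return idx[0]


def classify_mg_coordination(frame: Frame,
                             first_sphere_cutoff: float = 2.6,
                             water_bridge_cutoff: float = 3.5,
                             naming: PhosphateNaming = DEFAULT_PHOSPHATE_NAMING,
                             ) -> CoordinationState:
    """Coordination state of the single Mg²⁺ ion relative to ATP in one frame."""
    mg = _mg_index(frame)
    coords = frame.coords
    mg_xyz = coords[mg]

    phosphate: dict[str, list[int]] = {"alpha": [], "beta": [], "gamma": []}
    water_o: list[int] = []
    for i, a in enumerate(frame.atoms):
        if a.residue_name == "ATP":
            if a.atom_name in naming.alpha:
                phosphate["alpha"].append(i)
            elif a.atom_name in naming.beta:
                phosphate["beta"].append(i)
            elif a.atom_name in naming.gamma:
                phosphate["gamma"].append(i)
        elif a.residue_name in ("HOH", "WAT") and a.element == "O":
            water_o.append(i)

    direct = {
        grp: any(np.linalg.norm(coords[i] - mg_xyz) <= first_sphere_cutoff for i in idx)
        for grp, idx in phosphate.items()
    }
    if direct["alpha"] and direct["beta"] and not direct["gamma"]:
        return CoordinationState.FIRST_SPHERE_OA_OB
    if direct["beta"] and direct["gamma"] and not direct["alpha"]:
        return CoordinationState.FIRST_SPHERE_OB_OG
    if any(direct.values()):
        return CoordinationState.FIRST_SPHERE_OTHER

    all_phos = [i for idx in phosphate.values() for i in idx]
    for w in water_o:
        if np.linalg.norm(coords[w] - mg_xyz) <= first_sphere_cutoff:
            if any(np.linalg.norm(coords[w] - coords[p]) <= water_bridge_cutoff
                   for p in all_phos):
                return CoordinationState.SECOND_SPHERE
    return CoordinationState.UNBOUND


def coordination_occupancy(ensemble: Ensemble,
                           first_sphere_cutoff: float = 2.6,
                           water_bridge_cutoff: float = 3.5,
                           naming: PhosphateNaming = DEFAULT_PHOSPHATE_NAMING,
                           ) -> dict[CoordinationState, float]:
    """Fraction of post-equilibration frames in each coordination state.

    The returned fractions form a probability distribution (they sum to 1).
    """
    counts: Counter[CoordinationState] = Counter()
    total = 0
    for frame in ensemble.iter_analysis_frames():
        counts[classify_mg_coordination(frame, first_sphere_cutoff,
                                        water_bridge_cutoff, naming)] += 1
        total += 1
    return {state: counts[state] / total for state in counts}
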