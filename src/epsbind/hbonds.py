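"""Hydrogen-bond detection and distance-based energy estimation.

A hydrogen bond is recorded when the hydrogen-to-acceptor distance is at most
``d_max`` (default 2.7 Å, inclusive) and the deviation from donor–H–acceptor
linearity is at most ``angle_max`` (default 30°, inclusive).  The angle is
measured at the hydrogen between the donor→H and H→acceptor directions, so a
perfectly linear bond scores 0°; the alternative convention used by some
trajectory tools (angle at the donor between D→H and D→acceptor) is available
via ``angle_convention="donor"``.

Per-bond energies follow the empirical exponential relation of Espinosa and
co-workers, E(d) = −A·exp(−B·d) with defaults A = 25300 kJ/mol and
B = 3.6 Å⁻¹; by default the H···acceptor distance is used for the energy as
well as the detection (``energy_distance="H-A"``), with the donor–acceptor
distance available as ``"D-A"`` for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import Ensemble, Frame, SelectionSpec, SummaryStat, resolve_selection, run_statistics

__all__ = [
    "HBondCriteria",
    "HBondEvent",
    "DonorAcceptorRegistry",
    "DEFAULT_REGISTRY",
    "ESPINOSA_A_KJ_MOL",
    "ESPINOSA_B_PER_A",
    "detect_hbonds",
    "espinosa_energy",
    "network_energy",
    "ensemble_hbond_stats",
]

ESPINOSA_A_KJ_MOL = 25300.0
ESPINOSA_B_PER_A = 3.6


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (both cutoffs inclusive)."""

    d_max: float = 2.7
    angle_max: float = 30.0
    angle_convention: str = "deviation"  # "deviation" | "donor"
    energy_distance: str = "H-A"  # "H-A" | "D-A"

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be > 0")
        if not (0 < self.angle_max <= 180):
            raise ValueError("angle_max must be in (0, 180]")
        if self.angle_convention not in ("deviation", "donor"):
            raise ValueError("angle_convention must be 'deviation' or 'donor'")
        if self.energy_distance not in ("H-A", "D-A"):
            raise ValueError("energy_distance must be 'H-A' or 'D-A'")


@dataclass(frozen=True)
class HBondEvent:
    """One detected hydrogen bond in one frame."""

    frame_index: int
    donor: int
    hydrogen: int
    acceptor: int
    d_ha: float
    angle_dha: float
    energy: float  # kJ/mol, <= 0


@dataclass(frozen=True)
class DonorAcceptorRegistry:
    """Donor (heavy atom, attached hydrogen) pairs and acceptor atoms per residue name.

    ``donors`` maps residue name → tuple of (heavy atom name, hydrogen name)
    pairs; ``acceptors`` maps residue name → tuple of acceptor atom names.
    The hydrogen is tied to its parent donor purely by naming convention, as
    declared here — no bond perception is performed.
    """

    donors: Mapping[str, tuple[tuple[str, str], ...]]
    acceptors: Mapping[str, tuple[str, ...]]

    def donor_pairs(self, frame: Frame) -> list[tuple[int, int]]:
        """(donor index, hydrogen index) pairs resolved in ``frame``.

        Raises if a registered hydrogen name exists in a residue whose parent
        donor atom is missing.
        """
        by_residue: dict[tuple[str, int, str], dict[str, int]] = {}
        for i, a in enumerate(frame.atoms):
            by_residue.setdefault((a.residue_name, a.residue_id, a.chain_id), {})[a.atom_name] = i
        pairs = []
        for (res_name, _res_id, _chain), atom_map in by_residue.items():
            for heavy, hydrogen in self.donors.get(res_name, ()):
                if hydrogen in atom_map:
                    if heavy not in atom_map:
                        raise ValueError(
                            f"hydrogen {res_name}:{hydrogen} present without its "
                            f"registered parent donor {heavy}"
                        )
                    pairs.append((atom_map[heavy], atom_map[hydrogen]))
        pairs.sort(key=lambda p: p[1])
        return pairs

    def acceptor_indices(self, frame: Frame) -> list[int]:
        return [i for i, a in enumerate(frame.atoms)
                if a.atom_name in self.acceptors.get(a.residue_name, ())]


_ARG_DONORS = (("NE", "HE"), ("NH1", "HH11"), ("NH1", "HH12"),
               ("NH2", "HH21"), ("NH2", "HH22"))
_ATP_ACCEPTORS = ("O1A", "O2A", "O3A", "O1B", "O2B", "O3B", "O1G", "O2G", "O3G",
                  "O2'", "O3'", "O4'", "O5'", "N1", "N7")

#: Residue chemistry sufficient for binding-site analysis of the ε subunit:
#: arginine guanidinium donors, glutamate carboxylate acceptors, ATP phosphate
#: and ribose acceptors (with its 2'/3' hydroxyl donors), water, and the
#: generic donor/acceptor residues produced by the synthetic generator.
DEFAULT_REGISTRY = DonorAcceptorRegistry(
    donors={
        "ARG": _ARG_DONORS,
        "ATP": (("O2'", "HO2'"), ("O3'", "HO3'")),
        "HOH": (("O", "H1"), ("O", "H2")),
        "DNR": (("ND", "HD"),),
    },
    acceptors={
        "GLU": ("OE1", "OE2"),
        "ASP": ("OD1", "OD2"),
        "ATP": _ATP_ACCEPTORS,
        "HOH": ("O",),
        "ACC": ("OA",),
    },
)


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosang = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def espinosa_energy(d_ha: float, a_kj_mol: float = ESPINOSA_A_KJ_MOL,
                    b_per_angstrom: float = ESPINOSA_B_PER_A) -> float:
    """Hydrogen-bond energy in kJ/mol from the H···acceptor distance in Å.

    E(d) = −A·exp(−B·d): always negative, strictly increasing toward zero
    with distance.
    """
    if d_ha <= 0:
        raise ValueError(f"distance must be > 0, got {d_ha}")
    return -a_kj_mol * math.exp(-b_per_angstrom * d_ha)


def detect_hbonds(frame: Frame, registry: DonorAcceptorRegistry = DEFAULT_REGISTRY,
                  criteria: HBondCriteria = HBondCriteria(),
                  subset_donor: SelectionSpec | None = None,
                  subset_acceptor: SelectionSpec | None = None) -> list[HBondEvent]:
    """All hydrogen bonds in one frame satisfying the geometric criteria.

    ``subset_donor`` restricts which atoms may act as donors (matched against
    the donor heavy atom) and ``subset_acceptor`` which may accept; ``None``
    means no restriction.  Each (hydrogen, acceptor) pair is reported at most
    once.  Neighbour search uses a k-d tree; the criteria themselves are
    evaluated exactly.
    """
    pairs = registry.donor_pairs(frame)
    acceptors = registry.acceptor_indices(frame)
    if subset_donor is not None:
        allowed = set(resolve_selection(subset_donor, frame))
        pairs = [(d, h) for d, h in pairs if d in allowed]
    if subset_acceptor is not None:
        allowed = set(resolve_selection(subset_acceptor, frame))
        acceptors = [a for a in acceptors if a in allowed]
    if not pairs or not acceptors:
        return []

    coords = frame.coords
    h_idx = np.array([h for _, h in pairs])
    acc_idx = np.array(acceptors)
    tree = cKDTree(coords[acc_idx])
    neighbours = tree.query_ball_point(coords[h_idx], r=criteria.d_max)

    events = []
    for (d_i, h_i), local in zip(pairs, neighbours):
        for j in local:
            a_i = int(acc_idx[j])
            if a_i == d_i or a_i == h_i:
                continue
            d_ha = float(np.linalg.norm(coords[a_i] - coords[h_i]))
            if d_ha > criteria.d_max:
                continue
            if criteria.angle_convention == "deviation":
                # 0° when D, H, A are collinear with A beyond H
                ang = _angle_deg(coords[h_i] - coords[d_i], coords[a_i] - coords[h_i])
                ok = ang <= criteria.angle_max
            else:
                # angle at the donor between D->H and D->A
                ang = _angle_deg(coords[h_i] - coords[d_i], coords[a_i] - coords[d_i])
                ok = ang <= criteria.angle_max
            if not ok:
                continue
            if criteria.energy_distance == "H-A":
                e_dist = d_ha
            else:
                e_dist = float(np.linalg.norm(coords[a_i] - coords[d_i]))
            events.append(HBondEvent(
                frame_index=frame.frame_index, donor=d_i, hydrogen=h_i,
                acceptor=a_i, d_ha=d_ha, angle_dha=ang,
                energy=espinosa_energy(e_dist),
            ))
    events.sort(key=lambda e: (e.hydrogen, e.acceptor))
    return events


def network_energy(events: Sequence[HBondEvent]) -> float:
    """Total network energy: the sum of per-event energies (0 for none)."""
    return float(sum(e.energy for e in events))


def ensemble_hbond_stats(ensemble: Ensemble,
                         registry: DonorAcceptorRegistry = DEFAULT_REGISTRY,
                         criteria: HBondCriteria = HBondCriteria(),
                         group_a: SelectionSpec | None = None,
                         group_b: SelectionSpec | None = None,
                         ) -> tuple[SummaryStat, SummaryStat]:
    """Per-frame bond count and network energy between two groups, reduced
    over replicate runs.

    Bonds are counted in both directions (donors in ``group_a`` to acceptors
    in ``group_b`` and vice versa) and merged, deduplicating any (hydrogen,
    acceptor) pair that appears in both passes.  Equilibration frames were
    already removed by the ensemble, so no further discard is applied here.
    Returns ``(count_stat, energy_stat)`` with energies in kJ/mol.
    """
    counts_per_run: list[list[float]] = []
    energies_per_run: list[list[float]] = []
    for run in ensemble.analysis_runs():
        counts: list[float] = []
        energies: list[float] = []
        for frame in run:
            ev_ab = detect_hbonds(frame, registry, criteria, group_a, group_b)
            if group_a is None and group_b is None:
                merged = ev_ab
            else:
                ev_ba = detect_hbonds(frame, registry, criteria, group_b, group_a)
                seen = {(e.hydrogen, e.acceptor) for e in ev_ab}
                merged = list(ev_ab) + [e for e in ev_ba
                                        if (e.hydrogen, e.acceptor) not in seen]
            counts.append(float(len(merged)))
            energies.append(network_energy(merged))
        counts_per_run.append(counts)
        energies_per_run.append(energies)
    return run_statistics(counts_per_run), run_statistics(energies_per_run)
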