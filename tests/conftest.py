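"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from epsbind.core import AtomRecord, Frame


def atom(name, res_name, res_id, xyz, element=None, chain="A"):
    if element is None:
        element = name[0]
    return AtomRecord(name, res_name, res_id, chain, element,
                      tuple(float(x) for x in xyz))


def donor_acceptor_frame(acceptor_xyz, h_xyz=(1.0, 0.0, 0.0)):
    """Minimal frame: one DNR donor (ND at origin, HD) and one ACC acceptor."""
    return Frame([
        atom("ND", "DNR", 601, (0, 0, 0), "N"),
        atom("HD", "DNR", 601, h_xyz, "H"),
        atom("OA", "ACC", 701, acceptor_xyz, "O"),
    ])


def random_frame(rng: np.random.Generator, n_donors: int = 10,
                 n_acceptors: int = 30, box: float = 8.0) -> Frame:
    """~50-atom random frame of DNR donors and ACC acceptors in a box."""
    atoms = []
    for j in range(n_donors):
        nd = rng.uniform(0, box, 3)
        hd = nd + rng.normal(0, 1, 3)
        hd = nd + (hd - nd) / np.linalg.norm(hd - nd)  # 1 Å bond
        atoms.append(atom("ND", "DNR", 601 + j, nd, "N"))
        atoms.append(atom("HD", "DNR", 601 + j, hd, "H"))
    for j in range(n_acceptors):
        atoms.append(atom("OA", "ACC", 701 + j, rng.uniform(0, box, 3), "O"))
    return Frame(atoms)


def oracle_detect(frame: Frame, d_max: float = 2.7, angle_max: float = 30.0):
    """All-pairs brute-force hydrogen-bond detection, independent of the
    package implementation: pure-python loops, no neighbour search."""
    donors = {}  # hydrogen index -> donor index, by naming convention
    acceptors = []
    for i, a in enumerate(frame.atoms):
        if a.residue_name == "DNR" and a.atom_name == "HD":
            for j, b in enumerate(frame.atoms):
                if (b.residue_name == "DNR" and b.atom_name == "ND"
                        and b.residue_id == a.residue_id):
                    donors[i] = j
        elif a.residue_name == "ACC" and a.atom_name == "OA":
            acceptors.append(i)
    found = set()
    for h, d in donors.items():
        for acc in acceptors:
            hx = frame.atoms[h].position
            dx = frame.atoms[d].position
            ax = frame.atoms[acc].position
            d_ha = math.dist(hx, ax)
            if d_ha > d_max:
                continue
            v1 = tuple(hx[k] - dx[k] for k in range(3))
            v2 = tuple(ax[k] - hx[k] for k in range(3))
            n1 = math.sqrt(sum(x * x for x in v1))
            n2 = math.sqrt(sum(x * x for x in v2))
            if n1 == 0 or n2 == 0:
                continue
            cosang = sum(a * b for a, b in zip(v1, v2)) / (n1 * n2)
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if ang <= angle_max:
                found.add((h, acc))
    return found


def oracle_contacts(frame: Frame, groups, cutoff: float = 4.5):
    """Brute-force pair-level contact count over resolved index groups."""
    count = 0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if not groups[i] or not groups[j]:
                continue
            dmin = min(
                math.dist(frame.atoms[a].position, frame.atoms[b].position)
                for a in groups[i] for b in groups[j])
            if dmin <= cutoff:
                count += 1
    return count


def rigid_transform(frame: Frame, rng: np.random.Generator) -> Frame:
    """Random proper rotation + translation applied to every atom."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-50, 50, 3)
    return frame.with_coords(frame.coords @ rot.T + shift)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
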