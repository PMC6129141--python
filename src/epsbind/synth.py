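"""Synthetic inputs with known ground truth.

Every analysis stage in this package is validated against data whose answer
is known by construction: structural ensembles with hydrogen bonds, repulsive
contacts and Mg²⁺ coordination states *planted* at chosen per-frame
occupancies, TI tables sampled from a known integrand plus Gaussian window
noise, and toy ε-subunit alignments with planted substitutions.

Geometry is placed, not simulated.  Planted events satisfy the detection
criteria with a safety margin (default 0.1 Å / 5°) and non-events violate
them by at least the same margin, so tests never sit on a knife-edge float
comparison.  Decoy atoms are kept ≥ 8 Å from every planted interaction
partner; independent random streams are used per feature (bonds, contacts,
noise) so adding one feature never shifts another's draws.  All generators
are pure functions of their spec including the mandatory seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contacts import CoordinationState
from .core import AtomRecord, Ensemble, Frame
from .io import TIWindowTable

__all__ = [
    "PlantedHBond",
    "PlantedContact",
    "EnsembleSpec",
    "GroundTruth",
    "TISpec",
    "gen_ensemble",
    "gen_ti_tables",
    "gen_alignment",
    "fig6_like_alignment",
    "write_fasta",
]

_H_BOND_LENGTH = 1.0  # donor-hydrogen covalent distance, Å
_CLUSTER_SPACING = 20.0  # Å between planted interaction clusters
_DECOY_CLEARANCE = 8.0


@dataclass(frozen=True)
class PlantedHBond:
    """One candidate donor→acceptor bond present with probability ``occupancy``.

    In present frames the H···acceptor distance is drawn from a truncated
    normal and the deviation angle from a half-normal, both clipped to stay
    inside the cutoffs by ``margin``; in absent frames the acceptor is placed
    beyond the distance cutoff by at least ``margin``.
    """

    occupancy: float = 1.0
    d_mu: float = 1.9
    d_sigma: float = 0.1
    angle_sigma: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must be in [0, 1]")
        if self.d_mu <= 0 or self.d_sigma < 0 or self.angle_sigma < 0:
            raise ValueError("distance/angle parameters must be positive")


@dataclass(frozen=True)
class PlantedContact:
    """A group pair inside the contact cutoff with probability ``occupancy``.

    Realized as two single-atom arginine guanidinium groups (NH1) at the
    given residue ids; ``group_b`` may instead be the Mg²⁺ ion.
    """

    residue_a: int
    residue_b: int | str  # residue id, or "MG"
    occupancy: float = 1.0
    d_in: float = 4.0
    d_out: float = 6.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must be in [0, 1]")
        if not (0 < self.d_in < self.d_out):
            raise ValueError("need 0 < d_in < d_out")


@dataclass(frozen=True)
class EnsembleSpec:
    """Specification of a synthetic ensemble; the seed is mandatory."""

    seed: int
    n_runs: int = 3
    frames_per_run: int = 100
    hbonds: tuple[PlantedHBond, ...] = ()
    contacts: tuple[PlantedContact, ...] = ()
    mg_states: tuple[CoordinationState, ...] = ()  # cycled over frames
    n_decoys: int = 0
    d_max: float = 2.7
    angle_max: float = 30.0
    margin_d: float = 0.1
    margin_angle: float = 5.0
    equilibration_fraction: float = 0.0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_runs < 1 or self.frames_per_run < 1:
            raise ValueError("need >= 1 run and >= 1 frame per run")
        if self.margin_d <= 0 or self.margin_angle <= 0:
            raise ValueError("margins must be > 0 (zero-margin geometry is infeasible)")
        for hb in self.hbonds:
            if hb.d_mu >= self.d_max - self.margin_d and hb.d_sigma == 0:
                raise ValueError(
                    f"planted bond at d_mu={hb.d_mu} cannot satisfy "
                    f"d_max={self.d_max} with margin {self.margin_d}"
                )
        object.__setattr__(self, "hbonds", tuple(self.hbonds))
        object.__setattr__(self, "contacts", tuple(self.contacts))
        object.__setattr__(self, "mg_states", tuple(self.mg_states))


@dataclass(frozen=True)
class GroundTruth:
    """Per-run, per-frame planted truth sufficient to predict every stage."""

    hbond_present: tuple[tuple[tuple[bool, ...], ...], ...]  # [run][frame][bond]
    contact_present: tuple[tuple[tuple[bool, ...], ...], ...]
    mg_state: tuple[tuple[CoordinationState | None, ...], ...]


def _hbond_topology(spec: EnsembleSpec) -> list[AtomRecord]:
    atoms = []
    for j in range(len(spec.hbonds)):
        y = _CLUSTER_SPACING * j
        atoms.append(AtomRecord("ND", "DNR", 601 + j, "D", "N", (0.0, y, 0.0)))
        atoms.append(AtomRecord("HD", "DNR", 601 + j, "D", "H",
                                (_H_BOND_LENGTH, y, 0.0)))
        atoms.append(AtomRecord("OA", "ACC", 701 + j, "E", "O", (5.0, y, 0.0)))
    return atoms


def _contact_topology(spec: EnsembleSpec) -> list[AtomRecord]:
    atoms = []
    seen: set[int | str] = set()
    for j, c in enumerate(spec.contacts):
        y = -_CLUSTER_SPACING * (j + 1)
        if c.residue_a in seen or c.residue_b in seen:
            raise ValueError("each residue/ion may appear in only one planted contact")
        seen.update({c.residue_a, c.residue_b})
        atoms.append(AtomRecord("NH1", "ARG", c.residue_a, "A", "N", (0.0, y, 0.0)))
        if c.residue_b == "MG":
            atoms.append(AtomRecord("MG", "MG", 600, "M", "MG", (c.d_in, y, 0.0)))
        else:
            atoms.append(AtomRecord("NH1", "ARG", int(c.residue_b), "A", "N",
                                    (c.d_in, y, 0.0)))
    return atoms


# Mg/ATP/water cluster geometry (relative to the cluster base).  Phosphate
# oxygens sit 3 Å apart on the x-axis; first-sphere Mg positions sit on the
# perpendicular bisector of the coordinating pair at 2.1 Å from each.
_MG_CLUSTER_BASE = np.array([0.0, 0.0, 50.0])
_O1A = np.array([0.0, 0.0, 0.0])
_O1B = np.array([3.0, 0.0, 0.0])
_O1G = np.array([6.0, 0.0, 0.0])
_BISECTOR_H = math.sqrt(2.1**2 - 1.5**2)
_WATER_PARK = np.array([3.0, 10.0, 0.0])

_MG_POSITIONS = {
    CoordinationState.FIRST_SPHERE_OA_OB: np.array([1.5, _BISECTOR_H, 0.0]),
    CoordinationState.FIRST_SPHERE_OB_OG: np.array([4.5, _BISECTOR_H, 0.0]),
    CoordinationState.FIRST_SPHERE_OTHER: np.array([-2.1, 0.0, 0.0]),
    CoordinationState.SECOND_SPHERE: np.array([-4.0, 0.0, 0.0]),
    CoordinationState.UNBOUND: np.array([-20.0, 0.0, 0.0]),
}
_WATER_POSITIONS = {
    state: (np.array([-2.0, 0.0, 0.0]) if state is CoordinationState.SECOND_SPHERE
            else _WATER_PARK)
    for state in CoordinationState
}


def _mg_topology() -> list[AtomRecord]:
    base = _MG_CLUSTER_BASE
    mk = lambda name, res, rid, chain, el, rel: AtomRecord(
        name, res, rid, chain, el, tuple(float(x) for x in (base + rel)))
    return [
        mk("O1A", "ATP", 500, "L", "O", _O1A),
        mk("O1B", "ATP", 500, "L", "O", _O1B),
        mk("O1G", "ATP", 500, "L", "O", _O1G),
        mk("MG", "MG", 600, "M", "MG", _MG_POSITIONS[CoordinationState.UNBOUND]),
        mk("O", "HOH", 700, "W", "O", _WATER_PARK),
    ]


def gen_ensemble(spec: EnsembleSpec) -> tuple[Ensemble, GroundTruth]:
    """Generate an ensemble realizing the spec, plus its ground truth.

    Deterministic given the seed.  Per-frame randomness: each planted bond is
    present with its occupancy probability; present bonds draw a distance and
    deviation angle inside the cutoffs minus the margin; absent bonds place
    the acceptor past the distance cutoff plus the margin.  Contacts follow
    the same Bernoulli scheme at fixed in/out distances.  Mg²⁺ coordination
    states follow the requested schedule, cycled over frames.
    """
    if spec.contacts and any(c.residue_b == "MG" for c in spec.contacts) and spec.mg_states:
        raise ValueError("a planted Mg contact and an mg_states schedule would "
                         "both move the single Mg ion; request one or the other")

    topo_atoms = _hbond_topology(spec) + _contact_topology(spec)
    if spec.mg_states:
        topo_atoms += _mg_topology()
    for i in range(spec.n_decoys):
        topo_atoms.append(AtomRecord("C", "DCY", 801 + i, "X", "C",
                                     (100.0 + 10.0 * i, -100.0, 0.0)))
    if not topo_atoms:
        raise ValueError("spec plants nothing; ensemble would be empty")
    template = Frame(topo_atoms, 0)

    ss = np.random.SeedSequence(spec.seed)
    rng_bonds, rng_contacts, _rng_noise = (np.random.default_rng(s)
                                           for s in ss.spawn(3))

    n_hb = len(spec.hbonds)
    hb_base = 0  # atom offset of the h-bond block
    ct_base = 3 * n_hb
    mg_base = ct_base + 2 * len(spec.contacts)

    runs = []
    gt_hb, gt_ct, gt_mg = [], [], []
    d_cap = spec.d_max - spec.margin_d
    ang_cap = spec.angle_max - spec.margin_angle
    for _run in range(spec.n_runs):
        frames = []
        run_hb, run_ct, run_mg = [], [], []
        for f in range(spec.frames_per_run):
            coords = template.coords.copy()
            # hydrogen bonds
            present_flags = []
            for j, hb in enumerate(spec.hbonds):
                present = bool(rng_bonds.random() < hb.occupancy)
                present_flags.append(present)
                h_xyz = coords[hb_base + 3 * j + 1]
                if present:
                    d = -1.0
                    while not (0.5 <= d <= d_cap):
                        d = rng_bonds.normal(hb.d_mu, hb.d_sigma) if hb.d_sigma > 0 else hb.d_mu
                        d = min(d, d_cap) if hb.d_sigma == 0 else d
                    theta = abs(rng_bonds.normal(0.0, hb.angle_sigma))
                    theta = min(theta, ang_cap)
                    rad = math.radians(theta)
                    offset = np.array([d * math.cos(rad), d * math.sin(rad), 0.0])
                else:
                    d = spec.d_max + spec.margin_d + rng_bonds.random()
                    offset = np.array([d, 0.0, 0.0])
                coords[hb_base + 3 * j + 2] = h_xyz + offset
            run_hb.append(tuple(present_flags))
            # contacts
            contact_flags = []
            for j, c in enumerate(spec.contacts):
                present = bool(rng_contacts.random() < c.occupancy)
                contact_flags.append(present)
                a_xyz = coords[ct_base + 2 * j]
                dist = c.d_in if present else c.d_out
                coords[ct_base + 2 * j + 1] = a_xyz + np.array([dist, 0.0, 0.0])
            run_ct.append(tuple(contact_flags))
            # Mg coordination
            if spec.mg_states:
                state = spec.mg_states[f % len(spec.mg_states)]
                coords[mg_base + 3] = _MG_CLUSTER_BASE + _MG_POSITIONS[state]
                coords[mg_base + 4] = _MG_CLUSTER_BASE + _WATER_POSITIONS[state]
                run_mg.append(state)
            else:
                run_mg.append(None)
            frames.append(template.with_coords(coords, frame_index=f))
        runs.append(frames)
        gt_hb.append(tuple(run_hb))
        gt_ct.append(tuple(run_ct))
        gt_mg.append(tuple(run_mg))

    ensemble = Ensemble(runs, spec.equilibration_fraction, spec.label)
    truth = GroundTruth(hbond_present=tuple(gt_hb),
                        contact_present=tuple(gt_ct),
                        mg_state=tuple(gt_mg))
    return ensemble, truth


@dataclass(frozen=True)
class TISpec:
    """Synthetic TI tables from a known polynomial integrand g(λ).

    ``g_coeffs`` are ascending polynomial coefficients, so the true ΔG over
    [0, 1] is Σ cₖ/(k+1).  Window averages get i.i.d. normal noise with SD
    ``noise_sd``; forward and backward use independent streams.
    """

    g_coeffs: tuple[float, ...] = (0.0, 0.0, 3.0)  # g(λ) = 3λ²
    n_windows: int = 85
    noise_sd: float = 0.0
    seed_forward: int = 0
    seed_backward: int = 1

    def __post_init__(self) -> None:
        if self.n_windows < 2:
            raise ValueError("n_windows must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "g_coeffs", tuple(self.g_coeffs))

    @property
    def true_dG(self) -> float:
        return sum(c / (k + 1) for k, c in enumerate(self.g_coeffs))


def gen_ti_tables(spec: TISpec) -> tuple[TIWindowTable, TIWindowTable, float]:
    """(forward, backward) tables on an even λ grid, plus the analytic ΔG."""
    lam = np.linspace(0.0, 1.0, spec.n_windows)
    g = np.polynomial.polynomial.polyval(lam, spec.g_coeffs)
    tables = []
    for direction, seed in (("forward", spec.seed_forward),
                            ("backward", spec.seed_backward)):
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, spec.noise_sd, size=lam.size) if spec.noise_sd > 0 \
            else np.zeros(lam.size)
        tables.append(TIWindowTable(
            lambdas=tuple(float(x) for x in lam),
            dhdl=tuple(float(x) for x in (g + noise)),
            direction=direction,
        ))
    return tables[0], tables[1], spec.true_dG


# ---------------------------------------------------------------------------
# Alignment fixtures
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _default_template(length: int = 140) -> str:
    """Deterministic synthetic ε-subunit-like template with the PS3 binding
    residues (E83; R at 92, 99, 103, 115, 122, 126) in place."""
    seq = [_AA[i % len(_AA)] for i in range(length)]
    from .conservation import PS3_BINDING_RESIDUES
    for pos, res in PS3_BINDING_RESIDUES.items():
        seq[pos - 1] = res
    return "".join(seq)


def gen_alignment(template: str | None = None,
                  substitutions: Sequence[tuple[str, int, str]] = (),
                  mismatch_blocks: Sequence[tuple[str, int, int]] = (),
                  duplicates: Sequence[tuple[str, str, int]] = (),
                  gap_insertions: Sequence[tuple[int, int]] = (),
                  reference_id: str = "PS3"):
    """Deterministic aligned fixture around a PS3-like reference.

    * ``substitutions``: (row id, PS3 position, residue) — entries sharing an
      id accumulate on one row.
    * ``mismatch_blocks``: (row id, start position, n) — n consecutive benign
      mismatches from ``start`` (to control pairwise identity).
    * ``duplicates``: (new id, source id, n mismatches from position 51) —
      near-duplicates for redundancy-filter tests.
    * ``gap_insertions``: (after PS3 position, n columns) — all-gap columns
      shifting alignment numbering, e.g. (100, 4) and (110, 3) reproduce the
      103→column 107 and 115→column 122 mapping.

    Returns a :class:`~epsbind.conservation.Alignment`.
    """
    from .conservation import Alignment

    tpl = template if template is not None else _default_template()
    n = len(tpl)

    def mutate(seq: list[str], pos: int, res: str) -> None:
        if not (1 <= pos <= n):
            raise ValueError(f"position {pos} out of range 1..{n}")
        seq[pos - 1] = res

    def benign(seq: list[str], start: int, count: int) -> None:
        for p in range(start, start + count):
            orig = tpl[p - 1]
            mutate(seq, p, "A" if orig != "A" else "G")

    rows: dict[str, list[str]] = {reference_id: list(tpl)}
    order: list[str] = [reference_id]
    for rid, pos, res in substitutions:
        if rid not in rows:
            rows[rid] = list(tpl)
            order.append(rid)
        mutate(rows[rid], pos, res)
    for rid, start, count in mismatch_blocks:
        if rid not in rows:
            rows[rid] = list(tpl)
            order.append(rid)
        benign(rows[rid], start, count)
    for new_id, source_id, n_mm in duplicates:
        if source_id not in rows:
            raise ValueError(f"duplicate source {source_id!r} unknown")
        dup = list(rows[source_id])
        benign(dup, 51, n_mm)
        rows[new_id] = dup
        order.append(new_id)

    # insert all-gap columns (descending so earlier positions stay valid)
    for after_pos, n_cols in sorted(gap_insertions, reverse=True):
        if not (0 <= after_pos <= n):
            raise ValueError(f"gap insertion point {after_pos} out of range")
        for rid in rows:
            rows[rid][after_pos:after_pos] = ["-"] * n_cols

    return Alignment(
        ids=tuple(order),
        descriptions=tuple(order),
        sequences=tuple("".join(rows[rid]) for rid in order),
    )


def fig6_like_alignment():
    """Synthetic stand-in for the published ε-subunit alignment excerpt.

    Rows (all synthetic, patterned on the organisms discussed in the field):
    the PS3 reference; a *C. thermarum*-like row with L at 103; a
    *B. pumilus*-like row with H at 103; a *B. caldotenax*-like row with P at
    103 and the confounding S at 99; an *L. sphaericus*-like row with L at
    115; a 96%-identity near-duplicate of the reference (removed at the 0.95
    threshold) and a 94%-identity row (kept).  Gap columns are inserted so
    PS3 positions 103 and 115 fall in alignment columns 107 and 122.
    """
    return gen_alignment(
        substitutions=[
            ("CTHE_LIKE", 103, "L"),
            ("BPUM_LIKE", 103, "H"),
            ("BCAL_LIKE", 103, "P"), ("BCAL_LIKE", 99, "S"),
            ("LSPH_LIKE", 115, "L"),
        ],
        mismatch_blocks=[
            ("CTHE_LIKE", 1, 10),
            ("BPUM_LIKE", 11, 10),
            ("BCAL_LIKE", 21, 10),
            ("LSPH_LIKE", 31, 10),
            ("PAIR94", 41, 9),  # identity (140-9)/140 ≈ 0.936 < 0.95: kept
        ],
        duplicates=[("DUP96", "PS3", 5)],  # (140-5)/140 ≈ 0.964 >= 0.95: removed
        gap_insertions=[(100, 4), (110, 3)],  # 103 -> col 107, 115 -> col 122
    )


def write_fasta(alignment, path: str) -> None:
    """Write an alignment as aligned FASTA."""
    with open(path, "w") as fh:
        for rid, seq in zip(alignment.ids, alignment.sequences):
            fh.write(f">{rid}\n{seq}\n")
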