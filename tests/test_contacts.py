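import math

import numpy as np
import pytest

from epsbind.contacts import (
    CoordinationState, RepulsiveContactSpec, classify_mg_coordination,
    coordination_occupancy, count_repulsive_contacts, default_repulsive_groups,
    ensemble_contact_stats,
)
from epsbind.core import Ensemble, Frame, SelectionSpec, resolve_selection
from epsbind.synth import EnsembleSpec, PlantedContact, gen_ensemble
from conftest import atom, oracle_contacts, rigid_transform


def frame_with(atoms):
    return Frame(atoms)


class TestContactCounting:
    def test_mg_inside_cutoff(self):
        frame = frame_with([
            atom("NH1", "ARG", 122, (0, 0, 0), "N"),
            atom("MG", "MG", 600, (4.4, 0, 0), "MG"),
        ])
        count, pairs = count_repulsive_contacts(frame)
        assert count == 1 and pairs == [("R122", "MG")]

    def test_mg_outside_cutoff(self):
        frame = frame_with([
            atom("NH1", "ARG", 122, (0, 0, 0), "N"),
            atom("MG", "MG", 600, (4.6, 0, 0), "MG"),
        ])
        assert count_repulsive_contacts(frame)[0] == 0

    def test_pair_level_dedup(self):
        # two atom pairs of R92-R99 both inside the cutoff -> still one contact
        frame = frame_with([
            atom("NH1", "ARG", 92, (0, 0, 0), "N"),
            atom("NH2", "ARG", 92, (1, 0, 0), "N"),
            atom("NH1", "ARG", 99, (3, 0, 0), "N"),
            atom("NH2", "ARG", 99, (4, 0, 0), "N"),
        ])
        count, pairs = count_repulsive_contacts(frame)
        assert count == 1 and pairs == [("R92", "R99")]

    def test_fewer_than_two_groups_warns_and_counts_zero(self):
        frame = frame_with([atom("NH1", "ARG", 92, (0, 0, 0), "N")])
        with pytest.warns(UserWarning):
            count, _ = count_repulsive_contacts(frame)
        assert count == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_random_frames_equal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        atoms = []
        for rid in (92, 99, 103, 115, 122, 126):
            for name in ("NE", "NH1", "NH2"):
                atoms.append(atom(name, "ARG", rid, rng.uniform(0, 12, 3), "N"))
        atoms.append(atom("MG", "MG", 600, rng.uniform(0, 12, 3), "MG"))
        frame = frame_with(atoms)
        spec = RepulsiveContactSpec()
        groups = [resolve_selection(g, frame) for g in spec.groups]
        got, _ = count_repulsive_contacts(frame, spec)
        assert got == oracle_contacts(frame, groups, spec.cutoff)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(77)
        atoms = [atom("NH1", "ARG", rid, rng.uniform(0, 15, 3), "N")
                 for rid in (92, 99, 103, 115, 122, 126)]
        frame = frame_with(atoms)
        counts = [count_repulsive_contacts(
            frame, RepulsiveContactSpec(cutoff=c))[0] for c in (2.0, 4.5, 8.0, 20.0)]
        assert counts == sorted(counts)

    def test_mutant_missing_residue_contributes_nothing(self):
        # R103A topology: no arginine 103 -> pairs involving it are absent
        frame = frame_with([
            atom("NH1", "ARG", 92, (0, 0, 0), "N"),
            atom("NH1", "ARG", 99, (3, 0, 0), "N"),
            atom("CB", "ALA", 103, (1, 1, 0), "C"),
        ])
        count, pairs = count_repulsive_contacts(frame)
        assert count == 1 and all("R103" not in p for p in pairs)


class TestEnsembleContactStats:
    def test_constant_two_contacts(self):
        spec = EnsembleSpec(seed=2, n_runs=3, frames_per_run=10,
                            contacts=(PlantedContact(92, 99),
                                      PlantedContact(122, 126)))
        ens, _ = gen_ensemble(spec)
        stat = ensemble_contact_stats(ens)
        assert stat.mean == pytest.approx(2.0) and stat.sd == 0.0

    def test_bernoulli_occupancy_recovery(self):
        p, frames, runs = 0.5, 200, 3
        spec = EnsembleSpec(seed=11, n_runs=runs, frames_per_run=frames,
                            contacts=(PlantedContact(92, 99, occupancy=p),))
        ens, _ = gen_ensemble(spec)
        stat = ensemble_contact_stats(ens)
        se = math.sqrt(p * (1 - p) / (frames * runs))
        assert abs(stat.mean - p) < 3 * se


def mg_frame(state):
    spec = EnsembleSpec(seed=1, n_runs=1, frames_per_run=1, mg_states=(state,))
    ens, _ = gen_ensemble(spec)
    return ens.runs[0][0]


class TestMgCoordination:
    @pytest.mark.parametrize("state", list(CoordinationState))
    def test_planted_state_recovered(self, state):
        assert classify_mg_coordination(mg_frame(state)) is state

    def test_direct_construction_oa_ob(self):
        frame = frame_with([
            atom("O1A", "ATP", 500, (0, 0, 0), "O"),
            atom("O1B", "ATP", 500, (3, 0, 0), "O"),
            atom("O1G", "ATP", 500, (6, 0, 0), "O"),
            atom("MG", "MG", 600, (1.5, 1.47, 0), "MG"),
        ])
        assert classify_mg_coordination(frame) is CoordinationState.FIRST_SPHERE_OA_OB

    def test_unbound_far_mg_no_water(self):
        frame = frame_with([
            atom("O1A", "ATP", 500, (0, 0, 0), "O"),
            atom("MG", "MG", 600, (8, 0, 0), "MG"),
        ])
        assert classify_mg_coordination(frame) is CoordinationState.UNBOUND

    def test_second_sphere_requires_bridge(self):
        frame = frame_with([
            atom("O1A", "ATP", 500, (0, 0, 0), "O"),
            atom("MG", "MG", 600, (4.0, 0, 0), "MG"),
            atom("O", "HOH", 700, (2.0, 0, 0), "O"),
        ])
        assert classify_mg_coordination(frame) is CoordinationState.SECOND_SPHERE

    def test_multiple_mg_errors(self):
        frame = frame_with([
            atom("MG", "MG", 600, (0, 0, 0), "MG"),
            atom("MG", "MG", 601, (9, 0, 0), "MG"),
        ])
        with pytest.raises(ValueError, match="exactly one"):
            classify_mg_coordination(frame)

    def test_classification_rigid_motion_invariant(self):
        rng = np.random.default_rng(4)
        for state in CoordinationState:
            frame = mg_frame(state)
            for _ in range(3):
                assert classify_mg_coordination(rigid_transform(frame, rng)) is state


class TestCoordinationOccupancy:
    def test_all_one_state(self):
        spec = EnsembleSpec(seed=6, n_runs=2, frames_per_run=5,
                            mg_states=(CoordinationState.FIRST_SPHERE_OA_OB,))
        ens, _ = gen_ensemble(spec)
        occ = coordination_occupancy(ens)
        assert occ == {CoordinationState.FIRST_SPHERE_OA_OB: 1.0}

    def test_half_half_schedule(self):
        spec = EnsembleSpec(seed=6, n_runs=1, frames_per_run=10,
                            mg_states=(CoordinationState.FIRST_SPHERE_OA_OB,
                                       CoordinationState.SECOND_SPHERE))
        ens, _ = gen_ensemble(spec)
        occ = coordination_occupancy(ens)
        assert occ[CoordinationState.FIRST_SPHERE_OA_OB] == pytest.approx(0.5)
        assert occ[CoordinationState.SECOND_SPHERE] == pytest.approx(0.5)

    def test_fractions_form_distribution(self):
        states = (CoordinationState.FIRST_SPHERE_OA_OB,
                  CoordinationState.FIRST_SPHERE_OB_OG,
                  CoordinationState.UNBOUND,
                  CoordinationState.SECOND_SPHERE,
                  CoordinationState.FIRST_SPHERE_OTHER)
        spec = EnsembleSpec(seed=8, n_runs=3, frames_per_run=17, mg_states=states)
        ens, _ = gen_ensemble(spec)
        occ = coordination_occupancy(ens)
        assert sum(occ.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in occ.values())
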