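import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epsbind.core import Frame, SelectionSpec
from epsbind.hbonds import (
    DEFAULT_REGISTRY, DonorAcceptorRegistry, HBondCriteria, detect_hbonds,
    ensemble_hbond_stats, espinosa_energy, network_energy,
)
from epsbind.synth import EnsembleSpec, PlantedHBond, gen_ensemble
from conftest import atom, donor_acceptor_frame, oracle_detect, random_frame, rigid_transform


class TestGeometricCriteria:
    def test_collinear_inside_cutoffs(self):
        events = detect_hbonds(donor_acceptor_frame((2.8, 0, 0)))  # d_HA = 1.8
        assert len(events) == 1
        assert events[0].d_ha == pytest.approx(1.8)
        assert events[0].angle_dha == pytest.approx(0.0, abs=1e-9)

    def test_distance_cutoff_inclusive_at_2p70(self):
        assert len(detect_hbonds(donor_acceptor_frame((3.70, 0, 0)))) == 1  # d = 2.70
        assert len(detect_hbonds(donor_acceptor_frame((3.71, 0, 0)))) == 0  # d = 2.71

    def test_angle_cutoff(self):
        d = 1.8
        for angle, expect in [(29.0, 1), (31.0, 0)]:
            rad = math.radians(angle)
            acc = (1.0 + d * math.cos(rad), d * math.sin(rad), 0.0)
            assert len(detect_hbonds(donor_acceptor_frame(acc))) == expect, angle

    def test_hydrogen_without_parent_donor_errors(self):
        frame = Frame([atom("HD", "DNR", 601, (1, 0, 0), "H"),
                       atom("OA", "ACC", 701, (2.8, 0, 0), "O")])
        with pytest.raises(ValueError, match="parent donor"):
            detect_hbonds(frame)

    def test_donor_angle_convention_differs(self):
        # acceptor at 25 deg deviation: passes deviation convention; the
        # donor-angle convention measures a different (smaller) angle
        rad = math.radians(25.0)
        acc = (1.0 + 1.8 * math.cos(rad), 1.8 * math.sin(rad), 0.0)
        dev = detect_hbonds(donor_acceptor_frame(acc),
                            criteria=HBondCriteria(angle_convention="deviation"))
        don = detect_hbonds(donor_acceptor_frame(acc),
                            criteria=HBondCriteria(angle_convention="donor"))
        assert len(dev) == len(don) == 1
        assert don[0].angle_dha < dev[0].angle_dha


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(10))
    def test_detection_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(12):  # 120 random ~50-atom frames overall
            frame = random_frame(rng)
            got = {(e.hydrogen, e.acceptor) for e in detect_hbonds(frame)}
            assert got == oracle_detect(frame)

    def test_shrinking_cutoff_never_increases_count(self, rng):
        frame = random_frame(rng, n_donors=15, n_acceptors=40)
        counts = [len(detect_hbonds(frame, criteria=HBondCriteria(d_max=d)))
                  for d in (2.7, 2.2, 1.7, 1.2)]
        assert counts == sorted(counts, reverse=True)

    def test_rigid_motion_invariance(self, rng):
        frame = random_frame(rng)
        base = {(e.hydrogen, e.acceptor) for e in detect_hbonds(frame)}
        for _ in range(5):
            moved = rigid_transform(frame, rng)
            assert {(e.hydrogen, e.acceptor) for e in detect_hbonds(moved)} == base


class TestEspinosaEnergy:
    @pytest.mark.parametrize("d, expected", [
        (1.8, -25300.0 * math.exp(-3.6 * 1.8)),   # ~ -38.8 kJ/mol
        (2.0, -25300.0 * math.exp(-3.6 * 2.0)),   # ~ -18.9 kJ/mol
    ])
    def test_closed_form(self, d, expected):
        assert espinosa_energy(d) == pytest.approx(expected, rel=1e-12)

    def test_spot_values_match_hand_calculation(self):
        assert espinosa_energy(1.8) == pytest.approx(-38.8, abs=0.05)
        assert espinosa_energy(2.0) == pytest.approx(-18.9, abs=0.05)

    @given(st.floats(0.8, 3.99), st.floats(0.001, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_negative_and_strictly_monotone(self, d, step):
        e1, e2 = espinosa_energy(d), espinosa_energy(d + step)
        assert e1 < e2 < 0

    def test_nonpositive_distance_errors(self):
        with pytest.raises(ValueError):
            espinosa_energy(0.0)


class TestNetworkEnergy:
    def test_empty_is_zero(self):
        assert network_energy([]) == 0.0

    def test_additive_and_order_invariant(self):
        frame = donor_acceptor_frame((2.8, 0, 0))
        [e] = detect_hbonds(frame)
        assert network_energy([e, e]) == pytest.approx(2 * espinosa_energy(1.8))
        assert network_energy([e, e][::-1]) == network_energy([e, e])

    def test_detected_network_energy_nonpositive(self, rng):
        for _ in range(20):
            frame = random_frame(rng)
            assert network_energy(detect_hbonds(frame)) <= 0


class TestEnsembleStats:
    def test_planted_constant_bonds(self):
        spec = EnsembleSpec(seed=3, n_runs=3, frames_per_run=10,
                            hbonds=tuple(PlantedHBond(occupancy=1.0) for _ in range(9)))
        ens, _ = gen_ensemble(spec)
        count, energy = ensemble_hbond_stats(ens)
        assert count.mean == pytest.approx(9.0)
        assert count.sd == 0.0
        assert energy.mean < 0

    def test_binomial_occupancy_recovery(self):
        p, n_bonds, frames, runs = 0.7, 10, 200, 3
        spec = EnsembleSpec(seed=42, n_runs=runs, frames_per_run=frames,
                            hbonds=tuple(PlantedHBond(occupancy=p)
                                         for _ in range(n_bonds)))
        ens, _ = gen_ensemble(spec)
        count, _ = ensemble_hbond_stats(ens)
        se = math.sqrt(n_bonds * p * (1 - p) / (frames * runs))
        assert abs(count.mean - n_bonds * p) < 3 * se

    def test_group_restriction_counts_only_cross_boundary(self):
        # emulate "second helix vs remainder": restrict to residue subsets
        spec = EnsembleSpec(seed=5, n_runs=1, frames_per_run=4,
                            hbonds=tuple(PlantedHBond(occupancy=1.0) for _ in range(3)))
        ens, _ = gen_ensemble(spec)
        # bonds 0,1,2 use donor residues 601-603 and acceptors 701-703
        helix = SelectionSpec("helix", residue_ids={601, 701})
        rest = SelectionSpec("rest", residue_ids={602, 603, 702, 703})
        count_cross, _ = ensemble_hbond_stats(ens, group_a=helix, group_b=rest)
        assert count_cross.mean == 0.0  # planted bonds never cross the boundary
        count_within, _ = ensemble_hbond_stats(
            ens, group_a=SelectionSpec("d1", residue_ids={601}),
            group_b=SelectionSpec("a1", residue_ids={701}))
        assert count_within.mean == 1.0

    def test_stats_invariant_under_rigid_motion(self, rng):
        spec = EnsembleSpec(seed=9, n_runs=2, frames_per_run=5,
                            hbonds=(PlantedHBond(occupancy=0.6),
                                    PlantedHBond(occupancy=0.9)))
        ens, _ = gen_ensemble(spec)
        base_count, base_energy = ensemble_hbond_stats(ens)
        moved_runs = [[rigid_transform(f, rng) for f in run] for run in ens.runs]
        from epsbind.core import Ensemble
        moved = Ensemble(moved_runs, ens.equilibration_fraction, ens.label)
        count, energy = ensemble_hbond_stats(moved)
        assert count.mean == pytest.approx(base_count.mean)
        assert energy.mean == pytest.approx(base_energy.mean, rel=1e-9)
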