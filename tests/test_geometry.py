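import numpy as np
import pytest

from epsbind.core import Ensemble, Frame, SelectionSpec
from epsbind.geometry import (
    HelixPair, ReferenceDistances, com_distance, interaction_distance_series,
    superpose_rmsd,
)
from conftest import atom, rigid_transform


def two_group_frame():
    return Frame([
        atom("CA", "ALA", 1, (0, 0, 0), "C"),
        atom("CA", "ALA", 2, (2, 0, 0), "C"),
        atom("CA", "ALA", 10, (10, 0, 0), "C"),
        atom("CA", "ALA", 11, (12, 0, 0), "C"),
    ])


def pair(ids_a, ids_b, mass="unit"):
    return HelixPair(SelectionSpec("a", residue_ids=frozenset(ids_a)),
                     SelectionSpec("b", residue_ids=frozenset(ids_b)),
                     mass_convention=mass)


class TestComDistance:
    def test_two_single_atoms(self):
        frame = Frame([atom("CA", "ALA", 1, (0, 0, 0), "C"),
                       atom("CA", "ALA", 2, (3, 4, 0), "C")])
        assert com_distance(frame, pair({1}, {2})) == pytest.approx(5.0)

    def test_unit_mass_centroids(self):
        assert com_distance(two_group_frame(), pair({1, 2}, {10, 11})) == pytest.approx(10.0)

    def test_rotation_invariance(self, rng):
        frame = two_group_frame()
        p = pair({1, 2}, {10, 11})
        base = com_distance(frame, p)
        for _ in range(5):
            assert com_distance(rigid_transform(frame, rng), p) == pytest.approx(base)

    def test_element_masses_shift_centroid(self):
        frame = Frame([atom("N", "GLY", 1, (0, 0, 0), "N"),
                       atom("H", "GLY", 1, (1, 0, 0), "H"),
                       atom("CA", "GLY", 2, (10, 0, 0), "C")])
        d_unit = com_distance(frame, pair({1}, {2}))
        d_mass = com_distance(frame, pair({1}, {2}, mass="element"))
        assert d_unit == pytest.approx(9.5)
        assert d_mass > d_unit  # heavy N pulls the centroid toward x=0

    def test_overlapping_selections_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            com_distance(two_group_frame(), pair({1, 2}, {2, 10}))


class TestDistanceSeries:
    def ensemble(self, distances):
        frames = [Frame([atom("OE1", "GLU", 83, (0, 0, 0), "O"),
                         atom("O2'", "ATP", 500, (d, 0, 0), "O")], frame_index=i)
                  for i, d in enumerate(distances)]
        return Ensemble([frames])

    def test_zero_deviation_from_matching_reference(self):
        ens = self.ensemble([2.8, 2.8, 2.8])
        ref = ReferenceDistances({"E83-O2'": 2.8}, source="2E5Y")
        series = interaction_distance_series(
            ens, SelectionSpec("e83", residue_ids={83}, atom_names={"OE1"}),
            SelectionSpec("o2p", atom_names={"O2'"}),
            reference=ref, reference_key="E83-O2'")
        assert series.mean_deviation == pytest.approx(0.0)

    def test_min_distance_mode_for_nhx_groups(self):
        frames = [Frame([
            atom("NH1", "ARG", 122, (2.0, 0, 0), "N"),
            atom("NH2", "ARG", 122, (5.0, 0, 0), "N"),
            atom("O1B", "ATP", 500, (0, 0, 0), "O"),
        ])]
        ens = Ensemble([frames])
        series = interaction_distance_series(
            ens, SelectionSpec("r122nhx", residue_ids={122}, atom_names={"NH1", "NH2"}),
            SelectionSpec("ob", atom_names={"O1B"}), min_distance_mode=True)
        assert series.distances == (pytest.approx(2.0),)

    def test_multi_atom_without_min_mode_errors(self):
        frames = [Frame([
            atom("NH1", "ARG", 122, (2.0, 0, 0), "N"),
            atom("NH2", "ARG", 122, (5.0, 0, 0), "N"),
            atom("O1B", "ATP", 500, (0, 0, 0), "O"),
        ])]
        with pytest.raises(Exception, match="min-distance"):
            interaction_distance_series(
                Ensemble([frames]),
                SelectionSpec("r122nhx", residue_ids={122}, atom_names={"NH1", "NH2"}),
                SelectionSpec("ob", atom_names={"O1B"}))

    def test_histogram_counts_conserve_frames(self, rng):
        ens = self.ensemble(list(2.0 + rng.random(37)))
        series = interaction_distance_series(
            ens, SelectionSpec("a", atom_names={"OE1"}),
            SelectionSpec("b", atom_names={"O2'"}))
        assert sum(series.bin_counts) == 37


class TestSuperposeRMSD:
    def test_identical_frames_zero(self):
        frame = two_group_frame()
        assert superpose_rmsd(frame, frame) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_zero(self, rng):
        frame = two_group_frame()
        for _ in range(5):
            moved = rigid_transform(frame, rng)
            assert superpose_rmsd(frame, moved) == pytest.approx(0.0, abs=1e-6)

    def test_two_atom_closed_form(self):
        # centered configs (-0.5, +0.5) vs (-1.5, +1.5): RMSD = sqrt((1+1)/2) = 1
        a = Frame([atom("CA", "ALA", 1, (0, 0, 0), "C"),
                   atom("CA", "ALA", 2, (1, 0, 0), "C")])
        b = Frame([atom("CA", "ALA", 1, (0, 0, 0), "C"),
                   atom("CA", "ALA", 2, (3, 0, 0), "C")])
        assert superpose_rmsd(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, rng):
        a = Frame([atom("CA", "ALA", i, rng.uniform(0, 10, 3), "C")
                   for i in range(1, 8)])
        b = Frame([atom("CA", "ALA", i, rng.uniform(0, 10, 3), "C")
                   for i in range(1, 8)])
        assert superpose_rmsd(a, b) == pytest.approx(superpose_rmsd(b, a))

    def test_reflection_excluded(self):
        # a mirrored configuration cannot be superposed to zero by a proper rotation
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        mirrored = coords * np.array([1, 1, -1])
        a = Frame([atom("CA", "ALA", i + 1, c, "C") for i, c in enumerate(coords)])
        b = Frame([atom("CA", "ALA", i + 1, c, "C") for i, c in enumerate(mirrored)])
        assert superpose_rmsd(a, b) > 0.1

    def test_count_mismatch_errors(self):
        a = Frame([atom("CA", "ALA", 1, (0, 0, 0), "C")])
        b = Frame([atom("CA", "ALA", 1, (0, 0, 0), "C"),
                   atom("CA", "ALA", 2, (1, 0, 0), "C")])
        with pytest.raises(ValueError, match="mismatch"):
            superpose_rmsd(a, b)
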