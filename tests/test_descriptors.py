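"""Helix axes, angles, distances, SASA and correlation matrices."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from kirgate import descriptors, synth
from kirgate.core import Atom, Ensemble, Structure
from kirgate.descriptors import HelixSpec
from kirgate.errors import InsufficientAtomsError, NoVarianceError
from conftest import random_rotation


def _helix_structure(coords, chain="A", start=35):
    atoms = [
        Atom(i + 1, "CA", "C", "GLY", start + i, chain, xyz)
        for i, xyz in enumerate(coords)
    ]
    return Structure.from_atoms(atoms)


def _ideal_z_helix(n=9, rise=1.5, twist=100.0, radius=2.3):
    t = np.arange(n)
    ang = np.radians(twist) * t
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * t])


class TestHelixAxis:
    def test_z_helix_axis(self):
        s = _helix_structure(_ideal_z_helix())
        axis, _ = descriptors.helix_axis(s, HelixSpec(chain="A", kind="slide"))
        assert math.degrees(math.acos(abs(axis[2]))) < 1.0

    def test_rotated_helix_axis(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            R = random_rotation(rng)
            s = _helix_structure(_ideal_z_helix() @ R.T)
            axis, _ = descriptors.helix_axis(s, HelixSpec(chain="A", kind="slide"))
            expected = R @ np.array([0.0, 0.0, 1.0])
            angle = math.degrees(math.acos(min(1.0, abs(float(axis @ expected)))))
            assert angle < 1.0

    def test_collinear_points_fall_back_to_line(self):
        coords = np.outer(np.arange(9), [1.0, 0.0, 0.0])
        s = _helix_structure(coords)
        axis, _ = descriptors.helix_axis(s, HelixSpec(chain="A", kind="slide"))
        assert abs(abs(axis[0]) - 1.0) < 1e-9

    def test_too_few_atoms(self):
        s = _helix_structure(_ideal_z_helix(3))
        with pytest.raises(InsufficientAtomsError):
            descriptors.helix_axis(s, HelixSpec(chain="A", kind="slide", resid_range=(35, 37)))


class TestAngles:
    def test_in_plane_slide_helix_is_zero(self):
        coords = _ideal_z_helix()
        # rotate axis from +Z into the XY plane (+X)
        R = np.array([[0, 0, 1.0], [0, 1.0, 0], [-1.0, 0, 0]])
        s = _helix_structure(coords @ R.T)
        assert abs(descriptors.upward_angle(s, "A")) < 1.0

    def test_vertical_slide_helix_is_ninety(self):
        s = _helix_structure(_ideal_z_helix())
        assert descriptors.upward_angle(s, "A") > 89.0

    def test_tilt_limits(self):
        s_vert = _helix_structure(_ideal_z_helix(27), start=109)
        assert descriptors.tilt_angle(s_vert, "A", "inner") < 1.0
        R = np.array([[0, 0, 1.0], [0, 1.0, 0], [-1.0, 0, 0]])
        s_flat = _helix_structure(_ideal_z_helix(27) @ R.T, start=109)
        assert descriptors.tilt_angle(s_flat, "A", "inner") > 89.0

    @pytest.mark.parametrize("angle", [5.0, 15.0, 30.0])
    def test_generator_roundtrip(self, angle):
        s = synth.build_channel(
            synth.ChannelParams(slide_elevation=angle, inner_tilt=angle, outer_tilt=angle)
        )
        for c in "ABCD":
            assert abs(descriptors.upward_angle(s, c) - angle) < 1.0
            assert abs(descriptors.tilt_angle(s, c, "inner") - angle) < 1.0
            assert abs(descriptors.tilt_angle(s, c, "outer") - angle) < 1.0


class TestDistances:
    def test_single_atom_residues(self):
        atoms = [
            Atom(1, "CA", "C", "GLY", 1, "A", (0, 0, 0)),
            Atom(2, "CA", "C", "GLY", 2, "A", (5, 0, 0)),
        ]
        s = Structure.from_atoms(atoms)
        assert descriptors.shortest_distance(s, ("A", 1), ("A", 2)) == pytest.approx(5.0)

    def test_self_distance_warns_zero(self, default_channel):
        s, _ = default_channel
        with pytest.warns(UserWarning):
            assert descriptors.shortest_distance(s, ("A", 46), ("A", 46)) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        atoms = []
        for resid, chain in ((1, "A"), (2, "B")):
            for j in range(10):
                atoms.append(
                    Atom(len(atoms) + 1, f"X{j}", "C", "GLY", resid, chain,
                         rng.uniform(-10, 10, 3))
                )
        s = Structure.from_atoms(atoms)
        brute = min(
            np.linalg.norm(a.xyz - b.xyz)
            for a in s.atoms[:10]
            for b in s.atoms[10:]
        )
        assert descriptors.shortest_distance(s, ("A", 1), ("B", 2)) == pytest.approx(brute)

    def test_gate_distances_brute_force_and_symmetry(self):
        s = synth.build_channel(
            synth.ChannelParams(aperture_124=(5.0, 4.5), aperture_132=4.0)
        )
        g124ac, g124bd, g132ac, g132bd = descriptors.gate_distances(s)
        assert g124ac != pytest.approx(g124bd)
        for value, resid, pair in (
            (g124ac, 124, ("A", "C")),
            (g124bd, 124, ("B", "D")),
            (g132ac, 132, ("A", "C")),
            (g132bd, 132, ("B", "D")),
        ):
            ia = s.residue_indices(pair[0], resid)
            ib = s.residue_indices(pair[1], resid)
            brute = min(
                np.linalg.norm(s.coords[i] - s.coords[j]) for i in ia for j in ib
            )
            assert value == pytest.approx(brute)
            assert value >= 0

    def test_rigid_motion_invariance(self, default_channel):
        s, _ = default_channel
        rng = np.random.default_rng(8)
        R = random_rotation(rng)
        moved = s.with_coords(s.coords @ R.T + rng.uniform(-20, 20, 3))
        for res_pair in ((("A", 46), ("D", 36)), (("A", 124), ("C", 124))):
            assert descriptors.shortest_distance(s, *res_pair) == pytest.approx(
                descriptors.shortest_distance(moved, *res_pair), abs=1e-9
            )


class TestSasa:
    def test_isolated_carbon_sphere(self):
        s = Structure.from_atoms([Atom(1, "C", "C", "GLY", 1, "A", (0, 0, 0))])
        area = descriptors.sasa(s)[("A", 1)]
        expected = 4 * math.pi * (1.7 + 1.4) ** 2
        assert abs(area - expected) / expected < 0.01

    def test_caged_atom_is_buried(self):
        atoms = [Atom(1, "C", "C", "GLY", 1, "A", (0, 0, 0))]
        # tight octahedral-plus-cube cage
        k = 2
        for dx in (-2.0, 0.0, 2.0):
            for dy in (-2.0, 0.0, 2.0):
                for dz in (-2.0, 0.0, 2.0):
                    if dx == dy == dz == 0.0:
                        continue
                    atoms.append(Atom(k, "C", "C", "GLY", 2, "A", (dx, dy, dz)))
                    k += 1
        s = Structure.from_atoms(atoms)
        assert descriptors.sasa(s)[("A", 1)] == pytest.approx(0.0, abs=1e-9)

    def test_two_atom_pair_against_spherical_cap_formula(self):
        # two equal expanded spheres R at center distance d: each loses a
        # cap of height h = R - d/2, area 2*pi*R*h
        s = Structure.from_atoms(
            [
                Atom(1, "C", "C", "GLY", 1, "A", (0, 0, 0)),
                Atom(2, "C", "C", "GLY", 2, "A", (2.0, 0, 0)),
            ]
        )
        areas = descriptors.sasa(s)
        R = 1.7 + 1.4
        expected = 4 * math.pi * R**2 - 2 * math.pi * R * (R - 1.0)
        for v in areas.values():
            assert abs(v - expected) / expected < 0.02

    def test_per_residue_sums_to_total(self, default_channel):
        s, _ = default_channel
        sub = Structure.from_atoms(s.atoms[:40])
        per_res = descriptors.sasa(sub)
        # total from a single-residue relabeling of the same atoms
        merged = sub.copy()
        merged.resid[:] = 1
        merged.chain = ["A"] * merged.natoms
        merged.name = [f"X{i}" for i in range(merged.natoms)]
        merged._res_index = None
        total = descriptors.sasa(merged)[("A", 1)]
        assert sum(per_res.values()) == pytest.approx(total, rel=1e-9)


class TestDescriptorTable:
    def test_shape_and_columns(self, small_ensemble):
        ens, _ = small_ensemble
        table = descriptors.descriptor_table(ens)
        assert len(table) == 100
        assert table.shape[1] >= 20
        assert not table.isna().any().any()
        for name in ("d46a36d", "d46b36a", "d46c36b", "d46d36c"):
            assert name in table.columns

    def test_frozen_ensemble_zero_variance(self, default_channel):
        s, _ = default_channel
        ens = Ensemble([s.with_coords(s.coords) for _ in range(5)])
        table = descriptors.descriptor_table(ens)
        assert np.allclose(table.to_numpy().var(axis=0), 0.0)


class TestPearson:
    def test_self_correlation_is_one(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 1, 4, 3]})
        cm = descriptors.pearson_matrix(df, ["x", "y"])
        assert cm.values[0, 0] == 1.0

    def test_anticorrelation(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": -x})
        cm = descriptors.pearson_matrix(df)
        assert cm.values[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        # closed form: cov / (sigma_x sigma_y)
        expected = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        cm = descriptors.pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        assert cm.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_positive_semidefinite(self, small_ensemble):
        ens, _ = small_ensemble
        table = descriptors.descriptor_table(ens)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = descriptors.pearson_matrix(table)
        assert np.allclose(cm.values, cm.values.T)
        eigvals = np.linalg.eigvalsh(cm.values)
        assert eigvals.min() > -1e-8
        assert np.allclose(np.diag(cm.values), 1.0)

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "c": [5.0, 5, 5]})
        with pytest.warns(UserWarning):
            cm = descriptors.pearson_matrix(df)
        assert cm.labels == ["x"]

    def test_all_constant_raises(self):
        df = pd.DataFrame({"c": [5.0, 5, 5], "d": [1.0, 1, 1]})
        with pytest.raises(NoVarianceError):
            descriptors.pearson_matrix(df)

    def test_alias_resolution(self):
        assert descriptors.resolve_column("inclia") == "tilt_in_a"
        assert descriptors.resolve_column("inclob") == "tilt_out_b"
        assert descriptors.resolve_column("tiltic") == "tilt_in_c"
        assert descriptors.resolve_column("tiltod") == "tilt_out_d"
        assert descriptors.resolve_column("g124ac") == "g124ac"

    def test_imposed_coupling_sign_recovered(self):
        """A generator-imposed slide/gate coupling shows up in the matrix."""
        rng = np.random.default_rng(4)
        frames = []
        g_values = rng.uniform(4.0, 7.0, 40)
        for g in g_values:
            elev = 5.0 + 3.0 * (g - 4.0)  # positive linear coupling
            frames.append(
                synth.build_channel(
                    synth.ChannelParams(slide_elevation=elev, aperture_124=g)
                )
            )
        table = descriptors.descriptor_table(Ensemble(frames))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = descriptors.pearson_matrix(table, ["upa", "g124ac"])
        assert cm.values[0, 1] > 0.9
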