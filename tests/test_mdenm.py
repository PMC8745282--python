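"""Elastic-network modes, excitation protocol, clustering, relaxation."""

import math
import warnings

import numpy as np
import pytest

from kirgate import descriptors, mdenm, synth
from kirgate.errors import ConfigurationError, ConnectivityError
from kirgate.gating import kabsch
from kirgate.mdenm import KB, ENMSystem, ExcitationConfig


@pytest.fixture(scope="module")
def random_system():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0.0, 10.0, (20, 3))
    return ENMSystem(coords=coords, cutoff=12.0)


@pytest.fixture(scope="module")
def random_modes(random_system):
    return mdenm.enm_modes(random_system)


@pytest.fixture(scope="module")
def channel_system():
    s = synth.build_channel(synth.ChannelParams())
    return mdenm.ENMSystem.from_structure(s, atom_names=("CA", "CB"))


class TestModes:
    def test_six_rigid_body_modes(self, random_modes):
        vals = random_modes.eigenvalues
        assert random_modes.n_rigid == 6
        assert np.all(np.abs(vals[:6]) < 1e-8 * vals[6])

    def test_two_mass_spring_closed_form(self):
        """Two masses on one spring: the stretch eigenvalue is k(1/m1+1/m2)."""
        m1, m2, k = 10.0, 40.0, 2.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sys2 = ENMSystem(
                coords=np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                masses=np.array([m1, m2]),
                cutoff=5.0,
                k_spring=k,
            )
            modes = mdenm.enm_modes(sys2)
        nonzero = modes.eigenvalues[modes.n_rigid :]
        assert len(nonzero) == 1
        assert nonzero[0] == pytest.approx(k * (1 / m1 + 1 / m2), rel=1e-10)

    def test_eigen_residual(self, random_system, random_modes):
        H = mdenm._hessian(random_system)
        inv_sqrt_m = np.repeat(1.0 / np.sqrt(random_system.masses), 3)
        Hmw = H * np.outer(inv_sqrt_m, inv_sqrt_m)
        for j in range(len(random_modes.eigenvalues)):
            v = random_modes.eigenvectors[:, j]
            residual = Hmw @ v - random_modes.eigenvalues[j] * v
            assert np.abs(residual).max() < 1e-8

    def test_orthonormality_and_symmetry(self, random_system, random_modes):
        V = random_modes.eigenvectors
        assert np.abs(V.T @ V - np.eye(V.shape[1])).max() < 1e-6
        H = mdenm._hessian(random_system)
        assert np.abs(H - H.T).max() < 1e-8

    def test_disconnected_graph_rejected(self):
        coords = np.vstack(
            [np.random.default_rng(1).uniform(0, 5, (10, 3)),
             np.random.default_rng(2).uniform(100, 105, (10, 3))]
        )
        with pytest.raises(ConnectivityError):
            mdenm.enm_modes(ENMSystem(coords=coords, cutoff=12.0))


class TestSelectModes:
    def test_exact_mode_target_ranks_first(self, random_modes):
        target = random_modes.coordinate_displacement(9)
        sel = mdenm.select_modes(random_modes, target, k=5)
        assert sel.indices[0] == 9
        assert sel.overlaps[0] == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_target_warns(self, random_modes):
        # rigid translation is orthogonal to every internal mode
        target = np.tile([1.0, 0.0, 0.0], len(random_modes.masses))
        with pytest.warns(UserWarning):
            sel = mdenm.select_modes(random_modes, target, k=5)
        assert sel.overlaps.max() < 1e-12

    def test_cumulative_is_bessel_bounded(self, random_modes):
        rng = np.random.default_rng(3)
        target = rng.normal(size=3 * len(random_modes.masses))
        sel = mdenm.select_modes(random_modes, target, k=20)
        assert np.all(np.diff(sel.cumulative) >= -1e-12)
        assert sel.cumulative[-1] <= 1.0 + 1e-9

    def test_zero_target_rejected(self, random_modes):
        with pytest.raises(ConfigurationError):
            mdenm.select_modes(random_modes, np.zeros(3 * len(random_modes.masses)))


class TestIsotropicCombinations:
    def test_one_mode_two_directions(self):
        vecs = mdenm.isotropic_combinations(1, 2, seed=0)
        assert sorted(v[0] for v in vecs) == [-1.0, 1.0]

    def test_min_angle_honored(self):
        vecs = mdenm.isotropic_combinations(8, 130, min_angle_deg=15.0, seed=1)
        assert len(vecs) == 130
        dots = vecs @ vecs.T
        np.fill_diagonal(dots, -1.0)
        assert math.degrees(math.acos(dots.max())) >= 15.0

    def test_mean_is_near_zero(self):
        n = 130
        vecs = mdenm.isotropic_combinations(8, n, min_angle_deg=15.0, seed=2)
        assert np.abs(vecs.mean(axis=0)).max() < 3.0 / math.sqrt(n)

    def test_infeasible_request_warns_partial(self):
        with pytest.warns(UserWarning):
            vecs = mdenm.isotropic_combinations(2, 500, min_angle_deg=30.0, seed=3)
        assert len(vecs) < 500


class TestExcite:
    def test_bookkeeping_and_exact_ke_jump(self, random_system):
        modes = mdenm.enm_modes(random_system)
        coeffs = mdenm.isotropic_combinations(5, 4, seed=0)
        dirs = mdenm.combination_directions(modes, modes.internal_indices[:5], coeffs)
        cfg = ExcitationConfig(n_replicas=4, n_excitations=3, excitation_ps=0.2, seed=0)
        ens = mdenm.excite(random_system, dirs, cfg)
        assert len(ens) == 12
        expected = 1.5 * random_system.n_nodes * KB * cfg.delta_T_K
        jumps = np.asarray(ens.metadata["ke_jumps"])
        assert np.abs(jumps / expected - 1.0).max() < 1e-6

    def test_zero_momentum_kick_for_internal_directions(self, random_system):
        """Internal-mode directions carry no net linear momentum, so the
        velocity increment's total momentum vanishes."""
        modes = mdenm.enm_modes(random_system)
        d = modes.coordinate_displacement(8).ravel()
        d /= np.linalg.norm(d)
        rng = np.random.default_rng(5)
        v = rng.normal(size=(random_system.n_nodes, 3))
        dv = mdenm._ke_kick(random_system.masses, v, d, 1.0)
        momentum = (random_system.masses[:, None] * dv).sum(axis=0)
        assert np.abs(momentum).max() < 1e-10

    def test_provenance_structure(self, random_system):
        modes = mdenm.enm_modes(random_system)
        dirs = mdenm.combination_directions(
            modes, modes.internal_indices[:2], mdenm.isotropic_combinations(2, 3, seed=1)
        )
        cfg = ExcitationConfig(n_replicas=3, n_excitations=2, excitation_ps=0.1, seed=1)
        ens = mdenm.excite(random_system, dirs, cfg)
        assert ens.provenance == [(r, e, r * 2 + e) for r in range(3) for e in range(2)]


class TestCluster:
    def test_identical_frames_one_cluster(self, random_system):
        from kirgate.core import Ensemble

        s = random_system.node_structure()
        ens = Ensemble([s.with_coords(random_system.coords) for _ in range(5)])
        cs = mdenm.cluster_rmsd(ens, threshold=1.0)
        assert cs.n_clusters == 1
        assert cs.representatives[0] in range(5)

    def test_two_separated_groups(self, random_system):
        from kirgate.core import Ensemble

        rng = np.random.default_rng(7)
        base = random_system.coords
        stretched = base * 1.5  # non-rigid change: large superposed rmsd
        frames = [
            random_system.node_structure().with_coords(c + rng.normal(0, 0.05, c.shape))
            for c in ([base] * 4 + [stretched] * 4)
        ]
        cs = mdenm.cluster_rmsd(Ensemble(frames), threshold=1.0)
        assert cs.n_clusters == 2

    def test_members_within_threshold_of_leader(self, random_system):
        from kirgate.core import Ensemble

        rng = np.random.default_rng(9)
        frames = [
            random_system.node_structure().with_coords(
                random_system.coords + rng.normal(0, 0.3, random_system.coords.shape)
            )
            for _ in range(50)
        ]
        ens = Ensemble(frames)
        cs = mdenm.cluster_rmsd(ens, threshold=1.0)
        coords = ens.coords_array()
        leaders: dict[int, int] = {}
        for f, lab in enumerate(cs.labels):
            leaders.setdefault(int(lab), f)  # first member is the leader
        for f, lab in enumerate(cs.labels):
            _, _, r = kabsch(coords[f], coords[leaders[int(lab)]])
            assert r <= 1.0 + 1e-9


class TestRelax:
    def test_tail_bookkeeping(self, random_system):
        cfg = ExcitationConfig(
            n_replicas=1, relaxation_ps=2.0, snapshot_ps=0.2, tail_fraction=1.0, seed=2
        )
        reps = [random_system.node_structure().with_coords(random_system.coords)]
        ens = mdenm.relax(random_system, reps, cfg)
        assert len(ens) == 10  # all recorded frames kept at tail_fraction 1
        cfg75 = ExcitationConfig(
            n_replicas=1, relaxation_ps=2.0, snapshot_ps=0.2, tail_fraction=0.75, seed=2
        )
        ens75 = mdenm.relax(random_system, reps, cfg75)
        assert len(ens75) == 8  # snapshots at t > 0.5 ps out of 10

    def test_kinetic_temperature_near_setpoint(self, channel_system):
        cfg = ExcitationConfig(
            n_replicas=1, relaxation_ps=6.0, snapshot_ps=0.2,
            tail_fraction=0.5, temperature_K=300.0, seed=3,
        )
        reps = [channel_system.node_structure().with_coords(channel_system.coords)]
        ens = mdenm.relax(channel_system, reps, cfg)
        mean_T = float(np.mean(ens.metadata["kinetic_temperature_K"]))
        assert abs(mean_T - 300.0) / 300.0 < 0.05


class TestEndToEnd:
    def test_excitation_widens_gate_aperture_range(self, channel_system):
        """Exciting along gating modes explores farther along the gating
        coordinate than unexcited dynamics at the same temperature."""
        s_open, s_closed = synth.endpoint_pair(
            synth.ChannelParams(aperture_124=6.5, aperture_132=6.5),
            synth.ChannelParams(aperture_124=3.0, aperture_132=3.0),
        )
        target = (
            mdenm.ENMSystem.from_structure(s_open, atom_names=("CA", "CB")).coords
            - mdenm.ENMSystem.from_structure(s_closed, atom_names=("CA", "CB")).coords
        )
        modes = mdenm.enm_modes(channel_system)
        sel = mdenm.select_modes(modes, target, k=6)
        coeffs = mdenm.isotropic_combinations(6, 10, seed=4)
        dirs = mdenm.combination_directions(modes, sel.indices, coeffs)
        # cold bath, strong kicks: the excitation energy, injected along the
        # gating modes, dominates over thermal fluctuations
        cfg = ExcitationConfig(
            n_replicas=10, n_excitations=7, excitation_ps=0.3,
            delta_T_K=200.0, temperature_K=50.0, seed=4,
        )
        excited = mdenm.excite(channel_system, dirs, cfg)

        relax_cfg = ExcitationConfig(
            n_replicas=1, relaxation_ps=21.0, snapshot_ps=0.3,
            tail_fraction=1.0, temperature_K=50.0, seed=4,
        )
        ref = channel_system.node_structure().with_coords(channel_system.coords)
        unexcited = mdenm.relax(channel_system, [ref], relax_cfg)

        def aperture_range(ens):
            vals = [descriptors.gate_distances(f)[0] for f in ens]
            return min(vals), max(vals)

        lo_e, hi_e = aperture_range(excited)
        lo_u, hi_u = aperture_range(unexcited)
        assert lo_e < lo_u and hi_e > hi_u
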