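"""Excited-normal-mode conformational sampling on elastic networks.

A coarse-grained anisotropic elastic-network model (uniform springs
between nodes within a cutoff) supplies low-frequency normal modes.  Modes
are ranked by their overlap with a functional target displacement (e.g.
the closed→open difference vector of a channel), combined into
near-isotropically distributed unit directions, and each combination is
used as a *replica*: a series of kinetic-energy excitations injects
velocity along the replica's direction so that the instantaneous kinetic
energy jumps by (3N/2)·k_B·ΔT, followed by short Langevin dynamics on the
harmonic potential.  Excited snapshots are clustered on pairwise
superposed RMSD, each cluster's representative is relaxed by unexcited
thermostatted dynamics, and the tail of each relaxation is pooled into the
analysis ensemble.

Units: lengths in Å, energies in kcal/mol, masses in amu, temperatures in
K; the integrator works in AKMA time units (1 AKMA ≈ 48.89 fs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform

from .core import Atom, Ensemble, Structure
from .errors import ConfigurationError, ConnectivityError, IntegrationError
from .gating import kabsch

__all__ = [
    "ENMSystem",
    "ModeSet",
    "ModeSelection",
    "ExcitationConfig",
    "ClusterSet",
    "enm_modes",
    "select_modes",
    "isotropic_combinations",
    "combination_directions",
    "excite",
    "relax",
    "cluster_rmsd",
]

KB = 0.0019872041  # kcal/mol/K
AKMA_PS = 4.888821e-2  # one AKMA time unit in ps


@dataclass
class ENMSystem:
    """Elastic network: node coordinates, masses, spring cutoff & constant."""

    coords: np.ndarray  # (N, 3) Å
    masses: np.ndarray | float = 110.0  # amu (uniform residue-like default)
    cutoff: float = 12.0  # Å
    k_spring: float = 1.0  # kcal/mol/Å^2
    template: Structure | None = None  # atom identities for emitted frames

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        n = len(self.coords)
        if n < 2:
            raise ConfigurationError("an ENM needs at least 2 nodes")
        if n < 7:
            warnings.warn(
                f"{n} nodes give no internal-mode spectrum beyond textbook cases"
            )
        if np.isscalar(self.masses):
            self.masses = np.full(n, float(self.masses))
        else:
            self.masses = np.asarray(self.masses, float)
        if self.masses.shape != (n,) or np.any(self.masses <= 0):
            raise ConfigurationError("masses must be positive, one per node")

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @classmethod
    def from_structure(
        cls,
        structure: Structure,
        atom_names: tuple[str, ...] = ("CA",),
        mass: float = 110.0,
        cutoff: float = 12.0,
        k_spring: float = 1.0,
    ) -> "ENMSystem":
        """Coarse-grain a structure to one node per selected atom."""
        keep = [
            i
            for i in range(structure.natoms)
            if not structure.het[i] and structure.name[i] in atom_names
        ]
        template = Structure(
            structure.serial[keep],
            [structure.name[i] for i in keep],
            [structure.element[i] for i in keep],
            [structure.resname[i] for i in keep],
            structure.resid[keep],
            [structure.chain[i] for i in keep],
            structure.coords[keep],
        )
        return cls(
            coords=structure.coords[keep].copy(),
            masses=mass,
            cutoff=cutoff,
            k_spring=k_spring,
            template=template,
        )

    def pair_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Spring pairs (i, j, rest length) within the cutoff."""
        d = squareform(pdist(self.coords))
        i_idx, j_idx = np.nonzero(np.triu(d <= self.cutoff, k=1))
        return i_idx, j_idx, d[i_idx, j_idx]

    def node_structure(self) -> Structure:
        if self.template is not None:
            return self.template
        atoms = [
            Atom(i + 1, "CA", "C", "GLY", i + 1, "A", self.coords[i])
            for i in range(self.n_nodes)
        ]
        return Structure.from_atoms(atoms)


@dataclass
class ModeSet:
    """Eigenpairs of the mass-weighted ENM Hessian, ascending frequency.

    Eigenvectors are columns over mass-weighted coordinates q = √m·x and
    are orthonormal; the first ``n_rigid`` (near-zero) modes are rigid-body
    — six for a generic 3-D network, five for collinear ones.
    """

    eigenvalues: np.ndarray  # (M,)
    eigenvectors: np.ndarray  # (3N, M)
    masses: np.ndarray  # (N,)
    n_rigid: int = 6

    @property
    def internal_indices(self) -> np.ndarray:
        return np.arange(self.n_rigid, len(self.eigenvalues))

    def coordinate_displacement(self, mode_index: int) -> np.ndarray:
        """Un-mass-weighted displacement field of one mode, shape (N, 3)."""
        v = self.eigenvectors[:, mode_index].reshape(-1, 3)
        return v / np.sqrt(self.masses)[:, None]


def _hessian(system: ENMSystem) -> np.ndarray:
    n = system.n_nodes
    H = np.zeros((3 * n, 3 * n))
    i_idx, j_idx, r0 = system.pair_list()
    d = system.coords[i_idx] - system.coords[j_idx]
    u = d / np.linalg.norm(d, axis=1)[:, None]
    for p in range(len(i_idx)):
        block = system.k_spring * np.outer(u[p], u[p])
        i3, j3 = 3 * i_idx[p], 3 * j_idx[p]
        H[i3 : i3 + 3, i3 : i3 + 3] += block
        H[j3 : j3 + 3, j3 : j3 + 3] += block
        H[i3 : i3 + 3, j3 : j3 + 3] -= block
        H[j3 : j3 + 3, i3 : i3 + 3] -= block
    return H


def enm_modes(system: ENMSystem, n_modes: int | None = None) -> ModeSet:
    """Diagonalize the mass-weighted Hessian.

    ``n_modes`` caps the number of *internal* modes retained (the six
    rigid-body modes are always kept, flagged by ``n_rigid``).  More than
    six near-zero eigenvalues indicate a disconnected spring graph.
    """
    H = _hessian(system)
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(system.masses), 3)
    Hmw = H * np.outer(inv_sqrt_m, inv_sqrt_m)
    Hmw = (Hmw + Hmw.T) / 2.0
    vals, vecs = scipy.linalg.eigh(Hmw)
    tol = max(abs(vals).max() * 1e-9, 1e-12)
    n_zero = int(np.sum(np.abs(vals) < tol))
    if n_zero > 6:
        raise ConnectivityError(
            f"{n_zero} near-zero modes (expected at most 6): "
            "the spring graph is disconnected"
        )
    keep = len(vals) if n_modes is None else min(len(vals), n_zero + n_modes)
    return ModeSet(
        eigenvalues=vals[:keep],
        eigenvectors=vecs[:, :keep],
        masses=system.masses.copy(),
        n_rigid=n_zero,
    )


@dataclass
class ModeSelection:
    """Internal modes ranked by squared overlap with a target displacement."""

    indices: np.ndarray  # global mode indices, best first
    overlaps: np.ndarray  # squared normalized overlaps, descending
    cumulative: np.ndarray  # running sum of overlaps (Bessel-bounded by 1)


def select_modes(modes: ModeSet, target: np.ndarray, k: int = 8) -> ModeSelection:
    """Rank internal modes by contribution to a target displacement.

    The target (coordinate space, shape (N,3) or (3N,)) is mass-weighted
    and normalized; each internal mode's squared projection measures its
    contribution to the motion (e.g. channel opening/closing).  Returns the
    top-k modes with their overlaps and the cumulative contribution.
    """
    t = np.asarray(target, float).ravel()
    if t.size != modes.eigenvectors.shape[0]:
        raise ConfigurationError("target dimension does not match the mode space")
    t_mw = t * np.repeat(np.sqrt(modes.masses), 3)
    norm = np.linalg.norm(t_mw)
    if norm == 0:
        raise ConfigurationError("zero target displacement")
    t_mw /= norm
    internal = modes.internal_indices
    overlaps = (modes.eigenvectors[:, internal].T @ t_mw) ** 2
    if overlaps.max() < 1e-12:
        warnings.warn("target is orthogonal to every retained mode")
    order = np.argsort(overlaps)[::-1][:k]
    ranked = overlaps[order]
    return ModeSelection(
        indices=internal[order],
        overlaps=ranked,
        cumulative=np.cumsum(ranked),
    )


def isotropic_combinations(
    n_modes: int,
    n_replicas: int,
    min_angle_deg: float = 15.0,
    seed: int = 0,
) -> np.ndarray:
    """Unit coefficient vectors spread over the selected-mode subspace.

    Greedy rejection sampling: uniformly random unit vectors are accepted
    when at least ``min_angle_deg`` away from every accepted one.  If the
    requested count is geometrically unreachable the partial result is
    returned with a warning.  One mode admits only the two directions ±1.
    """
    if n_modes < 1:
        raise ConfigurationError("need at least one selected mode")
    if n_modes == 1:
        vecs = np.array([[1.0], [-1.0]])[: max(1, min(n_replicas, 2))]
        if n_replicas > 2:
            warnings.warn("one mode admits only 2 directions; returning 2")
        return vecs
    rng = np.random.default_rng(seed)
    cos_min = math.cos(math.radians(min_angle_deg))
    accepted: list[np.ndarray] = []
    attempts, max_attempts = 0, 2000 * n_replicas
    while len(accepted) < n_replicas and attempts < max_attempts:
        v = rng.normal(size=n_modes)
        v /= np.linalg.norm(v)
        if all(float(np.dot(v, a)) < cos_min for a in accepted):
            accepted.append(v)
        attempts += 1
    if len(accepted) < n_replicas:
        warnings.warn(
            f"min_angle {min_angle_deg}° admits only {len(accepted)} of "
            f"{n_replicas} requested directions"
        )
    return np.array(accepted)


def combination_directions(
    modes: ModeSet, mode_indices: np.ndarray, coefficients: np.ndarray
) -> np.ndarray:
    """Coordinate-space unit directions from mode-coefficient vectors.

    Each coefficient row combines the given modes (mass-weighted space);
    the result is un-mass-weighted and normalized, shape (R, 3N).
    """
    coefficients = np.atleast_2d(np.asarray(coefficients, float))
    basis = modes.eigenvectors[:, np.asarray(mode_indices, int)]  # (3N, k)
    q = coefficients @ basis.T  # (R, 3N) mass-weighted
    x = q / np.repeat(np.sqrt(modes.masses), 3)[None, :]
    return x / np.linalg.norm(x, axis=1)[:, None]


@dataclass
class ExcitationConfig:
    """Replica/excitation bookkeeping and integrator settings."""

    n_replicas: int = 130
    n_excitations: int = 7
    excitation_ps: float = 1.5
    delta_T_K: float = 8.0
    relaxation_ps: float = 400.0
    tail_fraction: float = 0.75  # kept tail of each relaxation (0.3/0.4 ns)
    snapshot_ps: float = 1.0
    dt_fs: float = 2.0
    friction_ps: float = 5.0  # Langevin collision frequency (ps^-1)
    temperature_K: float = 300.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_replicas",
            "n_excitations",
            "excitation_ps",
            "delta_T_K",
            "relaxation_ps",
            "snapshot_ps",
            "dt_fs",
            "friction_ps",
            "temperature_K",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 < self.tail_fraction <= 1.0:
            raise ConfigurationError("tail_fraction must be in (0, 1]")


class _Langevin:
    """BAOAB Langevin integrator on the harmonic pair potential."""

    def __init__(self, system: ENMSystem, config: ExcitationConfig, rng):
        self.i_idx, self.j_idx, self.r0 = system.pair_list()
        if len(self.i_idx) == 0:
            raise ConnectivityError("no springs within the cutoff")
        self.k = system.k_spring
        self.m = system.masses[:, None]
        self.n = system.n_nodes
        self.dt = (config.dt_fs * 1e-3) / AKMA_PS  # AKMA units
        gamma = config.friction_ps * AKMA_PS  # per AKMA unit
        self.c1 = math.exp(-gamma * self.dt)
        self.kT = KB * config.temperature_K
        self.c2 = math.sqrt((1.0 - self.c1**2) * self.kT)
        self.rng = rng

    def forces(self, x: np.ndarray) -> np.ndarray:
        d = x[self.i_idx] - x[self.j_idx]
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        coef = -self.k * (r - self.r0) / r
        fp = coef[:, None] * d
        F = np.empty((self.n, 3))
        for c in range(3):
            F[:, c] = np.bincount(self.i_idx, fp[:, c], self.n) - np.bincount(
                self.j_idx, fp[:, c], self.n
            )
        return F

    def maxwell_boltzmann(self) -> np.ndarray:
        return self.rng.normal(size=(self.n, 3)) * np.sqrt(self.kT / self.m)

    def kinetic_energy(self, v: np.ndarray) -> float:
        return 0.5 * float(np.sum(self.m * v * v))

    def run(self, x, v, n_steps, snapshot_every=0):
        """Integrate in place; optionally collect snapshots (copies)."""
        snaps = []
        F = self.forces(x)
        half = 0.5 * self.dt
        for step in range(n_steps):
            v += half * F / self.m
            x += half * v
            v = self.c1 * v + self.c2 / np.sqrt(self.m) * self.rng.normal(size=v.shape)
            x += half * v
            F = self.forces(x)
            v += half * F / self.m
            if snapshot_every and (step + 1) % snapshot_every == 0:
                snaps.append((step + 1, x.copy(), self.kinetic_energy(v)))
        return x, v, snaps


def _ke_kick(m: np.ndarray, v: np.ndarray, direction: np.ndarray, energy: float) -> np.ndarray:
    """Velocity increment along ``direction`` giving an exact KE jump.

    Solves (a/2)s² + b·s = E for the positive root, where a and b are the
    mass-weighted norms/projections; exact to machine precision including
    the cross term with the instantaneous velocity.
    """
    d = direction.reshape(-1, 3)
    a = float(np.sum(m[:, None] * d * d))
    b = float(np.sum(m[:, None] * v * d))
    s = (-b + math.sqrt(b * b + 2.0 * a * energy)) / a
    return s * d


def excite(
    system: ENMSystem,
    directions: np.ndarray,
    config: ExcitationConfig,
) -> Ensemble:
    """Run the kinetic-excitation protocol; one replica per direction.

    Each replica starts from the reference coordinates with thermal
    velocities; at the start of each of ``n_excitations`` segments a
    velocity increment along the replica's (sign-fixed) direction raises
    the kinetic energy by exactly (3N/2)·k_B·ΔT, then Langevin dynamics
    runs for ``excitation_ps``.  The snapshot at the end of every segment
    is recorded: replicas × excitations structures in total.  The measured
    kinetic-energy jumps are stored in ``metadata['ke_jumps']``.
    """
    directions = np.atleast_2d(np.asarray(directions, float))
    if directions.shape[1] != 3 * system.n_nodes:
        directions = directions.reshape(directions.shape[0], -1)
        if directions.shape[1] != 3 * system.n_nodes:
            raise ConfigurationError("direction dimensionality mismatch")
    directions = directions / np.linalg.norm(directions, axis=1)[:, None]
    if len(directions) != config.n_replicas:
        warnings.warn(
            f"{len(directions)} directions supplied; overriding n_replicas="
            f"{config.n_replicas}"
        )
    rng = np.random.default_rng(config.seed)
    template = system.node_structure()
    n_steps = max(1, int(round(config.excitation_ps * 1e3 / config.dt_fs)))
    energy = 1.5 * system.n_nodes * KB * config.delta_T_K

    frames, provenance, ke_jumps = [], [], []
    for r, d in enumerate(directions):
        integ = _Langevin(system, config, rng)
        x = system.coords.copy()
        v = integ.maxwell_boltzmann()
        sign = 1.0 if rng.random() < 0.5 else -1.0  # fixed per replica
        for e in range(config.n_excitations):
            ke0 = integ.kinetic_energy(v)
            v = v + _ke_kick(system.masses, v, sign * d, energy)
            ke_jumps.append(integ.kinetic_energy(v) - ke0)
            x, v, _ = integ.run(x, v, n_steps)
            if not np.all(np.isfinite(x)) or integ.kinetic_energy(v) > 1e6 * max(energy, 1.0):
                raise IntegrationError(f"replica {r} diverged at excitation {e}")
            frames.append(template.with_coords(x.copy()))
            provenance.append((r, e, len(frames) - 1))
    return Ensemble(
        frames,
        provenance=provenance,
        metadata={
            "ke_jumps": ke_jumps,
            "expected_ke_jump": energy,
            "n_replicas": len(directions),
            "n_excitations": config.n_excitations,
        },
    )


@dataclass
class ClusterSet:
    """RMSD-threshold clustering with per-cluster representatives."""

    labels: np.ndarray  # cluster index per frame
    representatives: list[int]  # frame index of each cluster's representative
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def cluster_rmsd(ensemble: Ensemble, threshold: float = 1.0) -> ClusterSet:
    """Leader-style clustering on pairwise superposed RMSD.

    A frame joins the first cluster whose leader it matches within the
    threshold, else founds a new cluster.  The representative of a cluster
    is the member closest (superposed RMSD) to the cluster's coordinate
    average.
    """
    coords = ensemble.coords_array()
    labels = np.empty(len(ensemble), int)
    leaders: list[int] = []
    for f in range(len(ensemble)):
        assigned = False
        for c, leader in enumerate(leaders):
            _, _, r = kabsch(coords[f], coords[leader])
            if r <= threshold:
                labels[f] = c
                assigned = True
                break
        if not assigned:
            leaders.append(f)
            labels[f] = len(leaders) - 1
    representatives = []
    for c, leader in enumerate(leaders):
        members = np.nonzero(labels == c)[0]
        aligned = []
        for f in members:
            R, t, _ = kabsch(coords[f], coords[leader])
            aligned.append(coords[f] @ R + t)
        mean = np.mean(aligned, axis=0)
        rmsds = [
            math.sqrt(float(np.mean(np.sum((a - mean) ** 2, axis=1)))) for a in aligned
        ]
        representatives.append(int(members[int(np.argmin(rmsds))]))
    return ClusterSet(labels=labels, representatives=representatives, threshold=threshold)


def relax(
    system: ENMSystem,
    representatives: Ensemble | list[Structure],
    config: ExcitationConfig,
) -> Ensemble:
    """Unexcited thermostatted dynamics from each representative.

    Snapshots are taken every ``snapshot_ps``; only the final
    ``tail_fraction`` of each relaxation (where excitation energy has
    dissipated) is pooled into the returned ensemble.  Per-snapshot kinetic
    temperatures are stored in ``metadata['kinetic_temperature_K']``.
    """
    reps = list(representatives)
    rng = np.random.default_rng(config.seed + 1)
    template = system.node_structure()
    total_steps = max(1, int(round(config.relaxation_ps * 1e3 / config.dt_fs)))
    snap_every = max(1, int(round(config.snapshot_ps * 1e3 / config.dt_fs)))
    cut_step = (1.0 - config.tail_fraction) * total_steps

    frames, provenance, temps = [], [], []
    for r, rep in enumerate(reps):
        if rep.natoms != system.n_nodes:
            raise ConfigurationError("representative does not match the ENM nodes")
        integ = _Langevin(system, config, rng)
        x = rep.coords.copy()
        v = integ.maxwell_boltzmann()
        x, v, snaps = integ.run(x, v, total_steps, snapshot_every=snap_every)
        if not np.all(np.isfinite(x)):
            raise IntegrationError(f"representative {r} diverged during relaxation")
        kept = 0
        for step, xc, ke in snaps:
            if step > cut_step:
                frames.append(template.with_coords(xc))
                provenance.append((r, 0, kept))
                temps.append(2.0 * ke / (3.0 * system.n_nodes * KB))
                kept += 1
    return Ensemble(
        frames,
        provenance=provenance,
        metadata={"kinetic_temperature_K": temps, "tail_fraction": config.tail_fraction},
    )
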