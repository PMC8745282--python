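"""Synthetic fixtures with known ground truth.

Everything the analysis pipeline consumes can be generated here with
controllable parameters:

* :func:`build_channel` — a C4-pseudo-symmetric four-chain channel built
  from ideal α-helix geometry (rise 1.5 Å, 100°/residue, Cα radius 2.3 Å):
  a slide helix (35–43) at a requested elevation angle, outer (46–71) and
  inner (109–135) transmembrane helices at requested tilts, pseudo
  side-chain probe atoms at the two gate residues (124, 132) placed so the
  measured opposite-chain apertures equal the request, plus residue 167 in
  the cytoplasmic region — every gating descriptor is computable;
* :func:`sample_ensemble` — conformational ensembles whose per-frame gating
  states are drawn from a specified four-state mixture, with the true
  labels returned alongside;
* :func:`endpoint_pair` — atom-matched open/closed structures whose
  difference vector serves as the gating-mode selection target;
* :func:`hdx_fixture` — peptide uptake tables following single-exponential
  kinetics toward a controllable plateau;
* :func:`simulate_trace` — two-state Markov single-channel currents (one or
  several independent channels for multi-level traces) with Gaussian noise
  and Gaussian low-pass filtering.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Atom, Ensemble, Structure
from .electrophys import Trace, lowpass
from .errors import ConfigurationError, GenerationError, PairingError
from .gating import GateState, K_ION_DIAMETER
from .hdx import PeptideRecord, max_exchangeable

__all__ = [
    "ChannelParams",
    "StateMixture",
    "HDXFixtureSpec",
    "TraceParams",
    "build_channel",
    "sample_ensemble",
    "endpoint_pair",
    "hdx_fixture",
    "simulate_trace",
    "interaction_fixture",
    "study_mixture_w46r",
    "study_mixture_wt",
]

# ideal alpha-helix geometry
HELIX_RISE = 1.5  # Å per residue along the axis
HELIX_TWIST = math.radians(100.0)  # per residue
HELIX_RADIUS = 2.3  # Cα radius, Å

R_INNER = 10.0  # axis distance of inner helices from the pore axis, Å
R_OUTER = 16.0  # axis distance of outer helices, Å
Z_GATE_124 = -2.5  # z height of the 124 gate probes, Å
Z_GATE_132 = -14.0  # z height of the 132 gate probes, Å

CHAINS = ("A", "B", "C", "D")

#: residue names of the positions the analyses talk about; others are GLY.
RESNAMES = {
    35: "ASP",
    36: "ASP",
    38: "TYR",
    43: "THR",
    71: "CYS",
    109: "ALA",
    124: "LEU",
    131: "ILE",
    132: "TYR",
    134: "ARG",
    135: "PHE",
    167: "ARG",
}


def _as_four(value, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, float))
    if arr.size == 1:
        arr = np.repeat(arr, 4)
    if arr.size != 4:
        raise ConfigurationError(f"{name} must be a scalar or length-4 sequence")
    return arr


def _as_pair(value, name: str) -> tuple[float, float]:
    arr = np.atleast_1d(np.asarray(value, float))
    if arr.size == 1:
        return float(arr[0]), float(arr[0])
    if arr.size == 2:
        return float(arr[0]), float(arr[1])
    raise ConfigurationError(f"{name} must be a scalar or an (AC, BD) pair")


@dataclass
class ChannelParams:
    """Controllable geometry of one synthetic channel conformation.

    Angles in degrees (per chain or broadcast scalar); apertures in Å
    (scalar, or an (AC, BD) pair per gate).  ``perturb_sd`` adds isotropic
    Gaussian jitter to every atom, breaking the exact C4 symmetry.
    """

    slide_elevation: float | Sequence[float] = 10.0
    inner_tilt: float | Sequence[float] = 10.0
    outer_tilt: float | Sequence[float] = 25.0
    aperture_124: float | tuple[float, float] = 5.0
    aperture_132: float | tuple[float, float] = 5.0
    perturb_sd: float = 0.0
    seed: int = 0
    mutant: bool = True  # residue 46 is ARG (W46R) rather than TRP

    def __post_init__(self):
        self.slide_elevation = _as_four(self.slide_elevation, "slide_elevation")
        self.inner_tilt = _as_four(self.inner_tilt, "inner_tilt")
        self.outer_tilt = _as_four(self.outer_tilt, "outer_tilt")
        self.aperture_124 = _as_pair(self.aperture_124, "aperture_124")
        self.aperture_132 = _as_pair(self.aperture_132, "aperture_132")
        for ang in (*self.slide_elevation, *self.inner_tilt, *self.outer_tilt):
            if not -90.0 <= ang <= 90.0:
                raise ConfigurationError(f"angle {ang} outside [-90, 90] deg")
        for g in (*self.aperture_124, *self.aperture_132):
            if g <= 0:
                raise ConfigurationError(f"aperture {g} must be positive")
        if self.perturb_sd < 0:
            raise ConfigurationError("perturb_sd must be >= 0")


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180° about any axis perpendicular to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    w = np.cross(u, v)
    wx = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + wx + wx @ wx / (1.0 + c)


def _helix_points(n: int) -> np.ndarray:
    """Ideal helix Cα points, centered, principal axis exactly +Z.

    The raw helix is built along +Z with a phase centered on the middle
    residue; the small principal-axis wobble of a finite helix is removed
    by rotating the point set so its first principal component is exactly
    +Z, oriented first-to-last residue.  This makes generator angles and
    descriptor angles agree by construction.
    """
    t = (np.arange(n) - (n - 1) / 2.0) * HELIX_RISE
    ang = (np.arange(n) - (n - 1) / 2.0) * HELIX_TWIST
    pts = np.column_stack(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), t]
    )
    pts -= pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    return pts @ _rotation_between(axis, np.array([0.0, 0.0, 1.0])).T


def _oriented_helix(n: int, direction: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Helix with n residues whose principal axis is exactly ``direction``
    (oriented resid-ascending), centered at ``center``."""
    base = _helix_points(n)
    R = _rotation_between(np.array([0.0, 0.0, 1.0]), direction)
    return base @ R.T + center


def build_channel(params: ChannelParams) -> Structure:
    """Realize one four-chain channel conformation from its parameters.

    Atom content per chain: Cα for residues 35–43 (slide helix), 46–71
    (outer helix), 109–135 (inner helix), a pseudo side-chain probe (CB)
    at the gate residues 124 and 132, and a Cα for residue 167.  The gate
    probes sit at half the requested aperture from the pore axis at a fixed
    height, so opposite-chain shortest distances reproduce the request
    exactly (zero perturbation).
    """
    atoms: list[Atom] = []
    serial = 1
    g124 = params.aperture_124  # (AC, BD)
    g132 = params.aperture_132

    for k, chain in enumerate(CHAINS):
        phi = math.radians(90.0 * k)
        u_hat = np.array([math.cos(phi), math.sin(phi), 0.0])  # radial
        t_hat = np.array([-math.sin(phi), math.cos(phi), 0.0])  # tangential (ccw)
        elev = math.radians(float(params.slide_elevation[k]))
        ti = math.radians(float(params.inner_tilt[k]))
        to = math.radians(float(params.outer_tilt[k]))

        # slide helix 35-43: runs from near the next chain's sector (35)
        # back to the bottom of its own outer helix (43); elevation above
        # the membrane plane is signed.
        d_slide = math.cos(elev) * (-t_hat) + math.sin(elev) * np.array([0, 0, 1.0])
        anchor43 = R_OUTER * u_hat - 1.5 * t_hat + np.array([0.0, 0.0, -21.0])
        c_slide = anchor43 - ((9 - 1) / 2.0) * HELIX_RISE * d_slide
        slide = _oriented_helix(9, d_slide, c_slide)

        # outer helix 46-71: ascends from the intracellular side
        d_out = math.sin(to) * t_hat + math.cos(to) * np.array([0, 0, 1.0])
        outer = _oriented_helix(26, d_out, R_OUTER * u_hat)

        # inner helix 109-135: descends toward the cytoplasm (resid-ascending
        # direction points down); tilt measured from the membrane normal.
        d_in = math.sin(ti) * t_hat - math.cos(ti) * np.array([0, 0, 1.0])
        inner = _oriented_helix(27, d_in, R_INNER * u_hat)

        def add(name: str, resid: int, xyz: np.ndarray):
            nonlocal serial
            resname = RESNAMES.get(resid, "GLY")
            if resid == 46:
                resname = "ARG" if params.mutant else "TRP"
            atoms.append(Atom(serial, name, "C", resname, resid, chain, xyz))
            serial += 1

        for j, resid in enumerate(range(35, 44)):
            add("CA", resid, slide[j])
        for j, resid in enumerate(range(46, 72)):
            add("CA", resid, outer[j])
        for j, resid in enumerate(range(109, 136)):
            add("CA", resid, inner[j])
            if resid == 124:
                g = g124[0] if chain in ("A", "C") else g124[1]
                add("CB", 124, (g / 2.0) * u_hat + np.array([0, 0, Z_GATE_124]))
            elif resid == 132:
                g = g132[0] if chain in ("A", "C") else g132[1]
                add("CB", 132, (g / 2.0) * u_hat + np.array([0, 0, Z_GATE_132]))
        # cytoplasmic residue 167
        phi167 = phi + math.radians(45.0)
        add(
            "CA",
            167,
            np.array([14.0 * math.cos(phi167), 14.0 * math.sin(phi167), -30.0]),
        )

    structure = Structure.from_atoms(atoms)
    if params.perturb_sd > 0:
        rng = np.random.default_rng(params.seed)
        structure.coords += rng.normal(0.0, params.perturb_sd, structure.coords.shape)
        # a probe pushed across the pore axis would invert its aperture
        for i in range(structure.natoms):
            if structure.name[i] == "CB":
                phi = math.radians(90.0 * CHAINS.index(structure.chain[i]))
                u_hat = np.array([math.cos(phi), math.sin(phi), 0.0])
                if float(structure.coords[i] @ u_hat) <= 0:
                    raise GenerationError(
                        "perturbation pushed a gate probe across the pore axis; "
                        "reduce perturb_sd or increase the apertures"
                    )
    return structure


# ---------------------------------------------------------------------------
# state mixtures and ensembles
# ---------------------------------------------------------------------------

@dataclass
class StateMixture:
    """Four-state population mixture with aperture sampling intervals.

    Intervals must keep a safety margin from the 3.53 Å open/closed
    threshold so that sampled frames are unambiguous.
    """

    probabilities: Sequence[float]  # (fully_open, fully_closed, half_1, half_2)
    open_interval: tuple[float, float] = (3.8, 8.0)
    closed_interval: tuple[float, float] = (2.5, 3.3)
    margin: float = 0.2

    def __post_init__(self):
        p = np.asarray(self.probabilities, float)
        if p.size != 4 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ConfigurationError(
                "probabilities must be 4 non-negative numbers summing to 1"
            )
        self.probabilities = p
        lo_o, hi_o = self.open_interval
        lo_c, hi_c = self.closed_interval
        if not (lo_o < hi_o and lo_c < hi_c):
            raise ConfigurationError("intervals must be non-empty")
        if hi_c > K_ION_DIAMETER - self.margin:
            raise ConfigurationError(
                f"closed interval must stay below {K_ION_DIAMETER - self.margin:.2f} Å"
            )
        if lo_o < K_ION_DIAMETER + self.margin:
            raise ConfigurationError(
                f"open interval must stay above {K_ION_DIAMETER + self.margin:.2f} Å"
            )


#: Four-state populations of the study ensembles (percent / 100), in the
#: order (fully open, fully closed, half-open 1, half-open 2).
def study_mixture_w46r(**kwargs) -> StateMixture:
    """The W46R mutant's relaxed-ensemble state mixture."""
    return StateMixture(probabilities=(0.074, 0.493, 0.325, 0.108), **kwargs)


def study_mixture_wt(**kwargs) -> StateMixture:
    """The wild-type relaxed-ensemble state mixture."""
    return StateMixture(probabilities=(0.068, 0.502, 0.288, 0.142), **kwargs)


_STATE_ORDER = (
    GateState.FULLY_OPEN,
    GateState.FULLY_CLOSED,
    GateState.HALF_OPEN_1,
    GateState.HALF_OPEN_2,
)


def sample_ensemble(
    mixture: StateMixture,
    n: int,
    params: ChannelParams | None = None,
    seed: int = 0,
) -> tuple[Ensemble, list[GateState]]:
    """Draw an ensemble whose frames follow the given state mixture.

    Each frame's state is drawn independently; both the A–C and B–D
    apertures of an open (closed) gate are drawn uniformly from the open
    (closed) interval.  Returns the ensemble together with the true labels.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    params = params or ChannelParams()
    rng = np.random.default_rng(seed)
    template = build_channel(params)

    # probe atom indices, in gate/pair order: (124,A),(124,B),(124,C),(124,D),(132,...)
    probe_idx: dict[tuple[int, str], int] = {}
    for i in range(template.natoms):
        if template.name[i] == "CB":
            probe_idx[(int(template.resid[i]), template.chain[i])] = i

    states = rng.choice(4, size=n, p=np.asarray(mixture.probabilities))
    lo_o, hi_o = mixture.open_interval
    lo_c, hi_c = mixture.closed_interval

    def draw(open_: bool, size: int) -> np.ndarray:
        return rng.uniform(lo_o, hi_o, size) if open_ else rng.uniform(lo_c, hi_c, size)

    open124 = np.isin(states, [0, 2])  # fully open or half-open 1
    open132 = np.isin(states, [0, 3])  # fully open or half-open 2
    g = {}
    for gate, open_mask in ((124, open124), (132, open132)):
        for pair in ("ac", "bd"):
            vals = np.empty(n)
            vals[open_mask] = draw(True, int(open_mask.sum()))
            vals[~open_mask] = draw(False, int((~open_mask).sum()))
            g[(gate, pair)] = vals

    u_hats = {c: np.array([math.cos(math.radians(90 * k)), math.sin(math.radians(90 * k)), 0.0])
              for k, c in enumerate(CHAINS)}
    z_gate = {124: Z_GATE_124, 132: Z_GATE_132}
    frames = []
    jitter = params.perturb_sd
    for f in range(n):
        coords = template.coords.copy()
        if jitter > 0:
            coords += rng.normal(0.0, jitter, coords.shape)
        for gate in (124, 132):
            for chain in CHAINS:
                pair = "ac" if chain in ("A", "C") else "bd"
                half = g[(gate, pair)][f] / 2.0
                coords[probe_idx[(gate, chain)]] = u_hats[chain] * half + [0, 0, z_gate[gate]]
        frames.append(template.with_coords(coords))

    labels = [_STATE_ORDER[s] for s in states]
    ensemble = Ensemble(
        frames,
        provenance=[(0, 0, i) for i in range(n)],
        metadata={
            "true_labels": labels,
            "mixture": tuple(float(p) for p in mixture.probabilities),
            "seed": seed,
        },
    )
    return ensemble, labels


def endpoint_pair(
    open_params: ChannelParams, closed_params: ChannelParams
) -> tuple[Structure, Structure]:
    """Atom-matched open and closed endpoint structures.

    Their coordinate difference (closed → open) is the natural target for
    gating-mode selection.
    """
    s_open = build_channel(open_params)
    s_closed = build_channel(closed_params)
    if not s_open.same_atoms(s_closed):
        raise PairingError("endpoint parameterizations yield different atom sets")
    return s_open, s_closed


# ---------------------------------------------------------------------------
# HDX fixtures
# ---------------------------------------------------------------------------

@dataclass
class HDXFixtureSpec:
    """Synthetic peptide set with single-exponential uptake kinetics.

    ``peptides`` are (sequence, start, end) triples and ``targets`` the
    per-peptide plateau exchange in percent of the observable maximum (the
    analysis-side normalization: max-exchangeable amides × labeling
    deuterium fraction).  ``rate_constant`` is the shared intrinsic
    exchange rate (min⁻¹); mass noise is Gaussian on each centroid.
    """

    peptides: list[tuple[str, int, int]]
    targets: list[float]
    times: Sequence[float] = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0)
    rate_constant: float = 5.0  # min^-1
    noise_sd: float = 0.0  # Da
    deuterium_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if len(self.peptides) != len(self.targets):
            raise ConfigurationError("one target per peptide required")
        for t in self.targets:
            if not 0.0 <= t <= 100.0:
                raise ConfigurationError(f"target {t} outside [0, 100] %")
        times = np.asarray(self.times, float)
        if times.size < 2 or np.any(np.diff(times) <= 0):
            raise ConfigurationError("need >= 2 strictly ascending time points")
        self.times = times


def _peptide_m0(sequence: str) -> float:
    from Bio.SeqUtils import molecular_weight

    return float(molecular_weight(sequence, seq_type="protein"))


def hdx_fixture(spec: HDXFixtureSpec) -> list[PeptideRecord]:
    """Generate peptide records with known plateau exchange.

    m(t) = m0 + maxD · fraction · (target/100) · (1 − exp(−k·t)) + noise,
    where maxD is the exchangeable-amide count; the labeling deuterium
    fraction enters the generated masses exactly as the analysis removes it,
    so noise-free fixtures round-trip to their target.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for (seq, start, end), target in zip(spec.peptides, spec.targets):
        m0 = _peptide_m0(seq)
        maxd = max_exchangeable(seq)
        plateau = maxd * spec.deuterium_fraction * target / 100.0
        masses = m0 + plateau * (1.0 - np.exp(-spec.rate_constant * spec.times))
        if spec.noise_sd > 0:
            masses = masses + rng.normal(0.0, spec.noise_sd, masses.shape)
        records.append(
            PeptideRecord(
                sequence=seq, start=start, end=end,
                times=spec.times.copy(), masses=masses, m0=m0,
            )
        )
    return records


_SEQ_ALPHABET = "ADEFGHIKLMNQRSTVWY"  # proline-free to keep maxD = len - 1


def synthetic_sequence(start: int, end: int) -> str:
    """Deterministic proline-free sequence for a residue stretch."""
    return "".join(
        _SEQ_ALPHABET[(start * 7 + i * 3) % len(_SEQ_ALPHABET)]
        for i in range(end - start + 1)
    )


#: Stretches and normalized rates observed for the mutant vs wild type,
#: usable directly as fixture targets (sequence, start, end) -> (mut, wt).
STUDY_STRETCH_RATES: dict[tuple[int, int], tuple[float, float]] = {
    (36, 42): (41.57, 26.92),
    (43, 56): (37.9, 65.1),
    (93, 112): (50.04, 30.08),
    (131, 143): (77.32, 61.26),
    (162, 174): (94.61, 83.1),
    (250, 260): (62.05, 55.25),
}


def study_peptides(which: str = "mutant") -> HDXFixtureSpec:
    """Fixture spec reproducing the study's reported per-stretch rates."""
    col = {"mutant": 0, "wt": 1}[which]
    peptides, targets = [], []
    for (start, end), rates in STUDY_STRETCH_RATES.items():
        peptides.append((synthetic_sequence(start, end), start, end))
        targets.append(rates[col])
    return HDXFixtureSpec(peptides=peptides, targets=targets, rate_constant=50.0)


# ---------------------------------------------------------------------------
# single-channel traces
# ---------------------------------------------------------------------------

@dataclass
class TraceParams:
    """Two-state Markov single-channel trace parameters.

    ``levels_pA`` lists the conductance-level amplitudes including the
    baseline; with more than two levels, len(levels)−1 identical
    independent channels are simulated and the occupied level is the number
    of simultaneously open channels.  Either ``po`` (with ``close_rate``)
    or both rates fix the gating kinetics; the stationary open probability
    of each channel is opening/(opening+closing).
    """

    levels_pA: Sequence[float] = (0.0, 3.6)
    open_rate: float | None = None  # s^-1 (closed -> open)
    close_rate: float = 50.0  # s^-1 (open -> closed)
    po: float | None = None
    noise_sd: float = 0.5  # pA, before filtering
    dt_us: float = 100.0
    filter_khz: float | None = 1.25
    duration_s: float = 10.0
    potential_mV: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.dt_us <= 0 or self.duration_s <= 0:
            raise ConfigurationError("sampling interval and duration must be positive")
        if len(self.levels_pA) < 2:
            raise ConfigurationError("need a baseline and at least one open level")
        if self.po is None and self.open_rate is None:
            raise ConfigurationError("give either po or open_rate")
        if self.po is not None and not 0.0 <= self.po <= 1.0:
            raise ConfigurationError("po must be in [0, 1]")
        if self.close_rate <= 0:
            raise ConfigurationError("close_rate must be positive")

    @property
    def stationary_po(self) -> float:
        if self.po is not None:
            return self.po
        return self.open_rate / (self.open_rate + self.close_rate)

    @property
    def resolved_open_rate(self) -> float:
        if self.open_rate is not None:
            return self.open_rate
        if self.po >= 1.0:
            return math.inf
        return self.close_rate * self.po / (1.0 - self.po)


def _channel_open_fraction(
    rng: np.random.Generator,
    ko: float,
    kc: float,
    duration: float,
    sample_times: np.ndarray,
) -> tuple[np.ndarray, list[tuple[bool, float]]]:
    """Sampled open/closed state of one channel plus its dwell sequence."""
    if ko == 0:
        return np.zeros(sample_times.size, bool), [(False, duration)]
    if not math.isfinite(ko):
        return np.ones(sample_times.size, bool), [(True, duration)]
    # start from the stationary distribution
    state_open = bool(rng.random() < ko / (ko + kc))
    t, events, states = 0.0, [0.0], [state_open]
    dwells: list[tuple[bool, float]] = []
    while t < duration:
        rate = kc if state_open else ko
        dwell = rng.exponential(1.0 / rate)
        dwells.append((state_open, min(dwell, duration - t)))
        t += dwell
        events.append(t)
        state_open = not state_open
        states.append(state_open)
    idx = np.searchsorted(np.asarray(events), sample_times, side="right") - 1
    open_at = np.asarray(states, bool)[idx]
    return open_at, dwells


def simulate_trace(params: TraceParams) -> Trace:
    """Simulate a filtered, noisy single-channel current trace.

    The trace's ``meta`` carries the ground truth: the noise-free level
    index per sample (``true_levels``), the generating stationary open
    probability, and the per-channel dwell fraction actually realized.
    """
    rng = np.random.default_rng(params.seed)
    n_samples = int(round(params.duration_s / (params.dt_us * 1e-6)))
    times = np.arange(n_samples) * params.dt_us * 1e-6
    n_channels = len(params.levels_pA) - 1
    ko, kc = params.resolved_open_rate, params.close_rate

    open_count = np.zeros(n_samples, dtype=int)
    dwell_open_time = 0.0
    for _ in range(n_channels):
        open_at, dwells = _channel_open_fraction(rng, ko, kc, params.duration_s, times)
        open_count += open_at
        dwell_open_time += sum(d for is_open, d in dwells if is_open)

    levels = np.asarray(params.levels_pA, float)
    clean = levels[open_count]
    current = clean + rng.normal(0.0, params.noise_sd, n_samples) if params.noise_sd > 0 else clean.copy()

    trace = Trace(
        dt_us=params.dt_us,
        current=current,
        potential_mV=params.potential_mV,
        label=f"synthetic Po={params.stationary_po:g}",
        meta={
            "true_levels": open_count,
            "generating_po": params.stationary_po,
            "dwell_open_fraction": dwell_open_time / (n_channels * params.duration_s),
            "unitary_pA": float(levels[1] - levels[0]),
        },
    )
    if params.filter_khz is not None:
        trace = lowpass(trace, params.filter_khz)
        trace.meta.update(
            true_levels=open_count,
            generating_po=params.stationary_po,
            dwell_open_fraction=dwell_open_time / (n_channels * params.duration_s),
            unitary_pA=float(levels[1] - levels[0]),
        )
    return trace


# ---------------------------------------------------------------------------
# interaction-network fixtures
# ---------------------------------------------------------------------------

def interaction_fixture(kind: str) -> Structure:
    """Minimal probe structures for contact-network tests.

    ``kind='flipped_in'``: the residue-46 side-chain probe of chain C packs
    against residues 134 and 135 at the bottom of the neighboring inner
    helix — the wild-type, pore-facing rotamer.  ``kind='mutant'``: the
    arginine-like residue-46 probe points away from the pore and contacts
    residues 36 and 38 on the slide helix of the n−1 chain.  Both variants
    contain the same residue set so their networks are directly
    comparable.
    """
    if kind not in ("flipped_in", "mutant"):
        raise ConfigurationError("kind must be 'flipped_in' or 'mutant'")
    mutant = kind == "mutant"

    def res(chain, resid, resname, ca, cb):
        return [
            Atom(0, "CA", "C", resname, resid, chain, np.asarray(ca, float)),
            Atom(0, "CB", "C", resname, resid, chain, np.asarray(cb, float)),
        ]

    # fixed partner positions; only the 46 side-chain probe moves
    atoms: list[Atom] = []
    atoms += res("B", 36, "ASP", (8.0, 6.0, 0.0), (8.0, 5.0, 0.0))
    atoms += res("B", 38, "TYR", (11.0, 6.0, 0.0), (11.0, 5.0, 0.0))
    atoms += res("B", 134, "ARG", (8.0, -6.0, 0.0), (8.0, -5.0, 0.0))
    atoms += res("B", 135, "PHE", (11.0, -6.0, 0.0), (11.0, -5.0, 0.0))
    ca46 = (9.5, 0.0, 0.0)
    cb46 = (9.5, 2.0, 0.0) if mutant else (9.5, -2.0, 0.0)
    atoms += res("C", 46, "ARG" if mutant else "TRP", ca46, cb46)
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    return Structure.from_atoms(atoms)
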