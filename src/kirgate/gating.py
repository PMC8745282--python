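"""Four-state open/closed classification and backbone superposition.

A K⁺ ion of diameter 3.53 Å must pass both pore constrictions (residues
124 and 132).  A gate is *open* when its shortest opposite-chain distance
strictly exceeds that diameter; the four combinations of the two gates
define the states: fully open, fully closed, half-open 1 (124 open / 132
closed) and half-open 2 (132 open / 124 closed).  Per frame, each gate's
aperture is the minimum over the A–C and B–D opposite-chain pairs: ion
conduction is limited by the narrowest point.

Ties (distance exactly equal to the diameter) classify as closed — the
conservative reading of "larger than the ionic diameter".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .core import Ensemble, Structure
from .descriptors import gate_distances
from .errors import (
    EmptyInputError,
    InsufficientAtomsError,
    InvalidMeasurementError,
)

__all__ = [
    "GateState",
    "StatePopulations",
    "K_ION_DIAMETER",
    "classify_state",
    "classify_frame",
    "populations",
    "superpose_rmsd",
]

#: Diameter of a non-hydrated K+ ion (Å), the open/closed threshold.
K_ION_DIAMETER = 3.53

#: Atom names making up the peptide backbone for superposition purposes.
BACKBONE_NAMES = ("N", "CA", "C", "O")


class GateState(Enum):
    FULLY_OPEN = "fully_open"
    FULLY_CLOSED = "fully_closed"
    HALF_OPEN_1 = "half_open_1"  # 124 open, 132 closed
    HALF_OPEN_2 = "half_open_2"  # 132 open, 124 closed


#: Human-readable row labels used in population reports.
STATE_LABELS = {
    GateState.FULLY_OPEN: "Fully open",
    GateState.FULLY_CLOSED: "Fully closed",
    GateState.HALF_OPEN_1: "Half open 1 (124 open, 132 closed)",
    GateState.HALF_OPEN_2: "Half open 2 (132 open, 124 closed)",
}


def classify_state(g124: float, g132: float, diameter: float = K_ION_DIAMETER) -> GateState:
    """Map one (g124, g132) aperture pair to its gating state."""
    if math.isnan(g124) or math.isnan(g132):
        raise InvalidMeasurementError("gate distance is NaN")
    if g124 < 0 or g132 < 0:
        raise InvalidMeasurementError("gate distance is negative")
    open124 = g124 > diameter
    open132 = g132 > diameter
    if open124 and open132:
        return GateState.FULLY_OPEN
    if open124:
        return GateState.HALF_OPEN_1
    if open132:
        return GateState.HALF_OPEN_2
    return GateState.FULLY_CLOSED


def classify_frame(
    structure: Structure,
    diameter: float = K_ION_DIAMETER,
    gate_rule: str = "min",
    mode: str = "shortest",
) -> GateState:
    """Classify one conformation from its coordinates.

    ``gate_rule='min'`` compares the narrower of the A–C / B–D apertures to
    the threshold; ``'both'`` requires each pair to clear it individually
    (for strictly positive distances the two rules coincide, the flag exists
    so the convention is explicit and auditable).
    """
    g124ac, g124bd, g132ac, g132bd = gate_distances(structure, mode=mode)
    if gate_rule == "min":
        return classify_state(min(g124ac, g124bd), min(g132ac, g132bd), diameter)
    if gate_rule == "both":
        open124 = g124ac > diameter and g124bd > diameter
        open132 = g132ac > diameter and g132bd > diameter
        if open124 and open132:
            return GateState.FULLY_OPEN
        if open124:
            return GateState.HALF_OPEN_1
        if open132:
            return GateState.HALF_OPEN_2
        return GateState.FULLY_CLOSED
    raise ValueError("gate_rule must be 'min' or 'both'")


@dataclass
class StatePopulations:
    """Ensemble state fractions (percent) at a given threshold."""

    fractions: dict[GateState, float]
    counts: dict[GateState, int]
    n_frames: int
    threshold: float

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"state fractions sum to {total}, not 100")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "state": STATE_LABELS[s],
                "percent": self.fractions[s],
                "count": self.counts[s],
            }
            for s in GateState
        ]
        return pd.DataFrame(rows)


def populations(
    ensemble: Ensemble,
    diameter: float = K_ION_DIAMETER,
    gate_rule: str = "min",
    mode: str = "shortest",
) -> StatePopulations:
    """Classify every frame and report per-state percentages."""
    if len(ensemble) == 0:
        raise EmptyInputError("empty ensemble")
    counts = {s: 0 for s in GateState}
    for frame in ensemble:
        counts[classify_frame(frame, diameter, gate_rule, mode)] += 1
    n = len(ensemble)
    fractions = {s: 100.0 * counts[s] / n for s in GateState}
    return StatePopulations(fractions=fractions, counts=counts, n_frames=n, threshold=diameter)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set A onto B.

    Returns ``(R, t, rmsd)`` with the proper rotation R and translation t
    such that ``A @ R + t`` best matches B.  The reflection branch of the
    SVD solution is rejected.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = cb - ca @ R
    diff = (A @ R + t) - B
    rmsd = math.sqrt(float(np.einsum("ij,ij->", diff, diff)) / len(A))
    return R, t, rmsd


def _matched_indices(a: Structure, b: Structure, names) -> tuple[np.ndarray, np.ndarray]:
    keyed_b = {}
    for i in range(b.natoms):
        if not b.het[i] and (names is None or b.name[i] in names):
            keyed_b[(b.chain[i], int(b.resid[i]), b.name[i])] = i
    ia, ib = [], []
    for i in range(a.natoms):
        if a.het[i] or (names is not None and a.name[i] not in names):
            continue
        j = keyed_b.get((a.chain[i], int(a.resid[i]), a.name[i]))
        if j is not None:
            ia.append(i)
            ib.append(j)
    return np.array(ia, int), np.array(ib, int)


def superpose_rmsd(
    struct_a: Structure,
    struct_b: Structure,
    atom_subset: str | tuple[str, ...] = "backbone",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal-superposition RMSD over matched atoms.

    Atoms are matched by their (chain, resid, name) identity;
    ``atom_subset`` may be ``'backbone'`` (N, CA, C, O), ``'all'``, or an
    explicit tuple of atom names.  Returns ``(rmsd, rotation, translation)``
    mapping ``struct_a`` onto ``struct_b``.
    """
    if atom_subset == "backbone":
        names: tuple[str, ...] | None = BACKBONE_NAMES
    elif atom_subset == "all":
        names = None
    else:
        names = tuple(atom_subset)
    ia, ib = _matched_indices(struct_a, struct_b, names)
    if ia.size < 3:
        raise InsufficientAtomsError(
            f"only {ia.size} matched atoms between structures (need >= 3)"
        )
    R, t, rmsd = kabsch(struct_a.coords[ia], struct_b.coords[ib])
    return rmsd, R, t
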