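"""Per-frame structural determinants of channel gating.

For each conformation of a tetrameric Kir-type channel the module computes:

* slide-helix *upward angles* ``upa``–``upd`` — the signed elevation of the
  slide-helix axis (residues 35–43, oriented resid-ascending) above the
  membrane plane (XY); the higher the value, the closer the helix is to the
  membrane;
* transmembrane *tilt angles* ``tilt_in_*`` / ``tilt_out_*`` — the angle
  between an inner (109–135) or outer (46–71) helix axis and the membrane
  normal (+Z), in [0°, 90°];
* *gate distances* ``g124ac``, ``g124bd``, ``g132ac``, ``g132bd`` — shortest
  opposite-chain heavy-atom distances at the two pore constriction points
  (residues 124 and 132);
* inter-chain coupling distances ``d46n36(n−1)`` and ``d35n167(n+1)`` with
  cyclic chain arithmetic A→B→C→D;
* solvent-accessible surface areas (Shrake–Rupley);
* Pearson correlation matrices over any selection of these columns.

Helix axes are taken as the first principal component of the Cα
coordinates, oriented from the lowest- toward the highest-numbered residue
so that elevation angles are signed and comparable across frames.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core import Ensemble, Selection, Structure, next_chain, prev_chain, select
from .errors import (
    EmptySelectionError,
    InsufficientAtomsError,
    KirgateError,
    NoVarianceError,
)

__all__ = [
    "HelixSpec",
    "CorrelationMatrix",
    "helix_axis",
    "upward_angle",
    "tilt_angle",
    "shortest_distance",
    "gate_distances",
    "sasa",
    "descriptor_table",
    "pearson_matrix",
    "BONDI_RADII",
    "resolve_column",
]

#: Default residue ranges of the three helix classes (KirBac3.1 numbering).
HELIX_RANGES = {"slide": (35, 43), "inner": (109, 135), "outer": (46, 71)}

#: Bondi van der Waals radii (Å); unknown elements fall back to 1.7 Å.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "K": 2.75,
    "NA": 2.27,
    "MG": 1.73,
}
FALLBACK_RADIUS = 1.70


@dataclass
class HelixSpec:
    """Identifies one helix: chain, inclusive resid range and kind."""

    chain: str
    kind: str = "inner"
    resid_range: tuple[int, int] | None = None

    def __post_init__(self):
        if self.kind not in HELIX_RANGES:
            raise ValueError(f"unknown helix kind {self.kind!r}")
        if self.resid_range is None:
            self.resid_range = HELIX_RANGES[self.kind]


def helix_axis(structure: Structure, spec: HelixSpec) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component axis of a helix's Cα trace.

    Returns ``(axis, centroid)`` with the unit axis oriented from the
    lowest-resid Cα toward the highest-resid Cα.
    """
    idx = select(
        structure,
        Selection(chain=spec.chain, resid_range=spec.resid_range, names={"CA"}),
    )
    if idx.size < 4:
        raise InsufficientAtomsError(
            f"helix {spec.kind} chain {spec.chain}: {idx.size} Cα atoms (< 4)"
        )
    order = np.argsort(structure.resid[idx])
    coords = structure.coords[idx[order]]
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis), centroid


def upward_angle(structure: Structure, chain: str) -> float:
    """Signed elevation (deg) of the slide-helix axis above the XY plane."""
    axis, _ = helix_axis(structure, HelixSpec(chain=chain, kind="slide"))
    return math.degrees(math.asin(float(np.clip(axis[2], -1.0, 1.0))))


def tilt_angle(structure: Structure, chain: str, kind: str = "inner") -> float:
    """Tilt (deg, in [0, 90]) of a TM helix axis from the membrane normal."""
    if kind not in ("inner", "outer"):
        raise ValueError("tilt is defined for inner/outer helices")
    axis, _ = helix_axis(structure, HelixSpec(chain=chain, kind=kind))
    return math.degrees(math.acos(float(np.clip(abs(axis[2]), 0.0, 1.0))))


def shortest_distance(
    structure: Structure,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    heavy_only: bool = True,
) -> float:
    """Minimum Euclidean distance (Å) between any atom pair of two residues."""
    if res_a == res_b:
        warnings.warn(f"shortest_distance of residue {res_a} against itself is 0")
        return 0.0
    ia = structure.residue_indices(*res_a)
    ib = structure.residue_indices(*res_b)
    if heavy_only:
        ia = ia[[structure.element[i].upper() != "H" for i in ia]]
        ib = ib[[structure.element[i].upper() != "H" for i in ib]]
    if ia.size == 0 or ib.size == 0:
        raise EmptySelectionError(f"no heavy atoms for {res_a} or {res_b}")
    return float(cdist(structure.coords[ia], structure.coords[ib]).min())


def gate_distances(
    structure: Structure, mode: str = "shortest"
) -> tuple[float, float, float, float]:
    """Opposite-chain apertures ``(g124ac, g124bd, g132ac, g132bd)`` in Å.

    ``mode='shortest'`` uses all heavy atoms of each gate residue;
    ``mode='ca'`` restricts to Cα atoms (the variant plotted in aperture
    scatter plots).
    """
    if mode not in ("shortest", "ca"):
        raise ValueError("mode must be 'shortest' or 'ca'")
    out = []
    for resid in (124, 132):
        for pair in (("A", "C"), ("B", "D")):
            if mode == "ca":
                ia = select(structure, Selection(chain=pair[0], resid_range=(resid, resid), names={"CA"}))
                ib = select(structure, Selection(chain=pair[1], resid_range=(resid, resid), names={"CA"}))
                out.append(float(cdist(structure.coords[ia], structure.coords[ib]).min()))
            else:
                out.append(shortest_distance(structure, (pair[0], resid), (pair[1], resid)))
    return tuple(out)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere point set (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    structure: Structure,
    residues: list[tuple[str, int]] | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> dict[tuple[str, int], float]:
    """Shrake–Rupley accessible surface area per residue (Å²).

    Each atom is sampled with ``n_points`` sphere points at radius
    r_vdW + probe; points inside any other atom's expanded sphere are
    occluded.  Residue ASA is the sum over its atoms.  ``residues=None``
    computes every protein residue.
    """
    mask = ~structure.het
    idx_all = np.nonzero(mask)[0]
    coords = structure.coords[idx_all]
    radii = np.array(
        [BONDI_RADII.get(structure.element[i].upper(), FALLBACK_RADIUS) for i in idx_all]
    )
    expanded = radii + probe
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    per_atom = np.zeros(len(idx_all))
    for a in range(len(idx_all)):
        pts = coords[a] + expanded[a] * sphere
        neighbors = tree.query_ball_point(coords[a], expanded[a] + max_r)
        neighbors = [j for j in neighbors if j != a]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > expanded[j] ** 2
        per_atom[a] = 4.0 * math.pi * expanded[a] ** 2 * accessible.sum() / n_points
    result: dict[tuple[str, int], float] = {}
    for pos, i in enumerate(idx_all):
        key = (structure.chain[i], int(structure.resid[i]))
        result[key] = result.get(key, 0.0) + per_atom[pos]
    if residues is not None:
        missing = [r for r in residues if r not in result]
        if missing:
            raise EmptySelectionError(f"residues absent from structure: {missing}")
        result = {r: result[r] for r in residues}
    return result


# ---------------------------------------------------------------------------
# descriptor tables & correlations
# ---------------------------------------------------------------------------

CHAINS = ("A", "B", "C", "D")


def descriptor_columns(include_asa: bool = False, asa_resids=(46, 131, 134, 135)) -> list[str]:
    cols = [f"up{c.lower()}" for c in CHAINS]
    cols += [f"tilt_in_{c.lower()}" for c in CHAINS]
    cols += [f"tilt_out_{c.lower()}" for c in CHAINS]
    cols += ["g124ac", "g124bd", "g132ac", "g132bd"]
    cols += [f"d46{c.lower()}36{prev_chain(c).lower()}" for c in CHAINS]
    cols += [f"d35{c.lower()}167{next_chain(c).lower()}" for c in CHAINS]
    if include_asa:
        cols += [f"asa{r}{c.lower()}" for r in asa_resids for c in CHAINS]
    return cols


def _frame_descriptors(s: Structure, include_asa, asa_resids, gate_mode) -> dict[str, float]:
    row: dict[str, float] = {}
    for c in CHAINS:
        row[f"up{c.lower()}"] = upward_angle(s, c)
    for c in CHAINS:
        row[f"tilt_in_{c.lower()}"] = tilt_angle(s, c, "inner")
    for c in CHAINS:
        row[f"tilt_out_{c.lower()}"] = tilt_angle(s, c, "outer")
    g = gate_distances(s, mode=gate_mode)
    row["g124ac"], row["g124bd"], row["g132ac"], row["g132bd"] = g
    for c in CHAINS:
        row[f"d46{c.lower()}36{prev_chain(c).lower()}"] = shortest_distance(
            s, (c, 46), (prev_chain(c), 36)
        )
    for c in CHAINS:
        row[f"d35{c.lower()}167{next_chain(c).lower()}"] = shortest_distance(
            s, (c, 35), (next_chain(c), 167)
        )
    if include_asa:
        wanted = [(c, r) for r in asa_resids for c in CHAINS]
        areas = sasa(s, residues=wanted)
        for (c, r), v in areas.items():
            row[f"asa{r}{c.lower()}"] = v
    return row


def descriptor_table(
    ensemble: Ensemble,
    include_asa: bool = False,
    asa_resids: tuple[int, ...] = (46, 131, 134, 135),
    gate_mode: str = "shortest",
    max_failure_fraction: float = 0.01,
) -> pd.DataFrame:
    """One row of structural determinants per frame.

    Frames whose descriptors cannot be computed are recorded in
    ``df.attrs['failures']``; the call hard-fails if they exceed
    ``max_failure_fraction`` of the ensemble.
    """
    rows, failures, kept = [], [], []
    for i, frame in enumerate(ensemble):
        try:
            rows.append(_frame_descriptors(frame, include_asa, asa_resids, gate_mode))
            kept.append(i)
        except KirgateError as exc:
            failures.append((i, str(exc)))
    if len(failures) > max_failure_fraction * len(ensemble):
        raise KirgateError(
            f"{len(failures)}/{len(ensemble)} frames unusable; first: {failures[0]}"
        )
    df = pd.DataFrame(rows, index=kept)
    df.attrs["failures"] = failures
    return df


#: aliases accepted on input for the tilt columns (two naming conventions
#: circulate for the same quantities).
def resolve_column(name: str) -> str:
    n = name.lower()
    for c in "abcd":
        if n == f"incli{c}" or n == f"tilti{c}":
            return f"tilt_in_{c}"
        if n == f"inclo{c}" or n == f"tilto{c}":
            return f"tilt_out_{c}"
    return name


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with its column labels."""

    labels: list[str]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def plot(self, path: str) -> None:
        """Circle-matrix rendering (diameter/intensity ∝ |r|); optional."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(self.labels)
        fig, ax = plt.subplots(figsize=(0.4 * n + 2, 0.4 * n + 2))
        for i in range(n):
            for j in range(n):
                r = self.values[i, j]
                color = "tab:blue" if r >= 0 else "tab:red"
                ax.scatter(j, n - 1 - i, s=250 * abs(r), c=color, alpha=min(1.0, 0.2 + 0.8 * abs(r)))
        ax.set_xticks(range(n), self.labels, rotation=90, fontsize=7)
        ax.set_yticks(range(n), self.labels[::-1], fontsize=7)
        ax.set_xlim(-0.5, n - 0.5)
        ax.set_ylim(-0.5, n - 0.5)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def pearson_matrix(
    table: pd.DataFrame, columns: list[str] | None = None
) -> CorrelationMatrix:
    """Pearson correlation matrix over selected descriptor columns.

    Constant columns are excluded with a warning; an all-constant selection
    raises.  Accepts both the ``tilt_in_a`` and the ``inclia``/``tiltia``
    naming conventions.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    else:
        columns = [resolve_column(c) for c in columns]
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    if len(table) < 3:
        raise KirgateError("need at least 3 rows for a correlation matrix")
    data = table[columns].to_numpy(dtype=float)
    variances = data.var(axis=0)
    keep = variances > 0
    if not keep.any():
        raise NoVarianceError("all selected columns are constant")
    if not keep.all():
        dropped = [c for c, k in zip(columns, keep) if not k]
        warnings.warn(f"constant columns excluded from correlation: {dropped}")
    labels = [c for c, k in zip(columns, keep) if k]
    r = np.corrcoef(data[:, keep], rowvar=False)
    r = np.atleast_2d(r)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(labels=labels, values=r)
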