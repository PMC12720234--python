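"""Potential-energy-distribution style categorization of normal modes.

Each mode's Cartesian displacement is projected onto a redundant set of
internal coordinates (bond stretches, angle bends, proper torsions and
out-of-plane coordinates at trigonal centers) perceived from the equilibrium
geometry. The squared projection onto each coordinate's first-order
displacement row (the Wilson-B row for that coordinate, here obtained by
central finite differences of the coordinate value) is normalized to
percentages, and the mode is labeled by the dominant motion type:
TORS, BEND, OUT, STRE with heavy atoms, STRE with hydrogen, or MIX when no
type reaches the dominance threshold.

This is a deliberately simple scheme: no iterative optimization of the
internal-coordinate set is performed, so the percentages are a redundant
projection, adequate for bucketing modes by motion type but not for
reproducing any particular PED program's numbers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from modescan.errors import ElementTableError, NullProjectionError
from modescan.mode_io import Geometry, ModeSet

Kind = Literal["STRE", "BEND", "TORS", "OUT"]

#: Covalent radii in Angstrom (Cordero et al. consensus values), main group.
COVALENT_RADIUS = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Fe": 1.32, "Zn": 1.22, "Br": 1.20, "I": 1.39,
}

#: Distance criterion: bonded when r < BOND_TOLERANCE * (r_cov_i + r_cov_j).
BOND_TOLERANCE = 1.2

DEFAULT_DOMINANCE = 60.0

_KIND_NATOMS = {"STRE": 2, "BEND": 3, "TORS": 4, "OUT": 4}


@dataclass(frozen=True)
class InternalCoordinate:
    """One redundant internal coordinate.

    For BEND the central atom is second; for TORS the atoms are the bonded
    chain a-b-c-d; for OUT the first atom is the trigonal center followed by
    its three neighbors.
    """

    kind: Kind
    atoms: tuple[int, ...]
    involves_hydrogen: bool = False

    def __post_init__(self) -> None:
        if len(self.atoms) != _KIND_NATOMS[self.kind]:
            raise ValueError(f"{self.kind} needs {_KIND_NATOMS[self.kind]} atoms, got {self.atoms}")
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError(f"atom indices must be distinct: {self.atoms}")


@dataclass
class PedBreakdown:
    """Percent contribution of each motion type to one mode, plus its category."""

    mode_index: int
    percentages: dict[str, float]
    category: str


# ---------------------------------------------------------------------------
# Topology perception


def _bond_graph(geometry: Geometry) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(geometry.n_atoms))
    radii = []
    for el in geometry.elements:
        if el not in COVALENT_RADIUS:
            raise ElementTableError(f"no covalent radius for element {el!r}")
        radii.append(COVALENT_RADIUS[el])
    coords = geometry.coords
    for i, j in itertools.combinations(range(geometry.n_atoms), 2):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < BOND_TOLERANCE * (radii[i] + radii[j]):
            g.add_edge(i, j)
    return g


def perceive_topology(geometry: Geometry) -> list[InternalCoordinate]:
    """Perceive a redundant internal-coordinate set from covalent distances.

    Bonds where r < 1.2 x (sum of covalent radii); an angle for every bonded
    triple; a proper torsion for every bonded quadruple; an out-of-plane
    coordinate at every atom with exactly three bonded neighbors.
    """
    g = _bond_graph(geometry)
    if geometry.n_atoms > 1 and not nx.is_connected(g):
        warnings.warn(
            f"molecular graph is disconnected ({nx.number_connected_components(g)} fragments)",
            UserWarning,
            stacklevel=2,
        )
    elements = geometry.elements
    coords_list: list[InternalCoordinate] = []
    for i, j in sorted(g.edges()):
        coords_list.append(
            InternalCoordinate(
                kind="STRE",
                atoms=(i, j),
                involves_hydrogen=elements[i] == "H" or elements[j] == "H",
            )
        )
    for b in sorted(g.nodes()):
        for a, c in itertools.combinations(sorted(g.neighbors(b)), 2):
            coords_list.append(InternalCoordinate(kind="BEND", atoms=(a, b, c)))
    for b, c in sorted(g.edges()):
        for a in sorted(g.neighbors(b)):
            if a == c:
                continue
            for d in sorted(g.neighbors(c)):
                if d == b or d == a:
                    continue
                coords_list.append(InternalCoordinate(kind="TORS", atoms=(a, b, c, d)))
    for center in sorted(g.nodes()):
        nbrs = sorted(g.neighbors(center))
        if len(nbrs) == 3:
            coords_list.append(InternalCoordinate(kind="OUT", atoms=(center, *nbrs)))
    return coords_list


# ---------------------------------------------------------------------------
# Internal-coordinate value functions and their B rows


def _bond_value(x: np.ndarray, atoms: tuple[int, ...]) -> float:
    i, j = atoms
    return float(np.linalg.norm(x[i] - x[j]))


def _angle_value(x: np.ndarray, atoms: tuple[int, ...]) -> float:
    a, b, c = atoms
    u = x[a] - x[b]
    v = x[c] - x[b]
    cosphi = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosphi, -1.0, 1.0)))


def _dihedral_value(x: np.ndarray, atoms: tuple[int, ...]) -> float:
    a, b, c, d = atoms
    b1 = x[b] - x[a]
    b2 = x[c] - x[b]
    b3 = x[d] - x[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


def _oop_value(x: np.ndarray, atoms: tuple[int, ...]) -> float:
    # signed distance of the trigonal center from the plane of its neighbors
    center, p, q, r = atoms
    n = np.cross(x[q] - x[p], x[r] - x[p])
    nn = np.linalg.norm(n)
    if nn == 0.0:
        return 0.0
    return float(np.dot(x[center] - x[p], n / nn))


_VALUE_FUNC = {
    "STRE": _bond_value,
    "BEND": _angle_value,
    "TORS": _dihedral_value,
    "OUT": _oop_value,
}


def b_row(geometry: Geometry, coord: InternalCoordinate, h: float = 1e-5) -> np.ndarray:
    """First-order N x 3 displacement row of one internal coordinate
    (central finite difference of the coordinate value)."""
    f = _VALUE_FUNC[coord.kind]
    x0 = geometry.coords.astype(float)
    row = np.zeros_like(x0)
    for atom in coord.atoms:
        for axis in range(3):
            xp = x0.copy()
            xm = x0.copy()
            xp[atom, axis] += h
            xm[atom, axis] -= h
            row[atom, axis] = (f(xp, coord.atoms) - f(xm, coord.atoms)) / (2 * h)
    return row


def _contribution_label(coord: InternalCoordinate) -> str:
    if coord.kind == "STRE":
        return "STRE_H" if coord.involves_hydrogen else "STRE_HEAVY"
    return coord.kind


PED_LABELS = ("STRE_HEAVY", "STRE_H", "BEND", "TORS", "OUT")


def ped_percentages(
    modeset: ModeSet,
    mode_index: int,
    coords: Sequence[InternalCoordinate],
    dominance: float = DEFAULT_DOMINANCE,
) -> PedBreakdown:
    """Percent contribution of each motion type to one normal mode.

    Contribution of a coordinate = squared projection of the (unit) mode
    vector onto the coordinate's unit-normalized B row; the contributions are
    normalized to sum to 100 and aggregated by motion type. Coordinates with
    a numerically degenerate B row (e.g., a bend through a linear angle) are
    skipped.
    """
    if not coords:
        raise NullProjectionError("empty internal-coordinate list")
    mode = modeset.mode(mode_index)
    d = mode.displacement.ravel()
    d = d / np.linalg.norm(d)
    raw: dict[str, float] = {label: 0.0 for label in PED_LABELS}
    total = 0.0
    for coord in coords:
        row = b_row(modeset.equilibrium, coord).ravel()
        norm = np.linalg.norm(row)
        if not np.isfinite(norm) or norm < 1e-8:
            continue
        contrib = float(np.dot(row / norm, d)) ** 2
        raw[_contribution_label(coord)] += contrib
        total += contrib
    if total <= 1e-12:
        raise NullProjectionError(
            f"mode {mode_index}: zero projection on all internal coordinates"
        )
    percentages = {label: 100.0 * v / total for label, v in raw.items()}
    return PedBreakdown(
        mode_index=mode_index,
        percentages=percentages,
        category=categorize(percentages, dominance),
    )


def categorize(percentages: dict[str, float] | PedBreakdown, dominance: float = DEFAULT_DOMINANCE) -> str:
    """The motion type holding >= *dominance* percent, else MIX.

    A percentage exactly at the threshold counts as dominant.
    """
    if isinstance(percentages, PedBreakdown):
        percentages = percentages.percentages
    label, pct = max(percentages.items(), key=lambda kv: kv[1])
    return label if pct >= dominance else "MIX"
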