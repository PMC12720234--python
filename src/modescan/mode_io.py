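"""Geometries, normal modes, and displaced-geometry generation.

The displacement construction is the standard normal-mode scan recipe: each
mode's Cartesian displacement vector (renormalized to unit L2 norm over all
3N components) is scaled by a unitless factor *i* and added to the
equilibrium coordinates,

    coords(i) = coords_eq + i * displacement.

The default grid is i = -0.10 ... +0.10 in steps of 0.01 (21 points), which
for M modes yields 20*M new geometries plus the shared equilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from modescan.errors import (
    DegenerateModeError,
    DomainError,
    LookupError_,
    ParseError,
    ShapeError,
)

_NORM_TOL = 1e-10

#: The scan grid used throughout: -0.10 <= i <= +0.10, step 0.01.
DEFAULT_GRID_SPEC = (-0.10, 0.10, 0.01)

#: A wider grid (step 0.1 out to +-1.0) is supported but known to distort
#: typical organic molecules too strongly for a meaningful harmonic analysis.
WIDE_GRID_SPEC = (-1.0, 1.0, 0.1)


@dataclass
class Geometry:
    """A molecular structure: element symbols plus N x 3 Cartesian coordinates in Angstrom."""

    elements: list[str]
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(f"coordinates must be N x 3, got shape {self.coords.shape}")
        if len(self.elements) != self.coords.shape[0]:
            raise ShapeError(
                f"{len(self.elements)} element symbols but {self.coords.shape[0]} coordinate rows"
            )
        if self.coords.shape[0] < 1:
            raise DomainError("geometry must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise DomainError("non-finite coordinate encountered")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class NormalMode:
    """One vibrational normal mode: 1-based index, harmonic frequency (cm^-1),
    and a unit-L2-norm N x 3 Cartesian displacement."""

    index: int
    frequency: float
    displacement: np.ndarray
    original_norm: float = 1.0

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.index < 1:
            raise DomainError(f"mode index must be >= 1, got {self.index}")
        norm = float(np.sqrt(np.sum(self.displacement**2)))
        if abs(norm - 1.0) > _NORM_TOL:
            raise DomainError(
                f"mode {self.index}: displacement norm {norm!r} not 1 within {_NORM_TOL}; "
                "use NormalMode.from_raw to renormalize"
            )

    @classmethod
    def from_raw(cls, index: int, frequency: float, raw: np.ndarray) -> "NormalMode":
        """Build a mode from an arbitrarily scaled vector, renormalizing to unit
        L2 norm and recording the original norm."""
        raw = np.asarray(raw, dtype=float)
        norm = float(np.sqrt(np.sum(raw**2)))
        if norm == 0.0:
            raise DegenerateModeError(f"mode {index}: zero-norm displacement vector")
        return cls(index=index, frequency=frequency, displacement=raw / norm, original_norm=norm)


@dataclass
class ModeSet:
    """The equilibrium geometry together with its normal modes."""

    equilibrium: Geometry
    modes: list[NormalMode]
    linear: bool = False

    def __post_init__(self) -> None:
        n = self.equilibrium.n_atoms
        for m in self.modes:
            if m.displacement.shape != (n, 3):
                raise ShapeError(
                    f"mode {m.index}: displacement shape {m.displacement.shape} "
                    f"does not match {n}-atom equilibrium"
                )
        indices = [m.index for m in self.modes]
        if len(set(indices)) != len(indices):
            raise DomainError("duplicate mode indices")
        if indices and indices != list(range(indices[0], indices[0] + len(indices))):
            raise DomainError("mode indices must be contiguous")

    def __len__(self) -> int:
        return len(self.modes)

    def mode(self, index: int) -> NormalMode:
        for m in self.modes:
            if m.index == index:
                return m
        raise LookupError_(f"no mode with index {index}")


@dataclass
class DisplacementGrid:
    """Ordered scaling factors i for a scan."""

    factors: np.ndarray
    includes_zero: bool = field(init=False)

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.ndim != 1 or self.factors.size == 0:
            raise DomainError("grid must be a nonempty 1D sequence")
        if not np.all(np.diff(self.factors) > 0):
            raise DomainError("grid factors must be strictly increasing")
        n_zero = int(np.sum(self.factors == 0.0))
        if n_zero > 1:
            raise DomainError("grid contains 0 more than once")
        self.includes_zero = n_zero == 1

    def __len__(self) -> int:
        return self.factors.size

    @classmethod
    def from_spec(cls, lo: float, hi: float, step: float) -> "DisplacementGrid":
        n = int(round((hi - lo) / step)) + 1
        factors = np.round(lo + step * np.arange(n), 10)
        return cls(factors=factors)


def default_grid() -> DisplacementGrid:
    """The 21-point grid i = -0.10 ... +0.10, step 0.01."""
    return DisplacementGrid.from_spec(*DEFAULT_GRID_SPEC)


def wide_grid() -> DisplacementGrid:
    """The 21-point grid i = -1.0 ... +1.0, step 0.1.

    Emits a warning: displacements this large are known to distort typical
    molecules beyond the regime a quadratic analysis is meaningful in.
    """
    warnings.warn(
        "the +-1.0 grid produces a distortion that is too large for many "
        "normal modes; prefer the default +-0.1 grid",
        UserWarning,
        stacklevel=2,
    )
    return DisplacementGrid.from_spec(*WIDE_GRID_SPEC)


# ---------------------------------------------------------------------------
# XYZ input/output


def load_geometry(path: str | Path) -> Geometry:
    """Read a standard XYZ file (count line, comment line, element x y z rows)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}, line 1: malformed atom-count line {lines[0]!r}") from exc
    comment = lines[1] if len(lines) > 1 else ""
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) < n:
        raise ParseError(
            f"{path}: count line declares {n} atoms but only {len(atom_lines)} atom rows found"
        )
    elements: list[str] = []
    coords = np.empty((n, 3), dtype=float)
    for k in range(n):
        parts = atom_lines[k].split()
        lineno = k + 3
        if len(parts) < 4:
            raise ParseError(f"{path}, line {lineno}: expected 'element x y z', got {atom_lines[k]!r}")
        elements.append(parts[0])
        try:
            coords[k] = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise ParseError(
                f"{path}, line {lineno}: non-numeric coordinate in {atom_lines[k]!r}"
            ) from exc
    return Geometry(elements=elements, coords=coords, label=comment.strip())


def write_geometry(geometry: Geometry, path: str | Path, precision: int = 6) -> None:
    """Write a geometry in XYZ format with the given coordinate precision."""
    path = Path(path)
    rows = [str(geometry.n_atoms), geometry.label]
    for el, (x, y, z) in zip(geometry.elements, geometry.coords):
        rows.append(f"{el:<3s} {x:>14.{precision}f} {y:>14.{precision}f} {z:>14.{precision}f}")
    path.write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Modes file
#
# Plain-text format:
#   nmodes M natoms N
#   mode k freq F          (F in cm^-1)
#   dx dy dz               (N rows)
#   <blank line between blocks>


def load_modes(path: str | Path, equilibrium: Geometry) -> ModeSet:
    """Read a modes file; every vector is renormalized to unit L2 norm."""
    path = Path(path)
    lines = path.read_text().splitlines()
    n_atoms = equilibrium.n_atoms
    idx = 0
    while idx < len(lines) and not lines[idx].strip():
        idx += 1
    if idx >= len(lines):
        raise ParseError(f"{path}: empty modes file")
    header = lines[idx].split()
    if len(header) != 4 or header[0] != "nmodes" or header[2] != "natoms":
        raise ParseError(f"{path}, line {idx + 1}: expected 'nmodes M natoms N', got {lines[idx]!r}")
    n_modes, n_header_atoms = int(header[1]), int(header[3])
    if n_header_atoms != n_atoms:
        raise ShapeError(
            f"{path}: header declares {n_header_atoms} atoms but equilibrium has {n_atoms}"
        )
    idx += 1
    modes: list[NormalMode] = []
    for _ in range(n_modes):
        while idx < len(lines) and not lines[idx].strip():
            idx += 1
        if idx >= len(lines):
            raise ParseError(f"{path}: expected {n_modes} mode blocks, found {len(modes)}")
        head = lines[idx].split()
        if len(head) != 4 or head[0] != "mode" or head[2] != "freq":
            raise ParseError(f"{path}, line {idx + 1}: expected 'mode k freq F', got {lines[idx]!r}")
        k, freq = int(head[1]), float(head[3])
        idx += 1
        raw = np.empty((n_atoms, 3), dtype=float)
        for row in range(n_atoms):
            if idx >= len(lines) or not lines[idx].strip():
                raise ShapeError(
                    f"{path}: mode {k} has {row} displacement rows, expected {n_atoms}"
                )
            parts = lines[idx].split()
            if len(parts) != 3:
                raise ParseError(
                    f"{path}, line {idx + 1}: expected 'dx dy dz', got {lines[idx]!r}"
                )
            try:
                raw[row] = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}, line {idx + 1}: non-numeric displacement") from exc
            idx += 1
        modes.append(NormalMode.from_raw(index=k, frequency=freq, raw=raw))
    return ModeSet(equilibrium=equilibrium, modes=modes)


def write_modes(modeset: ModeSet, path: str | Path, precision: int = 8) -> None:
    path = Path(path)
    n = modeset.equilibrium.n_atoms
    out = [f"nmodes {len(modeset)} natoms {n}"]
    for m in modeset.modes:
        out.append("")
        out.append(f"mode {m.index} freq {m.frequency:.4f}")
        for dx, dy, dz in m.displacement:
            out.append(f"{dx:> .{precision}e} {dy:> .{precision}e} {dz:> .{precision}e}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Displacement generation


def expected_mode_count(geometry: Geometry, linear: bool) -> int:
    """Number of vibrational modes: 3N-6 (nonlinear) or 3N-5 (linear)."""
    n = geometry.n_atoms
    if n < 2:
        raise DomainError(f"vibrational mode count undefined for {n} atom(s)")
    return 3 * n - 5 if linear else 3 * n - 6


def displacement_filename(mode_index: int, factor: float) -> str:
    """Canonical file name `mode{MM}_i{+/-0.NN}.xyz`; lexical sort == scan order."""
    return f"mode{mode_index:03d}_i{factor:+.2f}.xyz"


def generate_displacements(
    modeset: ModeSet, mode_index: int, grid: DisplacementGrid
) -> list[Geometry]:
    """One geometry per grid factor, coords = equilibrium + i * displacement.

    The i = 0 entry shares the equilibrium coordinates bit-for-bit.
    """
    mode = modeset.mode(mode_index)
    eq = modeset.equilibrium
    out: list[Geometry] = []
    for i in grid.factors:
        if i == 0.0:
            coords = eq.coords.copy()
        else:
            coords = eq.coords + i * mode.displacement
        out.append(
            Geometry(
                elements=list(eq.elements),
                coords=coords,
                label=f"mode {mode_index} i {i:+.4f}",
            )
        )
    return out


def generate_all(
    modeset: ModeSet,
    grid: DisplacementGrid,
    outdir: str | Path | None = None,
) -> tuple[dict[str, Geometry], pd.DataFrame]:
    """Displace every mode over the grid.

    Returns a mapping file-name -> Geometry covering all M*(len(grid)-1)
    displaced structures plus the single shared equilibrium (file
    ``equilibrium.xyz``), and a manifest table with columns ``file,mode,i``.
    If *outdir* is given, the XYZ files and ``manifest.csv`` are written there.
    """
    geometries: dict[str, Geometry] = {}
    records: list[dict] = []
    eq_name = "equilibrium.xyz"
    geometries[eq_name] = Geometry(
        elements=list(modeset.equilibrium.elements),
        coords=modeset.equilibrium.coords.copy(),
        label="equilibrium",
    )
    records.append({"file": eq_name, "mode": 0, "i": 0.0})
    for mode in modeset.modes:
        for geom, i in zip(
            generate_displacements(modeset, mode.index, grid), grid.factors
        ):
            if i == 0.0:
                continue  # the equilibrium is shared, not duplicated per mode
            name = displacement_filename(mode.index, i)
            geometries[name] = geom
            records.append({"file": name, "mode": mode.index, "i": float(i)})
    manifest = pd.DataFrame.from_records(records, columns=["file", "mode", "i"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, geom in geometries.items():
            write_geometry(geom, outdir / name)
        manifest.to_csv(outdir / "manifest.csv", index=False)
    return geometries, manifest


# ---------------------------------------------------------------------------
# Reporting helper

# Atomic masses (u) for the optional mass-weighted displacement-length report.
_ATOMIC_MASS = {
    "H": 1.008, "D": 2.014, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Br": 79.904, "I": 126.90,
}


def mass_weighted_length(modeset: ModeSet, mode_index: int, factor: float) -> float:
    """Mass-weighted length (amu^1/2 * Angstrom) of the displacement at scaling
    factor *factor* along one mode. For reporting only; the scan abscissa
    everywhere else is the unitless factor i."""
    mode = modeset.mode(mode_index)
    masses = np.array([_ATOMIC_MASS[el] for el in modeset.equilibrium.elements])
    disp = factor * mode.displacement
    return float(np.sqrt(np.sum(masses[:, None] * disp**2)))
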