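"""Synthetic two-state energy tables and mode fixtures with known ground truth.

The generator stands in for the external electronic-structure engine: for
each emulated mode it evaluates a ground-state potential and two excited
*diabatic* potentials V1, V2 on the scan grid, couples the diabats through a
constant off-diagonal element w, and emits the *adiabatic* energies

    S1, S2 = eigenvalues of [[V1, w], [w, V2]],  sorted ascending,

exactly the energy-ordered states an excited-state calculation would report.
With w = 0 a diabat crossing appears as an exact degeneracy and the
adiabatic labels exchange character past it; small w > 0 gives an avoided
crossing whose gap never closes below 2w. Potentials are harmonic,
V(x) = k (x - delta)^2, or Morse, V(x) = D (1 - exp(-alpha (x - delta)))^2,
whose i -> delta quadratic coefficient is D alpha^2; the minimum shift delta
models Franck-Condon activity (relaxation energy k delta^2 for a harmonic
state). Independent Gaussian noise of a chosen SD stresses fit robustness.

Every table comes with a :class:`SyntheticTruth` record (analytic
curvatures, relaxation energies, exact crossing position, per-point diabatic
labels, intended classification case) for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from modescan.errors import SpecError
from modescan.mode_io import DisplacementGrid, Geometry, ModeSet, NormalMode, default_grid


# ---------------------------------------------------------------------------
# Potentials


@dataclass(frozen=True)
class Harmonic:
    """V(x) = k x^2, k in eV per i^2."""

    k: float

    def __call__(self, x):
        return self.k * np.asarray(x, dtype=float) ** 2

    @property
    def curvature(self) -> float:
        """Quadratic coefficient at the minimum (the 'a' an exact fit recovers)."""
        return self.k


@dataclass(frozen=True)
class Morse:
    """V(x) = D (1 - exp(-alpha x))^2; quadratic coefficient at the minimum D alpha^2."""

    D: float
    alpha: float

    def __call__(self, x):
        return self.D * (1.0 - np.exp(-self.alpha * np.asarray(x, dtype=float))) ** 2

    @property
    def curvature(self) -> float:
        return self.D * self.alpha**2


@dataclass(frozen=True)
class StateSpec:
    """One diabatic state: a potential shape, a minimum shift delta (i units),
    and a vertical offset (eV) of the potential minimum."""

    potential: Harmonic | Morse
    shift: float = 0.0
    offset: float = 0.0

    def __call__(self, x):
        return self.potential(np.asarray(x, dtype=float) - self.shift) + self.offset


@dataclass
class TwoStateSpec:
    """Full scenario: ground state, two excited diabats, constant coupling w,
    grid, noise level, and seed."""

    ground: StateSpec
    s1_diabat: StateSpec
    s2_diabat: StateSpec
    coupling: float = 0.0
    grid: DisplacementGrid = field(default_factory=default_grid)
    noise_sd: float = 0.0
    seed: int = 0
    mode_index: int = 1
    require_crossing: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Analytic ground truth for one generated scan."""

    mode_index: int
    curvature: dict[str, float]          # state -> quadratic coefficient at its minimum
    lambda_true: dict[str, float]        # excited diabat -> V(0) - min over grid of V
    crossing_position: float | None      # exact i where the diabats are degenerate
    lower_labels: list[str]              # per grid point: which diabat ('d1'/'d2') is adiabatically lower
    intended_case: int | None = None
    scenario: str | None = None


def _diabat_crossings(spec: TwoStateSpec, n_fine: int = 2001) -> list[float]:
    x = np.linspace(spec.grid.factors[0], spec.grid.factors[-1], n_fine)
    d = spec.s1_diabat(x) - spec.s2_diabat(x)
    roots = []
    for k in range(n_fine - 1):
        if d[k] == 0.0:
            roots.append(float(x[k]))
        elif d[k] * d[k + 1] < 0:
            roots.append(float(brentq(lambda t: spec.s1_diabat(t) - spec.s2_diabat(t), x[k], x[k + 1])))
    if d[-1] == 0.0:
        roots.append(float(x[-1]))
    return sorted(set(np.round(roots, 12)))


def generate_two_state(spec: TwoStateSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Emit the energy table (columns mode, i, state, energy in eV) and the
    ground truth for one scenario. Deterministic for a fixed spec and seed."""
    x = spec.grid.factors
    v0 = spec.ground(x)
    v1 = spec.s1_diabat(x)
    v2 = spec.s2_diabat(x)
    w = spec.coupling
    mean = 0.5 * (v1 + v2)
    half_gap = np.sqrt(0.25 * (v1 - v2) ** 2 + w**2)
    s1 = mean - half_gap
    s2 = mean + half_gap

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v0 = v0 + rng.normal(0.0, spec.noise_sd, x.size)
        s1 = s1 + rng.normal(0.0, spec.noise_sd, x.size)
        s2 = s2 + rng.normal(0.0, spec.noise_sd, x.size)
        s1, s2 = np.minimum(s1, s2), np.maximum(s1, s2)  # keep adiabatic order

    crossings = _diabat_crossings(spec)
    crossing = crossings[0] if crossings else None
    if spec.require_crossing and crossing is None:
        raise SpecError("crossing requested but the diabats do not cross inside the grid")

    rows = []
    for state, e in (("S0", v0), ("S1", s1), ("S2", s2)):
        for xi, ei in zip(x, e):
            rows.append({"mode": spec.mode_index, "i": float(xi), "state": state, "energy": float(ei)})
    table = pd.DataFrame(rows, columns=["mode", "i", "state", "energy"])

    def lam(st: StateSpec) -> float:
        v = st(x)
        return max(float(st(0.0) - v.min()), 0.0)

    truth = SyntheticTruth(
        mode_index=spec.mode_index,
        curvature={
            "S0": spec.ground.potential.curvature,
            "S1": spec.s1_diabat.potential.curvature,
            "S2": spec.s2_diabat.potential.curvature,
        },
        lambda_true={"S1": lam(spec.s1_diabat), "S2": lam(spec.s2_diabat)},
        crossing_position=crossing,
        lower_labels=["d1" if a <= b else "d2" for a, b in zip(spec.s1_diabat(x), spec.s2_diabat(x))],
    )
    return table, truth


# ---------------------------------------------------------------------------
# Mode fixtures


_FIXTURE_ELEMENTS = ("C", "N", "O", "H")


def generate_mode_fixture(n_atoms: int, n_modes: int, seed: int = 0) -> tuple[Geometry, ModeSet]:
    """Random geometry with interatomic distances > 1 A and mutually
    orthonormal random mode vectors. Deterministic per seed."""
    if n_atoms < 2:
        raise SpecError("need at least 2 atoms")
    max_modes = 3 * n_atoms - 5 if n_atoms == 2 else 3 * n_atoms - 6  # a diatomic is linear
    if n_modes > max_modes:
        raise SpecError(f"{n_modes} modes infeasible for {n_atoms} atoms (max {max_modes})")
    rng = np.random.default_rng(seed)
    # jittered cubic lattice, 1.5 A spacing: min distance 1.5 - 2*0.2 > 1 A
    side = int(np.ceil(n_atoms ** (1 / 3)))
    lattice = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)][:n_atoms],
        dtype=float,
    )
    coords = 1.5 * lattice + rng.uniform(-0.2, 0.2, (n_atoms, 3))
    elements = list(rng.choice(_FIXTURE_ELEMENTS, size=n_atoms))
    geometry = Geometry(elements=elements, coords=coords, label=f"synthetic fixture seed={seed}")

    freqs = np.sort(rng.uniform(100.0, 1800.0, n_modes))
    if n_atoms == 2 and n_modes == 1:
        # the one vibration of a diatomic: a stretch along the bond axis
        axis = coords[1] - coords[0]
        axis /= np.linalg.norm(axis)
        raw = np.vstack([axis, -axis])
        modes = [NormalMode.from_raw(1, float(freqs[0]), raw)]
        return geometry, ModeSet(equilibrium=geometry, modes=modes, linear=True)
    q, _ = np.linalg.qr(rng.normal(size=(3 * n_atoms, 3 * n_atoms)))
    modes = [
        NormalMode(index=k + 1, frequency=float(freqs[k]), displacement=q[:, k].reshape(n_atoms, 3))
        for k in range(n_modes)
    ]
    return geometry, ModeSet(equilibrium=geometry, modes=modes)


# ---------------------------------------------------------------------------
# Benchmark suite
#
# Scenario mixture emulating one molecule's mode population: a majority of
# plain harmonic modes plus minority groups of FC-shifted, Morse-anharmonic,
# and state-crossing modes. Parameter ranges are chosen so that (a) grid-edge
# energies stay within ~1 eV of the minima, the regime the +-0.1 scans probe,
# and (b) each anomalous group's metric sits well clear of the population
# mean + 1 SD threshold at the default mixture (see docs/methods.md).

#: (scenario name, intended case, fraction of the suite)
SUITE_MIXTURE = (
    ("harmonic_inactive", 8, 0.56),
    ("fc_active", 7, 0.06),
    ("s1_anharmonic", 6, 0.08),
    ("s1_anharmonic_fc", 5, 0.04),
    ("both_anharmonic", 4, 0.08),
    ("excess_anharmonic", 2, 0.03),
    ("excess_anharmonic_fc", 1, 0.02),
    ("crossing", 8, 0.06),
)

#: ratio of excited- to ground-state curvature (excited states are softer)
_CURV_RATIO = 0.8


def _draw_scenario(name: str, mode_index: int, rng: np.random.Generator) -> TwoStateSpec:
    k0 = rng.uniform(35.0, 55.0)
    k1 = _CURV_RATIO * k0
    de1 = rng.uniform(2.7, 3.2)
    de2 = de1 + rng.uniform(0.8, 1.2)
    delta_fc = rng.uniform(0.07, 0.08)
    ground = StateSpec(Harmonic(k0))

    if name == "harmonic_inactive":
        s1 = StateSpec(Harmonic(k1), offset=de1)
    elif name == "fc_active":
        s1 = StateSpec(Harmonic(k1), shift=delta_fc, offset=de1)
    elif name == "s1_anharmonic":
        a1 = rng.uniform(1.9, 2.4)
        s1 = StateSpec(Morse(D=k1 / a1**2, alpha=a1), offset=de1)
    elif name == "s1_anharmonic_fc":
        a1 = rng.uniform(1.9, 2.4)
        s1 = StateSpec(Morse(D=k1 / a1**2, alpha=a1), shift=delta_fc, offset=de1)
    elif name == "both_anharmonic":
        a0 = rng.uniform(1.7, 2.1)
        ground = StateSpec(Morse(D=k0 / a0**2, alpha=a0))
        # same alpha, scaled depth: identical relative anharmonicity in S1
        s1 = StateSpec(Morse(D=k1 / a0**2, alpha=a0), offset=de1)
    elif name in ("excess_anharmonic", "excess_anharmonic_fc"):
        a0 = rng.uniform(1.5, 1.6)
        a1 = rng.uniform(3.0, 3.3)
        ground = StateSpec(Morse(D=k0 / a0**2, alpha=a0))
        shift = delta_fc if name == "excess_anharmonic_fc" else 0.0
        s1 = StateSpec(Morse(D=k1 / a1**2, alpha=a1), shift=shift, offset=de1)
    elif name == "crossing":
        # two harmonic diabats of equal curvature crossing at x_c > 0:
        # their difference is linear in i, so exactly one crossing exists
        x_c = rng.uniform(0.025, 0.055)
        delta2 = 0.12
        de2_cross = de1 + k1 * (x_c**2 - (x_c - delta2) ** 2)
        s1 = StateSpec(Harmonic(k1), offset=de1)
        s2 = StateSpec(Harmonic(k1), shift=delta2, offset=de2_cross)
        return TwoStateSpec(
            ground=ground, s1_diabat=s1, s2_diabat=s2, coupling=0.0,
            mode_index=mode_index, require_crossing=True,
        )
    else:
        raise SpecError(f"unknown scenario {name!r}")
    # S2 tracks S1's shape at a constant vertical separation, so the S1/S2
    # gap never closes in the non-crossing scenarios
    s2 = StateSpec(s1.potential, shift=s1.shift, offset=de2)
    return TwoStateSpec(ground=ground, s1_diabat=s1, s2_diabat=s2, mode_index=mode_index)


def generate_benchmark_suite(
    n_replicates: int,
    seed: int = 0,
    noise_sd: float = 0.0,
    mixture: Sequence[tuple[str, int, float]] = SUITE_MIXTURE,
) -> list[tuple[pd.DataFrame, SyntheticTruth]]:
    """A mixture of scenario scans with intended classification outcomes.

    Replicate r is emitted as mode index r+1, so concatenating the tables
    gives one molecule-like population directly consumable by
    ``assemble_scans``. Deterministic per seed.
    """
    if n_replicates < 1:
        raise SpecError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    names: list[tuple[str, int]] = []
    for name, case, frac in mixture[1:]:
        names.extend([(name, case)] * int(round(frac * n_replicates)))
    fill_name, fill_case, _ = mixture[0]
    names.extend([(fill_name, fill_case)] * (n_replicates - len(names)))
    names = names[:n_replicates]

    out: list[tuple[pd.DataFrame, SyntheticTruth]] = []
    for r, (name, case) in enumerate(names):
        spec = _draw_scenario(name, mode_index=r + 1, rng=rng)
        spec.noise_sd = noise_sd
        spec.seed = int(rng.integers(0, 2**31 - 1))
        table, truth = generate_two_state(spec)
        truth.intended_case = case
        truth.scenario = name
        out.append((table, truth))
    return out


def suite_table(suite: Sequence[tuple[pd.DataFrame, SyntheticTruth]]) -> pd.DataFrame:
    """Concatenate a benchmark suite into a single energy table."""
    return pd.concat([t for t, _ in suite], ignore_index=True)
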