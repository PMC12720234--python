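"""Per-mode, per-state energy scans: assembly, crossing detection, diabatization.

A scan along one normal mode holds, for each electronic state, the energy at
every grid factor i, referenced to the ground-state energy at i = 0 and
expressed in eV. Along some modes the adiabatic S1 and S2 curves cross (the
1D signature of a conical intersection): the energy-ordered states exchange
electronic character at the crossing, which makes the adiabatic S1 curve
kinked and spuriously anharmonic. Diabatization relabels the two states past
the crossing so that each curve follows a single electronic character and is
smooth; operationally, with energies alone, the branch swap is accepted when
it reduces the summed quadratic-fit RMSD of the two curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from modescan.errors import (
    AmbiguityError,
    CompletenessError,
    InsufficientDataError,
    LookupError_,
)
from modescan.harmonicity import fit_quadratic

#: CODATA hartree -> eV
HARTREE_TO_EV = 27.211386245988
EV_TO_KCALMOL = 23.060548
EV_TO_WAVENUMBER = 8065.544

#: Default maximum adiabatic gap (eV) at which an interior gap minimum is
#: treated as a state crossing. Chosen to admit near-degenerate crossings
#: on a 0.01-spaced grid while rejecting well-separated states.
DEFAULT_GAP_THRESHOLD = 0.15


@dataclass
class ScanSet:
    """Energies of one mode's scan, per electronic state, in eV relative to
    the ground state at i = 0."""

    mode_index: int
    factors: np.ndarray
    energies: dict[str, np.ndarray]
    relabeled: bool = False
    swap_points: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.energies = {s: np.asarray(e, dtype=float) for s, e in self.energies.items()}
        n = self.factors.size
        for state, e in self.energies.items():
            if e.size != n:
                raise CompletenessError(
                    f"mode {self.mode_index}, state {state}: {e.size} energies for {n} factors"
                )
            if not np.all(np.isfinite(e)):
                raise CompletenessError(f"mode {self.mode_index}, state {state}: non-finite energy")

    @property
    def states(self) -> list[str]:
        return list(self.energies)

    def copy(self) -> "ScanSet":
        return ScanSet(
            mode_index=self.mode_index,
            factors=self.factors.copy(),
            energies={s: e.copy() for s, e in self.energies.items()},
            relabeled=self.relabeled,
            swap_points=list(self.swap_points),
        )


@dataclass
class CrossingReport:
    """Location and energetics of a detected excited-state crossing.

    ``delta_E_CI_S1min`` is the energy of the crossing point above the
    minimum of the lower adiabatic state over the scanned grid.
    """

    mode_index: int
    crossing_index: int
    gap_min: float
    delta_E_CI_S1min: float
    state_a: str
    state_b: str
    swapped: bool = False

    def __post_init__(self) -> None:
        if self.gap_min < 0:
            raise ValueError("gap_min must be >= 0")


def assemble_scans(energy_table: pd.DataFrame, unit: str = "eV") -> list[ScanSet]:
    """Build per-mode scans from a tabular energy file.

    *energy_table* needs columns ``mode, i, state, energy``. Energies may be
    in hartree or eV (*unit*); they are converted to eV and shifted so that
    each mode's ground state (lowest state label) at i = 0 is zero. Every
    (mode, state) must cover the mode's full grid exactly once, and i = 0
    must be present.
    """
    if unit not in ("eV", "hartree"):
        raise ValueError(f"unit must be 'eV' or 'hartree', got {unit!r}")
    df = energy_table.copy()
    required = {"mode", "i", "state", "energy"}
    if not required.issubset(df.columns):
        raise CompletenessError(f"energy table must have columns {sorted(required)}")
    factor = HARTREE_TO_EV if unit == "hartree" else 1.0
    df["energy"] = df["energy"].astype(float) * factor
    df["i"] = df["i"].astype(float).round(10)

    dup = df.duplicated(subset=["mode", "i", "state"])
    if dup.any():
        row = df[dup].iloc[0]
        raise AmbiguityError(
            f"duplicate record for (mode {int(row['mode'])}, state {row['state']}, i {row['i']:+g})"
        )

    scans: list[ScanSet] = []
    for mode, g in df.groupby("mode", sort=True):
        factors = np.sort(g["i"].unique())
        if 0.0 not in factors:
            raise CompletenessError(f"mode {int(mode)}: grid has no i = 0 point")
        states = sorted(g["state"].unique())
        energies: dict[str, np.ndarray] = {}
        for state in states:
            sub = g[g["state"] == state].set_index("i")["energy"]
            missing = [i for i in factors if i not in sub.index]
            if missing:
                raise CompletenessError(
                    f"missing energy for (mode {int(mode)}, state {state}, "
                    f"i {', '.join(f'{i:+g}' for i in missing)})"
                )
            energies[state] = sub.loc[factors].to_numpy()
        ground = states[0]
        ref = energies[ground][int(np.argwhere(factors == 0.0)[0, 0])]
        energies = {s: e - ref for s, e in energies.items()}
        scans.append(ScanSet(mode_index=int(mode), factors=factors, energies=energies))
    return scans


def detect_crossing(
    scan: ScanSet,
    state_a: str,
    state_b: str,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    interpolate: bool = False,
) -> CrossingReport | None:
    """Locate a crossing between two states as an interior local minimum of
    their energy gap below *gap_threshold*; None when no point qualifies.

    The crossing-point energy is read at the minimum-gap grid point (mean of
    the two states there); with ``interpolate=True`` it is instead taken from
    the linear crossing of the two curves between the neighboring points.
    """
    for s in (state_a, state_b):
        if s not in scan.energies:
            raise LookupError_(f"mode {scan.mode_index}: state {s} not in scan")
    if scan.factors.size < 5:
        raise InsufficientDataError(
            f"mode {scan.mode_index}: need >= 5 grid points, have {scan.factors.size}"
        )
    ea = scan.energies[state_a]
    eb = scan.energies[state_b]
    gap = np.abs(eb - ea)
    interior = [
        k
        for k in range(1, gap.size - 1)
        if gap[k] <= gap[k - 1] and gap[k] <= gap[k + 1]
    ]
    if not interior:
        return None
    k = min(interior, key=lambda j: gap[j])
    if not gap[k] < gap_threshold:
        return None
    lower = np.minimum(ea, eb)
    e_ci = 0.5 * (ea[k] + eb[k])
    if interpolate and gap[k] > 0:
        e_ci = _interpolated_crossing_energy(scan.factors, ea, eb, k) or e_ci
    return CrossingReport(
        mode_index=scan.mode_index,
        crossing_index=k,
        gap_min=float(gap[k]),
        delta_E_CI_S1min=float(e_ci - lower.min()),
        state_a=state_a,
        state_b=state_b,
    )


def _interpolated_crossing_energy(x, ea, eb, k) -> float | None:
    """Energy where the linearly interpolated signed gap changes sign near k."""
    d = eb - ea
    for lo in (k - 1, k):
        hi = lo + 1
        if hi >= x.size or lo < 0:
            continue
        if d[lo] == d[hi] or d[lo] * d[hi] > 0:
            continue
        t = d[lo] / (d[lo] - d[hi])
        return float((1 - t) * ea[lo] + t * ea[hi])
    return None


def _total_fit_rmsd(factors: np.ndarray, curves: Sequence[np.ndarray]) -> float:
    return sum(fit_quadratic(factors, c).rmsd for c in curves)


def diabatize(scan: ScanSet, crossing: CrossingReport | None) -> ScanSet:
    """Relabel the two crossing states past the crossing so each curve is smooth.

    Only grid points beyond the swap point on the crossing's side of i = 0
    are exchanged, and only when the exchange reduces the summed
    quadratic-fit RMSD of the two curves; otherwise the scan is returned
    unchanged. The set of energies at every grid point is preserved.
    """
    if crossing is None:
        return scan
    out = scan.copy()
    ea = out.energies[crossing.state_a]
    eb = out.energies[crossing.state_b]
    x = out.factors
    k = crossing.crossing_index
    positive_side = x[k] >= 0

    # candidate swap start points: the minimum-gap point itself and the first
    # point past it, both on the side away from i = 0 (the exact crossing may
    # fall on or between grid points)
    if positive_side:
        candidates = [(s, np.arange(s, x.size)) for s in (k, k + 1) if s < x.size]
    else:
        candidates = [(s, np.arange(0, s + 1)) for s in (k, k - 1) if s >= 0]
    candidates = [(s, region) for s, region in candidates if region.size > 0]

    best_rmsd = _total_fit_rmsd(x, [ea, eb])
    best: tuple[int, np.ndarray] | None = None
    for s, region in candidates:
        ea2, eb2 = ea.copy(), eb.copy()
        ea2[region], eb2[region] = eb[region], ea[region]
        r = _total_fit_rmsd(x, [ea2, eb2])
        if r < best_rmsd - 1e-15:
            best_rmsd = r
            best = (s, region)

    if best is None:
        return scan
    s, region = best
    ea2, eb2 = ea.copy(), eb.copy()
    ea2[region], eb2[region] = eb[region], ea[region]
    out.energies[crossing.state_a] = ea2
    out.energies[crossing.state_b] = eb2
    out.relabeled = True
    out.swap_points = sorted(set(scan.swap_points) | {int(s)})
    crossing.swapped = True
    return out


# ---------------------------------------------------------------------------
# Scan archive (JSON)


def scans_to_json(
    scans: Sequence[ScanSet],
    crossings: dict[int, CrossingReport | None] | None = None,
    path: str | Path | None = None,
) -> str:
    """Serialize scans (and optional crossing reports) to the JSON archive."""
    records = []
    crossings = crossings or {}
    for scan in scans:
        rec = {
            "mode": scan.mode_index,
            "factors": scan.factors.tolist(),
            "energies": {s: e.tolist() for s, e in scan.energies.items()},
            "relabeled": scan.relabeled,
            "swap_points": scan.swap_points,
        }
        c = crossings.get(scan.mode_index)
        rec["crossing"] = None if c is None else {
            "crossing_index": c.crossing_index,
            "gap_min": c.gap_min,
            "delta_E_CI_S1min": c.delta_E_CI_S1min,
            "state_a": c.state_a,
            "state_b": c.state_b,
            "swapped": c.swapped,
        }
        records.append(rec)
    text = json.dumps(records, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def scans_from_json(path: str | Path) -> tuple[list[ScanSet], dict[int, CrossingReport | None]]:
    records = json.loads(Path(path).read_text())
    scans: list[ScanSet] = []
    crossings: dict[int, CrossingReport | None] = {}
    for rec in records:
        scans.append(
            ScanSet(
                mode_index=rec["mode"],
                factors=np.asarray(rec["factors"]),
                energies={s: np.asarray(e) for s, e in rec["energies"].items()},
                relabeled=rec["relabeled"],
                swap_points=list(rec["swap_points"]),
            )
        )
        c = rec.get("crossing")
        crossings[rec["mode"]] = None if c is None else CrossingReport(
            mode_index=rec["mode"],
            crossing_index=c["crossing_index"],
            gap_min=c["gap_min"],
            delta_E_CI_S1min=c["delta_E_CI_S1min"],
            state_a=c["state_a"],
            state_b=c["state_b"],
            swapped=c["swapped"],
        )
    return scans, crossings
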