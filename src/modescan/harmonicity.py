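"""Quadratic fits of 1D energy scans and per-mode anharmonicity metrics.

Each state's scan E(i) is fitted with y = a*i^2 + b*i + c by unweighted least
squares. Anharmonicity is probed by the fit residuals:

    RMSD            = sqrt( sum_k (y_k - fit_k)^2 / n )
    RMSD/E_average  = RMSD / mean(y)                      (ground state)
                    = RMSD / (mean(y) - E_vert)           (excited state)

where E_vert is the vertical excitation energy, so the excited-state
denominator measures the energy change caused by the distortion rather than
the absolute electronic energy. Differences (S1 minus S0) of a, b and of
RMSD/E_average localize *excess* excited-state anharmonicity; the per-mode
relaxation energy

    lambda = E_S1(i=0) - min_i E_S1(i)

(evaluated on the fitted parabola over the scanned interval) probes
Franck-Condon activity: a mode whose excited-state minimum is displaced from
the ground-state equilibrium relaxes by lambda after vertical excitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from modescan.errors import DegenerateFitError, UndefinedRatioError

__all__ = [
    "QuadraticFit",
    "ModeMetrics",
    "fit_quadratic",
    "rmsd_ratio",
    "relaxation_energy",
    "mode_metrics",
]


@dataclass
class QuadraticFit:
    """Least-squares fit y = a*i^2 + b*i + c with its goodness-of-fit statistics.

    Units: a in eV per i^2, b in eV per i, c and rmsd in eV; r2 unitless.
    """

    a: float
    b: float
    c: float
    r2: float
    rmsd: float
    n_points: int

    def __call__(self, i: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(i) ** 2 + self.b * np.asarray(i) + self.c

    @property
    def vertex(self) -> float | None:
        """Abscissa of the parabola's extremum, None when a == 0."""
        if self.a == 0.0:
            return None
        return -self.b / (2.0 * self.a)


@dataclass
class ModeMetrics:
    """All per-mode statistics derived from the S0 and S1 quadratic fits."""

    mode_index: int
    fit_s0: QuadraticFit
    fit_s1: QuadraticFit
    rmsd_ratio_s0: float
    rmsd_ratio_s1: float
    delta_a: float
    delta_b: float
    delta_rmsd: float
    delta_rmsd_ratio: float
    lamda: float
    excitation_offset: float
    diabatized: bool = False
    lambda_fallback: bool = False
    frequency: float = float("nan")


def fit_quadratic(factors: Sequence[float], energies: Sequence[float]) -> QuadraticFit:
    """Unweighted least-squares quadratic fit of an energy scan.

    R^2 follows the usual 1 - SS_res/SS_tot convention; for a constant scan
    (SS_tot = 0) it is reported as 1 when the residuals also vanish, and the
    fit is otherwise an error.
    """
    x = np.asarray(factors, dtype=float)
    y = np.asarray(energies, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateFitError("factors and energies must be equal-length 1D sequences")
    n = x.size
    if np.unique(x).size < 3:
        raise DegenerateFitError(f"need >= 3 distinct factors, got {np.unique(x).size}")
    # polynomial.polyfit returns coefficients in ascending order (c, b, a)
    c, b, a = np.polynomial.polynomial.polyfit(x, y, 2)
    residuals = y - (a * x**2 + b * x + c)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmsd = float(np.sqrt(ss_res / n))
    if ss_tot == 0.0:
        if ss_res > 1e-20 * max(1.0, float(np.sum(y**2))):
            raise UndefinedRatioError("R^2 undefined: zero variance with nonzero residuals")
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return QuadraticFit(a=float(a), b=float(b), c=float(c), r2=r2, rmsd=rmsd, n_points=n)


def rmsd_ratio(
    fit: QuadraticFit,
    energies: Sequence[float],
    state_kind: Literal["ground", "excited"],
    excitation_offset: float = 0.0,
) -> float:
    """RMSD normalized by the mean scan energy.

    ground:  rmsd / mean(energies)
    excited: rmsd / (mean(energies) - excitation_offset), the offset being the
    vertical excitation energy so the denominator is the distortion-induced
    energy change.
    """
    y = np.asarray(energies, dtype=float)
    denom = float(y.mean())
    if state_kind == "excited":
        denom -= excitation_offset
    elif state_kind != "ground":
        raise ValueError(f"state_kind must be 'ground' or 'excited', got {state_kind!r}")
    if denom == 0.0:
        raise UndefinedRatioError("mean scan energy (minus offset) is zero")
    return fit.rmsd / denom


def relaxation_energy(
    fit_s1: QuadraticFit,
    factors: Sequence[float],
    energies_s1: Sequence[float],
) -> tuple[float, bool]:
    """Per-mode relaxation energy lambda and whether the raw-data fallback was used.

    Default: lambda = fit(0) - min of the fitted parabola over the scanned
    interval (the vertex value when the vertex lies inside the grid, else the
    lower fitted endpoint). When the fit is concave (a <= 0) there is no
    parabola minimum, so the minimum raw data point is used instead and the
    fallback is flagged. lambda is clamped at >= 0.
    """
    x = np.asarray(factors, dtype=float)
    y = np.asarray(energies_s1, dtype=float)
    if fit_s1.a > 0.0:
        vertex = -fit_s1.b / (2.0 * fit_s1.a)
        candidates = [float(fit_s1(x[0])), float(fit_s1(x[-1]))]
        if x[0] <= vertex <= x[-1]:
            candidates.append(float(fit_s1(vertex)))
        lam = float(fit_s1(0.0)) - min(candidates)
        fallback = False
    else:
        lam = float(y[np.argmin(np.abs(x))]) - float(y.min())
        fallback = True
    return max(lam, 0.0), fallback


def mode_metrics(
    scan,
    fits: dict[str, QuadraticFit],
    excitation_offset: float | None = None,
    ground_state: str = "S0",
    excited_state: str = "S1",
) -> ModeMetrics:
    """Combine per-state fits into the full per-mode metric record.

    All deltas are excited minus ground. The excitation offset defaults to
    E_excited(i=0) - E_ground(i=0) of this scan (the molecule's vertical
    excitation energy along this mode); pass a fixed value to override.
    """
    fit0 = fits[ground_state]
    fit1 = fits[excited_state]
    e0 = np.asarray(scan.energies[ground_state], dtype=float)
    e1 = np.asarray(scan.energies[excited_state], dtype=float)
    x = np.asarray(scan.factors, dtype=float)
    if excitation_offset is None:
        i0 = int(np.argmin(np.abs(x)))
        excitation_offset = float(e1[i0] - e0[i0])
    ratio0 = rmsd_ratio(fit0, e0, "ground")
    ratio1 = rmsd_ratio(fit1, e1, "excited", excitation_offset)
    lam, fallback = relaxation_energy(fit1, x, e1)
    return ModeMetrics(
        mode_index=scan.mode_index,
        fit_s0=fit0,
        fit_s1=fit1,
        rmsd_ratio_s0=ratio0,
        rmsd_ratio_s1=ratio1,
        delta_a=fit1.a - fit0.a,
        delta_b=fit1.b - fit0.b,
        delta_rmsd=fit1.rmsd - fit0.rmsd,
        delta_rmsd_ratio=ratio1 - ratio0,
        lamda=lam,
        excitation_offset=excitation_offset,
        diabatized=getattr(scan, "relabeled", False),
        lambda_fallback=fallback,
    )
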