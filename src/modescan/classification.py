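"""Mean + k*SD thresholding of the per-mode metrics and the eight-case taxonomy.

Three boolean flags are derived for every mode by comparing its metrics with
thresholds computed over the whole mode population (mean + k_sd standard
deviations; strict inequality, so a value exactly at the threshold is not
flagged):

* ``s0_anharmonic``         — S0 RMSD/E_average above its threshold;
* ``s1_excess_anharmonic``  — Delta RMSD/E_average (S1 - S0) above its threshold;
* ``fc_active``             — relaxation energy lambda above its threshold.

The 2 x 2 x 2 combinations map onto eight cases:

    1  S0 anharmonic, S1 excess,     FC active
    2  S0 anharmonic, S1 excess,     FC inactive
    3  S0 anharmonic, similar S1,    FC active
    4  S0 anharmonic, similar S1,    FC inactive
    5  S0 harmonic,   S1 anharmonic, FC active
    6  S0 harmonic,   S1 anharmonic, FC inactive
    7  both harmonic,                FC active
    8  both harmonic,                FC inactive
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from modescan.errors import InsufficientDataError
from modescan.harmonicity import ModeMetrics

SdConvention = Literal["sample", "population"]

#: Absolute floors for the thresholds: metric spreads at or below numerical
#: noise (e.g., a population of exact quadratics whose residuals are machine
#: epsilon) must never produce flags.
NUMERICAL_FLOOR_RATIO = 1e-9
NUMERICAL_FLOOR_LAMBDA = 1e-9  # eV

_CASE_TABLE = {
    # (s0_anharmonic, s1_excess_anharmonic, fc_active) -> case
    (True, True, True): 1,
    (True, True, False): 2,
    (True, False, True): 3,
    (True, False, False): 4,
    (False, True, True): 5,
    (False, True, False): 6,
    (False, False, True): 7,
    (False, False, False): 8,
}


@dataclass
class ThresholdSet:
    """Population-derived flag thresholds (mean + k_sd * SD of each metric)."""

    s0_anh_threshold: float
    s1_excess_threshold: float
    fc_threshold: float
    k_sd: float = 1.0
    sd_convention: SdConvention = "sample"


@dataclass
class CaseAssignment:
    mode_index: int
    s0_anharmonic: bool
    s1_excess_anharmonic: bool
    fc_active: bool
    case_number: int


def compute_thresholds(
    metrics: Sequence[ModeMetrics],
    k_sd: float = 1.0,
    sd_convention: SdConvention = "sample",
) -> ThresholdSet:
    """Thresholds = mean + k_sd * SD over the mode population for the three
    flag metrics (S0 RMSD/E_average, Delta RMSD/E_average, lambda)."""
    if len(metrics) < 2:
        raise InsufficientDataError(f"need >= 2 modes to compute thresholds, got {len(metrics)}")
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    ddof = 1 if sd_convention == "sample" else 0
    def thr(values: list[float], floor: float) -> float:
        arr = np.asarray(values, dtype=float)
        return max(float(arr.mean() + k_sd * arr.std(ddof=ddof)), floor)
    return ThresholdSet(
        s0_anh_threshold=thr([m.rmsd_ratio_s0 for m in metrics], NUMERICAL_FLOOR_RATIO),
        s1_excess_threshold=thr([m.delta_rmsd_ratio for m in metrics], NUMERICAL_FLOOR_RATIO),
        fc_threshold=thr([m.lamda for m in metrics], NUMERICAL_FLOOR_LAMBDA),
        k_sd=k_sd,
        sd_convention=sd_convention,
    )


def assign_case(metrics: ModeMetrics, thresholds: ThresholdSet) -> CaseAssignment:
    """Flag one mode against the population thresholds and map to a case 1-8."""
    s0 = metrics.rmsd_ratio_s0 > thresholds.s0_anh_threshold
    excess = metrics.delta_rmsd_ratio > thresholds.s1_excess_threshold
    fc = metrics.lamda > thresholds.fc_threshold
    return CaseAssignment(
        mode_index=metrics.mode_index,
        s0_anharmonic=s0,
        s1_excess_anharmonic=excess,
        fc_active=fc,
        case_number=_CASE_TABLE[(s0, excess, fc)],
    )


def classify_all(
    metrics: Sequence[ModeMetrics],
    k_sd: float = 1.0,
    sd_convention: SdConvention = "sample",
) -> tuple[ThresholdSet, list[CaseAssignment]]:
    """Compute thresholds from the population and assign every mode a case."""
    thresholds = compute_thresholds(metrics, k_sd=k_sd, sd_convention=sd_convention)
    return thresholds, [assign_case(m, thresholds) for m in metrics]
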