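import numpy as np
import pandas as pd
import pytest

from modescan.errors import AmbiguityError, CompletenessError, InsufficientDataError
from modescan.harmonicity import fit_quadratic
from modescan.mode_io import default_grid
from modescan.scan_model import (
    HARTREE_TO_EV,
    ScanSet,
    assemble_scans,
    detect_crossing,
    diabatize,
    scans_from_json,
    scans_to_json,
)
from modescan.synthetic import Harmonic, StateSpec, TwoStateSpec, _draw_scenario, generate_two_state

GRID = default_grid().factors


def table_from_arrays(factors, **states):
    rows = []
    for state, e in states.items():
        for i, ei in zip(factors, e):
            rows.append({"mode": 1, "i": i, "state": state, "energy": ei})
    return pd.DataFrame(rows)


class TestAssemble:
    def test_ground_reference_shift(self):
        t = table_from_arrays(GRID, S0=30 * GRID**2 + 100.0, S1=25 * GRID**2 + 103.0)
        (scan,) = assemble_scans(t)
        k0 = int(np.argwhere(scan.factors == 0.0)[0, 0])
        assert scan.energies["S0"][k0] == 0.0
        assert np.isclose(scan.energies["S1"][k0], 3.0)

    def test_hartree_conversion_codata(self):
        t = table_from_arrays(GRID, S0=np.where(GRID == 0, 0.0, 0.1))
        (scan,) = assemble_scans(t, unit="hartree")
        off_zero = scan.energies["S0"][GRID != 0]
        assert np.allclose(off_zero, 0.1 * HARTREE_TO_EV)
        assert np.allclose(off_zero, 2.7211, atol=1e-3)

    def test_missing_point_names_triple(self):
        t = table_from_arrays(GRID, S0=30 * GRID**2, S1=25 * GRID**2 + 3)
        t = t[~((t["state"] == "S1") & (np.isclose(t["i"], 0.07)))]
        with pytest.raises(CompletenessError, match=r"mode 1.*S1.*0\.07"):
            assemble_scans(t)

    def test_duplicate_record(self):
        t = table_from_arrays(GRID, S0=30 * GRID**2)
        t = pd.concat([t, t.iloc[[3]]], ignore_index=True)
        with pytest.raises(AmbiguityError):
            assemble_scans(t)

    def test_modes_ordered(self):
        t1 = table_from_arrays(GRID, S0=30 * GRID**2)
        t2 = t1.copy()
        t2["mode"] = 5
        scans = assemble_scans(pd.concat([t2, t1], ignore_index=True))
        assert [s.mode_index for s in scans] == [1, 5]


def crossing_spec(x_c=0.03, w=0.0, k=40.0):
    k1 = 0.8 * k
    delta2 = 0.12
    de1 = 3.0
    de2 = de1 + k1 * (x_c**2 - (x_c - delta2) ** 2)
    return TwoStateSpec(
        ground=StateSpec(Harmonic(k)),
        s1_diabat=StateSpec(Harmonic(k1), offset=de1),
        s2_diabat=StateSpec(Harmonic(k1), shift=delta2, offset=de2),
        coupling=w,
        require_crossing=True,
    )


class TestDetectCrossing:
    def test_zero_coupling_crossing_located_at_nearest_grid_point(self):
        table, truth = generate_two_state(crossing_spec(x_c=0.031))
        (scan,) = assemble_scans(table)
        report = detect_crossing(scan, "S1", "S2", 0.15)
        assert report is not None
        assert truth.crossing_position is not None
        nearest = int(np.argmin(np.abs(scan.factors - truth.crossing_position)))
        assert report.crossing_index == nearest

    def test_parallel_curves_give_none(self):
        scan = ScanSet(1, GRID, {"S1": 30 * GRID**2 + 3, "S2": 30 * GRID**2 + 4})
        assert detect_crossing(scan, "S1", "S2", 0.1) is None

    def test_endpoint_minimum_rejected(self):
        # gap shrinks monotonically toward the right edge: no interior minimum
        e1 = 30 * GRID**2 + 3
        e2 = e1 + 1.0 - 4.8 * (GRID + 0.1)
        assert np.min(e2 - e1) > 0
        scan = ScanSet(1, GRID, {"S1": e1, "S2": e2})
        assert detect_crossing(scan, "S1", "S2", 0.15) is None

    def test_symmetric_in_states(self):
        table, _ = generate_two_state(crossing_spec())
        (scan,) = assemble_scans(table)
        r_ab = detect_crossing(scan, "S1", "S2", 0.15)
        r_ba = detect_crossing(scan, "S2", "S1", 0.15)
        assert r_ab.crossing_index == r_ba.crossing_index
        assert r_ab.gap_min == r_ba.gap_min
        assert r_ab.delta_E_CI_S1min == r_ba.delta_E_CI_S1min

    def test_too_few_points(self):
        scan = ScanSet(1, GRID[:4], {"S1": np.ones(4), "S2": 2 * np.ones(4)})
        with pytest.raises(InsufficientDataError):
            detect_crossing(scan, "S1", "S2", 0.15)

    def test_ci_energy_above_s1_minimum(self):
        table, _ = generate_two_state(crossing_spec())
        (scan,) = assemble_scans(table)
        report = detect_crossing(scan, "S1", "S2", 0.15)
        assert report.delta_E_CI_S1min >= 0

    def test_avoided_crossing_above_threshold_not_flagged(self):
        # constant coupling 0.5 eV: adiabatic gap >= 2w = 1.0 eV everywhere
        spec = crossing_spec(w=0.5)
        table, _ = generate_two_state(spec)
        (scan,) = assemble_scans(table)
        gap = np.abs(scan.energies["S2"] - scan.energies["S1"])
        assert gap.min() >= 2 * 0.5 - 1e-9
        assert detect_crossing(scan, "S1", "S2", 0.15) is None


class TestDiabatize:
    def _diabatized(self, x_c=0.03):
        spec = crossing_spec(x_c=x_c)
        table, truth = generate_two_state(spec)
        (scan,) = assemble_scans(table)
        report = detect_crossing(scan, "S1", "S2", 0.15)
        return spec, truth, scan, report, diabatize(scan, report)

    def test_exact_recovery_of_diabats(self):
        spec, truth, scan, report, d = self._diabatized()
        assert d.relabeled and report.swapped
        assert np.allclose(d.energies["S1"], spec.s1_diabat(d.factors), atol=1e-10)
        assert np.allclose(d.energies["S2"], spec.s2_diabat(d.factors), atol=1e-10)

    def test_no_crossing_is_noop(self):
        scan = ScanSet(1, GRID, {"S1": 30 * GRID**2 + 3, "S2": 30 * GRID**2 + 4})
        assert diabatize(scan, None) is scan

    def test_energy_multiset_conserved(self):
        _, _, scan, _, d = self._diabatized()
        for k in range(len(GRID)):
            before = sorted(scan.energies[s][k] for s in ("S1", "S2"))
            after = sorted(d.energies[s][k] for s in ("S1", "S2"))
            assert before == after

    def test_idempotent(self):
        _, _, scan, report, d = self._diabatized()
        d2 = diabatize(d, report)
        assert np.array_equal(d2.energies["S1"], d.energies["S1"])
        assert np.array_equal(d2.energies["S2"], d.energies["S2"])

    def test_swap_reduces_rmsd_over_100_draws(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            spec = _draw_scenario("crossing", 1, rng)
            table, _ = generate_two_state(spec)
            (scan,) = assemble_scans(table)
            report = detect_crossing(scan, "S1", "S2", 0.15)
            assert report is not None
            before = sum(fit_quadratic(GRID, scan.energies[s]).rmsd for s in ("S1", "S2"))
            d = diabatize(scan, report)
            after = sum(fit_quadratic(GRID, d.energies[s]).rmsd for s in ("S1", "S2"))
            assert after < before  # strict in the crossing case


class TestArchive:
    def test_json_round_trip(self, tmp_path):
        table, _ = generate_two_state(crossing_spec())
        (scan,) = assemble_scans(table)
        report = detect_crossing(scan, "S1", "S2", 0.15)
        d = diabatize(scan, report)
        path = tmp_path / "scans.json"
        scans_to_json([d], {1: report}, path)
        scans2, crossings2 = scans_from_json(path)
        assert np.allclose(scans2[0].energies["S1"], d.energies["S1"])
        assert scans2[0].relabeled
        assert crossings2[1].crossing_index == report.crossing_index
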