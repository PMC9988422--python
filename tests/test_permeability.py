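"""Clearance pipeline: cleared volume, PS slope fit, membrane correction, Pe, TEER."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transwellbench import (
    ClearancePoint,
    InsertGeometry,
    PermeabilitySurfaceProduct,
    Sample,
    TeerRecord,
    Timecourse,
    SimulationConfig,
    cleared_volume,
    compute_pe,
    correct_for_membrane,
    fit_ps,
    pe_from_ps,
    simulate_assay,
    teer,
)
from transwellbench.errors import (
    InsufficientDataError,
    MembraneInconsistencyError,
    NegativeNetResistanceError,
    UnusableFitError,
    ValidationError,
)
from transwellbench.permeability import PE_UNIT_FACTOR, clearance_points

from conftest import ols_slope_intercept


class TestClearedVolume:
    @pytest.mark.parametrize(
        "receiver_conc, receiver_volume, donor_conc, expected",
        [
            (0.0, 600.0, 10.0, 0.0),
            (1.0, 600.0, 10.0, 60.0),
            (0.05, 900.0, 5.0, 9.0),  # hand arithmetic: 0.05*900/5
        ],
    )
    def test_values(self, receiver_conc, receiver_volume, donor_conc, expected):
        assert cleared_volume(receiver_conc, receiver_volume, donor_conc) == pytest.approx(expected)

    def test_zero_donor_rejected(self):
        with pytest.raises(ValidationError):
            cleared_volume(1.0, 600.0, 0.0)


class TestFitPs:
    def test_exact_line(self):
        pts = [ClearancePoint(t, t) for t in (15, 30, 45, 60)]
        fit = fit_ps(pts)
        assert fit.value == pytest.approx(1.0)
        assert fit.fit_r2 == pytest.approx(1.0)
        assert fit.usable and fit.n_points == 4

    def test_all_zero_volumes_flagged_unusable(self):
        pts = [ClearancePoint(t, 0.0) for t in (15, 30, 45, 60)]
        fit = fit_ps(pts)
        assert fit.value == 0.0 and not fit.usable
        assert "nonpositive_slope" in fit.flags

    def test_matches_normal_equations_oracle(self):
        times = [15.0, 30.0, 45.0, 60.0]
        vols = [10.0, 22.0, 29.0, 41.0]
        slope, intercept = ols_slope_intercept(times, vols)
        fit = fit_ps([ClearancePoint(t, v) for t, v in zip(times, vols)])
        assert fit.value == pytest.approx(slope)  # = 0.6667 uL/min by hand
        assert slope == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept)

    def test_insufficient_points(self):
        with pytest.raises(InsufficientDataError):
            fit_ps([ClearancePoint(15, 1.0)])
        with pytest.raises(InsufficientDataError):
            fit_ps([ClearancePoint(15, 1.0), ClearancePoint(15, 2.0)])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        times=st.lists(st.integers(min_value=1, max_value=500), min_size=2, max_size=8, unique=True),
        data=st.data(),
    )
    def test_equals_closed_form_ols_on_random_instances(self, times, data):
        """Property: the fitted PS is the normal-equations slope, always."""
        times = sorted(float(t) for t in times)
        vols = [data.draw(st.floats(min_value=-50, max_value=50)) for _ in times]
        slope, _ = ols_slope_intercept(times, vols)
        fit = fit_ps([ClearancePoint(t, v) for t, v in zip(times, vols)])
        assert fit.value == pytest.approx(slope, abs=1e-9)


class TestMembraneCorrection:
    def _ps(self, value, condition="total"):
        return PermeabilitySurfaceProduct(value=value, condition=condition, n_points=4)

    def test_analytic_case(self):
        out = correct_for_membrane(self._ps(2.0), self._ps(4.0, "membrane"))
        assert out.value == pytest.approx(4.0)  # 1/(1/2 - 1/4)
        assert out.condition == "corrected"

    def test_very_permeable_blank_limit(self):
        out = correct_for_membrane(self._ps(1.0), self._ps(1e6, "membrane"))
        assert out.value == pytest.approx(1.0, rel=1e-4)

    def test_equal_ps_rejected(self):
        with pytest.raises(MembraneInconsistencyError):
            correct_for_membrane(self._ps(4.0), self._ps(4.0, "membrane"))

    def test_unusable_input_propagates(self):
        bad = PermeabilitySurfaceProduct(-0.1, "total", 4, usable=False)
        with pytest.raises(UnusableFitError):
            correct_for_membrane(bad, self._ps(4.0, "membrane"))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        ps_total=st.floats(min_value=0.01, max_value=10.0),
        factor=st.floats(min_value=1.001, max_value=1e6),
    )
    def test_corrected_always_at_least_total(self, ps_total, factor):
        """Removing the membrane's series resistance can only increase PS."""
        out = correct_for_membrane(
            self._ps(ps_total), self._ps(ps_total * factor, "membrane")
        )
        assert out.value >= ps_total


class TestPeFromPs:
    def test_unit_chain(self, geometry):
        ps = PermeabilitySurfaceProduct(4.0, "corrected", 4)
        pe = pe_from_ps(ps, geometry)
        # 4 uL/min = 4e-3 cm^3/min over 0.33 cm^2, /60 s -> 202.0e-6 cm/s
        assert pe.pe == pytest.approx(202.0, abs=0.1)
        assert pe.corrected

    def test_unit_chain_unit_area(self):
        geo = InsertGeometry(1.0, 400, 600)
        ps = PermeabilitySurfaceProduct(0.6, "corrected", 4)
        assert pe_from_ps(ps, geo).pe == pytest.approx(10.0)

    def test_doubling_area_halves_pe(self, geometry):
        ps = PermeabilitySurfaceProduct(1.0, "corrected", 4)
        double = InsertGeometry(2 * geometry.membrane_area, 400, 600)
        assert pe_from_ps(ps, geometry).pe == pytest.approx(2 * pe_from_ps(ps, double).pe)


class TestComputePe:
    def test_recovers_simulated_pe_in_sink_regime(self, geometry):
        """Noise-free forward model as oracle: configured Pe is recovered
        within 2% when every insert stays under 10% donor depletion."""
        cfg = SimulationConfig(
            geometry=geometry,
            ps_passive=2.0 * geometry.membrane_area / PE_UNIT_FACTOR,  # Pe 2e-6 cm/s
            ps_membrane_blank=20.0 * geometry.membrane_area / PE_UNIT_FACTOR,
            noise_cv=0.0,
            replicates=1,
        )
        cells = simulate_assay(cfg, "A2B", "cells")
        blank = simulate_assay(cfg, "A2B", "blank")
        pe = compute_pe(cells, blank, geometry)
        assert pe.pe == pytest.approx(cfg.true_pe("A2B"), rel=0.02)

    def test_zero_receiver_signal_is_unusable(self, geometry):
        flat = Timecourse(
            "s", "A2B", "E1", "r1", "cells", 5.0,
            tuple(Sample(t, 0.0, 5.0) for t in (15, 30, 45, 60)),
        )
        blank = Timecourse(
            "s", "A2B", "E1", "r1", "blank", 5.0,
            tuple(Sample(t, 0.001 * t, 5.0) for t in (15, 30, 45, 60)),
        )
        with pytest.raises(UnusableFitError, match="total"):
            compute_pe(flat, blank, geometry)

    def test_nominal_and_measured_donor_agree_under_sink(self, geometry):
        """With <10% donor depletion, dropping the measured donor column
        (sink approximation) changes Pe by well under 10%."""
        cfg = SimulationConfig(
            geometry=geometry,
            ps_passive=2.0 * geometry.membrane_area / PE_UNIT_FACTOR,
            ps_membrane_blank=20.0 * geometry.membrane_area / PE_UNIT_FACTOR,
            noise_cv=0.0,
            replicates=1,
        )
        cells = simulate_assay(cfg, "A2B", "cells")
        blank = simulate_assay(cfg, "A2B", "blank")
        measured = compute_pe(cells, blank, geometry, donor_mode="measured")
        nominal = compute_pe(cells, blank, geometry, donor_mode="nominal")
        assert nominal.pe == pytest.approx(measured.pe, rel=0.10)

    def test_pe_is_unit_invariant(self, geometry):
        """Rescaling every concentration by a common factor leaves Pe unchanged."""
        cfg = SimulationConfig(geometry=geometry, noise_cv=0.0, replicates=1)
        cells = simulate_assay(cfg, "A2B", "cells")
        blank = simulate_assay(cfg, "A2B", "blank")

        def rescale(tc, c):
            return Timecourse(
                tc.substrate_id, tc.direction, tc.experiment_id, tc.replicate_id,
                tc.insert_condition, tc.donor_initial_concentration * c,
                tuple(Sample(s.time, s.receiver_conc * c, s.donor_conc * c) for s in tc.samples),
            )

        base = compute_pe(cells, blank, geometry)
        scaled = compute_pe(rescale(cells, 137.0), rescale(blank, 137.0), geometry)
        assert scaled.pe == pytest.approx(base.pe, rel=1e-9)

    def test_clearance_points_donor_modes(self, geometry):
        tc = Timecourse(
            "s", "A2B", "E1", "r1", "cells", 10.0,
            (Sample(15, 0.1, 8.0), Sample(30, 0.2, None)),
        )
        measured = clearance_points(tc, geometry, "measured")
        assert measured[0].cleared_volume == pytest.approx(0.1 * 600 / 8.0)
        assert measured[1].cleared_volume == pytest.approx(0.2 * 600 / 10.0)  # fallback
        nominal = clearance_points(tc, geometry, "nominal")
        assert nominal[0].cleared_volume == pytest.approx(0.1 * 600 / 10.0)


class TestTeer:
    @pytest.mark.parametrize(
        "coculture, blank, area, expected",
        [(100.0, 20.0, 0.33, 26.4), (50.0, 50.0, 0.33, 0.0)],
    )
    def test_values(self, coculture, blank, area, expected):
        assert teer(TeerRecord(coculture, blank, area)) == pytest.approx(expected)

    def test_negative_net_resistance(self):
        with pytest.raises(NegativeNetResistanceError):
            teer(TeerRecord(10.0, 20.0, 0.33))
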