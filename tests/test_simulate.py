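"""Forward-model correctness: closed form, conservation, determinism, recovery."""

import math

import numpy as np
import pytest

from transwellbench import (
    SimulationConfig,
    analyze_bidirectional,
    simulate_assay,
    simulate_bidirectional_experiment,
    simulate_competition,
    simulate_study,
    save_simulation,
    read_timecourses,
)
from transwellbench.errors import ValidationError
from transwellbench.permeability import PE_UNIT_FACTOR


def pe_to_ps(pe, geometry):
    return pe * geometry.membrane_area / PE_UNIT_FACTOR


class TestForwardModel:
    def test_blank_matches_closed_form_relaxation(self, geometry):
        """Independent closed-form oracle: A_r(t) = A_eq (1 - e^{-kt}) with
        k = PS/V_d + PS/V_r and A_eq = (PS A_tot / V_d)/k."""
        cfg = SimulationConfig(geometry=geometry, noise_cv=0.0, ps_membrane_blank=4.0)
        tc = simulate_assay(cfg, "A2B", "blank")
        ps, vd, vr = 4.0, 400.0, 600.0
        a_tot = cfg.dosing_concentration * vd
        k = ps / vd + ps / vr
        a_eq = ps * a_tot / vd / k
        for s in tc.samples:
            expected = a_eq * (1.0 - math.exp(-k * s.time)) / vr
            assert s.receiver_conc == pytest.approx(expected, rel=1e-12)

    def test_mass_conservation_noise_free(self, geometry):
        for km in (None, 0.5):  # closed form and numeric integrator
            cfg = SimulationConfig(
                geometry=geometry, noise_cv=0.0, ps_active=0.1, km=km
            )
            for direction in ("A2B", "B2A"):
                tc = simulate_assay(cfg, direction, "cells")
                vd = geometry.donor_volume(direction)
                vr = geometry.receiver_volume(direction)
                total0 = cfg.dosing_concentration * vd
                for s in tc.samples:
                    total = s.donor_conc * vd + s.receiver_conc * vr
                    assert total == pytest.approx(total0, rel=1e-6)

    def test_same_seed_is_bit_identical(self, geometry):
        cfg = SimulationConfig(geometry=geometry, seed=7)
        assert simulate_assay(cfg, "A2B", "cells") == simulate_assay(cfg, "A2B", "cells")
        t1, _ = simulate_bidirectional_experiment(cfg)
        t2, _ = simulate_bidirectional_experiment(cfg)
        assert t1 == t2

    def test_saturation_reduces_active_transport(self, geometry):
        """With km far below the dosing concentration the pump is mostly
        saturated away and the directional asymmetry shrinks."""
        base = dict(geometry=geometry, noise_cv=0.0, ps_active=0.15, replicates=1)
        linear = SimulationConfig(**base)
        saturated = SimulationConfig(**base, km=0.01)  # dosing_concentration = 1
        r_lin = simulate_assay(linear, "B2A", "cells").samples[-1].receiver_conc
        r_sat = simulate_assay(saturated, "B2A", "cells").samples[-1].receiver_conc
        r_passive = simulate_assay(
            SimulationConfig(geometry=geometry, noise_cv=0.0, replicates=1), "B2A", "cells"
        ).samples[-1].receiver_conc
        assert r_sat < r_lin
        assert r_sat == pytest.approx(r_passive, rel=0.05)

    def test_invalid_config_names_field(self):
        with pytest.raises(ValidationError, match="ps_active"):
            SimulationConfig(ps_passive=0.4, ps_active=0.5)
        with pytest.raises(ValidationError, match="sample_times"):
            SimulationConfig(sample_times=(30.0, 15.0))
        with pytest.raises(ValidationError, match="noise_cv"):
            SimulationConfig(noise_cv=-0.1)


class TestParameterRecovery:
    def test_noise_free_er_recovery_in_sink_regime(self, geometry):
        """Full pipeline (clearance -> PS -> membrane correction -> Pe -> ER)
        recovers a configured ER of 2 within 2% when every insert, blank
        included, keeps donor depletion below 10% over the 60-min window."""
        cfg = SimulationConfig.from_target_pe(
            2.0, 4.0, geometry,
            ps_membrane_blank=10 * pe_to_ps(3.0, geometry),
            noise_cv=0.0, replicates=1,
        )
        tcs, truth = simulate_bidirectional_experiment(cfg)
        depletion = max(
            1 - tc.samples[-1].donor_conc / tc.donor_initial_concentration for tc in tcs
        )
        assert depletion < 0.10
        (res,) = analyze_bidirectional(tcs, geometry)
        assert truth.er == pytest.approx(2.0)
        assert res.experiments[0].er == pytest.approx(truth.er, rel=0.02)

    def test_symmetric_layer_gives_unit_er(self, geometry):
        cfg = SimulationConfig(geometry=geometry, noise_cv=0.0, replicates=1)
        tcs, truth = simulate_bidirectional_experiment(cfg)
        (res,) = analyze_bidirectional(tcs, geometry)
        assert truth.er == 1.0
        assert res.experiments[0].er == pytest.approx(1.0, rel=0.01)

    def test_er_grid_recovery_noise_free(self, geometry):
        """Seeded grid of (passive, active) pairs inside the estimator's
        validity envelope: ER recovered within 2% everywhere."""
        for pe_a2b, ratio in [(1.0, 1.5), (2.0, 2.0), (1.5, 3.0)]:
            cfg = SimulationConfig.from_target_pe(
                pe_a2b, pe_a2b * ratio, geometry,
                ps_membrane_blank=10 * pe_to_ps(pe_a2b * (1 + ratio) / 2, geometry),
                noise_cv=0.0, replicates=1,
            )
            tcs, truth = simulate_bidirectional_experiment(cfg)
            (res,) = analyze_bidirectional(tcs, geometry)
            assert res.experiments[0].er == pytest.approx(truth.er, rel=0.02)

    def test_noisy_aggregate_er_within_three_sem(self, geometry):
        """Monte-Carlo check at a fixed seed: the study-level mean ER lies
        within 3 standard errors of the configured truth."""
        cfg = SimulationConfig.from_target_pe(
            2.0, 4.0, geometry,
            ps_membrane_blank=10 * pe_to_ps(3.0, geometry),
            noise_cv=0.1, replicates=3, seed=42,
        )
        tcs, truth = simulate_study(cfg, n_experiments=4)
        (res,) = analyze_bidirectional(tcs, geometry)
        sem = res.er_sd / math.sqrt(res.n)
        assert abs(res.er_mean - truth.er) < 3 * sem

    def test_blank_correction_shifts_pe_by_expected_factor(self, geometry):
        """With PS_mem = 10x the passive PS, the corrected Pe should exceed the
        uncorrected one by the series-barrier factor 1/(1 - PS_total/PS_mem)."""
        cfg = SimulationConfig(geometry=geometry, noise_cv=0.0, replicates=1,
                               ps_passive=0.04, ps_membrane_blank=0.4)
        tcs, _ = simulate_bidirectional_experiment(cfg)
        (corr,) = analyze_bidirectional(tcs, geometry, correct=True)
        (uncorr,) = analyze_bidirectional(tcs, geometry, correct=False)
        ps_total = 1 / (1 / 0.04 + 1 / 0.4)
        expected_factor = 1 / (1 - ps_total / 0.4)
        measured = corr.experiments[0].pe_a2b / uncorr.experiments[0].pe_a2b
        assert measured == pytest.approx(expected_factor, rel=0.02)


class TestCompetitionSimulator:
    def test_rmt_off_arms_identical_noise_free(self):
        cfg = SimulationConfig(rmt_mode="off", noise_cv=0.0)
        assay = simulate_competition(cfg)
        assert assay.labeled_alone == assay.labeled_plus_competitor

    def test_equimolar_competitor_occupancy_ratio(self):
        """L = U = Kd with no passive leak: the competitor arm is exactly 2/3
        of the alone arm (occupancy algebra of the stated transport law)."""
        cfg = SimulationConfig(
            rmt_mode="on", rmt_kd=200.0, rmt_capacity=10.0, rmt_leak=0.0, noise_cv=0.0
        )
        assay = simulate_competition(cfg, labeled_dose=200.0, competitor_dose=200.0)
        ratio = np.mean(assay.labeled_plus_competitor) / np.mean(assay.labeled_alone)
        assert ratio == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_leak_equal_to_receptor_component_gives_five_sixths(self):
        # alone arm: receptor = cap*L/(kd+L) = cap/2; leak chosen equal to it
        kd = 200.0
        cap = 10.0
        leak = (cap / 2.0) / kd  # leak*L = cap/2 at L = kd
        cfg = SimulationConfig(
            rmt_mode="on", rmt_kd=kd, rmt_capacity=cap, rmt_leak=leak, noise_cv=0.0
        )
        assay = simulate_competition(cfg, labeled_dose=kd, competitor_dose=kd)
        ratio = np.mean(assay.labeled_plus_competitor) / np.mean(assay.labeled_alone)
        assert ratio == pytest.approx(5.0 / 6.0, rel=1e-12)


class TestProvenance:
    def test_save_simulation_round_trip_with_sidecar(self, tmp_path, geometry):
        cfg = SimulationConfig(geometry=geometry, seed=3, replicates=2)
        tcs, truth = simulate_bidirectional_experiment(cfg)
        csv_path = tmp_path / "sim.csv"
        sidecar = save_simulation(tcs, truth, cfg, csv_path)
        assert sidecar.exists() and "seed" in sidecar.read_text()
        back = read_timecourses(
            csv_path, geometry, dosing_concentrations={"sim": cfg.dosing_concentration}
        )
        assert len(back) == len(tcs)
        assert sorted(back, key=lambda t: t.group_key) == sorted(tcs, key=lambda t: t.group_key)
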