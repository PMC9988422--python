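"""Clearance-slope permeability from a tidy assay CSV, plus TEER.

Simulates one noise-free bidirectional experiment, writes it to the tidy CSV
format, reads it back, and runs the clearance pipeline: cleared volume per
timepoint -> PS slope -> blank-membrane correction -> Pe (10^-6 cm/s).
"""

import tempfile
from pathlib import Path

from transwellbench import (
    SimulationConfig,
    TeerRecord,
    analyze_bidirectional,
    read_timecourses,
    save_simulation,
    simulate_bidirectional_experiment,
    teer,
)

# a moderately tight barrier: true Pe 2 (A->B) vs 4 (B->A) x 1e-6 cm/s,
# i.e. an apically polarized efflux pump with true ER = 2
config = SimulationConfig.from_target_pe(2.0, 4.0, noise_cv=0.0, replicates=2)

with tempfile.TemporaryDirectory() as tmp:
    csv_path = Path(tmp) / "assay.csv"
    timecourses, truth = simulate_bidirectional_experiment(config)
    sidecar = save_simulation(timecourses, truth, config, csv_path)
    print(f"wrote {len(timecourses)} timecourses to {csv_path.name} (+ {sidecar.name})")

    back = read_timecourses(
        csv_path, config.geometry, dosing_concentrations={"sim": config.dosing_concentration}
    )
    (result,) = analyze_bidirectional(back, config.geometry)

experiment = result.experiments[0]
print(f"true  Pe A->B = {truth.pe_a2b:5.2f}, Pe B->A = {truth.pe_b2a:5.2f}  (x 1e-6 cm/s)")
print(f"fitted Pe A->B = {experiment.pe_a2b:5.2f}, Pe B->A = {experiment.pe_b2a:5.2f}")
print(f"efflux ratio: fitted {experiment.er:.3f} vs true {truth.er:.3f}")
print()

record = TeerRecord(coculture_resistance=100.0, blank_membrane_resistance=20.0, membrane_area=0.33)
print(f"TEER for a 100-ohm coculture over a 20-ohm blank membrane: {teer(record):.1f} Ohm*cm^2")
print()
print(
    "Fitted Pe comes from the slope of cleared volume vs time, corrected for\n"
    "the blank insert's series resistance; with zero noise it matches the\n"
    "configured ground truth to within the estimator's small sink-condition bias."
)
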