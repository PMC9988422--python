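"""Assemble the benchmark scorecard and compare two facilities.

Combines the bundled reference efflux results, a tracer tightness check,
a TEER reading, a simulated competition assay and declared expression
evidence into the pass/fail/not-assessed scorecard, then checks
inter-facility agreement of the efflux summaries.
"""

from transwellbench import (
    DeclaredEvidence,
    EffluxResult,
    SimulationConfig,
    TeerRecord,
    build_report,
    compare_facilities,
    competition_test,
    format_report,
    simulate_competition,
)
from transwellbench.datasets import FACILITY2_SUMMARIES, load_reference_efflux

reference = load_reference_efflux()

# transferrin transport in this model was passive: simulate the matching
# competition assay (no receptor component) for the RMT item
competition = competition_test(simulate_competition(SimulationConfig(rmt_mode="off", seed=5)))

declared = {
    item: DeclaredEvidence(True, "single band at expected size; membrane localization")
    for item in (
        "cd31_expression",
        "zo1_expression_localization",
        "pgp_expression",
        "bcrp_expression",
        "glut1_expression",
        "tfr_expression",
    )
}

items = build_report(
    efflux_results=list(reference.values()),
    tightness=([88.0, 90.2, 92.0], [1100.0, 1165.0, 1230.0]),  # LY-like vs caffeine-like Pe
    teer=TeerRecord(coculture_resistance=100.0, blank_membrane_resistance=20.0, membrane_area=0.33),
    competition=competition,
    declared_evidence=declared,
)
print(format_report(items))

print()
for substrate, (er_mean, er_sd, n) in FACILITY2_SUMMARIES.items():
    facility2 = EffluxResult.from_summary(substrate, er_mean, er_sd, n)
    comparison = compare_facilities(reference[substrate], facility2)
    m1, s1 = reference[substrate].rounded(1)
    print(
        f"{substrate:11s} facility 1: {m1} +/- {s1} (n={reference[substrate].n})  "
        f"facility 2: {er_mean} +/- {er_sd} (n={n})  -> "
        f"{'agree' if comparison.agree else 'disagree'}"
    )
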