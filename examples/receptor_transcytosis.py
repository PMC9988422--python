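"""Saturation and competition analysis of receptor-mediated transcytosis.

Checks a dose-uptake curve for saturability (slope drop beyond a breakpoint)
and runs the labeled-vs-unlabeled-competitor test on simulated assays in
both receptor-mediated and passive modes.
"""

from transwellbench import (
    DoseUptakeSeries,
    SimulationConfig,
    competition_test,
    saturation_check,
    simulate_competition,
)

# dose-uptake curve from a finite-capacity receptor (Langmuir binding with
# half-saturation at the 2400-pmol breakpoint)
km, vmax = 2400.0, 100.0
doses = (240.0, 720.0, 1440.0, 2400.0, 4800.0, 9600.0, 24000.0)
series = DoseUptakeSeries(doses, tuple(vmax * d / (km + d) for d in doses))
verdict = saturation_check(series, breakpoint=km)
print(
    f"saturation: slope {verdict.slope_low:.4f} -> {verdict.slope_high:.4f} "
    f"(drop {verdict.relative_slope_drop:.0%}) => {verdict.verdict}"
)

for mode in ("on", "off"):
    config = SimulationConfig(rmt_mode=mode, seed=11)
    assay = simulate_competition(config, labeled_dose=200.0, competitor_dose=200.0)
    outcome = competition_test(assay)
    print(
        f"competition (receptor transport {mode:3s}): "
        f"ratio with/without competitor = {outcome.transport_ratio:.2f}, "
        f"p = {outcome.p_value:.3g} => {outcome.verdict}"
    )

print()
print(
    "A saturable dose-response plus a significant drop under equimolar\n"
    "unlabeled competitor is the signature of receptor-mediated transcytosis;\n"
    "unchanged transport (ratio ~1) indicates passive/fluid-phase transfer."
)
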