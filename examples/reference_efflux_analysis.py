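"""Recompute efflux-ratio summaries from the bundled reference dataset.

Loads the packaged per-experiment directional Pe pairs (seven transporter
substrates measured by bidirectional assay in a tricellular transwell BBB
model), aggregates the per-experiment efflux ratios into mean +/- sample SD,
and classifies each transporter's efflux function.
"""

from transwellbench import classify_transporter
from transwellbench.datasets import load_reference_efflux

results = load_reference_efflux()

print(f"{'substrate':14s} {'transporter':11s} {'ER mean':>7s} {'SD':>5s} {'n':>2s}  classification")
for substrate, result in results.items():
    mean, sd = result.rounded(1)
    print(
        f"{substrate:14s} {result.transporter:11s} {mean:7.1f} {sd:5.1f} "
        f"{result.n:2d}  {classify_transporter(result)}"
    )

print()
print(
    "ER = Pe(B->A)/Pe(A->B); ER > 1 with significant directional asymmetry\n"
    "in at least half the experiments indicates functional efflux transport\n"
    "(expected for the P-gp and BCRP substrates, absent for the Glut1\n"
    "substrate 2-NBDG and for transferrin)."
)
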