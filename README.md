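# transwellbench

Benchmark analysis for transwell blood–brain-barrier (BBB) models and
microphysiological systems: given bidirectional transport timecourses from
cell-bearing and blank inserts, the package computes clearance-slope
permeability coefficients with blank-membrane correction, TEER, efflux
ratios with directional significance testing, receptor-mediated-transcytosis
(RMT) saturation/competition verdicts, and assembles them into a
pass/fail/not-assessed benchmark scorecard with inter-facility
reproducibility comparison. A ground-truthed forward simulator of
two-compartment transwell assays lets every stage be exercised and validated
without external data.

It is written for DMPK / in-vitro ADME scientists characterizing BBB models
(is the barrier tight? are P-gp and BCRP functional? is transferrin
transport receptor-mediated?) and for developers of such models who need a
reproducible, scriptable evaluation pipeline.

## The method

For each sampled timepoint the **cleared volume** is

```
V(t) = C_r(t) · V_r / C_d(t)        [μL]
```

with `C_r`, `C_d` the receiver/donor concentrations and `V_r` the receiver
volume. Under sink conditions V(t) is linear in time and its ordinary
least-squares slope is the permeability–surface-area product **PS**
(μL/min). The cell layer is isolated from the insert's porous membrane by
the series-barrier relation

```
1/PS_e = 1/PS_total − 1/PS_mem
```

(`PS_total`: cell-bearing insert, `PS_mem`: blank insert), and the
permeability coefficient of the cell layer is

```
Pe = PS_e / S        reported in 10⁻⁶ cm/s   (S = membrane area, cm²)
```

The **efflux ratio** per independent experiment is
`ER = Pe(B→A) / Pe(A→B)`; substrates are summarized as mean ± sample SD of
per-experiment ERs, with directional significance from a two-tailed
equal-variance Student's t-test (`**` p<0.01, `*` p<0.05). ER > 1 with
reproducible significant asymmetry indicates functional efflux (P-gp,
BCRP). TEER is net resistance × area: `(R_coculture − R_blank) · S` in
Ω·cm². RMT is probed by a two-slope saturation check on dose–uptake curves
and by competition of labeled ligand with unlabeled competitor.

## Worked example

```
python examples/reference_efflux_analysis.py
```

prints, from the bundled per-experiment reference dataset:

```
substrate      transporter ER mean    SD  n  classification
rhodamine123   P-gp            2.2   2.0  4  efflux_functional
hoechst33342   BCRP            3.1   2.3  4  efflux_functional
2-NBDG         Glut1           1.1   0.4  4  not_demonstrated
transferrin    TfR             0.7   0.2  3  not_demonstrated
digoxin        P-gp            1.3   0.2  4  efflux_functional
dantrolene     BCRP            2.3   0.9  4  efflux_functional
SASP           BCRP            1.4   0.3  4  efflux_functional
```

Each row is the mean ± sample SD of the per-experiment efflux ratios
recomputed from the stored directional Pe pairs; the classification applies
the default decision rule (mean ER > 1 and at least half the experiments
significantly B→A-dominant). The pattern — efflux function demonstrated for
the P-gp and BCRP substrates but not for the Glut1 substrate or transferrin
— is what a conventional static transwell BBB model is expected to show.

Other examples: `examples/permeability_from_csv.py` (tidy-CSV round trip
through the full clearance pipeline plus TEER),
`examples/receptor_transcytosis.py` (saturation + competition verdicts),
`examples/benchmark_scorecard.py` (full scorecard and two-facility
comparison).

## Layout

- `src/transwellbench/assay_io.py` — domain types, tidy-CSV and YAML config I/O
- `src/transwellbench/permeability.py` — cleared volume, PS fit, membrane correction, Pe, TEER
- `src/transwellbench/efflux.py` — efflux ratios, aggregation, t-tests, classification
- `src/transwellbench/transcytosis.py` — saturation and competition analysis
- `src/transwellbench/benchmark.py` — scorecard and facility comparison
- `src/transwellbench/simulate.py` — two-compartment forward simulator
- `src/transwellbench/datasets.py` — bundled reference efflux dataset
- `docs/methods.md` — model assumptions, parameter choices, validity envelope
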