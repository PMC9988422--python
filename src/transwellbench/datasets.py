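"""Bundled reference data.

``reference_efflux_pe.csv`` carries published per-experiment directional
permeability coefficients (Pe, 10⁻⁶ cm/s) for seven transporter substrates
measured by bidirectional assay in a humanized tricellular static transwell
BBB model, together with each experiment's directional-significance mark.
The second facility in the same inter-laboratory comparison reported only
summary efflux ratios (mean ± SD, n); those are provided as constants.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .efflux import EffluxExperiment, EffluxResult

__all__ = [
    "load_reference_efflux",
    "load_reference_efflux_frame",
    "FACILITY2_SUMMARIES",
    "REFERENCE_SUBSTRATES",
]

REFERENCE_SUBSTRATES = (
    "rhodamine123",
    "hoechst33342",
    "2-NBDG",
    "transferrin",
    "digoxin",
    "dantrolene",
    "SASP",
)

#: substrate → (er_mean, er_sd, n) reported by the second facility.
FACILITY2_SUMMARIES: dict[str, tuple[float, float, int]] = {
    "digoxin": (1.5, 0.4, 3),
    "dantrolene": (2.0, 0.7, 3),
    "SASP": (1.4, 0.1, 3),
}


def load_reference_efflux_frame() -> pd.DataFrame:
    """The raw per-experiment reference table as a DataFrame."""
    with resources.files("transwellbench.data").joinpath("reference_efflux_pe.csv").open() as fh:
        return pd.read_csv(fh)


def load_reference_efflux() -> dict[str, EffluxResult]:
    """Reference per-substrate efflux results keyed by substrate id."""
    frame = load_reference_efflux_frame()
    results: dict[str, EffluxResult] = {}
    for substrate, group in frame.groupby("substrate", sort=False):
        experiments = tuple(
            EffluxExperiment(
                experiment_id=row.experiment,
                pe_a2b=float(row.pe_a2b),
                pe_b2a=float(row.pe_b2a),
                significance_mark=row.mark,
            )
            for row in group.itertuples(index=False)
        )
        results[str(substrate)] = EffluxResult(
            substrate_id=str(substrate),
            transporter=str(group["transporter"].iloc[0]),
            experiments=experiments,
        )
    return results


def facility2_result(substrate: str) -> EffluxResult:
    """Summary-only EffluxResult for the second facility's reported values."""
    er_mean, er_sd, n = FACILITY2_SUMMARIES[substrate]
    transporter = {
        row.substrate: row.transporter for row in load_reference_efflux_frame().itertuples()
    }.get(substrate)
    return EffluxResult.from_summary(
        substrate_id=substrate, er_mean=er_mean, er_sd=er_sd, n=n, transporter=transporter
    )
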