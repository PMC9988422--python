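"""Data model and tidy-CSV / config I/O for transwell assay records.

The on-disk format is a tidy CSV with one row per sampled timepoint:

    substrate,direction,experiment,replicate,insert_condition,time_min,donor_conc,receiver_conc

``direction`` is ``A2B`` (dose luminal/apical, receive abluminal/basolateral)
or ``B2A`` (the reverse); ``insert_condition`` is ``cells`` (cell-bearing
insert) or ``blank`` (coated membrane without cells, used for the
blank-membrane correction). ``donor_conc`` may be left empty, in which case
the nominal dosing concentration is used at every timepoint (sink
approximation).

Concentrations are carried as amount per microlitre in whatever amount unit
the file uses; the cleared-volume statistic is a concentration ratio, so any
single consistent unit works. Times are minutes throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import yaml

from .errors import (
    DuplicateRecordError,
    ParseError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "InsertGeometry",
    "Sample",
    "Timecourse",
    "TeerRecord",
    "DoseUptakeSeries",
    "CompetitionAssay",
    "AssayConfig",
    "SubstrateInfo",
    "read_timecourses",
    "write_results",
    "read_efflux_results",
    "load_config",
    "TIMECOURSE_COLUMNS",
    "DIRECTIONS",
    "INSERT_CONDITIONS",
]

TIMECOURSE_COLUMNS = (
    "substrate",
    "direction",
    "experiment",
    "replicate",
    "insert_condition",
    "time_min",
    "donor_conc",
    "receiver_conc",
)
DIRECTIONS = ("A2B", "B2A")
INSERT_CONDITIONS = ("cells", "blank")


@dataclass(frozen=True)
class InsertGeometry:
    """Transwell insert geometry.

    Parameters
    ----------
    membrane_area:
        Growth area of the porous membrane, cm² (symbol S).
    luminal_volume:
        Volume of the luminal (apical, A) compartment, μL.
    abluminal_volume:
        Volume of the abluminal (basolateral, B) compartment, μL.
    """

    membrane_area: float
    luminal_volume: float
    abluminal_volume: float

    def __post_init__(self) -> None:
        for name in ("membrane_area", "luminal_volume", "abluminal_volume"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {value!r}")

    def donor_volume(self, direction: str) -> float:
        """Volume (μL) of the dosing compartment for ``direction``."""
        _check_direction(direction)
        return self.luminal_volume if direction == "A2B" else self.abluminal_volume

    def receiver_volume(self, direction: str) -> float:
        """Volume (μL) of the receiving compartment for ``direction``."""
        _check_direction(direction)
        return self.abluminal_volume if direction == "A2B" else self.luminal_volume


class Sample(NamedTuple):
    """One sampled timepoint: time (min), receiver and donor concentration.

    ``donor_conc`` is ``None`` when the donor compartment was not sampled;
    downstream code then falls back to the nominal dosing concentration.
    """

    time: float
    receiver_conc: float
    donor_conc: float | None = None


@dataclass(frozen=True)
class Timecourse:
    """One replicate's concentration series for one substrate and direction."""

    substrate_id: str
    direction: str
    experiment_id: str
    replicate_id: str
    insert_condition: str
    donor_initial_concentration: float
    samples: tuple[Sample, ...]
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_direction(self.direction)
        if self.insert_condition not in INSERT_CONDITIONS:
            raise ValidationError(
                f"insert_condition must be one of {INSERT_CONDITIONS}, "
                f"got {self.insert_condition!r}"
            )
        if self.donor_initial_concentration <= 0:
            raise ValidationError("donor_initial_concentration must be positive")
        object.__setattr__(self, "samples", tuple(sorted(self.samples, key=lambda s: s.time)))
        times = [s.time for s in self.samples]
        if any(t <= 0 for t in times):
            raise ValidationError("sample times must be strictly positive")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("sample times must be strictly increasing (duplicate time?)")
        for s in self.samples:
            if s.receiver_conc < 0 or (s.donor_conc is not None and s.donor_conc < 0):
                raise ValidationError("concentrations must be non-negative")
        if len(self.samples) < 2 and "insufficient_samples" not in self.flags:
            object.__setattr__(self, "flags", self.flags + ("insufficient_samples",))

    @property
    def usable_for_fit(self) -> bool:
        return len(self.samples) >= 2

    @property
    def group_key(self) -> tuple[str, str, str, str, str]:
        return (
            self.substrate_id,
            self.direction,
            self.experiment_id,
            self.replicate_id,
            self.insert_condition,
        )


@dataclass(frozen=True)
class TeerRecord:
    """Paired resistance readings for the TEER computation (Ω, Ω, cm²)."""

    coculture_resistance: float
    blank_membrane_resistance: float
    membrane_area: float

    def __post_init__(self) -> None:
        if self.coculture_resistance < 0 or self.blank_membrane_resistance < 0:
            raise ValidationError("resistances must be non-negative")
        if self.membrane_area <= 0:
            raise ValidationError("membrane_area must be positive")


@dataclass(frozen=True)
class DoseUptakeSeries:
    """Applied ligand doses (pmol) with matched uptake/transport responses."""

    doses: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(float(d) for d in self.doses))
        object.__setattr__(self, "responses", tuple(float(r) for r in self.responses))
        if len(self.doses) != len(self.responses):
            raise ValidationError("doses and responses must have the same length")
        if any(d1 >= d2 for d1, d2 in zip(self.doses, self.doses[1:])):
            raise ValidationError("doses must be strictly increasing")
        if any(r < 0 for r in self.responses):
            raise ValidationError("responses must be non-negative")


@dataclass(frozen=True)
class CompetitionAssay:
    """Transported amounts of labeled ligand with and without competitor."""

    labeled_alone: tuple[float, ...]
    labeled_plus_competitor: tuple[float, ...]
    labeled_dose: float
    competitor_dose: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "labeled_alone", tuple(float(v) for v in self.labeled_alone))
        object.__setattr__(
            self, "labeled_plus_competitor", tuple(float(v) for v in self.labeled_plus_competitor)
        )
        if not self.labeled_alone or not self.labeled_plus_competitor:
            raise ValidationError("each replicate list must be non-empty")
        if any(v < 0 for v in self.labeled_alone + self.labeled_plus_competitor):
            raise ValidationError("transported amounts must be non-negative")


@dataclass(frozen=True)
class SubstrateInfo:
    """Per-substrate assay metadata from the config file."""

    dosing_concentration: float
    transporter: str | None = None


@dataclass(frozen=True)
class AssayConfig:
    """Assay configuration: geometry, substrate metadata and analysis policy."""

    geometry: InsertGeometry
    substrates: Mapping[str, SubstrateInfo] = field(default_factory=dict)
    alpha: float = 0.05
    donor_mode: str = "measured"  # "measured" | "nominal"
    pe_decimals: int = 1

    def __post_init__(self) -> None:
        if self.donor_mode not in ("measured", "nominal"):
            raise ValidationError("donor_mode must be 'measured' or 'nominal'")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")

    @property
    def dosing_concentrations(self) -> dict[str, float]:
        return {k: v.dosing_concentration for k, v in self.substrates.items()}

    @property
    def transporters(self) -> dict[str, str]:
        return {k: v.transporter for k, v in self.substrates.items() if v.transporter}


def load_config(path: str | Path) -> AssayConfig:
    """Load an :class:`AssayConfig` from a YAML file.

    Expected layout::

        geometry: {area_cm2: 0.33, luminal_uL: 400, abluminal_uL: 600}
        substrates:
          digoxin: {dosing_concentration: 5.0, transporter: P-gp}
        alpha: 0.05
        donor_mode: measured
        pe_decimals: 1
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "geometry" not in raw:
        raise SchemaError("config must be a mapping with a 'geometry' section")
    geo = raw["geometry"]
    try:
        geometry = InsertGeometry(
            membrane_area=float(geo["area_cm2"]),
            luminal_volume=float(geo["luminal_uL"]),
            abluminal_volume=float(geo["abluminal_uL"]),
        )
    except KeyError as exc:
        raise SchemaError(f"geometry section missing key {exc}") from exc
    substrates = {}
    for name, info in (raw.get("substrates") or {}).items():
        substrates[str(name)] = SubstrateInfo(
            dosing_concentration=float(info["dosing_concentration"]),
            transporter=info.get("transporter"),
        )
    return AssayConfig(
        geometry=geometry,
        substrates=substrates,
        alpha=float(raw.get("alpha", 0.05)),
        donor_mode=str(raw.get("donor_mode", "measured")),
        pe_decimals=int(raw.get("pe_decimals", 1)),
    )


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}, got {direction!r}")


def read_timecourses(
    path: str | Path,
    geometry: InsertGeometry | None = None,
    *,
    dosing_concentrations: Mapping[str, float] | None = None,
) -> list[Timecourse]:
    """Read a tidy assay CSV into a list of :class:`Timecourse`.

    One Timecourse is produced per
    (substrate, direction, experiment, replicate, insert_condition) group,
    with samples sorted by time. Groups with fewer than two timepoints are
    returned flagged ``insufficient_samples`` rather than dropped.

    ``geometry`` is accepted for interface symmetry with the writers; the
    reader itself needs only the table. ``dosing_concentrations`` maps
    substrate → nominal dosing concentration and is required for any group
    whose ``donor_conc`` column is (partly) empty.
    """
    del geometry  # not needed to parse; kept in the signature for symmetry
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TIMECOURSE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    dosing = dict(dosing_concentrations or {})
    records: dict[tuple[str, ...], dict[float, Sample]] = {}
    for idx, row in enumerate(frame.itertuples(index=False), start=2):  # header is row 1
        direction = getattr(row, "direction").strip()
        if direction not in DIRECTIONS:
            raise ParseError(f"row {idx}: direction must be A2B or B2A, got {direction!r}")
        condition = getattr(row, "insert_condition").strip()
        if condition not in INSERT_CONDITIONS:
            raise ParseError(
                f"row {idx}: insert_condition must be cells or blank, got {condition!r}"
            )
        time = _parse_number(getattr(row, "time_min"), "time_min", idx)
        receiver = _parse_number(getattr(row, "receiver_conc"), "receiver_conc", idx)
        donor_raw = getattr(row, "donor_conc").strip()
        donor = None if donor_raw == "" else _parse_number(donor_raw, "donor_conc", idx)
        key = (
            getattr(row, "substrate").strip(),
            direction,
            getattr(row, "experiment").strip(),
            getattr(row, "replicate").strip(),
            condition,
        )
        group = records.setdefault(key, {})
        if time in group:
            raise DuplicateRecordError(
                f"row {idx}: duplicate measurement for group {key} at time {time}"
            )
        group[time] = Sample(time=time, receiver_conc=receiver, donor_conc=donor)

    timecourses = []
    for key in sorted(records):
        substrate, direction, experiment, replicate, condition = key
        samples = tuple(records[key][t] for t in sorted(records[key]))
        donor_initial = dosing.get(substrate)
        if donor_initial is None:
            measured = [s.donor_conc for s in samples if s.donor_conc is not None]
            if len(measured) < len(samples):
                raise SchemaError(
                    f"group {key}: donor_conc is empty for some timepoints and no "
                    f"dosing concentration was supplied for substrate {substrate!r}"
                )
            donor_initial = measured[0]
        timecourses.append(
            Timecourse(
                substrate_id=substrate,
                direction=direction,
                experiment_id=experiment,
                replicate_id=replicate,
                insert_condition=condition,
                donor_initial_concentration=float(donor_initial),
                samples=samples,
            )
        )
    return timecourses


def _parse_number(raw: str, column: str, row_number: int) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ParseError(f"row {row_number}: non-numeric {column} value {raw!r}") from None


# ---------------------------------------------------------------------------
# writers


def write_results(records: Sequence, path: str | Path) -> None:
    """Write a homogeneous collection of result records to CSV.

    Dispatches on the record type: Timecourse collections use the tidy assay
    schema; EffluxResult collections get one row per experiment plus a summary
    row per substrate; any other dataclass collection is written field-per-
    column. Reading the written file reproduces the records (round-trip).
    """
    records = list(records)
    if not records:
        raise ValidationError("refusing to write an empty record collection")
    first = records[0]
    if isinstance(first, Timecourse):
        _write_timecourses(records, path)
        return
    # EffluxResult lives in .efflux; duck-type on its fields to avoid a cycle
    if hasattr(first, "experiments") and hasattr(first, "er_mean"):
        _write_efflux_results(records, path)
        return
    frame = pd.DataFrame([_asdict_flat(r) for r in records])
    frame.to_csv(path, index=False)


def _asdict_flat(record) -> dict:
    return {f.name: getattr(record, f.name) for f in fields(record)}


def timecourses_to_frame(timecourses: Iterable[Timecourse]) -> pd.DataFrame:
    rows = []
    for tc in sorted(timecourses, key=lambda t: t.group_key):
        for s in tc.samples:
            rows.append(
                {
                    "substrate": tc.substrate_id,
                    "direction": tc.direction,
                    "experiment": tc.experiment_id,
                    "replicate": tc.replicate_id,
                    "insert_condition": tc.insert_condition,
                    "time_min": s.time,
                    "donor_conc": "" if s.donor_conc is None else s.donor_conc,
                    "receiver_conc": s.receiver_conc,
                }
            )
    return pd.DataFrame(rows, columns=list(TIMECOURSE_COLUMNS))


def _write_timecourses(timecourses: Sequence[Timecourse], path: str | Path) -> None:
    timecourses_to_frame(timecourses).to_csv(path, index=False)


_EFFLUX_COLUMNS = (
    "substrate",
    "transporter",
    "row_type",
    "experiment",
    "pe_a2b",
    "pe_b2a",
    "er",
    "p_value",
    "mark",
    "er_mean",
    "er_sd",
    "n",
)


def _write_efflux_results(results: Sequence, path: str | Path) -> None:
    rows = []
    for res in results:
        for exp in res.experiments:
            rows.append(
                {
                    "substrate": res.substrate_id,
                    "transporter": res.transporter or "",
                    "row_type": "experiment",
                    "experiment": exp.experiment_id,
                    "pe_a2b": exp.pe_a2b,
                    "pe_b2a": exp.pe_b2a,
                    "er": exp.er,
                    "p_value": "" if exp.p_value is None else exp.p_value,
                    "mark": exp.significance_mark,
                    "er_mean": "",
                    "er_sd": "",
                    "n": "",
                }
            )
        rows.append(
            {
                "substrate": res.substrate_id,
                "transporter": res.transporter or "",
                "row_type": "summary",
                "experiment": "",
                "pe_a2b": "",
                "pe_b2a": "",
                "er": "",
                "p_value": "",
                "mark": "",
                "er_mean": res.er_mean,
                "er_sd": "" if res.er_sd is None else res.er_sd,
                "n": res.n,
            }
        )
    pd.DataFrame(rows, columns=list(_EFFLUX_COLUMNS)).to_csv(path, index=False)


def read_efflux_results(path: str | Path) -> list:
    """Read back a CSV written by :func:`write_results` for EffluxResult records."""
    from .efflux import EffluxExperiment, EffluxResult  # local import: avoid cycle

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _EFFLUX_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    results = []
    pending: list[EffluxExperiment] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        if row.row_type == "experiment":
            pending.append(
                EffluxExperiment(
                    experiment_id=row.experiment,
                    pe_a2b=float(row.pe_a2b),
                    pe_b2a=float(row.pe_b2a),
                    p_value=None if row.p_value == "" else float(row.p_value),
                    significance_mark=row.mark,
                )
            )
        elif row.row_type == "summary":
            results.append(
                EffluxResult(
                    substrate_id=row.substrate,
                    transporter=row.transporter or None,
                    experiments=tuple(pending),
                )
            )
            pending = []
        else:
            raise ParseError(f"row {idx}: unknown row_type {row.row_type!r}")
    return results


def with_flags(tc: Timecourse, *flags: str) -> Timecourse:
    """Return a copy of ``tc`` with extra flags appended."""
    return replace(tc, flags=tc.flags + tuple(f for f in flags if f not in tc.flags))
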