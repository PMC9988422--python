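"""Clearance-slope permeability estimation and TEER.

The estimator is the classic cleared-volume method for transwell barriers.
For each sampled timepoint the *cleared volume* is

    V(t) = C_r(t) * V_r / C_d(t)        [μL]

where ``C_r`` and ``C_d`` are the receiver- and donor-compartment
concentrations and ``V_r`` the receiver volume. Under sink conditions V(t)
grows linearly and its slope is the permeability–surface-area product PS
(μL/min). A cell-bearing insert gives PS_total; a blank (cell-free) insert
gives PS_mem; the cell-layer contribution follows from the series-barrier
relation

    1/PS_e = 1/PS_total − 1/PS_mem

and the permeability coefficient of the cell layer is Pe = PS_e / S, reported
in 10⁻⁶ cm/s (S in cm²).

TEER is net resistance times membrane area: (R_coculture − R_blank) × S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .assay_io import InsertGeometry, Timecourse, TeerRecord
from .errors import (
    InsufficientDataError,
    MembraneInconsistencyError,
    NegativeNetResistanceError,
    UnusableFitError,
    ValidationError,
)

__all__ = [
    "ClearancePoint",
    "PermeabilitySurfaceProduct",
    "DirectionalPermeability",
    "PE_UNIT_FACTOR",
    "cleared_volume",
    "clearance_points",
    "fit_ps",
    "correct_for_membrane",
    "pe_from_ps",
    "compute_pe",
    "teer",
]

#: (μL/min)/cm² → 10⁻⁶ cm/s: 1 μL = 10⁻³ cm³ and 1 min = 60 s, so
#: 1 (μL/min)/cm² = 10⁻³/60 cm/s = (1000/60)·10⁻⁶ cm/s.
PE_UNIT_FACTOR = 1000.0 / 60.0


@dataclass(frozen=True)
class ClearancePoint:
    """One timepoint of the cleared-volume curve (min, μL)."""

    time: float
    cleared_volume: float


@dataclass(frozen=True)
class PermeabilitySurfaceProduct:
    """A fitted PS (μL/min) with fit diagnostics.

    ``condition`` is ``total`` (cell-bearing insert), ``membrane`` (blank
    insert) or ``corrected`` (cell layer after membrane correction).
    A non-positive slope marks the record unusable.
    """

    value: float
    condition: str
    n_points: int
    fit_r2: float | None = None
    intercept: float | None = None
    usable: bool = True
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.condition not in ("total", "membrane", "corrected"):
            raise ValidationError(f"unknown PS condition {self.condition!r}")


@dataclass(frozen=True)
class DirectionalPermeability:
    """Permeability coefficient Pe (10⁻⁶ cm/s) for one substrate/direction."""

    substrate_id: str
    direction: str
    experiment_id: str
    pe: float
    corrected: bool = True
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        if self.pe <= 0:
            raise ValidationError(f"pe must be positive, got {self.pe}")


def cleared_volume(receiver_conc: float, receiver_volume: float, donor_conc: float) -> float:
    """Cleared volume C_r·V_r/C_d in μL for one timepoint."""
    if donor_conc <= 0:
        raise ValidationError(f"donor concentration must be positive, got {donor_conc}")
    if receiver_volume <= 0:
        raise ValidationError(f"receiver volume must be positive, got {receiver_volume}")
    if receiver_conc < 0:
        raise ValidationError(f"receiver concentration must be non-negative, got {receiver_conc}")
    return receiver_conc * receiver_volume / donor_conc


def clearance_points(
    timecourse: Timecourse,
    geometry: InsertGeometry,
    donor_mode: str = "measured",
) -> list[ClearancePoint]:
    """Cleared-volume curve for one timecourse.

    ``donor_mode='measured'`` uses the per-timepoint donor concentration when
    sampled (falling back to the nominal dose otherwise); ``'nominal'`` always
    uses the dosing concentration (sink approximation).
    """
    if donor_mode not in ("measured", "nominal"):
        raise ValidationError("donor_mode must be 'measured' or 'nominal'")
    receiver_volume = geometry.receiver_volume(timecourse.direction)
    points = []
    for sample in timecourse.samples:
        if donor_mode == "measured" and sample.donor_conc is not None:
            donor = sample.donor_conc
        else:
            donor = timecourse.donor_initial_concentration
        points.append(
            ClearancePoint(
                time=sample.time,
                cleared_volume=cleared_volume(sample.receiver_conc, receiver_volume, donor),
            )
        )
    return points


def fit_ps(
    points: Iterable[ClearancePoint],
    condition: str = "total",
) -> PermeabilitySurfaceProduct:
    """Ordinary least-squares slope of cleared volume vs time, free intercept.

    The slope is PS in μL/min. A non-positive slope yields a record with
    ``usable=False`` and flag ``nonpositive_slope`` rather than an exception,
    so callers can report which replicate failed.
    """
    pts = sorted(points, key=lambda p: p.time)
    times = np.array([p.time for p in pts], dtype=float)
    volumes = np.array([p.cleared_volume for p in pts], dtype=float)
    if len(pts) < 2 or np.ptp(times) == 0:
        raise InsufficientDataError(
            f"slope fit needs >=2 points with distinct times, got {len(pts)}"
        )
    result = stats.linregress(times, volumes)
    slope = float(result.slope)
    r2 = float(result.rvalue) ** 2 if math.isfinite(result.rvalue) else None
    usable = slope > 0
    flags = () if usable else ("nonpositive_slope",)
    return PermeabilitySurfaceProduct(
        value=slope,
        condition=condition,
        n_points=len(pts),
        fit_r2=r2,
        intercept=float(result.intercept),
        usable=usable,
        flags=flags,
    )


def correct_for_membrane(
    ps_total: PermeabilitySurfaceProduct,
    ps_mem: PermeabilitySurfaceProduct,
) -> PermeabilitySurfaceProduct:
    """Series-barrier correction: 1/PS_e = 1/PS_total − 1/PS_mem.

    Requires PS_total < PS_mem — cells on the membrane cannot make the
    barrier leakier than the blank membrane alone; otherwise the replicate is
    inconsistent and must be excluded, not clamped.
    """
    if ps_total.condition != "total" or ps_mem.condition != "membrane":
        raise ValidationError(
            f"expected conditions (total, membrane), got "
            f"({ps_total.condition}, {ps_mem.condition})"
        )
    if not ps_total.usable:
        raise UnusableFitError(f"PS_total fit unusable (flags={ps_total.flags})")
    if not ps_mem.usable:
        raise UnusableFitError(f"PS_mem fit unusable (flags={ps_mem.flags})")
    if ps_total.value >= ps_mem.value:
        raise MembraneInconsistencyError(
            f"PS_total ({ps_total.value:g}) >= PS_mem ({ps_mem.value:g}); "
            "membrane correction undefined"
        )
    value = 1.0 / (1.0 / ps_total.value - 1.0 / ps_mem.value)
    return PermeabilitySurfaceProduct(
        value=value,
        condition="corrected",
        n_points=ps_total.n_points,
        fit_r2=None,
        intercept=None,
        usable=True,
    )


def pe_from_ps(
    ps_e: PermeabilitySurfaceProduct,
    geometry: InsertGeometry,
    *,
    substrate_id: str = "",
    direction: str = "A2B",
    experiment_id: str = "",
    replicate_id: str | None = None,
) -> DirectionalPermeability:
    """Pe = PS_e / S, converted from (μL/min)/cm² to 10⁻⁶ cm/s."""
    if not ps_e.usable:
        raise UnusableFitError(f"PS fit unusable (flags={ps_e.flags})")
    if ps_e.condition == "membrane":
        raise ValidationError("pe_from_ps expects a corrected or total PS, not membrane")
    pe = ps_e.value / geometry.membrane_area * PE_UNIT_FACTOR
    return DirectionalPermeability(
        substrate_id=substrate_id,
        direction=direction,
        experiment_id=experiment_id,
        replicate_id=replicate_id,
        pe=pe,
        corrected=ps_e.condition == "corrected",
    )


def compute_pe(
    timecourse: Timecourse,
    blank: Timecourse | None,
    geometry: InsertGeometry,
    *,
    donor_mode: str = "measured",
    correct: bool = True,
) -> DirectionalPermeability:
    """Full clearance pipeline for one cell-bearing replicate.

    Chains cleared volume per timepoint → slope fit on both inserts →
    membrane correction → Pe. ``blank`` may be omitted only when
    ``correct=False`` (uncorrected Pe from PS_total). Stage failures raise
    with the failing stage named.
    """
    if timecourse.insert_condition != "cells":
        raise ValidationError("timecourse must come from a cell-bearing insert")
    if correct:
        if blank is None:
            raise ValidationError("membrane correction requested but no blank timecourse given")
        if blank.insert_condition != "blank":
            raise ValidationError("blank must come from a blank insert")
        if (blank.substrate_id, blank.direction) != (
            timecourse.substrate_id,
            timecourse.direction,
        ):
            raise ValidationError("blank does not match the timecourse substrate/direction")
    if not timecourse.usable_for_fit:
        raise InsufficientDataError("cells timecourse has fewer than 2 samples")

    ps_total = fit_ps(clearance_points(timecourse, geometry, donor_mode), condition="total")
    if not ps_total.usable:
        raise UnusableFitError(
            f"stage fit_ps(total): non-positive slope for replicate "
            f"{timecourse.group_key}"
        )
    if correct:
        assert blank is not None
        ps_mem = fit_ps(clearance_points(blank, geometry, donor_mode), condition="membrane")
        if not ps_mem.usable:
            raise UnusableFitError(
                f"stage fit_ps(membrane): non-positive slope for blank {blank.group_key}"
            )
        ps_e = correct_for_membrane(ps_total, ps_mem)
    else:
        ps_e = ps_total
    return pe_from_ps(
        ps_e,
        geometry,
        substrate_id=timecourse.substrate_id,
        direction=timecourse.direction,
        experiment_id=timecourse.experiment_id,
        replicate_id=timecourse.replicate_id,
    )


def teer(record: TeerRecord) -> float:
    """TEER in Ω·cm²: (coculture − blank membrane resistance) × area."""
    net = record.coculture_resistance - record.blank_membrane_resistance
    if net < 0:
        raise NegativeNetResistanceError(
            f"coculture resistance ({record.coculture_resistance} Ω) below blank "
            f"membrane resistance ({record.blank_membrane_resistance} Ω)"
        )
    return net * record.membrane_area
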