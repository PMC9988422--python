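"""Receptor-mediated transcytosis (RMT) checks.

Two decision procedures, mirroring how transferrin-receptor function is
probed in transwell BBB models:

* **Saturation** — uptake/transport is plotted against applied ligand dose;
  receptor binding is finite-capacity, so the dose–response slope should
  flatten beyond a saturating dose. The check fits least-squares slopes to
  the sub- and supra-breakpoint dose ranges and calls the series *saturable*
  when the relative slope drop exceeds a threshold (default 0.2; the default
  breakpoint of 2400 pmol is where uptake flattens in this assay format).

* **Competition** — labeled ligand is applied with or without an excess of
  unlabeled ligand. Transport through a receptor is reduced by the
  competitor; passive or fluid-phase transport is not. The verdict is
  ``rmt_consistent`` only when the with-competitor arm is *lower* (ratio < 1)
  and the two arms differ significantly (Student's t-test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .assay_io import CompetitionAssay, DoseUptakeSeries
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "SaturationVerdict",
    "CompetitionVerdict",
    "saturation_check",
    "competition_test",
    "DEFAULT_SATURATION_BREAKPOINT_PMOL",
    "DEFAULT_SLOPE_DROP_THRESHOLD",
]

DEFAULT_SATURATION_BREAKPOINT_PMOL = 2400.0
DEFAULT_SLOPE_DROP_THRESHOLD = 0.2


@dataclass(frozen=True)
class SaturationVerdict:
    """Two-slope comparison of a dose–uptake curve around a breakpoint."""

    slope_low: float
    slope_high: float
    breakpoint: float
    relative_slope_drop: float
    verdict: str  # "saturable" | "linear"
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CompetitionVerdict:
    """Outcome of the labeled-vs-labeled-plus-competitor comparison."""

    transport_ratio: float
    p_value: float
    verdict: str  # "rmt_consistent" | "not_rmt"
    alpha: float = 0.05


def _ls_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    return float(np.dot(x, y - y.mean()) / np.dot(x, x))


def saturation_check(
    series: DoseUptakeSeries,
    breakpoint: float = DEFAULT_SATURATION_BREAKPOINT_PMOL,
    threshold: float = DEFAULT_SLOPE_DROP_THRESHOLD,
) -> SaturationVerdict:
    """Compare dose–response slopes below and at/above ``breakpoint``.

    ``saturable`` iff the relative slope drop 1 − slope_high/slope_low
    exceeds ``threshold``. Needs at least two doses strictly below and two
    at/above the breakpoint. An all-zero response yields ``linear`` with a
    ``zero_signal`` flag.
    """
    doses = np.asarray(series.doses, dtype=float)
    responses = np.asarray(series.responses, dtype=float)
    low = doses < breakpoint
    high = ~low
    if low.sum() < 2 or high.sum() < 2:
        raise InsufficientDataError(
            f"need >=2 doses on each side of breakpoint {breakpoint:g} "
            f"(got {int(low.sum())} below, {int(high.sum())} at/above)"
        )
    slope_low = _ls_slope(doses[low], responses[low])
    slope_high = _ls_slope(doses[high], responses[high])
    flags: tuple[str, ...] = ()
    if np.all(responses == 0):
        flags = ("zero_signal",)
    if slope_low > 0:
        drop = 1.0 - slope_high / slope_low
    else:
        drop = 0.0
        if "zero_signal" not in flags:
            flags = flags + ("nonpositive_low_slope",)
    verdict = "saturable" if drop > threshold else "linear"
    return SaturationVerdict(
        slope_low=slope_low,
        slope_high=slope_high,
        breakpoint=breakpoint,
        relative_slope_drop=drop,
        verdict=verdict,
        flags=flags,
    )


def competition_test(assay: CompetitionAssay, alpha: float = 0.05) -> CompetitionVerdict:
    """Decide whether transport is consistent with receptor mediation.

    ``rmt_consistent`` iff mean(with competitor)/mean(alone) < 1 and the
    equal-variance Student's t-test between arms has p < ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    alone = np.asarray(assay.labeled_alone, dtype=float)
    comp = np.asarray(assay.labeled_plus_competitor, dtype=float)
    if len(alone) < 2 or len(comp) < 2:
        raise InsufficientDataError("competition_test needs >=2 replicates per arm")
    if alone.mean() <= 0:
        raise ValidationError("mean transport in the alone arm must be positive")
    ratio = float(comp.mean() / alone.mean())
    if np.var(alone) == 0 and np.var(comp) == 0:
        p = 1.0 if alone.mean() == comp.mean() else 0.0
    else:
        _, p = stats.ttest_ind(alone, comp, equal_var=True)
        p = float(p)
        if math.isnan(p):  # defensive; zero-variance handled above
            p = 1.0
    verdict = "rmt_consistent" if (ratio < 1.0 and p < alpha) else "not_rmt"
    return CompetitionVerdict(transport_ratio=ratio, p_value=p, verdict=verdict, alpha=alpha)
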