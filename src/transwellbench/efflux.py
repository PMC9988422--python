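"""Bidirectional transport analysis: efflux ratios, aggregation, significance.

The efflux ratio for one independent experiment is

    ER = Pe(B→A) / Pe(A→B)

and a substrate's summary is the arithmetic mean ± sample SD (n−1 denominator)
of the per-experiment ERs. Directional significance within an experiment is a
two-sample, two-tailed Student's t-test (equal variances pooled) on the
replicate-level values, marked ``**`` for p < 0.01 and ``*`` for p < 0.05.

A substrate's efflux function is called demonstrated (``efflux_functional``)
when the mean ER exceeds 1 and at least half of the experiments show
significantly higher B→A than A→B permeability; both thresholds are
configurable through :class:`EffluxPolicy`.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .assay_io import InsertGeometry, Timecourse
from .errors import InsufficientDataError, UnusableFitError, ValidationError
from .permeability import (
    PermeabilitySurfaceProduct,
    clearance_points,
    correct_for_membrane,
    fit_ps,
    pe_from_ps,
)

__all__ = [
    "EffluxExperiment",
    "EffluxResult",
    "EffluxPolicy",
    "efflux_ratio",
    "mark_from_p",
    "directional_test",
    "aggregate_er",
    "classify_transporter",
    "analyze_bidirectional",
]

EFFLUX_FUNCTIONAL = "efflux_functional"
NOT_DEMONSTRATED = "not_demonstrated"


def efflux_ratio(pe_a2b: float, pe_b2a: float) -> float:
    """ER = Pe(B→A)/Pe(A→B); both inputs must be positive."""
    if pe_a2b <= 0:
        raise ValidationError(f"pe_a2b must be positive, got {pe_a2b}")
    if pe_b2a <= 0:
        raise ValidationError(f"pe_b2a must be positive, got {pe_b2a}")
    return pe_b2a / pe_a2b


def mark_from_p(p_value: float | None) -> str:
    """Significance mark from a p-value: ** (<0.01), * (<0.05) or none."""
    if p_value is None:
        return "none"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "none"


@dataclass(frozen=True)
class EffluxExperiment:
    """One independent experiment's directional Pe pair and its ER."""

    experiment_id: str
    pe_a2b: float
    pe_b2a: float
    p_value: float | None = None
    significance_mark: str = "none"
    er: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "er", efflux_ratio(self.pe_a2b, self.pe_b2a))
        if self.significance_mark not in ("none", "*", "**"):
            raise ValidationError(f"unknown significance mark {self.significance_mark!r}")
        if self.p_value is not None:
            if not 0 <= self.p_value <= 1:
                raise ValidationError("p_value must lie in [0, 1]")
            if self.significance_mark != mark_from_p(self.p_value):
                raise ValidationError(
                    f"significance_mark {self.significance_mark!r} inconsistent with "
                    f"p={self.p_value:g}"
                )


@dataclass(frozen=True)
class EffluxResult:
    """Per-substrate efflux summary: per-experiment ERs, mean, sample SD, n.

    May also be built from a published summary (mean/SD/n without the
    underlying experiments) via :meth:`from_summary`, e.g. for comparing a
    second facility that reports only aggregate values.
    """

    substrate_id: str
    transporter: str | None = None
    experiments: tuple[EffluxExperiment, ...] = ()
    summary_er_mean: float | None = None
    summary_er_sd: float | None = None
    summary_n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "experiments", tuple(self.experiments))
        if not self.experiments and self.summary_er_mean is None:
            raise ValidationError("EffluxResult needs experiments or summary statistics")

    @classmethod
    def from_summary(
        cls,
        substrate_id: str,
        er_mean: float,
        er_sd: float | None,
        n: int,
        transporter: str | None = None,
    ) -> "EffluxResult":
        return cls(
            substrate_id=substrate_id,
            transporter=transporter,
            summary_er_mean=er_mean,
            summary_er_sd=er_sd,
            summary_n=n,
        )

    @property
    def n(self) -> int:
        return len(self.experiments) if self.experiments else int(self.summary_n or 0)

    @property
    def er_values(self) -> tuple[float, ...]:
        return tuple(e.er for e in self.experiments)

    @property
    def er_mean(self) -> float:
        if self.experiments:
            return float(np.mean(self.er_values))
        assert self.summary_er_mean is not None
        return self.summary_er_mean

    @property
    def er_sd(self) -> float | None:
        """Sample SD (n−1 denominator); None when n < 2."""
        if self.experiments:
            if len(self.experiments) < 2:
                return None
            return statistics.stdev(self.er_values)
        return self.summary_er_sd

    def rounded(self, decimals: int = 1) -> tuple[float, float | None]:
        """(mean, sd) at report precision; full precision is kept internally."""
        sd = self.er_sd
        return (
            round(self.er_mean, decimals),
            None if sd is None else round(sd, decimals),
        )


def aggregate_er(
    experiments: Sequence[EffluxExperiment],
    *,
    substrate_id: str = "",
    transporter: str | None = None,
) -> EffluxResult:
    """Aggregate per-experiment ERs into an :class:`EffluxResult`."""
    if not experiments:
        raise InsufficientDataError("aggregate_er needs at least one experiment")
    return EffluxResult(
        substrate_id=substrate_id,
        transporter=transporter,
        experiments=tuple(experiments),
    )


def directional_test(
    a2b_replicates: Sequence[float],
    b2a_replicates: Sequence[float],
) -> tuple[float, float, str]:
    """Two-sample equal-variance two-tailed Student's t-test between directions.

    Returns (t, p, mark). Identical groups give (0, 1, "none"); zero pooled
    variance with different means gives p = 0.
    """
    a = np.asarray(a2b_replicates, dtype=float)
    b = np.asarray(b2a_replicates, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("directional_test needs >=2 replicates per direction")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0, "none"
        t = math.inf if np.mean(b) > np.mean(a) else -math.inf
        return t, 0.0, "**"
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), mark_from_p(float(p))


@dataclass(frozen=True)
class EffluxPolicy:
    """Decision rule for calling a transporter's efflux function demonstrated.

    ``efflux_functional`` iff mean ER > ``er_threshold`` and the fraction of
    experiments with Pe(B→A) > Pe(A→B) *and* a significance mark is at least
    ``min_significant_fraction``.
    """

    er_threshold: float = 1.0
    min_significant_fraction: float = 0.5


def classify_transporter(result: EffluxResult, policy: EffluxPolicy | None = None) -> str:
    """Classify a substrate's efflux function as demonstrated or not."""
    policy = policy or EffluxPolicy()
    if len(result.experiments) < 2:
        raise InsufficientDataError("classification needs >=2 experiments")
    supporting = sum(
        1
        for e in result.experiments
        if e.pe_b2a > e.pe_a2b and e.significance_mark != "none"
    )
    fraction = supporting / len(result.experiments)
    if result.er_mean > policy.er_threshold and fraction >= policy.min_significant_fraction:
        return EFFLUX_FUNCTIONAL
    return NOT_DEMONSTRATED


def analyze_bidirectional(
    timecourses: Iterable[Timecourse],
    geometry: InsertGeometry,
    *,
    transporters: Mapping[str, str] | None = None,
    donor_mode: str = "measured",
    correct: bool = True,
    blank_match: str = "per_direction",
) -> list[EffluxResult]:
    """Run the full clearance → Pe → ER pipeline on a set of timecourses.

    Groups timecourses by substrate and experiment; within each experiment the
    blank-membrane PS is pooled over the blank inserts matched on
    (substrate, direction, experiment), each cell replicate is corrected
    individually, the experiment's directional Pe is the replicate mean, and
    the directional t-test runs on replicate-level Pe values (when each
    direction has at least two replicates).

    ``blank_match`` chooses the blank-insert matching rule:
    ``"per_direction"`` (default) corrects each direction with blanks run in
    that direction; ``"luminal"`` estimates PS_mem from the A2B-orientation
    blanks only and applies it to both directions — an inert membrane's PS is
    orientation-independent, and the A2B orientation (large abluminal
    receiver) keeps the blank's cleared-volume curve closest to linear.
    """
    if blank_match not in ("per_direction", "luminal"):
        raise ValidationError("blank_match must be 'per_direction' or 'luminal'")
    transporters = dict(transporters or {})
    cells: dict[tuple[str, str], dict[str, list[Timecourse]]] = {}
    blanks: dict[tuple[str, str, str], list[Timecourse]] = {}
    for tc in timecourses:
        if tc.insert_condition == "blank":
            blanks.setdefault((tc.substrate_id, tc.direction, tc.experiment_id), []).append(tc)
        else:
            cells.setdefault((tc.substrate_id, tc.experiment_id), {}).setdefault(
                tc.direction, []
            ).append(tc)

    per_substrate: dict[str, list[EffluxExperiment]] = {}
    for (substrate, experiment) in sorted(cells):
        directions = cells[(substrate, experiment)]
        if "A2B" not in directions or "B2A" not in directions:
            continue
        pe_by_direction: dict[str, list[float]] = {}
        for direction, replicates in directions.items():
            ps_mem = None
            if correct:
                blank_direction = "A2B" if blank_match == "luminal" else direction
                blank_group = blanks.get((substrate, blank_direction, experiment), [])
                ps_mem = _pooled_membrane_ps(blank_group, geometry, donor_mode)
                if ps_mem is None:
                    raise InsufficientDataError(
                        f"no usable blank insert for ({substrate}, {direction}, "
                        f"{experiment}); cannot apply membrane correction"
                    )
            for tc in sorted(replicates, key=lambda t: t.replicate_id):
                ps_total = fit_ps(
                    clearance_points(tc, geometry, donor_mode), condition="total"
                )
                if not ps_total.usable:
                    raise UnusableFitError(
                        f"non-positive PS_total slope for replicate {tc.group_key}"
                    )
                ps_e = correct_for_membrane(ps_total, ps_mem) if correct else ps_total
                pe = pe_from_ps(
                    ps_e,
                    geometry,
                    substrate_id=substrate,
                    direction=direction,
                    experiment_id=experiment,
                    replicate_id=tc.replicate_id,
                )
                pe_by_direction.setdefault(direction, []).append(pe.pe)
        a2b = pe_by_direction["A2B"]
        b2a = pe_by_direction["B2A"]
        if len(a2b) >= 2 and len(b2a) >= 2:
            _, p, mark = directional_test(a2b, b2a)
        else:
            p, mark = None, "none"
        per_substrate.setdefault(substrate, []).append(
            EffluxExperiment(
                experiment_id=experiment,
                pe_a2b=float(np.mean(a2b)),
                pe_b2a=float(np.mean(b2a)),
                p_value=p,
                significance_mark=mark,
            )
        )

    return [
        aggregate_er(
            experiments,
            substrate_id=substrate,
            transporter=transporters.get(substrate),
        )
        for substrate, experiments in sorted(per_substrate.items())
    ]


def _pooled_membrane_ps(
    blank_group: Sequence[Timecourse],
    geometry: InsertGeometry,
    donor_mode: str,
) -> PermeabilitySurfaceProduct | None:
    """PS_mem pooled over the matched blank replicates (mean of usable fits)."""
    values = []
    n_points = 0
    for tc in sorted(blank_group, key=lambda t: t.replicate_id):
        if not tc.usable_for_fit:
            continue
        fit = fit_ps(clearance_points(tc, geometry, donor_mode), condition="membrane")
        if fit.usable:
            values.append(fit.value)
            n_points = max(n_points, fit.n_points)
    if not values:
        return None
    return PermeabilitySurfaceProduct(
        value=float(np.mean(values)),
        condition="membrane",
        n_points=n_points,
        usable=True,
    )
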