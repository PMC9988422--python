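"""Benchmark scorecard and inter-facility reproducibility comparison.

The scorecard covers the minimal essential items used to establish the
BBB-likeness of a transwell microphysiological system: endothelial marker
and tight-junction protein expression/localization (declared qualitative
evidence), practical barrier tightness (permeable vs non-permeable tracer
Pe), TEER, and the expression plus function of the transporters P-gp, BCRP
and Glut1 and of the transferrin receptor (RMT). Function items are wired to
quantitative results (efflux classification, tightness test, competition
test); expression/localization items rest on user-declared booleans with
provenance text. Missing inputs degrade to ``not_assessed``, never silently
to ``pass``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assay_io import TeerRecord
from .efflux import (
    EFFLUX_FUNCTIONAL,
    EffluxPolicy,
    EffluxResult,
    classify_transporter,
    directional_test,
)
from .errors import InsufficientDataError, ValidationError
from .permeability import teer as compute_teer
from .transcytosis import CompetitionVerdict

__all__ = [
    "BENCHMARK_ITEM_IDS",
    "BenchmarkItem",
    "FacilityComparison",
    "DeclaredEvidence",
    "tightness_check",
    "build_report",
    "compare_facilities",
    "report_to_frame",
    "format_report",
]

#: Scorecard items: expression/localization items take declared evidence;
#: *_function items are computed from stored quantitative results.
BENCHMARK_ITEM_IDS = (
    "cd31_expression",
    "zo1_expression_localization",
    "claudin5_expression_localization",
    "tightness_ly_caffeine",
    "teer_measured",
    "pgp_expression",
    "pgp_function",
    "bcrp_expression",
    "bcrp_function",
    "glut1_expression",
    "glut1_function",
    "tfr_expression",
    "tfr_function_rmt",
)

_EXPRESSION_ITEMS = (
    "cd31_expression",
    "zo1_expression_localization",
    "claudin5_expression_localization",
    "pgp_expression",
    "bcrp_expression",
    "glut1_expression",
    "tfr_expression",
)

#: transporter label (as carried on EffluxResult) → function item id
TRANSPORTER_ITEMS = {
    "P-gp": "pgp_function",
    "BCRP": "bcrp_function",
    "Glut1": "glut1_function",
}


@dataclass(frozen=True)
class BenchmarkItem:
    item_id: str
    status: str  # "pass" | "fail" | "not_assessed"
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.item_id not in BENCHMARK_ITEM_IDS:
            raise ValidationError(f"unknown benchmark item {self.item_id!r}")
        if self.status not in ("pass", "fail", "not_assessed"):
            raise ValidationError(f"unknown status {self.status!r}")
        if self.status == "pass" and not self.evidence:
            raise ValidationError("a passing item must carry an evidence reference")


@dataclass(frozen=True)
class DeclaredEvidence:
    """User-declared qualitative evidence for an expression/localization item."""

    observed: bool
    provenance: str = "declared by user"


@dataclass(frozen=True)
class FacilityComparison:
    substrate_id: str
    facility_results: tuple[EffluxResult, EffluxResult]
    agree: bool
    criterion: str


def tightness_check(
    pe_nonpermeable: Sequence[float],
    pe_permeable: Sequence[float],
    alpha: float = 0.05,
) -> BenchmarkItem:
    """Barrier-tightness item from tracer Pe values.

    Pass iff the permeable tracer's mean Pe exceeds the non-permeable
    tracer's and the two groups differ significantly (Student's t-test,
    p < alpha). Fewer than two values in either group → ``not_assessed``.
    """
    if len(pe_nonpermeable) < 2 or len(pe_permeable) < 2:
        return BenchmarkItem(
            "tightness_ly_caffeine",
            "not_assessed",
            evidence="insufficient replicates for the tightness t-test",
        )
    t, p, _ = directional_test(pe_nonpermeable, pe_permeable)
    mean_np = float(np.mean(pe_nonpermeable))
    mean_p = float(np.mean(pe_permeable))
    ok = mean_p > mean_np and p < alpha
    evidence = (
        f"mean Pe permeable {mean_p:.1f} vs non-permeable {mean_np:.1f} "
        f"(10^-6 cm/s), t={t:.2f}, p={p:.3g}, alpha={alpha}"
    )
    return BenchmarkItem("tightness_ly_caffeine", "pass" if ok else "fail", evidence=evidence)


def _mirrored(result: EffluxResult) -> EffluxResult:
    """Swap the directions of every experiment (influx view of the same data)."""
    from .efflux import EffluxExperiment

    return EffluxResult(
        substrate_id=result.substrate_id,
        transporter=result.transporter,
        experiments=tuple(
            EffluxExperiment(
                experiment_id=e.experiment_id,
                pe_a2b=e.pe_b2a,
                pe_b2a=e.pe_a2b,
                p_value=e.p_value,
                significance_mark=e.significance_mark,
            )
            for e in result.experiments
        ),
    )


def _directional_transport_demonstrated(
    result: EffluxResult, policy: EffluxPolicy
) -> bool:
    """True when the substrate shows reproducible directional transport in
    either direction (efflux rule applied to the data and to its mirror)."""
    try:
        if classify_transporter(result, policy) == EFFLUX_FUNCTIONAL:
            return True
        return classify_transporter(_mirrored(result), policy) == EFFLUX_FUNCTIONAL
    except InsufficientDataError:
        return False


def build_report(
    efflux_results: Iterable[EffluxResult] = (),
    tightness: tuple[Sequence[float], Sequence[float]] | None = None,
    teer: TeerRecord | float | None = None,
    competition: CompetitionVerdict | None = None,
    declared_evidence: Mapping[str, DeclaredEvidence | bool] | None = None,
    *,
    alpha: float = 0.05,
    policy: EffluxPolicy | None = None,
) -> list[BenchmarkItem]:
    """Assemble the benchmark scorecard.

    Parameters
    ----------
    efflux_results:
        Per-substrate :class:`EffluxResult` records carrying a ``transporter``
        label (P-gp, BCRP, Glut1, TfR). Efflux transporters pass on the
        efflux decision rule; Glut1 passes when directional transport is
        demonstrated in either direction.
    tightness:
        ``(pe_nonpermeable, pe_permeable)`` tracer Pe lists.
    teer:
        A :class:`TeerRecord` (converted to Ω·cm²) or a precomputed value.
        The item records that TEER was measured; no pass threshold is applied
        beyond the value being positive.
    competition:
        Competition-test verdict driving the ``tfr_function_rmt`` item.
    declared_evidence:
        item_id → :class:`DeclaredEvidence` (or bare bool) for the
        expression/localization items.
    """
    policy = policy or EffluxPolicy()
    items: dict[str, BenchmarkItem] = {}

    declared = {}
    for key, value in (declared_evidence or {}).items():
        if key not in _EXPRESSION_ITEMS:
            raise ValidationError(f"declared evidence for non-declarable item {key!r}")
        declared[key] = value if isinstance(value, DeclaredEvidence) else DeclaredEvidence(bool(value))
    for item_id in _EXPRESSION_ITEMS:
        if item_id in declared:
            ev = declared[item_id]
            items[item_id] = BenchmarkItem(
                item_id,
                "pass" if ev.observed else "fail",
                evidence=ev.provenance if ev.observed else ev.provenance or "declared absent",
            )
        else:
            items[item_id] = BenchmarkItem(item_id, "not_assessed", evidence="no declared evidence")

    if tightness is not None:
        items["tightness_ly_caffeine"] = tightness_check(*tightness, alpha=alpha)
    else:
        items["tightness_ly_caffeine"] = BenchmarkItem(
            "tightness_ly_caffeine", "not_assessed", evidence="no tracer Pe data"
        )

    if teer is not None:
        value = compute_teer(teer) if isinstance(teer, TeerRecord) else float(teer)
        items["teer_measured"] = BenchmarkItem(
            "teer_measured",
            "pass" if value > 0 else "fail",
            evidence=f"TEER = {value:.1f} Ohm*cm^2 (no pass threshold applied)",
        )
    else:
        items["teer_measured"] = BenchmarkItem(
            "teer_measured", "not_assessed", evidence="no TEER record"
        )

    by_item: dict[str, list[EffluxResult]] = {}
    tfr_results: list[EffluxResult] = []
    for res in efflux_results:
        if res.transporter in TRANSPORTER_ITEMS:
            by_item.setdefault(TRANSPORTER_ITEMS[res.transporter], []).append(res)
        elif res.transporter == "TfR":
            tfr_results.append(res)
    for item_id in ("pgp_function", "bcrp_function", "glut1_function"):
        results = by_item.get(item_id, [])
        if not results:
            items[item_id] = BenchmarkItem(item_id, "not_assessed", evidence="no transport data")
            continue
        if item_id == "glut1_function":
            demonstrated = [r for r in results if _directional_transport_demonstrated(r, policy)]
            rule = "directional transport in either direction (mirrored efflux rule)"
        else:
            demonstrated = []
            for r in results:
                try:
                    if classify_transporter(r, policy) == EFFLUX_FUNCTIONAL:
                        demonstrated.append(r)
                except InsufficientDataError:
                    pass
            rule = (
                f"mean ER > {policy.er_threshold:g} and >= "
                f"{policy.min_significant_fraction:.0%} of experiments significant B>A"
            )
        substrates = ", ".join(
            f"{r.substrate_id} (ER {r.er_mean:.2f}, n={r.n})" for r in results
        )
        if demonstrated:
            items[item_id] = BenchmarkItem(
                item_id, "pass", evidence=f"rule: {rule}; substrates: {substrates}"
            )
        else:
            items[item_id] = BenchmarkItem(
                item_id, "fail", evidence=f"rule: {rule}; substrates: {substrates}"
            )

    if competition is not None:
        ok = competition.verdict == "rmt_consistent"
        evidence = (
            f"competition transport ratio {competition.transport_ratio:.2f}, "
            f"p={competition.p_value:.3g} (alpha={competition.alpha})"
        )
        if tfr_results:
            evidence += "; directional data: " + ", ".join(
                f"{r.substrate_id} ER {r.er_mean:.2f}" for r in tfr_results
            )
        items["tfr_function_rmt"] = BenchmarkItem(
            "tfr_function_rmt", "pass" if ok else "fail", evidence=evidence
        )
    else:
        items["tfr_function_rmt"] = BenchmarkItem(
            "tfr_function_rmt", "not_assessed", evidence="no competition assay"
        )

    return [items[item_id] for item_id in BENCHMARK_ITEM_IDS]


DEFAULT_COMPARISON_CRITERION = (
    "mean +/- SD intervals overlap; classifications must match when both are computable"
)


def compare_facilities(r1: EffluxResult, r2: EffluxResult) -> FacilityComparison:
    """Compare one substrate's efflux summaries from two facilities.

    Default rule: agree iff the two mean ± SD intervals overlap and, when
    both results carry per-experiment data, their efflux classifications
    match. Summary-only results (mean/SD/n) are compared on the interval rule
    alone.
    """
    if r1.substrate_id != r2.substrate_id:
        raise ValidationError(
            f"substrate mismatch: {r1.substrate_id!r} vs {r2.substrate_id!r}"
        )
    s1 = r1.er_sd or 0.0
    s2 = r2.er_sd or 0.0
    overlap = (r1.er_mean - s1 <= r2.er_mean + s2) and (r2.er_mean - s2 <= r1.er_mean + s1)
    agree = overlap
    criterion = DEFAULT_COMPARISON_CRITERION
    if len(r1.experiments) >= 2 and len(r2.experiments) >= 2:
        agree = agree and (classify_transporter(r1) == classify_transporter(r2))
    return FacilityComparison(
        substrate_id=r1.substrate_id,
        facility_results=(r1, r2),
        agree=agree,
        criterion=criterion,
    )


def report_to_frame(items: Sequence[BenchmarkItem]) -> pd.DataFrame:
    """Machine-readable scorecard (one row per item)."""
    return pd.DataFrame(
        [{"item_id": i.item_id, "status": i.status, "evidence": i.evidence} for i in items]
    )


def format_report(items: Sequence[BenchmarkItem]) -> str:
    """Human-readable scorecard table."""
    width = max(len(i.item_id) for i in items)
    lines = [f"{'item':<{width}}  status        evidence", "-" * (width + 40)]
    for i in items:
        lines.append(f"{i.item_id:<{width}}  {i.status:<12}  {i.evidence}")
    return "\n".join(lines)
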