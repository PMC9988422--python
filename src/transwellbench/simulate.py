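"""Forward simulator of two-compartment transwell assays.

Mass-conserving two-compartment exchange across the insert: with donor
amount A_d in volume V_d and receiver amount A_r in volume V_r,

    dA_r/dt = PS_fwd · C_d − PS_bwd · C_r,      C = A / V

where PS_fwd / PS_bwd are the direction-resolved permeability–surface-area
products (μL/min). An apically polarized efflux pump adds a directional
increment ``ps_active`` to basolateral→apical transport and subtracts it
from apical→basolateral transport; optionally the increment saturates with
the instantaneous donor concentration as ps_active·km/(km + C_d). The
cell-free porous membrane is a series barrier: a cell-bearing insert's
effective PS per flux direction is 1/(1/PS_cell + 1/PS_mem); a blank insert
transports with PS_mem alone. The linear case is solved in closed form
(single-exponential relaxation towards the equilibrium partition), the
saturable case by numerical integration.

Measurement noise is multiplicative lognormal with a configured coefficient
of variation, applied independently to every sampled donor and receiver
concentration; all stochasticity derives from the configured seed, so a
given config yields a bit-identical dataset.

The simulator also generates receptor-mediated-transcytosis competition
assays: labeled-ligand transport follows
``capacity·L/(Kd + L + U) + leak·L`` (L labeled dose, U unlabeled
competitor dose), so an equimolar competitor reduces the receptor component
by (Kd + L)/(Kd + 2L) exactly in the noise-free case.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .assay_io import (
    CompetitionAssay,
    InsertGeometry,
    Sample,
    Timecourse,
    write_results,
)
from .errors import ValidationError
from .permeability import PE_UNIT_FACTOR

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_assay",
    "simulate_bidirectional_experiment",
    "simulate_study",
    "simulate_competition",
    "save_simulation",
    "DEFAULT_GEOMETRY",
]

#: 24-well hanging-insert defaults: 0.33 cm² growth area, 400 μL luminal /
#: 600 μL abluminal working volumes. Configurable; not asserted for any
#: particular vendor format.
DEFAULT_GEOMETRY = InsertGeometry(
    membrane_area=0.33, luminal_volume=400.0, abluminal_volume=600.0
)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated bidirectional transwell assay.

    ``ps_passive`` is the symmetric cell-layer PS (μL/min); ``ps_active`` the
    directional efflux increment (apical polarity); ``km`` the donor
    concentration at half-maximal active transport (None = non-saturable);
    ``ps_membrane_blank`` the blank-insert PS. RMT parameters feed
    :func:`simulate_competition`. ``noise_cv`` is the multiplicative
    measurement CV; ``replicates`` the number of inserts per direction and
    condition; ``seed`` drives all randomness.
    """

    geometry: InsertGeometry = DEFAULT_GEOMETRY
    ps_passive: float = 0.4
    ps_active: float = 0.0
    km: float | None = None
    ps_membrane_blank: float = 4.0
    rmt_mode: str = "off"  # "off" | "on"
    rmt_capacity: float = 10.0
    rmt_kd: float = 200.0
    rmt_leak: float = 0.002
    dosing_concentration: float = 1.0
    sample_times: tuple[float, ...] = (15.0, 30.0, 45.0, 60.0)
    noise_cv: float = 0.1
    replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_times", tuple(float(t) for t in self.sample_times))
        if self.ps_passive <= 0:
            raise ValidationError("ps_passive must be positive")
        if self.ps_active < 0:
            raise ValidationError("ps_active must be non-negative")
        if self.ps_passive - self.ps_active <= 0:
            raise ValidationError(
                "ps_active must be smaller than ps_passive so the effective PS "
                "stays positive in both directions"
            )
        if self.ps_membrane_blank <= 0:
            raise ValidationError("ps_membrane_blank must be positive")
        if self.km is not None and self.km <= 0:
            raise ValidationError("km must be positive (or None for non-saturable)")
        if self.rmt_mode not in ("off", "on"):
            raise ValidationError("rmt_mode must be 'off' or 'on'")
        if self.rmt_mode == "on":
            if self.rmt_capacity is None or self.rmt_capacity <= 0:
                raise ValidationError("rmt_capacity must be positive when rmt_mode='on'")
            if self.rmt_kd is None or self.rmt_kd <= 0:
                raise ValidationError("rmt_kd must be positive when rmt_mode='on'")
        if self.rmt_leak < 0:
            raise ValidationError("rmt_leak must be non-negative")
        if self.dosing_concentration <= 0:
            raise ValidationError("dosing_concentration must be positive")
        if len(self.sample_times) < 1 or any(t <= 0 for t in self.sample_times):
            raise ValidationError("sample_times must be positive")
        if any(a >= b for a, b in zip(self.sample_times, self.sample_times[1:])):
            raise ValidationError("sample_times must be strictly increasing")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")

    # -- derived ground truth -------------------------------------------------

    def cell_ps(self, direction: str) -> tuple[float, float]:
        """(PS_fwd, PS_bwd) of the cell layer alone for a dosing direction."""
        if direction == "A2B":
            return self.ps_passive - self.ps_active, self.ps_passive + self.ps_active
        if direction == "B2A":
            return self.ps_passive + self.ps_active, self.ps_passive - self.ps_active
        raise ValidationError(f"direction must be A2B or B2A, got {direction!r}")

    def true_pe(self, direction: str) -> float:
        """Ground-truth cell-layer Pe (10⁻⁶ cm/s) for a direction."""
        ps_fwd, _ = self.cell_ps(direction)
        return ps_fwd / self.geometry.membrane_area * PE_UNIT_FACTOR

    @property
    def true_er(self) -> float:
        return (self.ps_passive + self.ps_active) / (self.ps_passive - self.ps_active)

    @classmethod
    def from_target_pe(
        cls, pe_a2b: float, pe_b2a: float, geometry: InsertGeometry = DEFAULT_GEOMETRY, **kwargs
    ) -> "SimulationConfig":
        """Config whose ground-truth directional Pe (10⁻⁶ cm/s) match targets."""
        if pe_a2b <= 0 or pe_b2a <= 0 or pe_b2a < pe_a2b:
            raise ValidationError("need 0 < pe_a2b <= pe_b2a for an efflux-polarized layer")
        ps_a2b = pe_a2b * geometry.membrane_area / PE_UNIT_FACTOR
        ps_b2a = pe_b2a * geometry.membrane_area / PE_UNIT_FACTOR
        return cls(
            geometry=geometry,
            ps_passive=(ps_a2b + ps_b2a) / 2.0,
            ps_active=(ps_b2a - ps_a2b) / 2.0,
            **kwargs,
        )


@dataclass(frozen=True)
class GroundTruth:
    """True directional cell-layer permeabilities behind a simulated dataset."""

    ps_cell_a2b: float
    ps_cell_b2a: float
    pe_a2b: float
    pe_b2a: float
    er: float


def _receiver_amounts(
    config: SimulationConfig,
    direction: str,
    insert_condition: str,
    times: Sequence[float],
) -> np.ndarray:
    """Noise-free receiver amounts at the sample times."""
    geometry = config.geometry
    v_d = geometry.donor_volume(direction)
    v_r = geometry.receiver_volume(direction)
    a_tot = config.dosing_concentration * v_d
    times = np.asarray(times, dtype=float)

    if insert_condition == "blank":
        ps_fwd = ps_bwd = config.ps_membrane_blank
        saturable = False
    else:
        cell_fwd, cell_bwd = config.cell_ps(direction)
        ps_fwd = _series(cell_fwd, config.ps_membrane_blank)
        ps_bwd = _series(cell_bwd, config.ps_membrane_blank)
        saturable = config.km is not None and config.ps_active > 0

    if not saturable:
        k = ps_fwd / v_d + ps_bwd / v_r
        a_eq = ps_fwd * a_tot / v_d / k
        return a_eq * (1.0 - np.exp(-k * times))

    km = float(config.km)  # type: ignore[arg-type]
    sign = -1.0 if direction == "A2B" else 1.0  # pump pushes toward apical (A)

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        a_r = y[0]
        c_d = (a_tot - a_r) / v_d
        c_r = a_r / v_r
        act = config.ps_active * km / (km + max(c_d, 0.0))
        fwd = _series(config.ps_passive + sign * act, config.ps_membrane_blank)
        bwd = _series(config.ps_passive - sign * act, config.ps_membrane_blank)
        return np.array([fwd * c_d - bwd * c_r])

    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])),
        y0=[0.0],
        t_eval=times,
        rtol=1e-9,
        atol=1e-12 * a_tot,
        method="LSODA",
    )
    if not sol.success:
        raise RuntimeError(f"two-compartment integration failed: {sol.message}")
    return sol.y[0]


def _series(ps_cell: float, ps_mem: float) -> float:
    return 1.0 / (1.0 / ps_cell + 1.0 / ps_mem)


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def simulate_assay(
    config: SimulationConfig,
    direction: str,
    insert_condition: str,
    *,
    substrate_id: str = "sim",
    experiment_id: str = "E1",
    replicate_id: str = "r1",
    rng: np.random.Generator | None = None,
) -> Timecourse:
    """Simulate one insert's timecourse (donor and receiver sampled).

    With no ``rng`` supplied a fresh generator is seeded from ``config.seed``,
    so repeated calls with the same config are bit-identical.
    """
    if insert_condition not in ("cells", "blank"):
        raise ValidationError(f"insert_condition must be cells or blank, got {insert_condition!r}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    geometry = config.geometry
    v_d = geometry.donor_volume(direction)
    v_r = geometry.receiver_volume(direction)
    a_tot = config.dosing_concentration * v_d

    a_r = _receiver_amounts(config, direction, insert_condition, config.sample_times)
    receiver_conc = a_r / v_r
    donor_conc = (a_tot - a_r) / v_d
    n = len(config.sample_times)
    receiver_conc = receiver_conc * _noise_factors(rng, config.noise_cv, n)
    donor_conc = donor_conc * _noise_factors(rng, config.noise_cv, n)

    samples = tuple(
        Sample(time=t, receiver_conc=float(r), donor_conc=float(d))
        for t, r, d in zip(config.sample_times, receiver_conc, donor_conc)
    )
    return Timecourse(
        substrate_id=substrate_id,
        direction=direction,
        experiment_id=experiment_id,
        replicate_id=replicate_id,
        insert_condition=insert_condition,
        donor_initial_concentration=config.dosing_concentration,
        samples=samples,
    )


def _ground_truth(config: SimulationConfig) -> GroundTruth:
    return GroundTruth(
        ps_cell_a2b=config.cell_ps("A2B")[0],
        ps_cell_b2a=config.cell_ps("B2A")[0],
        pe_a2b=config.true_pe("A2B"),
        pe_b2a=config.true_pe("B2A"),
        er=config.true_er,
    )


def simulate_bidirectional_experiment(
    config: SimulationConfig,
    *,
    substrate_id: str = "sim",
    experiment_id: str = "E1",
    rng: np.random.Generator | None = None,
) -> tuple[list[Timecourse], GroundTruth]:
    """One complete experiment: both directions × replicates × {cells, blank}."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    timecourses = []
    for direction in ("A2B", "B2A"):
        for condition in ("cells", "blank"):
            for r in range(1, config.replicates + 1):
                timecourses.append(
                    simulate_assay(
                        config,
                        direction,
                        condition,
                        substrate_id=substrate_id,
                        experiment_id=experiment_id,
                        replicate_id=f"r{r}",
                        rng=rng,
                    )
                )
    return timecourses, _ground_truth(config)


def simulate_study(
    config: SimulationConfig,
    n_experiments: int = 4,
    *,
    substrate_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> tuple[list[Timecourse], GroundTruth]:
    """Several independent experiments sharing one ground truth."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    timecourses = []
    for i in range(1, n_experiments + 1):
        tcs, truth = simulate_bidirectional_experiment(
            config, substrate_id=substrate_id, experiment_id=f"E{i}", rng=rng
        )
        timecourses.extend(tcs)
    return timecourses, truth


def simulate_competition(
    config: SimulationConfig,
    labeled_dose: float = 200.0,
    competitor_dose: float = 200.0,
    *,
    rng: np.random.Generator | None = None,
) -> CompetitionAssay:
    """Simulate a labeled-ligand transport assay with and without competitor.

    Labeled transport is ``capacity·L/(Kd + L + U) + leak·L`` in ``rmt_mode
    'on'`` and ``leak·L`` alone in ``'off'``, with multiplicative lognormal
    replicate noise. The 15-min competitor preincubation of the wet assay is
    represented by the competitor being at receptor equilibrium from t = 0,
    i.e. it simply enters the occupancy denominator.
    """
    if labeled_dose <= 0 or competitor_dose < 0:
        raise ValidationError("labeled_dose must be positive and competitor_dose non-negative")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    def mean_transport(unlabeled: float) -> float:
        total = config.rmt_leak * labeled_dose
        if config.rmt_mode == "on":
            total += (
                config.rmt_capacity
                * labeled_dose
                / (config.rmt_kd + labeled_dose + unlabeled)
            )
        return total

    n = config.replicates
    alone = mean_transport(0.0) * _noise_factors(rng, config.noise_cv, n)
    comp = mean_transport(competitor_dose) * _noise_factors(rng, config.noise_cv, n)
    return CompetitionAssay(
        labeled_alone=tuple(float(v) for v in alone),
        labeled_plus_competitor=tuple(float(v) for v in comp),
        labeled_dose=labeled_dose,
        competitor_dose=competitor_dose,
    )


def save_simulation(
    timecourses: Sequence[Timecourse],
    truth: GroundTruth,
    config: SimulationConfig,
    csv_path: str | Path,
) -> Path:
    """Write the tidy assay CSV plus a JSON sidecar with config and truth.

    The sidecar (``<csv>.truth.json``) embeds the full simulation config —
    including the seed — so every simulated dataset is reproducible from its
    own provenance record. Returns the sidecar path.
    """
    csv_path = Path(csv_path)
    write_results(list(timecourses), csv_path)
    sidecar = csv_path.with_suffix(csv_path.suffix + ".truth.json")
    payload = {
        "config": dataclasses.asdict(config),
        "ground_truth": dataclasses.asdict(truth),
    }
    sidecar.write_text(json.dumps(payload, indent=2))
    return sidecar
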