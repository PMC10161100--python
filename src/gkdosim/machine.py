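"""Source geometry, plans, absolute calibration chain and sector sampling.

The treatment unit carries 192 ⁶⁰Co sources on 8 independently movable
sectors of 24 sources each, all aimed at the unit center point (UCP) at
(100, 100, 100) mm.  Each sector selects a 4, 8 or 16 mm collimation
channel or a blocked state, so a "composite" shot can mix field sizes
across sectors.  Absolute dose traces back to an ionization-chamber
measurement at the UCP of a 160 mm water sphere with the 16 mm field,
decay-corrected to the delivery date.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .grids import UCP

COBALT60_HALF_LIFE_YEARS = 5.2711
COLLIMATORS = (4, 8, 16)
BLOCKED = "blocked"
SOURCE_FOCUS_DISTANCE = 400.0  # mm
N_SECTORS = 8
SOURCES_PER_SECTOR = 24


@dataclass
class Source:
    position: np.ndarray  # mm
    direction: np.ndarray  # unit vector toward the focus
    sector: int


@dataclass
class MachineModel:
    """192-source geometry plus per-collimator beam parameters.

    ``output_factors`` are relative outputs at the focus (16 mm ≡ 1);
    ``mu`` is the effective narrow-beam attenuation coefficient in cm²/g;
    ``penumbra_sigma`` the erf-penumbra width (mm) per collimator;
    ``scatter_amplitude``/``scatter_range_mm`` shape the isotropic
    exponential scatter kernel of the deterministic engine.
    """

    sources: list[Source]
    output_factors: dict[int, float] = field(
        default_factory=lambda: {16: 1.0, 8: 0.9, 4: 0.814}
    )
    mu: float = 0.063  # cm²/g, ⁶⁰Co narrow-beam in water
    penumbra_sigma: dict[int, float] = field(
        default_factory=lambda: {16: 1.5, 8: 1.1, 4: 0.8}
    )
    scatter_amplitude: dict[int, float] = field(
        default_factory=lambda: {16: 0.12, 8: 0.10, 4: 0.08}
    )
    scatter_range_mm: float = 12.0
    focus: np.ndarray = field(default_factory=lambda: UCP.copy())

    def sector_sources(self, sector: int) -> list[Source]:
        return [s for s in self.sources if s.sector == sector]

    def field_radius(self, collimator: int) -> float:
        """Nominal field radius (mm) at the focus."""
        return collimator / 2.0


def default_machine(
    ring_polar_deg: tuple[float, ...] = (36.0, 44.0, 52.0, 60.0, 68.0),
    sources_per_ring: tuple[int, ...] = (4, 5, 5, 5, 5),
    sfd: float = SOURCE_FOCUS_DISTANCE,
) -> MachineModel:
    """Default source geometry: 8 sectors × 24 sources on 5 latitude rings.

    Sources sit on a cone around the z axis at source–focus distance
    ``sfd``; each sector owns a disjoint 45° azimuthal span.  Exact ring
    angles are configurable — downstream results depend on counts,
    normalisation and ratios, not on the precise placement.
    """
    if sum(sources_per_ring) != SOURCES_PER_SECTOR:
        raise ValueError("sources_per_ring must sum to 24")
    sources: list[Source] = []
    for sector in range(N_SECTORS):
        phi0 = sector * (360.0 / N_SECTORS)
        for theta_deg, n_ring in zip(ring_polar_deg, sources_per_ring):
            th = np.deg2rad(theta_deg)
            for j in range(n_ring):
                phi = np.deg2rad(phi0 + (j + 0.5) * (360.0 / N_SECTORS) / n_ring)
                u = np.array(
                    [np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi), np.cos(th)]
                )
                pos = UCP + sfd * u
                sources.append(Source(position=pos, direction=-u, sector=sector))
    return MachineModel(sources=sources)


@dataclass
class Shot:
    """One focal irradiation: a center and per-sector collimator states."""

    center: tuple[float, float, float] = tuple(UCP)
    sector_states: tuple = (16,) * N_SECTORS
    duration_weight: float = 1.0

    def __post_init__(self):
        if len(self.sector_states) != N_SECTORS:
            raise ValueError(f"need {N_SECTORS} sector states")
        for s in self.sector_states:
            if s != BLOCKED and s not in COLLIMATORS:
                raise ValueError(f"invalid sector state {s!r}")
        if self.duration_weight < 0:
            raise ValueError("duration_weight must be non-negative")
        if not self.active_sectors and self.duration_weight > 0:
            raise ValueError(
                "all sectors blocked; use duration_weight=0 for a null shot"
            )

    @property
    def active_sectors(self) -> list[int]:
        return [i for i, s in enumerate(self.sector_states) if s != BLOCKED]


@dataclass
class Plan:
    shots: list[Shot]
    prescription_dose: float = 4.0  # Gy
    prescription_isodose: float = 50.0  # % of maximum
    reference_dose_rate: float = 3.215  # Gy/min at reference_date
    reference_date: _dt.date | float = 0.0
    beam_on_time: float | None = None  # minutes, set by normalisation

    def __post_init__(self):
        if not self.shots:
            raise ValueError("plan must contain at least one shot")
        if not (0 < self.prescription_isodose <= 100):
            raise ValueError("prescription isodose must be in (0, 100] %")
        if self.reference_dose_rate <= 0:
            raise ValueError("reference dose rate must be positive")


def plan_to_yaml(plan: Plan, path) -> None:
    """Write a plan as YAML (shots, sector states, prescription, reference)."""
    import yaml
    from pathlib import Path

    payload = {
        "prescription_dose": plan.prescription_dose,
        "prescription_isodose": plan.prescription_isodose,
        "reference_dose_rate": plan.reference_dose_rate,
        "reference_date": plan.reference_date
        if isinstance(plan.reference_date, (int, float))
        else plan.reference_date.isoformat(),
        "beam_on_time": plan.beam_on_time,
        "shots": [
            {
                "center": [float(v) for v in shot.center],
                "sector_states": list(shot.sector_states),
                "duration_weight": shot.duration_weight,
            }
            for shot in plan.shots
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload))


def plan_from_yaml(path) -> Plan:
    """Read a plan from YAML (or JSON, which YAML subsumes)."""
    import yaml
    from pathlib import Path

    raw = yaml.safe_load(Path(path).read_text())
    shots = [
        Shot(
            center=tuple(s["center"]),
            sector_states=tuple(s["sector_states"]),
            duration_weight=s.get("duration_weight", 1.0),
        )
        for s in raw["shots"]
    ]
    return Plan(
        shots=shots,
        prescription_dose=raw.get("prescription_dose", 4.0),
        prescription_isodose=raw.get("prescription_isodose", 50.0),
        reference_dose_rate=raw.get("reference_dose_rate", 3.215),
        reference_date=raw.get("reference_date", 0.0),
        beam_on_time=raw.get("beam_on_time"),
    )


def plan_from_xml(path) -> Plan:
    """Stub loader for the planning-system XML export dialect.

    Maps the same fields as the YAML form from a minimal XML layout:
    ``<plan><shot x= y= z= weight=><sector state=/>…</shot>…</plan>``.
    """
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    shots = []
    for el in root.findall("shot"):
        states = tuple(
            int(s.get("state")) if s.get("state") != "blocked" else "blocked"
            for s in el.findall("sector")
        )
        shots.append(
            Shot(
                center=(float(el.get("x")), float(el.get("y")), float(el.get("z"))),
                sector_states=states or (16,) * N_SECTORS,
                duration_weight=float(el.get("weight", 1.0)),
            )
        )
    attrs = root.attrib
    return Plan(
        shots=shots,
        prescription_dose=float(attrs.get("prescription_dose", 4.0)),
        prescription_isodose=float(attrs.get("prescription_isodose", 50.0)),
        reference_dose_rate=float(attrs.get("reference_dose_rate", 3.215)),
    )


def reference_plan() -> Plan:
    """Calibration configuration: a single 16 mm shot at the UCP."""
    return Plan(shots=[Shot()])


def multi_shot_plan() -> Plan:
    """Synthetic 7-shot plan mimicking the verification field-size mix:
    four 4 mm shots, one 8 mm shot, and two composite shots mixing
    4/8/16 mm sectors.  Shot coordinates are the package's own layout
    (clustered around the phantom core); relative durations are equal."""
    c = UCP
    shots = [
        Shot(tuple(c + np.array([3.0, 2.0, 0.0])), (4,) * 8),
        Shot(tuple(c + np.array([-3.0, 2.0, 0.0])), (4,) * 8),
        Shot(tuple(c + np.array([0.0, -3.0, 1.0])), (4,) * 8),
        Shot(tuple(c + np.array([0.0, 3.5, -1.0])), (4,) * 8),
        Shot(tuple(c + np.array([0.0, 0.0, 0.0])), (8,) * 8),
        Shot(tuple(c + np.array([2.0, -2.0, 0.0])), (4, 4, 8, 8, 16, 16, 8, 4)),
        Shot(tuple(c + np.array([-2.0, -2.0, 0.0])), (4, 8, 16, 8, 4, 8, 16, 8)),
    ]
    return Plan(shots=shots)


# ---------------------------------------------------------------------------
# Absolute calibration chain
# ---------------------------------------------------------------------------

def _years_between(date0, date) -> float:
    if isinstance(date0, (int, float)) and isinstance(date, (int, float)):
        return float(date) - float(date0)
    if isinstance(date0, (_dt.date, _dt.datetime)) and isinstance(
        date, (_dt.date, _dt.datetime)
    ):
        return ((date - date0).total_seconds() / (365.25 * 86400.0)
                if isinstance(date0, _dt.datetime)
                else (date - date0).days / 365.25)
    raise TypeError("dates must both be calendar dates or both year numbers")


def decay_corrected_rate(rate0: float, date0, date) -> float:
    """Reference dose rate corrected for ⁶⁰Co decay from date0 to date.

    Dates may be ``datetime.date`` objects or plain year numbers (the
    latter make half-life identities exact in tests).
    """
    dt_years = _years_between(date0, date)
    if dt_years < 0:
        raise ValueError("correction date precedes the reference date")
    return rate0 * 2.0 ** (-dt_years / COBALT60_HALF_LIFE_YEARS)


@dataclass
class ChamberMeasurement:
    """Ionization-chamber reading and its correction chain.

    D = M · k_TP · k_pol · k_ion · N_D,w · K_Q,Qo · K_Qmsr, with the
    machine-specific-reference-field factor defaulting to 1.0037.
    """

    charge_nC: float
    k_tp: float = 1.0
    k_pol: float = 1.0
    k_ion: float = 1.0
    n_dw: float = 1.0  # Gy/nC
    k_q: float = 1.0
    k_qmsr: float = 1.0037

    def __post_init__(self):
        for name in ("k_tp", "k_pol", "k_ion", "n_dw", "k_q", "k_qmsr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def chamber_dose(m: ChamberMeasurement) -> float:
    """Absorbed dose to water from a corrected chamber reading (Gy)."""
    return (
        m.charge_nC * m.k_tp * m.k_pol * m.k_ion * m.n_dw * m.k_q * m.k_qmsr
    )


# ---------------------------------------------------------------------------
# Sector sampling distribution (stochastic engine)
# ---------------------------------------------------------------------------

@dataclass
class SectorSampling:
    """Per-(shot, sector) sampling categories with probabilities
    P_i = t_i·N_i / Σ t_j·N_j, where t_i is the time the sector was active
    and N_i the phase-space particle count of its collimator."""

    categories: list[tuple[int, int]]  # (shot index, sector index)
    collimators: list[int]
    t: np.ndarray
    n: np.ndarray
    p: np.ndarray


def sector_probabilities(
    plan: Plan, phsp_counts: dict[int, int] | None = None
) -> SectorSampling:
    """Sampling distribution over all active (shot, sector) pairs.

    ``phsp_counts`` maps collimator size → phase-space particle count
    (equal counts by default).  Blocked sectors are excluded; a plan with
    no active time raises.
    """
    phsp_counts = phsp_counts or {c: 1 for c in COLLIMATORS}
    cats, colls, t, n = [], [], [], []
    for si, shot in enumerate(plan.shots):
        for sec in shot.active_sectors:
            coll = shot.sector_states[sec]
            if phsp_counts.get(coll, 0) <= 0:
                raise ValueError(f"phase-space count for {coll} mm must be positive")
            cats.append((si, sec))
            colls.append(coll)
            t.append(shot.duration_weight)
            n.append(phsp_counts[coll])
    t = np.asarray(t, float)
    n = np.asarray(n, float)
    total = float(np.sum(t * n))
    if total <= 0:
        raise ValueError("no active sector time in plan")
    return SectorSampling(cats, colls, t, n, (t * n) / total)


def normalize_prescription(rel_dose, plan: Plan) -> tuple[float, float]:
    """Prescription normalisation of a relative dose grid.

    ``rel_dose`` is the engine's relative dose (an array or VoxelGrid)
    normalised so that 1.0 corresponds to the reference dose rate
    (Gy/min delivered at the UCP of the reference water sphere by the
    16 mm field).  Returns ``(scale, bot)`` where ``scale`` converts
    relative dose to Gy and ``bot`` is the beam-on time in minutes:
    the maximum scaled dose equals prescription / (isodose fraction),
    and BOT = max dose / (reference rate × relative dose at maximum).
    """
    data = rel_dose.data if hasattr(rel_dose, "data") else np.asarray(rel_dose)
    rel_max = float(np.max(data))
    if rel_max <= 0:
        raise ValueError("relative dose grid has no positive maximum")
    max_dose = plan.prescription_dose / (plan.prescription_isodose / 100.0)
    scale = max_dose / rel_max
    bot = max_dose / (plan.reference_dose_rate * rel_max)
    return scale, bot
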