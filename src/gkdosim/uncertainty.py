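"""GUM-style uncertainty budgets: quadrature combination of components."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


@dataclass
class UncertaintyComponent:
    label: str
    value: float  # % at k = 1
    kind: str = "B"  # "A" (statistical) or "B" (systematic)

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("uncertainty components must be non-negative")
        if self.kind not in ("A", "B"):
            raise ValueError("component type must be 'A' or 'B'")


@dataclass
class UncertaintyBudget:
    """Named list of k=1 percent uncertainties combined in quadrature."""

    name: str
    components: list[UncertaintyComponent] = field(default_factory=list)

    def add(self, label: str, value: float, kind: str = "B") -> "UncertaintyBudget":
        self.components.append(UncertaintyComponent(label, value, kind))
        return self

    @property
    def combined(self) -> float:
        return combine_quadrature([c.value for c in self.components])

    @property
    def combined_display(self) -> float:
        """Combined value rounded half-up to one decimal for display."""
        return round_half_up(self.combined, 1)


def combine_quadrature(values) -> float:
    """√(Σ uᵢ²) of k=1 components (≥ 1 component, all non-negative)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one uncertainty component")
    if np.any(vals < 0):
        raise ValueError("uncertainty components must be non-negative")
    return float(np.sqrt(np.sum(vals**2)))


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def default_budgets() -> dict[str, UncertaintyBudget]:
    """Packaged k=1 budgets for the three dosimetry chains.

    Calibration: chamber charge statistics, influence-quantity corrections,
    the chamber calibration coefficient and the machine-specific reference
    field correction.  Film: calibration-fit data, read-out repeatability,
    scanner homogeneity and the dose-to-medium correction factor.
    Stochastic engine: statistical and scaling-chain components.
    """
    cal = UncertaintyBudget("calibration")
    cal.add("collected charge", 0.1, "A")
    cal.add("influence-quantity corrections (k_TP, k_ion, k_pol)", 0.3)
    cal.add("chamber calibration coefficient N_D,w", 0.7)
    cal.add("msr-field correction K_Qmsr", 0.5)

    film = UncertaintyBudget("film")
    film.add("calibration data", 1.9)
    film.add("read-out repeatability", 0.3, "A")
    film.add("scanner homogeneity", 0.2)
    film.add("dose-to-medium correction K_med", 0.3)

    mc = UncertaintyBudget("mc")
    mc.add("statistical (batch)", 0.5, "A")
    mc.add("absolute scaling factor F", 0.9)
    mc.add("K_med dose ratios", 0.78)
    return {"calibration": cal, "film": film, "mc": mc}
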