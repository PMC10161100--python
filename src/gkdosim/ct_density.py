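"""CT number → density conversion.

Two pathways mirror how a convolution-style planning system and a Monte
Carlo engine consume the same CT series:

* the *convolution* (``lgp``) pathway maps HU → relative electron density η
  through the scanner calibration curve and derives mass density ρ from η
  with the continuous piecewise rule :func:`eta_to_rho`
  (ρ = η for η ≤ 1, ρ = (η − 0.15)/0.85 for η > 1);
* the *mc* pathway maps HU → ρ directly through a second set of calibration
  breakpoints and bins ρ into tissue-composition classes (a compact
  Schneider-style density → elemental-composition table).

HU outside the calibration range clamp to the end values, so image noise
can never produce negative densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import VoxelGrid


@dataclass
class CalibrationCurve:
    """Piecewise-linear HU → η (and optionally HU → ρ) scanner calibration.

    ``hu`` must be strictly increasing; ``eta`` (and ``rho`` if given)
    non-negative and non-decreasing.  At least two breakpoints.
    """

    hu: np.ndarray
    eta: np.ndarray
    rho: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.hu.size < 2:
            raise ValueError("calibration curve needs at least 2 breakpoints")
        if self.hu.size != self.eta.size:
            raise ValueError("hu and eta must have equal length")
        if np.any(np.diff(self.hu) <= 0):
            raise ValueError("HU breakpoints must be strictly increasing")
        if np.any(self.eta < 0) or np.any(np.diff(self.eta) < 0):
            raise ValueError("eta breakpoints must be non-negative, non-decreasing")
        if self.rho is not None:
            self.rho = np.asarray(self.rho, dtype=float)
            if self.rho.size != self.hu.size:
                raise ValueError("rho breakpoints must match hu length")
            if np.any(self.rho < 0) or np.any(np.diff(self.rho) < 0):
                raise ValueError("rho breakpoints must be non-negative, non-decreasing")

    @property
    def eta_range(self) -> tuple[float, float]:
        return float(self.eta[0]), float(self.eta[-1])

    def eta_to_hu(self, eta) -> np.ndarray:
        """Inverse map (used when synthesising CT from known materials).

        Requires strictly increasing η breakpoints; η outside the curve
        range raises, since the forward map could not recover it.
        """
        if np.any(np.diff(self.eta) <= 0):
            raise ValueError("eta breakpoints must be strictly increasing to invert")
        e = np.asarray(eta, dtype=float)
        lo, hi = self.eta_range
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"eta outside calibration range [{lo}, {hi}]; cannot invert"
            )
        return np.interp(e, self.eta, self.hu)

    @classmethod
    def default(cls) -> "CalibrationCurve":
        """Two-segment curve approximating a typical 120 kVp scanner."""
        return cls(
            hu=np.array([-1000.0, 0.0, 1600.0]),
            eta=np.array([0.001, 1.0, 1.9]),
            rho=np.array([0.001, 1.0, 1.9]),
        )

    # CSV round-trip (columns: hu, eta[, rho])
    def to_csv(self, path: str | Path) -> None:
        cols = [self.hu, self.eta] + ([self.rho] if self.rho is not None else [])
        header = "hu,eta" + (",rho" if self.rho is not None else "")
        np.savetxt(path, np.column_stack(cols), delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationCurve":
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            arr = np.loadtxt(fh, delimiter=",", ndmin=2)
        cols = {name: arr[:, i] for i, name in enumerate(header)}
        return cls(hu=cols["hu"], eta=cols["eta"], rho=cols.get("rho"))


def hu_to_eta(hu, curve: CalibrationCurve):
    """Relative electron density from HU by piecewise-linear interpolation.

    Values outside the breakpoint range clamp to the end values.
    Accepts scalars, arrays or a :class:`VoxelGrid` (returned as a grid).
    """
    if isinstance(hu, VoxelGrid):
        return hu.copy_with(hu_to_eta(hu.data, curve))
    return np.interp(np.asarray(hu, dtype=float), curve.hu, curve.eta)


def hu_to_rho_mc(hu, curve: CalibrationCurve):
    """Mass density from HU via the direct HU → ρ breakpoints (MC pathway)."""
    if curve.rho is None:
        raise ValueError("calibration curve carries no HU → rho breakpoints")
    if isinstance(hu, VoxelGrid):
        return hu.copy_with(hu_to_rho_mc(hu.data, curve))
    return np.interp(np.asarray(hu, dtype=float), curve.hu, curve.rho)


def eta_to_rho(eta):
    """Mass density ρ (g/cm³) from relative electron density η.

    Continuous piecewise map: identity for η ≤ 1, (η − 0.15)/0.85 for η > 1.
    Both branches meet at η = 1, so the map is continuous and monotone.
    """
    if isinstance(eta, VoxelGrid):
        return eta.copy_with(eta_to_rho(eta.data))
    e = np.asarray(eta, dtype=float)
    if np.any(e < 0):
        raise ValueError("relative electron density must be non-negative")
    out = np.where(e <= 1.0, e, (e - 0.15) / 0.85)
    return out if out.ndim else float(out)


# Compact Schneider-style density binning: (name, rho_low, rho_high,
# mass fractions).  Open-ended extreme bins; fractions sum to 1.
SCHNEIDER_BINS: list[tuple[str, float, float, dict[str, float]]] = [
    ("air", 0.0, 0.05, {"N": 0.755, "O": 0.232, "Ar": 0.013}),
    ("lung", 0.05, 0.85, {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749, "P": 0.002, "other": 0.010}),
    ("adipose", 0.85, 0.975, {"H": 0.114, "C": 0.598, "N": 0.007, "O": 0.278, "other": 0.003}),
    ("soft_tissue", 0.975, 1.101, {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708, "P": 0.003, "other": 0.010}),
    ("bone", 1.101, np.inf, {"H": 0.056, "C": 0.235, "N": 0.050, "O": 0.434, "P": 0.072, "Ca": 0.146, "other": 0.007}),
]


def rho_to_composition(rho):
    """Composition-bin index for a mass density (vectorised).

    Returns the index into :data:`SCHNEIDER_BINS` whose half-open density
    interval contains ρ; the extreme bins are open-ended.
    """
    scalar = np.isscalar(rho) or np.asarray(rho).ndim == 0
    r = np.asarray(rho, dtype=float)
    if np.any(r < 0):
        raise ValueError("mass density must be non-negative")
    edges = np.array([b[1] for b in SCHNEIDER_BINS[1:]])
    idx = np.digitize(r, edges, right=False)
    return int(idx) if scalar else idx


def composition_of_bin(index: int) -> dict[str, float]:
    return dict(SCHNEIDER_BINS[index][3])


@dataclass
class DensityMaps:
    """Per-voxel η, ρ and composition-bin grids sharing the CT geometry."""

    eta: VoxelGrid
    rho: VoxelGrid
    composition: VoxelGrid


def build_density_maps(
    ct: VoxelGrid, curve: CalibrationCurve, pathway: str = "lgp"
) -> DensityMaps:
    """Voxel-by-voxel density maps from a CT grid.

    ``pathway='lgp'`` derives ρ from η via :func:`eta_to_rho` (the
    convolution chain); ``pathway='mc'`` uses the direct HU → ρ
    calibration breakpoints.
    """
    eta = hu_to_eta(ct, curve)
    if pathway == "lgp":
        rho = eta_to_rho(eta)
    elif pathway == "mc":
        rho = hu_to_rho_mc(ct, curve)
    else:
        raise ValueError(f"unknown pathway {pathway!r} (expected 'lgp' or 'mc')")
    comp = ct.copy_with(rho_to_composition(rho.data))
    return DensityMaps(eta=eta, rho=rho, composition=comp)
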