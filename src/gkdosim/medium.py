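"""Dose-to-water ↔ dose-to-medium conversion with K_med factors.

A film calibrated in a ⁶⁰Co water beam reads dose-to-water even when it
lies inside bone or air.  The multiplicative correction
K_med = (D_med/D_film at the treatment geometry) × (D_film/D_w at
calibration) converts its reading to dose-to-medium.  The packaged
default factors (per medium and field size) come from full Monte Carlo
transport published for this phantom family; re-deriving them requires
electron transport and is outside this package's fidelity boundary —
users may supply their own table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .phantom import DOSE_TO_MEDIUM, DOSE_TO_WATER, FilmImage
from .dose import DoseGrid

#: default K_med factors: medium → {field size mm → factor}
DEFAULT_KMED = {
    "bone": {16: 0.941, 8: 0.946, 4: 0.946},
    "air": {16: 0.745, 8: 0.748, 4: 0.749},
}


def kmed_from_ratios(d_med_over_d_film_lgk: float, d_film_over_d_w_cal: float) -> float:
    """K_med as the product of the treatment-geometry and calibration ratios."""
    if d_med_over_d_film_lgk <= 0 or d_film_over_d_w_cal <= 0:
        raise ValueError("dose ratios must be positive")
    return d_med_over_d_film_lgk * d_film_over_d_w_cal


@dataclass
class KmedTable:
    """(medium, field size mm) → dose-to-medium correction factor.

    Water-equivalent media carry factor 1 exactly.
    """

    factors: dict[str, dict[int, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_KMED.items()}
    )

    def __post_init__(self):
        for medium, by_field in self.factors.items():
            for fs, k in by_field.items():
                if k <= 0:
                    raise ValueError(f"K_med({medium}, {fs} mm) must be positive")

    def lookup(self, medium: str, field_size: int) -> float:
        if medium in ("water", "solid_water", "rw3"):
            return 1.0
        try:
            return self.factors[medium][field_size]
        except KeyError:
            raise KeyError(
                f"no K_med entry for medium {medium!r}, field {field_size} mm"
            ) from None

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["medium", "field_mm", "kmed"])
            for medium, by_field in self.factors.items():
                for fs, k in sorted(by_field.items()):
                    w.writerow([medium, fs, k])

    @classmethod
    def from_csv(cls, path: str | Path) -> "KmedTable":
        factors: dict[str, dict[int, float]] = {}
        with open(path) as fh:
            for row in csv.DictReader(fh):
                factors.setdefault(row["medium"], {})[int(row["field_mm"])] = float(
                    row["kmed"]
                )
        return cls(factors)


def plan_average_kmed(
    table: KmedTable, medium: str, field_sizes_used, weights=None
) -> float:
    """Average K_med over the distinct field sizes a plan uses.

    The default is the unweighted arithmetic mean over distinct field
    sizes; pass ``weights`` (e.g. per-field beam-on times) for a weighted
    variant.
    """
    sizes = sorted(set(int(f) for f in field_sizes_used))
    if not sizes:
        raise ValueError("no field sizes given")
    vals = np.array([table.lookup(medium, fs) for fs in sizes])
    if weights is None:
        return float(vals.mean())
    w = np.asarray([weights[fs] for fs in sizes], dtype=float)
    return float(np.sum(vals * w) / np.sum(w))


@dataclass
class RegionMask:
    """Mutually exclusive boolean masks per medium on a map's raster."""

    masks: dict[str, np.ndarray]

    def __post_init__(self):
        arrs = list(self.masks.values())
        if arrs:
            total = np.zeros(arrs[0].shape, dtype=int)
            for a in arrs:
                if a.shape != arrs[0].shape:
                    raise ValueError("all masks must share one shape")
                total += a.astype(int)
            if np.any(total > 1):
                raise ValueError("region masks must be mutually exclusive")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def get(self, name: str, default=None):
        return self.masks.get(name, default)


def masks_from_labels(label_grid, points, shape, media=("bone", "air")) -> RegionMask:
    """Nearest-neighbour material masks at arbitrary sample points.

    ``points`` are stacked (N, 3) physical positions (e.g. transformed film
    pixel centers); the result is reshaped to ``shape``.
    """
    codes = label_grid.sample(points, order=0).astype(int).reshape(shape)
    masks = {}
    for name in media:
        sel = np.zeros(shape, dtype=bool)
        for code, lname in label_grid.labels.items():
            if lname == name:
                sel |= codes == code
        masks[name] = sel
    return RegionMask(masks)


def apply_kmed(
    dose_map: FilmImage | DoseGrid,
    masks: RegionMask,
    factors: dict[str, float] | None = None,
    table: KmedTable | None = None,
    field_sizes_used=None,
) -> FilmImage | DoseGrid:
    """Convert a dose-to-water map to dose-to-medium.

    Pixels inside each medium's mask are multiplied by that medium's
    factor (either given directly in ``factors`` or plan-averaged from
    ``table`` over ``field_sizes_used``); everything else is untouched.
    Applying the conversion twice is an error.
    """
    if dose_map.medium != DOSE_TO_WATER:
        raise ValueError(
            "input map already reports dose-to-medium; refusing double conversion"
        )
    if factors is None:
        if table is None or field_sizes_used is None:
            raise ValueError("give either factors or (table, field_sizes_used)")
        factors = {
            m: plan_average_kmed(table, m, field_sizes_used) for m in masks.masks
        }
    data = np.array(dose_map.data, dtype=float)
    for medium, k in factors.items():
        m = masks.get(medium)
        if m is not None:
            data[m] = data[m] * k
    if isinstance(dose_map, FilmImage):
        return dose_map.copy_with(data, medium=DOSE_TO_MEDIUM)
    return DoseGrid(
        grid=dose_map.grid.copy_with(data),
        medium=DOSE_TO_MEDIUM,
        uncertainty=dose_map.uncertainty,
        bot=dose_map.bot,
        calibration=dose_map.calibration,
    )
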