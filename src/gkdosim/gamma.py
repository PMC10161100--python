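"""Gamma-index comparison of dose distributions (1D/2D/3D).

γ at a reference point r is the minimum over evaluated points e of
√(|r − e|²/DTA² + (D_e − D_r)²/(f·D_r)²) with local normalisation
(f = DD%/100 of the reference point's own dose; global normalisation
uses the reference maximum instead).  The evaluated distribution is
resampled to a fine regular raster (default 0.1 mm) before the search,
points below the dose cut-off (default 1 Gy) are not evaluated, and the
passing rate is the percentage of evaluated points with γ ≤ 1.

The search is windowed to ``search_radius_mm`` (default 3×DTA) around
each reference point with an early exit on the sorted offsets; setting
``search_radius_mm=numpy.inf`` searches the whole resampled map
exhaustively (the brute-force form used as the oracle in tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .grids import VoxelGrid
from .phantom import FilmImage


@dataclass
class GammaCriteria:
    dd_percent: float = 3.0
    dta_mm: float = 1.0
    cutoff_gy: float = 1.0
    resample_step_mm: float = 0.1
    search_radius_mm: float | None = None  # None → 3×DTA; inf → exhaustive
    normalization: str = "local"

    def __post_init__(self):
        if min(self.dd_percent, self.dta_mm, self.resample_step_mm) <= 0:
            raise ValueError("criteria must be strictly positive")
        if self.cutoff_gy <= 0:
            raise ValueError("dose cut-off must be strictly positive")
        if self.resample_step_mm > self.dta_mm:
            raise ValueError("resample step must not exceed the DTA")
        if self.normalization not in ("local", "global"):
            raise ValueError("normalization must be 'local' or 'global'")

    @property
    def radius(self) -> float:
        return (
            3.0 * self.dta_mm
            if self.search_radius_mm is None
            else self.search_radius_mm
        )


def _as_map(obj) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coerce a dose map to (values, spacing, origin) in a shared mm frame."""
    if isinstance(obj, FilmImage):
        vals = obj.data
        nd = 2
        return vals, np.array([obj.pitch] * nd), np.zeros(nd)
    if isinstance(obj, VoxelGrid):
        return obj.data, np.asarray(obj.spacing), np.asarray(obj.origin)
    if hasattr(obj, "grid"):  # DoseGrid
        g = obj.grid
        return g.data, np.asarray(g.spacing), np.asarray(g.origin)
    if isinstance(obj, tuple):
        vals = np.asarray(obj[0], dtype=float)
        spacing = np.broadcast_to(np.asarray(obj[1], dtype=float).ravel(), (vals.ndim,)).copy()
        origin = (
            np.asarray(obj[2], dtype=float)
            if len(obj) > 2
            else np.zeros(vals.ndim)
        )
        return vals, spacing, origin
    vals = np.asarray(obj, dtype=float)
    return vals, np.ones(vals.ndim), np.zeros(vals.ndim)


def resample_map(values, spacing, step_mm: float):
    """Linearly resample a regular map onto a finer raster, same extent.

    Returns (fine values, fine spacing).  ``step_mm`` may be a scalar or
    per-axis; it must not exceed the map extent on any axis.
    """
    vals = np.asarray(values, dtype=float)
    sp = np.broadcast_to(np.asarray(spacing, dtype=float).ravel(), (vals.ndim,))
    step = np.broadcast_to(np.asarray(step_mm, dtype=float).ravel(), (vals.ndim,))
    if np.any(step <= 0):
        raise ValueError("resample step must be positive")
    extent = (np.asarray(vals.shape) - 1) * sp
    if np.any(step > np.maximum(extent, sp)):
        raise ValueError("resample step exceeds the map extent")
    axes = [
        np.arange(0.0, extent[a] + 0.5 * step[a], step[a]) / sp[a]
        for a in range(vals.ndim)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    fine = ndimage.map_coordinates(
        vals, np.stack([m.ravel() for m in mesh]), order=1, mode="nearest"
    ).reshape([len(a) for a in axes])
    return fine, step.copy()


@dataclass
class GammaResult:
    """Per-point γ map (NaN where not evaluated), the evaluated-point mask,
    the criteria used and the passing rate (% of evaluated points ≤ 1)."""

    gamma: np.ndarray
    mask: np.ndarray
    criteria: GammaCriteria
    passing_rate: float


def _gamma_core(
    ref_vals, ref_pos, eval_fine, fine_origin, fine_step, criteria
):
    """Minimum γ for each reference point (positions in mm)."""
    n = len(ref_vals)
    f = criteria.dd_percent / 100.0
    if criteria.normalization == "local":
        denom = f * np.abs(ref_vals)
    else:
        denom = np.full(n, f * np.abs(ref_vals).max())
    dta2 = criteria.dta_mm**2
    best = np.full(n, np.inf)

    nd = eval_fine.ndim
    shape = np.asarray(eval_fine.shape)
    radius = criteria.radius

    if np.isinf(radius):
        # exhaustive search over every resampled point, chunked over refs
        fine_flat = eval_fine.ravel()
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in eval_fine.shape], indexing="ij"),
            axis=-1,
        ).reshape(-1, nd)
        pos_e = fine_origin + idx * fine_step
        chunk = max(1, int(2e7) // max(len(fine_flat), 1))
        for i0 in range(0, n, chunk):
            sl = slice(i0, min(i0 + chunk, n))
            d2 = np.sum(
                (ref_pos[sl, None, :] - pos_e[None, :, :]) ** 2, axis=-1
            )
            g2 = d2 / dta2 + (
                (fine_flat[None, :] - ref_vals[sl, None]) / denom[sl, None]
            ) ** 2
            best[sl] = np.sqrt(g2.min(axis=1))
        return best

    # windowed search around each reference point
    base_f = (ref_pos - fine_origin) / fine_step
    base = np.floor(base_f).astype(int)
    w = np.ceil(radius / fine_step).astype(int) + 1
    offsets = np.array(list(product(*[range(-wi, wi + 1) for wi in w])))
    # visit near offsets first so the early-exit bound engages quickly
    off_norm = np.linalg.norm(offsets * fine_step, axis=1)
    order = np.argsort(off_norm)
    offsets, off_norm = offsets[order], off_norm[order]
    snap = float(np.linalg.norm(fine_step))  # max snap error of base index
    all_finite = False
    for o, on in zip(offsets, off_norm):
        lower = max(on - snap, 0.0) / criteria.dta_mm
        if not all_finite:
            all_finite = bool(np.all(np.isfinite(best)))
        if all_finite and lower >= best.max():
            break
        idx = base + o
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        if not np.any(ok):
            continue
        ii = idx[ok]
        de = eval_fine[tuple(ii.T)]
        pos_e = fine_origin + ii * fine_step
        d2 = np.sum((pos_e - ref_pos[ok]) ** 2, axis=-1)
        g2 = d2 / dta2 + ((de - ref_vals[ok]) / denom[ok]) ** 2
        best[ok] = np.minimum(best[ok], np.sqrt(g2))
    return best


def gamma_map(
    reference,
    evaluated,
    criteria: GammaCriteria | None = None,
    include_mask: np.ndarray | None = None,
    exclude_mask: np.ndarray | None = None,
) -> GammaResult:
    """γ of ``evaluated`` against ``reference`` at each reference point.

    Both maps must live in the same physical frame (after registration).
    Reference points below the dose cut-off or outside the masks are not
    evaluated (γ = NaN there).
    """
    criteria = criteria or GammaCriteria()
    ref_vals, ref_sp, ref_o = _as_map(reference)
    ev_vals, ev_sp, ev_o = _as_map(evaluated)
    if ref_vals.ndim != ev_vals.ndim:
        raise ValueError("reference and evaluated maps have mismatched frames")
    ref_hi = ref_o + (np.asarray(ref_vals.shape) - 1) * ref_sp
    ev_hi = ev_o + (np.asarray(ev_vals.shape) - 1) * ev_sp
    if np.any(ref_hi < ev_o) or np.any(ev_hi < ref_o):
        raise ValueError("reference and evaluated maps do not overlap")

    mask = ref_vals >= criteria.cutoff_gy
    if include_mask is not None:
        mask &= include_mask
    if exclude_mask is not None:
        mask &= ~exclude_mask
    if not np.any(mask):
        raise ValueError("empty evaluation set: no reference points above cut-off")

    fine, fine_step = resample_map(ev_vals, ev_sp, criteria.resample_step_mm)

    idx = np.argwhere(mask)
    ref_pos = ref_o + idx * ref_sp
    vals = ref_vals[mask]
    g = _gamma_core(vals, ref_pos, fine, ev_o, fine_step, criteria)

    gamma = np.full(ref_vals.shape, np.nan)
    gamma[mask] = g
    rate = 100.0 * float(np.mean(g <= 1.0))
    return GammaResult(gamma=gamma, mask=mask, criteria=criteria, passing_rate=rate)


def passing_rate(
    result: GammaResult,
    include_mask: np.ndarray | None = None,
    exclude_mask: np.ndarray | None = None,
) -> float:
    """Passing rate (%) over the evaluated points, optionally re-masked."""
    sel = result.mask.copy()
    if include_mask is not None:
        sel &= include_mask
    if exclude_mask is not None:
        sel &= ~exclude_mask
    g = result.gamma[sel]
    g = g[np.isfinite(g)]
    if g.size == 0:
        raise ValueError("empty evaluation set after masking")
    return 100.0 * float(np.mean(g <= 1.0))


def gamma_profile_1d(
    ref_profile,
    eval_profile,
    criteria: GammaCriteria | None = None,
    spacing: float = 1.0,
) -> np.ndarray:
    """1D specialisation: per-point γ of two dose profiles."""
    res = gamma_map(
        (np.asarray(ref_profile, float), spacing),
        (np.asarray(eval_profile, float), spacing),
        criteria,
    )
    return res.gamma
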