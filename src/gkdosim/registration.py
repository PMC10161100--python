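"""Fiducial-based rigid registration between film and 3D grids.

Three metal pins hold the film inside the phantom and lance through it,
so each pin appears as a bright blob in CT and as a zero-dose hole in
the scanned film.  Matching the pin mass-centroids (CT) with the hole
geometric centroids (film) yields a closed-form least-squares rigid
transform (Kabsch/Procrustes with a reflection guard), used to resample
the 3D planning dose onto the film raster.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import VoxelGrid
from .phantom import FilmImage, FilmPlane
from .transforms import RigidTransform


def _canonical_order(points: np.ndarray, plane_axes=None) -> np.ndarray:
    """Order 3 points by angle about their centroid (canonical pairing rule).

    For 3D points the angles are measured in the best plane through them;
    correspondence between two point sets ordered this way is consistent
    whenever both views see the same triangle (up to rotation the angular
    *order* is cyclic, so the starting point is fixed by the largest
    distance from the centroid).
    """
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    d = pts - c
    if pts.shape[1] == 2:
        u = np.array([1.0, 0.0])
        v = np.array([0.0, 1.0])
        x, y = d @ u, d @ v
    else:
        # in-plane basis from the triangle itself
        n = np.cross(d[1] - d[0], d[2] - d[0])
        n = n / np.linalg.norm(n)
        u = d[0] / np.linalg.norm(d[0])
        v = np.cross(n, u)
        x, y = d @ u, d @ v
    ang = np.arctan2(y, x)
    start = int(np.argmax(np.hypot(x, y)))
    order = np.argsort((ang - ang[start]) % (2 * np.pi))
    return pts[order]


def detect_pin_centroids_ct(ct: VoxelGrid, threshold: float = 2000.0) -> np.ndarray:
    """Intensity-weighted centroids (mm) of the 3 metal pins in a CT grid.

    Voxels above ``threshold`` HU are segmented into connected components;
    exactly three must be found.  Centroids are weighted by HU above the
    threshold and returned in canonical order.
    """
    mask = ct.data > threshold
    lab, n = ndimage.label(mask)
    if n != 3:
        raise ValueError(f"expected 3 metal-pin components above threshold, found {n}")
    weights = np.where(mask, ct.data - threshold, 0.0)
    cms = ndimage.center_of_mass(weights, lab, index=range(1, 4))
    pts = ct.index_to_world(np.asarray(cms))
    return _canonical_order(pts)


def detect_hole_centroids_film(film: FilmImage, eps: float = 1e-12) -> np.ndarray:
    """Geometric centroids (film-frame mm) of the 3 zero-dose pin holes."""
    mask = film.data <= eps
    lab, n = ndimage.label(mask)
    if n != 3:
        raise ValueError(f"expected 3 film holes, found {n}")
    cms = np.asarray(ndimage.center_of_mass(mask, lab, index=range(1, 4)))
    uv = cms * film.pitch
    return _canonical_order(uv)


def fit_rigid(fixed: np.ndarray, moving: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform T with T(moving) ≈ fixed.

    Closed-form Kabsch/Procrustes solution on the centered point sets;
    no scaling or shear, and reflections are rejected: if a mirrored
    matching fits the correspondences but no proper rotation does, a
    ``ValueError`` is raised rather than silently flipping.
    Points must be non-collinear.
    """
    fx = np.asarray(fixed, dtype=float)
    mv = np.asarray(moving, dtype=float)
    if fx.shape != mv.shape or fx.shape[1] != 3:
        raise ValueError("fixed and moving must both be (n, 3) point arrays")
    scale = max(np.ptp(fx), np.ptp(mv), 1.0)
    area = 0.5 * np.linalg.norm(np.cross(fx[1] - fx[0], fx[2] - fx[0])) if len(fx) == 3 else np.inf
    if len(fx) == 3 and area < 1e-9 * scale**2:
        raise ValueError("fiducial points are collinear; rigid fit is degenerate")
    cf, cm = fx.mean(axis=0), mv.mean(axis=0)
    h = (mv - cm).T @ (fx - cf)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cf - rot @ cm
    fit = RigidTransform(rot, t)
    rms = float(np.sqrt(np.mean(np.sum((fit.apply(mv) - fx) ** 2, axis=1))))
    if d < 0:
        # the best orthogonal map was a reflection; accept the constrained
        # proper rotation only if it still fits, otherwise refuse
        refl = vt.T @ u.T  # unconstrained fit (a reflection when d < 0)
        rms_refl = float(
            np.sqrt(np.mean(np.sum(((mv - cm) @ refl.T + cf - fx) ** 2, axis=1)))
        )
        if rms_refl < 1e-9 * scale and rms > 1e-9 * scale:
            raise ValueError(
                "point sets are mirror images; no proper rotation matches"
            )
    return fit


def fit_rigid_correspondence(
    fixed: np.ndarray, moving: np.ndarray
) -> tuple[RigidTransform, float]:
    """Rigid fit over all candidate point pairings; lowest RMS wins.

    With only three fiducials the pairing is not given a priori; all 6
    permutations of the moving points are tried (mirrored pairings raise
    inside :func:`fit_rigid` and are skipped) and the proper-rotation fit
    with the smallest RMS residual is returned together with that RMS.
    """
    from itertools import permutations

    best: tuple[RigidTransform, float] | None = None
    for perm in permutations(range(len(moving))):
        try:
            t = fit_rigid(fixed, moving[list(perm)])
        except ValueError:
            continue
        rms = float(
            np.sqrt(np.mean(np.sum((t.apply(moving[list(perm)]) - fixed) ** 2, axis=1)))
        )
        if best is None or rms < best[1]:
            best = (t, rms)
    if best is None:
        raise ValueError("no proper rigid transform fits any point pairing")
    return best


def register_film_to_ct(
    film: FilmImage, ct: VoxelGrid, threshold: float = 2000.0
) -> RigidTransform:
    """Transform mapping stereotactic (CT) space onto the film-frame plane.

    Film hole centroids (embedded at w = 0 in the film frame) are the
    fixed points; CT pin centroids are the moving points.  The pin ↔ hole
    pairing is resolved by the lowest-RMS fit over all permutations.
    """
    holes_uv = detect_hole_centroids_film(film)
    holes3d = np.column_stack([holes_uv, np.zeros(len(holes_uv))])
    pins = detect_pin_centroids_ct(ct, threshold)
    t, _ = fit_rigid_correspondence(fixed=holes3d, moving=pins)
    return t


def resample_dose_to_film(
    dose, transform: RigidTransform, plane: FilmPlane | None = None,
    pitch: float | None = None, shape: tuple[int, int] | None = None,
) -> FilmImage:
    """Trilinearly resample a 3D dose grid onto a film raster.

    ``transform`` maps stereotactic space to the film frame (as returned
    by :func:`register_film_to_ct`); pixel (i, j) of the output sits at
    film-frame (i·pitch, j·pitch, 0) and samples the dose at the
    inverse-transformed stereotactic position.
    """
    grid = dose.grid if hasattr(dose, "grid") else dose
    medium = getattr(dose, "medium", "dose_to_water")
    plane = plane or FilmPlane()
    pitch = pitch or plane.pitch
    shape = shape or plane.shape
    i = np.arange(shape[0])[:, None] * pitch
    j = np.arange(shape[1])[None, :] * pitch
    uvw = np.stack(
        [np.broadcast_to(i, shape), np.broadcast_to(j, shape), np.zeros(shape)],
        axis=-1,
    ).reshape(-1, 3)
    pts = transform.inverse().apply(uvw)
    if not np.any(grid.contains(pts)):
        raise ValueError("transformed film raster lies fully outside the dose grid")
    vals = grid.sample(pts).reshape(shape)
    return FilmImage(data=vals, pitch=pitch, plane=plane, medium=medium)
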