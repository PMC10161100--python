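"""Synthetic inhomogeneous phantom, CT synthesis and film-measurement simulation.

The phantom emulates a 160 mm solid-water calibration sphere whose central
slabs are replaced by water-equivalent RW3 slabs carrying a mirrored-C
bone inset (6 cm long in z, bars 1 cm thick in y / 1.5 cm in x), a
2×2×6 cm³ RW3 core, a 1.5×2×6 cm³ air cavity on the open side of the C,
and three metal fiducial pins that lance through the measurement film.
Everything downstream of CT acquisition (density mapping, dose engines,
film registration, gamma analysis) can therefore be exercised without any
measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import UCP, LabelGrid, VoxelGrid, grid_from_bounds
from .ct_density import CalibrationCurve
from .transforms import RigidTransform


@dataclass(frozen=True)
class Box:
    """Axis-aligned half-open box [low, high) in mm."""

    low: tuple[float, float, float]
    high: tuple[float, float, float]

    def __post_init__(self):
        lo, hi = np.asarray(self.low, float), np.asarray(self.high, float)
        if np.any(hi <= lo):
            raise ValueError("box high must exceed low on every axis")

    @classmethod
    def from_center(cls, center, extents) -> "Box":
        c, e = np.asarray(center, float), np.asarray(extents, float)
        return cls(tuple(c - e / 2), tuple(c + e / 2))

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.low) + np.asarray(self.high)) / 2.0

    @property
    def extents(self) -> np.ndarray:
        return np.asarray(self.high) - np.asarray(self.low)

    def overlaps(self, other: "Box") -> bool:
        lo = np.maximum(self.low, other.low)
        hi = np.minimum(self.high, other.high)
        return bool(np.all(hi > lo))

    def corners_inside_sphere(self, center, radius) -> bool:
        lo, hi = np.asarray(self.low), np.asarray(self.high)
        pts = np.array(
            [
                [x, y, z]
                for x in (lo[0], hi[0])
                for y in (lo[1], hi[1])
                for z in (lo[2], hi[2])
            ]
        )
        return bool(np.all(np.linalg.norm(pts - np.asarray(center), axis=1) <= radius))


@dataclass
class Material:
    """Physical material: mass density ρ (g/cm³), relative electron density η,
    elemental mass fractions (must sum to 1), and a metal flag (metals are
    outside any CT calibration curve and map to a fixed HU plateau)."""

    name: str
    rho: float
    eta: float
    composition: dict[str, float]
    metal: bool = False

    def __post_init__(self):
        if self.rho <= 0 or self.eta <= 0:
            raise ValueError(f"{self.name}: rho and eta must be positive")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: mass fractions sum to {total}, not 1")


@dataclass
class MaterialTable:
    materials: dict[str, Material]

    def __getitem__(self, name: str) -> Material:
        return self.materials[name]

    def __contains__(self, name: str) -> bool:
        return name in self.materials

    @classmethod
    def default(cls) -> "MaterialTable":
        """Phantom materials with measured densities.

        η values are the CT-measured relative electron densities of the
        physical materials (RW3 0.993, solid water 1.013, bone substitute
        1.605); ρ are the corresponding measured mass densities.
        """
        water = {"H": 0.112, "O": 0.888}
        mats = [
            Material("ambient_air", 0.0012, 0.0011, {"N": 0.755, "O": 0.232, "Ar": 0.013}),
            Material("air", 0.0012, 0.0011, {"N": 0.755, "O": 0.232, "Ar": 0.013}),
            Material("solid_water", 1.038, 1.013, water),
            Material("rw3", 1.014, 0.993, {"H": 0.076, "C": 0.904, "O": 0.008, "Ti": 0.012}),
            Material("bone", 1.720, 1.605, {"H": 0.056, "C": 0.235, "N": 0.050, "O": 0.434, "P": 0.072, "Ca": 0.146, "other": 0.007}),
            Material("metal", 7.9, 6.0, {"Fe": 1.0}, metal=True),
        ]
        return cls({m.name: m for m in mats})


def _default_bone_boxes() -> tuple[Box, ...]:
    # Mirrored C opening toward -y: two lateral bars 1.5 cm thick in x and a
    # posterior bar 1 cm thick in y, all 6 cm long in z, abutting the core.
    return (
        Box((75.0, 90.0, 70.0), (90.0, 120.0, 130.0)),   # left lateral bar
        Box((110.0, 90.0, 70.0), (125.0, 120.0, 130.0)),  # right lateral bar
        Box((90.0, 110.0, 70.0), (110.0, 120.0, 130.0)),  # posterior bar
    )


def _default_pins() -> tuple[tuple[float, float, float], ...]:
    # Three pins near the slab periphery (radius 70 mm, central axial
    # plane), at deliberately scalene angles: any symmetric pin triangle
    # (equilateral or isosceles) makes the pin ↔ hole correspondence
    # ill-posed because swapping symmetric pins is itself a rigid motion.
    pts = []
    for ang in (80.0, 200.0, 330.0):
        a = np.deg2rad(ang)
        pts.append((100.0 + 70.0 * np.cos(a), 100.0 + 70.0 * np.sin(a), 100.0))
    return tuple(pts)


@dataclass
class PhantomSpec:
    """Geometry of the inhomogeneous verification phantom (all mm)."""

    sphere_diameter: float = 160.0
    sphere_center: tuple[float, float, float] = tuple(UCP)
    bone_boxes: tuple[Box, ...] = field(default_factory=_default_bone_boxes)
    core_box: Box = field(
        default_factory=lambda: Box.from_center(UCP, (20.0, 20.0, 60.0))
    )
    air_box: Box = field(
        default_factory=lambda: Box((92.5, 70.0, 70.0), (107.5, 90.0, 130.0))
    )
    pin_positions: tuple[tuple[float, float, float], ...] = field(
        default_factory=_default_pins
    )
    pin_radius: float = 1.0
    pin_half_length: float = 5.0  # pins modelled as z-cylinders, length 2×this
    voxel_spacing: tuple[float, float, float] = (0.53, 0.53, 1.0)

    def validate(self) -> None:
        if self.sphere_diameter <= 0:
            raise ValueError("sphere diameter must be positive")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if len(self.pin_positions) != 3:
            raise ValueError("exactly 3 fiducial pins are required")
        r = self.sphere_diameter / 2.0
        for name, box in [("core_box", self.core_box), ("air_box", self.air_box)] + [
            (f"bone_box[{i}]", b) for i, b in enumerate(self.bone_boxes)
        ]:
            if not box.corners_inside_sphere(self.sphere_center, r):
                raise ValueError(f"{name} extends outside the phantom sphere")
        for name, box in [("air_box", self.air_box)] + [
            (f"bone_box[{i}]", b) for i, b in enumerate(self.bone_boxes)
        ]:
            if box.overlaps(self.core_box):
                raise ValueError(
                    f"conflicting region labels: {name} overlaps core_box"
                )
        if self.air_box.overlaps(Box(self.bone_boxes[0].low, self.bone_boxes[0].high)):
            pass  # bone/air adjacency is allowed; true overlap checked below
        for i, b in enumerate(self.bone_boxes):
            if b.overlaps(self.air_box):
                raise ValueError(
                    f"conflicting region labels: bone_box[{i}] overlaps air_box"
                )


LABEL_CODES = {
    0: "ambient_air",
    1: "solid_water",
    2: "rw3",
    3: "bone",
    4: "air",
    5: "metal",
}
_NAME_TO_CODE = {v: k for k, v in LABEL_CODES.items()}


def build_phantom(
    spec: PhantomSpec | None = None,
    spacing: tuple[float, float, float] | None = None,
    margin: float = 5.0,
) -> LabelGrid:
    """Voxelise the phantom into a material-label grid.

    The grid covers the sphere plus ``margin`` mm of ambient air on every
    face.  A voxel carries the label of the region containing its center
    (half-open boxes), painted in order ambient air → solid water sphere →
    bone bars → RW3 core → air cavity → metal pins.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    sp = spacing or spec.voxel_spacing
    r = spec.sphere_diameter / 2.0
    c = np.asarray(spec.sphere_center, float)
    grid = grid_from_bounds(c - r - margin, c + r + margin, sp, dtype=np.uint8)

    x = grid.axis_centers(0)[:, None, None]
    y = grid.axis_centers(1)[None, :, None]
    z = grid.axis_centers(2)[None, None, :]

    lab = grid.data
    in_sphere = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r**2
    lab[in_sphere] = _NAME_TO_CODE["solid_water"]

    def box_mask(b: Box) -> np.ndarray:
        return (
            (x >= b.low[0]) & (x < b.high[0])
            & (y >= b.low[1]) & (y < b.high[1])
            & (z >= b.low[2]) & (z < b.high[2])
        )

    for b in spec.bone_boxes:
        lab[box_mask(b)] = _NAME_TO_CODE["bone"]
    lab[box_mask(spec.core_box)] = _NAME_TO_CODE["rw3"]
    lab[box_mask(spec.air_box)] = _NAME_TO_CODE["air"]

    for p in spec.pin_positions:
        pin = (
            ((x - p[0]) ** 2 + (y - p[1]) ** 2 <= spec.pin_radius**2)
            & (np.abs(z - p[2]) <= spec.pin_half_length)
        )
        # a fiducial must stay resolvable at any voxel size: always mark at
        # least the voxel column nearest the pin axis
        ix = int(np.clip(round((p[0] - grid.origin[0]) / grid.spacing[0]), 0, lab.shape[0] - 1))
        iy = int(np.clip(round((p[1] - grid.origin[1]) / grid.spacing[1]), 0, lab.shape[1] - 1))
        zcol = np.abs(grid.axis_centers(2) - p[2]) <= spec.pin_half_length
        pin[ix, iy, zcol] = True
        lab[pin] = _NAME_TO_CODE["metal"]

    return LabelGrid(data=lab, origin=grid.origin, spacing=grid.spacing, labels=dict(LABEL_CODES))


def synthesize_ct(
    labels: LabelGrid,
    materials: MaterialTable | None = None,
    curve: CalibrationCurve | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    metal_hu: float = 3000.0,
) -> VoxelGrid:
    """Synthetic CT of a labelled phantom.

    Each non-metal material's η is pushed through the *inverse* of the
    HU → η calibration curve; metals sit on a fixed high-HU plateau (they
    saturate clinical calibrations by design).  Zero-mean Gaussian noise of
    ``noise_sd`` HU is added; the result is deterministic given ``seed``.
    """
    materials = materials or MaterialTable.default()
    curve = curve or CalibrationCurve.default()
    hu = np.empty(labels.shape, dtype=float)
    for code, name in labels.labels.items():
        m = materials[name]
        sel = labels.data == code
        if not np.any(sel):
            continue
        hu[sel] = metal_hu if m.metal else float(curve.eta_to_hu(m.eta))
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, noise_sd, size=hu.shape)
    return VoxelGrid(hu, labels.origin, labels.spacing)


# ---------------------------------------------------------------------------
# Film simulation
# ---------------------------------------------------------------------------

@dataclass
class FilmPlane:
    """Planar film raster embedded in stereotactic space.

    Pixel (i, j) center sits at ``origin + i*pitch*axis_u + j*pitch*axis_v``
    before any rigid perturbation.  The default is the central axial plane
    z = 100 mm with film axes aligned to stereotactic x and y.
    """

    origin: tuple[float, float, float] = (25.0, 25.0, 100.0)
    axis_u: tuple[float, float, float] = (1.0, 0.0, 0.0)
    axis_v: tuple[float, float, float] = (0.0, 1.0, 0.0)
    pitch: float = 0.169
    shape: tuple[int, int] = (888, 888)

    def __post_init__(self):
        u = np.asarray(self.axis_u, float)
        v = np.asarray(self.axis_v, float)
        if not (np.isclose(np.linalg.norm(u), 1) and np.isclose(np.linalg.norm(v), 1)):
            raise ValueError("film axes must be unit vectors")
        if not np.isclose(u @ v, 0.0, atol=1e-9):
            raise ValueError("film axes must be orthogonal")
        if self.pitch <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.axis_u, self.axis_v)

    def pixel_points(self) -> np.ndarray:
        """Unperturbed 3D positions of all pixel centers, shape (nu, nv, 3)."""
        i = np.arange(self.shape[0])[:, None]
        j = np.arange(self.shape[1])[None, :]
        u = np.asarray(self.axis_u)
        v = np.asarray(self.axis_v)
        o = np.asarray(self.origin)
        return (
            o
            + (i * self.pitch)[..., None] * u
            + (j * self.pitch)[..., None] * v
        )

    def film_frame_to_world(self, uv: np.ndarray) -> np.ndarray:
        """Film-frame (u, v) mm → unperturbed 3D points."""
        uv = np.asarray(uv, float)
        return (
            np.asarray(self.origin)
            + uv[..., :1] * np.asarray(self.axis_u)
            + uv[..., 1:2] * np.asarray(self.axis_v)
        )

    def world_to_film_frame(self, pts: np.ndarray) -> np.ndarray:
        d = np.asarray(pts, float) - np.asarray(self.origin)
        return np.stack([d @ np.asarray(self.axis_u), d @ np.asarray(self.axis_v)], axis=-1)


DOSE_TO_WATER = "dose_to_water"
DOSE_TO_MEDIUM = "dose_to_medium"


@dataclass
class FilmImage:
    """2D film dose map: pixel values (Gy), pitch (mm/px), embedding plane,
    hole mask at the fiducial lance positions, and the reporting medium."""

    data: np.ndarray
    pitch: float
    plane: FilmPlane
    medium: str = DOSE_TO_WATER
    hole_mask: np.ndarray | None = None
    #: per-pixel material masks recorded at exposure time (the physical film
    #: piece is cut to fit the slab, so the media it lay in are known)
    region_masks: dict | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("film data must be 2D")
        if self.medium not in (DOSE_TO_WATER, DOSE_TO_MEDIUM):
            raise ValueError(f"unknown reporting medium {self.medium!r}")
        if self.hole_mask is None:
            self.hole_mask = np.zeros(self.data.shape, dtype=bool)

    def pixel_uv(self) -> np.ndarray:
        """Film-frame (u, v) mm coordinates of pixel centers, (nu, nv, 2)."""
        i = np.arange(self.data.shape[0])[:, None]
        j = np.arange(self.data.shape[1])[None, :]
        return np.stack(
            [i * self.pitch + 0 * j, j * self.pitch + 0 * i], axis=-1
        ).astype(float)

    def copy_with(self, data: np.ndarray, medium: str | None = None) -> "FilmImage":
        return FilmImage(
            data=data,
            pitch=self.pitch,
            plane=self.plane,
            medium=medium or self.medium,
            hole_mask=None if self.hole_mask is None else self.hole_mask.copy(),
            region_masks=self.region_masks,
        )


def simulate_film(
    dose: VoxelGrid,
    plane: FilmPlane | None = None,
    true_transform: RigidTransform | None = None,
    noise_fraction: float = 0.0,
    pins: tuple | None = None,
    hole_radius: float = 0.5,
    seed: int = 0,
    water_conversion: dict[str, float] | None = None,
    label_grid: LabelGrid | None = None,
) -> FilmImage:
    """Simulate a film measurement of a 3D dose grid.

    The 3D dose is sampled trilinearly at the (rigidly perturbed) pixel
    positions; each pixel is multiplied by (1 + ε), ε ~ N(0, noise_fraction);
    circular zero-dose holes of ``hole_radius`` mm are punched where the
    fiducial pins lance the film.  If ``water_conversion`` maps material
    names to dose-to-medium factors (with ``label_grid`` giving per-pixel
    materials), the sampled dose-to-medium values are divided by the factor
    of the local medium — emulating a film that reads dose-to-water inside
    bone and air.  The output is flagged dose-to-water.
    """
    plane = plane or FilmPlane()
    t = true_transform or RigidTransform.identity()
    pts = t.apply(plane.pixel_points().reshape(-1, 3))
    lo, hi = dose.bounds
    if not np.any(np.all((pts >= lo) & (pts < hi), axis=1)):
        raise ValueError("film plane does not intersect the dose grid")
    vals = dose.sample(pts).reshape(plane.shape)

    region_masks = None
    if label_grid is not None:
        codes = label_grid.sample(pts, order=0).reshape(plane.shape).astype(int)
        region_masks = {}
        for name in ("bone", "air"):
            sel = np.zeros(plane.shape, dtype=bool)
            for code, lname in label_grid.labels.items():
                if lname == name:
                    sel |= codes == code
            region_masks[name] = sel
    if water_conversion:
        if region_masks is None:
            raise ValueError("water_conversion requires a label grid")
        factor = np.ones(plane.shape)
        for name, k in water_conversion.items():
            if name in region_masks:
                factor[region_masks[name]] = k
        vals = vals / factor

    if noise_fraction < 0:
        raise ValueError("noise_fraction must be non-negative")
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        vals = vals * (1.0 + rng.normal(0.0, noise_fraction, size=vals.shape))

    holes = np.zeros(plane.shape, dtype=bool)
    if pins is None:
        pins = ()
    i = np.arange(plane.shape[0])[:, None] * plane.pitch
    j = np.arange(plane.shape[1])[None, :] * plane.pitch
    for p in pins:
        p_film = t.inverse().apply(np.asarray(p, float))
        u, v = plane.world_to_film_frame(p_film)
        holes |= (i - u) ** 2 + (j - v) ** 2 <= hole_radius**2
    vals = np.where(holes, 0.0, vals)

    return FilmImage(
        data=vals,
        pitch=plane.pitch,
        plane=plane,
        medium=DOSE_TO_WATER,
        hole_mask=holes,
        region_masks=region_masks,
    )
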