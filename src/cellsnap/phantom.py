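"""Synthetic RI tomogram phantoms with exact ground truth.

Scenes emulate the failure modes the refinement pipeline must survive:
isolated adherent cells, clumped cells sharing an x-y boundary, debris
specks, interferometric fringe artifacts, and dish-floor roughness in the
lowest z slices.

Cells are uniform-RI ellipsoids, optionally truncated at a base plane to
model adherent morphology (a cell spread on the dish has its largest
cross-section at the bottom, which is what makes a half-maximum z-floor
rule meaningful).  Uniform bodies give closed-form volume and dry-mass
oracles:

    V(f)      = pi*a*b*c * (2/3 - f + f^3/3)   for base fraction f in [-1, 1]
    dry mass  = delta_n * V / alpha

where f = -1 is the full ellipsoid (V = 4/3 pi a b c) and f = 0 a half-
ellipsoid dome.

Fringe artifacts are modeled as a sinusoid over (x, y), axially confined
to a band of low z slices with a slight negative DC shift — tomographic
fringe artifacts concentrate near the substrate reflection plane and
appear as shadow-like modulation, not as full-height bright prisms.
Ground-truth labels mark cell bodies only, never debris, fringe or
roughness voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .config import DEFAULT_MEDIUM_RI, DEFAULT_RI_SCALE, VoxelGeometry
from .errors import CellSnapError
from .io import RITomogram


@dataclass(frozen=True)
class CellBody:
    """One uniform-RI ellipsoidal cell.

    Parameters
    ----------
    center : (z, y, x) in um.
    semi_axes : (az, ay, ax) in um (axis lengths along z, y, x before rotation).
    delta_n : RI elevation above the medium.
    rotation_deg : in-plane rotation about the z axis, degrees.
    base_fraction : f in [-1, 1]; voxels with (z - zc)/az < f are cut away.
        -1 keeps the full ellipsoid, 0 keeps the upper half (adherent dome).
    smooth_sigma_um : optional Gaussian smoothing of the RI elevation
        (labels stay the hard body).
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    delta_n: float
    rotation_deg: float = 0.0
    base_fraction: float = -1.0
    smooth_sigma_um: float = 0.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise CellSnapError(f"semi-axes must be positive, got {self.semi_axes}")
        if self.delta_n <= 0:
            raise CellSnapError(f"cell delta_n must be positive, got {self.delta_n}")
        if not (-1.0 <= self.base_fraction <= 1.0):
            raise CellSnapError(f"base_fraction must lie in [-1, 1], got {self.base_fraction}")

    @property
    def analytic_volume(self) -> float:
        """Closed-form body volume in um^3."""
        az, ay, ax = self.semi_axes
        f = self.base_fraction
        return float(np.pi * ax * ay * az * (2.0 / 3.0 - f + f**3 / 3.0))


@dataclass(frozen=True)
class DebrisSpec:
    count: int = 0
    radius_range_um: tuple[float, float] = (0.2, 0.4)
    delta_n: float = 0.03
    clearance_um: float = 0.3  # minimum gap between speck and any cell surface


@dataclass(frozen=True)
class FringeSpec:
    amplitude: float = 0.0  # RI units
    period_um: float = 2.0
    orientation_deg: float = 0.0
    z_range: tuple[int, int] | None = None  # slice band [lo, hi); None = all slices
    dc_fraction: float = -0.3  # DC shift as a fraction of the amplitude


@dataclass(frozen=True)
class FloorRoughnessSpec:
    n_slices: int = 0
    fill_fraction: float = 0.15
    delta_n: float = 0.02


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic scene."""

    shape: tuple[int, int, int]  # (nz, ny, nx)
    geometry: VoxelGeometry
    medium_ri: float = DEFAULT_MEDIUM_RI
    ri_scale: int = DEFAULT_RI_SCALE
    cells: tuple[CellBody, ...] = ()
    debris: DebrisSpec = field(default_factory=DebrisSpec)
    fringe: FringeSpec = field(default_factory=FringeSpec)
    floor_roughness: FloorRoughnessSpec = field(default_factory=FloorRoughnessSpec)
    seed: int = 0
    overlap_tol_voxels: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        return d


@dataclass(frozen=True)
class CellTruth:
    """Exact per-cell ground truth."""

    label: int
    voxel_count: int
    volume_voxelized: float  # um^3
    volume_analytic: float  # um^3
    dry_mass_voxelized: float  # pg, delta_n * V_vox / alpha
    dry_mass_analytic: float  # pg, delta_n * V_analytic / alpha
    delta_n: float


@dataclass(frozen=True)
class GroundTruth:
    """Label volume plus closed-form per-cell oracles for one phantom."""

    labels: np.ndarray  # (nz, ny, nx) int32, 0 background, k = cell k
    cells: tuple[CellTruth, ...]
    seed: int

    def footprint_labels(self) -> np.ndarray:
        """2D seed labels from the ground truth: per-column cell id (cells
        are disjoint in x-y for valid phantoms)."""
        return self.labels.max(axis=0).astype(np.int32)


def _coordinate_grids(shape, geometry):
    # voxel centers at (k + 1/2) * pitch: a body face that falls on a voxel
    # boundary is then sampled midpoint-accurately instead of over-counting
    # half a slab
    nz, ny, nx = shape
    z = (np.arange(nz) + 0.5) * geometry.dz
    y = (np.arange(ny) + 0.5) * geometry.dy
    x = (np.arange(nx) + 0.5) * geometry.dx
    return np.meshgrid(z, y, x, indexing="ij", sparse=True)


def _cell_interior(cell: CellBody, zz, yy, xx) -> np.ndarray:
    cz, cy, cx = cell.center
    az, ay, ax = cell.semi_axes
    dzc, dyc, dxc = zz - cz, yy - cy, xx - cx
    th = np.deg2rad(cell.rotation_deg)
    # rotate lab coords into the body frame (rotation about z only, so the
    # base-plane cut in lab z stays exact)
    u = np.cos(th) * dxc + np.sin(th) * dyc
    v = -np.sin(th) * dxc + np.cos(th) * dyc
    inside = (dzc / az) ** 2 + (v / ay) ** 2 + (u / ax) ** 2 <= 1.0
    if cell.base_fraction > -1.0:
        inside = inside & (dzc >= cell.base_fraction * az)
    return inside


def generate(spec: PhantomSpec, alpha: float = 0.19) -> tuple[RITomogram, GroundTruth]:
    """Render a phantom scene and its exact ground truth.

    Deterministic for a fixed ``spec.seed``.  Raises if cell bodies
    overlap in more than ``spec.overlap_tol_voxels`` voxels (ground truth
    would be ambiguous).
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    geometry = spec.geometry
    zz, yy, xx = _coordinate_grids(spec.shape, geometry)
    ri = np.full(spec.shape, spec.medium_ri, dtype=np.float64)
    labels = np.zeros(spec.shape, dtype=np.int32)

    if spec.fringe.amplitude > 0:
        for cell in spec.cells:
            if cell.delta_n <= spec.fringe.amplitude:
                warnings.warn(
                    f"cell delta_n {cell.delta_n} <= fringe amplitude "
                    f"{spec.fringe.amplitude}: scene not solvable by RI thresholding"
                )

    truths = []
    for k, cell in enumerate(spec.cells, start=1):
        inside = _cell_interior(cell, zz, yy, xx)
        clash = int(np.count_nonzero(inside & (labels > 0)))
        if clash > spec.overlap_tol_voxels:
            raise CellSnapError(
                f"cell {k} overlaps an earlier cell in {clash} voxels "
                f"(tolerance {spec.overlap_tol_voxels}); ground truth would be ambiguous"
            )
        inside = inside & (labels == 0)
        delta = np.where(inside, cell.delta_n, 0.0)
        if cell.smooth_sigma_um > 0:
            from scipy.ndimage import gaussian_filter

            sigma = (
                cell.smooth_sigma_um / geometry.dz,
                cell.smooth_sigma_um / geometry.dy,
                cell.smooth_sigma_um / geometry.dx,
            )
            delta = gaussian_filter(delta, sigma=sigma)
        ri += delta
        labels[inside] = k
        count = int(np.count_nonzero(inside))
        v_vox = count * geometry.voxel_volume
        v_ana = cell.analytic_volume
        truths.append(
            CellTruth(
                label=k,
                voxel_count=count,
                volume_voxelized=v_vox,
                volume_analytic=v_ana,
                dry_mass_voxelized=cell.delta_n * v_vox / alpha,
                dry_mass_analytic=cell.delta_n * v_ana / alpha,
                delta_n=cell.delta_n,
            )
        )

    if spec.debris.count > 0:
        _add_debris(ri, labels, spec, rng, zz, yy, xx)

    if spec.fringe.amplitude > 0:
        fr = spec.fringe
        th = np.deg2rad(fr.orientation_deg)
        phase = 2 * np.pi * (np.cos(th) * xx + np.sin(th) * yy) / fr.period_um
        band = np.zeros((nz, 1, 1))
        lo, hi = fr.z_range if fr.z_range is not None else (0, nz)
        band[lo:hi] = 1.0
        ri += band * fr.amplitude * (np.sin(phase) + fr.dc_fraction)

    fl = spec.floor_roughness
    if fl.n_slices > 0:
        rough = rng.random((fl.n_slices, ny, nx)) < fl.fill_fraction
        rough &= labels[: fl.n_slices] == 0
        ri[: fl.n_slices] += np.where(rough, fl.delta_n, 0.0)

    ri = np.maximum(ri, 1.0)  # physical floor; shadow-type artifacts cannot undercut vacuum
    tomo = RITomogram(
        values=ri, geometry=geometry, medium_ri=spec.medium_ri, ri_scale=spec.ri_scale
    )
    return tomo, GroundTruth(labels=labels, cells=tuple(truths), seed=spec.seed)


def _add_debris(ri, labels, spec, rng, zz, yy, xx) -> None:
    nz, ny, nx = spec.shape
    geometry = spec.geometry
    extent = (nz * geometry.dz, ny * geometry.dy, nx * geometry.dx)
    placed = 0
    attempts = 0
    while placed < spec.debris.count and attempts < spec.debris.count * 200:
        attempts += 1
        r = rng.uniform(*spec.debris.radius_range_um)
        c = rng.uniform((0.0, 0.0, 0.0), extent)
        # analytic clearance check against every (inflated) cell body
        clear = True
        for cell in spec.cells:
            cz, cy, cx = cell.center
            az, ay, ax = cell.semi_axes
            m = r + spec.debris.clearance_um
            d = (
                ((c[0] - cz) / (az + m)) ** 2
                + ((c[1] - cy) / (ay + m)) ** 2
                + ((c[2] - cx) / (ax + m)) ** 2
            )
            if d <= 1.0:
                clear = False
                break
        if not clear:
            continue
        speck = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= r**2
        speck &= labels == 0
        ri += np.where(speck, spec.debris.delta_n, 0.0)
        placed += 1
    if placed < spec.debris.count:
        warnings.warn(
            f"placed only {placed}/{spec.debris.count} debris specks within clearance limits"
        )


def standard_suite(
    shape: tuple[int, int, int] = (64, 128, 128),
    geometry: VoxelGeometry | None = None,
) -> dict[str, PhantomSpec]:
    """Named phantom presets exercising the pipeline's robustness claims.

    - ``isolated``: one adherent dome cell, clean background.
    - ``clumped_pair``: two domes whose x-y footprints share a boundary but
      whose bodies never overlap; separable given a correct 2-label seed.
    - ``fringe``: isolated cell plus a sinusoidal fringe band in the low
      slices (amplitude well under the cell contrast).
    - ``debris_field``: isolated cell plus 20 small high-RI specks kept
      clear of the cell surface.
    - ``rough_floor``: isolated cell plus speckled dish-floor roughness in
      the lowest slices, below the cell base.
    """
    if geometry is None:
        geometry = VoxelGeometry(dx=0.15, dy=0.15, dz=0.2)
    nz, ny, nx = shape
    cy = ny * geometry.dy / 2.0
    cx = nx * geometry.dx / 2.0
    base_z = 8 * geometry.dz  # cell base sits above the roughness-prone floor slices

    dome = CellBody(
        center=(base_z, cy, cx),
        semi_axes=(3.2, 5.0, 5.0),
        delta_n=0.04,
        base_fraction=0.0,
    )
    isolated = PhantomSpec(
        shape=shape, geometry=geometry, cells=(dome,), seed=101
    )
    pair_sep = 8.1  # um between centers; semi-axes 4.0 each -> 0.1 um gap
    clumped = PhantomSpec(
        shape=shape,
        geometry=geometry,
        cells=(
            CellBody(
                center=(base_z, cy, cx - pair_sep / 2),
                semi_axes=(3.0, 4.0, 4.0),
                delta_n=0.04,
                base_fraction=0.0,
            ),
            CellBody(
                center=(base_z, cy, cx + pair_sep / 2),
                semi_axes=(3.0, 4.0, 4.0),
                delta_n=0.042,
                base_fraction=0.0,
            ),
        ),
        seed=102,
    )
    fringe = PhantomSpec(
        shape=shape,
        geometry=geometry,
        cells=(dome,),
        fringe=FringeSpec(
            amplitude=0.005, period_um=2.0, orientation_deg=30.0, z_range=(1, 6)
        ),
        seed=103,
    )
    debris_field = PhantomSpec(
        shape=shape,
        geometry=geometry,
        cells=(dome,),
        debris=DebrisSpec(count=20, radius_range_um=(0.2, 0.4), delta_n=0.03),
        seed=104,
    )
    rough_floor = PhantomSpec(
        shape=shape,
        geometry=geometry,
        cells=(dome,),
        floor_roughness=FloorRoughnessSpec(n_slices=5, fill_fraction=0.15, delta_n=0.02),
        seed=105,
    )
    return {
        "isolated": isolated,
        "clumped_pair": clumped,
        "fringe": fringe,
        "debris_field": debris_field,
        "rough_floor": rough_floor,
    }
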