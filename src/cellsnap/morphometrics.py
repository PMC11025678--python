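"""Per-cell morphometry and segmentation-agreement metrics.

Dry mass follows the standard QPI relation

    OPD(x, y)  = sum_z mask * (n - n_medium) * dz          [um]
    dry mass   = (1 / alpha) * sum_xy OPD * dx * dy        [pg]

with alpha = 0.19 um^3/pg, the reciprocal of the specific refraction
increment of cellular dry matter.  Volume is the voxel count of the final
mask times the voxel volume.

The agreement metrics compare a predicted mask with a reference mask.
``pixel_accuracy`` is |pred AND truth| / |truth| — a recall: it cannot
penalize over-segmentation, so IoU and Dice are reported alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .config import VoxelGeometry
from .errors import EmptyTruthError, ShapeMismatchError
from .io import RITomogram
from .snap import CellMask3D


@dataclass(frozen=True)
class OPDMap:
    """Optical path difference per (y, x) pixel, in um, over one cell."""

    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class CellMeasurements:
    """Morphometry of one segmented cell."""

    cell_label: int
    voxel_count: int
    volume: float  # um^3
    dry_mass: float  # pg
    opd: OPDMap


@dataclass(frozen=True)
class AgreementReport:
    """Overlap metrics between a predicted and a reference 3D mask."""

    pixel_accuracy: float
    iou: float
    dice: float
    hausdorff_max: float  # um


def opd_map(tomo: RITomogram, mask: CellMask3D) -> OPDMap:
    """Integrate (RI - medium RI) over z through the mask, as a Riemann
    sum with slab thickness dz."""
    if mask.shape != tomo.shape:
        raise ShapeMismatchError(f"mask shape {mask.shape} != tomogram shape {tomo.shape}")
    delta = np.where(mask.mask, tomo.values - tomo.medium_ri, 0.0)
    return OPDMap(values=delta.sum(axis=0) * tomo.geometry.dz)


def dry_mass(opd: OPDMap, geometry: VoxelGeometry, alpha: float = 0.19) -> float:
    """Dry mass in pg: area integral of OPD divided by alpha (um^3/pg)."""
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return float(opd.values.sum() * geometry.pixel_area / alpha)


def cell_volume(mask: CellMask3D, geometry: VoxelGeometry) -> tuple[int, float]:
    """Voxel count of the mask and the corresponding volume in um^3."""
    count = mask.n_voxels
    return count, count * geometry.voxel_volume


def measure_cell(
    tomo: RITomogram,
    mask: CellMask3D,
    alpha: float = 0.19,
) -> CellMeasurements:
    """All morphometrics for one cell: OPD map, dry mass, volume."""
    opd = opd_map(tomo, mask)
    count, volume = cell_volume(mask, tomo.geometry)
    return CellMeasurements(
        cell_label=mask.cell_label,
        voxel_count=count,
        volume=volume,
        dry_mass=dry_mass(opd, tomo.geometry, alpha),
        opd=opd,
    )


def _voxel_coords_um(mask: np.ndarray, geometry: VoxelGeometry) -> np.ndarray:
    z, y, x = np.nonzero(mask)
    return np.column_stack(
        (z * geometry.dz, y * geometry.dy, x * geometry.dx)
    ).astype(np.float64)


def agreement(
    pred: CellMask3D,
    truth: CellMask3D,
    geometry: VoxelGeometry,
) -> AgreementReport:
    """Overlap metrics between predicted and reference masks.

    ``pixel_accuracy`` uses the reference-mask size as denominator.
    ``hausdorff_max`` is the symmetric (max over both directions)
    Hausdorff distance between voxel centers, in physical um.  IoU, Dice
    and Hausdorff are symmetric in their arguments; pixel accuracy is not.
    """
    if pred.shape != truth.shape:
        raise ShapeMismatchError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    p = pred.mask.astype(bool)
    t = truth.mask.astype(bool)
    n_truth = int(t.sum())
    if n_truth == 0:
        raise EmptyTruthError("pixel accuracy is undefined for an empty reference mask")
    n_pred = int(p.sum())
    inter = int((p & t).sum())
    union = int((p | t).sum())
    iou = inter / union if union else 1.0
    dice = 2 * inter / (n_pred + n_truth)
    if n_pred == 0:
        hausdorff = float("inf")
    elif inter == n_pred == n_truth:
        hausdorff = 0.0
    else:
        a = _voxel_coords_um(p, geometry)
        b = _voxel_coords_um(t, geometry)
        hausdorff = max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])
    return AgreementReport(
        pixel_accuracy=inter / n_truth,
        iou=iou,
        dice=dice,
        hausdorff_max=float(hausdorff),
    )
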