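"""Core 3D refinement: extrusion, rough segmentation, z-floor, connectivity cleanup.

Per cell, the chain is

    2D seed label -> extrude over z -> mask the tomogram, keep RI strictly
    above the medium -> zero slices below the z-floor (dish roughness) ->
    keep the largest 2D component per slice (debris) -> keep the largest
    3D component (disconnected noise)

and each cell is processed independently of the others, so processing
order does not matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .config import RunConfig
from .errors import EmptyCellError, ShapeMismatchError
from .io import LabelImage2D, RITomogram

_STRUCTURE_2D = {4: ndi.generate_binary_structure(2, 1), 8: ndi.generate_binary_structure(2, 2)}
_STRUCTURE_3D = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class RoughCellVolume:
    """One cell's rough segmentation: tomogram values inside the extruded
    footprint where RI exceeds the medium, zero elsewhere."""

    values: np.ndarray
    cell_label: int
    medium_ri: float

    @property
    def support(self) -> np.ndarray:
        return self.values > 0

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))


@dataclass(frozen=True)
class ZProfile:
    """Per-slice non-zero voxel counts of a rough volume and the z-floor
    index derived from them."""

    counts: np.ndarray
    normalized: np.ndarray
    floor_index: int
    threshold: float


@dataclass(frozen=True)
class CellMask3D:
    """Final binary mask of one cell, a single connected component."""

    mask: np.ndarray
    cell_label: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


def extrude_mask(labels: LabelImage2D, n_slices: int) -> np.ndarray:
    """Replicate a 2D label image over ``n_slices`` z planes.

    Returns a (nz, ny, nx) integer grid where every slice equals the
    input labels.
    """
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    return np.broadcast_to(labels.labels, (n_slices, *labels.labels.shape)).copy()


def rough_segmentation(
    tomo: RITomogram,
    extruded: np.ndarray,
    cell_label: int,
) -> RoughCellVolume:
    """Mask the tomogram to one cell's extruded footprint.

    Voxels outside the footprint, under other cells' labels, or with RI
    equal to or below the medium RI are zeroed; retained voxels keep
    their RI value.  Inputs are never mutated, so the call can be
    repeated per cell on shared arrays.
    """
    extruded = np.asarray(extruded)
    if extruded.shape != tomo.shape:
        raise ShapeMismatchError(
            f"extruded grid shape {extruded.shape} != tomogram shape {tomo.shape}"
        )
    if cell_label <= 0 or not np.any(extruded == cell_label):
        raise EmptyCellError(f"cell label {cell_label} not present in extruded grid")
    keep = (extruded == cell_label) & (tomo.values > tomo.medium_ri)
    return RoughCellVolume(
        values=np.where(keep, tomo.values, 0.0),
        cell_label=int(cell_label),
        medium_ri=tomo.medium_ri,
    )


def z_profile(rough: RoughCellVolume, z_floor_fraction: float = 0.5) -> ZProfile:
    """Per-slice voxel counts, normalized by the maximum slice count, and
    the z-floor index.

    The floor index is the smallest z (scanning upward from z = 0, the
    dish side) whose normalized count reaches ``z_floor_fraction``; it
    marks where the cell body proper starts above dish-surface roughness.
    """
    counts = np.count_nonzero(rough.values, axis=(1, 2))
    total = counts.sum()
    if total == 0:
        raise EmptyCellError(
            f"cell {rough.cell_label}: rough volume has no voxels above the medium RI"
        )
    normalized = counts / counts.max()
    above = np.nonzero(normalized >= z_floor_fraction)[0]
    floor_index = int(above[0])
    return ZProfile(
        counts=counts,
        normalized=normalized,
        floor_index=floor_index,
        threshold=float(z_floor_fraction),
    )


def apply_z_floor(rough: RoughCellVolume, floor_index: int) -> RoughCellVolume:
    """Zero every slice strictly below ``floor_index``; slices at or above
    it are untouched (the cell top is handled by connectivity, not by
    thresholding)."""
    n = rough.values.shape[0]
    if not (0 <= floor_index < n):
        raise ValueError(f"floor_index {floor_index} outside [0, {n})")
    out = rough.values.copy()
    out[:floor_index] = 0.0
    return RoughCellVolume(values=out, cell_label=rough.cell_label, medium_ri=rough.medium_ri)


def _largest_component(binary: np.ndarray, structure: np.ndarray) -> np.ndarray:
    """Retain exactly the largest connected component of a binary grid.

    Ties go to the component whose first voxel comes earliest in raster
    order; ``ndi.label`` numbers components in order of first encounter
    and ``argmax`` returns the first maximum, which implements that rule.
    """
    labeled, n = ndi.label(binary, structure=structure)
    if n == 0:
        return np.zeros_like(binary, dtype=bool)
    sizes = ndi.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return labeled == keep


def largest_component_2d(slice_mask: np.ndarray, connectivity_2d: int = 8) -> np.ndarray:
    """Largest 2D connected component of a binary slice (empty in, empty out)."""
    slice_mask = np.asarray(slice_mask).astype(bool)
    if slice_mask.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {slice_mask.shape}")
    return _largest_component(slice_mask, _STRUCTURE_2D[connectivity_2d])


def largest_component_3d(
    volume: np.ndarray,
    connectivity_3d: int = 26,
    cell_label: int = 1,
    provenance: dict | None = None,
) -> CellMask3D:
    """Largest 3D connected component of a binary volume as a CellMask3D."""
    volume = np.asarray(volume).astype(bool)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    mask = _largest_component(volume, _STRUCTURE_3D[connectivity_3d])
    return CellMask3D(mask=mask, cell_label=cell_label, provenance=provenance or {})


def refine_cell(
    tomo: RITomogram,
    extruded: np.ndarray,
    cell_label: int,
    config: RunConfig,
) -> tuple[CellMask3D, ZProfile]:
    """Run the full per-cell chain: rough -> z-floor -> 2D cleanup -> 3D cleanup."""
    rough = rough_segmentation(tomo, extruded, cell_label)
    profile = z_profile(rough, config.z_floor_fraction)
    floored = apply_z_floor(rough, profile.floor_index)
    cleaned = np.zeros(floored.values.shape, dtype=bool)
    for z in range(cleaned.shape[0]):
        sl = floored.values[z] > 0
        if sl.any():
            cleaned[z] = largest_component_2d(sl, config.connectivity_2d)
    provenance = {
        "cell_label": int(cell_label),
        "floor_index": profile.floor_index,
        "z_floor_fraction": config.z_floor_fraction,
        "connectivity_2d": config.connectivity_2d,
        "connectivity_3d": config.connectivity_3d,
        "medium_ri": tomo.medium_ri,
    }
    return (
        largest_component_3d(cleaned, config.connectivity_3d, cell_label, provenance),
        profile,
    )


def segment_cells(
    tomo: RITomogram,
    labels2d: LabelImage2D,
    config: RunConfig,
    *,
    return_profiles: bool = False,
) -> list[CellMask3D] | tuple[list[CellMask3D], dict[int, ZProfile]]:
    """Segment every labeled cell in a field of view.

    One :class:`CellMask3D` per positive 2D label, each produced
    independently.  Cells whose rough volume is empty (no voxel above the
    medium RI inside their footprint) are skipped with a warning.
    """
    if labels2d.shape != tomo.shape[1:]:
        raise ShapeMismatchError(
            f"2D label shape {labels2d.shape} != tomogram x-y shape {tomo.shape[1:]}"
        )
    extruded = extrude_mask(labels2d, tomo.n_slices)
    masks: list[CellMask3D] = []
    profiles: dict[int, ZProfile] = {}
    for lab in labels2d.cell_labels:
        try:
            mask, profile = refine_cell(tomo, extruded, lab, config)
        except EmptyCellError as exc:
            warnings.warn(f"skipping cell {lab}: {exc}")
            continue
        masks.append(mask)
        profiles[lab] = profile
    if return_profiles:
        return masks, profiles
    return masks
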