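"""TIFF I/O for RI tomograms and label masks.

Axis convention throughout the package: arrays are indexed ``(z, y, x)``;
TIFF page 0 is the lowest z slice (dish floor first) unless a reader is
told otherwise, rows are y and columns are x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .config import RunConfig, VoxelGeometry
from .errors import FormatError, ShapeMismatchError


@dataclass(frozen=True)
class RITomogram:
    """A 3D refractive-index tomogram.

    Attributes
    ----------
    values : ndarray, shape (nz, ny, nx)
        Decoded refractive index, dimensionless.
    geometry : VoxelGeometry
        Physical voxel pitches (um).
    medium_ri : float
        RI of the background medium.
    ri_scale : int
        Integer scale used on disk: stored value = round(RI * ri_scale).
    """

    values: np.ndarray
    geometry: VoxelGeometry
    medium_ri: float
    ri_scale: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3 or v.size == 0:
            raise FormatError(f"tomogram must be a non-empty 3D grid, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise FormatError("tomogram contains non-finite RI values")
        if v.min() < 1.0:
            raise FormatError(
                f"tomogram contains RI values below 1.0 (min {v.min():.4f}); "
                "check ri_scale"
            )
        if self.medium_ri < 1.0:
            raise FormatError(f"medium_ri must be >= 1.0, got {self.medium_ri}")
        if self.ri_scale < 1:
            raise FormatError(f"ri_scale must be >= 1, got {self.ri_scale}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class LabelImage2D:
    """Integer-labeled 2D seed mask over the x-y plane (0 = background)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise FormatError(f"2D label image must be 2D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise FormatError(f"2D label image must be integer-typed, got {lab.dtype}")
        if lab.size and lab.min() < 0:
            raise FormatError("2D label image contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def cell_labels(self) -> list[int]:
        """Sorted positive labels present in the image."""
        u = np.unique(self.labels)
        return [int(k) for k in u if k > 0]

    @property
    def n_cells(self) -> int:
        return len(self.cell_labels)


def _encode(values: np.ndarray, ri_scale: int) -> np.ndarray:
    enc = np.rint(np.asarray(values, dtype=np.float64) * ri_scale)
    if enc.max(initial=0) > np.iinfo(np.uint16).max:
        raise FormatError(
            f"encoded RI exceeds uint16 range (max {enc.max():.0f}); reduce ri_scale"
        )
    return enc.astype(np.uint16)


def read_tomogram(
    path: str | Path,
    config: RunConfig,
    *,
    z_top_first: bool = False,
) -> RITomogram:
    """Read an RI tomogram from a multi-page unsigned-integer TIFF stack.

    Stored integers are divided by ``config.ri_scale`` to recover RI.
    Page order is taken as bottom-of-dish first; set ``z_top_first`` if the
    exporting software wrote the stack top-down.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"tomogram file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise FormatError(f"{path}: TIFF has zero pages")
        if len(tif.series) != 1:
            shapes = [s.shape for s in tif.series]
            raise FormatError(
                f"{path}: pages do not form one uniform stack (series shapes {shapes})"
            )
        series = tif.series[0]
        if any(c in series.axes for c in "SC"):
            raise FormatError(
                f"{path}: multi-channel TIFF (axes {series.axes}); expected "
                "single-channel grayscale pages"
            )
        if not np.issubdtype(series.dtype, np.unsignedinteger):
            raise FormatError(
                f"{path}: pixel type {series.dtype} is not an unsigned-integer type"
            )
        stack = series.asarray()
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise FormatError(
            f"{path}: expected a stack of 2D pages, got shape {stack.shape} "
            f"(axes {series.axes})"
        )
    if z_top_first:
        stack = stack[::-1]
    values = stack.astype(np.float64) / config.ri_scale
    return RITomogram(
        values=values,
        geometry=config.geometry,
        medium_ri=config.medium_ri,
        ri_scale=config.ri_scale,
    )


def write_tomogram(path: str | Path, tomo: RITomogram) -> None:
    """Write a tomogram as a uint16 multi-page TIFF (RI * ri_scale per voxel)."""
    tifffile.imwrite(Path(path), _encode(tomo.values, tomo.ri_scale), photometric="minisblack")


def read_labels2d(
    path: str | Path,
    *,
    binarize: bool = False,
) -> LabelImage2D:
    """Read a single-page integer label image (TIFF or PNG).

    A binary 0/255-style image is rejected unless ``binarize`` is set, in
    which case all foreground becomes a single label 1; rejecting by
    default avoids silently merging touching cells whose mask was saved
    without per-cell labels.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"2D label file not found: {path}")
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-page 2D label image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        raise FormatError(f"{path}: floating-point pixel type {arr.dtype} is not a label image")
    if arr.min(initial=0) < 0:
        raise FormatError(f"{path}: negative label values")
    uniq = set(np.unique(arr).tolist())
    if binarize:
        arr = (arr > 0).astype(np.int32)
    elif uniq <= {0, 255} and 255 in uniq:
        raise FormatError(
            f"{path}: looks like a binary 0/255 mask, not a label image; "
            "pass binarize=True (CLI: --binarize) to treat foreground as one cell"
        )
    return LabelImage2D(labels=arr.astype(np.int32))


def write_labels2d(path: str | Path, labels: LabelImage2D) -> None:
    """Write a 2D label image as uint16 TIFF."""
    lab = labels.labels
    if lab.max(initial=0) > np.iinfo(np.uint16).max:
        raise FormatError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(Path(path), lab.astype(np.uint16))


def write_labels3d(
    path: str | Path,
    masks: Sequence["np.ndarray | object"],
    *,
    on_overlap: str = "error",
) -> None:
    """Write per-cell 3D binary masks as one uint16 label stack.

    Voxel value is the 1-based index of the mask claiming it (or the
    mask's own ``cell_label`` when the objects carry one); 0 is background.

    Parameters
    ----------
    masks : sequence of CellMask3D or binary ndarrays
        Must share one grid shape.
    on_overlap : {"error", "first", "last"}
        Policy when two masks claim one voxel. ``error`` (default) refuses;
        ``first``/``last`` resolve in favour of the earlier/later mask.
    """
    if on_overlap not in ("error", "first", "last"):
        raise ValueError(f"invalid on_overlap policy {on_overlap!r}")
    arrays: list[np.ndarray] = []
    label_ids: list[int] = []
    for i, m in enumerate(masks):
        arr = getattr(m, "mask", m)
        arr = np.asarray(arr).astype(bool)
        if arr.ndim != 3:
            raise FormatError(f"mask {i} is not 3D (shape {arr.shape})")
        arrays.append(arr)
        label_ids.append(int(getattr(m, "cell_label", i + 1)))
    if len(masks) > np.iinfo(np.uint16).max:
        raise FormatError("more than 65535 cells cannot be stored as uint16")
    if arrays:
        shape = arrays[0].shape
        for i, arr in enumerate(arrays):
            if arr.shape != shape:
                raise ShapeMismatchError(
                    f"mask {i} shape {arr.shape} differs from mask 0 shape {shape}"
                )
        if max(label_ids) > np.iinfo(np.uint16).max:
            raise FormatError("cell label exceeds uint16 range")
        out = np.zeros(shape, dtype=np.uint16)
        order = range(len(arrays)) if on_overlap != "first" else reversed(range(len(arrays)))
        claimed = np.zeros(shape, dtype=bool)
        for i in order:
            if on_overlap == "error" and np.any(claimed & arrays[i]):
                raise FormatError(
                    f"mask with label {label_ids[i]} overlaps a previous mask; "
                    "pass on_overlap='first' or 'last' to resolve"
                )
            claimed |= arrays[i]
            out[arrays[i]] = label_ids[i]
    else:
        out = np.zeros((1, 1, 1), dtype=np.uint16)
    tifffile.imwrite(Path(path), out, photometric="minisblack")


def read_labels3d(path: str | Path) -> np.ndarray:
    """Read a 3D integer label stack written by :func:`write_labels3d`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"3D label file not found: {path}")
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3D label stack, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: label stack must be integer-typed, got {arr.dtype}")
    return arr.astype(np.int32)


def estimate_medium_ri(tomo_values: np.ndarray, ri_scale: int) -> float:
    """Estimate background RI as the mode of the integer-encoded histogram.

    Off by default in the pipeline; the medium RI should normally come
    from the instrument configuration.
    """
    enc = np.rint(np.asarray(tomo_values) * ri_scale).astype(np.int64).ravel()
    vals, counts = np.unique(enc, return_counts=True)
    mode = vals[np.argmax(counts)]
    est = float(mode) / ri_scale
    if est < 1.0:
        warnings.warn(f"estimated medium RI {est:.4f} < 1.0; check ri_scale")
    return est
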