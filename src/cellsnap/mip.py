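"""Maximum-intensity projection and 2D seed segmentation.

The 3D refinement needs one 2D seed label per cell.  Any external 2D
segmenter can supply it (see :func:`cellsnap.io.read_labels2d`); the
built-in :func:`seed_segment_2d` is a deterministic Otsu + fill-holes +
distance-transform-watershed fallback so the pipeline runs end to end
without external software.  External masks always take precedence when
given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .errors import FormatError
from .io import LabelImage2D, RITomogram


@dataclass(frozen=True)
class MIPImage:
    """Maximum-intensity projection of a tomogram along z.

    Attributes
    ----------
    values : ndarray, shape (ny, nx)
        Per-pixel maximum RI over the z column.
    dx, dy : float
        Lateral pitches (um), carried for export metadata.
    """

    values: np.ndarray
    dx: float
    dy: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise FormatError(f"MIP must be 2D, got shape {v.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def max_intensity_projection(tomo: RITomogram) -> MIPImage:
    """Project a tomogram along z keeping the maximum RI per (y, x) column."""
    return MIPImage(
        values=tomo.values.max(axis=0),
        dx=tomo.geometry.dx,
        dy=tomo.geometry.dy,
    )


def seed_segment_2d(
    mip: MIPImage,
    medium_ri: float,
    min_area_px: int = 50,
    *,
    peak_min_distance: int = 10,
) -> LabelImage2D:
    """Segment a MIP image into per-cell seed labels.

    Foreground is everything above the Otsu threshold of the MIP (and
    strictly above ``medium_ri``); holes are filled; touching cells are
    split by a watershed on the euclidean distance transform seeded at
    its regional maxima.  Components under ``min_area_px`` pixels are
    dropped.  Deterministic for a fixed input: markers are ordered by
    descending distance peak then raster order, and watershed floods in
    marker order.

    An all-background image yields an empty labeling with a warning, not
    an error.
    """
    values = np.asarray(mip.values, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise FormatError("MIP contains non-finite values")

    flat = values.max() == values.min()
    if flat:
        thresh = values.max()  # nothing can exceed it
    else:
        thresh = threshold_otsu(values)
    foreground = (values > thresh) & (values > medium_ri)
    if not foreground.any():
        warnings.warn("seed_segment_2d: no foreground found; returning empty labeling")
        return LabelImage2D(labels=np.zeros(values.shape, dtype=np.int32))

    foreground = ndi.binary_fill_holes(foreground)
    if min_area_px > 1:
        foreground = remove_small_objects(foreground, max_size=min_area_px - 1)
    if not foreground.any():
        warnings.warn("seed_segment_2d: all components below min_area_px; empty labeling")
        return LabelImage2D(labels=np.zeros(values.shape, dtype=np.int32))

    distance = ndi.distance_transform_edt(foreground)
    # Regional maxima with a generous footprint merge plateau/fragmented
    # peaks so one convex cell gets one marker.
    size = max(3, 2 * peak_min_distance + 1)
    footprint = np.ones((size, size), dtype=bool)
    is_peak = (distance == ndi.maximum_filter(distance, footprint=footprint)) & foreground
    peak_labels, n_peaks = ndi.label(is_peak)
    if n_peaks == 0:
        # degenerate: foreground exists but no interior — single marker
        markers, _ = ndi.label(foreground)
    else:
        # one marker pixel per peak component: its first raster pixel;
        # markers numbered by descending peak height, ties by raster order
        order = []
        for k in range(1, n_peaks + 1):
            ys, xs = np.nonzero(peak_labels == k)
            i = np.lexsort((xs, ys))[0]
            order.append((-distance[ys[i], xs[i]], ys[i], xs[i]))
        markers = np.zeros(values.shape, dtype=np.int32)
        for rank, (_, y, x) in enumerate(sorted(order), start=1):
            markers[y, x] = rank
    labels = watershed(-distance, markers=markers, mask=foreground)

    if min_area_px > 1:
        for k in np.unique(labels):
            if k > 0 and np.count_nonzero(labels == k) < min_area_px:
                labels[labels == k] = 0
    # relabel contiguously 1..n preserving ordering
    out = np.zeros(values.shape, dtype=np.int32)
    for new, old in enumerate(sorted(k for k in np.unique(labels) if k > 0), start=1):
        out[labels == old] = new
    return LabelImage2D(labels=out)
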