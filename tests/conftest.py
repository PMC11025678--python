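"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid scipy.ndimage / skimage so that the
implementation and its checks share no code path: connected components by
hand-written BFS, z-floor by a linear scan, OPD by an explicit triple
loop, metrics by set arithmetic.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from cellsnap import (
    RITomogram,
    RunConfig,
    VoxelGeometry,
    generate,
    standard_suite,
)

# ---------------------------------------------------------------- oracles

_OFFSETS_2D = {
    4: [(-1, 0), (1, 0), (0, -1), (0, 1)],
    8: [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)],
}


def _offsets_3d(connectivity: int) -> list[tuple[int, int, int]]:
    out = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                out.append((dz, dy, dx))
    return out


def flood_fill_components(binary: np.ndarray, offsets) -> list[set[tuple]]:
    """All connected components as voxel-index sets, by BFS, in raster order
    of each component's first voxel."""
    binary = np.asarray(binary).astype(bool)
    seen = np.zeros_like(binary, dtype=bool)
    components = []
    for idx in np.ndindex(binary.shape):
        if not binary[idx] or seen[idx]:
            continue
        comp = set()
        queue = deque([idx])
        seen[idx] = True
        while queue:
            cur = queue.popleft()
            comp.add(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if all(0 <= n < s for n, s in zip(nb, binary.shape)):
                    if binary[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
        components.append(comp)
    return components


def largest_component_oracle(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Largest component by BFS; ties broken by earliest first voxel in
    raster order (components are discovered in that order)."""
    binary = np.asarray(binary).astype(bool)
    offsets = _OFFSETS_2D[connectivity] if binary.ndim == 2 else _offsets_3d(connectivity)
    comps = flood_fill_components(binary, offsets)
    out = np.zeros_like(binary, dtype=bool)
    if comps:
        best = max(comps, key=len)  # max() keeps the earliest of equals
        for idx in best:
            out[idx] = True
    return out


def floor_index_oracle(counts: np.ndarray, fraction: float) -> int:
    """First z (scanning upward) whose count reaches fraction * max count."""
    counts = np.asarray(counts, dtype=float)
    level = fraction * counts.max()
    for z, c in enumerate(counts):
        if c >= level:
            return z
    raise AssertionError("unreachable for fraction <= 1")


def opd_oracle(tomo: RITomogram, mask: np.ndarray) -> np.ndarray:
    """Explicit triple-loop OPD integration."""
    nz, ny, nx = tomo.shape
    out = np.zeros((ny, nx))
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if mask[z, y, x]:
                    out[y, x] += (tomo.values[z, y, x] - tomo.medium_ri) * tomo.geometry.dz
    return out


def metrics_oracle(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Set-arithmetic overlap metrics on voxel-index sets."""
    p = {tuple(i) for i in np.argwhere(pred)}
    t = {tuple(i) for i in np.argwhere(truth)}
    inter = len(p & t)
    union = len(p | t)
    return {
        "pixel_accuracy": inter / len(t),
        "iou": inter / union if union else 1.0,
        "dice": 2 * inter / (len(p) + len(t)),
    }


def hausdorff_oracle(pred: np.ndarray, truth: np.ndarray, geometry: VoxelGeometry) -> float:
    """Max over both directed max-min voxel-center distances, in um."""
    scale = np.array([geometry.dz, geometry.dy, geometry.dx])
    a = np.argwhere(pred) * scale
    b = np.argwhere(truth) * scale
    d_ab = max(np.min(np.linalg.norm(b - pa, axis=1)) for pa in a)
    d_ba = max(np.min(np.linalg.norm(a - pb, axis=1)) for pb in b)
    return max(d_ab, d_ba)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def suite():
    return standard_suite()


@pytest.fixture(scope="session")
def isolated_scene(suite):
    return generate(suite["isolated"])


@pytest.fixture(scope="session")
def clumped_scene(suite):
    return generate(suite["clumped_pair"])


@pytest.fixture(scope="session")
def preset_config(suite):
    return RunConfig(geometry=suite["isolated"].geometry)


def make_tomogram(
    values: np.ndarray,
    medium_ri: float = 1.337,
    geometry: VoxelGeometry | None = None,
    ri_scale: int = 10000,
) -> RITomogram:
    if geometry is None:
        geometry = VoxelGeometry(0.1, 0.1, 0.2)
    return RITomogram(
        values=np.asarray(values, dtype=np.float64),
        geometry=geometry,
        medium_ri=medium_ri,
        ri_scale=ri_scale,
    )


def random_ri_grid(rng: np.random.Generator, shape, medium_ri=1.337, spread=0.05):
    """Random RI grid slightly above/below the medium, ri-scale exact."""
    ints = rng.integers(
        round((medium_ri - spread) * 10000),
        round((medium_ri + spread) * 10000),
        size=shape,
        endpoint=True,
    )
    return ints.astype(np.float64) / 10000
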