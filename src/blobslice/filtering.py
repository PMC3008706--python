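"""3D Difference-of-Gaussians filtering and local-maxima seed detection.

The DoG response ``G(sigma_inner) * I - G(sigma_outer) * I`` acts as a
matched filter for a blurred sphere against a dark background: its 3D maxima
are candidate nuclear centers, its per-plane 2D maxima are candidate centers
of nuclear cross-sections, and its zero crossings trace nuclear boundaries.

Sigmas are set from the expected in-plane nuclear diameter D:
``sigma_inner = D / 4`` and ``sigma_outer = 1.6 * sigma_inner`` (the classic
ratio that makes the DoG approximate a Laplacian-of-Gaussian). Along z both
sigmas are divided by the anisotropy ratio (z spacing over in-plane spacing,
floored at 0.5 voxel) so the kernel is spherical in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from blobslice.volume_io import Config, ImageVolume

__all__ = [
    "FilteredVolume",
    "SeedPoint",
    "dog_filter",
    "find_3d_maxima",
    "find_2d_maxima",
    "dog_sigmas",
]

SIGMA_RATIO = 1.6  # outer/inner Gaussian width ratio (LoG approximation)
MIN_Z_SIGMA = 0.5  # voxels; floor for the anisotropy-corrected z sigma


@dataclass
class FilteredVolume:
    """DoG response grid sharing geometry with its source volume."""

    response: np.ndarray  # (y, x, z), signed float
    sigma_inner: tuple[float, float, float]  # per-axis (y, x, z), voxels
    sigma_outer: tuple[float, float, float]
    source_name: str = ""

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.response.shape

    def plane(self, z: int) -> np.ndarray:
        return self.response[:, :, z]


@dataclass(frozen=True)
class SeedPoint:
    """A local maximum of the filtered volume: a candidate center."""

    position: tuple[int, int, int]  # (y, x, z)
    response_value: float
    kind: str  # "maximum3d" | "maximum2d"


def dog_sigmas(config: Config, anisotropy: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Per-axis (y, x, z) inner and outer sigmas in voxels."""
    s_in = config.nuclear_diameter / 4.0
    s_out = SIGMA_RATIO * s_in
    ratio = max(anisotropy, 1e-12)
    inner = (s_in, s_in, max(s_in / ratio, MIN_Z_SIGMA))
    outer = (s_out, s_out, max(s_out / ratio, MIN_Z_SIGMA))
    return inner, outer


def dog_filter(volume: ImageVolume, config: Config) -> FilteredVolume:
    """Compute the 3D DoG response of a volume.

    Each Gaussian is applied separably per axis with reflect boundary
    handling; output shape equals input shape.
    """
    inner, outer = dog_sigmas(config, volume.anisotropy)
    data = volume.data
    # warn-and-clamp if kernel support exceeds the volume extent
    for ax, s in enumerate(outer):
        if 4 * s > data.shape[ax] * 4:  # pathological only
            import warnings

            warnings.warn(
                f"DoG sigma {s:.1f} very large for axis {ax} of extent {data.shape[ax]}; "
                "kernel support clamped by the volume size",
                stacklevel=2,
            )
    g_in = ndimage.gaussian_filter(data, sigma=inner, mode="reflect")
    g_out = ndimage.gaussian_filter(data, sigma=outer, mode="reflect")
    return FilteredVolume(g_in - g_out, inner, outer, source_name=volume.name)


def _plateau_maxima(values: np.ndarray, above: np.ndarray, connectivity: int) -> list[tuple]:
    """Positions of strict local maxima with deterministic plateau handling.

    A voxel qualifies when it is >= all neighbors and > at least one
    (connected plateaus of equal value count as one maximum, represented by
    their lexicographically smallest position). ``above`` masks the threshold.
    """
    footprint = ndimage.generate_binary_structure(values.ndim, connectivity)
    local_max = values >= ndimage.maximum_filter(values, footprint=footprint, mode="nearest")
    candidates = local_max & above
    if not candidates.any():
        return []
    # adjacent candidates necessarily share the same value (each >= the other),
    # so connected components of `candidates` are equal-valued plateaus
    labels, n = ndimage.label(candidates, structure=footprint)
    offsets = np.argwhere(footprint) - 1
    offsets = offsets[np.any(offsets != 0, axis=1)]
    shape = values.shape
    all_pos = np.argwhere(candidates)
    all_lab = labels[tuple(all_pos.T)]
    out: list[tuple] = []
    for lab in range(1, n + 1):
        positions = all_pos[all_lab == lab]
        v = values[tuple(positions[0])]
        # strictness: the plateau must have at least one strictly smaller neighbor
        neigh = (positions[:, None, :] + offsets[None, :, :]).reshape(-1, values.ndim)
        inside = np.all((neigh >= 0) & (neigh < np.array(shape)), axis=1)
        neigh = neigh[inside]
        nv = values[tuple(neigh.T)]
        if not np.any(nv < v):
            continue  # e.g. a constant field: no strict drop anywhere around it
        out.append(tuple(int(c) for c in positions[np.lexsort(positions.T[::-1])][0]))
    out.sort()
    return out


def find_3d_maxima(filtered: FilteredVolume, noise_threshold: float) -> list[SeedPoint]:
    """3D local maxima (26-connected) of the response above the noise threshold.

    Plateaus of equal value yield one seed at their lexicographically smallest
    (y, x, z) position, so runs are reproducible. Maxima on the volume border
    are kept (late embryos touch image edges).
    """
    resp = filtered.response
    positions = _plateau_maxima(resp, resp > noise_threshold, connectivity=3)
    return [SeedPoint(p, float(resp[p]), "maximum3d") for p in positions]


def find_2d_maxima(filtered: FilteredVolume, base_threshold: float) -> list[SeedPoint]:
    """Per-plane 8-connected local maxima above the base threshold.

    Every 3D maximum position is also a 2D maximum of its plane (the 2D
    plateau representative coincides because the lexicographic order on
    (y, x, z) restricts consistently to (y, x) within a plane).
    """
    resp = filtered.response
    seeds: list[SeedPoint] = []
    for z in range(resp.shape[2]):
        plane = resp[:, :, z]
        for (y, x) in _plateau_maxima(plane, plane > base_threshold, connectivity=2):
            seeds.append(SeedPoint((y, x, z), float(plane[y, x]), "maximum2d"))
    return seeds
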