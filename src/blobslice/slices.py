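"""2D slice segmentation by ray casting to zero crossings of the DoG response.

From every per-plane response maximum, evenly spaced rays march outward until
the filtered intensity crosses zero (the nuclear boundary in the band-passed
image). Ray endpoints, after pruning of outliers, define a polygonal nuclear
cross-section whose geometry and interior intensity are then measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath

from blobslice.filtering import FilteredVolume, SeedPoint, find_2d_maxima
from blobslice.volume_io import Config, ImageVolume

__all__ = [
    "NuclearSlice",
    "RayEndpoint",
    "cast_rays",
    "prune_rays",
    "build_slice",
    "segment_all_slices",
]

RAY_STEP = 0.5  # pixels; marching granularity along each ray


@dataclass(frozen=True)
class RayEndpoint:
    """Sub-pixel terminus of one boundary-search ray."""

    y: float
    x: float
    angle: float  # radians
    length: float  # pixels from ray origin
    truncated: bool  # hit max_len or the image border instead of a zero crossing


@dataclass
class NuclearSlice:
    """One polygonal nuclear cross-section within a single image plane."""

    id: int
    center: tuple[float, float]  # (y, x), pixels
    plane: int  # z index
    ray_endpoints: list[RayEndpoint]
    polygon_area: float  # pixels^2
    equivalent_radius: float  # pixels, sqrt(area/pi)
    mean_intensity: float  # raw-image units over the polygon interior
    peak_response: float  # filtered units at the center
    claimed_by: set[int] = field(default_factory=set)

    @property
    def polygon(self) -> np.ndarray:
        """(k, 2) array of (y, x) vertices in angular order."""
        return np.array([[e.y, e.x] for e in self.ray_endpoints], dtype=float)

    def center_physical(self, xy_spacing: float, z_spacing: float) -> np.ndarray:
        """Center position in micrometers, (y, x, z)."""
        return np.array(
            [self.center[0] * xy_spacing, self.center[1] * xy_spacing, self.plane * z_spacing]
        )


def _bilinear(plane: np.ndarray, y: float, x: float) -> float:
    """Bilinear interpolation of a 2D grid; clamps to the border."""
    ny, nx = plane.shape
    y = min(max(y, 0.0), ny - 1.0)
    x = min(max(x, 0.0), nx - 1.0)
    y0, x0 = int(y), int(x)
    y1, x1 = min(y0 + 1, ny - 1), min(x0 + 1, nx - 1)
    fy, fx = y - y0, x - x0
    return float(
        plane[y0, x0] * (1 - fy) * (1 - fx)
        + plane[y1, x0] * fy * (1 - fx)
        + plane[y0, x1] * (1 - fy) * fx
        + plane[y1, x1] * fy * fx
    )


def cast_rays(
    filtered_plane: np.ndarray,
    center: tuple[int, int],
    n_rays: int = 16,
    max_len: float = 10.0,
    angle_offset: float = 0.0,
) -> list[RayEndpoint]:
    """Cast ``n_rays`` evenly spaced rays from a positive-response center.

    Each ray marches outward in 0.5-pixel steps with bilinear interpolation of
    the response; its endpoint is the linearly interpolated sub-pixel zero
    crossing. Rays that reach ``max_len`` or the image border without crossing
    zero terminate there and are flagged ``truncated``.
    """
    cy, cx = center
    ny, nx = filtered_plane.shape
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ValueError(f"ray origin {center} outside plane of shape {filtered_plane.shape}")
    v0 = filtered_plane[cy, cx]
    if v0 <= 0:
        raise ValueError(f"response at ray origin {center} must be > 0 (got {v0})")
    endpoints: list[RayEndpoint] = []
    for k in range(n_rays):
        theta = angle_offset + 2.0 * np.pi * k / n_rays
        dy, dx = np.sin(theta), np.cos(theta)
        prev_r, prev_v = 0.0, v0
        r = RAY_STEP
        endpoint = None
        while r <= max_len + 1e-9:
            y, x = cy + r * dy, cx + r * dx
            if not (0 <= y <= ny - 1 and 0 <= x <= nx - 1):
                endpoint = RayEndpoint(
                    cy + prev_r * dy, cx + prev_r * dx, theta, prev_r, truncated=True
                )
                break
            v = _bilinear(filtered_plane, y, x)
            if v <= 0:
                # sub-pixel zero crossing between prev_r (v>0) and r (v<=0)
                frac = prev_v / (prev_v - v) if prev_v != v else 0.0
                rc = prev_r + frac * (r - prev_r)
                endpoint = RayEndpoint(cy + rc * dy, cx + rc * dx, theta, rc, truncated=False)
                break
            prev_r, prev_v = r, v
            r += RAY_STEP
        if endpoint is None:
            endpoint = RayEndpoint(
                cy + max_len * dy, cx + max_len * dx, theta, max_len, truncated=True
            )
        endpoints.append(endpoint)
    return endpoints


def prune_rays(
    endpoints: list[RayEndpoint],
    center: tuple[float, float],
    prune_factor: float = 2.0,
) -> list[RayEndpoint]:
    """Discard rays unusually longer or shorter than their angular neighbors.

    A ray is dropped when its length differs from the median of its two
    angular neighbors' lengths by more than ``prune_factor``-fold either way.
    All rays are judged against the original lengths simultaneously; survivors
    keep their angular order.
    """
    n = len(endpoints)
    if n < 3:
        raise ValueError("prune_rays needs at least 3 endpoints")
    lengths = np.array([e.length for e in endpoints])
    keep = []
    for i in range(n):
        ref = float(np.median([lengths[(i - 1) % n], lengths[(i + 1) % n]]))
        li = lengths[i]
        if ref <= 0:
            ok = li <= 0
        else:
            ratio = li / ref
            ok = (1.0 / prune_factor) <= ratio <= prune_factor
        if ok:
            keep.append(endpoints[i])
    return keep


def _shoelace_area(poly: np.ndarray) -> float:
    y, x = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _interior_mean(raw_plane: np.ndarray, poly: np.ndarray) -> float:
    """Mean of pixels whose centers fall inside the polygon (even-odd rule)."""
    ny, nx = raw_plane.shape
    y0 = max(int(np.floor(poly[:, 0].min())), 0)
    y1 = min(int(np.ceil(poly[:, 0].max())), ny - 1)
    x0 = max(int(np.floor(poly[:, 1].min())), 0)
    x1 = min(int(np.ceil(poly[:, 1].max())), nx - 1)
    if y1 < y0 or x1 < x0:
        return float("nan")
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    inside = MplPath(poly).contains_points(pts)
    if not inside.any():
        return float("nan")
    return float(raw_plane[y0 : y1 + 1, x0 : x1 + 1].ravel()[inside].mean())


def build_slice(
    center: tuple[int, int, int],
    endpoints: list[RayEndpoint],
    raw_plane: np.ndarray,
    filtered_plane: np.ndarray,
    slice_id: int = 0,
) -> NuclearSlice:
    """Measure slice geometry and intensity from pruned ray endpoints.

    Area by the shoelace formula over endpoints in angular order;
    ``equivalent_radius = sqrt(area / pi)``; mean intensity over raw pixels
    whose centers lie inside the polygon. Degenerate (zero-area) polygons and
    polygons not containing their center are rejected with ValueError.
    """
    cy, cx, cz = center
    if len(endpoints) < 3:
        raise ValueError("need at least 3 endpoints to form a polygon")
    poly = np.array([[e.y, e.x] for e in endpoints], dtype=float)
    area = _shoelace_area(poly)
    if area <= 0:
        raise ValueError("degenerate zero-area slice polygon")
    if not MplPath(poly).contains_point((cy, cx), radius=1e-9):
        raise ValueError("slice center not strictly inside its polygon")
    radius = float(np.sqrt(area / np.pi))
    mean_int = _interior_mean(raw_plane, poly)
    if not np.isfinite(mean_int):
        mean_int = float(raw_plane[cy, cx])
    return NuclearSlice(
        id=slice_id,
        center=(float(cy), float(cx)),
        plane=int(cz),
        ray_endpoints=list(endpoints),
        polygon_area=area,
        equivalent_radius=radius,
        mean_intensity=mean_int,
        peak_response=float(filtered_plane[cy, cx]),
    )


def segment_all_slices(
    volume: ImageVolume,
    filtered: FilteredVolume,
    config: Config,
    maxima2d: list[SeedPoint] | None = None,
) -> list[NuclearSlice]:
    """Segment one NuclearSlice per surviving 2D response maximum.

    Slices failing the ray criteria are silently omitted: fewer than
    ``min_ray_survivors`` rays after pruning, more than half the rays
    truncated (likely a noise ridge rather than a nucleus), or a degenerate
    polygon. Slice ids are unique and assigned in (z, y, x) scan order.
    """
    if maxima2d is None:
        maxima2d = find_2d_maxima(filtered, config.base_threshold)
    slices: list[NuclearSlice] = []
    next_id = 0
    for seed in sorted(maxima2d, key=lambda s: (s.position[2], s.position[0], s.position[1])):
        y, x, z = seed.position
        plane = filtered.plane(z)
        if plane[y, x] <= 0:
            continue
        rays = cast_rays(plane, (y, x), config.n_rays, config.max_ray_len)
        if sum(e.truncated for e in rays) > len(rays) / 2:
            continue
        survivors = prune_rays(rays, (y, x), config.prune_factor)
        if len(survivors) < config.min_ray_survivors:
            continue
        try:
            s = build_slice((y, x, z), survivors, volume.plane(z), plane, slice_id=next_id)
        except ValueError:
            continue
        slices.append(s)
        next_id += 1
    return slices
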