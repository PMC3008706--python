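"""I/O for image volumes, detection records, configurations and shape models.

Coordinate convention: volumes are indexed ``(y, x, z)`` with 0-based indices;
``z`` is the optical-section axis (page order of a TIFF stack maps to
ascending z). Physical voxel spacing is given per axis in micrometers as
``(sx, sy, sz)`` ordered x, y, z; z spacing is typically several-fold larger
than in-plane spacing and is never assumed equal to it.

Detection records are a simplified CSV dialect with columns
``id, x, y, z, diameter, status`` (one row per nucleus, coordinates in
voxel units). See the README for the mapping to the AceTree nuclei format.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageVolume",
    "NucleusEntry",
    "DetectionRecord",
    "Config",
    "load_volume",
    "save_volume",
    "write_detections",
    "read_detections",
    "read_ground_truth",
    "load_config",
    "save_config",
]

VALID_STATUS = ("seeded", "recovered", "merged")


@dataclass
class ImageVolume:
    """A single-channel 3D intensity volume with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (ny, nx, nz)
        Non-negative intensities, float64. Axis order is (y, x, z).
    spacing : tuple of float
        Physical size of one voxel step along (x, y, z), micrometers.
    name : str
        Free-text identifier.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D (y, x, z); got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1; got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        if np.any(self.data < 0):
            raise ValueError("volume contains negative intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals (x, y, z); got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_planes(self) -> int:
        return self.data.shape[2]

    @property
    def anisotropy(self) -> float:
        """z spacing over mean in-plane spacing."""
        sx, sy, sz = self.spacing
        return sz / ((sx + sy) / 2.0)

    def plane(self, z: int) -> np.ndarray:
        return self.data[:, :, z]


@dataclass
class NucleusEntry:
    """One detected (or ground-truth) nucleus: centroid in voxel coordinates."""

    id: int
    x: float
    y: float
    z: float
    diameter: float
    status: str = "seeded"


@dataclass
class DetectionRecord:
    """Final output of the pipeline: one entry per detected nucleus."""

    nuclei: list[NucleusEntry] = field(default_factory=list)
    volume_name: str = ""
    config_snapshot: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nuclei]
        if len(ids) != len(set(ids)):
            raise ValueError("nucleus ids must be unique")

    def __len__(self) -> int:
        return len(self.nuclei)

    def centroids(self) -> np.ndarray:
        """(n, 3) array of centroids in (x, y, z) voxel coordinates."""
        if not self.nuclei:
            return np.zeros((0, 3))
        return np.array([[n.x, n.y, n.z] for n in self.nuclei], dtype=float)


@dataclass
class Config:
    """Pipeline configuration.

    Two parameters matter most and are typically the only ones tuned per
    dataset: ``nuclear_diameter`` (expected in-plane nuclear diameter in
    pixels; sets the band-pass filter scale) and ``noise_threshold``
    (filtered-intensity cutoff below which 3D maxima are treated as noise).
    The advanced parameters default to values that scale with the diameter.
    """

    nuclear_diameter: float = 10.0  # pixels, in-plane
    noise_threshold: float = 1.0  # filtered-intensity units
    # advanced
    n_rays: int = 16
    max_ray_factor: float = 1.0  # max ray length = factor * nuclear_diameter
    prune_factor: float = 2.0
    min_ray_survivors: int = 8
    base_threshold_factor: float = 0.5  # 2D-maxima threshold = factor * noise_threshold
    recovery_radius_factor: float = 0.5  # recovery sphere = factor * nuclear_diameter (physical)
    min_cluster: int = 2
    overlap_min_shared: int = 1
    covariance_regularization: float = 1e-4
    candidate_z_window: int = 3  # planes searched either side of a seed for training candidates
    xy_spacing: float = 1.0  # um per pixel in-plane (used for physical distances)
    z_spacing: float = 1.0  # um per plane

    def __post_init__(self) -> None:
        if self.nuclear_diameter <= 0:
            raise ValueError("nuclear_diameter must be > 0")
        if self.noise_threshold < 0:
            raise ValueError("noise_threshold must be >= 0")

    @property
    def base_threshold(self) -> float:
        return self.base_threshold_factor * self.noise_threshold

    @property
    def max_ray_len(self) -> float:
        return self.max_ray_factor * self.nuclear_diameter

    @property
    def recovery_radius(self) -> float:
        """Recovery neighborhood radius in micrometers."""
        return self.recovery_radius_factor * self.nuclear_diameter * self.xy_spacing

    def with_spacing(self, spacing: Sequence[float]) -> "Config":
        """Copy with spacing taken from a volume's (sx, sy, sz)."""
        sx, sy, sz = spacing
        return dataclasses.replace(self, xy_spacing=(sx + sy) / 2.0, z_spacing=sz)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# volumes


def load_volume(path: str | Path, spacing: Sequence[float], name: str | None = None) -> ImageVolume:
    """Read a multi-page TIFF stack or raw array + JSON sidecar as an ImageVolume.

    TIFF pages map to ascending z; intensities are cast to float64 without
    rescaling. A ``.npy`` file is read as a raw (y, x, z) array; a ``.json``
    path is treated as a sidecar describing a raw binary file (keys: ``file``,
    ``shape``, ``dtype``, optional ``spacing``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        pages = tifffile.imread(str(path))
        if pages.ndim == 2:  # single page
            pages = pages[None, :, :]
        if pages.ndim != 3:
            raise ValueError(f"TIFF at {path} is not a single-channel z-stack (ndim={pages.ndim})")
        data = np.moveaxis(pages, 0, -1)  # (z, y, x) -> (y, x, z)
    elif suffix == ".npy":
        data = np.load(str(path))
    elif suffix == ".json":
        meta = json.loads(path.read_text())
        raw = path.parent / meta["file"]
        data = np.fromfile(raw, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
        if spacing is None and "spacing" in meta:
            spacing = meta["spacing"]
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return ImageVolume(np.asarray(data, dtype=np.float64), tuple(spacing), name or path.stem)


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write the volume as a multi-page float32 TIFF, pages in ascending z."""
    path = Path(path)
    pages = np.moveaxis(volume.data, -1, 0).astype(np.float32)  # (z, y, x)
    tifffile.imwrite(str(path), pages)


# ---------------------------------------------------------------------------
# detection records

_CSV_HEADER = "id,x,y,z,diameter,status"


def write_detections(record: DetectionRecord, path: str | Path) -> None:
    """Write a DetectionRecord as CSV; ``read_detections`` inverts it exactly.

    Floats are written with 9 significant digits so the round trip is the
    identity well past the 6-digit contract.
    """
    path = Path(path)
    lines = [_CSV_HEADER]
    for n in record.nuclei:
        lines.append(
            f"{n.id},{n.x:.9g},{n.y:.9g},{n.z:.9g},{n.diameter:.9g},{n.status}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_detections(path: str | Path, volume_name: str = "") -> DetectionRecord:
    """Read a detections CSV written by :func:`write_detections`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"detections file not found: {path}")
    lines = path.read_text().strip().splitlines()
    if not lines or lines[0].strip() != _CSV_HEADER:
        raise ValueError(f"{path}: expected header '{_CSV_HEADER}'")
    nuclei = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
        try:
            nid = int(parts[0])
            x, y, z, diam = (float(v) for v in parts[1:5])
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: non-numeric field ({e})") from None
        status = parts[5].strip()
        if status not in VALID_STATUS:
            raise ValueError(f"{path}:{lineno}: unknown status '{status}'")
        nuclei.append(NucleusEntry(nid, x, y, z, diam, status))
    return DetectionRecord(nuclei, volume_name=volume_name or path.stem)


def read_ground_truth(path: str | Path) -> DetectionRecord:
    """Read a ground-truth table (same CSV dialect as detections)."""
    return read_detections(path)


# ---------------------------------------------------------------------------
# configs


def save_config(config: Config, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def load_config(path: str | Path) -> Config:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    return Config.from_dict(json.loads(path.read_text()))
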