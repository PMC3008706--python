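"""The 7-D Gaussian shape model deciding slice membership in a nucleus.

Whether a candidate slice on a nearby plane belongs to a nucleus is decided
by a maximum-likelihood classifier over two 7-dimensional Gaussian class
models: *member* slices (true cross-sections of the nucleus) and *distractor*
slices (cross-sections of nearby nuclei). The feature vector measures the
candidate's position, size and intensity relative to the nucleus center slice
and relative to the closest intervening slice between them:

====  ======================================================================
d1    signed z-offset of the candidate from the center slice (planes)
d2    in-plane center offset from the center slice / center radius
d3    log(candidate radius / center radius)
d4    log(candidate mean intensity / center mean intensity)
d5    in-plane offset from the closest intervening slice / its radius
d6    log(candidate radius / intervening radius)
d7    log(candidate intensity / intervening intensity)
====  ======================================================================

When the candidate is adjacent to the center (no plane in between) the
intervening slice *is* the center slice, so d5..d7 duplicate d2..d4. Log
ratios make the classifier invariant to any common intensity rescaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from blobslice.slices import NuclearSlice

__all__ = [
    "FeatureVector",
    "ShapeModel",
    "compute_features",
    "find_intervening",
    "train_model",
    "classify",
    "generate_training_candidates",
    "worksheet_to_examples",
    "save_model",
    "load_model",
]

N_FEATURES = 7
LOG_EPS = 1e-6  # floor inside log ratios
MIN_EXAMPLES_PER_CLASS = 10

FeatureVector = np.ndarray  # shape (7,)


@dataclass
class ShapeModel:
    """Two-class Gaussian model of slice membership."""

    member_mean: np.ndarray
    member_cov: np.ndarray
    distractor_mean: np.ndarray
    distractor_cov: np.ndarray
    priors: tuple[float, float] = (0.5, 0.5)  # (p_member, p_distractor)
    n_training: tuple[int, int] = (0, 0)
    regularization: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("member_mean", "distractor_mean"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_FEATURES,):
                raise ValueError(f"{name} must have shape ({N_FEATURES},)")
            setattr(self, name, v)
        for name in ("member_cov", "distractor_cov"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (N_FEATURES, N_FEATURES):
                raise ValueError(f"{name} must be {N_FEATURES}x{N_FEATURES}")
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            setattr(self, name, m)
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")


def _safe_log_ratio(a: float, b: float) -> float:
    return float(np.log(max(a, LOG_EPS) / max(b, LOG_EPS)))


def compute_features(
    candidate: NuclearSlice,
    center: NuclearSlice,
    intervening: NuclearSlice,
) -> FeatureVector:
    """Feature vector for a (candidate, center, intervening) slice triple.

    ``intervening`` must lie on a plane strictly between candidate and center,
    or equal the center when the candidate is on an adjacent plane.
    """
    if candidate.plane == center.plane:
        raise ValueError("candidate and center must be on distinct planes")
    if center.equivalent_radius <= 0:
        raise ValueError("center slice radius must be > 0")
    d1 = float(candidate.plane - center.plane)
    off_c = np.hypot(
        candidate.center[0] - center.center[0], candidate.center[1] - center.center[1]
    )
    d2 = float(off_c / center.equivalent_radius)
    d3 = _safe_log_ratio(candidate.equivalent_radius, center.equivalent_radius)
    d4 = _safe_log_ratio(candidate.mean_intensity, center.mean_intensity)
    r_iv = max(intervening.equivalent_radius, LOG_EPS)
    off_i = np.hypot(
        candidate.center[0] - intervening.center[0], candidate.center[1] - intervening.center[1]
    )
    d5 = float(off_i / r_iv)
    d6 = _safe_log_ratio(candidate.equivalent_radius, intervening.equivalent_radius)
    d7 = _safe_log_ratio(candidate.mean_intensity, intervening.mean_intensity)
    return np.array([d1, d2, d3, d4, d5, d6, d7], dtype=float)


def find_intervening(
    candidate: NuclearSlice,
    center: NuclearSlice,
    slices_by_plane: dict[int, list[NuclearSlice]],
) -> NuclearSlice:
    """Closest slice between candidate and center, searching from the candidate.

    Walks plane-by-plane from the candidate toward the center and returns the
    in-plane nearest slice on the first populated strictly-in-between plane;
    falls back to the center slice when none exists (and by definition when
    the candidate is adjacent to the center).
    """
    step = 1 if center.plane > candidate.plane else -1
    z = candidate.plane + step
    while z != center.plane:
        pool = slices_by_plane.get(z, [])
        if pool:
            return min(
                pool,
                key=lambda s: (candidate.center[0] - s.center[0]) ** 2
                + (candidate.center[1] - s.center[1]) ** 2,
            )
        z += step
    return center


def train_model(
    examples: list[tuple[FeatureVector, str]],
    regularization: float = 1e-4,
    priors: tuple[float, float] | None = None,
    min_examples: int = MIN_EXAMPLES_PER_CLASS,
) -> ShapeModel:
    """Fit class means/covariances by maximum likelihood from labeled examples.

    Covariances use the unbiased 1/(n-1) estimator plus a ridge of
    ``regularization`` times the mean diagonal added to the diagonal, so small
    training sets from a single corrected frame cannot yield a singular model.
    Priors default to the empirical class frequencies.
    """
    groups: dict[str, list[np.ndarray]] = {"member": [], "distractor": []}
    for f, label in examples:
        if label not in groups:
            raise ValueError(f"unknown label '{label}'")
        groups[label].append(np.asarray(f, dtype=float))
    for label, g in groups.items():
        if len(g) < min_examples:
            raise ValueError(
                f"class '{label}' has {len(g)} examples; at least {min_examples} required"
            )
    stats_out = {}
    for label, g in groups.items():
        arr = np.vstack(g)
        mean = arr.mean(axis=0)
        if arr.shape[0] > 1:
            cov = np.cov(arr, rowvar=False, ddof=1)
        else:
            cov = np.zeros((N_FEATURES, N_FEATURES))
        ridge = regularization * max(float(np.mean(np.diag(cov))), 1.0)
        cov = cov + ridge * np.eye(N_FEATURES)
        stats_out[label] = (mean, cov, arr.shape[0])
    n_m, n_d = stats_out["member"][2], stats_out["distractor"][2]
    if priors is None:
        priors = (n_m / (n_m + n_d), n_d / (n_m + n_d))
    return ShapeModel(
        member_mean=stats_out["member"][0],
        member_cov=stats_out["member"][1],
        distractor_mean=stats_out["distractor"][0],
        distractor_cov=stats_out["distractor"][1],
        priors=priors,
        n_training=(n_m, n_d),
        regularization=regularization,
    )


def classify(feature: FeatureVector, model: ShapeModel) -> tuple[str, float]:
    """Label a feature vector and return its claim strength (log odds).

    ``log_odds = log N(f; member) + log p_m - log N(f; distractor) - log p_d``;
    the label is ``member`` iff log_odds > 0 (ties resolve to distractor:
    conservative claiming reduces under-segmentation of neighbors).
    """
    f = np.asarray(feature, dtype=float)
    try:
        lm = stats.multivariate_normal.logpdf(f, model.member_mean, model.member_cov)
        ld = stats.multivariate_normal.logpdf(f, model.distractor_mean, model.distractor_cov)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular class covariance despite regularization: {e}") from None
    log_odds = float(lm + np.log(model.priors[0]) - ld - np.log(model.priors[1]))
    return ("member" if log_odds > 0 else "distractor", log_odds)


# ---------------------------------------------------------------------------
# training-candidate worksheets


def generate_training_candidates(
    slices: list[NuclearSlice],
    seeds: list,
    config,
) -> list[dict]:
    """List, for each seed slice, all candidate member slices near it.

    The superset contains every slice within ``candidate_z_window`` planes of
    the seed (excluding the seed's own plane) whose in-plane center distance
    is below the sum of the two radii. Rows are dicts ready to be written as
    an editable worksheet CSV; the ``member`` column defaults to 1 and a human
    (or the synthetic ground truth) zeroes out non-members.
    """
    by_plane: dict[int, list[NuclearSlice]] = {}
    for s in slices:
        by_plane.setdefault(s.plane, []).append(s)
    by_id = {s.id: s for s in slices}
    rows: list[dict] = []
    for seed in seeds:
        if isinstance(seed, NuclearSlice):
            center = seed
        else:  # a SeedPoint: map to the slice centered at its position
            y, x, z = seed.position
            center = next(
                (s for s in by_plane.get(z, []) if s.center == (float(y), float(x))), None
            )
            if center is None:
                continue
        for dz in range(-config.candidate_z_window, config.candidate_z_window + 1):
            if dz == 0:
                continue
            for cand in by_plane.get(center.plane + dz, []):
                dist = np.hypot(
                    cand.center[0] - center.center[0], cand.center[1] - center.center[1]
                )
                if dist < cand.equivalent_radius + center.equivalent_radius:
                    rows.append(
                        {
                            "seed_slice_id": center.id,
                            "candidate_slice_id": cand.id,
                            "dz": dz,
                            "inplane_distance": float(dist),
                            "member": 1,
                        }
                    )
    _ = by_id
    return rows


def write_worksheet(rows: list[dict], path: str | Path) -> None:
    """Write candidate rows as an editable CSV worksheet."""
    cols = ["seed_slice_id", "candidate_slice_id", "dz", "inplane_distance", "member"]
    lines = [",".join(cols)]
    for r in rows:
        lines.append(",".join(str(r[c]) for c in cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_worksheet(path: str | Path) -> list[dict]:
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split(",")
    rows = []
    for line in lines[1:]:
        vals = line.split(",")
        r = dict(zip(header, vals))
        r["seed_slice_id"] = int(r["seed_slice_id"])
        r["candidate_slice_id"] = int(r["candidate_slice_id"])
        r["dz"] = int(r["dz"])
        r["inplane_distance"] = float(r["inplane_distance"])
        r["member"] = int(r["member"])
        rows.append(r)
    return rows


def worksheet_to_examples(
    rows: list[dict],
    slices: list[NuclearSlice],
) -> list[tuple[FeatureVector, str]]:
    """Convert a corrected worksheet to labeled feature vectors."""
    by_id = {s.id: s for s in slices}
    by_plane: dict[int, list[NuclearSlice]] = {}
    for s in slices:
        by_plane.setdefault(s.plane, []).append(s)
    examples = []
    for r in rows:
        center = by_id[r["seed_slice_id"]]
        cand = by_id[r["candidate_slice_id"]]
        iv = find_intervening(cand, center, by_plane)
        f = compute_features(cand, center, iv)
        examples.append((f, "member" if r["member"] else "distractor"))
    return examples


# ---------------------------------------------------------------------------
# serialization


def save_model(model: ShapeModel, path: str | Path) -> None:
    """Serialize a ShapeModel as JSON (covariances row-major)."""
    d = {
        "member_mean": model.member_mean.tolist(),
        "member_cov": model.member_cov.tolist(),
        "distractor_mean": model.distractor_mean.tolist(),
        "distractor_cov": model.distractor_cov.tolist(),
        "priors": list(model.priors),
        "n_training": list(model.n_training),
        "regularization": model.regularization,
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def load_model(path: str | Path) -> ShapeModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"shape-model file not found: {path}")
    d = json.loads(path.read_text())
    return ShapeModel(
        member_mean=np.array(d["member_mean"]),
        member_cov=np.array(d["member_cov"]),
        distractor_mean=np.array(d["distractor_mean"]),
        distractor_cov=np.array(d["distractor_cov"]),
        priors=tuple(d["priors"]),
        n_training=tuple(d["n_training"]),
        regularization=d.get("regularization", 0.0),
        metadata=d.get("metadata", {}),
    )
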