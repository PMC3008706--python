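"""Assembly of 2D slices into 3D nuclei.

Three stages, in order:

1. **Greedy claiming** (`extract_all`): each 3D response maximum seeds a
   nucleus at its slice, which claims slices on planes above and below it
   while the shape model classifies them as members. Seeds are processed in
   descending response order so bright nuclei claim first.
2. **Recovery** (`recover_overlooked`): dim nuclei masked by brighter
   neighbors are not 3D maxima, but their slices survive segmentation.
   Wherever multiple unclaimed slices cluster within a nuclear radius, a new
   nucleus is seeded at the locally brightest one, iteratively until no
   cluster remains.
3. **Conflict resolution** (`resolve_conflicts`): nuclei claiming the same
   slice are either merged into one (redundant detections of a single
   nucleus, e.g. its top and bottom halves) or their overlap is split, each
   contested slice going to the stronger claim; the shape model scores both
   configurations and the better one is applied.

After resolution every slice has at most one claimant and every nucleus
occupies a contiguous interval of planes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from blobslice.filtering import SeedPoint, dog_filter, find_2d_maxima, find_3d_maxima
from blobslice.shape_model import ShapeModel, classify, compute_features
from blobslice.slices import NuclearSlice, segment_all_slices
from blobslice.volume_io import Config, DetectionRecord, ImageVolume, NucleusEntry

logger = logging.getLogger(__name__)

__all__ = [
    "Nucleus",
    "SegmentationResult",
    "extract_nucleus",
    "extract_all",
    "recover_overlooked",
    "resolve_conflicts",
    "detect",
    "result_to_record",
]


@dataclass
class Nucleus:
    """A contiguous-in-z set of claimed slices with a center slice."""

    id: int
    center_slice_id: int
    member_slice_ids: list[int]  # ordered by plane, contiguous
    claim_strengths: dict[int, float]  # slice id -> log odds of the claim
    status: str = "seeded"  # seeded | recovered | merged

    @property
    def total_claim(self) -> float:
        return float(sum(self.claim_strengths.values()))

    def planes(self, slices_by_id: dict[int, NuclearSlice]) -> list[int]:
        return sorted(slices_by_id[i].plane for i in self.member_slice_ids)

    def centroid(self, slices_by_id: dict[int, NuclearSlice]) -> tuple[float, float, float]:
        """Intensity-weighted mean of member slice centers, (y, x, z) voxels."""
        members = [slices_by_id[i] for i in self.member_slice_ids]
        w = np.array([max(s.mean_intensity, 1e-12) for s in members])
        w = w / w.sum()
        y = float(np.dot(w, [s.center[0] for s in members]))
        x = float(np.dot(w, [s.center[1] for s in members]))
        z = float(np.dot(w, [s.plane for s in members]))
        return (y, x, z)

    def diameter(self, slices_by_id: dict[int, NuclearSlice]) -> float:
        """Twice the largest member slice's equivalent radius, pixels."""
        return 2.0 * max(slices_by_id[i].equivalent_radius for i in self.member_slice_ids)


@dataclass
class SegmentationResult:
    """All slices plus the nuclei assembled from them, with stage accounting."""

    nuclei: list[Nucleus]
    slices: list[NuclearSlice]
    stage_log: dict = field(default_factory=dict)

    @property
    def slices_by_id(self) -> dict[int, NuclearSlice]:
        return {s.id: s for s in self.slices}

    @property
    def unclaimed_slice_ids(self) -> list[int]:
        return sorted(s.id for s in self.slices if not s.claimed_by)

    def to_record(self, volume_name: str = "", config: Config | None = None) -> DetectionRecord:
        return result_to_record(self, volume_name, config)


def _slices_by_plane(slices: list[NuclearSlice]) -> dict[int, list[NuclearSlice]]:
    d: dict[int, list[NuclearSlice]] = {}
    for s in slices:
        d.setdefault(s.plane, []).append(s)
    return d


def _nearest_candidate(
    pool: list[NuclearSlice], center: NuclearSlice
) -> NuclearSlice | None:
    """In-plane nearest slice within the sum of the two radii, or None."""
    best, best_d = None, np.inf
    for s in pool:
        d = np.hypot(s.center[0] - center.center[0], s.center[1] - center.center[1])
        if d < s.equivalent_radius + center.equivalent_radius and d < best_d:
            best, best_d = s, d
    return best


def extract_nucleus(
    seed_slice: NuclearSlice,
    slices: list[NuclearSlice],
    model: ShapeModel,
    config: Config,
    nucleus_id: int = 0,
    status: str = "seeded",
) -> Nucleus:
    """Grow a nucleus from its seed slice by claiming members above and below.

    Walking plane-by-plane upward then downward from the seed, the in-plane
    nearest candidate on each adjacent plane is classified against the shape
    model (the previously claimed slice serving as the intervening slice);
    claiming continues while the classifier says member and stops at the
    first non-member or absent candidate, keeping the nucleus contiguous.
    A bare seed with no claimable neighbors is a valid single-slice nucleus.
    """
    by_plane = _slices_by_plane(slices)
    members: list[tuple[int, NuclearSlice]] = [(seed_slice.plane, seed_slice)]
    strengths: dict[int, float] = {seed_slice.id: 0.0}
    for step in (+1, -1):
        prev = seed_slice
        z = seed_slice.plane + step
        while True:
            pool = [s for s in by_plane.get(z, []) if s.id != seed_slice.id]
            cand = _nearest_candidate(pool, seed_slice)
            if cand is None:
                break
            intervening = prev if prev.plane != seed_slice.plane else seed_slice
            f = compute_features(cand, seed_slice, intervening)
            label, log_odds = classify(f, model)
            if label != "member":
                break
            members.append((z, cand))
            strengths[cand.id] = log_odds
            prev = cand
            z += step
    members.sort(key=lambda t: t[0])
    nuc = Nucleus(
        id=nucleus_id,
        center_slice_id=seed_slice.id,
        member_slice_ids=[s.id for _, s in members],
        claim_strengths=strengths,
        status=status,
    )
    for _, s in members:
        s.claimed_by.add(nucleus_id)
    return nuc


def extract_all(
    seeds: list[SeedPoint],
    slices: list[NuclearSlice],
    model: ShapeModel,
    config: Config,
) -> SegmentationResult:
    """Extract one nucleus per 3D-maximum seed, brightest first.

    Claims may overlap at this stage; conflict resolution arbitrates later.
    Seeds whose position has no segmented slice are skipped with a warning.
    """
    by_pos = {(s.center[0], s.center[1], s.plane): s for s in slices}
    nuclei: list[Nucleus] = []
    next_id = 1
    skipped = 0
    for seed in sorted(seeds, key=lambda s: (-s.response_value, s.position)):
        y, x, z = seed.position
        seed_slice = by_pos.get((float(y), float(x), z))
        if seed_slice is None:
            skipped += 1
            logger.warning("seed at (y=%d, x=%d, z=%d) has no segmented slice; skipped", y, x, z)
            continue
        nuclei.append(extract_nucleus(seed_slice, slices, model, config, nucleus_id=next_id))
        next_id += 1
    result = SegmentationResult(nuclei=nuclei, slices=slices)
    result.stage_log["seeds_found"] = len(seeds)
    result.stage_log["seeds_skipped"] = skipped
    result.stage_log["nuclei_seeded"] = len(nuclei)
    return result


def recover_overlooked(
    result: SegmentationResult,
    model: ShapeModel,
    config: Config,
) -> SegmentationResult:
    """Iteratively seed new nuclei in clusters of unclaimed slices.

    Any unclaimed slice with at least ``min_cluster`` unclaimed slices
    (itself included) inside a physical sphere of ``recovery_radius``
    micrometers qualifies as a cluster; a nucleus is seeded at the brightest
    qualifying slice and extracted from the *full* slice set (claimed slices
    included), and the search repeats until no cluster remains. Each
    iteration claims the previously unclaimed seed slice, so the loop
    terminates within the number of slices.
    """
    sx, sz = config.xy_spacing, config.z_spacing
    next_id = max((n.id for n in result.nuclei), default=0) + 1
    recovered = 0
    while True:
        unclaimed = [s for s in result.slices if not s.claimed_by]
        if len(unclaimed) < config.min_cluster:
            break
        pos = np.array([[s.center[0] * sx, s.center[1] * sx, s.plane * sz] for s in unclaimed])
        r = config.recovery_radius
        best = None
        for i, s in enumerate(unclaimed):
            n_near = int(np.sum(np.linalg.norm(pos - pos[i], axis=1) <= r))
            if n_near >= config.min_cluster:
                if best is None or s.peak_response > best.peak_response:
                    best = s
        if best is None:
            break
        nuc = extract_nucleus(
            best, result.slices, model, config, nucleus_id=next_id, status="recovered"
        )
        result.nuclei.append(nuc)
        next_id += 1
        recovered += 1
    result.stage_log["nuclei_recovered"] = recovered
    return result


# ---------------------------------------------------------------------------
# conflict resolution


def _contiguous(planes: list[int]) -> bool:
    ps = sorted(set(planes))
    return ps == list(range(ps[0], ps[-1] + 1))


def _score_membership(
    slice_ids: list[int],
    center: NuclearSlice,
    slices_by_id: dict[int, NuclearSlice],
    model: ShapeModel,
) -> float:
    """Total member log odds of a slice set against a given center slice.

    Slices are scored in order of distance from the center plane, each using
    the previously scored slice on the neighboring plane toward the center as
    its intervening slice (the same chain the claiming walk uses).
    """
    members = sorted((slices_by_id[i] for i in slice_ids), key=lambda s: s.plane)
    by_plane = {s.plane: s for s in members}
    total = 0.0
    for s in members:
        if s.plane == center.plane:
            continue
        step = 1 if s.plane < center.plane else -1
        iv = by_plane.get(s.plane + step)
        if iv is None or iv.plane == center.plane:
            iv = center
        f = compute_features(s, center, iv)
        _, log_odds = classify(f, model)
        total += log_odds
    return total


def _merge_center(
    slice_ids: list[int], slices_by_id: dict[int, NuclearSlice], config: Config
) -> NuclearSlice:
    """The slice closest to the geometric middle of the merged set."""
    members = [slices_by_id[i] for i in slice_ids]
    sx, sz = config.xy_spacing, config.z_spacing
    pts = np.array([[s.center[0] * sx, s.center[1] * sx, s.plane * sz] for s in members])
    middle = pts.mean(axis=0)
    dists = np.linalg.norm(pts - middle, axis=1)
    return members[int(np.argmin(dists))]


def resolve_conflicts(
    result: SegmentationResult,
    model: ShapeModel,
    config: Config,
) -> SegmentationResult:
    """Arbitrate overlapping claims: merge redundant nuclei or split overlaps.

    For every pair of nuclei sharing at least ``overlap_min_shared`` slices
    (processed in descending shared-slice count, rescanning after each applied
    decision), two configurations are scored against the shape model:

    * **merge** — the union of both slice sets treated as one nucleus whose
      center is the slice closest to the geometric middle of the merged set;
      score is the total member log odds of all slices against that center;
    * **split** — each contested slice assigned to the nucleus with the
      stronger claim on it, provided both nuclei stay plane-contiguous;
      score is the sum of both nuclei's claims on their remaining slices.

    The higher-scoring configuration is applied (ties and infeasible splits
    fall back to merge). Afterwards no slice has more than one claimant.
    """
    slices_by_id = result.slices_by_id
    merges = 0
    while True:
        by_id = {n.id: n for n in result.nuclei}
        # find the pair with the largest overlap
        best_pair, best_shared = None, 0
        ids = sorted(by_id)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                shared = set(by_id[a].member_slice_ids) & set(by_id[b].member_slice_ids)
                if len(shared) >= max(config.overlap_min_shared, 1) and len(shared) > best_shared:
                    best_pair, best_shared = (a, b), len(shared)
        if best_pair is None:
            break
        na, nb = by_id[best_pair[0]], by_id[best_pair[1]]
        shared = sorted(set(na.member_slice_ids) & set(nb.member_slice_ids))
        merged_ok, merge_score, merge_members, merge_center = _plan_merge(
            na, nb, slices_by_id, model, config
        )
        split_ok, split_score, split_assign = _plan_split(na, nb, shared, slices_by_id)
        if split_ok and (not merged_ok or split_score > merge_score):
            _apply_split(na, nb, split_assign, slices_by_id)
        else:
            _apply_merge(result, na, nb, merge_members, merge_center, slices_by_id, model)
            merges += 1
    result.stage_log["nuclei_merged"] = merges
    _finalize_claims(result)
    return result


def _plan_merge(na: Nucleus, nb: Nucleus, slices_by_id, model, config):
    union = sorted(set(na.member_slice_ids) | set(nb.member_slice_ids))
    members = [slices_by_id[i] for i in union]
    # a merged nucleus keeps one slice per plane: where both nuclei contributed
    # distinct slices on the same plane, keep the stronger-scoring one later;
    # first pick the center, then resolve per-plane duplicates against it
    center = _merge_center(union, slices_by_id, config)
    by_plane: dict[int, list[NuclearSlice]] = {}
    for s in members:
        by_plane.setdefault(s.plane, []).append(s)
    kept: list[int] = []
    for z in sorted(by_plane):
        pool = by_plane[z]
        if len(pool) == 1 or z == center.plane:
            chosen = center if z == center.plane else pool[0]
            if z == center.plane and center not in pool:
                chosen = pool[0]
        else:
            # keep the slice scoring higher as a member relative to the center
            def solo_score(s: NuclearSlice) -> float:
                if s.plane == center.plane:
                    return np.inf
                f = compute_features(s, center, center)
                return classify(f, model)[1]

            chosen = max(pool, key=solo_score)
        kept.append(chosen.id)
    planes = [slices_by_id[i].plane for i in kept]
    if not _contiguous(planes):
        return False, -np.inf, kept, center
    score = _score_membership(kept, center, slices_by_id, model)
    return True, score, kept, center


def _plan_split(na: Nucleus, nb: Nucleus, shared: list[int], slices_by_id):
    assign: dict[int, int] = {}
    for sid in shared:
        ca = na.claim_strengths.get(sid, -np.inf)
        cb = nb.claim_strengths.get(sid, -np.inf)
        assign[sid] = na.id if ca >= cb else nb.id
    new_a = [i for i in na.member_slice_ids if i not in assign or assign[i] == na.id]
    new_b = [i for i in nb.member_slice_ids if i not in assign or assign[i] == nb.id]
    if not new_a or not new_b:
        return False, -np.inf, assign
    for nuc, mem in ((na, new_a), (nb, new_b)):
        if nuc.center_slice_id not in mem:
            return False, -np.inf, assign
        if not _contiguous([slices_by_id[i].plane for i in mem]):
            return False, -np.inf, assign
    score = sum(na.claim_strengths[i] for i in new_a) + sum(
        nb.claim_strengths[i] for i in new_b
    )
    return True, score, assign


def _apply_split(na: Nucleus, nb: Nucleus, assign: dict[int, int], slices_by_id) -> None:
    for sid, owner in assign.items():
        loser = nb if owner == na.id else na
        if sid in loser.member_slice_ids:
            loser.member_slice_ids.remove(sid)
            loser.claim_strengths.pop(sid, None)
            slices_by_id[sid].claimed_by.discard(loser.id)


def _apply_merge(result, na: Nucleus, nb: Nucleus, kept: list[int], center, slices_by_id, model):
    union = set(na.member_slice_ids) | set(nb.member_slice_ids)
    strengths: dict[int, float] = {}
    for sid in kept:
        s = slices_by_id[sid]
        if s.plane == center.plane:
            strengths[sid] = 0.0
        else:
            f = compute_features(s, center, center)
            strengths[sid] = classify(f, model)[1]
    merged = Nucleus(
        id=na.id,
        center_slice_id=center.id,
        member_slice_ids=sorted(kept, key=lambda i: slices_by_id[i].plane),
        claim_strengths=strengths,
        status="merged",
    )
    for sid in union:
        slices_by_id[sid].claimed_by.discard(na.id)
        slices_by_id[sid].claimed_by.discard(nb.id)
    for sid in kept:
        slices_by_id[sid].claimed_by.add(merged.id)
    result.nuclei = [n for n in result.nuclei if n.id not in (na.id, nb.id)] + [merged]
    result.nuclei.sort(key=lambda n: n.id)


def _finalize_claims(result: SegmentationResult) -> None:
    """Assert the post-resolution invariants on every pipeline run."""
    by_id = result.slices_by_id
    for s in result.slices:
        if len(s.claimed_by) > 1:
            raise AssertionError(f"slice {s.id} still claimed by {sorted(s.claimed_by)}")
    for n in result.nuclei:
        if not n.member_slice_ids:
            raise AssertionError(f"nucleus {n.id} has no member slices")
        if not _contiguous([by_id[i].plane for i in n.member_slice_ids]):
            raise AssertionError(f"nucleus {n.id} spans non-contiguous planes")


# ---------------------------------------------------------------------------
# full pipeline


def result_to_record(
    result: SegmentationResult, volume_name: str = "", config: Config | None = None
) -> DetectionRecord:
    by_id = result.slices_by_id
    entries = []
    for n in sorted(result.nuclei, key=lambda n: n.id):
        y, x, z = n.centroid(by_id)
        entries.append(
            NucleusEntry(
                id=n.id, x=x, y=y, z=z, diameter=n.diameter(by_id), status=n.status
            )
        )
    return DetectionRecord(
        entries,
        volume_name=volume_name,
        config_snapshot=config.to_dict() if config else {},
    )


def detect(
    volume: ImageVolume,
    model: ShapeModel,
    config: Config,
    return_result: bool = False,
    stage_records: dict | None = None,
) -> DetectionRecord | tuple[DetectionRecord, SegmentationResult]:
    """Run the full pipeline: filter, segment slices, extract, recover, resolve.

    ``stage_records``, if given a dict, receives intermediate DetectionRecords
    under keys ``"seeded"`` (after greedy extraction) and ``"recovered"``
    (after recovery), enabling per-stage error accounting.
    """
    config = config.with_spacing(volume.spacing)
    filtered = dog_filter(volume, config)
    maxima2d = find_2d_maxima(filtered, config.base_threshold)
    maxima3d = find_3d_maxima(filtered, config.noise_threshold)
    slices = segment_all_slices(volume, filtered, config, maxima2d=maxima2d)
    result = extract_all(maxima3d, slices, model, config)
    result.stage_log["slices_segmented"] = len(slices)
    if stage_records is not None:
        stage_records["seeded"] = result_to_record(result, volume.name, config)
    result = recover_overlooked(result, model, config)
    if stage_records is not None:
        stage_records["recovered"] = result_to_record(result, volume.name, config)
    result = resolve_conflicts(result, model, config)
    record = result_to_record(result, volume.name, config)
    if return_result:
        return record, result
    return record
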