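"""Nucleus assembly: claiming, recovery, conflict resolution, full pipeline."""

from dataclasses import replace

import numpy as np
import pytest

from blobslice.extraction import (
    detect,
    extract_all,
    extract_nucleus,
    recover_overlooked,
    resolve_conflicts,
)
from blobslice.filtering import dog_filter, find_3d_maxima
from blobslice.metrics import match_detections
from blobslice.slices import segment_all_slices
from blobslice.synthetic_data import (
    NucleusSpec,
    crowded_spec,
    default_benchmark_spec,
    default_config,
    generate_scene,
    render_scene,
)
from blobslice.volume_io import ImageVolume


def _segment(vol, cfg):
    f = dog_filter(vol, cfg)
    slices = segment_all_slices(vol, f, cfg)
    seeds = find_3d_maxima(f, cfg.noise_threshold)
    return f, slices, seeds


def _mini_scene(nuclei, shape=(64, 64, 20), seed=0, **spec_overrides):
    base = dict(shape=shape, n_modes=0, depth_fade=0.0)
    base.update(spec_overrides)
    spec = replace(default_benchmark_spec(), **base)
    vol = render_scene(nuclei, spec, np.random.default_rng(seed))
    cfg = default_config(spec).with_spacing(vol.spacing)
    return spec, vol, cfg


class TestExtractNucleus:
    def test_isolated_nucleus_claims_its_slices(self, shape_model):
        nuc = NucleusSpec(1, (30.0, 30.0, 25.0), (4.0, 4.0, 4.0), 100.0)
        _, vol, cfg = _mini_scene([nuc])
        _, slices, seeds = _segment(vol, cfg)
        assert len(seeds) == 1
        y, x, z = seeds[0].position
        seed_slice = next(s for s in slices if s.center == (y, x) and s.plane == z)
        n = extract_nucleus(seed_slice, slices, shape_model, cfg)
        member_planes = sorted({next(s for s in slices if s.id == i).plane
                                for i in n.member_slice_ids})
        # central 3 geometric cross-sections must all be claimed, contiguously
        assert len(member_planes) >= 3
        assert member_planes == list(range(member_planes[0], member_planes[-1] + 1))
        for i in n.member_slice_ids:
            assert n.id in next(s for s in slices if s.id == i).claimed_by

    def test_bare_seed_is_single_slice_nucleus(self, shape_model, benchmark_config):
        from tests.test_shape_model import make_slice

        lone = make_slice(0, 30, 30, 5)
        n = extract_nucleus(lone, [lone], shape_model, benchmark_config)
        assert n.member_slice_ids == [0]

    def test_touching_stacked_nuclei_claim_own_slices(self, shape_model):
        a = NucleusSpec(1, (30.0, 30.0, 16.0), (4.0, 4.0, 4.0), 110.0)
        b = NucleusSpec(2, (30.0, 31.0, 25.0), (4.0, 4.0, 4.0), 90.0)
        _, vol, cfg = _mini_scene([a, b])
        _, slices, seeds = _segment(vol, cfg)
        assert len(seeds) == 2
        result = extract_all(seeds, slices, shape_model, cfg)
        result = resolve_conflicts(result, shape_model, cfg)
        assert len(result.nuclei) == 2
        by_id = result.slices_by_id
        cents = sorted(n.centroid(by_id)[2] for n in result.nuclei)
        assert cents[0] == pytest.approx(16.0 / 2.5, abs=1.0)
        assert cents[1] == pytest.approx(25.0 / 2.5, abs=1.0)


class TestExtractAll:
    def test_zero_seeds_all_unclaimed(self, benchmark_slices, shape_model, benchmark_config):
        for s in benchmark_slices:
            s.claimed_by.clear()
        result = extract_all([], benchmark_slices, shape_model, benchmark_config)
        assert result.nuclei == []
        assert len(result.unclaimed_slice_ids) == len(benchmark_slices)

    def test_separated_nuclei_all_claimed(self, shape_model):
        centers = [(18, 18, 12), (18, 46, 36), (46, 18, 24), (46, 46, 12)]
        nuclei = [
            NucleusSpec(i + 1, (float(y), float(x), float(z)), (4.0, 4.0, 4.0), 100.0)
            for i, (y, x, z) in enumerate(centers)
        ]
        _, vol, cfg = _mini_scene(nuclei, noise_sd=0.5)
        _, slices, seeds = _segment(vol, cfg)
        result = extract_all(seeds, slices, shape_model, cfg)
        assert len(result.nuclei) == 4
        # isolated bright nuclei leave at most their faint blur-tail slices
        assert len(result.unclaimed_slice_ids) <= len(slices) - 3 * 4

    def test_deterministic(self, benchmark_scene, shape_model, benchmark_config):
        r1 = detect(benchmark_scene.volume, shape_model, benchmark_config)
        r2 = detect(benchmark_scene.volume, shape_model, benchmark_config)
        assert [(n.id, n.x, n.y, n.z, n.diameter, n.status) for n in r1.nuclei] == [
            (n.id, n.x, n.y, n.z, n.diameter, n.status) for n in r2.nuclei
        ]


class TestRecovery:
    def test_all_claimed_unchanged(self, shape_model):
        nuc = NucleusSpec(1, (30.0, 30.0, 25.0), (4.0, 4.0, 4.0), 100.0)
        _, vol, cfg = _mini_scene([nuc])
        _, slices, seeds = _segment(vol, cfg)
        result = extract_all(seeds, slices, shape_model, cfg)
        for s in slices:  # claim everything by hand
            if not s.claimed_by:
                s.claimed_by.add(result.nuclei[0].id)
        n_before = len(result.nuclei)
        result = recover_overlooked(result, shape_model, cfg)
        assert len(result.nuclei) == n_before
        assert result.stage_log["nuclei_recovered"] == 0

    def test_single_isolated_unclaimed_slice_not_recovered(
        self, shape_model, benchmark_config
    ):
        from blobslice.extraction import SegmentationResult
        from tests.test_shape_model import make_slice

        lone = make_slice(0, 30, 30, 5)
        result = SegmentationResult(nuclei=[], slices=[lone])
        result = recover_overlooked(result, shape_model, benchmark_config)
        assert result.nuclei == []

    def test_masked_dim_nucleus_recovered(self, shape_model):
        """A dim nucleus beside a bright one is not a 3D maximum but its
        slices survive segmentation; recovery must find it."""
        bright = NucleusSpec(1, (30.0, 30.0, 15.0), (4.5, 4.5, 4.5), 140.0)
        dim = NucleusSpec(2, (31.0, 30.0, 23.5), (4.0, 4.0, 4.0), 40.0)
        _, vol, cfg = _mini_scene([bright, dim], seed=3)
        _, slices, seeds = _segment(vol, cfg)
        result = extract_all(seeds, slices, shape_model, cfg)
        truth_missing = len(seeds) < 2
        result = recover_overlooked(result, shape_model, cfg)
        result = resolve_conflicts(result, shape_model, cfg)
        by_id = result.slices_by_id
        cz = [n.centroid(by_id)[2] * 2.5 for n in result.nuclei]
        assert truth_missing, "scene no longer masks the dim nucleus"
        assert any(abs(c - 23.5) < 4.0 for c in cz), f"dim nucleus not recovered: z={cz}"
        assert any(n.status == "recovered" for n in result.nuclei)


class TestConflictResolution:
    def test_no_overlap_unchanged(self, shape_model):
        centers = [(18, 18, 12), (46, 46, 36)]
        nuclei = [
            NucleusSpec(i + 1, (float(y), float(x), float(z)), (4.0, 4.0, 4.0), 100.0)
            for i, (y, x, z) in enumerate(centers)
        ]
        _, vol, cfg = _mini_scene(nuclei)
        _, slices, seeds = _segment(vol, cfg)
        result = extract_all(seeds, slices, shape_model, cfg)
        before = {n.id: sorted(n.member_slice_ids) for n in result.nuclei}
        result = resolve_conflicts(result, shape_model, cfg)
        after = {n.id: sorted(n.member_slice_ids) for n in result.nuclei}
        assert before == after
        assert result.stage_log["nuclei_merged"] == 0

    def test_split_nucleus_merged_to_one(self, shape_model):
        """An oversized nucleus with two axial intensity modes seeds twice;
        the merge option must win and leave a single detection."""
        big = NucleusSpec(1, (30.0, 30.0, 25.0), (7.0, 6.8, 7.2), 100.0)
        spec, vol, cfg = _mini_scene(
            [big], shape=(72, 72, 24), n_modes=2, mode_amplitude=0.5, mode_placement="z"
        )
        # spec override above re-enables modes; keep the detection filter
        # sized for the *typical* nucleus (8 px), not this oversized one
        _, slices, seeds = _segment(vol, cfg)
        assert len(seeds) == 2, "scene must double-seed the nucleus"
        result = extract_all(seeds, slices, shape_model, cfg)
        result = resolve_conflicts(result, shape_model, cfg)
        assert len(result.nuclei) == 1
        assert result.nuclei[0].status == "merged"
        assert result.stage_log["nuclei_merged"] == 1

    def test_contested_boundary_slice_goes_to_stronger_claim(self, shape_model):
        """Two real stacked nuclei disputing boundary slices stay two."""
        a = NucleusSpec(1, (30.0, 30.0, 15.0), (4.2, 4.2, 4.4), 120.0)
        b = NucleusSpec(2, (30.0, 31.0, 24.0), (4.0, 4.0, 4.2), 100.0)
        _, vol, cfg = _mini_scene([a, b], seed=0)
        _, slices, seeds = _segment(vol, cfg)
        result = extract_all(seeds, slices, shape_model, cfg)
        result = resolve_conflicts(result, shape_model, cfg)
        assert len(result.nuclei) == 2
        for s in result.slices:
            assert len(s.claimed_by) <= 1


class TestDetectPipeline:
    def test_empty_volume_empty_record(self, shape_model):
        cfg = default_config(default_benchmark_spec())
        vol = ImageVolume(np.zeros((48, 48, 12)), (1, 1, 2.5))
        rec = detect(vol, shape_model, cfg)
        assert len(rec) == 0

    def test_benchmark_scene_error_within_1pct(
        self, benchmark_scene, shape_model, benchmark_config
    ):
        rec = detect(benchmark_scene.volume, shape_model, benchmark_config)
        tol = benchmark_config.nuclear_diameter / 2 * benchmark_config.xy_spacing
        rep = match_detections(benchmark_scene.truth, rec, benchmark_scene.spacing, tol)
        assert rep.total_error <= 1.0

    def test_pipeline_invariants_on_crowded_scene(self, shape_model):
        """Claim uniqueness and plane contiguity hold after resolution."""
        scene = generate_scene(crowded_spec(seed=11))
        cfg = default_config(scene.spec).with_spacing(scene.spacing)
        rec, result = detect(scene.volume, shape_model, cfg, return_result=True)
        by_id = result.slices_by_id
        for s in result.slices:
            assert len(s.claimed_by) <= 1
        for n in result.nuclei:
            planes = sorted(by_id[i].plane for i in n.member_slice_ids)
            assert planes == list(range(planes[0], planes[-1] + 1))
            assert n.center_slice_id in n.member_slice_ids or n.status == "merged"
        assert {e.status for e in rec.nuclei} <= {"seeded", "recovered", "merged"}

    def test_stage_monotonicity_on_crowded_scene(self, shape_model):
        """Recovery never raises FN; resolution never raises FP."""
        scene = generate_scene(crowded_spec(seed=23))
        cfg = default_config(scene.spec).with_spacing(scene.spacing)
        stages = {}
        rec = detect(scene.volume, shape_model, cfg, stage_records=stages)
        tol = cfg.nuclear_diameter / 2 * cfg.xy_spacing
        reps = [
            match_detections(scene.truth, r, scene.spacing, tol)
            for r in (stages["seeded"], stages["recovered"], rec)
        ]
        assert reps[1].false_negatives <= reps[0].false_negatives
        assert reps[2].false_positives <= reps[1].false_positives
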