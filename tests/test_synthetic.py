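import numpy as np
import pytest

import uvtrace as uv
from uvtrace.design import STAFF_ROLES
from uvtrace.segmentation import to_lab
from uvtrace.synthetic import Deposit, TransferKernel, _draw_blob


def zero_kernels():
    return [TransferKernel(role=r, deposits=[]) for r in STAFF_ROLES]


class TestDefaultDesign:
    def test_study_constants(self):
        d = uv.default_design()
        assert d.n_participants == 12
        assert len(d.teams) == 3
        assert all(len(t.roles) == 4 for t in d.teams)
        team_c = next(t for t in d.teams if t.name == "C")
        assert len(team_c.stages) == 3
        assert "post_don" not in team_c.stages
        assert [e.distance_mm for e in d.spit_events] == [150.0, 300.0]
        assert d.episode_duration_min == 4.5
        assert d.control_subjects == 1

    def test_one_patient_per_team_enforced(self):
        d = uv.default_design()
        bad = uv.TeamSpec(name="X", ppe_set="A", stages=("pre_don",), roles=("one", "two", "three", "one"))
        with pytest.raises(ValueError, match="patient"):
            uv.ExperimentDesign(teams=[bad], dyes=d.dyes, spit_events=d.spit_events)

    def test_design_yaml_round_trip(self, tmp_path):
        d = uv.default_design((256, 128), seed=3)
        d.to_yaml(tmp_path / "design.yaml")
        d2 = uv.ExperimentDesign.from_yaml(tmp_path / "design.yaml")
        assert d2.n_participants == 12
        assert d2.image_shape == (256, 128)
        assert [t.stages for t in d2.teams] == [t.stages for t in d.teams]


class TestSimulateTransfer:
    def test_deterministic_for_fixed_seed(self, small_design):
        a = uv.simulate_transfer(small_design, uv.default_kernels(), seed=9)
        b = uv.simulate_transfer(small_design, uv.default_kernels(), seed=9)
        for sid in a.subjects:
            for stage, masks in a.subjects[sid].stage_masks.items():
                for dye, mask in masks.items():
                    assert np.array_equal(mask, b.subjects[sid].stage_masks[stage][dye])

    def test_zero_transfer_leaves_every_staff_mask_empty(self, small_design):
        truth = uv.simulate_transfer(
            small_design, zero_kernels(), seed=1,
            control_deposits=[], baseline_blue_px=0,
        )
        for subj in truth.staff_subjects():
            for masks in subj.stage_masks.values():
                assert all(m.sum() == 0 for m in masks.values())

    def test_spit_dye_reaches_only_roles_one_and_two(self, small_truth):
        for subj in small_truth.subjects.values():
            red = sum(m["red"].sum() for m in subj.stage_masks.values())
            if subj.role in ("one", "two"):
                assert subj.stage_masks["post_pi"]["red"].sum() > 0
            elif subj.role in ("three", "control"):
                assert red == 0

    def test_exact_pixel_budget_lands_in_destination_zone(self):
        # single kernel depositing exactly 500 green px in role-two hands
        design = uv.default_design((1024, 512), seed=0)
        kernels = [
            TransferKernel(role="one", deposits=[]),
            TransferKernel(role="two", deposits=[Deposit("green", "hands", 500, 5.0)]),
            TransferKernel(role="three", deposits=[]),
        ]
        truth = uv.simulate_transfer(
            design, kernels, seed=0, control_deposits=[], baseline_blue_px=0
        )
        subj = next(s for s in truth.staff_subjects() if s.role == "two")
        mask = subj.stage_masks["post_pi"]["green"]
        # brute-force pixel counts on the constructed mask
        assert int(mask.sum()) == 500
        assert int((mask & subj.zones["hands"]).sum()) == 500
        assert subj.zone_counts("post_pi", "green")["hands"] == 500

    def test_unknown_zone_in_kernel_rejected(self, small_design):
        kernels = zero_kernels()
        kernels[0].deposits.append(Deposit("green", "tail", 10))
        with pytest.raises(ValueError, match="unknown zone"):
            uv.simulate_transfer(small_design, kernels, seed=0)

    def test_missing_role_rejected(self, small_design):
        with pytest.raises(ValueError, match="missing"):
            uv.simulate_transfer(small_design, zero_kernels()[:2], seed=0)

    def test_zone_counts_conserve_mask_totals(self, small_truth):
        # deposits land inside zones, so zonal counts must tile the mask
        for subj in small_truth.subjects.values():
            for stage in subj.stage_masks:
                for dye in small_truth.design.dye_names:
                    counts = subj.zone_counts(stage, dye)
                    assert sum(counts.values()) == subj.total(stage, dye)

    def test_accumulation_monotone_through_post_pi(self, small_design):
        truth = uv.simulate_transfer(
            small_design, uv.default_kernels(), seed=2,
            cleansing={z: 0.0 for z in uv.ZONE_NAMES},
        )
        for subj in truth.subjects.values():
            stages = [s for s in ("pre_don", "post_don", "post_pi") if s in subj.stage_masks]
            totals = [subj.total(s) for s in stages]
            assert totals == sorted(totals)
            # with zero cleansing efficiency nothing is removed at doffing
            if "post_doff" in subj.stage_masks:
                assert subj.total("post_doff") == subj.total("post_pi")

    def test_dye_masks_disjoint_within_stage(self, small_truth):
        for subj in small_truth.subjects.values():
            for masks in subj.stage_masks.values():
                total = np.zeros(subj.foreground.shape, np.int32)
                for m in masks.values():
                    total += m.astype(np.int32)
                assert total.max() <= 1


class TestRenderPhotoPair:
    def test_deterministic_for_fixed_seed(self, small_truth):
        a = uv.render_photo_pair(small_truth, "A1", "post_pi", seed=5)
        b = uv.render_photo_pair(small_truth, "A1", "post_pi", seed=5)
        assert np.array_equal(a.uv, b.uv)
        assert np.array_equal(a.visible, b.visible)

    def test_unknown_subject_or_stage_raises(self, small_truth):
        with pytest.raises(KeyError, match="unknown subject"):
            uv.render_photo_pair(small_truth, "Z9", "post_pi")
        with pytest.raises(KeyError, match="no stage"):
            uv.render_photo_pair(small_truth, "OBS1", "pre_don")

    def test_clean_subject_has_no_pixels_near_any_dye_color(self, small_design):
        truth = uv.simulate_transfer(
            small_design, zero_kernels(), seed=1,
            control_deposits=[], baseline_blue_px=0,
        )
        pair = uv.render_photo_pair(truth, "A1", "post_pi", uv.artefact_free(), seed=1)
        lab = to_lab(pair.uv).reshape(-1, 3)
        for dye in small_design.dyes:
            centroid = to_lab(np.array(dye.color_rgb, np.uint8).reshape(1, 1, 3)).reshape(3)
            dist = np.linalg.norm(lab - centroid, axis=1)
            assert dist.min() > 25.0

    def test_full_overexposure_pushes_contamination_above_lstar_97(self, small_truth):
        art = uv.ArtefactModel(overexposure_fraction=1.0, confounder_items=[], noise_sd=0.0)
        pair = uv.render_photo_pair(small_truth, "A1", "post_pi", art, seed=1)
        union = np.zeros(pair.uv.shape[:2], bool)
        for m in small_truth.subjects["A1"].stage_masks["post_pi"].values():
            union |= m
        lstar = to_lab(pair.uv)[..., 0]
        assert (lstar[union] > 97.0).all()

    def test_confounder_patch_appears_but_is_absent_from_truth(self, small_truth):
        from scipy.ndimage import label as cc_label

        art = uv.ArtefactModel(
            overexposure_fraction=0.0,
            confounder_items=[("hands", (80, 150, 225))],
            noise_sd=0.0,
        )
        pair = uv.render_photo_pair(small_truth, "A3", "post_pi", art, seed=1)
        subj = small_truth.subjects["A3"]
        truth_union = np.zeros(subj.foreground.shape, bool)
        for m in subj.stage_masks["post_pi"].values():
            truth_union |= m
        in_hands = pair.exclusion & subj.zones["hands"]
        n_components = cc_label(in_hands)[1]
        assert n_components >= 1
        assert not (pair.exclusion & truth_union).any()


def test_draw_blob_exact_area(rng):
    allowed = np.zeros((50, 50), bool)
    allowed[10:40, 10:40] = True
    blob = _draw_blob(rng, allowed, 123, spread=4.0)
    assert blob.sum() == 123
    assert not (blob & ~allowed).any()
    # request exceeding availability saturates at the allowed size
    blob = _draw_blob(rng, allowed, 10_000, spread=4.0)
    assert blob.sum() == allowed.sum()


def test_write_scene_layout(tmp_path, small_truth):
    manifest = uv.write_scene(small_truth, tmp_path / "scene", seed=1)
    assert (tmp_path / "scene" / "design.yaml").exists()
    assert (tmp_path / "scene" / "reference_uv.png").exists()
    row = manifest.iloc[0]
    assert (tmp_path / "scene" / row.team / row.subject).is_dir()
    stages_a1 = manifest[manifest.subject == "A1"].stage.tolist()
    assert stages_a1 == ["pre_don", "post_don", "post_pi", "post_doff"]
    # team C subjects have three photo stages
    stages_c1 = manifest[manifest.subject == "C1"].stage.tolist()
    assert len(stages_c1) == 3
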