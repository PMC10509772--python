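"""Two-stage rotation to neutral, resampling and angle decomposition."""

import json

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hipbmd import (
    DensityVolume,
    LandmarkSet,
    PoseError,
    PoseTransform,
    angles_from_landmarks,
    compose_transforms,
    decompose_angles,
    resample_trilinear,
    shaft_axis,
    stage1_transform,
    stage2_transform,
    transform_landmarks,
)
from hipbmd.synthetic_data import PoseParams

ORIGIN = np.zeros(3)


def lm_from(points, frame="original"):
    return LandmarkSet({k: np.asarray(v, float) for k, v in points.items()},
                       frame=frame)


class TestShaftAxis:
    def test_vertical_shaft(self):
        lm = lm_from({"LT_DISTAL_2CM": (0, 0, -20), "LT_DISTAL_5CM": (0, 0, -50)})
        assert np.allclose(shaft_axis(lm), (0, 0, 1))

    def test_hand_normalized_direction(self):
        lm = lm_from({"LT_DISTAL_2CM": (10, 0, 30), "LT_DISTAL_5CM": (0, 0, 0)})
        assert np.allclose(shaft_axis(lm), np.array([10, 0, 30]) / np.sqrt(1000))

    def test_coincident_points_rejected(self):
        with pytest.raises(Exception):
            lm_from({"LT_DISTAL_2CM": (1, 2, 3), "LT_DISTAL_5CM": (1, 2, 3)})


class TestStage1:
    def test_identity_for_vertical_axis(self):
        t = stage1_transform((0, 0, 1), ORIGIN)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)

    @pytest.mark.parametrize(
        "axis, expected",
        [
            # 20 deg tilt purely in the coronal (x-z) plane
            ((np.sin(np.radians(20)), 0, np.cos(np.radians(20))), (20.0, 0.0)),
            # 10 deg tilt purely in the sagittal (y-z) plane
            ((0, np.sin(np.radians(10)), np.cos(np.radians(10))), (0.0, 10.0)),
        ],
    )
    def test_pure_plane_tilts(self, axis, expected):
        t1 = stage1_transform(axis, ORIGIN)
        # the minimal rotation maps the axis exactly onto +z
        assert np.allclose(t1.rotation @ np.asarray(axis), (0, 0, 1), atol=1e-9)
        # independent construction: scipy's align_vectors for a single pair
        # returns the same minimal rotation
        expected_rot, _ = Rotation.align_vectors([(0, 0, 1)], [axis])
        assert np.allclose(t1.rotation, expected_rot.as_matrix(), atol=1e-9)
        t2 = PoseTransform(np.eye(3), ORIGIN, "stage2")
        ang = decompose_angles(t1, t2)
        assert ang.abduction == pytest.approx(expected[0], abs=1e-9)
        assert ang.flexion == pytest.approx(expected[1], abs=1e-9)

    def test_antiparallel_axis_rejected(self):
        with pytest.raises(PoseError):
            stage1_transform((0, 0, -1), ORIGIN)


class TestStage2:
    def test_neck_already_coronal_is_identity(self):
        lm = lm_from({"HEAD_CENTER": (-40, 0, 30), "NECK_CENTER": (-20, 0, 15)},
                     frame="stage1")
        t = stage2_transform(lm, lm["HEAD_CENTER"])
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)

    def test_30_deg_anteversion_compensated(self):
        av = np.radians(30)
        neck = np.array([-20, 0, 15])
        head = neck + 25 * np.array([-np.cos(av), -np.sin(av), 0.7])
        lm = lm_from({"HEAD_CENTER": head, "NECK_CENTER": neck}, frame="stage1")
        t2 = stage2_transform(lm, head)
        ang = decompose_angles(PoseTransform(np.eye(3), ORIGIN, "stage1"), t2)
        assert ang.axial_rotation == pytest.approx(30.0, abs=1e-9)
        # post-condition: rotated neck axis has no anteroposterior component
        # and points medially (-x)
        v = t2.apply(head) - t2.apply(neck)
        assert abs(v[1]) < 1e-9
        assert v[0] < 0

    def test_vertical_neck_axis_rejected(self):
        lm = lm_from({"HEAD_CENTER": (-20, 0, 40), "NECK_CENTER": (-20, 0, 10)},
                     frame="stage1")
        with pytest.raises(PoseError):
            stage2_transform(lm, lm["HEAD_CENTER"])


class TestResample:
    def geometry(self, voxels):
        return DensityVolume(voxels, (1, 1, 1), (0, 0, 0), np.eye(3))

    def test_identity_transform_exact(self, rng):
        vol = self.geometry(rng.uniform(0, 100, (12, 12, 12)))
        out = resample_trilinear(vol, PoseTransform.identity())
        assert np.abs(out.voxels - vol.voxels).max() < 1e-12

    def test_rotated_ball_conserves_mass(self):
        shape = (50, 50, 50)
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        ball = (((ii - 24.5) ** 2 + (jj - 24.5) ** 2 + (kk - 24.5) ** 2)
                <= 15**2) * 500.0
        vol = self.geometry(ball)
        rot = Rotation.from_rotvec([0.3, -0.5, 0.8]).as_matrix()
        t = PoseTransform(rot, np.full(3, 24.5), "composite")
        out = resample_trilinear(vol, t)
        assert out.voxels.sum() == pytest.approx(ball.sum(), rel=0.005)

    def test_rotate_then_inverse_on_smooth_field(self):
        shape = (50, 50, 50)
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        f = (np.sin(2 * np.pi * ii / 50) * np.cos(2 * np.pi * jj / 50)
             * np.sin(2 * np.pi * kk / 50 + 1) + 3.0)
        vol = self.geometry(f)
        rot = Rotation.from_euler("xyz", [15, 10, 8], degrees=True).as_matrix()
        pivot = np.full(3, 24.5)
        fwd = PoseTransform(rot, pivot, "composite")
        back = PoseTransform(rot.T, pivot, "composite")
        out = resample_trilinear(resample_trilinear(vol, fwd), back).voxels
        r2 = (ii - 24.5) ** 2 + (jj - 24.5) ** 2 + (kk - 24.5) ** 2
        inner = r2 < 14**2
        rel = np.abs(out[inner] - f[inner]) / np.abs(f[inner])
        assert rel.max() < 0.01


class TestTransformLandmarks:
    def test_identity_and_fixed_point(self, neutral_bundle):
        _, _, gt = neutral_bundle
        rot = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        pivot = gt.landmarks["HEAD_CENTER"]
        t = PoseTransform(rot, pivot, "stage2")
        out = transform_landmarks(gt.landmarks, t)
        assert out.frame == "stage2"
        assert np.allclose(out["HEAD_CENTER"], pivot, atol=1e-12)

    def test_isometry(self, neutral_bundle, rng):
        _, _, gt = neutral_bundle
        rot = Rotation.random(random_state=3).as_matrix()
        t = PoseTransform(rot, rng.normal(scale=30, size=3), "stage1")
        out = transform_landmarks(gt.landmarks, t)
        names = gt.landmarks.names()
        a = gt.landmarks.array(names)
        b = out.array(names)
        da = np.linalg.norm(a[:, None] - a[None], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None], axis=-1)
        assert np.abs(da - db).max() < 1e-9


class TestAngles:
    def test_identities_give_zero(self):
        ang = decompose_angles(PoseTransform(np.eye(3), ORIGIN, "stage1"),
                               PoseTransform(np.eye(3), ORIGIN, "stage2"))
        assert (ang.abduction, ang.flexion, ang.axial_rotation) == (0, 0, 0)

    def test_neutrality_idempotent(self, neutral_bundle):
        # running both stages on already-normalized landmarks is ~identity
        _, _, gt = neutral_bundle
        t1, t2, ang = angles_from_landmarks(gt.landmarks)
        lm1 = transform_landmarks(gt.landmarks, t1)
        lm2 = transform_landmarks(lm1, t2)
        t1b, t2b, angb = angles_from_landmarks(lm2)
        for t in (t1b, t2b):
            angle = np.arccos(np.clip((np.trace(t.rotation) - 1) / 2, -1, 1))
            assert angle < 1e-6

    def test_injected_pose_recovery(self, neutral_bundle, default_spec, rng):
        # ground-truth landmarks at 12 random poses inside the augmentation
        # ranges; decomposed angles must match the injected ones
        _, _, gt = neutral_bundle
        for _ in range(12):
            abd = rng.uniform(-15, 15)
            flex = rng.uniform(-30, 30)
            rot = rng.uniform(-15, 15)
            pose = PoseParams(abduction=abd, flexion=flex, axial_rotation=rot)
            lm = LandmarkSet(
                {n: pose.apply(p) for n, p in gt.landmarks.points.items()}
            )
            _, _, ang = angles_from_landmarks(lm)
            assert ang.abduction == pytest.approx(abd, abs=0.5)
            assert ang.flexion == pytest.approx(flex, abs=0.5)
            # axial rotation reports injected rotation plus anteversion
            assert ang.axial_rotation - default_spec.anteversion == (
                pytest.approx(rot, abs=0.5)
            )


class TestComposeAndSerialize:
    def test_composition_matches_sequential_application(self, rng):
        r1 = Rotation.random(random_state=1).as_matrix()
        r2 = Rotation.from_euler("z", 40, degrees=True).as_matrix()
        t1 = PoseTransform(r1, rng.normal(size=3), "stage1")
        t2 = PoseTransform(r2, rng.normal(size=3), "stage2")
        comp = compose_transforms(t2, t1)
        pts = rng.normal(scale=40, size=(20, 3))
        assert np.allclose(comp.apply(pts), t2.apply(t1.apply(pts)), atol=1e-9)

    def test_json_round_trip(self, rng):
        r = Rotation.random(random_state=2).as_matrix()
        t = PoseTransform(r, rng.normal(size=3), "stage1")
        back = PoseTransform.from_json(t.to_json())
        assert np.allclose(back.rotation, t.rotation)
        assert np.allclose(back.pivot, t.pivot)
        assert back.stage == "stage1"

    def test_improper_rotation_rejected(self):
        refl = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(PoseError):
            PoseTransform(refl, ORIGIN, "stage1")
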