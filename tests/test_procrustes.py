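"""OPA, GPA and symmetrisation, with scipy as an independent rotation oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import orthogonal_procrustes

from virtucrania.landmarks import (
    LandmarkConfiguration,
    PairingTable,
    centroid_size,
)
from virtucrania.procrustes import (
    DegenerateGeometryError,
    SimilarityTransform,
    gpa,
    opa_align,
    symmetrise,
)
from .conftest import random_rotation


def cfg(coords, names=None, **kw):
    coords = np.asarray(coords, dtype=float)
    names = names or [f"p{i}" for i in range(len(coords))]
    return LandmarkConfiguration(specimen_id="t", landmark_names=names, coords=coords, **kw)


class TestSimilarityTransform:
    def test_identity(self, rng):
        pts = rng.normal(size=(5, 3))
        np.testing.assert_allclose(SimilarityTransform.identity().apply(pts), pts)

    def test_compose_and_inverse(self, rng):
        R1, R2 = random_rotation(rng), random_rotation(rng)
        t1 = SimilarityTransform(rotation=R1, translation=rng.normal(size=3), scale=2.0)
        t2 = SimilarityTransform(rotation=R2, translation=rng.normal(size=3), scale=0.5)
        pts = rng.normal(size=(6, 3))
        np.testing.assert_allclose(
            t2.compose(t1).apply(pts), t2.apply(t1.apply(pts)), atol=1e-12
        )
        np.testing.assert_allclose(t1.inverse().apply(t1.apply(pts)), pts, atol=1e-12)

    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            SimilarityTransform(rotation=R, translation=np.zeros(3), scale=1.0)


class TestOPA:
    def test_exact_rigid_recovery(self, rng):
        pts = rng.normal(size=(10, 3)) * 40
        R = random_rotation(rng)
        t = rng.normal(size=3) * 30
        target = cfg(pts @ R.T + t)
        transform, aligned, rms = opa_align(cfg(pts), target, allow_scaling=False)
        assert rms < 1e-9
        np.testing.assert_allclose(aligned.coords, target.coords, atol=1e-9)
        np.testing.assert_allclose(transform.rotation, R, atol=1e-9)

    def test_similarity_recovery_with_scale(self, rng):
        pts = rng.normal(size=(8, 3)) * 40
        R = random_rotation(rng)
        target = cfg(3.7 * pts @ R.T + [5, 6, 7])
        transform, aligned, rms = opa_align(cfg(pts), target, allow_scaling=True)
        assert rms < 1e-9
        assert transform.scale == pytest.approx(3.7)

    def test_rotation_matches_scipy_oracle(self, rng):
        src = rng.normal(size=(12, 3)) * 20
        dst = src @ random_rotation(rng).T + rng.normal(size=(12, 3)) * 2.0
        sc = src - src.mean(axis=0)
        dc = dst - dst.mean(axis=0)
        R_sp, _ = orthogonal_procrustes(sc, dc)
        if np.linalg.det(R_sp) > 0:  # oracle valid only when unreflected
            transform, _, _ = opa_align(cfg(src), cfg(dst), allow_scaling=False)
            np.testing.assert_allclose(transform.rotation, R_sp.T, atol=1e-8)

    def test_never_reflects(self, rng):
        pts = rng.normal(size=(7, 3)) * 10
        mirrored = pts * [1, 1, -1]
        transform, _, rms = opa_align(cfg(pts), cfg(mirrored), allow_scaling=False)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0)
        assert rms > 0.1  # cannot reach a reflected target rigidly

    def test_collinear_degenerate(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            opa_align(cfg(line), cfg(line * 2 + 1), allow_scaling=False)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_residual_invariant_under_rigid_motion(self, seed):
        r = np.random.default_rng(seed)
        src = r.normal(size=(6, 3)) * 15
        dst = src + r.normal(size=(6, 3))
        _, _, rms0 = opa_align(cfg(src), cfg(dst), allow_scaling=False)
        R = random_rotation(r)
        _, _, rms1 = opa_align(cfg(src @ R.T + 5), cfg(dst), allow_scaling=False)
        assert rms1 == pytest.approx(rms0, abs=1e-8)


class TestGPA:
    def test_consensus_of_rotated_copies_recovers_shape(self, rng):
        base = rng.normal(size=(9, 3)) * 25
        configs = []
        for i in range(5):
            R = random_rotation(rng)
            configs.append(cfg(base @ R.T + rng.normal(size=3) * 10))
        consensus, aligned, dists = gpa(configs, with_scaling=True)
        assert max(dists) < 1e-8
        # consensus is the common shape up to similarity
        _, _, rms = opa_align(consensus, cfg(base), allow_scaling=True)
        assert rms < 1e-8

    def test_aligned_centroids_at_origin(self, population):
        _, aligned, _ = gpa([s.landmarks for s in population[:5]], with_scaling=True)
        for a in aligned:
            np.testing.assert_allclose(a.coords.mean(axis=0), 0, atol=1e-9)

    def test_unit_size_consensus(self, population):
        consensus, _, _ = gpa([s.landmarks for s in population[:5]], with_scaling=True)
        assert centroid_size(consensus) == pytest.approx(1.0, abs=1e-6)


PAIR_TABLE = PairingTable(
    pairs=(("a_L", "a_R"), ("b_L", "b_R")), midline=("m0", "m1", "m2")
)


def asym_config(rng):
    names = ["m0", "m1", "m2", "a_L", "a_R", "b_L", "b_R"]
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [10.0, 0.0, 2.0],
            [20.0, 0.0, -1.0],
            [5.0, 6.0, 1.0],
            [5.5, -5.0, 1.2],  # deliberately asymmetric
            [15.0, 7.0, 0.0],
            [14.0, -8.0, 0.5],
        ]
    )
    coords += rng.normal(size=coords.shape) * 0.3
    return LandmarkConfiguration(
        specimen_id="t", landmark_names=names, coords=coords, pairing=PAIR_TABLE
    )


class TestSymmetrise:
    def test_output_is_symmetric(self, rng):
        s = symmetrise(asym_config(rng))
        mid = np.array([s.get(n) for n in PAIR_TABLE.midline])
        centre = mid.mean(axis=0)
        _, _, vt = np.linalg.svd(mid - centre)
        normal = vt[-1]
        for left, right in PAIR_TABLE.pairs:
            dl = (s.get(left) - centre) @ normal
            dr = (s.get(right) - centre) @ normal
            assert dl == pytest.approx(-dr, abs=1e-9)
        for m in PAIR_TABLE.midline:
            assert (s.get(m) - centre) @ normal == pytest.approx(0.0, abs=1e-9)

    def test_idempotent(self, rng):
        s1 = symmetrise(asym_config(rng))
        s2 = symmetrise(s1)
        np.testing.assert_allclose(s2.coords, s1.coords, atol=1e-9)

    def test_symmetric_input_unchanged(self, template):
        s = symmetrise(template.landmarks)
        np.testing.assert_allclose(s.coords, template.landmarks.coords, atol=1e-8)

    def test_requires_pairing(self, rng):
        c = cfg(rng.normal(size=(5, 3)))
        with pytest.raises(Exception):
            symmetrise(c)
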