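"""The synthetic generator's own contracts: symmetry, ground truth, determinism."""

import numpy as np
import pytest
import trimesh as _trimesh

from virtucrania.landmarks import centroid_size
from virtucrania.meshes import mesh_volume
from virtucrania.synthetic import (
    BP_NAMES,
    FF_NAMES,
    OCCIPITAL_FIXED,
    SEMI_AXES,
    analytic_endocast_volume_cc,
    fragment_specimen,
    generate_endocast,
    generate_population,
    generate_template,
    simulate_characters,
    template_ellipsoid_volume_cc,
)
from virtucrania.traits import PhyloTree


class TestTemplate:
    def test_landmark_count_and_split(self, template):
        assert len(template.landmarks) == 28
        assert len(FF_NAMES) == 16 and len(BP_NAMES) == 12
        assert not set(FF_NAMES) & set(BP_NAMES)
        assert set(FF_NAMES) | set(BP_NAMES) == set(template.landmarks.landmark_names)

    def test_bilateral_symmetry(self, template):
        lm = template.landmarks
        for left, right in lm.pairing.pairs:
            pl, pr = lm.get(left), lm.get(right)
            np.testing.assert_allclose(pl * [1, -1, 1], pr, atol=1e-9)
        for name in lm.pairing.midline:
            assert lm.get(name)[1] == pytest.approx(0.0, abs=1e-9)

    def test_landmarks_on_surface(self, template):
        tm = template.mesh.as_trimesh()
        _, dist, _ = _trimesh.proximity.closest_point_naive(tm, template.landmarks.coords)
        assert np.max(dist) < 1.5  # mm; bounded by mesh discretisation

    def test_occipital_semis_on_surface(self, template):
        tm = template.mesh.as_trimesh()
        _, dist, _ = _trimesh.proximity.closest_point_naive(tm, template.occipital_semis)
        assert np.max(dist) < 1e-6

    def test_occipital_patch_shape(self, template):
        assert list(template.occipital_fixed.landmark_names) == list(OCCIPITAL_FIXED)
        assert template.occipital_semis.shape == (150, 3)
        n_pts = len(OCCIPITAL_FIXED) + 150
        assert template.occipital_faces.min() >= 0
        assert template.occipital_faces.max() < n_pts

    def test_mesh_watertight(self, template):
        assert template.mesh.watertight

    def test_deterministic_by_seed(self):
        a = generate_template(seed=3)
        b = generate_template(seed=3)
        np.testing.assert_array_equal(a.landmarks.coords, b.landmarks.coords)
        np.testing.assert_array_equal(a.mesh.vertices, b.mesh.vertices)
        c = generate_template(seed=4)
        assert not np.allclose(a.mesh.vertices, c.mesh.vertices)

    def test_smooth_template_volume_matches_analytic(self, smooth_template):
        expected = template_ellipsoid_volume_cc(smooth_template)
        a, b, c = SEMI_AXES
        assert expected == pytest.approx(4 / 3 * np.pi * a * b * c / 1000.0)
        vol = mesh_volume(smooth_template.mesh)
        assert vol == pytest.approx(expected, rel=0.02)  # icosphere discretisation


class TestPopulation:
    def test_sizes_and_groups(self, population):
        assert len(population) == 12
        groups = {s.group for s in population}
        assert groups == {"MPH", "ERN", "EWN", "MOD"}

    def test_ground_truth_deformation_consistent(self, population):
        s = population[0]
        from virtucrania.tps import tps_warp

        np.testing.assert_allclose(
            tps_warp(s.deformation, s.template.landmarks.coords),
            s.landmarks.coords,
            atol=1e-8,
        )

    def test_individuals_differ(self, population):
        d = np.linalg.norm(population[0].landmarks.coords - population[1].landmarks.coords, axis=1)
        assert d.mean() > 0.5

    def test_deterministic(self, template):
        p1 = generate_population(template, n=4, seed=5)
        p2 = generate_population(template, n=4, seed=5)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.landmarks.coords, b.landmarks.coords)

    def test_plausible_size(self, population):
        for s in population:
            cs = centroid_size(s.landmarks)
            assert 200 < cs < 600  # mm, cranial order of magnitude


class TestFragmentation:
    def test_disjoint_and_complete_partition(self, population):
        pair = fragment_specimen(population[0], seed=1)
        a, b = set(pair.frag_a.landmark_names), set(pair.frag_b.landmark_names)
        assert not a & b
        assert a | b <= set(population[0].landmarks.landmark_names)

    def test_truth_transforms_recorded(self, population):
        pair = fragment_specimen(population[0], seed=1)
        src = population[0].landmarks
        orig_a = src.subset(pair.frag_a.landmark_names)
        recovered = pair.truth_transform_a.inverse().apply(pair.frag_a.coords)
        np.testing.assert_allclose(recovered, orig_a.coords, atol=1e-9)

    def test_exclusion_band(self, population):
        spec = population[0]
        origin, normal = np.array([-8.0, 0, 0]), np.array([1.0, 0, 0])
        pair = fragment_specimen(spec, seed=2, exclusion_band_mm=2.0)
        for frag in (pair.frag_a, pair.frag_b):
            orig = spec.landmarks.subset(frag.landmark_names)
            d = np.abs((orig.coords - origin) @ normal)
            assert (d >= 2.0 - 1e-9).all()

    def test_jitter_adds_noise(self, population):
        clean = fragment_specimen(population[0], seed=3, rigid_jitter_sd=0.0)
        noisy = fragment_specimen(population[0], seed=3, rigid_jitter_sd=1.0)
        assert not np.allclose(clean.frag_a.coords, noisy.frag_a.coords)


class TestEndocast:
    def test_smooth_endocast_volume_analytic(self, smooth_template):
        from virtucrania.synthetic import specimen_from_template

        spec = specimen_from_template(smooth_template)
        endo = generate_endocast(spec, shell_thickness=8.0)
        expected = analytic_endocast_volume_cc(smooth_template, 8.0)
        assert mesh_volume(endo) == pytest.approx(expected, rel=0.02)

    def test_endocast_inside_cranium(self, population):
        endo = generate_endocast(population[0])
        assert mesh_volume(endo) < mesh_volume(population[0].mesh)


class TestCharacterSimulation:
    @staticmethod
    def _tree():
        t = PhyloTree()
        t.add_edge(-1, "A", 0.2)
        t.add_edge(-1, "B", 0.2)
        t.add_edge(-1, -2, 0.5)
        t.add_edge(-2, "C", 0.2)
        t.add_edge(-2, "D", 0.2)
        return t

    def test_matrix_shape(self):
        m = simulate_characters(self._tree(), n_characters=15, seed=0)
        assert len(m.taxa) == 4 and len(m.characters) == 15
        assert all(s in {"0", "1"} for row in m.states for s in row)

    def test_zero_rate_all_ancestral(self):
        m = simulate_characters(self._tree(), n_characters=10, substitution_rate=0.0, seed=0)
        assert all(s == "0" for row in m.states for s in row)

    def test_missing_injection(self):
        m = simulate_characters(self._tree(), n_characters=200, missing_rate=0.25, seed=0)
        frac = sum(s == "?" for row in m.states for s in row) / 800
        assert 0.15 < frac < 0.35
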