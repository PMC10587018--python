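import numpy as np
import pytest
from scipy import ndimage

from neglectmap.disconnect import disconnection_matrix, endpoint_pair
from neglectmap.synthetic import (
    CapacityError,
    EffectSpec,
    GammaVolumes,
    SyntheticAnatomy,
    box_region,
    make_behavior,
    make_lesions,
    make_parcellation,
    make_streamlines,
    make_template,
)
from neglectmap.volumes import LesionMask

STRUCT26 = ndimage.generate_binary_structure(3, 3)


class TestParcellation:
    def test_default_scale_gives_135_nodes(self):
        t = make_template((40, 48, 40))
        p = make_parcellation(t)  # 50 cortical per hemisphere + 35 subcortical
        assert p.n_nodes == 135
        assert (p.nodes["hemisphere"] == "left").sum() == 50
        assert (p.nodes["hemisphere"] == "right").sum() == 50

    def test_parcels_contiguous_and_non_overlapping(self, parcellation24):
        labels = parcellation24.labels
        seen = np.zeros(labels.shape, dtype=int)
        for node_id in parcellation24.node_ids:
            vox = labels == node_id
            assert vox.any()
            _, ncomp = ndimage.label(vox, structure=STRUCT26)
            assert ncomp == 1
            seen += vox
        assert seen.max() == 1  # non-overlapping

    def test_mirror_symmetry_of_cortical_labels(self, parcellation24):
        labels = parcellation24.labels
        n = (parcellation24.nodes["hemisphere"] == "left").sum()
        cx = parcellation24.template.midline_column
        flipped = labels[::-1]
        cortical = (labels > 0) & (labels <= 2 * n)
        renumbered = np.where(flipped > n, flipped - n,
                              np.where(flipped > 0, flipped + n, 0))
        np.testing.assert_array_equal(labels[cortical], renumbered[cortical])
        # homologue mapping is an involution
        for node_id in parcellation24.nodes.loc[
            parcellation24.nodes["hemisphere"] != "midline", "id"
        ]:
            h = parcellation24.homologue_of(int(node_id))
            assert parcellation24.homologue_of(h) == int(node_id)

    def test_five_node_parcellation_full_edge_matrix(self, template24):
        p = make_parcellation(template24, n_cortical_per_hemi=2, n_subcortical=1, seed=0)
        assert p.n_nodes == 5
        ss = make_streamlines(p, {"t": [(1, 3)]}, n_per_edge=2, seed=0)
        empty = LesionMask(template=template24,
                           data=np.zeros(template24.shape, bool))
        assert disconnection_matrix(ss, p, empty).n_entries == 25

    def test_capacity_error(self, template24):
        with pytest.raises(CapacityError):
            make_parcellation(template24, n_cortical_per_hemi=10**6)


class TestStreamlines:
    def test_counts_endpoints_and_bounds(self, parcellation24):
        grouping = {"t1": [(1, 7), (2, 8)], "t2": [(3, 9)]}
        ss = make_streamlines(parcellation24, grouping, n_per_edge=12, seed=0)
        assert len(ss) == 36
        assert len(ss.tract_indices("t1")) == 24  # union of 2 edges
        assert len(ss.tract_indices("t2")) == 12
        template = parcellation24.template
        for pts, tract in zip(ss.streamlines, ss.tract_of):
            assert np.all(template.contains_world(pts))
            pair = endpoint_pair(pts, parcellation24)
            intended = grouping[tract]
            assert tuple(sorted(pair)) in [tuple(sorted(e)) for e in intended]
            steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            assert steps.max() <= 0.5 * min(template.spacing_mm) + 1e-9

    def test_empty_parcel_raises(self, parcellation24):
        with pytest.raises((ValueError, KeyError)):
            make_streamlines(parcellation24, {"t": [(1, 999)]}, n_per_edge=1)


class TestLesions:
    def test_left_only_cohort_stays_left_of_midline(self, template24):
        masks = make_lesions(template24, 10, side_probabilities=(1, 0, 0), seed=0)
        cx = template24.midline_column
        for m in masks:
            assert m.data[:cx].any() and not m.data[cx:].any()

    def test_bilateral_lesions_cross_the_midline(self, template24):
        masks = make_lesions(template24, 10, side_probabilities=(0, 0, 1), seed=0)
        cx = template24.midline_column
        for m in masks:
            assert m.data[:cx].any() and m.data[cx:].any()

    def test_single_26_connected_blob(self, cohort24):
        for m in cohort24:
            _, ncomp = ndimage.label(m.data, structure=STRUCT26)
            assert ncomp == 1

    def test_same_seed_voxel_identical_cohorts(self, template24):
        a = make_lesions(template24, 8, seed=7)
        b = make_lesions(template24, 8, seed=7)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.data, mb.data)

    def test_empirical_mean_volume_within_3_se(self, template24):
        dist = GammaVolumes(mean=500.0, cv=0.6)
        masks = make_lesions(template24, 100, volume_distribution=dist, seed=1)
        vols = np.array([m.n_voxels for m in masks])
        se = dist.sd / np.sqrt(len(vols))
        assert abs(vols.mean() - 500.0) < 3 * se

    def test_capacity_error_for_oversized_lesion(self, template24):
        # a left-only lesion cannot exceed the hemisphere
        from neglectmap.synthetic import _grow_blob

        with pytest.raises(CapacityError):
            _grow_blob(template24, 10**7, 0, template24.midline_column,
                       np.random.default_rng(0))


@pytest.fixture(scope="module")
def anatomy24(template24, parcellation24, streamlines24):
    return SyntheticAnatomy(
        template=template24, parcellation=parcellation24,
        streamlines=streamlines24,
        regions={"roi": box_region(template24, "right", (5, 5, 5))},
    )


class TestBehavior:
    def test_null_model_gives_exact_zero_severity(self, cohort24, anatomy24):
        spec = EffectSpec("voxel_region", "roi", effect_size=0.0, noise_sd=0.0)
        records, truth = make_behavior(cohort24, anatomy24, [spec], seed=0)
        assert np.all(truth.ego_severity == 0.0)
        assert np.all(truth.allo_severity == 0.0)
        for r in records:
            assert r.true_ego_severity == 0.0

    def test_undamaged_patients_have_pure_noise_severity(self, template24, anatomy24):
        # lesions confined to the left hemisphere cannot touch a right-side region
        masks = make_lesions(template24, 40, side_probabilities=(1, 0, 0), seed=3)
        spec = EffectSpec("voxel_region", "roi", effect_size=2.0, noise_sd=0.3)
        _, truth = make_behavior(masks, anatomy24, [spec], seed=1)
        assert np.all(truth.damage.to_numpy() == 0.0)
        assert np.all(truth.linear_ego == 0.0)
        sev = truth.ego_severity
        assert abs(sev.mean()) < 3 * 0.3 / np.sqrt(len(sev))

    def test_unknown_target_raises(self, cohort24, anatomy24):
        spec = EffectSpec("tract", "no_such_tract", effect_size=1.0, noise_sd=0.1)
        with pytest.raises(KeyError):
            make_behavior(cohort24, anatomy24, [spec], seed=0)

    def test_planted_tract_slope_recovered_by_ols(self, template24, anatomy24):
        masks = make_lesions(template24, 200, seed=11)
        tract = anatomy24.streamlines.tract_names[0]
        spec = EffectSpec("tract", tract, effect_size=1.0, noise_sd=0.1)
        _, truth = make_behavior(masks, anatomy24, [spec], seed=2)
        dmg = truth.damage.iloc[:, 0].to_numpy()
        slope = np.polyfit(dmg, truth.ego_severity, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_residuals_mean_zero_over_large_cohort(self, template24, anatomy24):
        masks = make_lesions(template24, 1000, seed=21)
        spec = EffectSpec("voxel_region", "roi", effect_size=1.0, noise_sd=0.5)
        _, truth = make_behavior(masks, anatomy24, [spec], seed=4)
        resid = truth.ego_severity - truth.linear_ego
        assert abs(resid.mean()) < 3 * 0.5 / np.sqrt(len(resid))

    def test_rendering_tracks_severity_direction(self, template24, anatomy24):
        from neglectmap.scoring import default_layout, score_response

        masks = make_lesions(template24, 120, seed=31)
        spec = EffectSpec("voxel_region", "roi", effect_size=1.0, noise_sd=0.05,
                          laterality="left", dimension="ego")
        layout = default_layout()
        records, truth = make_behavior(masks, anatomy24, [spec], seed=5, layout=layout)
        cocs = np.array([
            score_response(layout, r.response).coc for r in records
        ])
        strong = truth.ego_severity > 0.4
        weak = truth.ego_severity < 0.05
        assert strong.any() and weak.any()
        # severe left neglect shifts the centre of cancellation rightward
        assert cocs[strong].mean() > cocs[weak].mean() + 0.1

    def test_same_seed_reproduces_behaviour(self, cohort24, anatomy24):
        spec = EffectSpec("voxel_region", "roi", effect_size=1.0, noise_sd=0.2)
        r1, t1 = make_behavior(cohort24, anatomy24, [spec], seed=9)
        r2, t2 = make_behavior(cohort24, anatomy24, [spec], seed=9)
        np.testing.assert_array_equal(t1.ego_severity, t2.ego_severity)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.response.marked, b.response.marked)
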