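import numpy as np
import pytest

from neglectmap.disconnect import (
    OutOfBoundsError,
    StreamlineSet,
    disconnection_matrices,
    disconnection_matrix,
    endpoint_pair,
    group_count_matrix,
    load_streamlines_json,
    load_tck,
    save_streamlines_json,
    save_tck,
    streamline_hit,
    tract_disconnection,
    tract_disconnection_table,
)
from neglectmap.synthetic import make_lesions, make_template
from neglectmap.volumes import LesionMask

from conftest import mask_from_voxels, straight_streamline


@pytest.fixture(scope="module")
def row_set(template24):
    """12 straight streamlines along x, one per y row, one tract."""
    lines = [straight_streamline(template24, (2, y, 12), (21, y, 12))
             for y in range(6, 18)]
    return StreamlineSet(template=template24, streamlines=lines,
                         tract_of=np.array(["bundle"] * 12, dtype=object))


class TestHit:
    def test_miss_and_vertex_hit(self, template24):
        line = straight_streamline(template24, (2, 2, 2), (20, 2, 2))
        far = mask_from_voxels(template24, [(10, 20, 20)])
        assert not streamline_hit(line, far)
        on_path = mask_from_voxels(template24, [(10, 2, 2)])
        assert streamline_hit(line, on_path)

    def test_between_vertex_crossing_detected(self, template24):
        # two vertices straddle a lesioned voxel without landing in it
        p0 = template24.voxel_to_world(np.array([4, 4, 4])) - [0.4, 0, 0]
        p1 = template24.voxel_to_world(np.array([6, 4, 4])) + [0.4, 0, 0]
        line = np.stack([p0, p1])
        mid = mask_from_voxels(template24, [(5, 4, 4)])
        assert streamline_hit(line, mid)  # exact traversal
        assert streamline_hit(line, mid, step=0.1)  # fine-sampling oracle agrees

    def test_out_of_bounds_raises(self, template24):
        line = np.array([[-5.0, 2.0, 2.0], [3.0, 2.0, 2.0]])
        mask = mask_from_voxels(template24, [(1, 2, 2)])
        with pytest.raises(OutOfBoundsError):
            streamline_hit(line, mask)

    def test_exact_traversal_agrees_with_fine_sampling(self, template24, rng):
        """Randomized polylines vs the 0.1 mm dense-sampling oracle."""
        masks = make_lesions(template24, 20, seed=17)
        mismatches = 0
        for i in range(200):
            start = rng.uniform(0.6, 23.4, size=3)
            steps = rng.normal(scale=2.0, size=(6, 3))
            pts = np.clip(start + np.cumsum(steps, axis=0), 0.6, 23.4)
            pts = np.vstack([start, pts])
            mask = masks[i % len(masks)]
            if streamline_hit(pts, mask) != streamline_hit(pts, mask, step=0.1):
                mismatches += 1
        assert mismatches == 0


class TestTract:
    def test_full_and_empty_lesion(self, row_set, template24):
        full = LesionMask(template=template24, data=np.ones(template24.shape, bool))
        assert tract_disconnection(row_set, "bundle", full) == 100.0
        empty = LesionMask(template=template24, data=np.zeros(template24.shape, bool))
        assert tract_disconnection(row_set, "bundle", empty) == 0.0

    def test_3_of_12_is_25_percent(self, row_set, template24):
        # lesion covering the rows of exactly 3 streamlines
        lesion = mask_from_voxels(
            template24, [(10, y, 12) for y in (6, 7, 8)]
        )
        assert tract_disconnection(row_set, "bundle", lesion) == 25.0

    def test_unknown_tract_raises(self, row_set, template24):
        empty = LesionMask(template=template24, data=np.zeros(template24.shape, bool))
        with pytest.raises(ValueError):
            tract_disconnection(row_set, "no_bundle", empty)

    def test_monotone_under_lesion_superset(self, streamlines24, template24):
        rng = np.random.default_rng(4)
        small = make_lesions(template24, 1, seed=8)[0]
        grown = small.data | (rng.random(template24.shape) < 0.1)
        big = LesionMask(template=template24, data=grown)
        t_small = tract_disconnection_table(streamlines24, [small]).iloc[0]
        t_big = tract_disconnection_table(streamlines24, [big]).iloc[0]
        assert np.all(t_small.to_numpy() <= t_big.to_numpy())


class TestEndpoints:
    def test_constructed_pair_and_reversal(self, parcellation24, streamlines24, grouping24):
        pairs = {tuple(sorted(e)) for edges in grouping24.values() for e in edges}
        for pts in streamlines24.streamlines[:10]:
            pair = endpoint_pair(pts, parcellation24)
            rev = endpoint_pair(pts[::-1], parcellation24)
            assert tuple(sorted(pair)) in pairs
            assert set(pair) == set(rev)

    def test_background_endpoint_is_none_and_excluded(self, template24):
        from neglectmap.disconnect import Parcellation
        import pandas as pd

        labels = np.zeros(template24.shape, dtype=np.int32)
        labels[2:4] = 1  # only one labelled slab
        parc = Parcellation(
            template=template24, labels=labels,
            nodes=pd.DataFrame([{"id": 1, "name": "a", "hemisphere": "left",
                                 "network": "n", "homologue": -1}]),
        )
        line = straight_streamline(template24, (3, 5, 5), (20, 5, 5))
        assert endpoint_pair(line, parc) == (1, None)
        ss = StreamlineSet(template=template24, streamlines=[line],
                           tract_of=np.array(["t"], dtype=object))
        full = LesionMask(template=template24, data=np.ones(template24.shape, bool))
        mat = disconnection_matrix(ss, parc, full)
        assert mat.denominator.sum() == 0  # excluded from every edge


class TestMatrix:
    def test_empty_lesion_all_zero(self, streamlines24, parcellation24, template24):
        empty = LesionMask(template=template24, data=np.zeros(template24.shape, bool))
        mat = disconnection_matrix(streamlines24, parcellation24, empty)
        assert np.all(mat.percent == 0.0)
        assert mat.defined.any()

    def test_single_edge_lesion(self, parcellation24, template24, grouping24):
        from neglectmap.synthetic import make_streamlines

        ss = make_streamlines(parcellation24, grouping24, n_per_edge=6, seed=2)
        # lesion = every voxel of the first tract's first-edge streamlines only
        target = tuple(sorted(grouping24["tract_1"][0]))
        data = np.zeros(template24.shape, dtype=bool)
        others = np.zeros(template24.shape, dtype=bool)
        for pts in ss.streamlines:
            pair = tuple(sorted(endpoint_pair(pts, parcellation24)))
            grid = data if pair == target else others
            from neglectmap.disconnect import streamline_voxel_indices

            grid.ravel()[streamline_voxel_indices(pts, template24)] = True
        data &= ~others  # keep only voxels unique to the target edge
        mat = disconnection_matrix(
            ss, parcellation24, LesionMask(template=template24, data=data)
        )
        if mat.entry(*target) > 0:  # the edge must own some unique voxels
            assert np.all((mat.percent > 0) == (mat.percent.T > 0))
            ids = list(mat.node_ids)
            nonzero = {(ids[i], ids[j]) for i, j in zip(*np.nonzero(mat.percent)) if i <= j}
            assert nonzero <= {target}

    def test_symmetry_and_permutation_invariance(self, streamlines24, parcellation24, cohort24):
        mat = disconnection_matrix(streamlines24, parcellation24, cohort24[0])
        np.testing.assert_array_equal(mat.percent, mat.percent.T)
        perm = np.random.default_rng(1).permutation(len(streamlines24))
        shuffled = StreamlineSet(
            template=streamlines24.template,
            streamlines=[streamlines24.streamlines[i] for i in perm],
            tract_of=streamlines24.tract_of[perm],
        )
        mat2 = disconnection_matrix(shuffled, parcellation24, cohort24[0])
        np.testing.assert_allclose(mat.percent, mat2.percent)
        reversed_set = StreamlineSet(
            template=streamlines24.template,
            streamlines=[s[::-1].copy() for s in streamlines24.streamlines],
            tract_of=streamlines24.tract_of,
        )
        mat3 = disconnection_matrix(reversed_set, parcellation24, cohort24[0])
        np.testing.assert_allclose(mat.percent, mat3.percent)

    def test_monotone_under_lesion_superset(self, streamlines24, parcellation24, template24):
        small = make_lesions(template24, 1, seed=19)[0]
        grown = small.data | (np.random.default_rng(2).random(template24.shape) < 0.15)
        big = LesionMask(template=template24, data=grown)
        m_small, m_big = disconnection_matrices(
            streamlines24, parcellation24, [small, big]
        )
        assert np.all(m_small.percent <= m_big.percent + 1e-12)


class TestGroupCounts:
    def test_zero_and_inclusive_threshold(self, streamlines24, parcellation24, template24):
        empty = LesionMask(template=template24, data=np.zeros(template24.shape, bool))
        mats = disconnection_matrices(streamlines24, parcellation24, [empty] * 3)
        assert group_count_matrix(mats).sum() == 0
        # a patient at exactly the threshold is counted ("at least 50%")
        m = mats[0]
        half = m.percent.copy()
        half[m.defined] = 50.0
        from neglectmap.disconnect import DisconnectionMatrix

        exact = DisconnectionMatrix(node_ids=m.node_ids, percent=half,
                                    denominator=m.denominator)
        counts = group_count_matrix([exact], threshold_percent=50.0)
        assert np.all(counts[m.defined] == 1)

    def test_counts_equal_brute_force_tally(self, streamlines24, parcellation24, cohort24):
        mats = disconnection_matrices(streamlines24, parcellation24, cohort24[:5])
        counts = group_count_matrix(mats, threshold_percent=30.0)
        brute = np.zeros_like(counts)
        for m in mats:
            for i in range(len(m.node_ids)):
                for j in range(len(m.node_ids)):
                    if m.denominator[i, j] > 0 and m.percent[i, j] >= 30.0:
                        brute[i, j] += 1
        np.testing.assert_array_equal(counts, brute)


class TestIO:
    def test_json_round_trip(self, tmp_path, streamlines24, template24):
        path = tmp_path / "streamlines.json"
        save_streamlines_json(streamlines24, path)
        loaded = load_streamlines_json(path, template24)
        assert len(loaded) == len(streamlines24)
        np.testing.assert_allclose(loaded.streamlines[0], streamlines24.streamlines[0])
        assert list(loaded.tract_of) == list(streamlines24.tract_of)

    def test_tck_round_trip(self, tmp_path, streamlines24, template24):
        tck, labels = tmp_path / "atlas.tck", tmp_path / "tracts.json"
        save_tck(streamlines24, tck, labels)
        loaded = load_tck(tck, labels, template24)
        assert len(loaded) == len(streamlines24)
        np.testing.assert_allclose(
            loaded.streamlines[5], streamlines24.streamlines[5], atol=1e-5
        )
        assert list(loaded.tract_of) == list(streamlines24.tract_of)
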