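import numpy as np
import pytest

from atlasfuse.atlas import ReferenceSpace, VOI
from atlasfuse.connectome import (
    PROJECTION_THRESHOLD,
    Connectome,
    GrayordinateMap,
    InjectionRecord,
    aggregate_incoming,
    aggregate_outgoing,
    assemble_structural,
    map_grayordinates,
    region_profile,
    strongest_targets,
)
from atlasfuse.errors import EmptySelectionError
from helpers import brute_assemble

SHAPE = (4, 4, 4)


def record_at(voxel_linear, image, shape=SHAPE):
    return InjectionRecord(
        site=np.unravel_index(voxel_linear, shape),
        volume=VOI(shape, np.atleast_1d(voxel_linear)),
        image=image,
    )


def random_records(rng, n=5, shape=SHAPE):
    out = []
    for _ in range(n):
        vol = rng.choice(np.prod(shape), size=rng.integers(1, 4), replace=False)
        image = rng.uniform(0, 1, size=shape)
        image[rng.random(shape) < 0.5] *= 1e-5  # some sub-threshold values
        out.append(
            InjectionRecord(site=np.unravel_index(vol[0], shape), volume=VOI(shape, vol), image=image)
        )
    return out


class TestAssembly:
    def test_single_record_row_equals_thresholded_image(self):
        rng = np.random.default_rng(0)
        image = rng.uniform(0, 1, size=SHAPE)
        image[0, 0, 1] = 1e-6
        conn = assemble_structural([record_at(3, image)])
        assert conn.sources.tolist() == [3]
        expected = image.ravel().copy()
        expected[expected < PROJECTION_THRESHOLD] = 0
        assert np.array_equal(conn.weights[0], expected)

    def test_overlapping_records_take_per_target_maximum(self):
        img1 = np.full(SHAPE, 0.2)
        img2 = np.full(SHAPE, 0.5)
        conn = assemble_structural([record_at(7, img1), record_at(7, img2)])
        assert (conn.weights[0] == 0.5).all()

    def test_mirroring_doubles_effective_sites(self):
        rng = np.random.default_rng(1)
        records = random_records(rng, n=10)
        conn = assemble_structural(records, mirror=0)
        assert conn.n_injection_sites == 20

    def test_threshold_boundary_values(self):
        image = np.zeros(SHAPE)
        image[0, 0, 0] = 1e-5  # below 10^-4.5 -> zeroed
        image[0, 0, 1] = 1e-4  # above -> kept
        conn = assemble_structural([record_at(0, image)])
        assert conn.weights[0][0] == 0.0
        assert conn.weights[0][1] == 1e-4

    def test_mirror_axis_out_of_range(self):
        with pytest.raises(ValueError):
            assemble_structural([record_at(0, np.zeros(SHAPE))], mirror=3)

    def test_empty_record_list(self):
        with pytest.raises(ValueError):
            assemble_structural([])

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("mirror", [None, 0])
    def test_random_record_sets_match_brute_force(self, seed, mirror):
        rng = np.random.default_rng(300 + seed)
        records = random_records(rng, n=6)
        conn = assemble_structural(records, mirror=mirror)
        expected = brute_assemble(records, PROJECTION_THRESHOLD, mirror=mirror)
        assert set(conn.sources.tolist()) == set(expected)
        for i, src in enumerate(conn.sources):
            assert np.array_equal(conn.weights[i], expected[int(src)])

    def test_max_combine_dominates_every_contributor(self):
        rng = np.random.default_rng(2)
        records = random_records(rng, n=4)
        conn = assemble_structural(records)
        for rec in records:
            img = rec.image.ravel().copy()
            img[img < PROJECTION_THRESHOLD] = 0
            for v in rec.volume.linear:
                assert (conn.row(int(v)) >= img - 1e-15).all()

    def test_mirror_symmetric_fixture_yields_mirror_invariant_connectome(self):
        rng = np.random.default_rng(3)
        records = random_records(rng, n=4)
        conn = assemble_structural(records, mirror=0)
        # reflecting sources and targets about axis 0 leaves weights unchanged
        n0 = SHAPE[0]
        for i, src in enumerate(conn.sources):
            x, y, z = np.unravel_index(int(src), SHAPE)
            msrc = np.ravel_multi_index((n0 - 1 - x, y, z), SHAPE)
            mrow = conn.row(int(msrc))
            assert np.array_equal(
                conn.weights[i].reshape(SHAPE), np.flip(mrow.reshape(SHAPE), axis=0)
            )

    def test_no_weight_in_forbidden_band_and_threshold_idempotent(self):
        rng = np.random.default_rng(4)
        conn = assemble_structural(random_records(rng, n=8))
        w = conn.weights
        assert not ((w > 0) & (w < PROJECTION_THRESHOLD)).any()
        w2 = w.copy()
        w2[w2 < PROJECTION_THRESHOLD] = 0
        assert np.array_equal(w, w2)


class TestGrayordinates:
    def test_entry_at_voxel_center_claims_it(self):
        space = ReferenceSpace((3, 3, 3))
        gmap = GrayordinateMap(
            indices=[10, 20],
            coords=[[1.5, 1.5, 1.5], [0.1, 0.1, 0.1]],
            kinds=["voxel", "vertex"],
        )
        vol = map_grayordinates(gmap, space)
        assert vol[1, 1, 1] == 10
        assert vol[0, 0, 0] == 20

    def test_equidistant_tie_resolves_to_lowest_index(self):
        space = ReferenceSpace((1, 1, 3))
        gmap = GrayordinateMap(
            indices=[7, 3],
            coords=[[0.5, 0.5, 0.5], [0.5, 0.5, 2.5]],
            kinds=["voxel", "voxel"],
        )
        vol = map_grayordinates(gmap, space)
        assert vol[0, 0, 1] == 3  # exactly between entries 7 and 3

    def test_random_entries_match_exhaustive_search(self):
        rng = np.random.default_rng(5)
        space = ReferenceSpace((8, 8, 8))
        coords = rng.uniform(0, 8, size=(100, 3))
        gmap = GrayordinateMap(indices=np.arange(100), coords=coords, kinds=["voxel"] * 100)
        vol = map_grayordinates(gmap, space)
        for _ in range(50):
            i, j, k = rng.integers(0, 8, size=3)
            c = np.array([i + 0.5, j + 0.5, k + 0.5])
            d = np.linalg.norm(coords - c, axis=1)
            best = np.flatnonzero(d == d.min()).min()
            assert vol[i, j, k] == best


class TestAggregation:
    @pytest.fixture
    def conn(self):
        rng = np.random.default_rng(6)
        return assemble_structural(random_records(rng, n=8))

    def test_single_voxel_voi_returns_its_row(self, conn):
        src = int(conn.sources[0])
        out = aggregate_outgoing(conn, VOI(SHAPE, np.array([src])))
        assert np.array_equal(out.ravel(), conn.weights[0])

    def test_uncovered_voi_raises_empty_signal(self, conn):
        uncovered = sorted(set(range(64)) - set(conn.sources.tolist()))
        if uncovered:
            with pytest.raises(EmptySelectionError):
                aggregate_outgoing(conn, VOI(SHAPE, np.array(uncovered[:1])))

    def test_matches_brute_force_row_mean(self, conn):
        rng = np.random.default_rng(7)
        voi = VOI(SHAPE, rng.choice(64, size=20, replace=False))
        covered = [int(s) for s in conn.sources if s in set(voi.linear.tolist())]
        expected = np.mean([conn.row(s) for s in covered], axis=0)
        assert np.allclose(aggregate_outgoing(conn, voi).ravel(), expected)

    def test_linearity_in_weights(self, conn):
        voi = VOI(SHAPE, conn.sources[:3])
        base = aggregate_outgoing(conn, voi)
        scaled = Connectome(
            shape=conn.shape, sources=conn.sources, weights=conn.weights * 2.5,
            n_injection_sites=conn.n_injection_sites,
        )
        assert np.allclose(aggregate_outgoing(scaled, voi), base * 2.5)

    def test_incoming_aggregates_columns(self, conn):
        voi = VOI(SHAPE, np.arange(10))
        vol = aggregate_incoming(conn, voi)
        expected = conn.weights[:, :10].mean(axis=1)
        got = vol.ravel()[conn.sources]
        assert np.allclose(got, expected)


class TestStrongestTargets:
    def test_k1_is_argmax(self):
        tmap = np.zeros(SHAPE)
        tmap[2, 1, 3] = 0.9
        tmap[0, 0, 0] = 0.5
        voi = strongest_targets(tmap, 1)
        assert [tuple(v) for v in voi.voxels] == [(2, 1, 3)]

    def test_k_all_positive_is_support(self):
        rng = np.random.default_rng(8)
        tmap = rng.uniform(0, 1, size=SHAPE) * (rng.random(SHAPE) < 0.3)
        n_pos = int((tmap > 0).sum())
        voi = strongest_targets(tmap, n_pos)
        assert set(voi.linear.tolist()) == set(np.flatnonzero(tmap.ravel()).tolist())

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            strongest_targets(np.ones(SHAPE), 0)

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValueError):
            strongest_targets(np.zeros(SHAPE), 1)


class TestRegionProfile:
    def test_profile_length_and_zero_outside_support(self, small_ontology, small_parcellation):
        shape = small_parcellation.space.shape
        image = np.zeros(shape)
        image.ravel()[np.arange(16, 32)] = 0.4  # mass on region A2 (leaf 5)
        rec = InjectionRecord(site=(0, 0, 0), volume=VOI(shape, np.array([0])), image=image)
        conn = assemble_structural([rec])
        prof = region_profile(conn, VOI(shape, np.array([0])), [4, 5, 6, 7],
                              small_ontology, small_parcellation)
        assert prof.shape == (4,)
        assert prof[1] == pytest.approx(0.4)
        assert prof[2] == 0.0 and prof[3] == 0.0

    def test_matches_brute_force_double_mean(self, small_ontology, small_parcellation):
        rng = np.random.default_rng(9)
        records = random_records(rng, n=6)
        conn = assemble_structural(records)
        voi = VOI(SHAPE, conn.sources[:4])
        prof = region_profile(conn, voi, [4, 5], small_ontology, small_parcellation)
        tmap = conn.weights[:4].mean(axis=0)
        for idx, rid in enumerate([4, 5]):
            vox = np.flatnonzero(np.isin(small_parcellation.labels.ravel(), [rid]))
            assert prof[idx] == pytest.approx(tmap[vox].mean())
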