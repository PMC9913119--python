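"""ICCS and object-based colocalization against brute-force oracles and
generator truth."""

import numpy as np
import pandas as pd
import pytest

from cytocorr import colocalization as co
from cytocorr import phantom as ph
from cytocorr import registration as reg
from cytocorr import smlm
from cytocorr.io_formats import ImagePlane, LocalizationTable


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_single_linkage(xy: np.ndarray, radius: float) -> list[set]:
    """Union-find over the full distance matrix (quadratic, test-only)."""
    n = len(xy)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] <= radius ** 2:
                parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda s: min(s))


def brute_force_greedy_match(xy_a, xy_b, radius):
    """Independent re-implementation of ascending-distance greedy matching
    over the full distance matrix."""
    cand = []
    for i in range(len(xy_a)):
        for j in range(len(xy_b)):
            d = float(np.hypot(*(xy_a[i] - xy_b[j])))
            if d <= radius:
                cand.append((d, i, j))
    cand.sort()
    ua, ub, pairs = set(), set(), []
    for d, i, j in cand:
        if i not in ua and j not in ub:
            ua.add(i)
            ub.add(j)
            pairs.append((i, j, d))
    return pairs


def _points_to_clusters(table: LocalizationTable) -> pd.DataFrame:
    xy = table.xy_nm
    return pd.DataFrame({"cluster_id": np.arange(1, len(xy) + 1),
                         "channel": "c", "x_nm": xy[:, 0], "y_nm": xy[:, 1],
                         "n_members": 1, "radius_gyration_nm": 0.0})


class TestICCS:
    def test_identical_channels_give_unit_fraction(self):
        img = ph.random_blob_image(shape=(256, 256), n_blobs=200, seed=1)
        r = co.compute_iccs(img, img)
        assert r.f1 == pytest.approx(1.0, abs=0.02)
        assert r.f2 == pytest.approx(1.0, abs=0.02)

    def test_independent_channels_give_near_zero(self):
        fs = []
        for seed in range(3):
            t1, t2, _ = ph.generate_two_channel_points(1000, 1000, 0.0, 400.0,
                                                       0.0, seed)
            im1 = smlm.render(t1, (20, 20), 50.0, sigma_nm=150.0,
                              photon_weighted=False).plane
            im2 = smlm.render(t2, (20, 20), 50.0, sigma_nm=150.0,
                              photon_weighted=False).plane
            r = co.compute_iccs(im1, im2)
            fs.extend([r.f1, r.f2])
        assert max(fs) <= 0.1

    def test_half_colocalized_fraction_recovered(self):
        f1s, f2s = [], []
        for seed in range(10):
            t1, t2, _ = ph.generate_two_channel_points(1000, 1000, 0.5, 400.0,
                                                       10.0, seed)
            im1 = smlm.render(t1, (20, 20), 50.0, sigma_nm=150.0,
                              photon_weighted=False).plane
            im2 = smlm.render(t2, (20, 20), 50.0, sigma_nm=150.0,
                              photon_weighted=False).plane
            r = co.compute_iccs(im1, im2)
            f1s.append(r.f1)
            f2s.append(r.f2)
        assert np.mean(f1s) == pytest.approx(0.5, abs=0.1)
        assert np.mean(f2s) == pytest.approx(0.5, abs=0.1)

    def test_zero_mean_channel_rejected(self):
        blank = ImagePlane(np.zeros((64, 64)), 50.0)
        img = ph.random_blob_image(shape=(64, 64), seed=2)
        with pytest.raises(ValueError, match="zero-mean"):
            co.compute_iccs(img, blank)


class TestClustering:
    def test_two_points_at_49_nm_form_one_cluster(self):
        t = LocalizationTable.from_arrays([0.0, 49.0], [0.0, 0.0])
        assert len(co.cluster_localizations(t, 50.0)) == 1

    def test_two_points_at_51_nm_stay_separate(self):
        t = LocalizationTable.from_arrays([0.0, 51.0], [0.0, 0.0])
        assert len(co.cluster_localizations(t, 50.0)) == 2

    def test_threshold_is_inclusive(self):
        t = LocalizationTable.from_arrays([0.0, 50.0], [0.0, 0.0])
        assert len(co.cluster_localizations(t, 50.0)) == 1

    def test_min_points_filter(self):
        t = LocalizationTable.from_arrays([0.0, 10.0, 500.0], [0.0, 0.0, 0.0])
        table = co.cluster_localizations(t, 50.0, min_points=2)
        assert len(table) == 1
        assert table.iloc[0]["n_members"] == 2

    def test_empty_input_gives_empty_table(self):
        assert len(co.cluster_localizations(LocalizationTable.concat([]),
                                            50.0)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_partition(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 500))
        xy = rng.uniform(0, 3000, (n, 2))
        t = LocalizationTable.from_arrays(xy[:, 0], xy[:, 1])
        ours = co.cluster_localizations(t, 50.0)
        oracle = brute_force_single_linkage(xy, 50.0)
        assert len(ours) == len(oracle)
        oracle_centroids = sorted(tuple(np.round(xy[list(g)].mean(0), 6))
                                  for g in oracle)
        ours_centroids = sorted(zip(np.round(ours["x_nm"], 6),
                                    np.round(ours["y_nm"], 6)))
        assert ours_centroids == oracle_centroids

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        xy = rng.uniform(0, 2000, (200, 2))
        t1 = LocalizationTable.from_arrays(xy[:, 0], xy[:, 1])
        perm = rng.permutation(200)
        t2 = LocalizationTable.from_arrays(xy[perm, 0], xy[perm, 1])
        a = co.cluster_localizations(t1, 50.0)
        b = co.cluster_localizations(t2, 50.0)
        ca = sorted(zip(np.round(a["x_nm"], 6), np.round(a["y_nm"], 6)))
        cb = sorted(zip(np.round(b["x_nm"], 6), np.round(b["y_nm"], 6)))
        assert ca == cb


class TestMask:
    def test_uniform_bright_plane_gives_full_mask(self):
        plane = ImagePlane(np.ones((64, 64)), 65.0)
        target = ImagePlane(np.zeros((64, 64)), 65.0)
        mask = co.mask_from_confocal(plane, None, target)
        assert mask.all()

    def test_binary_input_identity_transform_idempotent(self):
        rng = np.random.default_rng(3)
        binary = (rng.random((64, 64)) > 0.6).astype(float)
        plane = ImagePlane(binary, 65.0)
        target = ImagePlane(np.zeros((64, 64)), 65.0)
        mask = co.mask_from_confocal(plane, reg.Transform2D(), target,
                                     closing_radius_px=0)
        np.testing.assert_array_equal(mask, binary.astype(bool))

    def test_filament_mask_covers_truth(self):
        plane, truth_mask = ph.filament_image(shape=(256, 256), seed=4)
        target = ImagePlane(np.zeros((256, 256)), 65.0)
        mask = co.mask_from_confocal(plane, None, target)
        coverage = mask[truth_mask].mean()
        background_hit = mask[~truth_mask].mean()
        assert coverage >= 0.95
        assert background_hit <= 0.05


class TestObjectColocalization:
    def test_identical_sets_fully_matched_one_to_one(self):
        t1, _, _ = ph.generate_two_channel_points(100, 100, 1.0, 100.0, 0.0, 5)
        c = _points_to_clusters(t1)
        r = co.object_colocalization(c, c.copy(), 50.0)
        assert (r.fraction_a, r.fraction_b) == (1.0, 1.0)
        assert set(r.stoichiometry_a) == {1}

    def test_disjoint_sets_give_zero_fractions(self):
        a = _points_to_clusters(LocalizationTable.from_arrays(
            [0.0, 10.0], [0.0, 10.0]))
        b = _points_to_clusters(LocalizationTable.from_arrays(
            [5000.0, 6000.0], [5000.0, 6000.0]))
        r = co.object_colocalization(a, b, 50.0)
        assert (r.fraction_a, r.fraction_b) == (0.0, 0.0)
        assert len(r.pairs) == 0

    def test_empty_channel_gives_zero(self):
        a = _points_to_clusters(LocalizationTable.from_arrays([0.0], [0.0]))
        empty = a.iloc[:0]
        r = co.object_colocalization(a, empty, 50.0)
        assert (r.fraction_a, r.fraction_b) == (0.0, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matching_agrees_with_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        na, nb = rng.integers(20, 100, 2)
        xy_a = rng.uniform(0, 2000, (na, 2))
        xy_b = rng.uniform(0, 2000, (nb, 2))
        ca = _points_to_clusters(LocalizationTable.from_arrays(xy_a[:, 0], xy_a[:, 1]))
        cb = _points_to_clusters(LocalizationTable.from_arrays(xy_b[:, 0], xy_b[:, 1]))
        r = co.object_colocalization(ca, cb, 100.0)
        oracle = brute_force_greedy_match(xy_a, xy_b, 100.0)
        ours = sorted((int(i) - 1, int(j) - 1)
                      for i, j in zip(r.pairs["id_a"], r.pairs["id_b"]))
        assert ours == sorted((i, j) for i, j, _ in oracle)

    def test_symmetric_truth_swapping_channels_swaps_fractions(self):
        t1, t2, _ = ph.generate_two_channel_points(500, 500, 0.5, 400.0, 5.0, 7)
        a, b = _points_to_clusters(t1), _points_to_clusters(t2)
        r1 = co.object_colocalization(a, b, 50.0)
        r2 = co.object_colocalization(b, a, 50.0)
        assert r1.fraction_a == pytest.approx(r2.fraction_b)
        assert r1.fraction_b == pytest.approx(r2.fraction_a)

    @pytest.mark.parametrize("f_true", [0.0, 0.5, 1.0])
    def test_generator_fraction_recovered(self, f_true):
        fracs = []
        for seed in range(5):
            t1, t2, _ = ph.generate_two_channel_points(1000, 1000, f_true,
                                                       400.0, 10.0, seed)
            ca = co.cluster_localizations(t1, 50.0)
            cb = co.cluster_localizations(t2, 50.0)
            r = co.object_colocalization(ca, cb, 50.0)
            fracs.extend([r.fraction_a, r.fraction_b])
        assert np.mean(fracs) == pytest.approx(f_true, abs=0.05)


class TestDistances:
    def test_three_four_five_distance(self):
        a = _points_to_clusters(LocalizationTable.from_arrays([0.0], [0.0]))
        b = _points_to_clusters(LocalizationTable.from_arrays([300.0], [400.0]))
        d = co.distance_distribution(a, b)
        assert d[0] == pytest.approx(500.0)

    def test_cluster_inside_mask_has_zero_distance(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:40, 20:40] = True
        a = _points_to_clusters(LocalizationTable.from_arrays(
            [30 * 65.0], [30 * 65.0]))
        d = co.distance_distribution(a, mask, pixel_size_nm=65.0)
        assert d[0] == 0.0

    def test_matches_brute_force_all_pairs_minimum(self):
        rng = np.random.default_rng(9)
        xy_a = rng.uniform(0, 5000, (200, 2))
        xy_b = rng.uniform(0, 5000, (150, 2))
        a = _points_to_clusters(LocalizationTable.from_arrays(xy_a[:, 0], xy_a[:, 1]))
        b = _points_to_clusters(LocalizationTable.from_arrays(xy_b[:, 0], xy_b[:, 1]))
        d = co.distance_distribution(a, b)
        oracle = np.sqrt(((xy_a[:, None, :] - xy_b[None, :, :]) ** 2
                          ).sum(-1)).min(axis=1)
        np.testing.assert_allclose(d, oracle, rtol=1e-12)

    def test_empty_reference_rejected(self):
        a = _points_to_clusters(LocalizationTable.from_arrays([0.0], [0.0]))
        with pytest.raises(ValueError, match="empty"):
            co.distance_distribution(a, a.iloc[:0])


class TestCompartmentSplit:
    def test_full_mask_all_on(self):
        a = _points_to_clusters(LocalizationTable.from_arrays(
            [100.0, 200.0], [100.0, 200.0]))
        out = co.compartment_split(a, np.ones((64, 64), dtype=bool), 65.0)
        assert out["on_mask"].all()

    def test_empty_mask_all_off(self):
        a = _points_to_clusters(LocalizationTable.from_arrays(
            [100.0, 200.0], [100.0, 200.0]))
        out = co.compartment_split(a, np.zeros((64, 64), dtype=bool), 65.0)
        assert not out["on_mask"].any()

    def test_known_placement_recovered(self):
        """Clusters placed on / off a band mask are labeled correctly for
        at least 98% of clusters."""
        rng = np.random.default_rng(10)
        px = 65.0
        mask = np.zeros((200, 200), dtype=bool)
        mask[:, 80:120] = True  # vertical band x in [5200, 7800) nm
        x_on = rng.uniform(80.5 * px, 119.0 * px, 200)
        x_off = np.concatenate([rng.uniform(0, 75 * px, 100),
                                rng.uniform(125 * px, 199 * px, 100)])
        y = rng.uniform(0, 199 * px, 400)
        a = _points_to_clusters(LocalizationTable.from_arrays(
            np.concatenate([x_on, x_off]), y))
        out = co.compartment_split(a, mask, px)
        truth = np.concatenate([np.ones(200, bool), np.zeros(200, bool)])
        assert (out["on_mask"].to_numpy() == truth).mean() >= 0.98
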