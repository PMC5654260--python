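import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbcmorph import separation
from rbcmorph.separation import (
    SeedSet,
    distance_transform,
    generate_seeds,
    random_walk_segment,
    split_cells,
)

from conftest import disc_mask, dumbbell_mask


def dense_absorbing_oracle(image, mask, seeds, beta):
    """Absorbing-Markov-chain solve, built independently from transition
    probabilities P_ij = w_ij / deg_i with dense linear algebra."""
    h, w = mask.shape
    nodes = [(r, c) for r in range(h) for c in range(w) if mask[r, c]]
    index = {rc: i for i, rc in enumerate(nodes)}
    n = len(nodes)
    g = image.astype(float)
    vals = g[mask]
    lo, hi = vals.min(), vals.max()
    g = (g - lo) / (hi - lo) if hi > lo else np.zeros_like(g)
    weights = np.zeros((n, n))
    for (r, c), i in index.items():
        for dr, dc in ((0, 1), (1, 0)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                j = index[(rr, cc)]
                wgt = max(np.exp(-beta * (g[r, c] - g[rr, cc]) ** 2), 1e-6)
                weights[i, j] = weights[j, i] = wgt
    deg = weights.sum(axis=1)
    trans = weights / deg[:, None]
    seed_idx = [index[rc] for rc in seeds.points]
    k = len(seed_idx)
    absorbing = np.zeros(n, bool)
    absorbing[seed_idx] = True
    q = trans[~absorbing][:, ~absorbing]
    r_mat = trans[~absorbing][:, seed_idx]
    fund = np.linalg.solve(np.eye(q.shape[0]) - q, r_mat)
    probs = np.zeros((n, k))
    probs[np.array(seed_idx)] = np.eye(k)
    probs[~absorbing] = fund
    out = np.zeros((k, h, w))
    for (rc, i) in index.items():
        out[:, rc[0], rc[1]] = probs[i]
    return out


def random_blob(rng, max_px=100):
    """Random connected mask of at most max_px pixels."""
    from scipy import ndimage

    while True:
        field = ndimage.gaussian_filter(rng.normal(size=(12, 12)), 2.0)
        mask = field > np.quantile(field, 0.55)
        lab, n = ndimage.label(mask)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
        mask = lab == (1 + np.argmax(sizes))
        if 8 <= mask.sum() <= max_px:
            return mask


class TestDistanceTransform:
    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        dmap = distance_transform(mask)
        assert dmap[2, 2] == 1.0
        assert dmap.sum() == 1.0

    def test_disc_max_is_radius(self):
        dmap = distance_transform(disc_mask(15))
        assert abs(dmap.max() - 15) <= 1.0

    def test_all_foreground_rejected(self):
        with pytest.raises(ValueError, match="background"):
            distance_transform(np.ones((4, 4), bool))

    def test_dumbbell_two_maxima(self):
        # brute-force regional-maxima scan above h=2
        mask = dumbbell_mask(radius=10, gap=16)
        dmap = distance_transform(mask)
        from skimage.morphology import h_maxima

        peaks = h_maxima(dmap, 2.0)
        from scipy import ndimage

        _, n = ndimage.label(peaks, structure=np.ones((3, 3)))
        assert n == 2


class TestGenerateSeeds:
    def test_single_disc_one_seed(self):
        dmap = distance_transform(disc_mask(15))
        seeds = generate_seeds(dmap)
        assert len(seeds) == 1
        center = np.array(disc_mask(15).shape) // 2
        assert np.hypot(*(np.array(seeds.points[0]) - center)) <= 2

    def test_dumbbell_two_seeds(self):
        mask = dumbbell_mask(radius=10, gap=16)
        seeds = generate_seeds(distance_transform(mask))
        assert len(seeds) == 2
        rows = {p[0] for p in seeds.points}
        cols = sorted(p[1] for p in seeds.points)
        assert cols[1] - cols[0] > 20  # one per lobe

    def test_synthetic_cluster_seeds_inside_cells(self):
        from rbcmorph import roi, synthetic

        mix = {"discocyte": 0.4, "oval": 0.3, "granular": 0.3}
        cfg = synthetic.SceneConfig(frame_width=320, frame_height=320, n_cells=4,
                                    touching_fraction=1.0, class_mix=mix, seed=3)
        frame, truth = synthetic.render_scene(cfg)
        mask = roi.threshold_and_refine(roi.entropy_map(frame), frame.shape)
        refined = roi.cell_level_mask(frame, mask)
        dmap = distance_transform(np.pad(refined, 1))[1:-1, 1:-1]
        seeds = generate_seeds(dmap)
        assert len(seeds) == 4
        owners = set()
        for r, c in seeds.points:
            owner = truth.label_image[r, c]
            assert owner > 0
            owners.add(owner)
        assert len(owners) == 4


class TestRandomWalk:
    def test_single_seed_everything_one_label(self):
        mask = disc_mask(8)
        r, c = np.array(mask.shape) // 2
        probs, label_map = random_walk_segment(
            np.full(mask.shape, 100, np.uint8), mask, SeedSet([(r, c)])
        )
        assert (label_map[mask] == 1).all()
        assert probs[0][mask].min() == 1.0

    def test_symmetric_dumbbell_equal_split(self):
        mask = dumbbell_mask(radius=10, gap=16)
        image = np.full(mask.shape, 120, np.uint8)
        cy, cx = mask.shape[0] // 2, mask.shape[1] // 2
        seeds = SeedSet([(cy, cx - 16), (cy, cx + 16)])
        _, label_map = random_walk_segment(image, mask, seeds, beta=130.0)
        a1 = (label_map == 1).sum()
        a2 = (label_map == 2).sum()
        assert abs(a1 - a2) / max(a1, a2) <= 0.02

    def test_matches_dense_oracle_toy(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((8, 8), bool)
        mask[1:7, 1:7] = True
        image = rng.integers(80, 180, size=(8, 8)).astype(np.uint8)
        seeds = SeedSet([(1, 1), (6, 6)])
        probs, _ = random_walk_segment(image, mask, seeds, beta=50.0)
        oracle = dense_absorbing_oracle(image, mask, seeds, beta=50.0)
        np.testing.assert_allclose(probs[:, mask], oracle[:, mask], atol=1e-6)

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_oracle_equivalence_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_blob(rng)
        image = rng.integers(0, 256, size=mask.shape).astype(np.uint8)
        fg = np.argwhere(mask)
        k = int(rng.integers(2, 4))
        sel = rng.choice(len(fg), size=min(k, len(fg)), replace=False)
        seeds = SeedSet([tuple(map(int, fg[i])) for i in sel])
        probs, _ = random_walk_segment(image, mask, seeds, beta=90.0)
        oracle = dense_absorbing_oracle(image, mask, seeds, beta=90.0)
        np.testing.assert_allclose(probs[:, mask], oracle[:, mask], atol=1e-6)
        # maximum principle and normalization
        assert probs.min() >= 0 and probs.max() <= 1 + 1e-9
        np.testing.assert_allclose(probs[:, mask].sum(axis=0), 1.0, atol=1e-6)

    def test_orphan_component_warns_and_assigns(self):
        mask = np.zeros((5, 9), bool)
        mask[1:4, 1:4] = True
        mask[1:4, 6:8] = True  # disconnected, unseeded
        image = np.full(mask.shape, 50, np.uint8)
        seeds = SeedSet([(2, 1), (2, 3)])
        with pytest.warns(UserWarning, match="without seed"):
            probs, label_map = random_walk_segment(image, mask, seeds)
        assert (label_map[mask] > 0).all()
        # orphan pixels go to the nearest seed (label 2 at column 3)
        assert (label_map[1:4, 6:8] == 2).all()

    def test_requires_seed_on_foreground(self):
        mask = disc_mask(5)
        with pytest.raises(ValueError, match="foreground"):
            random_walk_segment(np.zeros(mask.shape, np.uint8), mask,
                                SeedSet([(0, 0), (5, 5)]))


class TestSplitCells:
    def test_dumbbell_two_patches(self):
        mask = dumbbell_mask(radius=10, gap=16)
        image = np.full(mask.shape, 100, np.uint8)
        seeds = generate_seeds(distance_transform(mask))
        _, label_map = random_walk_segment(image, mask, seeds)
        cells = split_cells(label_map, mask, min_area=100)
        assert len(cells) == 2

    def test_partition_exact(self):
        mask = dumbbell_mask(radius=10, gap=16)
        image = np.full(mask.shape, 100, np.uint8)
        seeds = generate_seeds(distance_transform(mask))
        _, label_map = random_walk_segment(image, mask, seeds)
        cells = split_cells(label_map, mask, min_area=100)
        total = sum(c.mask.sum() for c in cells)
        assert total == mask.sum()
        union = np.zeros_like(mask)
        for c in cells:
            assert not (union & c.mask).any()
            union |= c.mask
        np.testing.assert_array_equal(union, mask)

    def test_fragment_merged_into_neighbor(self):
        mask = np.zeros((10, 20), bool)
        mask[2:8, 2:18] = True
        label_map = np.zeros_like(mask, int)
        label_map[2:8, 2:10] = 1
        label_map[2:8, 10:18] = 2
        label_map[2:8, 17] = 3  # 6-px sliver
        cells = split_cells(label_map, mask, min_area=100)
        assert len(cells) == 2
        assert sum(c.mask.sum() for c in cells) == mask.sum()

    def test_four_cell_cluster_four_patches(self):
        from rbcmorph import roi, synthetic

        mix = {"discocyte": 0.4, "oval": 0.3, "granular": 0.3}
        cfg = synthetic.SceneConfig(frame_width=320, frame_height=320, n_cells=4,
                                    touching_fraction=1.0, class_mix=mix, seed=2)
        frame, truth = synthetic.render_scene(cfg)
        mask = roi.threshold_and_refine(roi.entropy_map(frame), frame.shape)
        refined = roi.cell_level_mask(frame, mask)
        dmap = distance_transform(np.pad(refined, 1))[1:-1, 1:-1]
        seeds = generate_seeds(dmap)
        _, label_map = random_walk_segment(frame, refined, seeds, beta=5.0)
        cells = split_cells(label_map, refined)
        assert len(cells) == 4
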