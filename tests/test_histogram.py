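"""Camouflage-degree metric: histograms, chi-square distance, CD ratio."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from keyfg.histogram import (
    BackgroundMode,
    CamouflageScore,
    CDConfig,
    CDUndefinedError,
    RegionHistogram,
    build_region_histogram,
    compute_cd,
    compute_tgc,
    score_dataset,
)


def _score(tgc, oid=0, thr=0.9):
    return CamouflageScore(object_id=oid, tgc=tgc, is_camouflaged=tgc < thr)


class TestRegionHistogram:
    def test_single_colour_region_concentrates_in_one_bin(self):
        px = np.zeros((100, 3))
        h = build_region_histogram(px, n_bins=32)
        assert h.n_pixels == 100
        for c in range(3):
            assert h.channels[c, 0] == 1.0
            assert h.channels[c, 1:].sum() == 0.0

    def test_equal_split_two_bins(self):
        px = np.array([[0, 0, 0], [0, 0, 0], [255, 255, 255], [255, 255, 255]])
        h = build_region_histogram(px, n_bins=2)
        assert np.allclose(h.channels, 0.5)

    def test_normalisation_invariant(self, rng):
        px = rng.integers(0, 256, size=(100, 3))
        h = build_region_histogram(px, n_bins=32)
        assert np.allclose(h.channels.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match="empty region"):
            build_region_histogram(np.zeros((0, 3)), 32)

    def test_grayscale_replicated_with_warning(self, caplog):
        h = build_region_histogram(np.full((10, 1), 128.0), n_bins=4)
        assert h.channels.shape == (3, 4)
        assert np.allclose(h.channels[:, 2], 1.0)

    def test_bin_edges_half_open_last_closed(self):
        # 255 falls in the last bin, 8 in bin 1 of 32 (edge 8.0 inclusive-left)
        h = build_region_histogram(np.array([[255, 8, 0]]), n_bins=32)
        assert h.channels[0, 31] == 1.0
        assert h.channels[1, 1] == 1.0


class TestTgc:
    def test_identical_histograms_give_zero(self, rng):
        px = rng.integers(0, 256, size=(50, 3))
        h = build_region_histogram(px, 16)
        assert compute_tgc(h, h) == 0.0

    def test_disjoint_support_gives_maximum(self):
        a = np.zeros((3, 4)); a[:, 0] = 1.0
        b = np.zeros((3, 4)); b[:, 1] = 1.0
        tgc = compute_tgc(RegionHistogram(a, 10), RegionHistogram(b, 10))
        assert tgc == pytest.approx(6.0)

    def test_hand_evaluated_example(self):
        # one channel differs: [0.5,0.5,0,0] vs uniform quarter histogram
        h1 = np.array([[0.5, 0.5, 0, 0], [0.25, 0.25, 0.25, 0.25],
                       [0.25, 0.25, 0.25, 0.25]])
        h2 = np.full((3, 4), 0.25)
        tgc = compute_tgc(RegionHistogram(h1, 4), RegionHistogram(h2, 4))
        assert tgc == pytest.approx(0.6667, abs=1e-4)

    def test_mismatched_bins_raise(self):
        a = RegionHistogram(np.full((3, 4), 0.25), 4)
        b = RegionHistogram(np.full((3, 8), 0.125), 8)
        with pytest.raises(ValueError, match="bin counts differ"):
            compute_tgc(a, b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_bounds_and_permutation_invariance(self, seed):
        r = np.random.default_rng(seed)
        h1 = build_region_histogram(r.integers(0, 256, size=(30, 3)), 8)
        h2 = build_region_histogram(r.integers(0, 256, size=(40, 3)), 8)
        t12 = compute_tgc(h1, h2)
        t21 = compute_tgc(h2, h1)
        assert t12 == pytest.approx(t21)
        assert 0.0 <= t12 <= 6.0
        perm = r.permutation(8)
        p1 = RegionHistogram(h1.channels[:, perm], h1.n_pixels)
        p2 = RegionHistogram(h2.channels[:, perm], h2.n_pixels)
        assert compute_tgc(p1, p2) == pytest.approx(t12)


class TestCD:
    @pytest.mark.parametrize(
        "n_below,n_above,expected",
        [(1426, 1363, 1.05), (1689, 1641, 1.03),
         (7687, 29094, 0.26), (1746, 18224, 0.10)],
    )
    def test_reference_dataset_count_ratios(self, n_below, n_above, expected):
        scores = [_score(0.5, i) for i in range(n_below)] + \
                 [_score(1.5, n_below + i) for i in range(n_above)]
        report = compute_cd(scores, threshold=0.9)
        assert report.n_below == n_below
        assert report.n_above == n_above
        assert round(report.cd, 2) == expected

    def test_symmetric_counts_give_unity(self):
        scores = [_score(0.1, 0), _score(2.0, 1)]
        assert compute_cd(scores).cd == 1.0

    def test_no_conspicuous_objects_raises_with_counts(self):
        with pytest.raises(CDUndefinedError) as e:
            compute_cd([_score(0.1, 0)])
        assert e.value.n_below == 1 and e.value.n_above == 0

    def test_empty_scores_raise(self):
        with pytest.raises(ValueError):
            compute_cd([])


class TestScoreDataset:
    def test_one_score_per_annotation(self, toy_dataset):
        report = score_dataset(toy_dataset, CDConfig())
        assert len(report.scores) == 3
        assert report.n_below + report.n_above == 3

    def test_conspicuous_toy_boxes_score_above_threshold(self, toy_dataset):
        # bright 200-valued boxes on a dark field are not camouflaged
        report = score_dataset(toy_dataset, CDConfig())
        assert all(s.tgc >= 0.9 for s in report.scores)

    def test_local_surround_mode_runs(self, toy_dataset):
        cfg = CDConfig(background_mode=BackgroundMode.LOCAL_SURROUND)
        report = score_dataset(toy_dataset, cfg)
        assert len(report.scores) == 3

    def test_blended_vs_disjoint_synthetic_objects(self):
        from keyfg.synthetic import SceneSpec, generate_dataset

        spec = dict(height=96, width=96, n_objects=1, min_radius=12, max_radius=18)
        blended = generate_dataset(3, SceneSpec(alpha=1.0, **spec), seed=11)
        disjoint = generate_dataset(3, SceneSpec(alpha=0.0, **spec), seed=11)
        rep_b = score_dataset(blended, CDConfig())
        for s in rep_b.scores:
            assert s.tgc < 0.9
        try:
            rep_d = score_dataset(disjoint, CDConfig())
            tgcs = [s.tgc for s in rep_d.scores]
        except CDUndefinedError:  # pragma: no cover
            tgcs = []
        assert all(t >= 0.9 for t in tgcs)

    def test_empty_dataset_raises(self, toy_dataset):
        toy_dataset.annotations = []
        with pytest.raises(ValueError):
            score_dataset(toy_dataset, CDConfig())
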