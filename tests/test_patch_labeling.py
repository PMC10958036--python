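"""Patch grid construction and the hierarchical overlap-threshold
labeling rule, checked against an independent pixel-rasterization
oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from wsidiag import (
    AnnotationSet,
    ClassLabel,
    assign_label_40x,
    build_patch_grid,
    class_coverage,
    extract_dataset,
    label_patch,
    merge_sublabels,
    n_subpatches,
)
from wsidiag.labels import DEFAULT_SEVERITY_ORDER, severity_rank

N, A, T = ClassLabel.N, ClassLabel.A, ClassLabel.T
R3, R4, R5 = ClassLabel.R3, ClassLabel.R4, ClassLabel.R5


class TestPatchGrid:
    @pytest.mark.parametrize(
        "dims,expected",
        [((512, 512), 9), ((256, 256), 1), ((500, 500), 4), ((640, 384), 4 * 2)],
    )
    def test_grid_counts(self, dims, expected):
        grid = build_patch_grid(dims)
        assert len(grid) == expected
        for x, y in grid:
            assert x % 128 == 0 and y % 128 == 0
            assert x + 256 <= dims[0] and y + 256 <= dims[1]

    def test_grid_positions_row_major(self):
        grid = build_patch_grid((512, 512))
        assert list(grid)[:4] == [(0, 0), (128, 0), (256, 0), (0, 128)]

    def test_too_small_scan_gives_empty_grid_with_warning(self):
        with pytest.warns(UserWarning, match="smaller"):
            grid = build_patch_grid((200, 300))
        assert len(grid) == 0


def _rect_annotations(rects):
    """AnnotationSet from [(x0, y0, x1, y1, label), ...]."""
    return AnnotationSet(
        "t", [(box(x0, y0, x1, y1), lab) for x0, y0, x1, y1, lab in rects]
    )


class TestCoverage:
    def test_patch_inside_single_region(self):
        ann = _rect_annotations([(0, 0, 512, 512, R3)])
        cov = class_coverage((128, 128, 384, 384), ann)
        assert cov == {R3: 1.0}

    def test_half_covered_patch(self):
        ann = _rect_annotations([(0, 0, 128, 256, N)])
        cov = class_coverage((0, 0, 256, 256), ann)
        assert cov[N] == pytest.approx(0.5)

    def test_degenerate_region_contributes_nothing(self):
        ann = AnnotationSet("t", [(box(0, 0, 0, 0), N)])
        assert class_coverage((0, 0, 256, 256), ann) == {}

    def test_coverage_matches_rasterization_oracle(self, rng):
        """Exact clipping agrees with 1px pixel counting on integer rects."""
        for _ in range(25):
            rects = []
            for _ in range(int(rng.integers(1, 6))):
                x0, y0 = rng.integers(0, 400, 2)
                w, h = rng.integers(10, 300, 2)
                lab = list(ClassLabel)[int(rng.integers(9))]
                rects.append((int(x0), int(y0), int(x0 + w), int(y0 + h), lab))
            ann = _rect_annotations(rects)
            px, py = (int(v) for v in rng.integers(0, 2, 2) * 128)
            patch = (px, py, px + 256, py + 256)
            cov = class_coverage(patch, ann)
            # oracle: rasterize each class union on a 1px grid
            for lab in {r[4] for r in rects}:
                mask = np.zeros((512, 512), bool)
                for x0, y0, x1, y1, rl in rects:
                    if rl is lab:
                        mask[y0 : min(y1, 512), x0 : min(x1, 512)] = True
                frac = mask[py : py + 256, px : px + 256].mean()
                assert cov.get(lab, 0.0) == pytest.approx(frac, abs=0.01)


class TestAssignLabel:
    @pytest.mark.parametrize(
        "coverage,expected",
        [
            ({N: 0.80}, N),
            ({R4: 0.75}, R4),  # boundary inclusive
            ({N: 0.50, R3: 0.40}, None),
            ({N: 0.80, R3: 0.80}, None),  # contradictory overlapping classes
            ({}, None),
            ({N: 0.7499}, None),
        ],
    )
    def test_threshold_rule(self, coverage, expected):
        assert assign_label_40x(coverage) is expected

    def test_exact_three_quarters_from_clipping(self):
        # 256x192 rectangle over a 256x256 patch: coverage exactly 0.75
        ann = _rect_annotations([(0, 0, 256, 192, R4)])
        cov = class_coverage((0, 0, 256, 256), ann)
        assert assign_label_40x(cov) is R4


class TestMergeSublabels:
    def test_most_severe_wins(self):
        assert merge_sublabels([N, R3, R3, R4]) is R4

    def test_identity_and_empty_cases(self):
        assert merge_sublabels([N, N, N, N]) is N
        assert merge_sublabels([None, None, None, None]) is None
        assert merge_sublabels([T, A, None, None]) is A

    @pytest.mark.parametrize("length", [0, 1, 3, 5, 32])
    def test_wrong_length_rejected(self, length):
        with pytest.raises(ValueError):
            merge_sublabels([N] * length)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        labels=st.lists(
            st.sampled_from(list(ClassLabel) + [None]), min_size=16, max_size=16
        ),
        seed=st.integers(0, 2**16),
    )
    def test_merge_is_order_free_maximum(self, labels, seed):
        """Merging is the severity maximum: permutation-invariant, and
        equal to the rank-wise max of the labeled entries."""
        perm = [labels[i] for i in np.random.default_rng(seed).permutation(16)]
        merged = merge_sublabels(labels)
        assert merge_sublabels(perm) is merged
        present = [lab for lab in labels if lab is not None]
        if present:
            assert severity_rank(merged) == max(severity_rank(p) for p in present)
        else:
            assert merged is None

    def test_commutative_and_idempotent(self, rng):
        pool = list(ClassLabel) + [None]
        for _ in range(50):
            labels = [pool[int(rng.integers(len(pool)))] for _ in range(16)]
            perm = [labels[i] for i in rng.permutation(16)]
            assert merge_sublabels(labels) is merge_sublabels(perm)
            merged = merge_sublabels(labels)
            if merged is not None:
                assert merge_sublabels([merged] * 4) is merged


def _oracle_label(x, y, magnification, rects, scan=512, threshold=0.75):
    """Independent pipeline: rasterize -> per-sub-patch coverage -> merge."""
    scale = 40 // magnification
    masks = {}
    # canvas large enough for the deepest sub-patch footprint
    for x0, y0, x1, y1, lab in rects:
        masks.setdefault(lab, np.zeros((scan * 4, scan * 4), bool))[
            y0:y1, x0:x1
        ] = True
    sub = []
    for sy in range(scale):
        for sx in range(scale):
            bx, by = x * scale + sx * 256, y * scale + sy * 256
            hits = [
                lab
                for lab, m in masks.items()
                if m[by : by + 256, bx : bx + 256].mean() >= threshold
            ]
            sub.append(hits[0] if len(hits) == 1 else None)
    present = [lab for lab in sub if lab is not None]
    if not present:
        return None
    return max(present, key=severity_rank)


class TestLabelPatch:
    def test_subdivision_counts(self):
        assert [n_subpatches(m) for m in (40, 20, 10, 5)] == [1, 4, 16, 64]

    def test_low_magnification_patch_inside_one_region(self):
        ann = _rect_annotations([(0, 0, 512, 512, R5)])
        assert label_patch(0, 0, 20, ann) is R5

    def test_label_matches_pixel_oracle_across_magnifications(self, rng):
        """Hierarchical labels agree with the rasterized brute-force pipeline."""
        for _ in range(10):
            rects = []
            for _ in range(int(rng.integers(1, 6))):
                x0, y0 = rng.integers(0, 700, 2)
                w, h = rng.integers(50, 324, 2)
                lab = list(ClassLabel)[int(rng.integers(9))]
                rects.append((int(x0), int(y0), int(x0 + w), int(y0 + h), lab))
            ann = _rect_annotations(rects)
            for mag in (40, 20, 10):
                x = int(rng.integers(0, 2)) * 128
                y = int(rng.integers(0, 2)) * 128
                assert label_patch(x, y, mag, ann) is _oracle_label(x, y, mag, rects)

    def test_monotone_in_added_disjoint_cancer_region(self):
        """Adding a cancer region disjoint from existing annotations
        never lowers any labeled patch's severity (a labeled patch has
        >= 0.75 of its class, so a disjoint addition cannot contradict
        it)."""
        base = [(0, 0, 256, 256, N), (256, 256, 512, 512, T)]
        ann0 = _rect_annotations(base)
        ann1 = _rect_annotations(base + [(256, 0, 512, 256, R4)])
        for x, y in build_patch_grid((512, 512)):
            before = label_patch(x, y, 40, ann0)
            after = label_patch(x, y, 40, ann1)
            if before is not None:
                assert after is not None
                assert severity_rank(after) >= severity_rank(before)
        # the patch fully inside the new region is upgraded from unlabeled
        assert label_patch(256, 0, 40, ann0) is None
        assert label_patch(256, 0, 40, ann1) is R4

    def test_pyramid_consistency(self, scan_bundle):
        """A coarse patch is at least as severe as any labeled sub-patch."""
        pyramid, annotations, _ = scan_bundle
        for x, y in list(build_patch_grid(pyramid.dims(10), 10))[:12]:
            coarse = label_patch(x, y, 10, annotations)
            sub = [
                label_patch(x * 4 + sx * 256, y * 4 + sy * 256, 40, annotations)
                for sy in range(4)
                for sx in range(4)
            ]
            labeled = [lab for lab in sub if lab is not None]
            if labeled:
                assert coarse is not None
                assert severity_rank(coarse) >= max(severity_rank(s) for s in labeled)
            else:
                assert coarse is None


class TestExtractDataset:
    def test_grid_rows_and_self_consistency(self, scan_bundle):
        pyramid, annotations, _ = scan_bundle
        manifest = extract_dataset(
            [pyramid],
            {pyramid.scan_id: annotations},
            {pyramid.scan_id: "train"},
            magnifications=(40, 20),
        )
        w, h = pyramid.dims(40)
        n40 = len(build_patch_grid((w, h)))
        n20 = len(build_patch_grid(pyramid.dims(20), 20))
        assert len(manifest) == n40 + n20
        for row in manifest.rows.sample(30, random_state=0).itertuples():
            expected = label_patch(row.x, row.y, row.magnification, annotations)
            assert row.label == (expected.value if expected else "")

    def test_missing_level_skipped_with_warning(self, scan_bundle):
        pyramid, annotations, _ = scan_bundle
        from wsidiag import ScanPyramid

        partial = ScanPyramid(pyramid.scan_id, {40: pyramid.levels[40]})
        with pytest.warns(UserWarning, match="missing"):
            manifest = extract_dataset(
                [partial],
                {pyramid.scan_id: annotations},
                {pyramid.scan_id: "train"},
                magnifications=(40, 5),
            )
        assert set(manifest.rows["magnification"]) == {40}

    def test_patch_images_written(self, scan_bundle, tmp_path):
        pyramid, annotations, _ = scan_bundle
        extract_dataset(
            [pyramid],
            {pyramid.scan_id: annotations},
            {pyramid.scan_id: "test"},
            out_dir=tmp_path,
            magnifications=(5,),
        )
        pngs = list((tmp_path / pyramid.scan_id / "5x").glob("*.png"))
        grid = build_patch_grid(pyramid.dims(5), 5)
        assert len(pngs) == len(grid)
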