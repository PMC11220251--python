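"""Area + roundness component filtering vs. independent flood-fill oracle."""

import numpy as np
import pytest

from maseg.morph_filter import (
    FilterParams,
    area_filter,
    fine_segment,
    label_regions,
    region_table,
    shape_filter,
    trace_perimeter,
)


def _disk_mask(radius, pad=3):
    r = int(np.ceil(radius))
    size = 2 * (r + pad) + 1
    y, x = np.mgrid[0:size, 0:size]
    c = r + pad
    return (y - c) ** 2 + (x - c) ** 2 <= radius * radius


def _disk_with_area(target):
    """Digital disk with an exact pixel count, found by scanning radius and
    sub-pixel center offsets (lattice-point counts only take certain values
    for a centered disk)."""
    for r in np.arange(1.0, 20.0, 0.01):
        for dx in (0.0, 0.25, 0.5):
            for dy in (0.0, 0.25, 0.5):
                R = int(np.ceil(r)) + 2
                y, x = np.mgrid[-R : R + 1, -R : R + 1]
                d = (y - dy) ** 2 + (x - dx) ** 2 <= r * r
                if d.sum() == target:
                    return d
    raise AssertionError(f"no digital disk with area {target}")


def _flood_fill_areas(mask):
    """Independent 8-connected component areas via stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    areas = []
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack = [(r0, c0)]
            seen[r0, c0] = True
            count = 0
            while stack:
                r, c = stack.pop()
                count += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < h
                            and 0 <= cc < w
                            and mask[rr, cc]
                            and not seen[rr, cc]
                        ):
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            areas.append(count)
    return sorted(areas)


def _place(canvas, shape_mask, row, col):
    h, w = shape_mask.shape
    canvas[row : row + h, col : col + w] |= shape_mask


@pytest.fixture
def mixed_mask():
    """Disks of exact areas {4, 5, 12, 60, 100, 101} plus a 1x20 line."""
    canvas = np.zeros((200, 200), dtype=bool)
    positions = {4: (5, 5), 5: (5, 40), 12: (5, 80), 60: (40, 5), 100: (40, 60), 101: (40, 130)}
    for area, pos in positions.items():
        _place(canvas, _disk_with_area(area), *pos)
    _place(canvas, np.ones((1, 20), dtype=bool), 120, 20)
    return canvas


class TestLabeling:
    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        regions = label_regions(mask)
        assert len(regions) == 1 and regions[0].area == 1
        assert regions[0].roundness == 0.0  # degenerate contour

    def test_two_separated_dots(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[1, 1:3] = True
        mask[1, 2] = True
        mask[4, 4:6] = True
        assert len(label_regions(mask)) == 2

    def test_empty_mask(self):
        assert label_regions(np.zeros((10, 10), dtype=bool)) == []

    def test_areas_match_flood_fill_oracle(self, rng):
        mask = np.zeros((256, 256), dtype=bool)
        for _ in range(50):
            r = int(rng.integers(1, 6))
            row = int(rng.integers(r, 256 - r))
            col = int(rng.integers(r, 256 - r))
            y, x = np.mgrid[0:256, 0:256]
            mask |= (y - row) ** 2 + (x - col) ** 2 <= r * r
        areas = sorted(reg.area for reg in label_regions(mask))
        assert areas == _flood_fill_areas(mask)

    def test_deterministic_label_order(self, rng):
        mask = rng.random((64, 64)) > 0.8
        a = [r.label for r in label_regions(mask)]
        b = [r.label for r in label_regions(mask)]
        assert a == b == sorted(a)


class TestRoundness:
    def test_digital_disk_scores_near_one(self):
        disk = _disk_mask(10)
        regions = label_regions(disk)
        assert len(regions) == 1
        assert 0.85 <= regions[0].roundness <= 1.15

    def test_disk_radius_eight_passes_gate(self):
        # release gate for the perimeter estimator
        for radius in (8, 9, 10, 12, 15):
            reg = label_regions(_disk_mask(radius))[0]
            assert reg.roundness > 0.51, f"radius {radius}: {reg.roundness}"

    def test_line_scores_low(self):
        mask = np.zeros((5, 26), dtype=bool)
        mask[2, 3:23] = True
        reg = label_regions(mask)[0]
        assert reg.area == 20
        assert reg.roundness < 0.51

    def test_approximate_scale_invariance(self):
        small = label_regions(_disk_mask(6))[0]
        large = label_regions(_disk_mask(12))[0]
        assert abs(large.roundness - small.roundness) <= 0.1 * small.roundness

    def test_perimeter_of_small_shapes(self):
        domino = np.zeros((4, 4), dtype=bool)
        domino[1, 1:3] = True
        assert trace_perimeter(domino) == pytest.approx(2.0)  # there and back
        square = np.ones((2, 2), dtype=bool)
        # clockwise walk around the 2x2 block: 4 axial steps
        assert trace_perimeter(np.pad(square, 1)) == pytest.approx(4.0)

    def test_holes_do_not_inflate_perimeter(self):
        ring = _disk_mask(8, pad=3) & ~_disk_mask(3, pad=8)
        solid = _disk_mask(8, pad=3)
        assert trace_perimeter(ring) == pytest.approx(trace_perimeter(solid))


class TestFilters:
    def test_area_boundaries_kept(self, mixed_mask):
        regions = label_regions(mixed_mask)
        kept = sorted(r.area for r in area_filter(regions))
        assert kept == [5, 12, 20, 60, 100]  # the 1x20 line passes area, not shape

    def test_fine_segment_keeps_exactly_the_round_in_band(self, mixed_mask):
        out = fine_segment(mixed_mask)
        survivors = sorted(r.area for r in label_regions(out))
        assert survivors == [5, 12, 60, 100]

    def test_empty_in_empty_out(self):
        assert area_filter([]) == []
        assert shape_filter([]) == []
        empty = np.zeros((8, 8), dtype=bool)
        assert not fine_segment(empty).any()

    def test_output_subset_and_idempotent(self, rng):
        mask = rng.random((128, 128)) > 0.7
        out = fine_segment(mask)
        assert not (out & ~mask).any()
        assert np.array_equal(fine_segment(out), out)

    def test_survivors_satisfy_both_rules(self, rng):
        mask = rng.random((128, 128)) > 0.75
        params = FilterParams()
        out = fine_segment(mask, params)
        for reg in label_regions(out):
            assert params.area_min <= reg.area <= params.area_max
            assert reg.roundness >= params.roundness_min

    def test_monotone_in_params(self, rng):
        mask = rng.random((128, 128)) > 0.75
        tight = fine_segment(mask, FilterParams(area_min=5, area_max=100, roundness_min=0.51))
        loose = fine_segment(mask, FilterParams(area_min=3, area_max=200, roundness_min=0.3))
        assert not (tight & ~loose).any()  # loose keeps every tight survivor

    def test_matches_independent_reimplementation(self, rng):
        """Survivor set equals a from-scratch flood-fill + chain-walk filter."""
        mask = rng.random((128, 128)) > 0.78
        out = fine_segment(mask)

        # independent route: flood fill components, recompute area, reuse only
        # the public perimeter tracer on isolated component crops
        from scipy import ndimage as ndi

        lab, n = ndi.label(mask, structure=np.ones((3, 3)))
        expected = np.zeros_like(mask)
        for lbl in range(1, n + 1):
            comp = lab == lbl
            area = int(comp.sum())
            if not 5 <= area <= 100:
                continue
            C = trace_perimeter(comp)
            rnd = 4 * np.pi * area / (C * C) if C > 0 else 0.0
            if rnd >= 0.51:
                expected |= comp
        assert np.array_equal(out, expected)

    def test_region_table_reasons(self, mixed_mask):
        df = region_table(label_regions(mixed_mask))
        assert set(df["status"]) == {"kept", "removed"}
        line_row = df[df["area_px"] == 20].iloc[0]
        assert line_row["status"] == "removed" and line_row["reason"] == "not round"
        big = df[df["area_px"] == 101].iloc[0]
        assert big["reason"] == "area above maximum"

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FilterParams(area_min=0).validate()
        with pytest.raises(ValueError):
            FilterParams(roundness_min=2.0).validate()
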