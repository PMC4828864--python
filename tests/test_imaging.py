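"""Aggregation-assay quantification: thresholding, clusters, classes, statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from humspec.errors import (
    EmptyInputError,
    InsufficientReplicatesError,
    ZeroReferenceError,
)
from humspec.imaging import (
    ConditionSummary,
    adhesive_strength,
    cell_count_cutoff,
    classify_and_summarize,
    cluster_channel_table,
    condition_tests,
    extract_cluster_areas,
    mixed_fraction,
    mode_single_cell_area,
    size_class,
    threshold_image,
    triangle_threshold,
)


# ---------------------------------------------------------------------------
# triangle threshold


def oracle_triangle(hist):
    """Exhaustive max-distance search over all bins, scalar arithmetic only."""
    hist = [float(v) for v in hist]
    nz = [i for i, v in enumerate(hist) if v > 0]
    lo, hi = nz[0], nz[-1]
    peak = hist.index(max(hist))
    if (hi - peak) >= (peak - lo):
        end, step = hi, 1
    else:
        end, step = lo, -1
    if end == peak:
        return peak
    x1, y1, x2, y2 = peak, hist[peak], end, hist[end]
    norm = math.hypot(x2 - x1, y2 - y1)
    best_bin, best = peak, -1.0
    b = peak + step
    while b != end + step:
        d = abs((y2 - y1) * b - (x2 - x1) * hist[b] + x2 * y1 - y2 * x1) / norm
        if d > best + 1e-12:
            best, best_bin = d, b
        b += step
    return min(len(hist) - 1, max(0, best_bin + step))


class TestTriangleThreshold:
    def test_matches_exhaustive_oracle_on_random_histograms(self, rng):
        """100 seeded histograms, assorted shapes, equal the brute-force search."""
        for _ in range(100):
            hist = np.zeros(256)
            peak = int(rng.integers(5, 250))
            hist[peak] = rng.integers(500, 5000)
            for _ in range(int(rng.integers(1, 40))):
                b = int(rng.integers(0, 256))
                hist[b] += rng.integers(1, 200)
            assert triangle_threshold(hist) == oracle_triangle(hist)

    def test_spike_with_monotone_tail(self):
        hist = np.zeros(256)
        hist[10] = 1000
        for b in range(11, 201):
            hist[b] = max(0.0, 200 - b)  # monotone decay to bin 200
        assert triangle_threshold(hist) == oracle_triangle(hist)

    def test_two_level_image_threshold_separates(self):
        img = np.full((100, 100), 20, dtype=np.uint8)
        img[:20, :20] = 220  # minority foreground
        mask, t = threshold_image(img)
        assert 20 < t < 220
        assert mask.sum() == 400

    def test_symmetric_histogram_deterministic(self):
        hist = np.zeros(256)
        hist[100:157] = np.concatenate([np.arange(1, 30), np.arange(28, 0, -1)])
        t1 = triangle_threshold(hist)
        assert t1 == triangle_threshold(hist.copy())
        assert t1 == oracle_triangle(hist)
        assert t1 > 128  # tie on tail length resolved toward the brighter side

    def test_all_zero_rejected(self):
        with pytest.raises(EmptyInputError):
            triangle_threshold(np.zeros(256))


# ---------------------------------------------------------------------------
# connected components


def oracle_flood_fill_areas(mask, min_area):
    """Iterative 8-neighbour flood fill, independent of scipy labeling."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    areas = []
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if mask[sy, sx] and not seen[sy, sx]:
                stack, area = [(sy, sx)], 0
                seen[sy, sx] = True
                while stack:
                    y, x = stack.pop()
                    area += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (0 <= ny < h and 0 <= nx < w
                                    and mask[ny, nx] and not seen[ny, nx]):
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                if area >= min_area:
                    areas.append(area)
    return sorted(areas)


class TestExtractClusters:
    def test_min_area_floor(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[:5, :10] = True   # 50 px, below the floor
        mask[20:30, 20:35] = True  # 150 px
        areas = extract_cluster_areas(mask, min_area=100)
        assert list(areas) == [150]

    def test_empty_mask(self):
        assert len(extract_cluster_areas(np.zeros((10, 10), dtype=bool))) == 0

    def test_diagonal_connectivity_8_vs_4(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[:10, :10] = True
        mask[10:20, 10:20] = True  # touches only at one corner
        assert list(extract_cluster_areas(mask, min_area=1, connectivity=8)) == [200]
        assert sorted(extract_cluster_areas(mask, min_area=1, connectivity=4)) == [100, 100]

    def test_random_blobs_match_flood_fill_oracle(self, rng):
        mask = rng.random((80, 80)) < 0.45
        got = sorted(extract_cluster_areas(mask, min_area=5))
        assert got == oracle_flood_fill_areas(mask, 5)


# ---------------------------------------------------------------------------
# spherical model


class TestCellCountCutoff:
    @pytest.mark.parametrize("area,n,expected", [(150, 10, 696), (150, 30, 1448)])
    def test_published_cutoffs(self, area, n, expected):
        assert cell_count_cutoff(area, n) == expected

    @pytest.mark.parametrize("area", [1, 97, 150, 1000])
    def test_single_cell_identity(self, area):
        assert cell_count_cutoff(area, 1) == area

    def test_strictly_increasing_in_cells_linear_in_area(self):
        cuts = [cell_count_cutoff(150, n) for n in range(1, 60)]
        assert all(a < b for a, b in zip(cuts, cuts[1:]))
        assert cell_count_cutoff(300, 10) == pytest.approx(2 * 696, abs=1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cell_count_cutoff(0, 10)
        with pytest.raises(ValueError):
            cell_count_cutoff(150, 0)


class TestSizeClasses:
    def test_boundaries_inclusive_medium(self):
        assert size_class(695) == "small"
        assert size_class(696) == "medium"
        assert size_class(1448) == "medium"
        assert size_class(1449) == "large"

    def test_exhaustive_and_exclusive(self):
        for area in range(100, 2000, 7):
            assert size_class(area) in {"small", "medium", "large"}

    def test_fractions_and_ge10(self):
        s = classify_and_summarize([150, 700, 1500], 150)
        assert (s.fraction_small, s.fraction_medium, s.fraction_large) == (
            pytest.approx(1 / 3), pytest.approx(1 / 3), pytest.approx(1 / 3))
        assert s.fraction_ge10 == pytest.approx(2 / 3)
        assert s.fraction_small + s.fraction_medium + s.fraction_large == pytest.approx(1)

    def test_all_small(self):
        s = classify_and_summarize([100, 200, 650], 150)
        assert (s.fraction_small, s.fraction_ge10) == (1.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            classify_and_summarize([], 150)


class TestModeSingleCellArea:
    def test_control_like_sample(self, rng):
        areas = np.concatenate([
            rng.integers(145, 156, size=200),  # singles around 150
            rng.integers(290, 320, size=30),   # a few doublets
        ])
        assert abs(mode_single_cell_area(areas) - 150) <= 5

    def test_single_area(self):
        assert mode_single_cell_area([137]) == 135.0  # its bin center

    def test_bimodal_heavier_mode_wins(self, rng):
        light = rng.integers(100, 110, size=40)
        heavy = rng.integers(300, 310, size=60)
        got = mode_single_cell_area(np.concatenate([light, heavy]))
        assert 300 <= got <= 310

    def test_tie_takes_smaller_bin(self):
        assert mode_single_cell_area([100, 100, 300, 300]) == 105.0


class TestAdhesiveStrength:
    def _summary(self, ge10):
        return ConditionSummary(10, 1 - ge10, ge10, 0.0, ge10)

    def test_ratio(self):
        assert adhesive_strength(self._summary(0.2), self._summary(0.4)) == pytest.approx(0.5)

    def test_self_normalization(self):
        s = self._summary(0.37)
        assert adhesive_strength(s, s) == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroReferenceError):
            adhesive_strength(self._summary(0.2), self._summary(0.0))

    def test_day_paired_batch_matches_hand_ratios(self):
        days = {"d1": (0.1, 0.5), "d2": (0.3, 0.6)}
        got = {d: adhesive_strength(self._summary(a), self._summary(b))
               for d, (a, b) in days.items()}
        assert got == {"d1": pytest.approx(0.2), "d2": pytest.approx(0.5)}


# ---------------------------------------------------------------------------
# mixing


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


class TestMixedFraction:
    def test_disjoint_single_color_clusters(self):
        g = _disk_mask((200, 200), 50, 50, 10)
        r = _disk_mask((200, 200), 150, 150, 10)
        assert mixed_fraction(g, r, min_area=100) == 0.0

    def test_every_cluster_mixed(self):
        g = _disk_mask((200, 200), 50, 50, 10) | _disk_mask((200, 200), 150, 150, 10)
        r = _disk_mask((200, 200), 52, 52, 10) | _disk_mask((200, 200), 148, 148, 10)
        assert mixed_fraction(g, r, min_area=100) == 1.0

    def test_symmetric_under_channel_swap(self, rng):
        g = rng.random((120, 120)) < 0.3
        r = rng.random((120, 120)) < 0.3
        assert mixed_fraction(g, r, 20) == mixed_fraction(r, g, 20)

    def test_min_area_applies_to_union(self):
        # two sub-floor half-disks merge into one above-floor mixed cluster
        g = np.zeros((60, 60), dtype=bool)
        r = np.zeros((60, 60), dtype=bool)
        g[20:30, 20:27] = True  # 70 px
        r[20:30, 27:34] = True  # 70 px, adjacent
        assert mixed_fraction(g, r, min_area=100) == 1.0
        table = cluster_channel_table(g, r, min_area=100)
        assert table["area"].tolist() == [140]

    def test_no_clusters_rejected(self):
        empty = np.zeros((50, 50), dtype=bool)
        with pytest.raises(EmptyInputError):
            mixed_fraction(empty, empty)


# ---------------------------------------------------------------------------
# condition-level statistics


def _one_way_frame(rng, means, sd=0.05, n=4):
    rows = []
    for name, mu in means.items():
        for v in rng.normal(mu, sd, size=n):
            rows.append({"condition": name, "value": v})
    return pd.DataFrame(rows)


class TestConditionTests:
    def test_separated_conditions_all_pairwise_significant(self):
        """Means 0.1/0.5/1.0, sd 0.05, n=4: Tukey separates all pairs >=95% of reruns."""
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            df = _one_way_frame(rng, {"none": 0.1, "weak": 0.5, "strong": 1.0})
            rep = condition_tests(df, design="one_way")
            if (rep.contrasts["p-adj"] < 0.05).all():
                hits += 1
        assert hits / n_rep >= 0.95

    def test_null_type_one_error_near_nominal(self):
        """Identical distributions: one-way ANOVA rejects at ~the 0.05 level."""
        rejections = 0
        n_sim = 400
        for seed in range(n_sim):
            rng = np.random.default_rng(50_000 + seed)
            df = _one_way_frame(rng, {"a": 0.5, "b": 0.5, "c": 0.5}, sd=0.1, n=5)
            rep = condition_tests(df, design="one_way")
            rejections += float(rep.anova["p"].iloc[0]) < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_duplicated_condition_contrast_not_significant(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0.5, 0.05, size=6)
        df = pd.DataFrame({
            "condition": ["a"] * 6 + ["b"] * 6,
            "value": np.concatenate([base, base]),
        })
        rep = condition_tests(df, design="one_way")
        assert float(rep.contrasts["p-adj"].iloc[0]) > 0.9

    def test_insufficient_replicates_rejected(self):
        df = pd.DataFrame({"condition": ["a", "b"], "value": [1.0, 2.0]})
        with pytest.raises(InsufficientReplicatesError):
            condition_tests(df, design="one_way")

    def test_two_way_mixing_design(self, rng):
        rows = []
        for pop_g in ["control", "B11", "GA3"]:
            for pop_r in ["control", "B11", "GA3"]:
                mu = 0.6 if (pop_g == pop_r != "control") else 0.05
                for v in rng.normal(mu, 0.04, size=6):
                    rows.append({"pop_green": pop_g, "pop_red": pop_r,
                                 "mixed_fraction": max(0.0, v)})
        df = pd.DataFrame(rows)
        rep = condition_tests(df, design="two_way", control="control")
        assert {"C(fa)", "C(fb)", "C(fa):C(fb)"} <= set(rep.anova.index)
        assert (rep.anova.loc["C(fa):C(fb)", "PR(>F)"]) < 1e-8
        match = rep.contrasts.query("subpanel == 'B11' and comparison == 'B11 vs control'")
        assert float(match["p_adj"].iloc[0]) < 0.01
        assert (rep.contrasts["p_adj"] <= 1.0).all()
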