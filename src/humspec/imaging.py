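"""Quantification of cell-aggregation assay micrographs.

Adhesion in the K562 aggregation assay is read out from fluorescence images:
each field is auto-thresholded with the triangle algorithm, connected
components of at least 100 px are counted as cell clusters, and cluster
pixel areas are converted to cell-count classes under a spherical-cluster
model — a ball of N close-packed cells projects an area proportional to
N^(2/3) times the single-cell area (150 px by default, the mode cluster size
of control-transfected cells). Adhesive strength is the fraction of clusters
of >= 10 cells, normalised to a strong-adhesion reference condition imaged
the same day. Cross-adhesion between two differently labelled populations is
the fraction of clusters containing both green and red cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import (
    EmptyInputError,
    InsufficientReplicatesError,
    ZeroReferenceError,
)

DEFAULT_MIN_AREA = 100
DEFAULT_SINGLE_CELL_AREA = 150
#: cell-count boundaries of the small / medium / large classes
CLASS_CELLS = (10, 30)

SizeClass = Literal["small", "medium", "large"]


# ---------------------------------------------------------------------------
# thresholding


def triangle_threshold(histogram: np.ndarray) -> int:
    """Triangle auto-threshold over a 256-bin intensity histogram.

    A line is drawn from the histogram peak to the far end of the nonzero
    range on the longer-tail side (tie -> brighter side); the threshold is
    the bin with maximal perpendicular distance to that line (tie -> bin
    closest to the peak), offset by one bin toward the tail.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or len(hist) == 0 or not np.any(hist > 0):
        raise EmptyInputError("histogram has no nonzero bin")
    nz = np.nonzero(hist)[0]
    lo, hi = int(nz[0]), int(nz[-1])
    peak = int(np.argmax(hist))
    # longer tail side; tie -> brighter (right) side
    if (hi - peak) >= (peak - lo):
        end, step = hi, 1
    else:
        end, step = lo, -1
    if end == peak:
        return peak
    x1, y1 = float(peak), hist[peak]
    x2, y2 = float(end), hist[end]
    norm = math.hypot(x2 - x1, y2 - y1)
    best_bin, best_dist = peak, -1.0
    for b in range(peak + step, end + step, step):
        # perpendicular distance from (b, hist[b]) to the peak-end line
        d = abs((y2 - y1) * b - (x2 - x1) * hist[b] + x2 * y1 - y2 * x1) / norm
        if d > best_dist + 1e-12:
            best_dist, best_bin = d, b
    return int(np.clip(best_bin + step, 0, len(hist) - 1))


def threshold_image(image: np.ndarray) -> tuple[np.ndarray, int]:
    """Binarize one channel (bright objects on dark background).

    8-bit images use the native 0..255 histogram; other dtypes are binned
    into 256 equal-width bins over the observed range. Returns (mask,
    threshold on the image's own intensity scale).
    """
    image = np.asarray(image)
    if image.dtype == np.uint8:
        hist = np.bincount(image.ravel(), minlength=256)
        t = triangle_threshold(hist)
        return image >= t, t
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        raise EmptyInputError("constant image cannot be thresholded")
    hist, edges = np.histogram(image, bins=256, range=(lo, hi))
    t_bin = triangle_threshold(hist)
    t = edges[t_bin]
    return image >= t, t


# ---------------------------------------------------------------------------
# clusters and the spherical-cluster model


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def label_clusters(
    mask: np.ndarray, min_area: int = DEFAULT_MIN_AREA, connectivity: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of a binary mask with the area floor applied.

    Returns (label image with sub-threshold components zeroed, areas of the
    retained components in label order).
    """
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=_structure(connectivity))
    if n == 0:
        return labels, np.array([], dtype=int)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = areas >= min_area
    remap = np.zeros(n + 1, dtype=int)
    remap[1:][keep] = np.arange(1, keep.sum() + 1)
    return remap[labels], areas[keep].astype(int)


def extract_cluster_areas(
    mask: np.ndarray, min_area: int = DEFAULT_MIN_AREA, connectivity: int = 8
) -> np.ndarray:
    """Pixel areas of all connected components of at least ``min_area``."""
    _, areas = label_clusters(mask, min_area, connectivity)
    return areas


def cell_count_cutoff(single_cell_area: int, n_cells: int) -> int:
    """Projected area of a spherical cluster of ``n_cells`` cells, in pixels.

    round(single_cell_area * n_cells^(2/3)), half away from zero — e.g.
    150 px cells give cutoffs 696 px (10 cells) and 1448 px (30 cells).
    """
    if single_cell_area <= 0:
        raise ValueError("single_cell_area must be positive")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return int(math.floor(single_cell_area * n_cells ** (2.0 / 3.0) + 0.5))


def size_class(area: int, single_cell_area: int = DEFAULT_SINGLE_CELL_AREA) -> SizeClass:
    """small: < 10 cells; medium: 10-30 cells inclusive; large: > 30 cells."""
    lo = cell_count_cutoff(single_cell_area, CLASS_CELLS[0])
    hi = cell_count_cutoff(single_cell_area, CLASS_CELLS[1])
    if area < lo:
        return "small"
    if area <= hi:
        return "medium"
    return "large"


def mode_single_cell_area(areas: Iterable[int], bin_width: int = 10) -> float:
    """Center of the most populated area-histogram bin (ties -> smaller bin).

    Applied to control-transfected (mostly single-cell) images, this
    estimates the single-cell area that anchors the spherical model.
    """
    areas = np.asarray(list(areas))
    if areas.size == 0:
        raise EmptyInputError("no areas given")
    idx = (areas // bin_width).astype(int)
    counts = np.bincount(idx)
    best = int(np.argmax(counts))  # argmax takes the first (smaller) bin on ties
    return (best + 0.5) * bin_width


@dataclass(frozen=True)
class ConditionSummary:
    """Cluster-size composition of one condition (one field or one pooled day)."""

    n_clusters: int
    fraction_small: float
    fraction_medium: float
    fraction_large: float
    fraction_ge10: float
    normalized_strength: float | None = None
    mixed_fraction: float | None = None


def classify_and_summarize(
    areas: Iterable[int], single_cell_area: int = DEFAULT_SINGLE_CELL_AREA
) -> ConditionSummary:
    """Size-class fractions of a set of cluster areas."""
    areas = np.asarray(list(areas))
    if areas.size == 0:
        raise EmptyInputError("no clusters to summarize")
    classes = np.array([size_class(a, single_cell_area) for a in areas])
    n = len(areas)
    f_small = float(np.mean(classes == "small"))
    f_medium = float(np.mean(classes == "medium"))
    f_large = float(np.mean(classes == "large"))
    return ConditionSummary(n, f_small, f_medium, f_large, f_medium + f_large)


def adhesive_strength(summary: ConditionSummary, reference: ConditionSummary) -> float:
    """Fraction of >=10-cell clusters, relative to the reference condition."""
    if reference.fraction_ge10 <= 0:
        raise ZeroReferenceError("reference condition has no clusters of >= 10 cells")
    return summary.fraction_ge10 / reference.fraction_ge10


# ---------------------------------------------------------------------------
# two-channel mixing


def cluster_channel_table(
    green_mask: np.ndarray,
    red_mask: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    connectivity: int = 8,
) -> pd.DataFrame:
    """Per-cluster channel membership on the union of the two masks.

    The channel masks are combined by logical OR; each union component of at
    least ``min_area`` is tested for overlap with either channel.
    """
    green_mask = np.asarray(green_mask, dtype=bool)
    red_mask = np.asarray(red_mask, dtype=bool)
    if green_mask.shape != red_mask.shape:
        raise ValueError("green and red masks differ in shape")
    labels, areas = label_clusters(green_mask | red_mask, min_area, connectivity)
    rows = []
    for k, area in enumerate(areas, start=1):
        member = labels == k
        rows.append(
            {
                "cluster": k,
                "area": int(area),
                "has_green": bool(np.any(member & green_mask)),
                "has_red": bool(np.any(member & red_mask)),
            }
        )
    return pd.DataFrame(rows, columns=["cluster", "area", "has_green", "has_red"])


def mixed_fraction(
    green_mask: np.ndarray,
    red_mask: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    connectivity: int = 8,
) -> float:
    """Proportion of union clusters containing both green and red pixels."""
    table = cluster_channel_table(green_mask, red_mask, min_area, connectivity)
    if table.empty:
        raise EmptyInputError("no clusters of sufficient area in the union mask")
    return float((table["has_green"] & table["has_red"]).mean())


# ---------------------------------------------------------------------------
# condition-level statistics


@dataclass(frozen=True)
class TestReport:
    design: str
    anova: pd.DataFrame
    contrasts: pd.DataFrame

    def to_text(self) -> str:
        return (
            f"design: {self.design}\n\n"
            + self.anova.to_string()
            + "\n\n"
            + self.contrasts.to_string(index=False)
        )


def _check_replicates(df: pd.DataFrame, factor: str, value: str) -> None:
    sizes = df.groupby(factor)[value].count()
    if len(sizes) < 2 or (sizes < 2).any():
        raise InsufficientReplicatesError(
            f"need >= 2 levels of {factor!r} with >= 2 replicates each"
        )


def one_way_condition_test(
    df: pd.DataFrame, value: str = "value", condition: str = "condition"
) -> TestReport:
    """One-way ANOVA over conditions plus all-pairs Tukey HSD contrasts."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    _check_replicates(df, condition, value)
    groups = [g[value].to_numpy() for _, g in df.groupby(condition)]
    f, p = stats.f_oneway(*groups)
    anova = pd.DataFrame({"F": [float(f)], "p": [float(p)]}, index=["condition"])
    tk = pairwise_tukeyhsd(df[value], df[condition])
    summary = tk.summary()
    contrasts = pd.DataFrame(
        summary.data[1:], columns=[str(c).lower() for c in summary.data[0]]
    )
    return TestReport("one_way", anova, contrasts)


def two_way_mixing_test(
    df: pd.DataFrame,
    value: str = "mixed_fraction",
    factor_a: str = "pop_green",
    factor_b: str = "pop_red",
    control: str = "control",
) -> TestReport:
    """Two-way ANOVA on mixed fractions with per-subpanel Bonferroni contrasts.

    The two population identities (and their interaction) are the factors.
    Within each level of ``factor_a`` (a subpanel), every level of
    ``factor_b`` is compared against ``control`` by a linear model; the
    contrast p-values are Bonferroni-adjusted within the subpanel.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multitest import multipletests

    _check_replicates(df, factor_a, value)
    _check_replicates(df, factor_b, value)
    data = df.rename(columns={value: "y", factor_a: "fa", factor_b: "fb"})
    model = smf.ols("y ~ C(fa) * C(fb)", data=data).fit()
    anova = anova_lm(model, typ=2)
    rows = []
    for level_a, sub in data.groupby("fa"):
        if control not in set(sub["fb"]) or sub["fb"].nunique() < 2:
            continue
        m = smf.ols(f"y ~ C(fb, Treatment(reference={control!r}))", data=sub).fit()
        coefs = [c for c in m.params.index if c != "Intercept"]
        pvals = np.array([m.pvalues[c] for c in coefs])
        adj = multipletests(pvals, method="bonferroni")[1]
        for c, p_raw, p_adj in zip(coefs, pvals, adj):
            level_b = c.split("[T.")[-1].rstrip("]")
            rows.append(
                {
                    "subpanel": level_a,
                    "comparison": f"{level_b} vs {control}",
                    "estimate": float(m.params[c]),
                    "p": float(p_raw),
                    "p_adj": float(min(1.0, p_adj)),
                }
            )
    contrasts = pd.DataFrame(rows, columns=["subpanel", "comparison", "estimate", "p", "p_adj"])
    return TestReport("two_way", anova, contrasts)


def condition_tests(
    df: pd.DataFrame,
    design: str = "one_way",
    control: str = "control",
    **kwargs,
) -> TestReport:
    """Dispatch to the one-way (adhesive strength) or two-way (mixing) test."""
    if design == "one_way":
        return one_way_condition_test(df, **kwargs)
    if design == "two_way":
        return two_way_mixing_test(df, control=control, **kwargs)
    raise ValueError(f"unknown design {design!r}")
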