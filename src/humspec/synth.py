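"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Every downstream stage can be exercised without the original panel data or
raw micrographs:

* ortholog panels with *planted* fixed human-lineage substitutions — at a
  planted site all human haplotypes carry the derived residue and all
  outgroups the ancestral one; elsewhere human and outgroup consensus agree,
  with haplotype-level polymorphism at a configurable per-site rate that
  never touches planted sites (so fixation stays testable at any rate);
* dbSNP-like variant tables with exact per-gene consequence-class totals;
* GO annotation tables that round-trip losslessly through the reader;
* two-channel micrographs of disk-shaped cell clusters whose pixel areas
  follow the spherical N^(2/3) law exactly, with per-cluster ground truth
  (center, area, cell count, channel membership) and a controllable
  co-clustering rate.

All randomness flows from one ``numpy`` generator seeded per call; identical
spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DuplicateIdError, PlacementError, PlantingError, UnknownClassError
from .ontology import (
    MEMBRANE_TERMS,
    AnnotationRecord,
    write_annotations,
)
from .panel import AMINO_ACIDS, DEFAULT_OUTGROUPS, OrthologPanel
from .variability import CONSEQUENCE_CLASSES


# ---------------------------------------------------------------------------
# ortholog panels


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of one synthetic ortholog panel.

    ``planted_substitutions`` are (1-based position, ancestral, human)
    triples; ``polymorphism_rate`` is the per-site probability that a human
    haplotype carries a random non-consensus residue at a *non-planted* site.
    ``break_fixation`` flips one haplotype at one planted site, for negative
    tests of the fixation criterion.
    """

    protein_id: str = "SYN"
    n_human_haplotypes: int = 100
    protein_length: int = 300
    planted_substitutions: tuple[tuple[int, str, str], ...] = ()
    polymorphism_rate: float = 0.0
    outgroup_names: tuple[str, ...] = DEFAULT_OUTGROUPS
    break_fixation: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.polymorphism_rate <= 1.0:
            raise PlantingError("polymorphism_rate outside [0, 1]")
        if self.n_human_haplotypes < 1 or self.protein_length < 1:
            raise PlantingError("need >= 1 haplotype and >= 1 residue")
        positions = [p for p, _, _ in self.planted_substitutions]
        if len(set(positions)) != len(positions):
            raise PlantingError("planted positions must be unique")
        for pos, anc, hum in self.planted_substitutions:
            if not 1 <= pos <= self.protein_length:
                raise PlantingError(
                    f"planted position {pos} outside [1, {self.protein_length}]"
                )
            if anc == hum:
                raise PlantingError(f"planted site {pos}: ancestral == human ({anc})")
            if anc not in AMINO_ACIDS or hum not in AMINO_ACIDS:
                raise PlantingError(f"planted site {pos}: residues must be standard")


def gen_ortholog_panel(spec: PanelSpec) -> OrthologPanel:
    """Generate an aligned panel with the planted fixed substitutions."""
    rng = np.random.default_rng(spec.seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    consensus = rng.choice(aa, size=spec.protein_length)
    planted_idx = np.array(
        [p - 1 for p, _, _ in spec.planted_substitutions], dtype=int
    )
    ancestral = consensus.copy()
    human_base = consensus.copy()
    for pos, anc, hum in spec.planted_substitutions:
        ancestral[pos - 1] = anc.encode()
        human_base[pos - 1] = hum.encode()

    humans = np.tile(human_base, (spec.n_human_haplotypes, 1))
    if spec.polymorphism_rate > 0:
        noise = rng.random(humans.shape) < spec.polymorphism_rate
        if planted_idx.size:
            noise[:, planted_idx] = False  # planted sites stay fixed
        n_flips = int(noise.sum())
        if n_flips:
            humans[noise] = rng.choice(aa, size=n_flips)
    if spec.break_fixation:
        if not spec.planted_substitutions:
            raise PlantingError("break_fixation requires a planted site")
        pos, anc, _ = spec.planted_substitutions[0]
        humans[0, pos - 1] = anc.encode()

    human_seqs = [h.tobytes().decode() for h in humans]
    ancestral_seq = ancestral.tobytes().decode()
    return OrthologPanel(
        spec.protein_id,
        human_seqs,
        {name: ancestral_seq for name in spec.outgroup_names},
    )


# ---------------------------------------------------------------------------
# variant tables


def gen_variant_table(
    class_counts: Mapping[str, Mapping[str, int]], seed: int = 0
) -> pd.DataFrame:
    """One row per variant (gene, consequence_class, position).

    ``class_counts`` maps gene -> consequence class -> count; per-gene class
    totals in the output equal the request exactly. Positions are distinct
    within a gene; row order is shuffled by the seeded generator.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted(class_counts):
        counts = class_counts[gene]
        unknown = set(counts) - CONSEQUENCE_CLASSES
        if unknown:
            raise UnknownClassError(f"{gene}: unknown classes {sorted(unknown)}")
        if any(c < 0 for c in counts.values()):
            raise UnknownClassError(f"{gene}: negative count")
        total = sum(counts.values())
        positions = rng.permutation(np.arange(1, 3 * total + 1))[:total] if total else []
        i = 0
        for cls in sorted(counts):
            for _ in range(counts[cls]):
                rows.append(
                    {"gene": gene, "consequence_class": cls, "position": int(positions[i])}
                )
                i += 1
    df = pd.DataFrame(rows, columns=["gene", "consequence_class", "position"])
    if len(df):
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# GO annotation tables


def gen_go_table(
    entries: Iterable[tuple[str, str, Sequence[str]]], path: str | Path | None = None
) -> list[AnnotationRecord]:
    """Build annotation records from (protein id, accession, terms) entries."""
    records = []
    seen = set()
    for pid, accession, terms in entries:
        if pid in seen:
            raise DuplicateIdError(f"duplicate protein id {pid!r}")
        seen.add(pid)
        records.append(AnnotationRecord(pid, accession, frozenset(terms)))
    if path is not None:
        write_annotations(records, path)
    return records


_NEURAL_VOCAB = (
    "neuron projection",
    "axon guidance",
    "dendrite morphogenesis",
    "synaptic membrane",
    "nervous system development",
)
_DECOY_VOCAB = (
    "synaptonemal complex",
    "axonemal dynein complex",
    "dendritic cell differentiation",
    "enteric nervous system development",
    "cytoplasm",
    "nucleus",
    "extracellular region",
)


def gen_random_annotations(
    n: int, seed: int = 0, p_surface: float = 0.3, p_neural: float = 0.5
) -> list[AnnotationRecord]:
    """Random annotation universe mixing qualifying and decoy term sets."""
    rng = np.random.default_rng(seed)
    letters = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
    entries = []
    for i in range(n):
        accession = "".join(rng.choice(letters, size=3)) + str(rng.integers(10, 99))
        terms = set(rng.choice(_DECOY_VOCAB, size=2, replace=False))
        if rng.random() < p_surface:
            terms.add(MEMBRANE_TERMS[int(rng.random() < 0.2)])
        if rng.random() < p_neural:
            terms.add(str(rng.choice(_NEURAL_VOCAB)))
        entries.append((f"P{i:04d}", accession, sorted(map(str, terms))))
    return gen_go_table(entries)


# ---------------------------------------------------------------------------
# cluster images

#: cells-per-cluster distributions emulating the three adhesion regimes of
#: the aggregation assay: no protocadherin (almost only single cells), weak
#: homophilic adhesion (PCDHB11-like) and strong adhesion (PCDHGA3-like).
#: Zero-truncated geometric p of 0.8 / 0.35 / 0.15 gives expected >=10-cell
#: cluster fractions of ~0, ~2% and ~23%.
ADHESION_PRESETS: dict[str, tuple[str, Mapping[str, float]]] = {
    "none": ("geometric", {"p": 0.8}),
    "pcdhb11_like": ("geometric", {"p": 0.35}),
    "pcdhga3_like": ("geometric", {"p": 0.15}),
}


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic two-channel aggregation field.

    ``cell_count_distribution`` is a (name, params) pair over cells per
    cluster: ``("geometric", {"p": ...})`` (zero-truncated, long-tailed small
    clusters — the default regime of the assay), ``("fixed", {"n": ...})`` or
    ``("uniform", {"low": ..., "high": ...})``. ``channel_mix_rate`` is the
    probability that a cluster contains cells of both colors.
    """

    image_size: tuple[int, int] = (512, 512)
    single_cell_area: int = 150
    cluster_count: int = 30
    cell_count_distribution: tuple[str, Mapping[str, float]] = (
        "geometric",
        {"p": 0.5},
    )
    channel_mix_rate: float = 0.0
    background_level: float = 20.0
    foreground_level: float = 220.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.single_cell_area <= 0:
            raise ValueError("single_cell_area must be positive")
        if not 0.0 <= self.channel_mix_rate <= 1.0:
            raise ValueError("channel_mix_rate outside [0, 1]")
        if self.foreground_level <= self.background_level:
            raise ValueError("foreground_level must exceed background_level")


def _draw_cells(rng: np.random.Generator, dist: tuple[str, Mapping[str, float]], size: int):
    name, params = dist
    if name == "geometric":
        return rng.geometric(params["p"], size=size)  # zero-truncated by construction
    if name == "fixed":
        return np.full(size, int(params["n"]), dtype=int)
    if name == "uniform":
        return rng.integers(int(params["low"]), int(params["high"]) + 1, size=size)
    raise ValueError(f"unknown cell count distribution {name!r}")


def _disk_pixels(cy: int, cx: int, area: int, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """The ``area`` pixels nearest the center: a rasterized disk of exact area."""
    r = int(np.ceil(np.sqrt(area / np.pi))) + 2
    yy, xx = np.mgrid[cy - r: cy + r + 1, cx - r: cx + r + 1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    flat = np.argsort(d2, axis=None, kind="stable")[:area]
    return yy.ravel()[flat], xx.ravel()[flat]


@dataclass(frozen=True)
class SyntheticField:
    """One generated two-channel field.

    ``green``/``red`` are the rendered noisy 8-bit images; ``green_mask``/
    ``red_mask`` the noise-free ground-truth channel masks; ``truth`` has one
    row per cluster (center, pixel area — exactly round(A1 * N^(2/3)) —,
    drawn cell count, channel membership).
    """

    green: np.ndarray
    red: np.ndarray
    green_mask: np.ndarray
    red_mask: np.ndarray
    truth: pd.DataFrame


def gen_cluster_image(spec: ImageSpec) -> SyntheticField:
    """Render a two-channel field of non-overlapping disk clusters.

    Raises ``PlacementError`` when the requested clusters cannot be placed
    without overlap within a bounded number of attempts.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    n_cells = _draw_cells(rng, spec.cell_count_distribution, spec.cluster_count)
    areas = np.floor(spec.single_cell_area * n_cells ** (2.0 / 3.0) + 0.5).astype(int)
    radii = np.sqrt(areas / np.pi)

    centers: list[tuple[int, int]] = []
    margin = 2
    for i in range(spec.cluster_count):
        r = radii[i] + margin
        placed = False
        for _ in range(2000):
            cy = int(rng.integers(int(np.ceil(r)), int(h - r)))
            cx = int(rng.integers(int(np.ceil(r)), int(w - r)))
            if all(
                (cy - y) ** 2 + (cx - x) ** 2 > (r + radii[j] + margin) ** 2
                for j, (y, x) in enumerate(centers)
            ):
                centers.append((cy, cx))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place cluster {i + 1}/{spec.cluster_count} "
                f"(area {areas[i]}) in {spec.image_size}"
            )

    mixed = rng.random(spec.cluster_count) < spec.channel_mix_rate
    green_only = rng.random(spec.cluster_count) < 0.5

    green = np.zeros((h, w), dtype=bool)
    red = np.zeros((h, w), dtype=bool)
    truth_rows = []
    for i, (cy, cx) in enumerate(centers):
        ys, xs = _disk_pixels(cy, cx, areas[i], (h, w))
        if mixed[i]:
            left = xs < cx  # split the disk: both colors present
            if not left.any() or left.all():
                left = np.zeros_like(left)
                left[: len(left) // 2] = True
            green[ys[left], xs[left]] = True
            red[ys[~left], xs[~left]] = True
            has_green = has_red = True
        elif green_only[i]:
            green[ys, xs] = True
            has_green, has_red = True, False
        else:
            red[ys, xs] = True
            has_green, has_red = False, True
        truth_rows.append(
            {
                "cluster": i + 1,
                "cy": cy,
                "cx": cx,
                "n_cells": int(n_cells[i]),
                "area": int(areas[i]),
                "has_green": has_green,
                "has_red": has_red,
            }
        )

    def render(mask: np.ndarray) -> np.ndarray:
        img = np.full((h, w), spec.background_level, dtype=float)
        img[mask] = spec.foreground_level
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        return np.clip(img, 0, 255).astype(np.uint8)

    truth = pd.DataFrame(truth_rows)
    return SyntheticField(render(green), render(red), green, red, truth)


def write_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, image)
    return path
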