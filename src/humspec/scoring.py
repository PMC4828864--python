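"""Exchange-rareness weights from substitution matrices; protein scoring and ranking.

A substitution score matrix (BLOSUM family) assigns high scores to amino-acid
pairs that frequently replace one another between closely related proteins.
To weight fixed human-lineage substitutions by how *unusual* the exchange is,
the off-diagonal scores are mapped affinely and decreasingly onto integer
weights: the most common exchanges get weight 3, the least common exchange
weight 15. Per-protein scores are the weighted sum over that protein's
substitutions, optionally normalised by protein length.

The default BLOSUM100 weighting uses a calibration frozen once against the
published PCDHB11 exchange weights: ``w = clip(5 - s, 3, 15)``. For any other
score matrix the generic endpoint map (max off-diagonal score -> 3, min -> 15)
applies; rate/exchangeability matrices (e.g. the JTT data), whose scale is not
log-odds, are rank-transformed before the same map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateMatrixError, IdMismatchError, MissingPairError
from .panel import AMINO_ACIDS, Substitution

#: weight assigned to the most common exchange / the least common exchange
WEIGHT_MIN, WEIGHT_MAX = 3, 15

#: frozen affine calibration reproducing the published PCDHB11 pair weights
#: under the bundled BLOSUM100 (slope, intercept, clipped into [3, 15])
FROZEN_BLOSUM100_CALIBRATION = (-1.0, 5.0)

#: named matrices treated as rates/exchangeabilities rather than log-odds
RATE_MATRICES = frozenset({"JONES", "DAYHOFF", "BENNER22", "BENNER6", "BENNER74"})


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric amino-acid pair scores over the 20-letter alphabet."""

    name: str
    entries: Mapping[tuple[str, str], float]
    kind: Literal["score", "rate"] = "score"

    def score(self, a: str, b: str) -> float:
        return self.entries[(a, b)] if (a, b) in self.entries else self.entries[(b, a)]

    def off_diagonal(self) -> dict[frozenset, float]:
        out = {}
        for i, a in enumerate(AMINO_ACIDS):
            for b in AMINO_ACIDS[i + 1:]:
                out[frozenset((a, b))] = self.score(a, b)
        return out


def load_matrix(source: str | Path, kind: str | None = None) -> ScoreMatrix:
    """Load a matrix by name ("BLOSUM100", "BLOSUM62", "JONES", ...) or file path.

    BLOSUM100 comes from biotite's matrix database; other names from
    biopython; paths are parsed as NCBI-style whitespace-delimited square
    matrices. ``kind`` overrides rate-vs-score detection.
    """
    name = str(source)
    if isinstance(source, Path) or "/" in name or name.endswith((".txt", ".mat")):
        from Bio.Align import substitution_matrices

        with open(source) as fh:
            arr = substitution_matrices.read(fh)
        entries = _from_biopython(arr)
        name = Path(source).stem
    elif name.upper() == "BLOSUM100":
        import biotite.sequence as bseq
        import biotite.sequence.align as balign

        alph = bseq.ProteinSequence.alphabet
        m = balign.SubstitutionMatrix(alph, alph, "BLOSUM100")
        entries = {
            (a, b): float(m.get_score(a, b))
            for a in AMINO_ACIDS
            for b in AMINO_ACIDS
        }
    else:
        from Bio.Align import substitution_matrices

        arr = substitution_matrices.load(name.upper())
        entries = _from_biopython(arr)
        name = name.upper()
    resolved_kind = kind or ("rate" if name.upper() in RATE_MATRICES else "score")
    return ScoreMatrix(name=name, entries=entries, kind=resolved_kind)


def _from_biopython(arr) -> dict[tuple[str, str], float]:
    present = set(arr.alphabet)
    return {
        (a, b): float(arr[a, b])
        for a in AMINO_ACIDS
        for b in AMINO_ACIDS
        if a in present and b in present
    }


def write_matrix(matrix: ScoreMatrix, path: str | Path) -> Path:
    """Write an NCBI-style whitespace-delimited square matrix."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("   " + "  ".join(AMINO_ACIDS) + "\n")
        for a in AMINO_ACIDS:
            row = "  ".join(f"{matrix.score(a, b):g}" for b in AMINO_ACIDS)
            fh.write(f"{a}  {row}\n")
    return path


@dataclass(frozen=True)
class WeightTable:
    """Symmetric unordered-pair -> integer weight map on the 3..15 scale."""

    weights: Mapping[frozenset, int]
    name: str = ""
    overridden_pairs: frozenset = field(default_factory=frozenset)

    def get(self, a: str, b: str) -> int:
        key = frozenset((a, b))
        if key not in self.weights:
            raise MissingPairError(f"pair ({a}, {b}) absent from weight table {self.name!r}")
        return self.weights[key]

    def with_overrides(self, overrides: Mapping[frozenset, int]) -> "WeightTable":
        """Layer explicit pair weights over the derived table (flagged)."""
        merged = dict(self.weights)
        changed = frozenset(k for k, v in overrides.items() if merged.get(k) != v)
        merged.update(overrides)
        return WeightTable(merged, self.name, self.overridden_pairs | changed)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"res1": min(p), "res2": max(p), "weight": w}
            for p, w in sorted(self.weights.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["res1", "res2", "weight"])


def derive_weights(
    matrix: ScoreMatrix,
    calibration: tuple[float, float] | None = None,
) -> WeightTable:
    """Map off-diagonal matrix entries to exchange-rareness weights.

    Without a calibration: affine decreasing map sending the maximum
    off-diagonal entry to 3 and the minimum to 15 (rate matrices are
    rank-transformed first, highest rate = rank 0). With a frozen
    ``(slope, intercept)`` calibration: ``clip(round(slope*s + intercept),
    3, 15)``. Rounding is half-away-from-zero.
    """
    off = matrix.off_diagonal()
    values = np.array(list(off.values()), dtype=float)
    if np.ptp(values) == 0:
        raise DegenerateMatrixError(
            f"matrix {matrix.name!r} has constant off-diagonal {values[0]}"
        )
    pairs = list(off.keys())
    if calibration is not None:
        slope, intercept = calibration
        weights = {
            p: min(WEIGHT_MAX, max(WEIGHT_MIN, _round_half_away(slope * off[p] + intercept)))
            for p in pairs
        }
    else:
        if matrix.kind == "rate":
            # highest rate -> rank 0 (most common); average ranks on ties
            ranks = stats.rankdata(-values, method="average") - 1.0
            scaled = WEIGHT_MIN + (WEIGHT_MAX - WEIGHT_MIN) * ranks / (len(values) - 1)
        else:
            smax, smin = values.max(), values.min()
            scaled = WEIGHT_MIN + (smax - values) * (WEIGHT_MAX - WEIGHT_MIN) / (smax - smin)
        weights = {p: _round_half_away(v) for p, v in zip(pairs, scaled)}
    return WeightTable(weights, name=matrix.name)


def blosum100_weights(overrides: Mapping[frozenset, int] | None = None) -> WeightTable:
    """The default weighting: bundled BLOSUM100 under the frozen calibration.

    ``overrides`` (pair -> published weight) installs an explicit lookup
    layer on top; overridden pairs are flagged on the returned table.
    """
    table = derive_weights(load_matrix("BLOSUM100"), FROZEN_BLOSUM100_CALIBRATION)
    if overrides:
        table = table.with_overrides(overrides)
    return table


@dataclass(frozen=True)
class ProteinScore:
    """Per-protein substitution burden (raw and exchange-weighted)."""

    protein_id: str
    n_subst: int
    length: int
    weighted_sum: int

    @property
    def subst_per_length(self) -> float:
        return self.n_subst / self.length

    @property
    def weighted_per_length(self) -> float:
        return self.weighted_sum / self.length

    @classmethod
    def from_totals(cls, protein_id: str, n_subst: int, length: int, weighted_sum: int):
        return cls(protein_id, n_subst, length, weighted_sum)


def score_protein(
    protein_id: str,
    subs: Sequence[Substitution],
    length: int,
    weights: WeightTable,
) -> ProteinScore:
    """Weighted substitution burden of one protein."""
    if length < 1:
        raise ValueError(f"{protein_id}: length must be >= 1, got {length}")
    total = sum(weights.get(s.ancestral, s.human) for s in subs)
    return ProteinScore(protein_id, len(subs), length, total)


RANK_KEYS = ("n_subst", "subst_per_length", "weighted_sum", "weighted_per_length")


def rank_proteins(scores: Iterable[ProteinScore], key: str = "weighted_per_length") -> pd.DataFrame:
    """Descending stable sort by ``key``; ties by (n_subst desc, protein id asc)."""
    if key not in RANK_KEYS:
        raise ValueError(f"rank key must be one of {RANK_KEYS}, got {key!r}")
    rows = [
        {
            "protein": s.protein_id,
            "n_subst": s.n_subst,
            "length": s.length,
            "subst_per_length": s.subst_per_length,
            "weighted_sum": s.weighted_sum,
            "weighted_per_length": s.weighted_per_length,
        }
        for s in scores
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        [key, "n_subst", "protein"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def compare_rankings(r1: Sequence[str], r2: Sequence[str]) -> float:
    """Spearman rank correlation between two orderings of the same id set."""
    if set(r1) != set(r2) or len(r1) != len(r2):
        raise IdMismatchError("rankings must order the same id set")
    pos2 = {pid: i for i, pid in enumerate(r2)}
    rho = stats.spearmanr(np.arange(len(r1)), [pos2[p] for p in r1]).statistic
    return float(rho)
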