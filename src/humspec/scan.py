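"""Detection of fixed human-lineage amino-acid substitutions.

A position counts as a fixed human-specific substitution when every sampled
human haplotype carries the same residue and the non-human primate outgroups
agree on a *different* residue. Columns containing a gap or an unknown
residue in any sequence are skipped (they correspond to positions that could
not be aligned across all four genomes), never treated as errors.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio.Seq import Seq

from .errors import CdsError
from .panel import OrthologPanel, Substitution

ConsensusMode = Literal["unanimous", "majority"]

_SKIP = {"-", "X"}


def _valid(residue: str) -> bool:
    return residue not in _SKIP


def outgroup_consensus(residues: Iterable[str], mode: ConsensusMode = "unanimous") -> str | None:
    """Consensus residue of the three outgroup genomes at one column.

    ``unanimous``: the residue iff all three agree (and it is not gap/X).
    ``majority``: any residue occurring at least twice; ``None`` on a
    three-way disagreement. Total function: never raises on residue content.
    """
    res = list(residues)
    if mode == "unanimous":
        if len(set(res)) == 1 and _valid(res[0]):
            return res[0]
        return None
    if mode == "majority":
        for r in set(res):
            if res.count(r) >= 2 and _valid(r):
                return r
        return None
    raise ValueError(f"unknown consensus mode {mode!r}")


def is_fixed_in_humans(column: str | Iterable[str]) -> str | None:
    """Residue carried by *all* human haplotypes at a column, else ``None``.

    Gap or X anywhere in the column disqualifies it (no call).
    """
    residues = set(column)
    if len(residues) == 1:
        (r,) = residues
        if _valid(r):
            return r
    return None


def find_fixed_substitutions(
    panel: OrthologPanel, mode: ConsensusMode = "unanimous"
) -> list[Substitution]:
    """Scan a panel for fixed human-lineage substitutions, ascending position.

    Positions are 1-based on the ungapped first human haplotype (the
    reference numbering used for reporting). A column is skipped whenever any
    human haplotype or any outgroup carries a gap or X there.
    """
    out: list[Substitution] = []
    ref = panel.human_seqs[0]
    pos = 0
    for i in range(panel.length):
        if ref[i] != "-":
            pos += 1
        humans, outgroups = panel.column(i)
        if any(c in _SKIP for c in humans) or any(c in _SKIP for c in outgroups):
            continue
        h = is_fixed_in_humans(humans)
        if h is None:
            continue
        a = outgroup_consensus(outgroups, mode)
        if a is None or a == h:
            continue
        out.append(Substitution(position=pos, ancestral=a, human=h))
    return out


def translate_cds(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    Stop codons become ``*``; codons containing ``N`` that do not resolve to
    a single amino acid become ``X``. Length must be a multiple of three.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise CdsError(f"CDS length {len(cds)} is not a multiple of 3")
    bad = set(cds) - set("ACGTN")
    if bad:
        raise CdsError(f"illegal nucleotides {sorted(bad)}")
    return str(Seq(cds).translate())


def substitutions_to_frame(per_protein: dict[str, list[Substitution]]) -> pd.DataFrame:
    """Flatten a per-protein substitution map into a tidy table."""
    rows = [
        {"protein": pid, "position": s.position, "ancestral": s.ancestral, "human": s.human}
        for pid, subs in per_protein.items()
        for s in subs
    ]
    return pd.DataFrame(rows, columns=["protein", "position", "ancestral", "human"])


def write_substitutions(per_protein: dict[str, list[Substitution]], path: str | Path) -> Path:
    path = Path(path)
    substitutions_to_frame(per_protein).to_csv(path, sep="\t", index=False)
    return path


def read_substitutions(path: str | Path) -> dict[str, list[Substitution]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[Substitution]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.protein, []).append(
            Substitution(position=int(row.position), ancestral=row.ancestral, human=row.human)
        )
    return out
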