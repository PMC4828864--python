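"""Aligned ortholog panels: the input unit of the substitution scan.

A panel holds, for one protein, an aligned set of human haplotype sequences
(e.g. 100 haploid genomes) together with three non-human primate outgroup
sequences (chimpanzee, orangutan, rhesus macaque by default). All sequences
share one alignment length; residues come from the 20-letter amino-acid
alphabet plus the gap character ``-`` and the unknown character ``X``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import PanelError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues allowed in an aligned panel ("*" tolerated for stop codons)
PANEL_ALPHABET = frozenset(AMINO_ACIDS + "-X*")

DEFAULT_OUTGROUPS = ("PTR", "PAB", "MML")
DEFAULT_HUMAN_PREFIX = "HUM_"


@dataclass(frozen=True)
class Substitution:
    """One fixed human-lineage difference at a protein position.

    Positions are 1-based on the ungapped human reference (first haplotype).
    ``weight`` (exchange-rareness, 3..15) and ``domain`` are optional labels
    attached downstream.
    """

    position: int
    ancestral: str
    human: str
    weight: int | None = None
    domain: str | None = None

    def __post_init__(self):
        if self.ancestral == self.human:
            raise PanelError(
                f"substitution at {self.position}: ancestral == human ({self.human})"
            )
        if self.position < 1:
            raise PanelError(f"position must be 1-based positive, got {self.position}")
        if self.weight is not None and not 3 <= self.weight <= 15:
            raise PanelError(f"weight {self.weight} outside [3, 15]")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.ancestral, self.human))


@dataclass
class OrthologPanel:
    """Aligned human haplotypes plus named outgroups for one protein."""

    protein_id: str
    human_seqs: list[str]
    outgroup_seqs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.human_seqs:
            raise PanelError(f"{self.protein_id}: no human sequences")
        lengths = {len(s) for s in self.human_seqs} | {
            len(s) for s in self.outgroup_seqs.values()
        }
        if len(lengths) != 1:
            raise PanelError(f"{self.protein_id}: unequal sequence lengths {lengths}")
        (self._length,) = lengths
        if self._length < 1:
            raise PanelError(f"{self.protein_id}: empty alignment")
        for s in list(self.human_seqs) + list(self.outgroup_seqs.values()):
            bad = set(s) - PANEL_ALPHABET
            if bad:
                raise PanelError(f"{self.protein_id}: illegal residues {sorted(bad)}")

    @property
    def length(self) -> int:
        """Alignment length in columns."""
        return self._length

    def column(self, i: int) -> tuple[str, tuple[str, ...]]:
        """Residues at 0-based alignment column ``i``: (human column, outgroup column)."""
        humans = "".join(s[i] for s in self.human_seqs)
        outgroups = tuple(s[i] for s in self.outgroup_seqs.values())
        return humans, outgroups


def read_panel(
    path: str | Path,
    protein_id: str | None = None,
    human_prefix: str = DEFAULT_HUMAN_PREFIX,
) -> OrthologPanel:
    """Read an aligned panel from FASTA.

    Records whose id starts with ``human_prefix`` are human haplotypes; all
    other records are outgroups keyed by their full id.
    """
    path = Path(path)
    humans: list[str] = []
    outgroups: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if rec.id.startswith(human_prefix):
            humans.append(s)
        else:
            outgroups[rec.id] = s
    if not humans:
        raise PanelError(f"{path}: no records with human prefix '{human_prefix}'")
    return OrthologPanel(protein_id or path.stem, humans, outgroups)


def write_panel(panel: OrthologPanel, path: str | Path,
                human_prefix: str = DEFAULT_HUMAN_PREFIX) -> Path:
    """Write a panel to FASTA (human ids ``HUM_001`` ..., outgroups by name)."""
    path = Path(path)
    records = [
        SeqRecord(Seq(s), id=f"{human_prefix}{i + 1:03d}", description="")
        for i, s in enumerate(panel.human_seqs)
    ]
    records += [
        SeqRecord(Seq(s), id=name, description="")
        for name, s in panel.outgroup_seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path
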