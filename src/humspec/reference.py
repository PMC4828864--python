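"""Published reference values for the PCDHB11 case study.

The 12 fixed human-lineage substitutions in β-protocadherin 11 (PCDHB11,
797 residues), with their exchange-rareness weights and domain locations,
and the published ranking of the top neural cell-surface proteins by
substitution burden. These printed values serve as worked examples and as
calibration anchors for the BLOSUM100 weight map; the actual human panel
data behind them (100 haploid genomes vs chimpanzee/orangutan/macaque) is
not redistributed here.
"""

from __future__ import annotations

import numpy as np

from .panel import AMINO_ACIDS, OrthologPanel, Substitution

PCDHB11_LENGTH = 797

#: (position, ancestral, human, weight, domain) — primate consensus vs human
PCDHB11_SUBSTITUTIONS: tuple[Substitution, ...] = tuple(
    Substitution(*row)
    for row in [
        (4, "E", "Q", 3, "Signal peptide"),
        (106, "F", "L", 5, "EC1"),
        (134, "L", "S", 11, "EC2"),
        (185, "N", "I", 12, "EC2"),
        (213, "T", "S", 3, "EC2"),
        (252, "P", "R", 10, "EC3"),
        (263, "T", "I", 8, "EC3"),
        (281, "L", "F", 5, "EC3"),
        (304, "T", "R", 8, "EC3"),
        (334, "R", "I", 12, "EC3"),
        (336, "Q", "H", 4, "EC3"),
        (724, "R", "S", 8, "Cytoplasmic"),
    ]
)

#: published ranking rows: (protein, n_subst, length, weighted_sum) with the
#: printed 3-decimal ratios (subst/length, weighted/length) kept for checks
SURFACE_RANKING: tuple[tuple[str, int, int, int, float, float], ...] = (
    ("PCDHB11", 12, 797, 89, 0.015, 0.112),
    ("ICAM1", 6, 532, 41, 0.011, 0.077),
    ("HTR3E", 4, 456, 33, 0.009, 0.072),
    ("HRH1", 5, 487, 31, 0.010, 0.064),
    ("DRD5", 5, 477, 30, 0.010, 0.063),
    ("PCDHB13", 6, 798, 47, 0.008, 0.059),
    ("GLRA4", 4, 417, 24, 0.010, 0.058),
    ("HOMER3", 2, 361, 19, 0.006, 0.053),
    ("PCDHB6", 5, 794, 40, 0.006, 0.050),
    ("VIPR1", 2, 457, 20, 0.004, 0.044),
    ("CCKAR", 2, 428, 18, 0.005, 0.042),
    ("PCDHB12", 4, 797, 30, 0.005, 0.038),
    ("OXYR", 3, 389, 14, 0.008, 0.036),
    ("GRIN3A", 6, 1115, 38, 0.005, 0.034),
    ("PCDHB10", 3, 797, 27, 0.004, 0.034),
    ("SEMA5B", 5, 1151, 32, 0.004, 0.028),
    ("PCDHA5", 4, 936, 26, 0.004, 0.028),
    ("PCDHB14", 4, 798, 21, 0.005, 0.026),
    ("GRIN2C", 4, 1236, 32, 0.003, 0.026),
    ("PCDHA2", 4, 948, 23, 0.004, 0.024),
    ("CD44", 3, 742, 17, 0.004, 0.023),
    ("PCDHB15", 4, 787, 18, 0.005, 0.023),
    ("PCDH15", 9, 1955, 43, 0.005, 0.022),
)

#: pair -> published weight, usable as an explicit lookup override layer
PCDHB11_PAIR_WEIGHTS: dict[frozenset, int] = {
    s.pair: s.weight for s in PCDHB11_SUBSTITUTIONS
}


def build_pcdhb11_panel(
    n_human: int = 100,
    seed: int | None = 0,
    outgroup_names: tuple[str, str, str] = ("PTR", "PAB", "MML"),
) -> OrthologPanel:
    """Reconstruct a PCDHB11-like panel from the published substitution set.

    A 797-residue placeholder background is drawn (seeded); human haplotypes
    carry the published human residues at the 12 substitution positions and
    the outgroups the primate-consensus residues, identical elsewhere. The
    true PCDHB11 sequence is not needed to exercise the scan: only the 12
    planted differences are informative.
    """
    rng = np.random.default_rng(seed)
    background = rng.choice(list(AMINO_ACIDS), size=PCDHB11_LENGTH)
    human = background.copy()
    ancestral = background.copy()
    for s in PCDHB11_SUBSTITUTIONS:
        human[s.position - 1] = s.human
        ancestral[s.position - 1] = s.ancestral
    human_seq, ancestral_seq = "".join(human), "".join(ancestral)
    return OrthologPanel(
        "PCDHB11",
        [human_seq] * n_human,
        {name: ancestral_seq for name in outgroup_names},
    )
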