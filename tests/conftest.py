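import numpy as np
import pytest

from humspec.panel import AMINO_ACIDS
from humspec.synth import PanelSpec, gen_ortholog_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_panel_spec(rng: np.random.Generator, protein_id: str = "SYN",
                      polymorphism_rate: float = 0.0) -> PanelSpec:
    """A small random panel spec with 0..5 planted substitutions."""
    length = int(rng.integers(30, 120))
    n_planted = int(rng.integers(0, 6))
    positions = rng.choice(np.arange(1, length + 1), size=n_planted, replace=False)
    planted = []
    for pos in positions:
        anc, hum = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
        planted.append((int(pos), str(anc), str(hum)))
    return PanelSpec(
        protein_id=protein_id,
        n_human_haplotypes=int(rng.integers(2, 20)),
        protein_length=length,
        planted_substitutions=tuple(planted),
        polymorphism_rate=polymorphism_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def brute_force_scan(panel, mode="unanimous"):
    """Independent per-column oracle for the substitution scan.

    Plain double loop over columns and sequences, written without reusing
    any scan helper.
    """
    found = []
    ref = panel.human_seqs[0]
    pos = 0
    for i in range(len(ref)):
        if ref[i] != "-":
            pos += 1
        column_h = [s[i] for s in panel.human_seqs]
        column_o = [s[i] for s in panel.outgroup_seqs.values()]
        if any(c in "-X" for c in column_h + column_o):
            continue
        if len(set(column_h)) != 1:
            continue
        h = column_h[0]
        if mode == "unanimous":
            if len(set(column_o)) != 1:
                continue
            a = column_o[0]
        else:
            a = None
            for cand in set(column_o):
                if column_o.count(cand) >= 2:
                    a = cand
            if a is None:
                continue
        if a != h:
            found.append((pos, a, h))
    return found


@pytest.fixture
def small_panel():
    spec = PanelSpec(
        protein_id="TOY",
        n_human_haplotypes=5,
        protein_length=40,
        planted_substitutions=((7, "N", "I"), (21, "E", "Q")),
        seed=7,
    )
    return gen_ortholog_panel(spec)
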