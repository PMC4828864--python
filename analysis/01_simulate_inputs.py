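"""Generate the synthetic input universe for the downstream analyses.

Emulates the real study's inputs: 40 aligned ortholog panels (100 human
haplotypes + 3 outgroups each) with planted fixed substitutions — one
protein, TOP01, carries a dense set of evolutionarily rare exchanges and is
the intended top hit — a GO annotation table in which roughly half the
proteins qualify as neural surface proteins, and a dbSNP-like variant table
for a 15-gene cluster. Bulky FASTA panels go to scratch/; tables to
results/synthetic/.

Run from the repository root:  python analysis/01_simulate_inputs.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from humspec.ontology import MEMBRANE_TERMS, write_annotations
from humspec.panel import write_panel
from humspec.synth import PanelSpec, gen_go_table, gen_ortholog_panel, gen_variant_table

SEED = 20240901
N_PROTEINS = 40
PANEL_DIR = Path("scratch/synthetic/panels")
OUT_DIR = Path("results/synthetic")

RARE = [("N", "I"), ("R", "I"), ("L", "S"), ("P", "R"), ("D", "W"), ("T", "R")]
COMMON = [("E", "Q"), ("T", "S"), ("K", "R"), ("I", "V")]


def main() -> None:
    rng = np.random.default_rng(SEED)
    PANEL_DIR.mkdir(parents=True, exist_ok=True)
    OUT_DIR.mkdir(parents=True, exist_ok=True)

    entries, lengths = [], []
    for i in range(N_PROTEINS):
        pid = f"TOP01" if i == 0 else f"SYN{i:02d}"
        length = 300 if i == 0 else int(rng.integers(150, 900))
        if i == 0:
            pairs = RARE  # dense rare exchanges: the planted winner
        else:
            k = int(rng.integers(0, 4))
            pairs = [COMMON[int(rng.integers(len(COMMON)))] for _ in range(k)]
        positions = rng.choice(np.arange(1, length + 1), size=len(pairs), replace=False)
        planted = tuple(
            (int(p), a, h) for p, (a, h) in zip(sorted(positions), pairs)
        )
        spec = PanelSpec(
            protein_id=pid,
            n_human_haplotypes=100,
            protein_length=length,
            planted_substitutions=planted,
            polymorphism_rate=0.002,
            seed=int(rng.integers(2**31)),
        )
        write_panel(gen_ortholog_panel(spec), PANEL_DIR / f"{pid}.fasta")
        lengths.append({"protein": pid, "length": length, "n_planted": len(planted)})

        # half the universe qualifies as neural surface proteins; families of
        # three share accession prefixes so expansion has something to do
        family = f"F{i // 3:02d}"
        terms = (
            [MEMBRANE_TERMS[0], "neuron projection"]
            if i % 2 == 0
            else ["cytoplasm", "synaptonemal complex"]
        )
        entries.append((pid, f"{family}A{i % 3}", terms))

    write_annotations(gen_go_table(entries), OUT_DIR / "annotations.tsv")
    pd.DataFrame(lengths).to_csv(OUT_DIR / "proteins.tsv", sep="\t", index=False)

    # 15-gene cluster, non-synonymous counts planted in the 92..167 range,
    # the focal gene planted exactly at the middle of the range
    genes = {f"CLUST{i:02d}": int(c) for i, c in enumerate(
        rng.integers(92, 168, size=15))}
    genes["FOCAL"] = 139
    class_counts = {
        g: {
            "missense": c - 6,
            "nonsense": 2,
            "stop_lost": 1,
            "frameshift": 3,
            "synonymous": int(rng.integers(40, 120)),
            "intron": int(rng.integers(100, 400)),
        }
        for g, c in genes.items()
    }
    table = gen_variant_table(class_counts, seed=SEED)
    # row-per-variant extract is bulky: scratch, not results
    table.to_csv(PANEL_DIR.parent / "variants.tsv", sep="\t", index=False)
    lineage = pd.DataFrame(
        {"gene": sorted(genes), "n_subst": [
            12 if g == "FOCAL" else int(rng.integers(0, 7)) for g in sorted(genes)]}
    )
    lineage.to_csv(OUT_DIR / "lineage_subs.tsv", sep="\t", index=False)

    print(f"wrote {N_PROTEINS} panels to {PANEL_DIR}")
    print(f"wrote annotations, protein lengths and variant tables to {OUT_DIR}")


if __name__ == "__main__":
    main()
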