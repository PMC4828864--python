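"""Scan the synthetic panels, apply the GO surface filter, score and rank.

The genomic arm of the pipeline end to end: fixed human-lineage
substitutions per protein, restriction to the neural surface universe with
family expansion, BLOSUM100 exchange-rareness weighting, and the final
ranking by weighted substitutions per length. Also reports matrix
robustness: the same ranking under BLOSUM62 and the JTT exchangeability
data, compared by Spearman correlation.

Requires 01_simulate_inputs.py to have run.
"""

from pathlib import Path

import pandas as pd

from humspec.ontology import apply_filter, read_annotations
from humspec.panel import read_panel
from humspec.scan import find_fixed_substitutions
from humspec.scoring import (
    FROZEN_BLOSUM100_CALIBRATION,
    compare_rankings,
    derive_weights,
    load_matrix,
    rank_proteins,
    score_protein,
)

PANEL_DIR = Path("scratch/synthetic/panels")
IN_DIR = Path("results/synthetic")
OUT_DIR = Path("results")


def main() -> None:
    lengths = pd.read_csv(IN_DIR / "proteins.tsv", sep="\t").set_index("protein")
    per_protein = {}
    for fasta in sorted(PANEL_DIR.glob("*.fasta")):
        panel = read_panel(fasta)
        per_protein[panel.protein_id] = find_fixed_substitutions(panel, "unanimous")
    n_subs = sum(len(v) for v in per_protein.values())
    print(f"scan: {len(per_protein)} proteins, {n_subs} fixed substitutions")

    records = read_annotations(IN_DIR / "annotations.tsv")
    summary = apply_filter(records, {p: len(s) for p, s in per_protein.items()})
    print(
        f"filter: {summary.n_selected} neural surface proteins, "
        f"{summary.n_with_substitution} carry at least one fixed substitution"
    )

    rankings = {}
    for matrix_name in ("BLOSUM100", "BLOSUM62", "JONES"):
        matrix = load_matrix(matrix_name)
        calibration = (
            FROZEN_BLOSUM100_CALIBRATION if matrix_name == "BLOSUM100" else None
        )
        weights = derive_weights(matrix, calibration)
        scores = [
            score_protein(pid, per_protein[pid], int(lengths.loc[pid, "length"]), weights)
            for pid in sorted(summary.selected)
        ]
        ranked = rank_proteins(scores, "weighted_per_length")
        rankings[matrix_name] = ranked
        if matrix_name == "BLOSUM100":
            ranked.to_csv(OUT_DIR / "ranking.tsv", sep="\t", index=False)
            print(f"top of the BLOSUM100 ranking:\n{ranked.head(3).to_string(index=False)}")

    rows = []
    base = rankings["BLOSUM100"]["protein"].tolist()
    for other in ("BLOSUM62", "JONES"):
        rho = compare_rankings(base, rankings[other]["protein"].tolist())
        rows.append({"matrix_a": "BLOSUM100", "matrix_b": other, "spearman_rho": rho})
        print(f"robustness: BLOSUM100 vs {other}: Spearman rho = {rho:.3f}")
    pd.DataFrame(rows).to_csv(OUT_DIR / "robustness.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
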