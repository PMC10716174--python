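#!/usr/bin/env python
"""Temporal response classes and over-representation analysis.

Reads the time-course pipeline run of the previous step, reports how the
selected proteins (|log2 FC| > 1 significant at any time point, CV <
20%) distribute over the early/intermediate/late classes, and checks
class recovery against the planted ground truth.  A synthetic gene-set
collection is then built — one set enriched in the planted responders,
plus unrelated sets — and the upregulated proteins are tested by
hypergeometric ORA against the quantified background.  Outputs:
results/timecourse_classes.tsv and results/ora_results.tsv.
"""

from pathlib import Path

import pandas as pd

from nspquant import ora

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "analysis" / "timecourse"
RESULTS = ROOT / "results"


def main() -> None:
    classes = pd.read_csv(RUN / "timecourse_classes.tsv", sep="\t")
    truth = pd.read_csv(RUN / "ground_truth_proteins.tsv", sep="\t")

    merged = classes.merge(
        truth[["protein_group", "gene", "regulation_class"]],
        on="protein_group", suffixes=("", "_truth"),
    )
    up_truth = merged[merged["regulation_class"].isin(["early", "intermediate", "late"])]
    acc = (up_truth["response_class"] == up_truth["regulation_class"]).mean()
    print("selected proteins per class:")
    print(classes["response_class"].value_counts().to_string())
    print(f"class recovery on planted up-regulated proteins: {100 * acc:.1f}%")

    # synthetic gene sets: the true responders plus unrelated decoys
    responders = frozenset(
        truth.loc[truth["regulation_class"] != "none", "gene"].str.upper()
    )
    all_genes = truth["gene"].str.upper().tolist()
    sets = {
        "PLANTED_RESPONDERS": responders,
        "DECOY_FIRST_100": frozenset(all_genes[:100]),
        "DECOY_SECOND_100": frozenset(all_genes[100:200]),
    }
    query = classes["gene"].dropna().str.upper().tolist()
    background = all_genes
    table = ora.run_ora(query, sets, background)
    RESULTS.mkdir(exist_ok=True)
    classes.to_csv(RESULTS / "timecourse_classes.tsv", sep="\t", index=False)
    table.to_csv(RESULTS / "ora_results.tsv", sep="\t", index=False)
    print("\nORA of selected proteins against synthetic sets:")
    print(table[["set", "k", "K", "p", "q", "significant"]].to_string(index=False))


if __name__ == "__main__":
    main()
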