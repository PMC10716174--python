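#!/usr/bin/env python
"""Generate the two synthetic triple-SILAC benchmark mixtures.

Mix 1 (70% L / 15% M / 15% H) emulates a pulse-labeled sample without
enrichment of newly synthesized proteins; mix 2 (20% L / 40% M / 40% H)
an enriched one.  Each is generated at 1000 proteins x 3 replicate runs
with log2 intensity noise SD 0.25 and written as a channel-resolved
precursor report (DIA-NN column dialect) with its ground truth, under
scratch/analysis/.
"""

from pathlib import Path

from nspquant.benchmarks import MIX1, MIX2
from nspquant.simulate import (
    SimDesign,
    generate_ground_truth,
    simulate_precursor_report,
    write_design,
    write_ground_truth,
    write_report,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "analysis"


def main() -> None:
    for name, proportions, seed in [("mix1", MIX1, 41), ("mix2", MIX2, 42)]:
        outdir = OUT / name
        outdir.mkdir(parents=True, exist_ok=True)
        design = SimDesign(
            n_proteins=1000, channel_proportions=dict(proportions),
            n_replicates=3, noise_sd_log2=0.25, seed=seed,
        )
        truth = generate_ground_truth(design)
        report = simulate_precursor_report(truth, design)
        write_report(report, outdir / "report.tsv")
        write_ground_truth(truth, outdir / "ground_truth_proteins.tsv")
        write_design(design, outdir / "design.yaml")
        print(
            f"{name}: {len(report)} precursor rows "
            f"({design.n_proteins} proteins, {len(design.runs)} runs, "
            f"proportions L/M/H = "
            f"{proportions['L']:.2f}/{proportions['M']:.2f}/{proportions['H']:.2f})"
        )
    print(f"reports written under {OUT}")


if __name__ == "__main__":
    main()
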