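"""IHC and qPCR quantification arithmetic on worked examples.

Applies the H-score formula to the published SCLC-04 intensity breakdown
(expected 71.41), computes T-cell densities for illustrative region
counts, and runs the qPCR fold-change pipeline on a small replicate
table. Writes results/05_quantify.tsv.
"""

from pathlib import Path

import pandas as pd

import nescore as ns

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    h = ns.h_score(ns.IntensityBreakdown(1.22, 9.97, 47.81))
    print(f"SCLC-04 H-score: 3*1.22 + 2*9.97 + 1*47.81 = {h:.2f}")

    density_high = ns.cell_density(420, 1.75)
    density_low = ns.cell_density(35, 1.4)
    print(f"CD8 density, ASCL1-low region: {density_high:.0f} cells/mm^2; "
          f"ASCL1-high region: {density_low:.0f} cells/mm^2")

    ct = pd.DataFrame(
        {"sample": ["parental"] * 3 + ["resistant"] * 3,
         "replicate": [1, 2, 3] * 2,
         "ct_target": [20.0, 20.1, 19.9, 18.0, 18.1, 17.9],
         "ct_control": [20.0] * 6}
    )
    folds = ns.qpcr_fold_changes(ct, ["parental"])
    print("qPCR fold changes (PPIA-normalized, parental-median-scaled):")
    print(folds.to_string(index=False))

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    rows = [("SCLC-04_h_score", h),
            ("cd8_density_ascl1_low", density_high),
            ("cd8_density_ascl1_high", density_low)]
    rows += [(f"qpcr_fold_{r.sample}", r.fold) for r in folds.itertuples()]
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(
        out / "05_quantify.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
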