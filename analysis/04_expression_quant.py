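"""Comparative-Ct quantification of the simulated expression experiment.

Computes 2^-ddCt fold changes for the mature miRNA against the three
endogenous reference genes, and the nuclear/cytoplasmic 2^-dCt split of the
T-UCR.  Writes results/expression_quant.tsv.
"""

from pathlib import Path

import pandas as pd

from tucrmir.qpcr import ddct_table, fraction_percentages

RESULTS = Path(__file__).resolve().parents[1] / "results"
INPUTS = RESULTS / "inputs"


def main() -> None:
    if not (INPUTS / "ct_table.csv").exists():
        raise SystemExit("run analysis/01_simulate_inputs.py first")
    ct = pd.read_csv(INPUTS / "ct_table.csv")
    folds = ddct_table(ct, reference_targets=["GUSB", "PPIA", "HPRT1"], control_condition="EV")
    folds.to_csv(RESULTS / "expression_quant.tsv", sep="\t", index=False)
    induced = folds[(folds.target == "miR-376c") & (folds.condition == "uc160")]
    print(f"miR-376c fold change on uc160 overexpression: {induced.fold_change.iloc[0]:.2f}")

    frac = pd.read_csv(INPUTS / "fraction_ct.csv")
    by_sample = frac.groupby("sample")["ct"].mean()
    pn, pc = fraction_percentages(by_sample["nuclear"], by_sample["cytoplasmic"])
    print(f"uc160 fractionation: {pn:.0f}% nuclear / {pc:.0f}% cytoplasmic")


if __name__ == "__main__":
    main()
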