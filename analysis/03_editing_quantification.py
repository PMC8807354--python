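"""Quantify A-to-I editing in the two simulated conditions and contrast them.

Reads the clone sets written by 01_simulate_inputs.py (empty vector vs
T-UCR overexpression), tabulates per-position substitutions, reports
editing frequencies at the planted stem-loop +48 and +55 adenosines, and
tests the condition contrast with Fisher exact and chi-squared statistics.
Writes results/editing_comparison.tsv.
"""

import csv
from pathlib import Path

from tucrmir.editing import (
    CloneSet,
    call_editing_sites,
    compare_editing,
    editing_frequency,
    tabulate_substitutions,
)
from tucrmir.io import read_fasta

RESULTS = Path(__file__).resolve().parents[1] / "results"
INPUTS = RESULTS / "inputs"
STEMLOOP_START = 21


def main() -> None:
    if not (INPUTS / "editing_reference.fasta").exists():
        raise SystemExit("run analysis/01_simulate_inputs.py first")
    ref_id, ref_seq = read_fasta(INPUTS / "editing_reference.fasta")[0]
    tables = {}
    for cond in ("clones_ev", "clones_uc160"):
        cs = CloneSet(ref_id, ref_seq, STEMLOOP_START, read_fasta(INPUTS / f"{cond}.fasta"))
        tables[cond] = tabulate_substitutions(cs)

    positions = sorted(
        {s.ref_pos for tbl in tables.values() for s in call_editing_sites(tbl, min_count=2)}
    )
    with open(RESULTS / "editing_comparison.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["position", "stemloop_coord", "freq_ev", "freq_uc160",
                    "fisher_p", "chi2_p"])
        for pos in positions:
            ev = editing_frequency(tables["clones_ev"], pos)
            uc = editing_frequency(tables["clones_uc160"], pos)
            res = compare_editing(uc.edited_count, uc.total_count, ev.edited_count, ev.total_count)
            w.writerow([pos, f"+{ev.position_stemloop}", f"{ev.frequency:.3f}",
                        f"{uc.frequency:.3f}", f"{res.fisher_p:.3g}", f"{res.chi2_p:.3g}"])
            print(
                f"site +{ev.position_stemloop}: EV {ev.frequency:.2f} vs uc160 "
                f"{uc.frequency:.2f} (Fisher p = {res.fisher_p:.2g})"
            )


if __name__ == "__main__":
    main()
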