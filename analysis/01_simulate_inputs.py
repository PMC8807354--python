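"""Generate every synthetic input the downstream analyses consume.

Writes UCR/hairpin sequence databases with planted complementary segments,
clone-sequencing sets for two expression conditions (empty vector vs T-UCR
overexpression), a Ct table for comparative-Ct quantification, and the
637-case glioma-like cohort, all under results/inputs/.
"""

import csv
import json
from pathlib import Path

from tucrmir.io import write_clinical_csv, write_fasta, write_hairpin_table
from tucrmir.simulate import (
    CloneSimConfig,
    gen_clone_set,
    gen_cohort,
    gen_editing_reference,
    gen_sequence_db,
)

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    ucrs, hairpins, seq_truth = gen_sequence_db(seed=SEED)
    write_fasta([(u.ucr_id, u.sequence) for u in ucrs], OUT / "ucrs.fasta")
    write_hairpin_table(hairpins, OUT / "hairpins.tsv")
    (OUT / "truth_sequences.json").write_text(json.dumps(seq_truth, indent=2) + "\n")
    print(f"sequence db: 1 UCR, {len(hairpins)} hairpins, {len(seq_truth)} planted segments")

    # editing reference: stem-loop starts at position 21; editable adenosines
    # at stem-loop +48 and +55, mirroring the assayed pri-miRNA sites
    stemloop_start = 21
    ref = list(gen_editing_reference(length=120, seed=SEED))
    for pos in (stemloop_start + 47, stemloop_start + 54):
        ref[pos - 1] = "A"
    ref = "".join(ref)
    write_fasta([("pri-mir-376-sim", ref)], OUT / "editing_reference.fasta")
    conditions = {
        "clones_ev": (CloneSimConfig(site_probs={68: 0.05, 75: 0.04}, n_clones=90), 1),
        "clones_uc160": (CloneSimConfig(site_probs={68: 0.35, 75: 0.30}, n_clones=90), 2),
    }
    for name, (cfg, offset) in conditions.items():
        cs, truth = gen_clone_set("pri-mir-376-sim", ref, stemloop_start, cfg,
                                  seed=SEED + offset)
        write_fasta(cs.clones, OUT / f"{name}.fasta")
        (OUT / f"truth_{name}.json").write_text(json.dumps(truth, indent=2) + "\n")
        print(f"{name}: {len(cs.clones)} clones, planted {truth['planted_counts']}")

    # Ct table: mature miRNA induction (~2.5-fold) plus fractionation Cts
    with open(OUT / "ct_table.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["target", "condition", "replicate", "ct"])
        for rep in (1, 2, 3):
            for refgene in ("GUSB", "PPIA", "HPRT1"):
                w.writerow([refgene, "EV", rep, 20.0 + 0.1 * rep])
                w.writerow([refgene, "uc160", rep, 20.0 + 0.1 * rep])
            w.writerow(["miR-376c", "EV", rep, 26.0 + 0.1 * rep])
            w.writerow(["miR-376c", "uc160", rep, 26.0 + 0.1 * rep - 1.32])  # ~2.5-fold
    with open(OUT / "fraction_ct.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["target", "sample", "replicate", "ct"])
        w.writerow(["uc160", "nuclear", 1, 24.0])
        w.writerow(["uc160", "cytoplasmic", 1, 26.0])  # nuclear-enriched transcript
    print("Ct tables written")

    cohort, truth = gen_cohort(seed=SEED)
    write_clinical_csv(cohort, OUT / "cohort.csv")
    (OUT / "truth_cohort.json").write_text(
        json.dumps(truth["groups"], indent=2, default=str) + "\n"
    )
    print(f"cohort: {len(cohort)} cases "
          f"({truth['groups']['LGG']['n']} LGG / {truth['groups']['GBM']['n']} GBM)")


if __name__ == "__main__":
    main()
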