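"""Optional validation against the real TCGA glioma cohort.

The published survival effect sizes (LGG univariate HR 0.135, 95% CI
0.085-0.213; multivariate HR 0.486, 95% CI 0.248-0.953) were estimated on
TCGA LGG/GBM clinical and 450K methylation data, which this repository does
not redistribute.  Supply a clinical CSV (columns
case_id,cohort,grade,beta,idh1,age,sex,os_time,event; beta = the uc.160+
island probe summary) assembled from the TCGA Data Portal to run the same
pipeline on the real cohort:

    python analysis/06_tcga_validation.py path/to/tcga_cohort.csv

Without an argument the script only documents the procedure and exits.
"""

import sys
from pathlib import Path

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(argv: list[str]) -> int:
    if len(argv) < 2:
        print(__doc__)
        print("No external TCGA clinical table supplied; nothing to validate.")
        return 0
    path = Path(argv[1])
    if not path.is_file():
        print(f"external cohort file not found: {path}", file=sys.stderr)
        return 1
    from tucrmir.io import read_clinical_csv
    from tucrmir.survival import run_clinical_pipeline, write_clinical_report

    cohort = read_clinical_csv(path)
    report = run_clinical_pipeline(cohort)
    write_clinical_report(report, RESULTS / "tcga_validation")
    uni = report["cox_univariate"].get("LGG", {})
    if "hypermethylated" in uni:
        hr = uni["hypermethylated"]
        print(f"LGG univariate HR = {hr['hr']:.3f} "
              f"(95% CI {hr['ci_low']:.3f}-{hr['ci_high']:.3f})")
    multi = report["cox_multivariate_lgg"]
    if "hypermethylated" in multi:
        hr = multi["hypermethylated"]
        print(f"LGG multivariate HR = {hr['hr']:.3f} "
              f"(95% CI {hr['ci_low']:.3f}-{hr['ci_high']:.3f})")
    print(f"full report written to {RESULTS / 'tcga_validation'}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main(sys.argv))
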