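"""Comparative-Ct quantification (2^-ddCt fold changes and 2^-dCt fractions).

Technical replicates are averaged on the Ct scale before any delta is
taken; multi-reference normalization subtracts the arithmetic mean of the
reference Cts (equivalently, divides by the geometric mean of reference
expressions).  Amplification efficiency is fixed at 2, as the method's name
implies.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class CtMeasurement:
    target: str
    sample: str
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not self.ct > 0:
            raise ValueError(f"Ct must be positive, got {self.ct}")


def _mean(values: list[float], what: str) -> float:
    if not values:
        raise ValueError(f"empty {what} list")
    return sum(values) / len(values)


def relative_expression(
    ct_target_sample: float,
    ct_refs_sample: list[float],
    ct_target_control: float,
    ct_refs_control: list[float],
) -> float:
    """2^-ddCt fold change of the target in sample relative to control.

    dCt = Ct(target) - mean(Ct(references)) per condition; the fold change is
    2^-(dCt_sample - dCt_control).
    """
    dct_sample = ct_target_sample - _mean(ct_refs_sample, "sample reference")
    dct_control = ct_target_control - _mean(ct_refs_control, "control reference")
    return 2.0 ** -(dct_sample - dct_control)


def fraction_percentages(ct_nuclear: float, ct_cytoplasmic: float) -> tuple[float, float]:
    """Nuclear/cytoplasmic percentages from fraction Cts via 2^-Ct abundances."""
    for name, ct in (("nuclear", ct_nuclear), ("cytoplasmic", ct_cytoplasmic)):
        if not (ct == ct and abs(ct) != float("inf")):
            raise ValueError(f"{name} Ct must be finite")
    a_nuc = 2.0**-ct_nuclear
    a_cyt = 2.0**-ct_cytoplasmic
    total = a_nuc + a_cyt
    return 100.0 * a_nuc / total, 100.0 * a_cyt / total


def average_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates: one mean Ct per (target, sample, condition)."""
    keys = [c for c in ("target", "sample", "condition") if c in df.columns]
    return df.groupby(keys, as_index=False)["ct"].mean()


def ddct_table(
    df: pd.DataFrame,
    reference_targets: list[str],
    control_condition: str,
) -> pd.DataFrame:
    """Fold changes (2^-ddCt) for every non-reference target and condition.

    ``df`` columns: target, sample/condition, replicate, ct.  Replicates are
    averaged first; each condition is normalized against the mean reference
    Ct and expressed relative to ``control_condition``.
    """
    if not reference_targets:
        raise ValueError("at least one reference target is required")
    cond_col = "condition" if "condition" in df.columns else "sample"
    avg = df.groupby(["target", cond_col], as_index=False)["ct"].mean()
    conditions = avg[cond_col].unique().tolist()
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent from table")
    ref_mean = (
        avg[avg["target"].isin(reference_targets)].groupby(cond_col)["ct"].mean()
    )
    missing = [c for c in conditions if c not in ref_mean.index]
    if missing:
        raise ValueError(f"conditions without reference Cts: {missing}")
    rows = []
    for target in avg["target"].unique():
        if target in reference_targets:
            continue
        sub = avg[avg["target"] == target].set_index(cond_col)["ct"]
        if control_condition not in sub.index:
            raise ValueError(f"target {target!r} missing in control condition")
        dct_control = sub[control_condition] - ref_mean[control_condition]
        for cond in conditions:
            if cond not in sub.index:
                continue
            dct = sub[cond] - ref_mean[cond]
            rows.append(
                {
                    "target": target,
                    "condition": cond,
                    "dct": dct,
                    "fold_change": 2.0 ** -(dct - dct_control),
                }
            )
    return pd.DataFrame(rows)
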