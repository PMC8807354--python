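"""Readers and writers for the pipeline's external formats.

All sequence records are normalized at load time: uppercase, RNA ``U``
mapped to DNA ``T`` (every internal computation runs on the DNA alphabet),
and every normalization is logged.  All intervals are 1-based inclusive,
matching miRBase convention.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_DNA_ALPHABET = set("ACGTN")
_NA_STRINGS = {"", "NA", "NAN", "NONE", "NULL", "."}


class FormatError(ValueError):
    """Raised when an input file violates its contract."""


@dataclass
class UCRRecord:
    """An ultraconserved transcript: id, genomic location, transcribed-strand sequence."""

    ucr_id: str
    sequence: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence, self.ucr_id)
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.ucr_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start is not None and self.end is not None:
            expected = self.end - self.start + 1
            if len(self.sequence) != expected:
                raise FormatError(
                    f"{self.ucr_id}: sequence length {len(self.sequence)} does not match "
                    f"coordinates [{self.start}, {self.end}] (expected {expected})"
                )


@dataclass
class HairpinRecord:
    """A pri-miRNA stem-loop with cluster membership and mature-arm intervals."""

    hairpin_id: str
    cluster_id: str
    sequence: str
    matures: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence, self.hairpin_id)
        if not self.cluster_id:
            # blank cluster -> singleton cluster named after the hairpin
            self.cluster_id = self.hairpin_id
        n = len(self.sequence)
        for mid, s, e in self.matures:
            if not (1 <= s <= e <= n):
                raise FormatError(
                    f"{self.hairpin_id}: mature arm {mid} interval [{s}, {e}] outside "
                    f"hairpin of length {n}"
                )
        intervals = sorted((s, e) for _, s, e in self.matures)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"{self.hairpin_id}: overlapping mature intervals [{s1},{e1}] and [{s2},{e2}]"
                )


@dataclass
class PatientRecord:
    """One glioma case: methylation beta-value plus clinical covariates."""

    case_id: str
    cohort: str  # LGG | GBM
    beta: float
    grade: str | None = None  # II | III | IV
    idh1: str | None = None  # WT | MUT
    age: float | None = None
    sex: str | None = None  # M | F
    os_time: float | None = None  # days
    event: int | None = None  # 1 death, 0 censored

    def __post_init__(self) -> None:
        if self.cohort not in {"LGG", "GBM"}:
            raise FormatError(f"{self.case_id}: cohort must be LGG or GBM, got {self.cohort!r}")
        if not (0.0 <= self.beta <= 1.0):
            raise FormatError(f"{self.case_id}: beta-value {self.beta} outside [0, 1]")
        if self.grade is not None and self.grade not in {"II", "III", "IV"}:
            raise FormatError(f"{self.case_id}: grade must be II/III/IV, got {self.grade!r}")
        if self.grade is not None:
            if (self.cohort == "GBM") != (self.grade == "IV"):
                raise FormatError(
                    f"{self.case_id}: cohort {self.cohort} inconsistent with grade {self.grade}"
                )
        if self.idh1 is not None and self.idh1 not in {"WT", "MUT"}:
            raise FormatError(f"{self.case_id}: idh1 must be WT/MUT/NA, got {self.idh1!r}")
        if self.sex is not None and self.sex not in {"M", "F"}:
            raise FormatError(f"{self.case_id}: sex must be M/F/NA, got {self.sex!r}")
        if self.os_time is not None and self.os_time < 0:
            raise FormatError(f"{self.case_id}: os_time must be >= 0, got {self.os_time}")
        if self.event is not None and self.event not in {0, 1}:
            raise FormatError(f"{self.case_id}: event must be 0 or 1, got {self.event!r}")

    @property
    def has_survival(self) -> bool:
        """True when the record can enter survival analyses."""
        return self.os_time is not None and self.event is not None


def normalize_sequence(seq: str, name: str) -> str:
    """Uppercase a nucleotide string and map U->T; reject non-{A,C,G,T,N} characters."""
    up = seq.upper()
    if "U" in up:
        logger.info("record %s: RNA alphabet normalized (U -> T)", name)
        up = up.replace("U", "T")
    bad = set(up) - _DNA_ALPHABET
    if bad:
        raise FormatError(f"record {name}: non-IUPAC characters {sorted(bad)}")
    return up


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, normalized sequence) pairs, order preserved.

    Errors on an empty file, duplicate ids, or characters outside {A,C,G,T,N,U}.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, normalize_sequence(str(rec.seq), rec.id)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    seq_records = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_ucr_fasta(
    path: str | Path,
    sidecar: str | Path | None = None,
    genomic_strand: bool = False,
) -> list[UCRRecord]:
    """Load UCR sequences with an optional strand/coordinate sidecar TSV.

    The sidecar has columns ``ucr_id  chrom  start  end  strand``.  When the
    FASTA stores genomic-strand sequence, ``genomic_strand=True`` reverse-
    complements '-'-strand records so the stored sequence is the transcribed one.
    """
    from .seqmatch import reverse_complement

    meta: dict[str, tuple[str, int, int, str]] = {}
    if sidecar is not None:
        with open(sidecar) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                meta[row["ucr_id"]] = (
                    row["chrom"],
                    int(row["start"]),
                    int(row["end"]),
                    row.get("strand", "+") or "+",
                )
    out = []
    for ucr_id, seq in read_fasta(path):
        if ucr_id in meta:
            chrom, start, end, strand = meta[ucr_id]
        else:
            chrom = start = end = None
            strand = "+"
            logger.info("UCR %s: no sidecar entry; strand defaults to '+'", ucr_id)
        if genomic_strand and strand == "-":
            seq = reverse_complement(seq)
            logger.info("UCR %s: '-' strand genomic sequence reverse-complemented", ucr_id)
        out.append(UCRRecord(ucr_id, seq, chrom, start, end, strand))
    return out


_HAIRPIN_COLUMNS = ["hairpin_id", "cluster_id", "sequence", "mature_id", "mature_start", "mature_end"]


def read_hairpin_table(path: str | Path) -> list[HairpinRecord]:
    """Read the hairpin annotation TSV (one row per mature arm; hairpin rows repeat)."""
    path = Path(path)
    by_id: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_HAIRPIN_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            hid = row["hairpin_id"]
            if hid not in by_id:
                by_id[hid] = {
                    "cluster_id": row["cluster_id"].strip(),
                    "sequence": row["sequence"],
                    "matures": [],
                }
                order.append(hid)
            entry = by_id[hid]
            if row["sequence"] != entry["sequence"]:
                raise FormatError(f"{path}: hairpin {hid} rows carry differing sequences")
            if row["mature_id"].strip():
                entry["matures"].append(
                    (row["mature_id"], int(row["mature_start"]), int(row["mature_end"]))
                )
    if not by_id:
        raise FormatError(f"{path}: no hairpin rows found")
    return [
        HairpinRecord(hid, by_id[hid]["cluster_id"], by_id[hid]["sequence"], by_id[hid]["matures"])
        for hid in order
    ]


def write_hairpin_table(hairpins: list[HairpinRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HAIRPIN_COLUMNS)
        for hp in hairpins:
            if hp.matures:
                for mid, s, e in hp.matures:
                    writer.writerow([hp.hairpin_id, hp.cluster_id, hp.sequence, mid, s, e])
            else:
                writer.writerow([hp.hairpin_id, hp.cluster_id, hp.sequence, "", "", ""])


_CLINICAL_COLUMNS = ["case_id", "cohort", "grade", "beta", "idh1", "age", "sex", "os_time", "event"]


def _na(value: str | None) -> bool:
    return value is None or value.strip().upper() in _NA_STRINGS


def read_clinical_csv(path: str | Path) -> list[PatientRecord]:
    """Read the clinical CSV; rows lacking beta are dropped (count logged).

    Missing survival fields are tolerated: the record loads but is flagged
    unusable for survival operations (``has_survival`` False).  Missing
    optional fields are encoded as None (NA), never 0.
    """
    path = Path(path)
    records: list[PatientRecord] = []
    dropped = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_CLINICAL_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            if _na(row["beta"]):
                dropped += 1
                continue
            beta = float(row["beta"])
            if not (0.0 <= beta <= 1.0) or math.isnan(beta):
                raise FormatError(f"{path}: case {row['case_id']}: beta {beta} outside [0, 1]")
            records.append(
                PatientRecord(
                    case_id=row["case_id"],
                    cohort=row["cohort"].strip().upper(),
                    beta=beta,
                    grade=None if _na(row["grade"]) else row["grade"].strip(),
                    idh1=None if _na(row["idh1"]) else row["idh1"].strip().upper(),
                    age=None if _na(row["age"]) else float(row["age"]),
                    sex=None if _na(row["sex"]) else row["sex"].strip().upper(),
                    os_time=None if _na(row["os_time"]) else float(row["os_time"]),
                    event=None if _na(row["event"]) else int(row["event"]),
                )
            )
    if dropped:
        logger.info("%s: dropped %d rows with missing beta-value", path, dropped)
    return records


def read_clinical_csv_wide(
    path: str | Path, probe_columns: list[str], summary: str = "mean"
) -> list[PatientRecord]:
    """Read a wide per-probe clinical CSV, collapsing island probes to one beta.

    ``summary`` is ``mean`` (default), ``median``, or the name of a single probe
    column to use directly.
    """
    import numpy as np

    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            vals = [float(row[c]) for c in probe_columns if not _na(row.get(c))]
            if not vals:
                continue
            if summary == "mean":
                beta = float(np.mean(vals))
            elif summary == "median":
                beta = float(np.median(vals))
            elif summary in probe_columns:
                if _na(row.get(summary)):
                    continue
                beta = float(row[summary])
            else:
                raise ValueError(f"unknown probe summary {summary!r}")
            records.append(
                PatientRecord(
                    case_id=row["case_id"],
                    cohort=row["cohort"].strip().upper(),
                    beta=beta,
                    grade=None if _na(row.get("grade")) else row["grade"].strip(),
                    idh1=None if _na(row.get("idh1")) else row["idh1"].strip().upper(),
                    age=None if _na(row.get("age")) else float(row["age"]),
                    sex=None if _na(row.get("sex")) else row["sex"].strip().upper(),
                    os_time=None if _na(row.get("os_time")) else float(row["os_time"]),
                    event=None if _na(row.get("event")) else int(row["event"]),
                )
            )
    return records


def write_clinical_csv(records: list[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_CLINICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.case_id,
                    r.cohort,
                    "NA" if r.grade is None else r.grade,
                    repr(r.beta),
                    "NA" if r.idh1 is None else r.idh1,
                    "NA" if r.age is None else repr(float(r.age)),
                    "NA" if r.sex is None else r.sex,
                    "NA" if r.os_time is None else repr(float(r.os_time)),
                    "NA" if r.event is None else str(r.event),
                ]
            )


def write_json_report(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")
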