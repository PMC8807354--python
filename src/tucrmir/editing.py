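"""A-to-I editing quantification from clone sequencing.

Each sequenced cDNA clone is anchored (ungapped) onto its pri-miRNA
reference; per-position substitution counts are tabulated over accepted
clones, and the editing frequency at an adenosine is the number of A->G
clones divided by the number of usable clones covering that position.
Positions are also reported in stem-loop coordinates, where the 5' end of
the annotated stem-loop is +1.  Condition contrasts use the two-sided
Fisher exact test and the Pearson chi-squared test on the 2x2 table of
edited vs unedited clone counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class CloneSet:
    """Sequenced clones of one pri-miRNA amplicon."""

    reference_id: str
    reference_seq: str
    stemloop_start: int  # 1-based position of the stem-loop 5' end in reference_seq
    clones: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.stemloop_start <= len(self.reference_seq)):
            raise ValueError(
                f"{self.reference_id}: stemloop_start {self.stemloop_start} outside reference"
            )
        if not self.clones:
            raise ValueError(f"{self.reference_id}: clone set is empty")


@dataclass
class EditingTable:
    """Per-position substitution counts over the accepted clones of a CloneSet."""

    reference_id: str
    reference_seq: str
    stemloop_start: int
    n_clones: int  # accepted clones
    sub_counts: np.ndarray  # (L, 4): clone-base counts at mismatching positions, columns ACGT
    match_counts: np.ndarray  # (L,)
    usable: np.ndarray  # (L,): accepted clones covering each position
    rejected: list[str] = field(default_factory=list)

    def substitution_count(self, ref_pos: int, clone_base: str) -> int:
        return int(self.sub_counts[ref_pos - 1, _BASE_INDEX[clone_base]])


@dataclass
class EditingSiteStat:
    """Editing frequency at one adenosine of the reference."""

    ref_pos: int
    position_stemloop: int  # "+N" convention; <= 0 flags an upstream position
    ref_base: str
    edited_count: int
    total_count: int

    @property
    def frequency(self) -> float:
        return self.edited_count / self.total_count

    @property
    def upstream(self) -> bool:
        return self.position_stemloop <= 0


@dataclass
class ContingencyResult:
    """Two-sided Fisher exact and Pearson chi-squared results on a 2x2 table."""

    table: list[list[int]]
    fisher_p: float
    chi2_stat: float
    chi2_p: float


def anchor_clone(
    reference: str, clone: str, max_mismatch_frac: float = 0.10
) -> tuple[int, list[tuple[int, str, str]]] | None:
    """Ungapped placement of a clone on the reference at minimal Hamming distance.

    Returns ``(offset, mismatches)`` with a 1-based offset and mismatches as
    ``(ref_pos, ref_base, clone_base)``, or ``None`` when the best placement
    exceeds ``max_mismatch_frac`` (quality gate; indel-bearing or unrelated
    clones are rejected).  Ties favour the leftmost offset.
    """
    if not clone:
        raise ValueError("empty clone sequence")
    if len(clone) > len(reference):
        raise ValueError("clone longer than reference; amplicons must fit the reference")
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    cl = np.frombuffer(clone.encode(), dtype=np.uint8)
    n_off = len(reference) - len(clone) + 1
    best_off, best_mm = 0, len(clone) + 1
    for off in range(n_off):
        mm = int(np.count_nonzero(ref[off : off + len(clone)] != cl))
        if mm < best_mm:
            best_off, best_mm = off, mm
            if mm == 0:
                break
    if best_mm / len(clone) > max_mismatch_frac:
        return None
    window = ref[best_off : best_off + len(clone)]
    idx = np.nonzero(window != cl)[0]
    mismatches = [
        (int(i) + best_off + 1, reference[best_off + int(i)], clone[int(i)]) for i in idx
    ]
    return best_off + 1, mismatches


def tabulate_substitutions(cs: CloneSet, max_mismatch_frac: float = 0.10) -> EditingTable:
    """Aggregate per-position substitution counts over the accepted clones."""
    L = len(cs.reference_seq)
    sub_counts = np.zeros((L, 4), dtype=np.int64)
    match_counts = np.zeros(L, dtype=np.int64)
    usable = np.zeros(L, dtype=np.int64)
    rejected: list[str] = []
    n_accepted = 0
    for clone_id, seq in cs.clones:
        placed = anchor_clone(cs.reference_seq, seq, max_mismatch_frac)
        if placed is None:
            rejected.append(clone_id)
            logger.info("%s: clone %s rejected by mismatch gate", cs.reference_id, clone_id)
            continue
        offset, mismatches = placed
        n_accepted += 1
        span = slice(offset - 1, offset - 1 + len(seq))
        usable[span] += 1
        match_counts[span] += 1
        for ref_pos, _ref_base, clone_base in mismatches:
            match_counts[ref_pos - 1] -= 1
            if clone_base in _BASE_INDEX:
                sub_counts[ref_pos - 1, _BASE_INDEX[clone_base]] += 1
            # clone N at a position: neither match nor substitution, stays in usable
    if n_accepted == 0:
        raise ValueError(f"{cs.reference_id}: all {len(cs.clones)} clones rejected")
    return EditingTable(
        reference_id=cs.reference_id,
        reference_seq=cs.reference_seq,
        stemloop_start=cs.stemloop_start,
        n_clones=n_accepted,
        sub_counts=sub_counts,
        match_counts=match_counts,
        usable=usable,
        rejected=rejected,
    )


def to_stemloop_coord(ref_pos: int, stemloop_start: int) -> int:
    """Map a 1-based reference position to the stem-loop "+N" convention.

    The stem-loop 5' end is +1.  Values <= 0 denote upstream positions and
    are flagged by callers.
    """
    return ref_pos - stemloop_start + 1


def editing_frequency(tbl: EditingTable, ref_pos: int) -> EditingSiteStat:
    """Editing frequency at an adenosine: A->G clones over usable clones there."""
    ref_base = tbl.reference_seq[ref_pos - 1]
    if ref_base != "A":
        raise ValueError(f"reference base at {ref_pos} is {ref_base}, not A")
    edited = tbl.substitution_count(ref_pos, "G")
    total = int(tbl.usable[ref_pos - 1])
    if total == 0:
        raise ValueError(f"no usable clones cover position {ref_pos}")
    stat = EditingSiteStat(
        ref_pos=ref_pos,
        position_stemloop=to_stemloop_coord(ref_pos, tbl.stemloop_start),
        ref_base=ref_base,
        edited_count=edited,
        total_count=total,
    )
    if stat.upstream:
        logger.info("%s: position %d is upstream of the stem-loop", tbl.reference_id, ref_pos)
    return stat


def call_editing_sites(tbl: EditingTable, min_count: int = 1) -> list[EditingSiteStat]:
    """All adenosine positions with >= min_count A->G clones, by stem-loop coordinate."""
    sites = []
    for pos0, base in enumerate(tbl.reference_seq):
        if base != "A" or tbl.usable[pos0] == 0:
            continue
        if tbl.sub_counts[pos0, _BASE_INDEX["G"]] >= min_count:
            sites.append(editing_frequency(tbl, pos0 + 1))
    sites.sort(key=lambda s: s.position_stemloop)
    return sites


def compare_editing(
    a_edited: int, a_total: int, b_edited: int, b_total: int
) -> ContingencyResult:
    """Contrast editing between two conditions on the 2x2 clone-count table.

    Fisher's exact p is two-sided (sum of hypergeometric probabilities no
    larger than the observed table's); the chi-squared test is Pearson's
    without continuity correction.  A degenerate chi-squared (a margin of
    zero edited or zero unedited clones overall) is reported as stat 0, p 1.
    """
    for label, edited, total in (("a", a_edited, a_total), ("b", b_edited, b_total)):
        if total <= 0:
            raise ValueError(f"condition {label}: total clone count must be positive")
        if not (0 <= edited <= total):
            raise ValueError(f"condition {label}: edited count outside [0, total]")
    table = [[a_edited, a_total - a_edited], [b_edited, b_total - b_edited]]
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    arr = np.asarray(table)
    if (arr.sum(axis=0) == 0).any():
        chi2_stat, chi2_p = 0.0, 1.0
    else:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(arr, correction=False)
    return ContingencyResult(
        table=table, fisher_p=float(fisher_p), chi2_stat=float(chi2_stat), chi2_p=float(chi2_p)
    )
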