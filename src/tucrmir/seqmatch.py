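"""Exact-complementarity screening between T-UCRs and pri-miRNA hairpins.

The screen reports every *maximal* exactly complementary segment of at least
``min_len`` nucleotides between a UCR and a hairpin: a segment such that the
UCR subsequence equals the reverse complement of the hairpin subsequence
(the duplex-forming convention) and that cannot be extended by one
nucleotide in either direction.  Matches overlapping mature-arm intervals
can be excluded, and identical matches shared by hairpins of one miRNA
cluster are grouped.  A seed-site scanner classifies canonical miRNA target
sites (8mer / 7mer-m8 / 7mer-A1 / 6mer) for unedited and A-to-I-edited
mature sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import HairpinRecord, UCRRecord, normalize_sequence

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    pass


@dataclass
class MatchConfig:
    """Screen configuration; the defaults reproduce the published screen."""

    min_len: int = 11
    mode: str = "complement"  # complement | identity
    exclude_mature: bool = True
    allow_wobble: bool = False  # reserved; wobble pairs are never counted

    def __post_init__(self) -> None:
        if self.min_len < 4:
            raise ValueError(f"min_len must be >= 4, got {self.min_len}")
        if self.mode not in {"complement", "identity"}:
            raise ValueError(f"mode must be complement|identity, got {self.mode!r}")
        if self.allow_wobble:
            raise NotImplementedError("G:U wobble pairing is not counted as a match")


@dataclass(frozen=True)
class ComplementarityMatch:
    """A maximal exact (complementary) segment; all coordinates 1-based inclusive."""

    ucr_id: str
    hairpin_id: str
    ucr_start: int
    ucr_end: int
    hp_start: int
    hp_end: int
    length: int
    ucr_subseq: str


@dataclass
class MatchGroup:
    """Identical matches between one UCR and the hairpins of one miRNA cluster."""

    ucr_id: str
    cluster_id: str
    ucr_subseq: str
    members: list[ComplementarityMatch] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.ucr_subseq)

    @property
    def hairpin_ids(self) -> list[str]:
        return [m.hairpin_id for m in self.members]


def _check_alphabet(seq: str, name: str = "sequence") -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise AlphabetError(f"{name}: characters outside {{A,C,G,T,N}}: {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _maximal_identity_runs(q: str, t: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal runs (qi, tj, L >= min_len) with q[qi:qi+L] == t[tj:tj+L], 0-based.

    Scans each diagonal of the comparison matrix once; a run is maximal by
    construction.  ``N`` never matches anything, itself included.
    """
    n, m = len(q), len(t)
    runs = []
    for d in range(-(m - 1), n):
        i = max(0, d)
        j = i - d
        run = 0
        while i <= n and j <= m:
            if i < n and j < m and q[i] == t[j] and q[i] != "N":
                run += 1
            else:
                if run >= min_len:
                    runs.append((i - run, j - run, run))
                run = 0
            i += 1
            j += 1
    return runs


def find_maximal_matches(
    query: str, subject: str, cfg: MatchConfig | None = None,
    query_id: str = "query", subject_id: str = "subject",
) -> list[ComplementarityMatch]:
    """Every maximal exact match between ``query`` and ``subject``.

    In ``complement`` mode a match means query[i..i+L-1] equals the reverse
    complement of subject[j..j+L-1]; in ``identity`` mode the subsequences are
    equal.  Results are sorted by descending length, then query position, then
    subject position; each maximal (i, j) pair is reported once.
    """
    cfg = cfg or MatchConfig()
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    _check_alphabet(query, "query")
    _check_alphabet(subject, "subject")
    if cfg.mode == "complement":
        target = reverse_complement(subject)
    else:
        target = subject
    m = len(subject)
    out = []
    for qi, tj, L in _maximal_identity_runs(query, target, cfg.min_len):
        if cfg.mode == "complement":
            # run on reverse-complemented subject; map back to subject coordinates
            hp_start = m - (tj + L) + 1
            hp_end = m - tj
        else:
            hp_start = tj + 1
            hp_end = tj + L
        out.append(
            ComplementarityMatch(
                ucr_id=query_id,
                hairpin_id=subject_id,
                ucr_start=qi + 1,
                ucr_end=qi + L,
                hp_start=hp_start,
                hp_end=hp_end,
                length=L,
                ucr_subseq=query[qi : qi + L],
            )
        )
    out.sort(key=lambda mt: (-mt.length, mt.ucr_start, mt.hp_start))
    return out


def filter_mature_overlap(
    matches: list[ComplementarityMatch], hairpin: HairpinRecord
) -> list[ComplementarityMatch]:
    """Drop matches sharing >= 1 hairpin position with any mature-arm interval.

    Adjacency (match ending at mature_start - 1) is not overlap.
    """
    kept = []
    for mt in matches:
        overlaps = any(
            mt.hp_start <= me and ms <= mt.hp_end for _, ms, me in hairpin.matures
        )
        if not overlaps:
            kept.append(mt)
    return kept


def group_by_cluster(
    matches: list[ComplementarityMatch], hairpins: list[HairpinRecord]
) -> list[MatchGroup]:
    """Merge identical matches (same UCR, cluster and matched subsequence)."""
    cluster_of = {hp.hairpin_id: hp.cluster_id for hp in hairpins}
    groups: dict[tuple[str, str, str], MatchGroup] = {}
    order: list[tuple[str, str, str]] = []
    for mt in matches:
        if mt.hairpin_id not in cluster_of:
            raise KeyError(f"unknown hairpin id {mt.hairpin_id!r}")
        key = (mt.ucr_id, cluster_of[mt.hairpin_id], mt.ucr_subseq)
        if key not in groups:
            groups[key] = MatchGroup(*key)
            order.append(key)
        groups[key].members.append(mt)
    return [groups[k] for k in order]


def screen_database(
    ucrs: list[UCRRecord], hairpins: list[HairpinRecord], cfg: MatchConfig | None = None
) -> list[MatchGroup]:
    """Run the full screen: match every UCR/hairpin pair, filter, group, rank.

    Groups are sorted by descending match length, ties broken by ucr_id then
    cluster_id lexicographically (then subsequence, for full determinism).
    """
    cfg = cfg or MatchConfig()
    if not ucrs or not hairpins:
        raise ValueError("both databases must be non-empty")
    all_matches: list[ComplementarityMatch] = []
    for ucr in ucrs:
        for hp in hairpins:
            matches = find_maximal_matches(
                ucr.sequence, hp.sequence, cfg, query_id=ucr.ucr_id, subject_id=hp.hairpin_id
            )
            if cfg.exclude_mature:
                matches = filter_mature_overlap(matches, hp)
            all_matches.extend(matches)
    groups = group_by_cluster(all_matches, hairpins)
    groups.sort(key=lambda g: (-g.length, g.ucr_id, g.cluster_id, g.ucr_subseq))
    return groups


def apply_editing_to_mature(mature: str, site: int) -> str:
    """Apply one A-to-I edit (read as A->G) at a 1-based position of a mature miRNA."""
    seq = normalize_sequence(mature, "mature")
    if not (1 <= site <= len(seq)):
        raise IndexError(f"site {site} outside sequence of length {len(seq)}")
    if seq[site - 1] != "A":
        raise ValueError(f"position {site} is {seq[site - 1]}, not A; cannot edit")
    return seq[: site - 1] + "G" + seq[site:]


def seed_match_scan(mature: str, utr: str) -> list[tuple[int, int, str]]:
    """Scan a 3'UTR for canonical seed sites of a mature miRNA.

    The seed core is miRNA nucleotides 2-7; every UTR occurrence of its
    reverse complement is classified by the standard extension rules:
    ``8mer`` (match at position 8 plus A opposite position 1), ``7mer-m8``
    (match at position 8), ``7mer-A1`` (A opposite position 1), else
    ``6mer``.  Returns 1-based inclusive UTR spans of the full matched site.
    """
    seq = normalize_sequence(mature, "mature")
    utr_n = normalize_sequence(utr, "utr")
    if len(seq) < 8:
        raise ValueError("mature sequence must be at least 8 nt")
    core = reverse_complement(seq[1:7])  # pairs miRNA nt 2-7
    m8 = reverse_complement(seq[7])  # base pairing miRNA nt 8
    sites = []
    start = 0
    while True:
        idx = utr_n.find(core, start)
        if idx == -1:
            break
        start = idx + 1
        # UTR runs 5'->3'; the base 5' of the core pairs nt 8, the base 3' pairs nt 1
        has_m8 = idx >= 1 and utr_n[idx - 1] == m8
        has_a1 = idx + len(core) < len(utr_n) and utr_n[idx + len(core)] == "A"
        if has_m8 and has_a1:
            cls, s, e = "8mer", idx - 1, idx + len(core)
        elif has_m8:
            cls, s, e = "7mer-m8", idx - 1, idx + len(core) - 1
        elif has_a1:
            cls, s, e = "7mer-A1", idx, idx + len(core)
        else:
            cls, s, e = "6mer", idx, idx + len(core) - 1
        sites.append((s + 1, e + 1, cls))
    return sites
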