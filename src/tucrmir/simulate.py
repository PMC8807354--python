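"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Three generators cover the pipeline's inputs:

* ``gen_sequence_db`` — random UCR/hairpin databases with reverse-complement
  segments planted at recorded coordinates, guarded by rejection sampling
  against accidental matches at or above the screen threshold.  The default
  plant list mirrors the study conditions: one 13-nt top hit, a 12-nt site
  shared by all four hairpins of a miR-376-like cluster, two further 12-nt
  singleton hits, and one sub-threshold 10-nt plant.
* ``gen_clone_set`` — clone-sequencing sets with per-site Bernoulli A->G
  editing plus uniform sequencing error, with a per-clone truth table.
* ``gen_cohort`` — glioma-like cohorts: group-specific hypermethylation
  prevalence (Bernoulli or deterministic exact-count mode), exponential
  survival with planted hazard ratios, and uniform censoring tuned to a
  requested censoring fraction.

Every generator is deterministic under a fixed seed (NumPy PCG64) and emits
a machine-readable truth table so downstream estimates can be tested
against the planted parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import HairpinRecord, PatientRecord, UCRRecord
from .seqmatch import MatchConfig, reverse_complement, screen_database

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# sequence databases


@dataclass(frozen=True)
class PlantSpec:
    """One planted complementary segment between the UCR and hairpin(s).

    ``hairpin_ids`` lists every hairpin carrying the identical site (all
    members of one cluster for a shared plant); ``in_mature`` places the
    segment inside the first mature-arm interval instead of the stem base.
    """

    length: int
    hairpin_ids: tuple[str, ...]
    cluster_id: str
    in_mature: bool = False


def _default_plants() -> tuple[PlantSpec, ...]:
    return (
        PlantSpec(13, ("hp-1289",), "clu-1289"),
        PlantSpec(12, ("hp-376c", "hp-376a-2", "hp-376b", "hp-376a-1"), "clu-376"),
        PlantSpec(12, ("hp-1248",), "clu-1248"),
        PlantSpec(12, ("hp-5004",), "clu-5004"),
        PlantSpec(10, ("hp-sub",), "clu-sub"),
    )


@dataclass
class SequenceSimConfig:
    """Sequence-database block of the simulation configuration."""

    ucr_id: str = "uc.160"
    ucr_length: int = 322  # the ultraconserved region assayed in vitro is 322 nt
    hairpin_length: int = 85
    n_background_hairpins: int = 4
    plants: tuple[PlantSpec, ...] = field(default_factory=_default_plants)
    mature_intervals: tuple[tuple[int, int], ...] = ((17, 38), (48, 69))  # 5p and 3p arms
    guard_min_len: int = 11  # no accidental complementary run >= this survives
    max_attempts: int = 50

    def __post_init__(self) -> None:
        for p in self.plants:
            if p.length > self.ucr_length or p.length > self.hairpin_length:
                raise ValueError(f"plant of length {p.length} exceeds a sequence length")
            if p.length <= 0:
                raise ValueError("plant length must be positive")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _block_extension(hp_seq: str, h_start: int, h_end: int, ucr_seq: str, u_start: int, u_end: int) -> str:
    """Mutate hairpin flank bases so the planted match cannot extend.

    In the duplex convention ucr[u_start] pairs hp[h_end] and ucr[u_end]
    pairs hp[h_start]; the flanking hairpin bases are forced away from the
    complement of the adjacent UCR bases, making the plant maximal by
    construction.  All coordinates 1-based inclusive.
    """
    s = list(hp_seq)
    if u_start >= 2 and h_end < len(s):  # UCR-left extension pairs hp position h_end+1
        bad = _COMP[ucr_seq[u_start - 2]]
        if s[h_end] == bad:
            s[h_end] = "A" if bad != "A" else "C"
    if u_end < len(ucr_seq) and h_start >= 2:  # UCR-right extension pairs hp position h_start-1
        bad = _COMP[ucr_seq[u_end]]
        if s[h_start - 2] == bad:
            s[h_start - 2] = "A" if bad != "A" else "C"
    return "".join(s)


def _hairpin_slot(cfg: SequenceSimConfig, plant: PlantSpec) -> tuple[int, int]:
    """1-based hairpin interval receiving the plant (inside or clear of mature arms)."""
    L = plant.length
    if plant.in_mature:
        ms, me = cfg.mature_intervals[0]
        if me - ms + 1 < L:
            raise ValueError("plant longer than the mature interval")
        return ms, ms + L - 1
    # base of the stem: after the 3' mature arm, at the junction with the flank
    start = cfg.mature_intervals[-1][1] + 2  # leave one spacer: adjacency is not overlap
    if start + L - 1 > cfg.hairpin_length:
        raise ValueError("no room for plant outside mature intervals")
    return start, start + L - 1


def gen_sequence_db(
    cfg: SequenceSimConfig | None = None, seed: int = 0
) -> tuple[list[UCRRecord], list[HairpinRecord], list[dict]]:
    """Generate a UCR + hairpin database with planted complementary segments.

    Returns ``(ucrs, hairpins, truth)`` where each truth row records the plant
    coordinates on both sequences and the planted subsequence.  Rejection
    sampling regenerates the random background until the screen at
    ``guard_min_len`` (mature filter off) recovers exactly the planted
    segments of qualifying length; exceeding ``max_attempts`` is an error.
    """
    cfg = cfg or SequenceSimConfig()
    rng = np.random.default_rng(seed)
    hairpin_ids = [hid for p in cfg.plants for hid in p.hairpin_ids]
    if len(set(hairpin_ids)) != len(hairpin_ids):
        raise ValueError("a hairpin may carry at most one plant")
    hairpin_ids += [f"hp-bg{i + 1}" for i in range(cfg.n_background_hairpins)]
    cluster_of = {hid: p.cluster_id for p in cfg.plants for hid in p.hairpin_ids}

    for _attempt in range(cfg.max_attempts):
        ucr_seq = _random_seq(rng, cfg.ucr_length)
        hp_seqs = {hid: _random_seq(rng, cfg.hairpin_length) for hid in hairpin_ids}
        # carve non-overlapping UCR windows for the plants, then write them in
        truth: list[dict] = []
        cursor = 5
        ok = True
        for plant in cfg.plants:
            if cursor + plant.length - 1 > cfg.ucr_length:
                ok = False
                break
            u_start, u_end = cursor, cursor + plant.length - 1
            cursor = u_end + 8  # spacer so plants cannot merge into longer runs
            subseq = ucr_seq[u_start - 1 : u_end]
            hp_segment = reverse_complement(subseq)
            h_start, h_end = _hairpin_slot(cfg, plant)
            for hid in plant.hairpin_ids:
                s = hp_seqs[hid]
                s = s[: h_start - 1] + hp_segment + s[h_end:]
                hp_seqs[hid] = _block_extension(s, h_start, h_end, ucr_seq, u_start, u_end)
                truth.append(
                    {
                        "ucr_id": cfg.ucr_id,
                        "hairpin_id": hid,
                        "cluster_id": plant.cluster_id,
                        "length": plant.length,
                        "ucr_start": u_start,
                        "ucr_end": u_end,
                        "hp_start": h_start,
                        "hp_end": h_end,
                        "in_mature": plant.in_mature,
                        "ucr_subseq": subseq,
                    }
                )
        if not ok:
            raise ValueError("plants do not fit in the UCR sequence")
        ucrs = [UCRRecord(cfg.ucr_id, ucr_seq)]
        hairpins = [
            HairpinRecord(
                hid,
                cluster_of.get(hid, ""),
                hp_seqs[hid],
                [(f"{hid}-5p", *cfg.mature_intervals[0]), (f"{hid}-3p", *cfg.mature_intervals[1])],
            )
            for hid in hairpin_ids
        ]
        if _only_planted_matches(ucrs, hairpins, truth, cfg.guard_min_len):
            return ucrs, hairpins, truth
    raise RuntimeError(
        f"rejection sampling failed after {cfg.max_attempts} attempts; "
        "background sequences keep producing accidental matches"
    )


def _only_planted_matches(ucrs, hairpins, truth, guard_min_len) -> bool:
    """True when the screen recovers exactly the qualifying planted segments."""
    groups = screen_database(
        ucrs, hairpins, MatchConfig(min_len=guard_min_len, exclude_mature=False)
    )
    found = {
        (m.hairpin_id, m.ucr_start, m.ucr_end, m.hp_start, m.hp_end)
        for g in groups
        for m in g.members
    }
    expected = {
        (t["hairpin_id"], t["ucr_start"], t["ucr_end"], t["hp_start"], t["hp_end"])
        for t in truth
        if t["length"] >= guard_min_len
    }
    return found == expected


def mutate_plant(
    ucrs: list[UCRRecord], truth_row: dict, k: int, seed: int = 0
) -> list[UCRRecord]:
    """Mutate ``k`` of the planted complementary nucleotides on the UCR.

    Each chosen position is substituted by a different base, destroying the
    Watson-Crick pairing there (the mut12/mut5-style substrates).
    """
    rng = np.random.default_rng(seed)
    L = truth_row["length"]
    if not (1 <= k <= L):
        raise ValueError(f"k must be in [1, {L}]")
    positions = np.sort(rng.choice(L, size=k, replace=False))
    out = []
    for ucr in ucrs:
        if ucr.ucr_id != truth_row["ucr_id"]:
            out.append(ucr)
            continue
        seq = list(ucr.sequence)
        for off in positions:
            pos0 = truth_row["ucr_start"] - 1 + int(off)
            choices = [b for b in "ACGT" if b != seq[pos0]]
            seq[pos0] = choices[rng.integers(0, 3)]
        out.append(replace(ucr, sequence="".join(seq)))
    return out


def compensate_hairpin(
    hairpins: list[HairpinRecord], truth_row: dict, mutated_ucr: UCRRecord
) -> list[HairpinRecord]:
    """Apply compensatory substitutions so the hairpin again pairs the mutated UCR.

    The planted hairpin segment is replaced by the reverse complement of the
    (possibly mutated) UCR window, restoring full complementarity.
    """
    window = mutated_ucr.sequence[truth_row["ucr_start"] - 1 : truth_row["ucr_end"]]
    segment = reverse_complement(window)
    out = []
    for hp in hairpins:
        if hp.hairpin_id != truth_row["hairpin_id"]:
            out.append(hp)
            continue
        s = hp.sequence
        new_seq = s[: truth_row["hp_start"] - 1] + segment + s[truth_row["hp_end"] :]
        out.append(HairpinRecord(hp.hairpin_id, hp.cluster_id, new_seq, list(hp.matures)))
    return out


# ---------------------------------------------------------------------------
# clone sets


@dataclass
class CloneSimConfig:
    """Editing block: per-site editing probabilities and sequencing error."""

    site_probs: dict[int, float] = field(default_factory=dict)  # 1-based ref pos -> P(A->G)
    n_clones: int | None = None  # fixed count; None draws uniformly from clone_range
    clone_range: tuple[int, int] = (75, 100)  # clones isolated per cDNA in the protocol
    error_rate: float = 0.001  # per-base uniform sequencing error

    def __post_init__(self) -> None:
        for pos, p in self.site_probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"site {pos}: probability {p} outside [0, 1]")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate outside [0, 1)")


def gen_clone_set(
    reference_id: str,
    reference_seq: str,
    stemloop_start: int,
    cfg: CloneSimConfig | None = None,
    seed: int = 0,
):
    """Simulate a clone-sequencing set; returns ``(CloneSet, truth)``.

    Each clone is independently edited A->G at each configured site with its
    probability, then subjected to uniform per-base sequencing error.  The
    truth table records the number of clones actually edited at each site.
    """
    from .editing import CloneSet

    cfg = cfg or CloneSimConfig()
    rng = np.random.default_rng(seed)
    for pos in cfg.site_probs:
        if reference_seq[pos - 1] != "A":
            raise ValueError(f"site {pos} is {reference_seq[pos - 1]}, not A")
    n = cfg.n_clones if cfg.n_clones is not None else int(
        rng.integers(cfg.clone_range[0], cfg.clone_range[1] + 1)
    )
    clones = []
    planted_counts = {pos: 0 for pos in cfg.site_probs}
    per_clone_edits = []
    for i in range(n):
        seq = list(reference_seq)
        edits = []
        for pos, p in sorted(cfg.site_probs.items()):
            if rng.random() < p:
                seq[pos - 1] = "G"
                planted_counts[pos] += 1
                edits.append(pos)
        if cfg.error_rate > 0:
            err_mask = rng.random(len(seq)) < cfg.error_rate
            for pos0 in np.nonzero(err_mask)[0]:
                choices = [b for b in "ACGT" if b != seq[pos0]]
                seq[pos0] = choices[rng.integers(0, 3)]
        clones.append((f"clone{i + 1:03d}", "".join(seq)))
        per_clone_edits.append(edits)
    truth = {
        "n_clones": n,
        "site_probs": dict(cfg.site_probs),
        "planted_counts": planted_counts,
        "per_clone_edits": per_clone_edits,
        "error_rate": cfg.error_rate,
    }
    return CloneSet(reference_id, reference_seq, stemloop_start, clones), truth


def gen_editing_reference(length: int = 120, stemloop_start: int = 21, seed: int = 0) -> str:
    """A random pri-miRNA-like reference with adenosines guaranteed at common sites."""
    rng = np.random.default_rng(seed)
    return _random_seq(rng, length)


# ---------------------------------------------------------------------------
# clinical cohorts


@dataclass
class CohortSimConfig:
    """Cohort block: group sizes, prevalences, planted hazards, censoring.

    Defaults are the study conditions: 503 LGG / 134 GBM cases,
    hypermethylation prevalence 0.813 / 0.216, planted LGG methylation hazard
    ratio 0.135.  Quantities the source analysis does not state (IDH1
    mutation fractions, baseline hazards, censoring fractions, age/sex
    distributions) are set to field-realistic TCGA-like values.
    """

    n_lgg: int = 503
    n_gbm: int = 134
    prevalence_lgg: float = 0.813
    prevalence_gbm: float = 0.216
    deterministic_prevalence: bool = True  # exact rounded counts via shuffled assignment
    hr_methylation: float = 0.135
    hr_idh1: float = 0.35
    idh1_mut_frac_lgg: float = 0.80
    idh1_mut_frac_gbm: float = 0.10
    baseline_hazard_lgg: float = math.log(2) / 1500.0  # per day; unmeth. IDH1-WT LGG
    baseline_hazard_gbm: float = math.log(2) / 400.0
    censoring_frac_lgg: float = 0.60
    censoring_frac_gbm: float = 0.20
    age_mean_lgg: float = 43.0
    age_mean_gbm: float = 60.0
    age_sd: float = 12.0
    male_frac: float = 0.55

    def __post_init__(self) -> None:
        for name in ("prevalence_lgg", "prevalence_gbm"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be inside (0, 1), got {v}")
        for name in ("censoring_frac_lgg", "censoring_frac_gbm"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.hr_methylation <= 0 or self.hr_idh1 <= 0:
            raise ValueError("hazard ratios must be positive")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _draw_betas(rng: np.random.Generator, hyper: np.ndarray) -> np.ndarray:
    """Two-component beta-value mixture: hyper cases strictly above 0.33."""
    n = hyper.size
    low = 0.33 * rng.beta(2.0, 2.0, size=n)
    high = 0.33 + (1.0 - 0.33) * rng.beta(2.0, 2.0, size=n)
    # keep the dichotomy strict at the boundary
    high = np.maximum(high, np.nextafter(0.33, 1.0))
    return np.where(hyper, high, low)


def _tune_tmax(hazards: np.ndarray, target_frac: float) -> float:
    """T_max for uniform censoring on [0, T_max] hitting the target censoring fraction.

    For exponential survival with rate h and C ~ U(0, T_max),
    P(censored | h) = (1 - exp(-h T_max)) / (h T_max); average over cases and
    solve for T_max by bisection.
    """

    def frac(tmax: float) -> float:
        x = hazards * tmax
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-6, 1e9
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if frac(mid) > target_frac:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def gen_cohort(
    cfg: CohortSimConfig | None = None, seed: int = 0
) -> tuple[list[PatientRecord], dict]:
    """Simulate a glioma cohort; returns ``(patients, truth)``.

    Survival is exponential with hazard
    ``baseline * hr_methylation^hyper * hr_idh1^idh1_mut`` per group;
    censoring is independent uniform on [0, T_max] with T_max tuned to the
    requested censoring fraction.  In deterministic-prevalence mode the
    hypermethylated count per group is exactly ``round(prevalence * n)``
    (half-up), assigned by shuffling.
    """
    cfg = cfg or CohortSimConfig()
    rng = np.random.default_rng(seed)
    patients: list[PatientRecord] = []
    truth: dict = {"config": cfg, "groups": {}}
    for group, n, prev, mut_frac, base_h, cens_frac, age_mean in (
        ("LGG", cfg.n_lgg, cfg.prevalence_lgg, cfg.idh1_mut_frac_lgg,
         cfg.baseline_hazard_lgg, cfg.censoring_frac_lgg, cfg.age_mean_lgg),
        ("GBM", cfg.n_gbm, cfg.prevalence_gbm, cfg.idh1_mut_frac_gbm,
         cfg.baseline_hazard_gbm, cfg.censoring_frac_gbm, cfg.age_mean_gbm),
    ):
        if n == 0:
            continue
        if cfg.deterministic_prevalence:
            n_hyper = _round_half_up(prev * n)
            hyper = np.zeros(n, dtype=bool)
            hyper[rng.permutation(n)[:n_hyper]] = True
        else:
            hyper = rng.random(n) < prev
            n_hyper = int(hyper.sum())
        betas = _draw_betas(rng, hyper)
        idh1_mut = rng.random(n) < mut_frac
        age = np.clip(rng.normal(age_mean, cfg.age_sd, size=n), 18.0, 90.0)
        male = rng.random(n) < cfg.male_frac
        hazards = base_h * cfg.hr_methylation**hyper * cfg.hr_idh1**idh1_mut
        death_t = rng.exponential(1.0 / hazards)
        if cens_frac > 0:
            tmax = _tune_tmax(hazards, cens_frac)
            cens_t = rng.uniform(0.0, tmax, size=n)
        else:
            tmax = float("inf")
            cens_t = np.full(n, np.inf)
        os_time = np.minimum(death_t, cens_t)
        event = (death_t <= cens_t).astype(int)
        grade = "IV" if group == "GBM" else None
        for i in range(n):
            patients.append(
                PatientRecord(
                    case_id=f"{group}-{i + 1:04d}",
                    cohort=group,
                    beta=float(betas[i]),
                    grade=grade,
                    idh1="MUT" if idh1_mut[i] else "WT",
                    age=float(round(age[i], 1)),
                    sex="M" if male[i] else "F",
                    os_time=float(round(os_time[i], 2)),
                    event=int(event[i]),
                )
            )
        truth["groups"][group] = {
            "n": n,
            "n_hypermethylated": int(n_hyper),
            "prevalence": prev,
            "hr_methylation": cfg.hr_methylation,
            "hr_idh1": cfg.hr_idh1,
            "baseline_hazard": base_h,
            "censoring_frac_target": cens_frac,
            "censoring_frac_realized": float(1.0 - np.mean(event)),
            "t_max": tmax,
        }
    return patients, truth
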