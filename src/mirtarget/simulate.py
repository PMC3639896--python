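"""Synthetic data: transcriptomes with planted target sites and NB count tables.

Everything the pipeline consumes can be generated here, with a ground-truth
ledger, so every stage is testable end to end without external downloads:

* transcripts carrying *planted* miRNA target sites — each site is built from
  the miRNA's reverse complement and then perturbed at chosen miRNA positions
  into mismatches or G:U wobbles, so the resulting duplex has an exactly known
  pairing configuration;
* *decoy* sites that violate exactly one of the four duplex rules (verified at
  construction), for boundary testing of the scanner;
* two-condition count tables with negative-binomial noise (variance
  mu + phi*mu^2), planted fold-change tiers, zero-in-control (ND) genes, and a
  per-gene exact-test p-value for the planted mean shift (Fisher's exact test
  on the expected per-library counts) for use as the optional p column;
* a full synthetic elicitation study tying the two together, with planted
  complementary / concordant miRNA:target expression pairs.

All generators are deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .duplex import (
    DEFAULT_RULES,
    MiRNA,
    PairState,
    RuleConfig,
    evaluate_rules,
    pair_state,
    reverse_complement,
    score_duplex,
)
from .errors import GenerationError, InputError
from .scanner import Transcript

BASES = ("A", "C", "G", "U")
RULE_NAMES = ("total", "contiguous", "seed", "central")


# ---------------------------------------------------------------------------
# site construction


def build_site(
    mirna: MiRNA,
    mismatch_positions: Iterable[int] = (),
    gu_positions: Iterable[int] = (),
) -> str:
    """Target site (5'→3') pairing the miRNA with a prescribed configuration.

    Starts from the miRNA's exact reverse complement, then rewrites the target
    base opposite each listed miRNA position: mismatch positions get the
    lexicographically first base that yields MISMATCH; G:U positions get the
    base making the pair a wobble (requires the miRNA base to be G or U).
    Positions are 1-based from the miRNA 5' end and the two sets must be
    disjoint.
    """
    mm = frozenset(mismatch_positions)
    gu = frozenset(gu_positions)
    L = len(mirna)
    if mm & gu:
        raise InputError(f"overlapping mismatch/G:U positions: {sorted(mm & gu)}")
    for p in mm | gu:
        if not 1 <= p <= L:
            raise InputError(f"position {p} outside miRNA length {L}")
    site = list(reverse_complement(mirna.sequence))
    for p in mm:
        b = mirna.sequence[p - 1]
        for cand in BASES:
            if pair_state(b, cand) is PairState.MISMATCH:
                site[L - p] = cand
                break
    for p in gu:
        b = mirna.sequence[p - 1]
        if b == "G":
            site[L - p] = "U"
        elif b == "U":
            site[L - p] = "G"
        else:
            raise GenerationError(
                f"miRNA base {b!r} at position {p} cannot form a G:U wobble"
            )
    return "".join(site)


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted site (or decoy) on a transcript."""

    mirna_id: str
    transcript_id: str
    position: int  # 0-based start on the transcript
    mismatch_positions: frozenset[int]
    gu_positions: frozenset[int]
    expected_pass: bool
    rule_violated: str | None = None  # set for decoys

    def to_dict(self) -> dict:
        return {
            "mirna_id": self.mirna_id,
            "transcript_id": self.transcript_id,
            "position": self.position,
            "mismatch_positions": sorted(self.mismatch_positions),
            "gu_positions": sorted(self.gu_positions),
            "expected_pass": self.expected_pass,
            "rule_violated": self.rule_violated,
        }


@dataclass(frozen=True)
class SitePlan:
    """Request to plant one site; position is chosen at random when None."""

    mirna_id: str
    transcript_index: int
    mismatch_positions: frozenset[int] = frozenset()
    gu_positions: frozenset[int] = frozenset()
    position: int | None = None
    rule_violated: str | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for the transcriptome and count-table generators.

    Fold tiers are ``(fold, n_genes)`` pairs; a ``None`` fold marks the ND tier
    (zero mean in the nonelicited library).  ``mean_range`` is the log-uniform
    range of nonelicited mean counts.
    """

    seed: int
    # transcriptome
    n_transcripts: int = 100
    length_range: tuple[int, int] = (300, 1500)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    mirnas: tuple[MiRNA, ...] = ()
    site_plans: tuple[SitePlan, ...] = ()
    rule_config: RuleConfig = DEFAULT_RULES
    # counts
    n_genes: int = 200
    fold_tiers: tuple[tuple[float | None, int], ...] = (
        (1.0, 140),
        (2.0, 20),
        (4.0, 20),
        (None, 20),
    )
    mean_range: tuple[float, float] = (20.0, 2000.0)
    dispersion: float = 0.1
    depths: tuple[int, int] = (100_000, 100_000)

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise InputError("base composition must sum to 1")
        if any(n < 0 for _, n in self.fold_tiers):
            raise InputError("tier gene counts must be non-negative")
        if min(self.depths) <= 0:
            raise InputError("library depths must be positive")


def _random_seq(rng: np.random.Generator, length: int, comp) -> list[str]:
    return list(rng.choice(BASES, size=length, p=list(comp)))


def make_transcriptome(
    config: SimulationConfig,
) -> tuple[list[Transcript], list[PlantedSite]]:
    """Random transcripts with the configured sites planted; returns the ledger.

    Site placement avoids overlap between sites on the same transcript;
    ``expected_pass`` in the ledger is evaluated through the duplex rule
    engine on the exact planted window.
    """
    rng = np.random.default_rng(config.seed)
    mirnas = {m.id: m for m in config.mirnas}
    lo, hi = config.length_range
    seqs = [
        _random_seq(rng, int(rng.integers(lo, hi + 1)), config.base_composition)
        for _ in range(config.n_transcripts)
    ]
    occupied: dict[int, list[tuple[int, int]]] = {}
    ledger: list[PlantedSite] = []
    for plan in config.site_plans:
        if plan.mirna_id not in mirnas:
            raise InputError(f"unknown miRNA id {plan.mirna_id!r} in site plan")
        mirna = mirnas[plan.mirna_id]
        L = len(mirna)
        if not 0 <= plan.transcript_index < config.n_transcripts:
            raise InputError(f"transcript index {plan.transcript_index} out of range")
        seq = seqs[plan.transcript_index]
        if plan.position is not None:
            if plan.position + L > len(seq):
                raise GenerationError(
                    f"site at {plan.position} overlaps end of transcript "
                    f"{plan.transcript_index} (length {len(seq)})"
                )
            start = plan.position
            if any(
                start < e and s < start + L
                for s, e in occupied.get(plan.transcript_index, [])
            ):
                raise GenerationError("requested site overlaps an existing site")
        else:
            if len(seq) < L:
                raise GenerationError("transcript shorter than miRNA")
            start = None
            for _ in range(200):
                cand = int(rng.integers(0, len(seq) - L + 1))
                if all(
                    cand >= e or s >= cand + L
                    for s, e in occupied.get(plan.transcript_index, [])
                ):
                    start = cand
                    break
            if start is None:
                raise GenerationError(
                    f"no room for site on transcript {plan.transcript_index}"
                )
        site = build_site(mirna, plan.mismatch_positions, plan.gu_positions)
        seq[start : start + L] = list(site)
        occupied.setdefault(plan.transcript_index, []).append((start, start + L))
        duplex = score_duplex(mirna, site, config.rule_config)
        verdict = evaluate_rules(duplex, config.rule_config)
        ledger.append(
            PlantedSite(
                mirna_id=mirna.id,
                transcript_id=_transcript_id(plan.transcript_index),
                position=start,
                mismatch_positions=frozenset(plan.mismatch_positions),
                gu_positions=frozenset(plan.gu_positions),
                expected_pass=verdict.passed,
                rule_violated=plan.rule_violated,
            )
        )
    transcripts = [
        Transcript(id=_transcript_id(i), sequence="".join(seq))
        for i, seq in enumerate(seqs)
    ]
    return transcripts, ledger


def _transcript_id(index: int) -> str:
    return f"t{index + 1:04d}"


# ---------------------------------------------------------------------------
# decoys


def make_decoy(
    rule_to_violate: str,
    mirna: MiRNA,
    config: RuleConfig = DEFAULT_RULES,
) -> tuple[frozenset[int], frozenset[int]]:
    """Mismatch/G:U position sets violating exactly one rule for this miRNA.

    The returned configuration fails the named rule and passes the other
    three, verified through the rule engine before returning.  Raises
    GenerationError when the miRNA is too short or lacks the G/U bases a
    construction needs.
    """
    if rule_to_violate not in RULE_NAMES:
        raise InputError(f"unknown rule {rule_to_violate!r}; expected {RULE_NAMES}")
    L = len(mirna)
    s_lo, s_hi = config.seed_region
    c_lo, c_hi = config.central_region
    candidates: list[tuple[frozenset[int], frozenset[int]]] = []
    if rule_to_violate == "central":
        candidates.append((frozenset({min(c_hi, L)}), frozenset()))
    elif rule_to_violate == "seed":
        need = config.max_seed_mismatch + 1
        # spread inside the seed, non-adjacent so the run rule stays satisfied
        picks = list(range(s_lo + 1, s_hi + 1, 2))[:need]
        if len(picks) == need:
            candidates.append((frozenset(picks), frozenset()))
    elif rule_to_violate == "contiguous":
        run = config.max_contiguous_mismatch + 1
        start = c_hi + 2  # leave a matched position after the central region
        if start + run - 1 <= L and run <= config.max_total_score:
            candidates.append((frozenset(range(start, start + run)), frozenset()))
    else:  # total
        gu_sites = [
            p
            for p in range(1, L + 1)
            if mirna.sequence[p - 1] in ("G", "U")
            and not (c_lo <= p <= c_hi)
            and not (s_lo <= p <= s_hi)
        ]
        gu_sites += [
            p
            for p in range(s_lo, s_hi + 1)
            if mirna.sequence[p - 1] in ("G", "U")
        ]
        # non-adjacent mismatch slots outside seed and central regions
        mm_slots = [
            p
            for p in range(c_hi + 2, L + 1, 2)
        ]
        seed_slot = [s_lo + 1] if s_hi - s_lo >= 1 else []
        for n_mm in (4, 3, 2, 1, 0):
            n_gu = int(
                math.ceil(
                    (config.max_total_score + config.gu_score / 2 - n_mm)
                    / config.gu_score
                )
            )
            if n_gu < 0:
                n_gu = 0
            if n_mm + n_gu == 0:
                continue
            mm_pick: list[int] = mm_slots[:n_mm]
            if len(mm_pick) < n_mm:
                extra = [p for p in seed_slot if p not in mm_pick]
                mm_pick = mm_pick + extra[: n_mm - len(mm_pick)]
            if len(mm_pick) < n_mm:
                continue
            gu_pick = [p for p in gu_sites if p not in mm_pick][:n_gu]
            if len(gu_pick) < n_gu:
                continue
            candidates.append((frozenset(mm_pick), frozenset(gu_pick)))
    for mm, gu in candidates:
        try:
            site = build_site(mirna, mm, gu)
        except GenerationError:
            continue
        verdict = evaluate_rules(score_duplex(mirna, site, config), config)
        flags = {
            "total": verdict.pass_total,
            "contiguous": verdict.pass_contiguous,
            "seed": verdict.pass_seed,
            "central": verdict.pass_central,
        }
        if not flags[rule_to_violate] and all(
            v for k, v in flags.items() if k != rule_to_violate
        ):
            return mm, gu
    raise GenerationError(
        f"cannot construct a decoy violating only {rule_to_violate!r} for "
        f"miRNA {mirna.id!r} (length {L})"
    )


# ---------------------------------------------------------------------------
# counts


def _nb_counts(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2 (gamma-Poisson)."""
    means = np.asarray(means, dtype=float)
    counts = np.zeros(means.shape, dtype=int)
    pos = means > 0
    if dispersion <= 0:
        counts[pos] = rng.poisson(means[pos])
    else:
        lam = rng.gamma(1.0 / dispersion, means[pos] * dispersion)
        counts[pos] = rng.poisson(lam)
    return counts


def _exact_shift_p(
    mean_non: float, mean_eli: float, depth_non: int, depth_eli: int
) -> float:
    """Two-proportion exact p-value for the planted mean shift.

    Fisher's exact test on the expected per-library counts, i.e. the p-value
    the planted truth itself would produce; fold-1 genes get p = 1 exactly.
    """
    a = int(round(mean_non))
    b = int(round(mean_eli))
    table = [[a, depth_non - a], [b, depth_eli - b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def simulate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-condition NB count table with planted fold tiers and an ND tier.

    Returns ``(table, truth)``.  ``table`` has columns ``id``,
    ``count_nonelicited``, ``count_elicited``, ``adjusted_p`` (the exact-test
    p-value of the planted mean shift).  ``truth`` records the planted fold
    (NaN for the ND tier), per-library true means, and the tier label.
    """
    if sum(n for _, n in config.fold_tiers) != config.n_genes:
        raise InputError("fold tier gene counts must sum to n_genes")
    rng = np.random.default_rng(config.seed)
    folds: list[float | None] = []
    for fold, n in config.fold_tiers:
        folds.extend([fold] * n)
    order = rng.permutation(config.n_genes)
    folds = [folds[i] for i in order]
    ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    lo, hi = config.mean_range
    base = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), config.n_genes)
    mean_non = np.where([f is None for f in folds], 0.0, base)
    mean_eli = np.array(
        [b if f is None else b * f for b, f in zip(base, folds)]
    )
    table, truth = _counts_from_truth(
        ids, folds, mean_non, mean_eli, rng, config.dispersion, config.depths
    )
    return table, truth


def _counts_from_truth(
    ids: Sequence[str],
    folds: Sequence[float | None],
    mean_non: np.ndarray,
    mean_eli: np.ndarray,
    rng: np.random.Generator,
    dispersion: float,
    depths: tuple[int, int],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    count_non = _nb_counts(rng, mean_non, dispersion)
    count_eli = _nb_counts(rng, mean_eli, dispersion)
    pvals = [
        _exact_shift_p(mn, me, depths[0], depths[1])
        for mn, me in zip(mean_non, mean_eli)
    ]
    table = pd.DataFrame(
        {
            "id": list(ids),
            "count_nonelicited": count_non,
            "count_elicited": count_eli,
            "adjusted_p": pvals,
        }
    )
    truth = pd.DataFrame(
        {
            "id": list(ids),
            "true_fold": [math.nan if f is None else f for f in folds],
            "nd_tier": [f is None for f in folds],
            "mean_nonelicited": mean_non,
            "mean_elicited": mean_eli,
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# full synthetic study


@dataclass(frozen=True)
class StudyConfig:
    """Design of the synthetic elicitation study.

    Pattern pairs plant one perfect target site per (miRNA, transcript) pair
    and give the target a strong planted fold (``pattern_fold_up`` /
    ``pattern_fold_down``) so the expression direction of every planted target
    is unambiguous; remaining transcripts are fold-1 nulls.  Random extra sites
    carry 0-3 mismatches outside the seed/central regions and 0-2 wobbles, and
    belong to direction-neutral miRNAs so they never contribute
    complementary/concordant pairs.
    """

    seed: int
    n_mirnas: int = 10
    mirna_length: int = 21
    n_transcripts: int = 100
    length_range: tuple[int, int] = (300, 1500)
    n_random_sites: int = 52
    n_decoys_per_rule: int = 3
    # (miRNA direction, target regulation) plan: 5 complementary + 3 concordant
    pattern_plan: tuple[tuple[str, str], ...] = (
        ("down", "up"),
        ("down", "up"),
        ("down", "up"),
        ("up", "down"),
        ("up", "down"),
        ("up", "up"),
        ("up", "up"),
        ("down", "down"),
    )
    pattern_fold_up: float = 8.0
    pattern_fold_down: float = 0.125
    pattern_mean_range: tuple[float, float] = (200.0, 2000.0)
    null_mean_range: tuple[float, float] = (20.0, 2000.0)
    dispersion: float = 0.01
    depths: tuple[int, int] = (100_000, 100_000)
    rule_config: RuleConfig = DEFAULT_RULES


@dataclass
class StudyData:
    """All generated study inputs plus the ground-truth ledger."""

    mirnas: list[MiRNA]
    transcripts: list[Transcript]
    planted_sites: list[PlantedSite]
    counts: pd.DataFrame
    truth: pd.DataFrame
    mirna_directions: pd.DataFrame
    pathway_map: pd.DataFrame
    ground_truth: dict


def _random_mirna(rng: np.random.Generator, mid: str, length: int, direction: str) -> MiRNA:
    return MiRNA(
        id=mid,
        sequence="".join(rng.choice(BASES, size=length)),
        direction=direction,
    )


def _random_site_config(
    rng: np.random.Generator, mirna: MiRNA, config: RuleConfig
) -> tuple[frozenset[int], frozenset[int]]:
    """0-3 mismatches outside seed/central plus 0-2 feasible wobbles."""
    L = len(mirna)
    outside = [
        p
        for p in range(1, L + 1)
        if not (config.seed_region[0] <= p <= config.seed_region[1])
        and not (config.central_region[0] <= p <= config.central_region[1])
    ]
    n_mm = int(rng.integers(0, 4))
    mm = rng.choice(outside, size=min(n_mm, len(outside)), replace=False)
    mm_set = frozenset(int(p) for p in mm)
    gu_ok = [
        p
        for p in range(1, L + 1)
        if mirna.sequence[p - 1] in ("G", "U") and p not in mm_set
    ]
    n_gu = int(rng.integers(0, 3))
    gu = rng.choice(gu_ok, size=min(n_gu, len(gu_ok)), replace=False)
    return mm_set, frozenset(int(p) for p in gu)


def simulate_study(config: StudyConfig) -> StudyData:
    """Generate a complete synthetic elicitation study with ground truth."""
    rng = np.random.default_rng(config.seed)
    n_pattern = len(config.pattern_plan)
    if config.n_mirnas < n_pattern + 1:
        raise InputError("need at least one direction-neutral miRNA beyond the plan")
    mirnas: list[MiRNA] = []
    for i in range(config.n_mirnas):
        direction = (
            config.pattern_plan[i][0] if i < n_pattern else "unchanged"
        )
        mirnas.append(
            _random_mirna(rng, f"m{i + 1:02d}", config.mirna_length, direction)
        )
    neutral = mirnas[n_pattern:]

    plans: list[SitePlan] = []
    # one perfect site per pattern pair, on its own transcript
    for i in range(n_pattern):
        plans.append(SitePlan(mirna_id=mirnas[i].id, transcript_index=i))
    # random extra sites on distinct non-pattern transcripts, neutral miRNAs
    free = list(range(n_pattern, config.n_transcripts))
    if config.n_random_sites + config.n_decoys_per_rule * len(RULE_NAMES) > len(free):
        raise InputError("not enough transcripts for the requested sites")
    site_tx = rng.choice(free, size=config.n_random_sites, replace=False)
    for tx in site_tx:
        mirna = neutral[int(rng.integers(0, len(neutral)))]
        mm, gu = _random_site_config(rng, mirna, config.rule_config)
        plans.append(
            SitePlan(
                mirna_id=mirna.id,
                transcript_index=int(tx),
                mismatch_positions=mm,
                gu_positions=gu,
            )
        )
    # decoys, each violating exactly one rule, on their own transcripts
    remaining = [t for t in free if t not in set(int(x) for x in site_tx)]
    decoy_tx = rng.choice(
        remaining, size=config.n_decoys_per_rule * len(RULE_NAMES), replace=False
    )
    k = 0
    for rule in RULE_NAMES:
        for _ in range(config.n_decoys_per_rule):
            mm = gu = None
            for mirna in neutral + mirnas[:n_pattern]:
                try:
                    mm, gu = make_decoy(rule, mirna, config.rule_config)
                except GenerationError:
                    continue
                break
            if mm is None:
                raise GenerationError(f"no miRNA admits a {rule!r} decoy")
            plans.append(
                SitePlan(
                    mirna_id=mirna.id,
                    transcript_index=int(decoy_tx[k]),
                    mismatch_positions=mm,
                    gu_positions=gu,
                    rule_violated=rule,
                )
            )
            k += 1

    sim = SimulationConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_transcripts=config.n_transcripts,
        length_range=config.length_range,
        mirnas=tuple(mirnas),
        site_plans=tuple(plans),
        rule_config=config.rule_config,
    )
    transcripts, ledger = make_transcriptome(sim)

    # counts: pattern targets get the planted strong fold, the rest are nulls
    folds: list[float | None] = []
    means = np.zeros(config.n_transcripts)
    p_lo, p_hi = config.pattern_mean_range
    n_lo, n_hi = config.null_mean_range
    for i in range(config.n_transcripts):
        if i < n_pattern:
            fold = (
                config.pattern_fold_up
                if config.pattern_plan[i][1] == "up"
                else config.pattern_fold_down
            )
            means[i] = 10.0 ** rng.uniform(math.log10(p_lo), math.log10(p_hi))
        else:
            fold = 1.0
            means[i] = 10.0 ** rng.uniform(math.log10(n_lo), math.log10(n_hi))
        folds.append(fold)
    ids = [t.id for t in transcripts]
    mean_eli = means * np.array(folds)
    counts, truth = _counts_from_truth(
        ids, folds, means, mean_eli, rng, config.dispersion, config.depths
    )

    mirna_directions = pd.DataFrame(
        {"mirna_id": [m.id for m in mirnas], "direction": [m.direction for m in mirnas]}
    )

    # small pathway map over planted and null genes
    pw_rows = []
    pw_plan = {
        "pw_increased_a": [0, 1],
        "pw_decreased": [3, 4],
        "pw_mixed": [2, 7],
        "pw_none": [8, 9, 10],
        "pw_increased_b": [5, 6],
    }
    for pw, idxs in pw_plan.items():
        for i in idxs:
            pw_rows.append({"pathway_id": pw, "member_id": ids[i]})
    pathway_map = pd.DataFrame(pw_rows, columns=["pathway_id", "member_id"])

    pattern_counts = {"complementary": 0, "concordant": 0}
    for mdir, treg in config.pattern_plan:
        if mdir == treg:
            pattern_counts["concordant"] += 1
        else:
            pattern_counts["complementary"] += 1

    ground_truth = {
        "seed": config.seed,
        "n_planted_sites": len(
            [s for s in ledger if s.rule_violated is None]
        ),
        "n_expected_pass": len([s for s in ledger if s.expected_pass]),
        "n_decoys": len([s for s in ledger if s.rule_violated is not None]),
        "planted_sites": [s.to_dict() for s in ledger],
        "pattern_counts": pattern_counts,
        "pattern_pairs": [
            {
                "mirna_id": mirnas[i].id,
                "transcript_id": ids[i],
                "mirna_direction": config.pattern_plan[i][0],
                "target_regulation": config.pattern_plan[i][1],
            }
            for i in range(n_pattern)
        ],
        "true_folds": {i_: (None if f is None else f) for i_, f in zip(ids, folds)},
    }
    return StudyData(
        mirnas=mirnas,
        transcripts=transcripts,
        planted_sites=ledger,
        counts=counts,
        truth=truth,
        mirna_directions=mirna_directions,
        pathway_map=pathway_map,
        ground_truth=ground_truth,
    )
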