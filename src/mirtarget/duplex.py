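"""miRNA:mRNA duplex alphabet, G:U-weighted scoring, and the four-rule verdict engine.

Plant miRNAs repress their targets through near-perfect, antiparallel
complementarity, so target prediction reduces to counting imperfections in the
ungapped duplex between a miRNA (read 5'→3') and a candidate site on the mRNA.
Each aligned position is in one of three states: a Watson–Crick MATCH, a G:U
wobble (tolerated but penalized at half weight), or a MISMATCH.  A candidate
site is accepted when it satisfies four rules:

i.   the G:U-weighted total score (mismatches x 1.0 + wobbles x ``gu_score``)
     does not exceed ``max_total_score`` (default 4.0);
ii.  no run of consecutive mismatches longer than ``max_contiguous_mismatch``
     (default 2);
iii. at most ``max_seed_mismatch`` (default 1) mismatches in the seed region,
     miRNA positions 1-9 from the 5' end;
iv.  no mismatch at the central, cleavage-site-spanning positions 10-11.

By default a G:U wobble contributes only to the total score and does not count
as a mismatch for the run/seed/central rules; set
``RuleConfig.gu_counts_in_positional_rules`` for the stricter reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, InputError

RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}
_WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

DIRECTIONS = ("up", "down", "unchanged")


class PairState(Enum):
    """Pairing state of one duplex position."""

    MATCH = "match"
    GU = "gu"
    MISMATCH = "mismatch"


def normalize_sequence(raw: str) -> str:
    """Uppercase a nucleotide string and convert the DNA alphabet to RNA (T→U).

    Raises
    ------
    InputError
        If the string is empty or contains a character outside ``{A,C,G,T,U,N}``
        (case-insensitive); the message names the character and its 1-based
        position.
    """
    if not raw:
        raise InputError("empty sequence")
    seq = raw.upper().replace("T", "U")
    for pos, ch in enumerate(seq, start=1):
        if ch not in RNA_ALPHABET:
            raise InputError(f"illegal character {ch!r} at position {pos}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement in the RNA alphabet (input must be normalized)."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise InputError(f"unnormalized base {exc.args[0]!r}") from None


def pair_state(mirna_base: str, target_base: str) -> PairState:
    """Classify one miRNA/target base pair as MATCH, GU, or MISMATCH.

    ``N`` never pairs: any pairing involving ``N`` is a MISMATCH.
    """
    for b in (mirna_base, target_base):
        if b not in RNA_ALPHABET:
            raise InputError(f"unnormalized base {b!r}")
    pair = (mirna_base, target_base)
    if pair in _WATSON_CRICK:
        return PairState.MATCH
    if pair in _WOBBLE:
        return PairState.GU
    return PairState.MISMATCH


@dataclass(frozen=True)
class MiRNA:
    """A small RNA query, 5'→3', with optional family and expression direction."""

    id: str
    sequence: str
    family: str | None = None
    direction: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if len(self.sequence) < 12:
            raise InputError(
                f"miRNA {self.id!r}: length {len(self.sequence)} < 12"
            )
        if self.direction is not None and self.direction not in DIRECTIONS:
            raise InputError(
                f"miRNA {self.id!r}: direction {self.direction!r} not in {DIRECTIONS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds and regions for the four duplex rules.

    ``seed_region`` and ``central_region`` are 1-based inclusive miRNA position
    ranges counted from the miRNA 5' end.
    """

    max_total_score: float = 4.0
    max_contiguous_mismatch: int = 2
    seed_region: tuple[int, int] = (1, 9)
    max_seed_mismatch: int = 1
    central_region: tuple[int, int] = (10, 11)
    gu_score: float = 0.5
    gu_counts_in_positional_rules: bool = False

    def __post_init__(self) -> None:
        if self.max_total_score < 0 or self.max_contiguous_mismatch < 0:
            raise ConfigError("thresholds must be non-negative")
        if self.max_seed_mismatch < 0 or self.gu_score < 0:
            raise ConfigError("thresholds must be non-negative")
        for name, (lo, hi) in (
            ("seed_region", self.seed_region),
            ("central_region", self.central_region),
        ):
            if lo < 1 or hi < lo:
                raise ConfigError(f"{name} {lo}-{hi} is not a valid 1-based range")

    # -- flat key:value serialization ------------------------------------

    def to_mapping(self) -> dict[str, str]:
        return {
            "max_total_score": repr(self.max_total_score),
            "max_contiguous_mismatch": str(self.max_contiguous_mismatch),
            "seed_region": f"{self.seed_region[0]}-{self.seed_region[1]}",
            "max_seed_mismatch": str(self.max_seed_mismatch),
            "central_region": f"{self.central_region[0]}-{self.central_region[1]}",
            "gu_score": repr(self.gu_score),
            "gu_counts_in_positional_rules": str(
                self.gu_counts_in_positional_rules
            ).lower(),
        }

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "RuleConfig":
        kwargs: dict = {}
        for key, raw in mapping.items():
            if key in ("seed_region", "central_region"):
                lo, _, hi = raw.partition("-")
                kwargs[key] = (int(lo), int(hi))
            elif key in ("max_contiguous_mismatch", "max_seed_mismatch"):
                kwargs[key] = int(raw)
            elif key in ("max_total_score", "gu_score"):
                kwargs[key] = float(raw)
            elif key == "gu_counts_in_positional_rules":
                kwargs[key] = raw.strip().lower() in ("true", "1", "yes")
            else:
                raise ConfigError(f"unknown rule parameter {key!r}")
        return cls(**kwargs)


DEFAULT_RULES = RuleConfig()


@dataclass(frozen=True)
class DuplexAlignment:
    """Position-resolved pairing of one miRNA against one same-length site.

    ``states[i]`` is the state of miRNA position ``i+1`` (1-based from the
    miRNA 5' end), which pairs with site position ``L-i`` (the alignment is
    antiparallel: the site is stored 5'→3' on the target).  ``score`` is the
    G:U-weighted mismatch score; ``seed_mismatches``/``central_mismatches``
    count MISMATCH states in the scoring config's regions (wobbles excluded).
    """

    mirna_id: str
    mirna_sequence: str
    site_sequence: str
    states: tuple[PairState, ...]
    score: float
    n_match: int
    n_gu: int
    n_mismatch: int
    max_run_mismatch: int
    seed_mismatches: int
    central_mismatches: int

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class RuleVerdict:
    """Per-rule pass flags; ``passed`` is the conjunction of the four."""

    pass_total: bool
    pass_contiguous: bool
    pass_seed: bool
    pass_central: bool

    @property
    def passed(self) -> bool:
        return (
            self.pass_total
            and self.pass_contiguous
            and self.pass_seed
            and self.pass_central
        )


def _max_run(flags: Sequence[bool]) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        if run > best:
            best = run
    return best


def _region_count(flags: Sequence[bool], region: tuple[int, int]) -> int:
    lo, hi = region
    return sum(flags[lo - 1 : hi])


def score_duplex(
    mirna: MiRNA, site: str, config: RuleConfig = DEFAULT_RULES
) -> DuplexAlignment:
    """Score one ungapped duplex of a miRNA against a same-length target site.

    ``site`` is the target subsequence written 5'→3'; miRNA position ``i``
    (1-based from the 5' end) pairs with site position ``L-i+1``.
    """
    seq = mirna.sequence
    L = len(seq)
    if len(site) != L:
        raise InputError(
            f"site length {len(site)} != miRNA length {L} (mirna {mirna.id!r})"
        )
    states = tuple(pair_state(seq[i], site[L - 1 - i]) for i in range(L))
    n_match = sum(s is PairState.MATCH for s in states)
    n_gu = sum(s is PairState.GU for s in states)
    n_mismatch = L - n_match - n_gu
    mm_flags = [s is PairState.MISMATCH for s in states]
    return DuplexAlignment(
        mirna_id=mirna.id,
        mirna_sequence=seq,
        site_sequence=site,
        states=states,
        score=n_mismatch + config.gu_score * n_gu,
        n_match=n_match,
        n_gu=n_gu,
        n_mismatch=n_mismatch,
        max_run_mismatch=_max_run(mm_flags),
        seed_mismatches=_region_count(mm_flags, config.seed_region),
        central_mismatches=_region_count(mm_flags, config.central_region),
    )


def evaluate_rules(
    duplex: DuplexAlignment, config: RuleConfig = DEFAULT_RULES
) -> RuleVerdict:
    """Apply the four target-acceptance rules to a scored duplex.

    All quantities are recomputed from ``duplex.states`` under ``config``, so a
    duplex scored under one configuration can be judged under another.  With
    ``gu_counts_in_positional_rules`` set, wobbles count as mismatches for the
    run, seed, and central rules; they always contribute ``gu_score`` to the
    total score.
    """
    L = len(duplex.states)
    if config.seed_region[1] > L or config.central_region[1] > L:
        raise ConfigError(
            f"rule regions {config.seed_region}/{config.central_region} exceed "
            f"miRNA length {L}"
        )
    if config.gu_counts_in_positional_rules:
        flags = [s is not PairState.MATCH for s in duplex.states]
    else:
        flags = [s is PairState.MISMATCH for s in duplex.states]
    score = duplex.n_mismatch + config.gu_score * duplex.n_gu
    return RuleVerdict(
        pass_total=score <= config.max_total_score,
        pass_contiguous=_max_run(flags) <= config.max_contiguous_mismatch,
        pass_seed=_region_count(flags, config.seed_region)
        <= config.max_seed_mismatch,
        pass_central=_region_count(flags, config.central_region) == 0,
    )
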