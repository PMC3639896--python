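"""Transcriptome-wide target-site scanning.

``scan_pair`` slides a miRNA along every window of a transcript and reports the
windows whose duplex passes the four-rule engine.  It uses a vectorized
prefilter over all windows and hands the few survivors to
:func:`mirtarget.duplex.score_duplex` / :func:`mirtarget.duplex.evaluate_rules`,
so the rule engine remains the single authority on acceptance.  ``oracle_scan``
is a deliberately naive per-window, per-position reimplementation sharing only
``pair_state`` with the fast path; the two are held equivalent by tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .duplex import (
    DEFAULT_RULES,
    DuplexAlignment,
    MiRNA,
    PairState,
    RuleConfig,
    RuleVerdict,
    evaluate_rules,
    normalize_sequence,
    pair_state,
    score_duplex,
)
from .errors import InputError

HIT_COLUMNS = [
    "mirna_id",
    "transcript_id",
    "start",
    "end",
    "score",
    "n_match",
    "n_gu",
    "n_mismatch",
    "max_run_mismatch",
    "seed_mismatches",
    "central_mismatches",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

# pair-class lookup: rows = miRNA base, cols = target base; 0 MATCH, 1 GU, 2 MISMATCH
_PAIR_CLASS = np.full((5, 5), 2, dtype=np.int8)
for _m, _t in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")):
    _PAIR_CLASS[_BASE_INDEX[_m], _BASE_INDEX[_t]] = 0
for _m, _t in (("G", "U"), ("U", "G")):
    _PAIR_CLASS[_BASE_INDEX[_m], _BASE_INDEX[_t]] = 1


@dataclass(frozen=True)
class Transcript:
    """An oriented mRNA contig ("unique sequence"), stored 5'→3' in RNA alphabet."""

    id: str
    sequence: str
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("transcript id must be non-empty")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TargetHit:
    """One accepted target site: coordinates are 0-based half-open, forward strand."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    duplex: DuplexAlignment
    verdict: RuleVerdict


def candidate_windows(transcript_length: int, mirna_length: int) -> list[tuple[int, int]]:
    """All ungapped site windows ``(i, i+L)``; empty if the transcript is shorter."""
    if transcript_length < 0 or mirna_length < 0:
        raise InputError("lengths must be non-negative")
    return [
        (i, i + mirna_length)
        for i in range(transcript_length - mirna_length + 1)
    ]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode("ascii").translate(_ENCODE_TABLE), dtype=np.uint8
    ).astype(np.intp)


_ENCODE_TABLE = bytes(
    _BASE_INDEX.get(chr(c), 0) for c in range(256)
)


def scan_pair(
    mirna: MiRNA, transcript: Transcript, config: RuleConfig = DEFAULT_RULES
) -> list[TargetHit]:
    """Report every window of ``transcript`` whose duplex with ``mirna`` passes.

    Hits are ordered by start; overlapping sites are all reported.
    """
    L = len(mirna)
    t = transcript.sequence
    n_win = len(t) - L + 1
    if n_win <= 0:
        return []
    enc = _encode(t)
    # window matrix reversed so column j is the target base paired with miRNA pos j+1
    win = np.lib.stride_tricks.sliding_window_view(enc, L)[:, ::-1]
    m = _encode(mirna.sequence)
    cls = _PAIR_CLASS[m[np.newaxis, :], win]
    n_mm = (cls == 2).sum(axis=1)
    n_gu = (cls == 1).sum(axis=1)
    score = n_mm + config.gu_score * n_gu
    pos = (cls >= 1) if config.gu_counts_in_positional_rules else (cls == 2)
    s_lo, s_hi = config.seed_region
    c_lo, c_hi = config.central_region
    ok = (
        (score <= config.max_total_score)
        & (pos[:, s_lo - 1 : s_hi].sum(axis=1) <= config.max_seed_mismatch)
        & (pos[:, c_lo - 1 : c_hi].sum(axis=1) == 0)
    )
    hits: list[TargetHit] = []
    for start in np.nonzero(ok)[0]:
        site = t[start : start + L]
        duplex = score_duplex(mirna, site, config)
        verdict = evaluate_rules(duplex, config)
        if verdict.passed:
            hits.append(
                TargetHit(
                    mirna_id=mirna.id,
                    transcript_id=transcript.id,
                    start=int(start),
                    end=int(start) + L,
                    duplex=duplex,
                    verdict=verdict,
                )
            )
    return hits


def oracle_scan(
    mirna: MiRNA, transcript: Transcript, config: RuleConfig = DEFAULT_RULES
) -> list[TargetHit]:
    """Reference scanner: straight-line loops, no shared logic beyond ``pair_state``.

    Same contract as :func:`scan_pair`; kept deliberately naive so the two
    implementations can check each other.
    """
    mseq = mirna.sequence
    L = len(mseq)
    tseq = transcript.sequence
    hits: list[TargetHit] = []
    for start in range(len(tseq) - L + 1):
        site = tseq[start : start + L]
        states = []
        for i in range(L):
            states.append(pair_state(mseq[i], site[L - 1 - i]))
        n_match = n_gu = n_mismatch = 0
        for s in states:
            if s is PairState.MATCH:
                n_match += 1
            elif s is PairState.GU:
                n_gu += 1
            else:
                n_mismatch += 1
        score = n_mismatch * 1.0 + n_gu * config.gu_score
        if config.gu_counts_in_positional_rules:
            posflags = [s is not PairState.MATCH for s in states]
        else:
            posflags = [s is PairState.MISMATCH for s in states]
        run = best_run = 0
        for f in posflags:
            run = run + 1 if f else 0
            best_run = max(best_run, run)
        seed_ct = 0
        for p in range(config.seed_region[0], config.seed_region[1] + 1):
            if posflags[p - 1]:
                seed_ct += 1
        central_ct = 0
        for p in range(config.central_region[0], config.central_region[1] + 1):
            if posflags[p - 1]:
                central_ct += 1
        if (
            score <= config.max_total_score
            and best_run <= config.max_contiguous_mismatch
            and seed_ct <= config.max_seed_mismatch
            and central_ct == 0
        ):
            mm_flags = [s is PairState.MISMATCH for s in states]
            mm_run = best = 0
            for f in mm_flags:
                mm_run = mm_run + 1 if f else 0
                best = max(best, mm_run)
            duplex = DuplexAlignment(
                mirna_id=mirna.id,
                mirna_sequence=mseq,
                site_sequence=site,
                states=tuple(states),
                score=score,
                n_match=n_match,
                n_gu=n_gu,
                n_mismatch=n_mismatch,
                max_run_mismatch=best,
                seed_mismatches=sum(
                    mm_flags[config.seed_region[0] - 1 : config.seed_region[1]]
                ),
                central_mismatches=sum(
                    mm_flags[config.central_region[0] - 1 : config.central_region[1]]
                ),
            )
            verdict = RuleVerdict(True, True, True, True)
            hits.append(
                TargetHit(mirna.id, transcript.id, start, start + L, duplex, verdict)
            )
    return hits


def hit_record(hit: TargetHit) -> dict:
    """Flatten a hit into the standard table row."""
    d = hit.duplex
    return {
        "mirna_id": hit.mirna_id,
        "transcript_id": hit.transcript_id,
        "start": hit.start,
        "end": hit.end,
        "score": d.score,
        "n_match": d.n_match,
        "n_gu": d.n_gu,
        "n_mismatch": d.n_mismatch,
        "max_run_mismatch": d.max_run_mismatch,
        "seed_mismatches": d.seed_mismatches,
        "central_mismatches": d.central_mismatches,
    }


def scan_all(
    mirnas: Iterable[MiRNA],
    transcripts: Iterable[Transcript],
    config: RuleConfig = DEFAULT_RULES,
    best_per_pair: bool = False,
) -> pd.DataFrame:
    """Scan every miRNA against every transcript and return the hit table.

    The table is sorted by ``(mirna_id, transcript_id, start)``.  With
    ``best_per_pair`` only the lowest-score site per (miRNA, transcript) pair is
    kept, ties broken by smallest start.  Summary counts (sites and distinct
    target transcripts per miRNA) are attached as ``df.attrs["summary"]``.
    """
    mirnas = list(mirnas)
    transcripts = list(transcripts)
    for kind, items in (("miRNA", mirnas), ("transcript", transcripts)):
        ids = [x.id for x in items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate {kind} ids: {dupes}")
    rows = []
    for mirna in mirnas:
        for transcript in transcripts:
            for hit in scan_pair(mirna, transcript, config):
                rows.append(hit_record(hit))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    df = df.sort_values(["mirna_id", "transcript_id", "start"]).reset_index(drop=True)
    if best_per_pair and len(df):
        df = (
            df.sort_values(["mirna_id", "transcript_id", "score", "start"])
            .groupby(["mirna_id", "transcript_id"], as_index=False)
            .first()[HIT_COLUMNS]
            .sort_values(["mirna_id", "transcript_id", "start"])
            .reset_index(drop=True)
        )
    df.attrs["summary"] = summarize_hits(df)
    return df


def summarize_hits(df: pd.DataFrame) -> dict:
    """Per-miRNA site and distinct-transcript counts plus overall totals.

    Both the per-site and the per-transcript tallies are reported, labeled, so
    downstream text never conflates "target sites" with "target transcripts".
    """
    if not len(df):
        return {
            "n_sites": 0,
            "n_target_transcripts": 0,
            "per_mirna_sites": {},
            "per_mirna_transcripts": {},
        }
    per_sites = df.groupby("mirna_id").size().to_dict()
    per_tx = df.groupby("mirna_id")["transcript_id"].nunique().to_dict()
    return {
        "n_sites": int(len(df)),
        "n_target_transcripts": int(df["transcript_id"].nunique()),
        "per_mirna_sites": {k: int(v) for k, v in per_sites.items()},
        "per_mirna_transcripts": {k: int(v) for k, v in per_tx.items()},
    }
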