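"""Pair target-scan hits with miRNA and target expression directions.

In plants, a functional miRNA:target relationship is expected to leave a
complementary footprint after elicitation: when the miRNA goes up its target's
transcript abundance tends to go down, and vice versa.  This module aggregates
hits to the (miRNA, transcript) level — expression direction is a transcript
property, not a site property — and labels each pair:

* ``complementary`` — the two directions are opposite (up/down or down/up);
* ``concordant``    — both up or both down;
* ``indeterminate`` — either side unchanged (or expression missing).

The labels describe expression patterns only; no claim of validated regulation
is made.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .duplex import DIRECTIONS
from .errors import InputError

PATTERNS = ("complementary", "concordant", "indeterminate")

INTEGRATION_COLUMNS = [
    "mirna_id",
    "mirna_direction",
    "transcript_id",
    "target_direction",
    "n_sites",
    "best_score",
    "pattern",
    "missing_expression",
]


@dataclass(frozen=True)
class IntegratedPair:
    mirna_id: str
    mirna_direction: str
    transcript_id: str
    target_direction: str
    n_sites: int
    best_score: float
    pattern: str
    missing_expression: bool = False


def classify_pair(mirna_direction: str, target_direction: str) -> str:
    """Pattern label for one (miRNA direction, target direction) combination."""
    for label in (mirna_direction, target_direction):
        if label not in DIRECTIONS:
            raise InputError(f"unknown direction label {label!r}")
    if "unchanged" in (mirna_direction, target_direction):
        return "indeterminate"
    return "complementary" if mirna_direction != target_direction else "concordant"


def build_integration_table(
    hits: pd.DataFrame,
    mirna_directions: Mapping[str, str] | pd.DataFrame,
    expression: pd.DataFrame | None = None,
    default_direction: str = "unchanged",
) -> pd.DataFrame:
    """One row per (miRNA, transcript) pair with aggregated sites and pattern.

    ``hits`` is a scan table (``mirna_id``, ``transcript_id``, ``score`` ...);
    ``mirna_directions`` maps miRNA id → direction (or is a table with those
    two columns); ``expression`` is an annotated table with ``id`` and
    ``direction`` columns.  Transcripts missing from the expression table get
    ``default_direction`` and a ``missing_expression`` flag.  Pattern counts
    are attached as ``df.attrs["pattern_counts"]``.
    """
    if isinstance(mirna_directions, pd.DataFrame):
        mirna_directions = dict(
            zip(
                mirna_directions["mirna_id"].astype(str),
                mirna_directions["direction"].astype(str),
            )
        )
    unknown = sorted(
        set(hits["mirna_id"].astype(str)) - set(mirna_directions)
    )
    if unknown:
        raise InputError(f"miRNA ids missing from direction table: {unknown}")
    target_dir: dict[str, str] = {}
    if expression is not None and len(expression):
        target_dir = dict(
            zip(expression["id"].astype(str), expression["direction"].astype(str))
        )
    rows = []
    grouped = hits.groupby(["mirna_id", "transcript_id"], sort=True)
    for (mirna_id, transcript_id), grp in grouped:
        mdir = mirna_directions[str(mirna_id)]
        missing = str(transcript_id) not in target_dir
        tdir = target_dir.get(str(transcript_id), default_direction)
        rows.append(
            {
                "mirna_id": mirna_id,
                "mirna_direction": mdir,
                "transcript_id": transcript_id,
                "target_direction": tdir,
                "n_sites": int(len(grp)),
                "best_score": float(grp["score"].min()),
                "pattern": classify_pair(mdir, tdir),
                "missing_expression": missing,
            }
        )
    df = pd.DataFrame(rows, columns=INTEGRATION_COLUMNS)
    df.attrs["pattern_counts"] = pattern_counts(df)
    return df


def pattern_counts(integrated: pd.DataFrame) -> dict[str, int]:
    """Tally of complementary/concordant/indeterminate pairs."""
    counts = {p: 0 for p in PATTERNS}
    if len(integrated):
        counts.update(
            {k: int(v) for k, v in integrated["pattern"].value_counts().items()}
        )
    return counts
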