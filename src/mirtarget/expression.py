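"""Abundance, fold-change, differential-expression, and pathway-direction conventions.

Expression is compared between a nonelicited (control) and a MeJA-elicited
culture.  Abundances are expressed as transcripts per million (per-library
relative abundance).  Fold change is elicited/nonelicited; a transcript seen
only after elicitation (control abundance zero) has no finite fold and is
flagged ``ND`` ("not determined") — such records are treated as up-regulated
for counting but keep an explicit flag.  A record absent from both libraries is
``UNDEFINED`` and excluded from differential calling.

A transcript is called differentially expressed when its fold change is no less
than twofold (inclusive, reciprocal for down-regulation: fold ≤ 0.5) and its
(adjusted) p-value is ≤ 0.05.  Statistical testing itself is not performed
here; p-values are consumed as an input column and the p criterion is skipped
(and flagged) when the column is absent.

Pathways are summarized at a stricter fourfold threshold: a pathway is
"increased" when it has members at ≥ 4-fold up and none at ≤ 1/4-fold down,
"decreased" for the converse, "mixed" when both occur, "none" otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name


#: Fold-change sentinel: control abundance zero, elicited positive ("n.d.").
ND = _Sentinel("ND")
#: Fold-change sentinel: zero in both libraries; excluded from DE calling.
UNDEFINED = _Sentinel("UNDEFINED")

FOLD_STATUS = ("ok", "nd", "undefined")


def relative_abundance(counts: Sequence[float] | np.ndarray) -> np.ndarray:
    """Scale one library's counts to transcripts per million.

    Values sum to 1e6 within numerical tolerance.  All-zero or negative input
    is rejected.
    """
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise InputError("counts must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise InputError("all-zero library: relative abundance undefined")
    return arr / total * 1e6


def fold_change(elicited: float, nonelicited: float):
    """Elicited/nonelicited fold change, or ``ND``/``UNDEFINED`` sentinels.

    ``ND`` when the nonelicited abundance is zero but the elicited one is
    positive; ``UNDEFINED`` when both are zero.
    """
    if elicited < 0 or nonelicited < 0:
        raise InputError("abundances must be non-negative")
    if nonelicited > 0:
        return elicited / nonelicited
    return ND if elicited > 0 else UNDEFINED


@dataclass
class ExpressionRecord:
    """Two-condition abundances for one transcript, in per-million units."""

    id: str
    abundance_nonelicited: float
    abundance_elicited: float
    adjusted_p: float | None = None

    @property
    def fold(self):
        return fold_change(self.abundance_elicited, self.abundance_nonelicited)


def classify_de(
    record: ExpressionRecord,
    fold_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> str:
    """Direction label under the inclusive twofold / p ≤ 0.05 convention.

    "up" when fold ≥ ``fold_threshold`` or fold is ``ND``; "down" when
    fold ≤ 1/``fold_threshold``; both additionally require the p criterion,
    which is skipped when ``adjusted_p`` is None.  ``UNDEFINED`` records are
    "unchanged".
    """
    p = record.adjusted_p
    if p is not None and not (0.0 <= p <= 1.0):
        raise InputError(f"record {record.id!r}: p-value {p} outside [0, 1]")
    p_ok = True if p is None else p <= p_threshold
    fold = record.fold
    if fold is UNDEFINED:
        return "unchanged"
    if (fold is ND or fold >= fold_threshold) and p_ok:
        return "up"
    if fold is not ND and fold <= 1.0 / fold_threshold and p_ok:
        return "down"
    return "unchanged"


def annotate_expression(
    df: pd.DataFrame,
    input_is_counts: bool = True,
    fold_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Annotate a two-condition expression table with fold and direction columns.

    Input columns: ``id`` plus either ``count_nonelicited``/``count_elicited``
    (converted to per-million abundances) or ``abundance_nonelicited``/
    ``abundance_elicited``, and optionally ``adjusted_p``.  Output adds
    ``abundance_*``, ``fold`` (NaN for ND/UNDEFINED), ``fold_status``
    (ok/nd/undefined), ``nd_flag``, ``direction``, and ``p_criterion_used``.
    """
    out = df.copy()
    if input_is_counts:
        for cond in ("nonelicited", "elicited"):
            col = f"count_{cond}"
            if col not in out.columns:
                raise InputError(f"missing column {col!r}")
            out[f"abundance_{cond}"] = relative_abundance(out[col].to_numpy())
    else:
        for cond in ("nonelicited", "elicited"):
            if f"abundance_{cond}" not in out.columns:
                raise InputError(f"missing column 'abundance_{cond}'")
    has_p = "adjusted_p" in out.columns
    folds: list[float] = []
    statuses: list[str] = []
    directions: list[str] = []
    for row in out.itertuples(index=False):
        rec = ExpressionRecord(
            id=str(getattr(row, "id")),
            abundance_nonelicited=float(getattr(row, "abundance_nonelicited")),
            abundance_elicited=float(getattr(row, "abundance_elicited")),
            adjusted_p=(
                None
                if not has_p or pd.isna(getattr(row, "adjusted_p"))
                else float(getattr(row, "adjusted_p"))
            ),
        )
        fold = rec.fold
        if fold is ND:
            folds.append(math.nan)
            statuses.append("nd")
        elif fold is UNDEFINED:
            folds.append(math.nan)
            statuses.append("undefined")
        else:
            folds.append(fold)
            statuses.append("ok")
        directions.append(classify_de(rec, fold_threshold, p_threshold))
    out["fold"] = folds
    out["fold_status"] = statuses
    out["nd_flag"] = [s == "nd" for s in statuses]
    out["direction"] = directions
    out["p_criterion_used"] = has_p
    return out


@dataclass(frozen=True)
class PathwaySummary:
    """Direction tally of one pathway at the pathway fold threshold."""

    pathway_id: str
    member_ids: tuple[str, ...]
    n_up: int
    n_down: int
    n_missing: int
    classification: str  # increased | decreased | mixed | none


def _member_counts(
    sub: pd.DataFrame, fold_threshold: float
) -> tuple[int, int]:
    n_up = n_down = 0
    for row in sub.itertuples(index=False):
        if row.direction == "up" and (
            row.fold_status == "nd" or row.fold >= fold_threshold
        ):
            n_up += 1
        elif row.direction == "down" and row.fold <= 1.0 / fold_threshold:
            n_down += 1
    return n_up, n_down


def summarize_pathways(
    annotated: pd.DataFrame,
    pathway_map: pd.DataFrame,
    pathway_fold_threshold: float = 4.0,
) -> pd.DataFrame:
    """Classify each pathway as increased/decreased/mixed/none at the fourfold bar.

    ``annotated`` is the output of :func:`annotate_expression`; ``pathway_map``
    is long-format with columns ``pathway_id``, ``member_id``.  Members may
    belong to several pathways.  Members absent from the expression table are
    counted in ``n_missing``; empty pathways classify as "none" with a warning.
    """
    for col in ("pathway_id", "member_id"):
        if col not in pathway_map.columns:
            raise InputError(f"pathway map missing column {col!r}")
    indexed = annotated.set_index(annotated["id"].astype(str))
    rows = []
    for pathway_id, grp in pathway_map.groupby("pathway_id", sort=True):
        members = [str(m) for m in grp["member_id"]]
        if not members:
            warnings.warn(f"pathway {pathway_id!r} has no members")
        present = [m for m in members if m in indexed.index]
        missing = len(members) - len(present)
        sub = indexed.loc[present]
        n_up, n_down = _member_counts(sub, pathway_fold_threshold)
        if n_up > 0 and n_down == 0:
            cls = "increased"
        elif n_down > 0 and n_up == 0:
            cls = "decreased"
        elif n_up > 0 and n_down > 0:
            cls = "mixed"
        else:
            cls = "none"
        rows.append(
            {
                "pathway_id": pathway_id,
                "n_members": len(members),
                "n_up": n_up,
                "n_down": n_down,
                "n_missing": missing,
                "classification": cls,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pathway_id",
            "n_members",
            "n_up",
            "n_down",
            "n_missing",
            "classification",
        ],
    )
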