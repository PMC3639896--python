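"""Readers/writers for FASTA, TSV tables, the run config, and duplex rendering.

Conventions: tables are tab-separated with a header row and ``.`` for missing
values; all output files are written atomically (temp file + rename) so a
failed run never leaves a partial artifact; FASTA sequences are normalized to
the RNA alphabet on read with the original alphabet recorded.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .duplex import DEFAULT_RULES, MiRNA, PairState, RuleConfig, normalize_sequence
from .errors import FormatError, InputError
from .scanner import TargetHit, Transcript

MISSING = "."

_PAIR_SYMBOL = {PairState.MATCH: "|", PairState.GU: "o", PairState.MISMATCH: " "}


@dataclass(frozen=True)
class FastaRecord:
    """One FASTA entry: id = first whitespace token of the header."""

    id: str
    sequence: str  # normalized RNA
    description: str = ""
    was_dna: bool = False


def _header_line_number(path: Path, record_id: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[:1] == [record_id]:
                return i
    return 0


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a FASTA file, normalizing sequences to the RNA alphabet.

    Raises FormatError (with the header's line number) for sequence-less
    records and for empty files.
    """
    path = Path(path)
    records: list[FastaRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not raw:
            line = _header_line_number(path, rec.id)
            raise FormatError(
                f"{path}: record {rec.id!r} at line {line} has no sequence"
            )
        try:
            seq = normalize_sequence(raw)
        except InputError as exc:
            raise FormatError(f"{path}: record {rec.id!r}: {exc}") from None
        records.append(
            FastaRecord(
                id=rec.id,
                sequence=seq,
                description=rec.description,
                was_dna="T" in raw.upper(),
            )
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[FastaRecord | MiRNA | Transcript], path: str | Path
) -> None:
    """Write records as FASTA (RNA alphabet), atomically."""
    lines = []
    for rec in records:
        lines.append(f">{rec.id}\n{rec.sequence}\n")
    _atomic_write_text(Path(path), "".join(lines))


def read_mirna_fasta(
    path: str | Path, directions: dict[str, str] | None = None
) -> list[MiRNA]:
    return [
        MiRNA(
            id=r.id,
            sequence=r.sequence,
            direction=(directions or {}).get(r.id),
        )
        for r in read_fasta(path)
    ]


def read_transcript_fasta(path: str | Path) -> list[Transcript]:
    return [
        Transcript(id=r.id, sequence=r.sequence, annotation=r.description or None)
        for r in read_fasta(path)
    ]


# ---------------------------------------------------------------------------
# tables


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with header, '.' for missing, atomically."""
    text = df.to_csv(sep="\t", index=False, na_rep=MISSING)
    _atomic_write_text(Path(path), text)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=[MISSING], **kwargs)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from None


def _atomic_write_text(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# duplex rendering


def render_duplex(hit_or_duplex) -> str:
    """Three-line text block: target 5'→3', pairing symbols, miRNA 3'→5'.

    Symbols: ``|`` Watson–Crick match, ``o`` G:U wobble, space mismatch.
    """
    duplex = getattr(hit_or_duplex, "duplex", hit_or_duplex)
    L = len(duplex.states)
    # site index k (5'→3') pairs miRNA position L-k (1-based) => state L-1-k
    symbols = "".join(_PAIR_SYMBOL[duplex.states[L - 1 - k]] for k in range(L))
    target = f"5' {duplex.site_sequence} 3'  target"
    middle = f"   {symbols}"
    mirna = f"3' {duplex.mirna_sequence[::-1]} 5'  {duplex.mirna_id}"
    return "\n".join([target, middle, mirna])


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Whole-run settings: duplex rules plus expression thresholds and seed."""

    rules: RuleConfig = DEFAULT_RULES
    fold_threshold: float = 2.0
    p_threshold: float = 0.05
    pathway_fold_threshold: float = 4.0
    input_is_counts: bool = True
    seed: int = 0

    def to_mapping(self) -> dict[str, str]:
        m = dict(self.rules.to_mapping())
        m.update(
            {
                "fold_threshold": repr(self.fold_threshold),
                "p_threshold": repr(self.p_threshold),
                "pathway_fold_threshold": repr(self.pathway_fold_threshold),
                "input_is_counts": str(self.input_is_counts).lower(),
                "seed": str(self.seed),
            }
        )
        return m

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "RunConfig":
        rule_keys = set(RuleConfig().to_mapping())
        rules = RuleConfig.from_mapping(
            {k: v for k, v in mapping.items() if k in rule_keys}
        )
        kwargs: dict = {"rules": rules}
        for key, raw in mapping.items():
            if key in rule_keys:
                continue
            if key in ("fold_threshold", "p_threshold", "pathway_fold_threshold"):
                kwargs[key] = float(raw)
            elif key == "input_is_counts":
                kwargs[key] = raw.strip().lower() in ("true", "1", "yes")
            elif key == "seed":
                kwargs[key] = int(raw)
            else:
                raise FormatError(f"unknown config key {key!r}")
        return cls(**kwargs)


def write_config(config: RunConfig, path: str | Path) -> None:
    lines = [f"{k}: {v}\n" for k, v in config.to_mapping().items()]
    _atomic_write_text(Path(path), "".join(lines))


def read_config(path: str | Path) -> RunConfig:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, value = line.partition(":")
            if not sep:
                raise FormatError(f"{path}:{lineno}: expected 'key: value'")
            mapping[key.strip()] = value.strip()
    return RunConfig.from_mapping(mapping)
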