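"""File formats and metric reports.

* Puzzle files: plain text, one dot-bracket target per line, optionally
  followed by a whitespace-separated puzzle name; blank lines and lines
  starting with ``#`` are ignored.  Unnamed targets get ``puzzle<k>``.
* Designed sequences: FASTA (60-column), record IDs
  ``<puzzle>|<criterion>|<objective>`` where criterion is one of
  ``mfe``/``umfe``/``best``.
* Reports: TSV tables, floats at 6 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .folding import FoldingBackend, positional_entropy
from .objectives import ensemble_defect
from .structures import SecondaryStructure, StructureParseError, parse_dotbracket

REPORT_COLUMNS = [
    "puzzle",
    "solved_mfe",
    "solved_umfe",
    "n_mfe_solutions",
    "n_umfe_solutions",
    "best_probability",
    "best_ned",
    "mean_positional_entropy",
]


@dataclass
class PuzzleSet:
    """Named collection of target structures (names unique, all validated)."""

    entries: dict[str, SecondaryStructure]

    def __post_init__(self) -> None:
        for name, y in self.entries.items():
            if not isinstance(y, SecondaryStructure):
                raise TypeError(f"puzzle {name!r} is not a SecondaryStructure")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    def __getitem__(self, name: str) -> SecondaryStructure:
        return self.entries[name]


def read_puzzles(path: str | Path) -> PuzzleSet:
    """Parse a puzzle file; parse errors carry the 1-based line number."""
    entries: dict[str, SecondaryStructure] = {}
    auto = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        db = parts[0]
        if len(parts) > 1:
            name = parts[1]
        else:
            auto += 1
            name = f"puzzle{auto}"
        if name in entries:
            raise ValueError(f"line {lineno}: duplicate puzzle name {name!r}")
        try:
            entries[name] = parse_dotbracket(db)
        except StructureParseError as exc:
            raise StructureParseError(f"line {lineno}: {exc}") from exc
    return PuzzleSet(entries)


def write_puzzles(pset: PuzzleSet, path: str | Path) -> None:
    lines = [f"{y.dotbracket}\t{name}" for name, y in pset]
    Path(path).write_text("\n".join(lines) + "\n")


def write_designs_fasta(
    path: str | Path,
    records: Iterable[tuple[str, str, float, str]],
) -> None:
    """Write (puzzle, criterion, objective, sequence) records as FASTA."""
    seqrecords = [
        SeqRecord(Seq(seq), id=f"{puzzle}|{kind}|{obj:.6g}", description="")
        for puzzle, kind, obj, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecords)


def read_designs_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read design records back as (puzzle, criterion, sequence) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.id.split("|")
        if len(fields) < 2:
            raise ValueError(f"record id {rec.id!r} lacks '|'-separated fields")
        out.append((fields[0], fields[1], str(rec.seq)))
    return out


def evaluate_designs(
    pset: PuzzleSet,
    designs: Iterable[tuple[str, str]],
    backend: FoldingBackend,
) -> pd.DataFrame:
    """Recompute all per-puzzle metrics for (puzzle, sequence) designs.

    Independent of how the designs were produced: every metric (criterion
    satisfaction, target probability, ensemble defect, positional
    entropy) is recomputed from scratch with the given backend.  Raises
    if a design names an unknown puzzle or mismatches its length.
    """
    by_puzzle: dict[str, list[str]] = {}
    unmatched = []
    for puzzle, seq in designs:
        if puzzle not in pset.entries:
            unmatched.append(puzzle)
            continue
        if len(seq) != pset[puzzle].n:
            raise ValueError(
                f"design for {puzzle!r} has length {len(seq)},"
                f" target has {pset[puzzle].n}"
            )
        by_puzzle.setdefault(puzzle, [])
        if seq not in by_puzzle[puzzle]:
            by_puzzle[puzzle].append(seq)
    if unmatched:
        raise ValueError(f"designs reference unknown puzzles: {sorted(set(unmatched))}")

    rows = []
    for puzzle, seqs in by_puzzle.items():
        y = pset[puzzle]
        n_mfe = n_umfe = 0
        best_prob = -1.0
        best_ned = np.inf
        best_entropy = np.nan
        for seq in seqs:
            crit = backend.criterion(seq, y)
            n_mfe += crit.satisfies_mfe
            n_umfe += crit.satisfies_umfe
            analysis = backend.analyze(seq, y)
            prob = analysis.target_prob
            ned = ensemble_defect(analysis.summary, y) / y.n
            best_ned = min(best_ned, ned)
            if prob > best_prob:
                best_prob = prob
                best_entropy = float(np.mean(positional_entropy(analysis.summary)))
        rows.append(
            {
                "puzzle": puzzle,
                "solved_mfe": bool(n_mfe > 0),
                "solved_umfe": bool(n_umfe > 0),
                "n_mfe_solutions": n_mfe,
                "n_umfe_solutions": n_umfe,
                "best_probability": best_prob,
                "best_ned": float(best_ned),
                "mean_positional_entropy": best_entropy,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_manifest(path: str | Path, payload: Mapping) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
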