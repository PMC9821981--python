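"""Per-program docking score tables: reading, validation, writing, ranking.

Docking programs disagree on sign conventions (Vina emits binding energies
where more negative is better; XScore emits pKd-like values where larger is
better), so every :class:`ScoreTable` carries an explicit orientation flag.
Orientation is metadata supplied by the user — it is never inferred from the
data, because sign conventions differ by program and inference is unsafe.

Ranks use the average ("fractional") tie convention throughout: tied scores
receive the mean of the positions they span, so rank sums are exactly
N(N+1)/2 and rank-based consensus methods are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "Orientation",
    "ScoreTable",
    "RankTable",
    "read_score_table",
    "write_score_table",
    "to_ranks",
]


class Orientation(str, Enum):
    """Score sign convention of a docking program."""

    LOWER_BETTER = "lower_better"
    HIGHER_BETTER = "higher_better"

    @classmethod
    def coerce(cls, value: "Orientation | str") -> "Orientation":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"orientation must be 'lower_better' or 'higher_better', got {value!r}"
            ) from None


@dataclass(frozen=True)
class ScoreTable:
    """One program's docking scores keyed by molecule ID.

    Parameters
    ----------
    program_id:
        Short label for the docking program ("vina", "plants", ...).
    orientation:
        Whether lower or higher native scores indicate better binding.
    entries:
        Mapping molecule ID -> finite score in the program's native units.
    """

    program_id: str
    orientation: Orientation
    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "orientation", Orientation.coerce(self.orientation))
        cleaned: dict[str, float] = {}
        for raw_id, raw_score in dict(self.entries).items():
            mol_id = str(raw_id).strip()
            if not mol_id:
                raise ValueError(f"[{self.program_id}] empty molecule_id")
            if mol_id in cleaned:
                raise ValueError(
                    f"[{self.program_id}] duplicate molecule_id {mol_id!r}"
                )
            score = float(raw_score)
            if not math.isfinite(score):
                raise ValueError(
                    f"[{self.program_id}] non-finite score for molecule {mol_id!r}"
                )
            cleaned[mol_id] = score
        if not cleaned:
            raise ValueError(f"[{self.program_id}] score table is empty")
        object.__setattr__(self, "entries", cleaned)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.entries)

    def oriented(self) -> dict[str, float]:
        """Scores re-expressed so that higher is always better."""
        if self.orientation is Orientation.HIGHER_BETTER:
            return dict(self.entries)
        return {m: -s for m, s in self.entries.items()}


@dataclass(frozen=True)
class RankTable:
    """Average-tie ranks for one program; rank 1 is the best molecule."""

    program_id: str
    ranks: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = {str(m): float(r) for m, r in dict(self.ranks).items()}
        n = len(ranks)
        if n == 0:
            raise ValueError(f"[{self.program_id}] rank table is empty")
        total = sum(ranks.values())
        if not math.isclose(total, n * (n + 1) / 2, rel_tol=0, abs_tol=1e-6 * n):
            raise ValueError(
                f"[{self.program_id}] ranks must sum to N(N+1)/2; got {total}"
            )
        object.__setattr__(self, "ranks", ranks)

    def __len__(self) -> int:
        return len(self.ranks)


def to_ranks(table: ScoreTable) -> RankTable:
    """Rank a score table under its own orientation (1 = best, average ties).

    The output depends only on the score ordering, so any strictly monotone,
    orientation-preserving transform of the scores leaves it unchanged.
    """
    oriented = table.oriented()
    ids = list(oriented)
    values = np.fromiter(oriented.values(), dtype=float, count=len(ids))
    ranks = rankdata(-values, method="average")
    return RankTable(table.program_id, dict(zip(ids, ranks)))


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_score_table(
    path: str | Path,
    program_id: str | None = None,
    orientation: Orientation | str | None = None,
    delimiter: str | None = None,
) -> ScoreTable:
    """Read a delimited score table (columns ``molecule_id``, ``score``).

    ``#``-prefixed header comments may carry ``orientation=...`` and
    ``program_id=...``; explicit arguments override them.  Row order is
    irrelevant to every downstream result.

    Raises
    ------
    ValueError
        On duplicate molecule IDs (naming the ID), non-numeric or non-finite
        scores (naming the row), an empty table, or missing orientation.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[int, str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                stripped = line.lstrip().lstrip("#").strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            sep = delimiter or _sniff_delimiter(line)
            fields = [f.strip() for f in line.split(sep)]
            if header is None:
                header = [f.lower() for f in fields]
                continue
            rows.append((lineno, fields[0] if fields else "", fields[1] if len(fields) > 1 else ""))
    if header is None or not rows:
        raise ValueError(f"{path}: empty score table")
    try:
        id_col = header.index("molecule_id")
        score_col = header.index("score")
    except ValueError:
        raise ValueError(
            f"{path}: header must contain 'molecule_id' and 'score' columns, got {header}"
        ) from None
    del id_col, score_col  # columns validated; positional split already done

    if orientation is None:
        if "orientation" not in meta:
            raise ValueError(
                f"{path}: orientation not given and no '# orientation=' header present"
            )
        orientation = meta["orientation"]
    if program_id is None:
        program_id = meta.get("program_id", path.stem)

    entries: dict[str, float] = {}
    for lineno, mol_id, score_text in rows:
        mol_id = mol_id.strip()
        if mol_id in entries:
            raise ValueError(f"{path}: duplicate molecule_id {mol_id!r} (line {lineno})")
        try:
            score = float(score_text)
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric score {score_text!r} at line {lineno}"
            ) from None
        if not math.isfinite(score):
            raise ValueError(f"{path}: non-finite score at line {lineno}")
        entries[mol_id] = score
    return ScoreTable(program_id, Orientation.coerce(orientation), entries)


def write_score_table(table: ScoreTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a score table so that re-reading reproduces it exactly.

    Scores are written with ``repr`` (shortest round-trip) precision and the
    orientation and program ID are recorded in header comments.
    """
    if not isinstance(table, ScoreTable):
        raise TypeError("write_score_table expects a ScoreTable")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# program_id={table.program_id}\n")
        fh.write(f"# orientation={table.orientation.value}\n")
        fh.write(f"molecule_id{delimiter}score\n")
        for mol_id, score in table.entries.items():
            fh.write(f"{mol_id}{delimiter}{score!r}\n")
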