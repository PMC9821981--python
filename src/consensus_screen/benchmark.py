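"""Active/decoy benchmark assembly and multi-program score alignment.

A screening benchmark is a labeled library: n actives with confirmed target
activity plus property-matched (or simulated) decoys presumed inactive.
Actives are selected from an activity table by a strict potency cutoff
(IC50 strictly below 200 nM by default), and decoys are attached at a fixed
ratio per active.

`align_programs` turns a set of per-program score tables into a single
molecule x program matrix in a common higher-is-better orientation, which is
the input every consensus strategy consumes.  Molecules a program failed to
score are, by default, penalized to that program's worst rank rather than
dropped, because silently dropping them biases enrichment estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .score_io import Orientation, ScoreTable

__all__ = [
    "BenchmarkSet",
    "AlignedScores",
    "filter_actives",
    "assemble_benchmark",
    "align_programs",
    "read_label_table",
    "read_activity_table",
    "write_label_table",
]

logger = logging.getLogger(__name__)

ACTIVE = "active"
DECOY = "decoy"

#: default potency cutoff, nM; actives must be strictly below it
DEFAULT_IC50_THRESHOLD_NM = 200.0


@dataclass(frozen=True)
class BenchmarkSet:
    """Molecule labels with active/decoy bookkeeping.

    Attributes
    ----------
    labels:
        Mapping molecule ID -> ``"active"`` or ``"decoy"``.
    """

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        cleaned: dict[str, str] = {}
        for mol_id, label in dict(self.labels).items():
            mol_id = str(mol_id).strip()
            label = str(label).strip().lower()
            if label not in (ACTIVE, DECOY):
                raise ValueError(f"label for {mol_id!r} must be active/decoy, got {label!r}")
            if mol_id in cleaned:
                raise ValueError(f"duplicate molecule_id {mol_id!r} in labels")
            cleaned[mol_id] = label
        if not cleaned:
            raise ValueError("benchmark has no molecules")
        object.__setattr__(self, "labels", cleaned)

    @property
    def n_actives(self) -> int:
        return sum(1 for v in self.labels.values() if v == ACTIVE)

    @property
    def n_decoys(self) -> int:
        return sum(1 for v in self.labels.values() if v == DECOY)

    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def active_ids(self) -> list[str]:
        return sorted(m for m, v in self.labels.items() if v == ACTIVE)

    @property
    def decoy_ids(self) -> list[str]:
        return sorted(m for m, v in self.labels.items() if v == DECOY)

    def is_active(self, mol_id: str) -> bool:
        return self.labels[mol_id] == ACTIVE

    def require_both_classes(self) -> None:
        if self.n_actives == 0 or self.n_decoys == 0:
            raise ValueError(
                f"evaluation needs both classes; got {self.n_actives} actives, "
                f"{self.n_decoys} decoys"
            )

    def subset(self, molecule_ids: Iterable[str]) -> "BenchmarkSet":
        return BenchmarkSet({m: self.labels[m] for m in molecule_ids})


def filter_actives(
    activities: Mapping[str, float],
    threshold: float = DEFAULT_IC50_THRESHOLD_NM,
) -> list[str]:
    """Select actives: molecules with IC50 strictly below ``threshold`` (nM).

    The comparison is strict, so a molecule at exactly the threshold is
    excluded.  Returns IDs sorted for order stability.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    selected = []
    for mol_id, potency in activities.items():
        potency = float(potency)
        if not (math.isfinite(potency) and potency > 0):
            raise ValueError(f"non-positive or non-finite IC50 for {mol_id!r}: {potency}")
        if potency < threshold:
            selected.append(str(mol_id).strip())
    return sorted(selected)


def assemble_benchmark(
    active_ids: Sequence[str],
    decoys_per_active: int = 50,
    decoy_ids: Sequence[str] | None = None,
) -> BenchmarkSet:
    """Build a BenchmarkSet with a fixed decoy:active ratio.

    If ``decoy_ids`` is omitted, synthetic placeholder IDs are generated.
    An oversupply of decoys is resolved deterministically: IDs are sorted and
    the first ``n_actives * decoys_per_active`` are taken, so assembly is
    reproducible without a seed.
    """
    actives = [str(a).strip() for a in active_ids]
    if len(set(actives)) != len(actives):
        raise ValueError("duplicate IDs in active_ids")
    if not actives:
        raise ValueError("no actives supplied")
    if decoys_per_active < 1:
        raise ValueError(f"decoys_per_active must be >= 1, got {decoys_per_active}")
    n_decoys = len(actives) * decoys_per_active
    if decoy_ids is None:
        width = len(str(n_decoys))
        decoys = [f"decoy_{i:0{width}d}" for i in range(1, n_decoys + 1)]
    else:
        decoys = sorted({str(d).strip() for d in decoy_ids})
        overlap = set(actives) & set(decoys)
        if overlap:
            raise ValueError(f"active and decoy IDs overlap: {sorted(overlap)[:5]}")
        if len(decoys) < n_decoys:
            raise ValueError(
                f"need {n_decoys} decoys ({decoys_per_active} per active), got {len(decoys)}"
            )
        decoys = decoys[:n_decoys]
    labels = {m: ACTIVE for m in actives}
    labels.update({m: DECOY for m in decoys})
    return BenchmarkSet(labels)


@dataclass(frozen=True)
class AlignedScores:
    """Molecule x program score matrix in a common higher-better orientation.

    ``matrix[i, j]`` is molecule ``molecules[i]``'s oriented score in program
    ``programs[j]``; lower-better native scores have been negated.  All cells
    are finite after the missing-molecule policy has been applied.
    """

    programs: tuple[str, ...]
    molecules: tuple[str, ...]
    matrix: np.ndarray
    missing_policy: str
    benchmark: BenchmarkSet
    missing_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.shape != (len(self.molecules), len(self.programs)):
            raise ValueError("matrix shape does not match molecule/program lists")
        if not self.programs:
            raise ValueError("program list is empty")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("aligned matrix contains non-finite cells")
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "programs", tuple(self.programs))
        object.__setattr__(self, "molecules", tuple(self.molecules))

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_programs(self) -> int:
        return len(self.programs)

    def ranks(self) -> np.ndarray:
        """Per-program average-tie ranks (1 = best) as a molecule x program array."""
        return np.column_stack(
            [rankdata(-self.matrix[:, j], method="average") for j in range(self.n_programs)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.molecules), columns=list(self.programs))

    def labels_array(self) -> np.ndarray:
        """Boolean active mask aligned with ``molecules``."""
        return np.array([self.benchmark.is_active(m) for m in self.molecules], dtype=bool)


def _penalty_score(oriented: np.ndarray) -> float:
    """Worst oriented score minus one resolution step.

    The resolution step is the smallest positive gap between distinct scores,
    so the penalized molecules rank strictly below every scored molecule.
    """
    worst = float(np.min(oriented))
    distinct = np.unique(oriented)
    step = float(np.min(np.diff(distinct))) if distinct.size > 1 else 1.0
    return worst - step


def align_programs(
    tables: Sequence[ScoreTable],
    benchmark: BenchmarkSet,
    missing_policy: str = "penalize",
) -> AlignedScores:
    """Align per-program score tables on the benchmark molecule set.

    Under ``penalize`` (default), a molecule absent from program *j* gets that
    program's worst oriented score minus one resolution step, hence rank
    N_j + 1 where N_j molecules were scored.  Under ``intersect``, molecules
    missing from any program are dropped and the benchmark counts updated.
    """
    if not tables:
        raise ValueError("need at least one score table")
    if missing_policy not in ("penalize", "intersect"):
        raise ValueError(f"missing_policy must be 'penalize' or 'intersect', got {missing_policy!r}")
    program_ids = [t.program_id for t in tables]
    if len(set(program_ids)) != len(program_ids):
        raise ValueError(f"duplicate program_ids: {program_ids}")

    oriented_maps = [t.oriented() for t in tables]
    bench_ids = set(benchmark.labels)
    never_scored = [m for m in sorted(bench_ids) if not any(m in om for om in oriented_maps)]
    if never_scored:
        raise ValueError(
            f"{len(never_scored)} benchmark molecule(s) missing from every program, "
            f"e.g. {never_scored[:5]}"
        )

    if missing_policy == "intersect":
        keep = sorted(bench_ids.intersection(*[set(om) for om in oriented_maps]))
        if not keep:
            raise ValueError("empty molecule intersection across programs")
        molecules = keep
        bench_out = benchmark.subset(keep)
    else:
        molecules = sorted(bench_ids)
        bench_out = benchmark

    matrix = np.empty((len(molecules), len(tables)), dtype=float)
    missing_counts: dict[str, int] = {}
    for j, (pid, om) in enumerate(zip(program_ids, oriented_maps)):
        present = np.array([m in om for m in molecules])
        n_missing = int((~present).sum())
        missing_counts[pid] = n_missing
        col = np.array([om.get(m, np.nan) for m in molecules], dtype=float)
        if n_missing:
            col[~present] = _penalty_score(col[present])
        matrix[:, j] = col
        logger.info("align_programs: program %s missing %d of %d molecules", pid, n_missing, len(molecules))

    return AlignedScores(
        programs=tuple(program_ids),
        molecules=tuple(molecules),
        matrix=matrix,
        missing_policy=missing_policy,
        benchmark=bench_out,
        missing_counts=missing_counts,
    )


def read_label_table(path: str | Path, delimiter: str | None = None) -> BenchmarkSet:
    """Read a label table (columns ``molecule_id``, ``label``) into a BenchmarkSet."""
    df = pd.read_csv(path, sep=delimiter, comment="#", engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"molecule_id", "label"} <= set(df.columns):
        raise ValueError(f"{path}: need columns molecule_id,label; got {list(df.columns)}")
    return BenchmarkSet(dict(zip(df["molecule_id"].astype(str), df["label"].astype(str))))


def read_activity_table(path: str | Path, delimiter: str | None = None) -> dict[str, float]:
    """Read an activity table (columns ``molecule_id``, ``ic50_nm``)."""
    df = pd.read_csv(path, sep=delimiter, comment="#", engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"molecule_id", "ic50_nm"} <= set(df.columns):
        raise ValueError(f"{path}: need columns molecule_id,ic50_nm; got {list(df.columns)}")
    return dict(zip(df["molecule_id"].astype(str), df["ic50_nm"].astype(float)))


def write_label_table(benchmark: BenchmarkSet, path: str | Path, delimiter: str = ",") -> None:
    """Write a BenchmarkSet as a label table."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"molecule_id{delimiter}label\n")
        for mol_id in sorted(benchmark.labels):
            fh.write(f"{mol_id}{delimiter}{benchmark.labels[mol_id]}\n")
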