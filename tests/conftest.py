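import numpy as np
import pytest

from consensus_screen.benchmark import BenchmarkSet, align_programs
from consensus_screen.score_io import Orientation, ScoreTable


@pytest.fixture
def three_mol_table() -> ScoreTable:
    return ScoreTable("prog", Orientation.LOWER_BETTER, {"A": -9.1, "B": -7.0, "C": -8.2})


def make_aligned(matrix, labels=None, programs=None, molecules=None):
    """Build an AlignedScores from a molecule x program array of oriented scores."""
    matrix = np.asarray(matrix, dtype=float)
    n_mol, n_prog = matrix.shape
    molecules = molecules or [f"m{i:02d}" for i in range(n_mol)]
    programs = programs or [f"p{j}" for j in range(n_prog)]
    if labels is None:
        labels = ["active"] * (n_mol // 2) + ["decoy"] * (n_mol - n_mol // 2)
    benchmark = BenchmarkSet(dict(zip(molecules, labels)))
    tables = [
        ScoreTable(pid, Orientation.HIGHER_BETTER, dict(zip(molecules, matrix[:, j])))
        for j, pid in enumerate(programs)
    ]
    return align_programs(tables, benchmark)


@pytest.fixture
def aligned_factory():
    return make_aligned
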