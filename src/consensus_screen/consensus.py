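"""Consensus strategies for combining multi-program docking results.

Each strategy maps an aligned molecule x program score matrix to a single
consensus ranking.  Rank-based strategies (RBR, RBV, ECR, top-k intersection)
depend only on each program's ordering and are therefore invariant under any
strictly monotone orientation-preserving transform of its scores; score-based
strategies (RBN, AASS, Z-score, NSR) combine the numeric values and are, at
best, invariant under positive affine transforms.

All combined values are emitted higher = better, with 1-based average-tie
ranks regenerated from them, so downstream metrics see one convention.

Strategies
----------
RBR   rank-by-rank: mean of per-program ranks (negated so higher = better).
RBN   rank-by-number: mean of oriented raw scores.  Unscaled averaging lets
      programs with wide score ranges dominate; a warning notes this.
RBV   rank-by-vote: one vote per program whose top x% contains the molecule;
      equal-vote ties broken by the rank-by-rank value.
AASS  auto-scaled score: per-program min-max scaling to [0, 1], then mean.
Z     Z-score: per-program standardization (population SD), then mean.
ECR   exponential consensus ranking: sum over programs of
      (1/sigma) * exp(-rank / sigma); emphasizes early ranks.
NSR   normalized score ratio: per-program scores shifted non-negative when
      needed, divided by the shifted maximum, then averaged.  This statistic
      is named in the consensus-docking literature without a published
      definition; the shift-and-ratio form used here is this package's own
      documented choice (it coincides with AASS when no shift is needed and
      the minimum is zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping

import numpy as np
from scipy.stats import rankdata

from .benchmark import AlignedScores, BenchmarkSet

__all__ = [
    "ConsensusConfig",
    "ConsensusResult",
    "TopKReport",
    "rank_by_rank",
    "rank_by_number",
    "rank_by_vote",
    "auto_scaled_score",
    "z_score_consensus",
    "exponential_consensus_ranking",
    "normalized_score_ratio",
    "top_k_intersection",
    "CONSENSUS_METHODS",
    "combine",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConsensusConfig:
    """Tunable parameters shared by the consensus strategies.

    Attributes
    ----------
    vote_fraction:
        Top fraction x of each program's ranking that earns a vote in RBV
        (default 0.10, the conventional 10% of the benchmark).
    ecr_sigma:
        Rank-scale parameter sigma of ECR.  ``None`` (default) resolves to
        0.05 * N at combination time, tying the exponential window to the
        early-recognition region of the library.
    topk_k:
        List depth for top-k intersection reporting (default 1000).
    zscore_ddof:
        Delta degrees of freedom of the Z-score SD; 0 (default) is the
        population SD over the N scored molecules.
    """

    vote_fraction: float = 0.10
    ecr_sigma: float | None = None
    topk_k: int = 1000
    zscore_ddof: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.vote_fraction <= 1):
            raise ValueError(f"vote_fraction must be in (0, 1], got {self.vote_fraction}")
        if self.ecr_sigma is not None and self.ecr_sigma <= 0:
            raise ValueError(f"ecr_sigma must be positive, got {self.ecr_sigma}")
        if self.topk_k < 1:
            raise ValueError(f"topk_k must be >= 1, got {self.topk_k}")
        if self.zscore_ddof not in (0, 1):
            raise ValueError(f"zscore_ddof must be 0 or 1, got {self.zscore_ddof}")


@dataclass(frozen=True)
class ConsensusResult:
    """Combined score (higher = better) and average-tie rank per molecule."""

    method: str
    score: Mapping[str, float]
    rank: Mapping[str, float]
    extras: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def ordered_ids(self) -> list[str]:
        """Molecule IDs best-first; rank ties broken by ID for determinism."""
        return sorted(self.rank, key=lambda m: (self.rank[m], m))


def _result(method: str, aligned: AlignedScores, values: np.ndarray, **extras) -> ConsensusResult:
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{method}: non-finite consensus values")
    ranks = rankdata(-values, method="average")
    ids = aligned.molecules
    return ConsensusResult(
        method=method,
        score=dict(zip(ids, values.tolist())),
        rank=dict(zip(ids, ranks.tolist())),
        extras={k: dict(zip(ids, np.asarray(v, dtype=float).tolist())) for k, v in extras.items()},
    )


def _check(aligned: AlignedScores) -> None:
    if aligned.n_molecules == 0:
        raise ValueError("empty molecule set")


def rank_by_rank(aligned: AlignedScores, config: ConsensusConfig | None = None) -> ConsensusResult:
    """RBR: negated mean of per-program average-tie ranks."""
    _check(aligned)
    return _result("RBR", aligned, -aligned.ranks().mean(axis=1))


def rank_by_number(aligned: AlignedScores, config: ConsensusConfig | None = None) -> ConsensusResult:
    """RBN: mean of the oriented raw scores across programs."""
    _check(aligned)
    spans = aligned.matrix.max(axis=0) - aligned.matrix.min(axis=0)
    if spans.size > 1 and spans.max() > 0 and spans.min() >= 0:
        ratio = spans.max() / max(spans.min(), np.finfo(float).tiny)
        if ratio > 10:
            logger.warning(
                "rank_by_number: score ranges differ by a factor of %.1f across programs; "
                "unscaled averaging lets wide-range programs dominate", ratio,
            )
    return _result("RBN", aligned, aligned.matrix.mean(axis=1))


def rank_by_vote(aligned: AlignedScores, config: ConsensusConfig | None = None) -> ConsensusResult:
    """RBV: votes from each program's top x%, RBR value as secondary key.

    The cutoff is ceil(x * N) ranks; a molecule votes in program j iff its
    average-tie rank there is <= the cutoff.  The stored combined value embeds
    the tie-break (votes dominate, the RBR ordering refines), so the emitted
    rank is consistent with the combined value; the raw vote counts are kept
    in ``extras['votes']``.
    """
    config = config or ConsensusConfig()
    _check(aligned)
    n = aligned.n_molecules
    cutoff = math.ceil(config.vote_fraction * n)
    ranks = aligned.ranks()
    votes = (ranks <= cutoff).sum(axis=1).astype(float)
    mean_rank = ranks.mean(axis=1)
    # secondary key: RBR ordering, scaled into (0, 1) so votes dominate
    secondary = rankdata(mean_rank, method="average")
    combined = votes - secondary / (n + 1)
    return _result("RBV", aligned, combined, votes=votes)


def auto_scaled_score(aligned: AlignedScores, config: ConsensusConfig | None = None) -> ConsensusResult:
    """AASS: per-program min-max scaling (best -> 1, worst -> 0), then mean.

    A program with all-equal scores carries no ordering information; it
    contributes 0 for every molecule and a warning is logged.
    """
    _check(aligned)
    scaled = np.zeros_like(aligned.matrix)
    for j, pid in enumerate(aligned.programs):
        col = aligned.matrix[:, j]
        span = col.max() - col.min()
        if span == 0:
            logger.warning("auto_scaled_score: program %s has constant scores; contributes 0", pid)
            continue
        scaled[:, j] = (col - col.min()) / span
    return _result("AASS", aligned, scaled.mean(axis=1))


def z_score_consensus(aligned: AlignedScores, config: ConsensusConfig | None = None) -> ConsensusResult:
    """Z-score consensus: per-program standardization, then mean across programs.

    Uses the population SD (divide by N) by default: the scored library is the
    whole population of interest.  The sample-SD variant is ``zscore_ddof=1``.
    """
    config = config or ConsensusConfig()
    _check(aligned)
    if aligned.n_molecules < 2:
        raise ValueError("z_score_consensus needs at least 2 molecules")
    z = np.zeros_like(aligned.matrix)
    for j, pid in enumerate(aligned.programs):
        col = aligned.matrix[:, j]
        sd = col.std(ddof=config.zscore_ddof)
        if sd == 0:
            logger.warning("z_score_consensus: program %s has zero score SD; z set to 0", pid)
            continue
        z[:, j] = (col - col.mean()) / sd
    return _result("Z", aligned, z.mean(axis=1))


def exponential_consensus_ranking(
    aligned: AlignedScores, config: ConsensusConfig | None = None
) -> ConsensusResult:
    """ECR: sum over programs of (1/sigma) * exp(-rank / sigma).

    Strictly decreasing in every per-program rank, so early ranks dominate.
    ``sigma`` defaults to 0.05 * N, matching the early-recognition window.
    """
    config = config or ConsensusConfig()
    _check(aligned)
    sigma = config.ecr_sigma if config.ecr_sigma is not None else 0.05 * aligned.n_molecules
    if sigma <= 0:
        raise ValueError(f"ECR sigma must be positive, got {sigma}")
    ranks = aligned.ranks()
    return _result("ECR", aligned, np.exp(-ranks / sigma).sum(axis=1) / sigma)


def normalized_score_ratio(
    aligned: AlignedScores, config: ConsensusConfig | None = None
) -> ConsensusResult:
    """NSR: per-program score-to-maximum ratios, shifted non-negative, averaged.

    Per program the oriented scores are shifted by the minimum when any score
    is negative, then divided by the maximum of the shifted scores; the
    consensus value is the mean ratio.  See the module docstring: this
    definition is the package's own documented choice.
    """
    _check(aligned)
    if aligned.n_molecules < 2:
        raise ValueError("normalized_score_ratio needs at least 2 molecules")
    ratios = np.zeros_like(aligned.matrix)
    for j, pid in enumerate(aligned.programs):
        col = aligned.matrix[:, j].copy()
        if col.max() == col.min():
            logger.warning("normalized_score_ratio: program %s has constant scores; contributes 0", pid)
            continue
        if col.min() < 0:
            col = col - col.min()
        top = col.max()
        if top == 0:
            logger.warning("normalized_score_ratio: program %s has zero maximum; contributes 0", pid)
            continue
        ratios[:, j] = col / top
    return _result("NSR", aligned, ratios.mean(axis=1))


@dataclass(frozen=True)
class TopKReport:
    """Per-program top-k sets with all subset intersections (Venn report)."""

    k: int
    top_sets: Mapping[str, frozenset[str]]
    intersections: Mapping[tuple[str, ...], frozenset[str]]
    active_counts: Mapping[tuple[str, ...], int] | None = None

    def sizes(self) -> dict[tuple[str, ...], int]:
        return {subset: len(mols) for subset, mols in self.intersections.items()}


def top_k_intersection(
    aligned: AlignedScores,
    k: int | None = None,
    benchmark: BenchmarkSet | None = None,
    config: ConsensusConfig | None = None,
) -> TopKReport:
    """Classical consensus: overlap of the programs' top-k molecule sets.

    Returns each program's k best-ranked molecules and the intersection over
    every subset of two or more programs, with active counts when labels are
    supplied — the numbers a Venn diagram of program agreement reports.
    """
    config = config or ConsensusConfig()
    if k is None:
        k = config.topk_k
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    _check(aligned)
    ranks = aligned.ranks()
    top_sets: dict[str, frozenset[str]] = {}
    mols = np.array(aligned.molecules)
    for j, pid in enumerate(aligned.programs):
        top_sets[pid] = frozenset(mols[ranks[:, j] <= k])
    intersections: dict[tuple[str, ...], frozenset[str]] = {}
    for size in range(1, aligned.n_programs + 1):
        for subset in combinations(aligned.programs, size):
            inter = frozenset.intersection(*(top_sets[p] for p in subset))
            intersections[subset] = inter
    active_counts = None
    if benchmark is not None:
        active_counts = {
            subset: sum(1 for m in mols_set if benchmark.is_active(m))
            for subset, mols_set in intersections.items()
        }
    return TopKReport(k=k, top_sets=top_sets, intersections=intersections, active_counts=active_counts)


CONSENSUS_METHODS: dict[str, Callable[[AlignedScores, ConsensusConfig | None], ConsensusResult]] = {
    "RBR": rank_by_rank,
    "RBN": rank_by_number,
    "RBV": rank_by_vote,
    "AASS": auto_scaled_score,
    "Z": z_score_consensus,
    "ECR": exponential_consensus_ranking,
    "NSR": normalized_score_ratio,
}


def combine(
    aligned: AlignedScores,
    methods: list[str] | None = None,
    config: ConsensusConfig | None = None,
) -> dict[str, ConsensusResult]:
    """Run the named consensus strategies (all seven by default)."""
    config = config or ConsensusConfig()
    if methods is None:
        methods = list(CONSENSUS_METHODS)
    results = {}
    for name in methods:
        key = name.strip().upper()
        if key not in CONSENSUS_METHODS:
            raise ValueError(f"unknown consensus method {name!r}; choose from {list(CONSENSUS_METHODS)}")
        results[key] = CONSENSUS_METHODS[key](aligned, config)
    return results
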