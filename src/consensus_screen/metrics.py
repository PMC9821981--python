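"""Screening-power metrics with bootstrap error estimation.

Every metric consumes a :class:`HitList`: the benchmark molecules ordered
best-first by one ranking method, together with their active/decoy labels.
Ties in the underlying scores are carried as average-tie rank values (used by
the tie-aware ROC-AUC estimator) while the list order itself resolves ties
deterministically by molecule ID.

Metrics
-------
- Confusion counts and rates (TPR, PRE, FPR, TNR) at a selection cutoff.
- Enrichment factor EF(chi) and the enrichment plot (EP): percentage of
  actives recovered versus percentage of the library screened.
- ROC curve and AUC: the probability that a random active outranks a random
  decoy, estimated by pair counting with half credit for ties (the rank-sum
  estimator), identical to the trapezoidal area of the tie-aware step curve.
- PR curve and AUC as average precision (no interpolation).
- RIE and BEDROC: exponentially weighted early-recognition statistics.
  RIE divides the actives' exponential rank weight by its closed-form
  expectation under uniformly random ranks; BEDROC min-max normalizes RIE
  between the inverted-ranking and perfect-ranking endpoints, so it lies in
  [0, 1] with 0.5 + epsilon meaning barely better than random.
- Bootstrap: the hit list is resampled with replacement B times (default
  1000) and each metric recomputed per resample, giving a mean, SD and
  95% percentile confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import stable_child_seed
from .benchmark import BenchmarkSet
from .consensus import ConsensusResult
from .score_io import RankTable, ScoreTable, to_ranks

__all__ = [
    "HitList",
    "make_hit_list",
    "ConfusionCounts",
    "RateSet",
    "MetricCurve",
    "confusion_at",
    "enrichment_factor",
    "enrichment_curve",
    "roc_curve_auc",
    "pr_curve_auc",
    "rie",
    "bedroc",
    "bootstrap_metric",
    "BootstrapSummary",
    "EvalConfig",
    "EvalReport",
    "evaluate_all",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 20.0
DEFAULT_BOOTSTRAP_SAMPLES = 1000


@dataclass(frozen=True)
class HitList:
    """A ranked, labeled screening hit list (best first).

    Attributes
    ----------
    ids:
        Molecule IDs best-first; ties resolved by ID so the order is
        deterministic.
    labels:
        Boolean array aligned with ``ids``; True = active.
    tie_ranks:
        Average-tie rank values aligned with ``ids`` (1 = best); equal values
        mark score ties, which the AUC estimator credits half.
    """

    ids: tuple[str, ...]
    labels: np.ndarray
    tie_ranks: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=bool)
        tie_ranks = np.asarray(self.tie_ranks, dtype=float)
        if not (len(self.ids) == labels.size == tie_ranks.size):
            raise ValueError("ids, labels and tie_ranks must have equal length")
        if labels.size == 0:
            raise ValueError("empty hit list")
        if np.any(np.diff(tie_ranks) < 0):
            raise ValueError("hit list must be ordered best-first (tie_ranks non-decreasing)")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "tie_ranks", tie_ranks)

    @property
    def N(self) -> int:
        return self.labels.size

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    @property
    def n_decoys(self) -> int:
        return self.N - self.n_actives

    def require_both_classes(self) -> None:
        if self.n_actives == 0 or self.n_decoys == 0:
            raise ValueError(
                f"metric needs both classes: {self.n_actives} actives, {self.n_decoys} decoys"
            )


def make_hit_list(
    source: "ConsensusResult | ScoreTable | RankTable | Mapping[str, float]",
    benchmark: BenchmarkSet,
) -> HitList:
    """Build a HitList for the benchmark molecules from a ranking source.

    Accepts a consensus result, a score table, a rank table, or a plain
    mapping molecule ID -> rank (lower = better).  The source must cover
    every benchmark molecule; extra molecules are ignored.  Ranks are
    recomputed on the benchmark subset so tie structure is preserved.
    """
    benchmark.require_both_classes()
    if isinstance(source, ScoreTable):
        oriented = source.oriented()
        rank_map = None
    elif isinstance(source, ConsensusResult):
        oriented = dict(source.score)
        rank_map = None
    elif isinstance(source, RankTable):
        oriented = None
        rank_map = dict(source.ranks)
    elif isinstance(source, Mapping):
        oriented = None
        rank_map = {str(m): float(r) for m, r in source.items()}
    else:
        raise TypeError(f"cannot build a hit list from {type(source).__name__}")

    ids = sorted(benchmark.labels)
    if oriented is not None:
        missing = [m for m in ids if m not in oriented]
        if missing:
            raise ValueError(f"ranking source missing {len(missing)} benchmark molecules, e.g. {missing[:5]}")
        values = np.array([oriented[m] for m in ids], dtype=float)
        tie_ranks = rankdata(-values, method="average")
    else:
        missing = [m for m in ids if m not in rank_map]
        if missing:
            raise ValueError(f"ranking source missing {len(missing)} benchmark molecules, e.g. {missing[:5]}")
        # re-rank on the subset so rank values stay in 1..N with average ties
        raw = np.array([rank_map[m] for m in ids], dtype=float)
        tie_ranks = rankdata(raw, method="average")

    order = np.lexsort((np.array(ids), tie_ranks))
    ids_sorted = tuple(ids[i] for i in order)
    labels = np.array([benchmark.is_active(m) for m in ids_sorted], dtype=bool)
    return HitList(ids=ids_sorted, labels=labels, tie_ranks=tie_ranks[order])


# ---------------------------------------------------------------------------
# confusion matrix and rates


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class RateSet:
    """TPR = TP/(TP+FN); PRE = TP/(TP+FP); FPR = FP/(FP+TN); TNR = TN/(TN+FP)."""

    TPR: float
    PRE: float
    FPR: float
    TNR: float


def _resolve_cutoff(N: int, fraction: float | None, count: int | None) -> int:
    if (fraction is None) == (count is None):
        raise ValueError("give exactly one of fraction= or count=")
    if fraction is not None:
        if not (0 < fraction <= 1):
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        return math.ceil(fraction * N)
    if not (1 <= count <= N):
        raise ValueError(f"count must be in 1..{N}, got {count}")
    return int(count)


def confusion_at(
    hits: HitList, fraction: float | None = None, count: int | None = None
) -> tuple[ConfusionCounts, RateSet]:
    """Confusion counts and rates when the top k = ceil(fraction*N) are selected."""
    hits.require_both_classes()
    k = _resolve_cutoff(hits.N, fraction, count)
    tp = int(hits.labels[:k].sum())
    fp = k - tp
    fn = hits.n_actives - tp
    tn = hits.n_decoys - fp
    counts = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    rates = RateSet(
        TPR=tp / (tp + fn),
        PRE=tp / (tp + fp) if (tp + fp) else 0.0,
        FPR=fp / (fp + tn),
        TNR=tn / (tn + fp),
    )
    return counts, rates


# ---------------------------------------------------------------------------
# enrichment


def _ef_ordered(labels: np.ndarray, fraction: float) -> float:
    N = labels.size
    n = int(labels.sum())
    k = math.ceil(fraction * N)
    a_k = int(labels[:k].sum())
    return (a_k / k) / (n / N)


def enrichment_factor(hits: HitList, fraction: float) -> float:
    """EF(chi) = (actives in top ceil(chi*N) / ceil(chi*N)) / (n/N).

    Bounded by 0 <= EF <= min(1/chi, N/n); EF(1) = 1 by construction.
    """
    hits.require_both_classes()
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return _ef_ordered(hits.labels, fraction)


@dataclass(frozen=True)
class MetricCurve:
    """An evaluation curve (ROC, PR or enrichment plot) plus its area."""

    kind: str
    points: np.ndarray  # (n_points, 2); x non-decreasing
    area: float

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if np.any(np.diff(points[:, 0]) < -1e-12):
            raise ValueError("curve x values must be non-decreasing")
        object.__setattr__(self, "points", points)

    def to_frame(self) -> pd.DataFrame:
        names = {"ROC": ("fpr", "tpr"), "PR": ("recall", "precision"), "EP": ("pct_screened", "pct_actives")}
        x, y = names.get(self.kind, ("x", "y"))
        return pd.DataFrame(self.points, columns=[x, y])


def default_ep_fractions(n_points: int = 30) -> np.ndarray:
    """Log-spaced screening fractions from 0.1% to 100% (semi-log EP grid)."""
    return np.geomspace(0.001, 1.0, n_points)


def enrichment_curve(hits: HitList, fractions: Sequence[float] | None = None) -> MetricCurve:
    """Enrichment plot: % of actives recovered vs % of library screened."""
    hits.require_both_classes()
    fracs = np.asarray(default_ep_fractions() if fractions is None else fractions, dtype=float)
    if np.any((fracs <= 0) | (fracs > 1)):
        raise ValueError("EP fractions must lie in (0, 1]")
    fracs = np.sort(fracs)
    cum_act = np.cumsum(hits.labels)
    ks = np.ceil(fracs * hits.N).astype(int)
    recovered = cum_act[ks - 1] / hits.n_actives
    points = np.column_stack([fracs * 100.0, recovered * 100.0])
    area = float(np.trapezoid(recovered, fracs))
    return MetricCurve(kind="EP", points=points, area=area)


# ---------------------------------------------------------------------------
# ROC


def _auc_from_tie_ranks(tie_ranks: np.ndarray, labels: np.ndarray) -> float:
    """Rank-sum AUC with half credit for ties.

    With ranks 1 = best, AUC = [n(N+1) - sum(active ranks) - n(n+1)/2] / (n*m):
    exactly the Mann-Whitney U statistic scaled to [0, 1].
    """
    n = int(labels.sum())
    m = labels.size - n
    s = float(tie_ranks[labels].sum())
    N = labels.size
    return (n * (N + 1) - s - n * (n + 1) / 2) / (n * m)


def roc_curve_auc(hits: HitList) -> MetricCurve:
    """Tie-aware ROC curve and its AUC.

    The curve steps once per distinct rank value (diagonal segments across tie
    groups); its trapezoidal area equals the pair-counting estimator used for
    the reported AUC.
    """
    hits.require_both_classes()
    n, m = hits.n_actives, hits.n_decoys
    # group by distinct tie-rank value, best first
    _, starts = np.unique(hits.tie_ranks, return_index=True)
    bounds = np.append(starts, hits.N)
    tpr = [0.0]
    fpr = [0.0]
    cum_tp = 0
    cum_fp = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = hits.labels[lo:hi]
        cum_tp += int(seg.sum())
        cum_fp += int(seg.size - seg.sum())
        tpr.append(cum_tp / n)
        fpr.append(cum_fp / m)
    points = np.column_stack([fpr, tpr])
    area = _auc_from_tie_ranks(hits.tie_ranks, hits.labels)
    return MetricCurve(kind="ROC", points=points, area=area)


# ---------------------------------------------------------------------------
# precision-recall


def _average_precision_ordered(labels: np.ndarray) -> float:
    n = int(labels.sum())
    positions = np.flatnonzero(labels) + 1
    precisions = np.arange(1, n + 1) / positions
    return float(precisions.sum() / n)


def pr_curve_auc(hits: HitList) -> MetricCurve:
    """Precision-recall curve; area = average precision (no interpolation).

    AP averages the precision observed at each active's position over the
    actives, i.e. precision integrated over equal recall increments of 1/n.
    """
    hits.require_both_classes()
    cum_act = np.cumsum(hits.labels)
    positions = np.arange(1, hits.N + 1)
    precision = cum_act / positions
    recall = cum_act / hits.n_actives
    points = np.column_stack([recall, precision])
    return MetricCurve(kind="PR", points=points, area=_average_precision_ordered(hits.labels))


# ---------------------------------------------------------------------------
# RIE / BEDROC


def _rie_denominator(n: int, N: int, alpha: float) -> float:
    """Expected exponential weight sum under uniformly random active ranks."""
    return (n / N) * (1 - math.exp(-alpha)) / (math.exp(alpha / N) - 1)


def _rie_ordered(labels: np.ndarray, alpha: float) -> float:
    N = labels.size
    n = int(labels.sum())
    positions = np.flatnonzero(labels) + 1  # resolved ranks 1..N
    numerator = float(np.exp(-alpha * positions / N).sum())
    return numerator / _rie_denominator(n, N, alpha)


def rie(hits: HitList, alpha: float = DEFAULT_ALPHA) -> float:
    """Robust initial enhancement at exponential weight ``alpha``.

    RIE = sum over actives of exp(-alpha * r_i / N), divided by the
    closed-form expectation of that sum under uniformly random ranks
    (n/N) * (1 - e^-alpha) / (e^(alpha/N) - 1).  A random ranking therefore
    scores ~1; larger alpha concentrates the weight on earlier ranks.  Uses
    the deterministically resolved list positions, so the normalization
    endpoints below are exact.
    """
    hits.require_both_classes()
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return _rie_ordered(hits.labels, alpha)


def _rie_bounds(n: int, N: int, alpha: float) -> tuple[float, float]:
    denom = _rie_denominator(n, N, alpha)
    best = float(np.exp(-alpha * np.arange(1, n + 1) / N).sum()) / denom
    worst = float(np.exp(-alpha * np.arange(N - n + 1, N + 1) / N).sum()) / denom
    return worst, best


def _bedroc_ordered(labels: np.ndarray, alpha: float) -> float:
    N = labels.size
    n = int(labels.sum())
    worst, best = _rie_bounds(n, N, alpha)
    return (_rie_ordered(labels, alpha) - worst) / (best - worst)


def bedroc(hits: HitList, alpha: float = DEFAULT_ALPHA) -> float:
    """BEDROC(alpha): RIE min-max normalized to [0, 1].

    0 corresponds to all actives ranked last, 1 to all actives ranked first.
    """
    hits.require_both_classes()
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return _bedroc_ordered(hits.labels, alpha)


# ---------------------------------------------------------------------------
# bootstrap

#: metric registry: name -> (callable on ordered labels, parameter names)
_ORDERED_METRICS: dict[str, Callable[..., float]] = {
    "roc_auc": lambda labels, tie_ranks=None, **kw: _auc_from_tie_ranks(
        np.arange(1, labels.size + 1, dtype=float) if tie_ranks is None else tie_ranks, labels
    ),
    "pr_auc": lambda labels, **kw: _average_precision_ordered(labels),
    "ef": lambda labels, fraction=0.01, **kw: _ef_ordered(labels, fraction),
    "rie": lambda labels, alpha=DEFAULT_ALPHA, **kw: _rie_ordered(labels, alpha),
    "bedroc": lambda labels, alpha=DEFAULT_ALPHA, **kw: _bedroc_ordered(labels, alpha),
}


@dataclass(frozen=True)
class BootstrapSummary:
    """Point value plus bootstrap mean/SD and 95% percentile CI."""

    point: float
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    B: int
    seed: int
    n_redraws: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("bootstrap sd must be >= 0")
        if not (self.ci_low - 1e-12 <= self.mean <= self.ci_high + 1e-12):
            raise ValueError("bootstrap CI must contain the bootstrap mean")


def _point_metric(hits: HitList, name: str, params: Mapping[str, float]) -> float:
    if name == "roc_auc":
        return _auc_from_tie_ranks(hits.tie_ranks, hits.labels)
    return _ORDERED_METRICS[name](hits.labels, **params)


def _bootstrap_many(
    hits: HitList,
    metrics: Mapping[str, tuple[str, Mapping[str, float]]],
    B: int,
    seed: int,
    max_redraws: int = 100,
) -> dict[str, BootstrapSummary]:
    """Resample the hit list B times; recompute every requested metric per resample.

    A resample that loses an entire class is redrawn (at most ``max_redraws``
    consecutive redraws, then a hard error); redraw events are logged.  Ties in
    a resample are re-ranked by original position, so resampled metrics use
    plain 1..N ranks.
    """
    hits.require_both_classes()
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(seed)
    N = hits.N
    values: dict[str, np.ndarray] = {key: np.empty(B) for key in metrics}
    total_redraws = 0
    for b in range(B):
        redraws = 0
        while True:
            idx = np.sort(rng.integers(0, N, size=N))
            labels = hits.labels[idx]
            if 0 < labels.sum() < N:
                break
            redraws += 1
            total_redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    f"bootstrap: {max_redraws} consecutive degenerate resamples; "
                    "class balance too extreme"
                )
        for key, (name, params) in metrics.items():
            values[key][b] = _ORDERED_METRICS[name](labels, **params)
    if total_redraws:
        logger.info("bootstrap: redrew %d degenerate resamples", total_redraws)
    out = {}
    for key, (name, params) in metrics.items():
        vals = values[key]
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[key] = BootstrapSummary(
            point=_point_metric(hits, name, params),
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if B > 1 else 0.0,
            ci_low=float(lo),
            ci_high=float(hi),
            B=B,
            seed=seed,
            n_redraws=total_redraws,
        )
    return out


def bootstrap_metric(
    hits: HitList,
    metric: str,
    B: int = DEFAULT_BOOTSTRAP_SAMPLES,
    seed: int = 0,
    **params: float,
) -> BootstrapSummary:
    """Bootstrap one named metric (``roc_auc``, ``pr_auc``, ``ef``, ``rie``, ``bedroc``).

    Deterministic for a fixed seed.  Metric parameters (``fraction`` for EF,
    ``alpha`` for RIE/BEDROC) are passed as keyword arguments.
    """
    if metric not in _ORDERED_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_ORDERED_METRICS)}")
    return _bootstrap_many(hits, {metric: (metric, params)}, B=B, seed=seed)[metric]


# ---------------------------------------------------------------------------
# full evaluation


@dataclass(frozen=True)
class EvalConfig:
    """Metric-suite parameters: EF fractions, alpha, bootstrap size, seed."""

    ef_fractions: tuple[float, ...] = (0.01, 0.10)
    alpha: float = DEFAULT_ALPHA
    bootstrap_samples: int = DEFAULT_BOOTSTRAP_SAMPLES
    seed: int = 0
    ep_fractions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if any(not (0 < f <= 1) for f in self.ef_fractions):
            raise ValueError("EF fractions must lie in (0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.bootstrap_samples < 1:
            raise ValueError("bootstrap_samples must be >= 1")


@dataclass(frozen=True)
class EvalReport:
    """Long-format metric table plus curves for every evaluated method."""

    table: pd.DataFrame  # columns: method, metric, value, boot_mean, boot_sd, ci_low, ci_high
    curves: Mapping[tuple[str, str], MetricCurve]
    config: EvalConfig

    def value(self, method: str, metric: str) -> float:
        sel = self.table[(self.table["method"] == method) & (self.table["metric"] == metric)]
        if sel.empty:
            raise KeyError(f"no entry for method={method!r}, metric={metric!r}")
        return float(sel["value"].iloc[0])


def evaluate_all(
    sources: Mapping[str, "ConsensusResult | ScoreTable | RankTable | HitList"],
    benchmark: BenchmarkSet,
    config: EvalConfig | None = None,
) -> EvalReport:
    """Evaluate every ranking source (programs and consensus methods) at once.

    For each source the report holds EF at the configured fractions, ROC-AUC,
    PR-AUC, RIE and BEDROC, each with bootstrap mean/SD/95% CI, plus ROC, PR
    and enrichment-plot curves.  Bootstrap streams are derived per source from
    the master seed, so results do not depend on mapping order.
    """
    config = config or EvalConfig()
    if not sources:
        raise ValueError("no ranking sources to evaluate")
    metric_plan: dict[str, tuple[str, dict[str, float]]] = {}
    for frac in config.ef_fractions:
        metric_plan[f"EF{frac * 100:g}%"] = ("ef", {"fraction": frac})
    metric_plan["ROC-AUC"] = ("roc_auc", {})
    metric_plan["PR-AUC"] = ("pr_auc", {})
    metric_plan[f"RIE({config.alpha:g})"] = ("rie", {"alpha": config.alpha})
    metric_plan[f"BEDROC({config.alpha:g})"] = ("bedroc", {"alpha": config.alpha})

    rows = []
    curves: dict[tuple[str, str], MetricCurve] = {}
    for name in sources:
        hits = sources[name] if isinstance(sources[name], HitList) else make_hit_list(sources[name], benchmark)
        child_seed = stable_child_seed(config.seed, "bootstrap", name)
        summaries = _bootstrap_many(hits, metric_plan, B=config.bootstrap_samples, seed=child_seed)
        for metric_name, summary in summaries.items():
            rows.append(
                {
                    "method": name,
                    "metric": metric_name,
                    "value": summary.point,
                    "boot_mean": summary.mean,
                    "boot_sd": summary.sd,
                    "ci_low": summary.ci_low,
                    "ci_high": summary.ci_high,
                }
            )
        curves[(name, "ROC")] = roc_curve_auc(hits)
        curves[(name, "PR")] = pr_curve_auc(hits)
        curves[(name, "EP")] = enrichment_curve(hits, config.ep_fractions)
    table = pd.DataFrame(rows).sort_values(["method", "metric"], kind="stable").reset_index(drop=True)
    return EvalReport(table=table, curves=curves, config=config)
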