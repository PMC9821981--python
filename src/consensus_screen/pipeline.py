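"""End-to-end workflow: simulate/ingest -> align -> combine -> evaluate -> report.

`run_pipeline` executes the post-docking portion of a virtual-screening
campaign from a single declarative configuration and writes a reproducible
report directory: one consensus score table per method, a long-format metric
report, curve tables, and a JSON manifest echoing the configuration, seed and
per-stage row counts.  Identical configurations with identical seeds produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import __version__
from .benchmark import (
    AlignedScores,
    BenchmarkSet,
    align_programs,
    read_label_table,
    write_label_table,
)
from .consensus import CONSENSUS_METHODS, ConsensusConfig, ConsensusResult, combine
from .metrics import EvalConfig, EvalReport, evaluate_all, make_hit_list
from .score_io import Orientation, ScoreTable, read_score_table, write_score_table
from .synthetic import ProgramSpec, SimConfig, simulate_scores, trpv1_preset

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_run_config"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of one pipeline run.

    Exactly one of ``simulate`` (a SimConfig) or ``tables`` (paths of
    per-program score tables plus a ``labels`` path) must be given.
    """

    out_dir: str | Path
    simulate: SimConfig | None = None
    tables: tuple[Mapping[str, str], ...] = ()
    labels: str | Path | None = None
    missing_policy: str = "penalize"
    methods: tuple[str, ...] = tuple(CONSENSUS_METHODS)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    metrics: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (not self.tables):
            raise ValueError("give exactly one of 'simulate' or 'tables'")
        if self.tables and self.labels is None:
            raise ValueError("'tables' input requires a 'labels' path")
        object.__setattr__(self, "methods", tuple(m.strip().upper() for m in self.methods))
        object.__setattr__(self, "tables", tuple(self.tables))


def _sim_config_from_mapping(raw: Mapping[str, Any]) -> SimConfig:
    raw = dict(raw)
    preset = raw.pop("preset", None)
    if preset is not None:
        if preset != "trpv1":
            raise ValueError(f"unknown preset {preset!r}; available: trpv1")
        base = trpv1_preset(
            seed=int(raw.pop("seed", 0)),
            n_actives=int(raw.pop("n_actives", 212)),
            decoys_per_active=int(raw.pop("decoys_per_active", 50)),
        )
        if raw:
            raise ValueError(f"unknown simulate keys with preset: {sorted(raw)}")
        return base
    programs = tuple(ProgramSpec(**p) for p in raw.pop("programs"))
    return SimConfig(programs=programs, **raw)


def load_run_config(mapping: Mapping[str, Any], out_dir: str | Path | None = None) -> RunConfig:
    """Build a RunConfig from a plain mapping (parsed YAML/JSON)."""
    raw = dict(mapping)
    sim = raw.pop("simulate", None)
    return RunConfig(
        out_dir=out_dir or raw.pop("out_dir", "."),
        simulate=_sim_config_from_mapping(sim) if sim is not None else None,
        tables=tuple(raw.pop("tables", ()) or ()),
        labels=raw.pop("labels", None),
        missing_policy=raw.pop("missing_policy", "penalize"),
        methods=tuple(raw.pop("methods", tuple(CONSENSUS_METHODS))),
        consensus=ConsensusConfig(**raw.pop("consensus", {})),
        metrics=EvalConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.pop("metrics", {}).items()}),
    )


def _ingest(config: RunConfig) -> tuple[list[ScoreTable], BenchmarkSet]:
    if config.simulate is not None:
        sim = simulate_scores(config.simulate)
        return list(sim.tables), sim.benchmark
    tables = []
    for entry in config.tables:
        path = Path(entry["path"])
        if not path.exists():
            raise FileNotFoundError(f"score table not found: {path}")
        tables.append(
            read_score_table(
                path,
                program_id=entry.get("program_id"),
                orientation=entry.get("orientation"),
            )
        )
    labels_path = Path(config.labels)
    if not labels_path.exists():
        raise FileNotFoundError(f"label table not found: {labels_path}")
    return tables, read_label_table(labels_path)


def _consensus_to_table(result: ConsensusResult) -> ScoreTable:
    return ScoreTable(result.method, Orientation.HIGHER_BETTER, dict(result.score))


def _config_echo(config: RunConfig) -> dict:
    echo: dict[str, Any] = {
        "out_dir": str(config.out_dir),
        "missing_policy": config.missing_policy,
        "methods": list(config.methods),
        "consensus": asdict(config.consensus),
        "metrics": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config.metrics).items()
        },
        "labels": None if config.labels is None else str(config.labels),
        "tables": [dict(t) for t in config.tables],
    }
    if config.simulate is not None:
        sim = asdict(config.simulate)
        sim["programs"] = [
            {**p, "orientation": p["orientation"].value if isinstance(p["orientation"], Orientation) else p["orientation"]}
            for p in sim["programs"]
        ]
        echo["simulate"] = sim
    return echo


def run_pipeline(config: RunConfig) -> EvalReport:
    """Run the full workflow and write report artifacts to ``config.out_dir``.

    Stages: ingest/simulate -> align -> consensus combination -> metric
    evaluation (individual programs and consensus methods side by side) ->
    report/manifest writing.  Any stage failure raises :class:`PipelineError`
    naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    try:
        tables, benchmark = _ingest(config)
    except Exception as exc:
        raise PipelineError("ingest", str(exc)) from exc
    counts["programs"] = len(tables)
    counts["molecules"] = benchmark.N
    counts["actives"] = benchmark.n_actives

    try:
        aligned = align_programs(tables, benchmark, missing_policy=config.missing_policy)
    except Exception as exc:
        raise PipelineError("align", str(exc)) from exc
    counts["aligned_molecules"] = aligned.n_molecules
    counts["penalized_cells"] = int(sum(aligned.missing_counts.values()))

    try:
        results = combine(aligned, list(config.methods), config.consensus)
    except Exception as exc:
        raise PipelineError("consensus", str(exc)) from exc

    try:
        sources: dict[str, Any] = {pid: t for pid, t in zip(aligned.programs, tables)}
        sources.update(results)
        # hit lists built against the aligned benchmark (intersect may shrink it)
        hit_sources = {
            name: make_hit_list(
                src if not isinstance(src, ScoreTable) else _restrict(src, aligned),
                aligned.benchmark,
            )
            for name, src in sources.items()
        }
        report = evaluate_all(hit_sources, aligned.benchmark, config.metrics)
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc
    counts["report_rows"] = len(report.table)

    try:
        _write_artifacts(out_dir, config, benchmark, results, report, counts)
    except Exception as exc:
        raise PipelineError("report", str(exc)) from exc
    return report


def _restrict(table: ScoreTable, aligned: AlignedScores) -> ScoreTable:
    """Project a program table onto the aligned molecule set (penalized cells included)."""
    j = aligned.programs.index(table.program_id)
    return ScoreTable(
        table.program_id,
        Orientation.HIGHER_BETTER,
        dict(zip(aligned.molecules, aligned.matrix[:, j])),
    )


def _write_artifacts(
    out_dir: Path,
    config: RunConfig,
    benchmark: BenchmarkSet,
    results: Mapping[str, ConsensusResult],
    report: EvalReport,
    counts: Mapping[str, int],
) -> None:
    for method, result in results.items():
        write_score_table(_consensus_to_table(result), out_dir / f"consensus_{method}.csv")
    write_label_table(benchmark, out_dir / "labels.csv")
    report.table.to_csv(out_dir / "report.csv", index=False)
    curves_dir = out_dir / "curves"
    curves_dir.mkdir(exist_ok=True)
    for (name, kind), curve in report.curves.items():
        curve.to_frame().to_csv(curves_dir / f"{name}_{kind}.csv", index=False)
    manifest = {
        "package": "consensus-screen",
        "version": __version__,
        "seed": report.config.seed,
        "bootstrap_samples": report.config.bootstrap_samples,
        "stage_counts": dict(counts),
        "config": _config_echo(config),
    }
    with (out_dir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
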