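"""Orchestration: simulate -> extract -> correlate -> discover -> mediate -> report."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from cardioresp import __version__
from cardioresp import io as crio
from cardioresp.association import correlation_matrix, position_tests
from cardioresp.discovery import (
    DERIVED_PAIR_MASK,
    cam_learn,
    consensus,
    gc_graph,
    ges_learn,
    hc_learn,
    tabu_learn,
)
from cardioresp.mediation import STANDARD_PATHS, mediate_standard_paths
from cardioresp.parameters import ExtractionLog, extract_table
from cardioresp.synthetic import SignalScenario, generate_signals
from cardioresp.types import ParameterTable, SignalRecord

__all__ = ["RunConfig", "RunReport", "run_pipeline", "render_report", "METHODS"]

METHODS = ("gc", "hc", "tabu", "ges", "cam")


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Either ``signal_records`` (in-memory) / ``signal_dir`` (CSV+YAML pairs)
    feed the extraction stage, or ``parameter_csv`` skips straight to the
    statistics.  Thresholds default to the analysis conventions: MPE 0.9,
    alpha 0.05, CAM pruning alpha 0.001.
    """

    out_dir: Path
    signal_records: list = field(default_factory=list)
    signal_dir: Path | None = None
    parameter_csv: Path | None = None
    positions: tuple = ("supine", "standing")
    methods: tuple = METHODS
    seed: int = 0
    mask_derived: bool = True
    mpe_threshold: float = 0.9
    alpha: float = 0.05
    prune_alpha: float = 0.001
    min_support: float = 3.0
    mediation_paths: tuple = STANDARD_PATHS

    def validate(self) -> None:
        for thr in (self.mpe_threshold, self.alpha, self.prune_alpha):
            if not 0 < thr < 1:
                raise ValueError("thresholds must lie in (0, 1)")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown method name(s): {unknown}; known: {METHODS}")
        for p in (self.signal_dir, self.parameter_csv):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        if not (self.signal_records or self.signal_dir or self.parameter_csv):
            raise ValueError("no input: provide signals or a parameter CSV")


@dataclass
class RunReport:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)   # stage -> record counts etc.
    exclusions: list = field(default_factory=list)
    artifacts: list = field(default_factory=list)
    consensus_summaries: dict = field(default_factory=dict)
    mediation_summaries: list = field(default_factory=list)
    position_test_summaries: list = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "config": {k: str(v) if isinstance(v, Path) else v
                       for k, v in self.config.items() if k != "signal_records"},
            "stages": self.stages,
            "exclusions": self.exclusions,
            "artifacts": [str(a) for a in self.artifacts],
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


def _load_records(config: RunConfig) -> list[SignalRecord]:
    records = list(config.signal_records)
    if config.signal_dir is not None:
        for csv_path in sorted(Path(config.signal_dir).glob("*.csv")):
            records.append(crio.read_signal_record(csv_path.with_suffix("")))
    return records


def _learn(method: str, table: ParameterTable, config: RunConfig):
    mask = DERIVED_PAIR_MASK if config.mask_derived else None
    if method == "gc":
        return gc_graph(table, mask=mask, alpha=config.alpha, seed=config.seed,
                        mpe_threshold=config.mpe_threshold)
    if method == "hc":
        return hc_learn(table, mask=mask, seed=config.seed)
    if method == "tabu":
        return tabu_learn(table, mask=mask, seed=config.seed)
    if method == "ges":
        return ges_learn(table, mask=mask)
    if method == "cam":
        return cam_learn(table, prune_alpha=config.prune_alpha, mask=mask)
    raise ValueError(f"unknown method {method!r}")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages; every artifact lands under out_dir.

    The supine and standing analyses are fully independent; the orthostatic
    change itself is reported descriptively through the paired tests.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))

    # ---- extract -------------------------------------------------------
    tables: dict = {}
    if config.parameter_csv is not None:
        for position in config.positions:
            tables[position] = crio.read_parameter_table(
                config.parameter_csv, position=position
            )
            report.stages[f"load[{position}]"] = tables[position].n_subjects
    else:
        records = _load_records(config)
        report.stages["input_records"] = len(records)
        for position in config.positions:
            log = ExtractionLog()
            subset = [r for r in records if r.position == position]
            if not subset:
                continue
            table = extract_table(subset, position=position, log=log)
            tables[position] = table
            report.stages[f"extract[{position}]"] = table.n_subjects
            report.exclusions.extend(
                {"subject_id": s, "position": p, "stage": st, "reason": m}
                for s, p, st, m in log.excluded
            )
            path = crio.write_parameter_table(table, out / f"params_{position}.csv")
            report.artifacts.append(path)
    if not tables:
        raise ValueError("no parameter tables produced")

    # ---- correlate -----------------------------------------------------
    corr = {pos: correlation_matrix(t, mpe_threshold=config.mpe_threshold)
            for pos, t in tables.items()}
    matrix_path, long_path = crio.write_correlation_report(
        corr.get("supine") or next(iter(corr.values())),
        corr.get("standing"),
        out / "correlations",
    )
    report.artifacts += [matrix_path, long_path]
    for pos, res in corr.items():
        report.stages[f"correlate[{pos}]"] = len(res.significant_pairs())

    if len(tables) == 2 and set(tables) == {"supine", "standing"}:
        tests = position_tests(tables["supine"], tables["standing"], alpha=config.alpha)
        report.position_test_summaries = [t.summary() for t in tests]

    # ---- discover ------------------------------------------------------
    for position, table in tables.items():
        graphs = []
        for method in config.methods:
            graph = _learn(method, table, config)
            graphs.append(graph)
            stem = out / f"graph_{position}_{method}"
            report.artifacts += list(crio.write_graph(graph, stem))
            report.stages[f"discover[{position},{method}]"] = len(graph.edges)
        cons = consensus(graphs, min_support=config.min_support)
        report.consensus_summaries[position] = cons.summary()
        edge_path = crio.write_edge_list(
            graphs, out / f"edges_{position}.csv", support=cons.support
        )
        report.artifacts.append(edge_path)

    # ---- mediate -------------------------------------------------------
    if set(tables) >= {"supine", "standing"}:
        results = mediate_standard_paths(
            tables["supine"], tables["standing"], paths=config.mediation_paths
        )
        report.mediation_summaries = [r.summary() for r in results]
        import pandas as pd

        med_path = out / "mediation.csv"
        pd.DataFrame([{
            "path": f"{r.x_name} -> {r.m_name} -> {r.y_name}",
            "position": r.position,
            "a": r.a, "b": r.b, "c_prime": r.c_prime,
            "indirect": r.indirect, "sobel_z": r.sobel_z, "sobel_p": r.sobel_p,
        } for r in results]).to_csv(med_path, index=False, float_format="%.6g")
        report.artifacts.append(med_path)

    (out / "run_report.json").write_text(report.to_json())
    report.artifacts.append(out / "run_report.json")
    return report


def render_report(report: RunReport) -> str:
    """Human-readable run summary (plain text; plotting is optional elsewhere)."""
    lines = [f"cardioresp v{report.version} run report", "=" * 40]
    lines.append("Stages:")
    for stage, count in report.stages.items():
        lines.append(f"  {stage}: {count}")
    lines.append(f"Exclusions: {len(report.exclusions)}")
    for exc in report.exclusions:
        lines.append(f"  {exc['subject_id']} [{exc['position']}] "
                     f"failed {exc['stage']}: {exc['reason']}")
    if report.position_test_summaries:
        lines.append("Position tests:")
        lines += ["  " + s for s in report.position_test_summaries]
    for position, summary in report.consensus_summaries.items():
        lines.append(f"--- {position} ---")
        lines.append(summary)
    if report.mediation_summaries:
        lines.append("Mediation:")
        lines += ["  " + s for s in report.mediation_summaries]
    else:
        lines.append("Mediation: not run (both positions required)")
    if not report.consensus_summaries:
        lines.append("Graphs: no edges discovered")
    return "\n".join(lines)


def simulate_cohort(
    n_subjects: int,
    seed: int = 0,
    duration_s: float = 180.0,
    scenario_overrides: dict | None = None,
) -> list[SignalRecord]:
    """Generate a synthetic cohort: one supine and one standing record each.

    Standing physiology shifts the generator defaults the way an orthostatic
    challenge does: higher heart rate, lower RMSSD, slightly faster and more
    variable breathing.
    """
    records = []
    overrides = scenario_overrides or {}
    for i in range(n_subjects):
        base_seed = seed * 10007 + i * 211
        for position, adjust in (
            ("supine", {}),
            ("standing", {"mean_hr": 78.0, "rmssd_target": 32.0,
                          "resp_rate": 16.0, "cv_breath_duration": 0.14,
                          "cv_breath_amplitude": 0.20}),
        ):
            params = dict(duration_s=duration_s, seed=base_seed + (0 if position == "supine" else 1))
            params.update(adjust)
            params.update(overrides)
            record, _ = generate_signals(SignalScenario(**params))
            record.subject_id = f"S{i:03d}"
            record.position = position
            records.append(record)
    return records
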