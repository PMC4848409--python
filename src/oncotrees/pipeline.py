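"""End-to-end analysis: frequencies -> both trees -> bootstrap -> consensus,
written as a deterministic report bundle."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .bootstrap import bootstrap, consensus_report, frequent_trees_text
from .branching import fit_branching_tree
from .data import (
    BinaryAlterationMatrix,
    estimate_probabilities,
    frequency_summary,
    read_matrix,
)
from .distance import fit_distance_tree
from .exceptions import UserInputError

log = logging.getLogger("oncotrees")


@dataclass(frozen=True)
class RunConfig:
    input_path: str
    out_dir: str
    dialect: str = "binary_tsv"
    genes: tuple[str, ...] = ()  # empty = all columns
    methods: tuple[str, ...] = ("branching", "distance")
    bootstrap_B: int = 1000
    seed: int = 0
    consensus_threshold: float = 0.10
    clamp_floor: float | None = None
    call_threshold: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.consensus_threshold < 1.0):
            raise UserInputError("consensus threshold must be in [0, 1)")
        bad = [m for m in self.methods if m not in ("branching", "distance")]
        if bad:
            raise UserInputError(f"unknown method(s): {bad}")


def _load_panel(config: RunConfig) -> BinaryAlterationMatrix:
    path = Path(config.input_path)
    if not path.exists():
        raise UserInputError(f"input file not found: {path}")
    matrix = read_matrix(path, dialect=config.dialect,
                         call_threshold=config.call_threshold)
    if config.genes:
        missing = [g for g in config.genes if g not in matrix.event_names]
        if missing:
            raise UserInputError(
                f"panel gene(s) not in input header: {', '.join(missing)}"
            )
        matrix = matrix.select_events(list(config.genes))
    return matrix


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_analysis(config: RunConfig) -> dict:
    """Run the full workflow and write the report bundle.

    Returns a dict of artifact name -> path.  All JSON outputs are
    byte-identical across reruns of the same config; timestamps live only in
    the logging stream.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = _load_panel(config)
    floor = config.clamp_floor
    artifacts: dict[str, str] = {}
    log.info(
        "run: n=%d k=%d seed=%d clamp_floor=%s version=%s python=%s",
        matrix.n, matrix.k, config.seed,
        floor if floor is not None else f"1/(2n)={1 / (2 * matrix.n):g}",
        __version__, platform.python_version(),
    )

    summary = frequency_summary(matrix)
    _dump(summary.to_dict(), out / "frequencies.json")
    artifacts["frequencies"] = str(out / "frequencies.json")

    report = ["# Oncogenetic tree report", ""]
    report += ["## Alteration frequencies", ""]
    report += [f"n = {matrix.n} samples, {matrix.k} events", ""]
    report += ["| event | count | percent |", "|---|---|---|"]
    for e in matrix.event_names:
        report.append(f"| {e} | {summary.counts[e]} | {summary.percents[e]}% |")
    report.append(
        f"| any | {summary.any_count} | {summary.any_percent}% |"
    )
    report.append("")

    freq = estimate_probabilities(matrix, floor=floor)
    if "branching" in config.methods:
        btree = fit_branching_tree(matrix, floor=floor)
        _dump(btree.to_json_dict(), out / "branching.json")
        (out / "branching.dot").write_text(btree.to_dot())
        artifacts["branching"] = str(out / "branching.json")
        report += ["## Branching tree", "", "```", btree.to_dot().rstrip(), "```", ""]
    if "distance" in config.methods:
        dtree = fit_distance_tree(matrix, floor=floor)
        _dump(dtree.to_json_dict(), out / "distance.json")
        (out / "distance.nwk").write_text(dtree.to_newick() + "\n")
        artifacts["distance"] = str(out / "distance.json")
        report += ["## Distance tree", "", "```", dtree.to_newick(), "```", ""]

    for method in config.methods:
        res = bootstrap(matrix, method, config.bootstrap_B, config.seed,
                        floor=floor)
        res.save(out / f"bootstrap_{method}.json")
        cons = consensus_report(res, config.consensus_threshold)
        (out / f"consensus_{method}.txt").write_text(cons.to_text())
        (out / f"frequent_trees_{method}.txt").write_text(
            frequent_trees_text(res)
        )
        artifacts[f"bootstrap_{method}"] = str(out / f"bootstrap_{method}.json")
        top = sorted(res.topology_counts.items(), key=lambda t: (-t[1], t[0]))[:5]
        report += [f"## Bootstrap ({method}, B={res.B}, seed={res.seed})", ""]
        report += ["| count | topology |", "|---|---|"]
        for topo, cnt in top:
            report.append(f"| {cnt} | `{topo}` |")
        report += [
            "",
            f"Splits with support > {config.consensus_threshold:g}: "
            + (", ".join(f"`{s}` ({sup:.2f})" for s, sup in cons.splits)
               or "none"),
            "",
        ]
    report += [
        "## Parameters",
        "",
        f"- seed: {config.seed}",
        f"- clamp floor: {freq.pseudo_floor:g}",
        f"- bootstrap replicates: {config.bootstrap_B}",
        "",
    ]
    (out / "report.md").write_text("\n".join(report))
    artifacts["report"] = str(out / "report.md")
    return artifacts
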