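"""High-level analysis requests: the library face of the command line.

An :class:`AnalysisRequest` bundles a parsed model with the analysis
choices (simulation vs. algebraic algorithm, limit-cycle length, update
scheme, optional initial state) and :func:`run_analysis` dispatches to the
appropriate operations, always including the functional wiring diagram in
the report.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .conjunctive import conjunctive_attractors, detect_class
from .conversion import Schedule, sequential_compose
from .modelio import (
    REPORT_SCHEMA_VERSION,
    cycle_set_report,
    dot_phase_space,
    dot_trajectory,
    dot_wiring_diagram,
)
from .pds import PDS, state_to_string
from .probabilistic import (
    ProbabilisticPDS,
    probabilistic_transition_graph,
    true_steady_states,
)
from .solver import (
    EXHAUSTIVE_THRESHOLD,
    attractors_from_phase_space,
    build_phase_space,
    limit_cycles,
    trajectory,
)
from .structure import functional_circuits, functional_wiring_diagram

__all__ = ["AnalysisRequest", "run_analysis"]


@dataclass
class AnalysisRequest:
    """One analysis run over an in-memory model."""

    system: object  # PDS or ProbabilisticPDS
    mode: str = "algorithm"  # "algorithm" | "simulation"
    cycle_length: int = 1
    schedule: Schedule | None = None  # sequential sweep order, else synchronous
    initial_state: tuple | None = None
    threshold: int = EXHAUSTIVE_THRESHOLD
    fast_path: bool = True  # use the conjunctive shortcut when it applies

    def __post_init__(self):
        if self.mode not in ("algorithm", "simulation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.cycle_length < 1:
            raise ValueError("cycle length must be >= 1")


def _effective_system(req: AnalysisRequest) -> PDS:
    system = req.system
    if req.schedule is not None:
        system = sequential_compose(system, req.schedule)
    return system


def run_analysis(req: AnalysisRequest) -> dict:
    """Execute the request; returns a JSON-ready report dictionary.

    The report always contains the functional wiring diagram (DOT text and
    an edge list); the rest depends on the request: attractor sets from the
    algebraic solver or from exhaustive simulation, a trajectory when an
    initial state is given, the all-transitions graph for probabilistic
    systems, and the structure-based summary for conjunctive networks.
    """
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION}
    if isinstance(req.system, ProbabilisticPDS):
        return _run_probabilistic(req, report)

    system = _effective_system(req)
    report["n"] = system.nvars
    report["p"] = system.field.p
    report["update"] = (
        "synchronous"
        if req.schedule is None
        else {"sequential_schedule": list(req.schedule.ordering)}
    )

    wd = functional_wiring_diagram(system)
    report["wiring_diagram"] = {
        "edges": [
            {"from": u, "to": v, **({"sign": d["sign"]} if "sign" in d else {})}
            for u, v, d in sorted(wd.edges(data=True))
        ],
        "dot": dot_wiring_diagram(wd),
    }
    if system.field.p == 2:
        circuits = functional_circuits(system)
        report["functional_circuits"] = [
            {
                "nodes": list(c.nodes),
                "sign": c.sign,
                "positive": c.positive,
            }
            for c in circuits
        ]

    if req.initial_state is not None:
        traj = trajectory(system, req.initial_state)
        report["trajectory"] = {
            "states": [state_to_string(s) for s in traj.states],
            "transient_length": len(traj.transient),
            "period": traj.period,
            "dot": dot_trajectory(traj),
        }

    if req.mode == "simulation":
        graph = build_phase_space(system, threshold=req.threshold)
        cs = attractors_from_phase_space(graph)
        report["attractors"] = cycle_set_report(cs)
        comps = [len(c) for c in nx.weakly_connected_components(graph)]
        report["phase_space"] = {
            "components": len(comps),
            "component_sizes": sorted(comps, reverse=True),
            "dot": dot_phase_space(graph),
        }
        return report

    # algebraic mode
    if req.fast_path and system.field.p == 2:
        cls = detect_class(system)
        if cls != "neither":
            if wd.number_of_edges() > 0 and nx.is_strongly_connected(wd):
                summary = conjunctive_attractors(system)
                report["conjunctive_fast_path"] = {
                    "class": summary.network_class,
                    "loop_number": summary.loop_number,
                    "admissible_periods": list(summary.admissible_periods or ()),
                    "steady_states": [
                        state_to_string(s) for s in summary.steady_states
                    ],
                    "provenance": "fast-path",
                }
    cs = limit_cycles(system, req.cycle_length)
    report["attractors"] = cycle_set_report(cs)
    return report


def _run_probabilistic(req: AnalysisRequest, report: dict) -> dict:
    pp: ProbabilisticPDS = req.system
    report["n"] = pp.nvars
    report["p"] = pp.field.p
    report["probabilistic"] = True
    report["true_steady_states"] = [
        state_to_string(s) for s in true_steady_states(pp)
    ]
    if req.mode == "simulation":
        graph = probabilistic_transition_graph(pp, threshold=req.threshold)
        report["phase_space"] = {
            "dot": dot_phase_space(graph, weighted=True),
        }
    return report
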