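"""Single-bead micro-occlusion scenarios.

A 25 um bead entering the penetrating arteriole travels with the flow and
lodges at the inlet of the first vessel it reaches whose diameter is below
the bead size.  Every distinct first-trap segment reachable from the column
inlet through supra-threshold, flow-directed segments is one equally
probable blockage scenario; the trapped segment's conductance is set to
zero and flow plus oxygen are re-solved at the unchanged healthy inlet
pressure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .column import BEAD_DIAMETER
from .flow import FlowSolution, HemoParams, calibrate_perfusion, solve_flow
from .graph import VesselGraph
from .oxygen import (ConvergenceError, GreensSolver, OxygenSolution, OxyParams,
                     TissueGrid, hypoxia_mask)


@dataclass
class BlockageScenario:
    """One trapped-bead state of a column."""

    site_segment: int
    bead_xyz: np.ndarray  # um; the trapped segment's upstream node
    path_segments: tuple  # flow-directed supra-threshold path from the inlet
    flow: FlowSolution | None = None
    oxygen: OxygenSolution | None = None
    perfusion_drop: float | None = None  # 1 - Q_blocked / Q_healthy
    hypoxia: np.ndarray | None = None  # boolean voxel mask
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def enumerate_trapping_sites(
    graph: VesselGraph,
    flow: FlowSolution,
    bead_diameter_um: float = BEAD_DIAMETER,
) -> list[BlockageScenario]:
    """All distinct first-trap segments, in canonical (segment id) order.

    A segment s is a trapping site iff diameter(s) < bead and there is a
    flow-directed path from the inlet to s's upstream node using only
    segments with diameter >= bead.  Capillaries and connectors never trap
    (the bead arrives through the arteriole tree).
    """
    if graph.inlet is None:
        raise ValueError("graph has no inlet")
    adj = graph.adjacency()
    q_eps = 1e-9 * max(1.0, float(np.abs(flow.flows).max()))
    sites: dict[int, tuple] = {}
    seen_nodes = set()
    stack: list[tuple[int, tuple]] = [(graph.inlet, ())]
    while stack:
        u, path = stack.pop()
        if u in seen_nodes:
            continue
        seen_nodes.add(u)
        for s_ix, v in adj[u]:
            a, b = graph.seg_nodes[s_ix]
            downstream = (flow.flows[s_ix] > q_eps and u == a) or (
                flow.flows[s_ix] < -q_eps and u == b
            )
            if not downstream:
                continue
            if graph.diameters[s_ix] >= bead_diameter_um:
                stack.append((v, path + (s_ix,)))
            elif graph.kinds[s_ix] == "arteriole" and s_ix not in sites:
                sites[s_ix] = (u, path)
    if not sites:
        warnings.warn("no trapping site found: tree never tapers below the bead size")
    return [
        BlockageScenario(
            site_segment=s,
            bead_xyz=graph.node_xyz[sites[s][0]].copy(),
            path_segments=sites[s][1],
        )
        for s in sorted(sites)
    ]


def apply_blockage(graph: VesselGraph, site: BlockageScenario
                   ) -> tuple[VesselGraph, frozenset]:
    """Blocked form of a column: the geometry is retained (distances still
    see the trapped segment); only its conductance is forced to zero, via
    the occlusion set understood by the flow solver."""
    return graph, frozenset({site.site_segment})


@dataclass
class ScenarioBatch:
    """Healthy state plus all completed occlusion scenarios of a column."""

    graph: VesselGraph
    healthy_flow: FlowSolution
    healthy_oxygen: OxygenSolution | None
    baseline_hypoxia: np.ndarray | None
    scenarios: list[BlockageScenario]

    @property
    def completed(self) -> list[BlockageScenario]:
        return [s for s in self.scenarios if s.ok]

    def manifest(self) -> list[dict]:
        out = []
        for s in self.scenarios:
            out.append(
                {
                    "site_segment": int(s.site_segment),
                    "bead_xyz_um": [float(v) for v in s.bead_xyz],
                    "perfusion_drop": None if s.perfusion_drop is None
                    else float(s.perfusion_drop),
                    "hypoxic_voxels": None if s.hypoxia is None
                    else int(s.hypoxia.sum()),
                    "error": s.error,
                }
            )
        return out


def run_scenarios(
    column: VesselGraph,
    hemo: HemoParams | None = None,
    oxy: OxyParams | None = None,
    bead_diameter_um: float = BEAD_DIAMETER,
    solve_oxygen_fields: bool = True,
    grid: TissueGrid | None = None,
) -> ScenarioBatch:
    """Enumerate sites and re-solve flow (and optionally oxygen) per site.

    The inlet pressure stays at its healthy calibrated value, so the
    perfusion drop is 1 - Q_blocked / Q_healthy.  Solver failures are
    contained per scenario.
    """
    hemo = hemo or HemoParams()
    oxy = oxy or OxyParams()
    inlet_pressure, healthy = calibrate_perfusion(column, hemo)
    sites = enumerate_trapping_sites(column, healthy, bead_diameter_um)

    solver = None
    healthy_ox = None
    baseline = None
    if solve_oxygen_fields:
        solver = GreensSolver(column, oxy, grid)
        healthy_ox = solver.solve(healthy)
        baseline = hypoxia_mask(healthy_ox.grid, oxy.hypoxia_threshold)

    for sc in sites:
        try:
            blocked = solve_flow(
                column, hemo, inlet_pressure,
                occluded_segments={sc.site_segment},
            )
            sc.flow = blocked
            sc.perfusion_drop = 1.0 - blocked.inlet_flow / healthy.inlet_flow
            if solve_oxygen_fields:
                sc.oxygen = solver.solve(blocked, warm_start=healthy_ox)
                sc.hypoxia = hypoxia_mask(sc.oxygen.grid, oxy.hypoxia_threshold)
        except (RuntimeError, ConvergenceError) as exc:
            sc.error = f"{type(exc).__name__}: {exc}"
    return ScenarioBatch(
        graph=column,
        healthy_flow=healthy,
        healthy_oxygen=healthy_ox,
        baseline_hypoxia=baseline,
        scenarios=sites,
    )


def write_manifest(batch: ScenarioBatch, path: str | Path) -> None:
    payload = {
        "schema": "cortox.scenarios.v1",
        "healthy": batch.healthy_flow.summary(),
        "baseline_hypoxic_voxels": None if batch.baseline_hypoxia is None
        else int(batch.baseline_hypoxia.sum()),
        "scenarios": batch.manifest(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
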