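"""Steady Poiseuille blood flow on a vessel graph.

Each segment obeys the Hagen-Poiseuille law Q = pi r^4 dp / (8 mu L) with an
apparent blood viscosity from the in-vitro diameter/haematocrit law of
Pries, Neuhaus & Gaehtgens (Am J Physiol 263, 1992).  Conservation of mass
at every interior node gives a sparse symmetric linear system; Dirichlet
conditions pin all box-face nodes to a common reference pressure (0) and
the arteriole inlet to the driving pressure.  Because viscosity does not
depend on flow, calibrating the inlet pressure to a target perfusion is a
single linear rescale of a unit-pressure solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import VesselGraph
from .units import MMHG_TO_MPA, PERFUSION_FACTOR

#: mass-conservation tolerance (relative)
MASS_TOL = 1e-8


@dataclass
class HemoParams:
    """Haemodynamic parameters.

    haematocrit and plasma viscosity are the fixed values used for human
    cortical microcirculation; target perfusion is the normal grey-matter
    value the inlet pressure is calibrated to.
    """

    haematocrit: float = 0.45
    plasma_viscosity_mPas: float = 1.2
    target_perfusion: float = 55.0  # mL/100mL/min

    def __post_init__(self):
        if not (0.0 <= self.haematocrit < 1.0):
            raise ValueError("haematocrit must lie in [0, 1)")
        if self.plasma_viscosity_mPas <= 0:
            raise ValueError("plasma viscosity must be positive")


def relative_viscosity_invitro(diameter_um, haematocrit=0.45):
    """Relative apparent viscosity of blood in a glass tube.

    Empirical in-vitro law of Pries et al. (1992) as a function of tube
    diameter D (um) and discharge haematocrit H:

        eta_45 = 220 exp(-1.3 D) + 3.2 - 2.44 exp(-0.06 D^0.645)
        C      = (0.8 + exp(-0.075 D)) (-1 + 1/(1 + 1e-11 D^12))
                 + 1/(1 + 1e-11 D^12)
        eta    = 1 + (eta_45 - 1) ((1-H)^C - 1) / ((1-0.45)^C - 1)
    """
    D = np.asarray(diameter_um, dtype=float)
    if np.any(D <= 0):
        raise ValueError("diameter must be positive")
    H = haematocrit
    eta45 = 220.0 * np.exp(-1.3 * D) + 3.2 - 2.44 * np.exp(-0.06 * D**0.645)
    t = 1.0 / (1.0 + 1e-11 * D**12)
    C = (0.8 + np.exp(-0.075 * D)) * (-1.0 + t) + t
    if H == 0:
        return np.ones_like(D) if D.shape else 1.0
    rel = 1.0 + (eta45 - 1.0) * ((1.0 - H) ** C - 1.0) / ((1.0 - 0.45) ** C - 1.0)
    return rel if rel.shape else float(rel)


def apparent_viscosity(diameter_um, haematocrit=0.45, plasma_viscosity_mPas=1.2):
    """Apparent blood viscosity in mPa*s (plasma viscosity x relative law)."""
    return plasma_viscosity_mPas * relative_viscosity_invitro(diameter_um, haematocrit)


def segment_conductance(diameter_um, length_um, viscosity_mPas):
    """Poiseuille conductance pi r^4 / (8 mu L) in um^3 / (s * mmHg)."""
    L = np.asarray(length_um, dtype=float)
    if np.any(L <= 0):
        raise ValueError("segment length must be positive")
    r = np.asarray(diameter_um, dtype=float) / 2.0
    return np.pi * r**4 / (8.0 * np.asarray(viscosity_mPas) * L) * MMHG_TO_MPA


@dataclass
class FlowSolution:
    """Pressures, flows and viscosities of a solved network."""

    pressures: np.ndarray  # mmHg per node (boundary reference 0)
    flows: np.ndarray  # um^3/s per segment, positive node_a -> node_b
    viscosities: np.ndarray  # mPa*s per segment
    conductances: np.ndarray  # um^3/(s*mmHg) per segment
    inlet_pressure: float  # mmHg
    inlet_flow: float  # um^3/s
    perfusion: float  # mL/100mL/min
    boundary: np.ndarray  # boolean mask of Dirichlet-boundary nodes
    occluded: frozenset = field(default_factory=frozenset)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            {"id": np.arange(len(self.pressures)), "pressure_mmHg": self.pressures}
        )
        segs = pd.DataFrame(
            {
                "id": np.arange(len(self.flows)),
                "flow_um3_per_s": self.flows,
                "viscosity_mPas": self.viscosities,
            }
        )
        return nodes, segs

    def summary(self) -> dict:
        return {
            "inlet_pressure_mmHg": self.inlet_pressure,
            "inlet_flow_um3_per_s": self.inlet_flow,
            "perfusion_mL_per_100mL_per_min": self.perfusion,
            "n_occluded": len(self.occluded),
        }


def boundary_mask(graph: VesselGraph, tol: float = 1e-6) -> np.ndarray:
    """Nodes on any face of the bounding box, excluding the inlet."""
    if graph.box is None:
        raise ValueError("graph has no bounding box")
    xyz = graph.node_xyz
    on_face = np.zeros(len(xyz), dtype=bool)
    for ax in range(3):
        on_face |= np.abs(xyz[:, ax]) <= tol
        on_face |= np.abs(xyz[:, ax] - graph.box[ax]) <= tol
    if graph.inlet is not None:
        on_face[graph.inlet] = False
    return on_face


def solve_flow(
    graph: VesselGraph,
    params: HemoParams | None = None,
    inlet_pressure: float = 1.0,
    occluded_segments: "frozenset[int] | set[int] | None" = None,
) -> FlowSolution:
    """Solve the network pressure field for a given inlet pressure.

    All box-face nodes share the reference pressure 0; the inlet node is
    held at ``inlet_pressure``.  Occluded segments have their conductance
    forced to zero (the segment stays in the geometry).
    """
    params = params or HemoParams()
    if graph.inlet is None:
        raise ValueError("graph has no inlet node")
    occluded = frozenset(occluded_segments or ())

    mu = apparent_viscosity(
        graph.diameters, params.haematocrit, params.plasma_viscosity_mPas
    )
    cond = segment_conductance(graph.diameters, graph.lengths, mu)
    cond = np.asarray(cond, dtype=float).copy()
    if occluded:
        cond[list(occluded)] = 0.0

    n = graph.n_nodes
    bnd = boundary_mask(graph)
    if not bnd.any():
        raise ValueError("no boundary nodes found")
    fixed = bnd.copy()
    fixed[graph.inlet] = True
    p_fixed = np.zeros(n)
    p_fixed[graph.inlet] = inlet_pressure

    a, b = graph.seg_nodes[:, 0], graph.seg_nodes[:, 1]
    # Laplacian
    rows = np.concatenate([a, b, a, b])
    cols = np.concatenate([b, a, a, b])
    vals = np.concatenate([-cond, -cond, cond, cond])
    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    free = ~fixed
    # nodes with no conductive attachment at all (e.g. a dead end whose only
    # segment is occluded) are pinned at the reference pressure
    attached = np.zeros(n)
    np.add.at(attached, a, cond)
    np.add.at(attached, b, cond)
    free &= attached > 0
    p = p_fixed.copy()
    if free.any():
        A = L[free][:, free]
        rhs = -L[free][:, fixed] @ p_fixed[fixed]
        try:
            if free.sum() < 200:
                p[free] = np.linalg.solve(A.toarray(), rhs)
            else:
                p[free] = spla.spsolve(A.tocsc(), rhs)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                "singular flow system (disconnected component?)") from exc
        if not np.all(np.isfinite(p)):
            raise RuntimeError("singular flow system (disconnected component?)")

    flows = cond * (p[a] - p[b])

    # mass conservation at interior nodes
    net = np.zeros(n)
    np.add.at(net, a, -flows)
    np.add.at(net, b, flows)
    gross = np.zeros(n)
    np.add.at(gross, a, np.abs(flows))
    np.add.at(gross, b, np.abs(flows))
    interior = free
    scale = np.maximum(gross[interior], 1e-300)
    if np.any(np.abs(net[interior]) > MASS_TOL * np.maximum(scale, 1.0)):
        raise RuntimeError("mass conservation violated beyond tolerance")

    inlet_flow = float(-net[graph.inlet])
    volume_um3 = float(np.prod(graph.box))
    perfusion = inlet_flow / volume_um3 * PERFUSION_FACTOR
    return FlowSolution(
        pressures=p,
        flows=flows,
        viscosities=np.asarray(mu, dtype=float),
        conductances=cond,
        inlet_pressure=float(inlet_pressure),
        inlet_flow=inlet_flow,
        perfusion=float(perfusion),
        boundary=bnd,
        occluded=occluded,
    )


def calibrate_perfusion(
    graph: VesselGraph,
    params: HemoParams | None = None,
    occluded_segments=None,
) -> tuple[float, FlowSolution]:
    """Inlet pressure achieving the target perfusion, plus the solution.

    Viscosity is flow-independent, so the network is linear and the
    calibration is an exact rescale of a unit-pressure solve.
    """
    params = params or HemoParams()
    unit = solve_flow(graph, params, 1.0, occluded_segments)
    if unit.inlet_flow <= 0:
        raise RuntimeError("zero inlet flow at unit pressure; cannot calibrate")
    scale = params.target_perfusion / unit.perfusion
    sol = FlowSolution(
        pressures=unit.pressures * scale,
        flows=unit.flows * scale,
        viscosities=unit.viscosities,
        conductances=unit.conductances,
        inlet_pressure=float(scale),
        inlet_flow=unit.inlet_flow * scale,
        perfusion=unit.perfusion * scale,
        boundary=unit.boundary,
        occluded=unit.occluded,
    )
    return float(scale), sol
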