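"""Shared fixtures: one default column with flow, reused across modules."""

import numpy as np
import pytest

from cortox.column import generate_column
from cortox.flow import calibrate_perfusion


@pytest.fixture(scope="session")
def default_column():
    return generate_column(seed=0)


@pytest.fixture(scope="session")
def calibrated_flow(default_column):
    inlet_pressure, sol = calibrate_perfusion(default_column)
    return inlet_pressure, sol


@pytest.fixture(scope="session")
def ten_columns():
    """Ten default columns (generation only; no transport solves)."""
    return [generate_column(seed=s) for s in range(10)]


def toy_graph(node_xyz, seg_nodes, diameters, lengths=None, kinds=None,
              inlet=0, box=(100.0, 100.0, 100.0)):
    """Small hand-built VesselGraph for solver tests."""
    from cortox.graph import VesselGraph

    node_xyz = np.asarray(node_xyz, dtype=float)
    seg_nodes = np.asarray(seg_nodes)
    if lengths is None:
        lengths = np.linalg.norm(
            node_xyz[seg_nodes[:, 1]] - node_xyz[seg_nodes[:, 0]], axis=1)
    if kinds is None:
        kinds = np.array(["arteriole"] * len(seg_nodes), dtype=object)
    return VesselGraph(node_xyz=node_xyz, seg_nodes=seg_nodes,
                       diameters=np.asarray(diameters, dtype=float),
                       lengths=np.asarray(lengths, dtype=float),
                       kinds=np.asarray(kinds, dtype=object),
                       inlet=inlet, box=np.asarray(box, dtype=float))
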