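"""Vascular network container.

A :class:`VesselGraph` is a node/segment list representation of a
microvascular network: nodes carry 3D positions in micrometres, segments
carry a diameter, a length and a kind (``arteriole``, ``capillary`` or
``connector``).  Segments are straight, so the stored length equals the
Euclidean node distance except for periodic capillary cubes, where lengths
follow the minimum-image convention.

The on-disk form is two CSV tables (nodes, segments) plus a JSON header;
round-trips are lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SEGMENT_KINDS = ("arteriole", "capillary", "connector")


@dataclass
class VesselGraph:
    """Geometric/topological vascular network.

    Parameters
    ----------
    node_xyz : (n_nodes, 3) float array
        Node positions in um. z increases downward from the cortical surface.
    seg_nodes : (n_segments, 2) int array
        Endpoint node indices (node_a, node_b) of each segment.
    diameters : (n_segments,) float array, um
    lengths : (n_segments,) float array, um
    kinds : (n_segments,) object array of strings
    inlet : int or None
        Index of the inlet node (penetrating-arteriole root), if any.
    box : (3,) float array or None
        Bounding box edge lengths in um (origin at 0).
    periodic : bool
        True for capillary cubes whose wrap-around segments use
        minimum-image lengths.
    meta : dict
        Seed, generator spec and other provenance.
    """

    node_xyz: np.ndarray
    seg_nodes: np.ndarray
    diameters: np.ndarray
    lengths: np.ndarray
    kinds: np.ndarray
    inlet: int | None = None
    box: np.ndarray | None = None
    periodic: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_xyz = np.asarray(self.node_xyz, dtype=float).reshape(-1, 3)
        self.seg_nodes = np.asarray(self.seg_nodes, dtype=np.int64).reshape(-1, 2)
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=object)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_xyz)

    @property
    def n_segments(self) -> int:
        return len(self.seg_nodes)

    @property
    def radii(self) -> np.ndarray:
        return self.diameters / 2.0

    def validate(self) -> None:
        if self.n_segments:
            if self.seg_nodes.min() < 0 or self.seg_nodes.max() >= self.n_nodes:
                raise ValueError("segment references a non-existent node")
            if np.any(self.diameters <= 0):
                raise ValueError("non-positive segment diameter")
            if np.any(self.lengths <= 0):
                raise ValueError("non-positive segment length")
            unknown = set(self.kinds) - set(SEGMENT_KINDS)
            if unknown:
                raise ValueError(f"unknown segment kinds: {unknown}")
        if self.inlet is not None and not (0 <= self.inlet < self.n_nodes):
            raise ValueError("inlet node out of range")

    def segment_vectors(self) -> np.ndarray:
        """End-minus-start position vectors; minimum-image if periodic."""
        d = self.node_xyz[self.seg_nodes[:, 1]] - self.node_xyz[self.seg_nodes[:, 0]]
        if self.periodic and self.box is not None:
            d -= self.box * np.round(d / self.box)
        return d

    def euclidean_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segment_vectors(), axis=1)

    def adjacency(self) -> "list[list[tuple[int, int]]]":
        """Per-node list of (segment index, other node) pairs."""
        adj: list[list[tuple[int, int]]] = [[] for _ in range(self.n_nodes)]
        for s, (a, b) in enumerate(self.seg_nodes):
            adj[a].append((s, b))
            adj[b].append((s, a))
        return adj

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return True
        adj = self.adjacency()
        seen = np.zeros(self.n_nodes, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            u = stack.pop()
            for _, v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        return bool(seen.all())

    # ------------------------------------------------------------------
    # serialisation
    def write(self, directory: str | Path, prefix: str = "graph") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nodes = pd.DataFrame(
            {
                "id": np.arange(self.n_nodes),
                "x": self.node_xyz[:, 0],
                "y": self.node_xyz[:, 1],
                "z": self.node_xyz[:, 2],
            }
        )
        segs = pd.DataFrame(
            {
                "id": np.arange(self.n_segments),
                "node_a": self.seg_nodes[:, 0],
                "node_b": self.seg_nodes[:, 1],
                "diameter_um": self.diameters,
                "length_um": self.lengths,
                "kind": self.kinds,
            }
        )
        nodes.to_csv(directory / f"{prefix}_nodes.csv", index=False,
                     float_format="%.17g")
        segs.to_csv(directory / f"{prefix}_segments.csv", index=False,
                    float_format="%.17g")
        header = {
            "schema": "cortox.vesselgraph.v1",
            "inlet": None if self.inlet is None else int(self.inlet),
            "box_um": None if self.box is None else list(map(float, self.box)),
            "periodic": self.periodic,
            "meta": self.meta,
        }
        (directory / f"{prefix}_header.json").write_text(json.dumps(header, indent=1))

    @classmethod
    def read(cls, directory: str | Path, prefix: str = "graph") -> "VesselGraph":
        directory = Path(directory)
        nodes = pd.read_csv(directory / f"{prefix}_nodes.csv",
                            float_precision="round_trip")
        segs = pd.read_csv(directory / f"{prefix}_segments.csv",
                           float_precision="round_trip")
        header = json.loads((directory / f"{prefix}_header.json").read_text())
        return cls(
            node_xyz=nodes[["x", "y", "z"]].to_numpy(),
            seg_nodes=segs[["node_a", "node_b"]].to_numpy(),
            diameters=segs["diameter_um"].to_numpy(),
            lengths=segs["length_um"].to_numpy(),
            kinds=segs["kind"].to_numpy(dtype=object),
            inlet=header["inlet"],
            box=header["box_um"],
            periodic=header["periodic"],
            meta=header.get("meta", {}),
        )
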