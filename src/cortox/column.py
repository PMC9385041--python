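"""Synthetic cortical-column generation.

A cortical column is the 375x375x1500 um^3 tissue block supplied by one
penetrating arteriole.  It is assembled from four periodic 375 um capillary
cubes stacked in depth plus a stochastic bifurcating penetrating-arteriole
tree placed at the lateral centre with its inlet on the cortical surface
(z = 0).  Branches leaving the box are trimmed at the faces and every
arteriole terminal is connected to the closest capillary node.

The capillary generator is a statistical stand-in: a jittered periodic
simple-cubic lattice pruned to a target segment count, with diameters drawn
from a clipped normal law.  Its defaults are calibrated so that assembled
columns reproduce a human-cortex vessel density of ~10846/mm^3 and a
vascular volume fraction of ~2.82% (surface density of penetrating
arterioles 7.11/mm^2 follows from one arteriole per 375x375 um^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .graph import VesselGraph
from .units import MM3_TO_ML, UM3_TO_MM3

#: default column box, um
COLUMN_BOX = (375.0, 375.0, 1500.0)
#: bead size used throughout, um
BEAD_DIAMETER = 25.0

# Cube-level defaults calibrated once so that assembled columns (where
# face-cut periodic stubs and the arteriole add segments) match the
# column-level targets above.
DEFAULT_CUBE_DENSITY = 9435.0  # segments/mm^3 at cube level
DEFAULT_CAP_DIAMETER_MEAN = 7.55  # um
DEFAULT_CAP_DIAMETER_SD = 0.8
DEFAULT_CAP_DIAMETER_CLIP = (4.5, 11.0)


@dataclass
class DiameterLaw:
    """Clipped-normal capillary diameter distribution (um)."""

    mean: float = DEFAULT_CAP_DIAMETER_MEAN
    sd: float = DEFAULT_CAP_DIAMETER_SD
    lo: float = DEFAULT_CAP_DIAMETER_CLIP[0]
    hi: float = DEFAULT_CAP_DIAMETER_CLIP[1]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.clip(rng.normal(self.mean, self.sd, size=n), self.lo, self.hi)


@dataclass
class BranchingSpec:
    """Penetrating-arteriole tree parameters.

    The number of side branches leaving the trunk while it is still above
    the 25 um bead size is drawn uniformly from
    ``n_supra_branches = [min, max]``; together with the first sub-25 um
    trunk segment this fixes the number of distinct bead trapping sites per
    tree to ``n_supra_branches + 1``, the physiological 6-15 range observed
    for single penetrating arterioles.  Trunk diameters between branch
    points decrease linearly from the inlet to cross 25 um at a mid-cortex
    depth (``trunk_cross_depth``), so the deepest trapping site commands
    the whole lower part of the column; side branches are genuine subtrees
    (two to three Murray-law bifurcation levels) feeding territories a few
    hundred micrometres across, and the sub-threshold trunk keeps shedding
    (shadowed) offshoots on its way down.
    """

    n_supra_branches: tuple[int, int] = (5, 14)
    first_branch_depth: tuple[float, float] = (60.0, 120.0)
    trunk_cross_depth: tuple[float, float] = (1050.0, 1300.0)
    trunk_segment_length: float = 60.0
    trunk_wobble: float = 8.0  # lateral jitter per trunk segment, um
    sub25_trunk_diameter: float = 24.0  # trunk diameter just past the last site
    sub25_twig_spacing: float = 120.0  # offshoot spacing on the deep trunk
    deep_trunk_bottom_diameter: float = 15.0  # trunk calibre at full depth
    leaf_diameter: float = 7.5
    murray_exponent: float = 3.0
    side_polar_deg: tuple[float, float] = (30.0, 70.0)  # from the downward axis
    side_segment_length: tuple[float, float] = (40.0, 60.0)
    side_total_length: tuple[float, float] = (250.0, 650.0)  # path-length budget
    #: branches reflect off this lateral half-width, staying inside the
    #: column territory (adjacent columns' trees fold back symmetrically)
    lateral_halfwidth: float = 175.0


# ----------------------------------------------------------------------
# capillary cube
def generate_capillary_cube(
    edge_length: float = 375.0,
    target_density: float = DEFAULT_CUBE_DENSITY,
    diameter_law: DiameterLaw | None = None,
    seed: int = 0,
) -> VesselGraph:
    """Generate a triply periodic capillary cube.

    Nodes sit on a jittered simple-cubic lattice; the full periodic
    edge set is pruned by connectivity-preserving random deletion to the
    exact segment count implied by ``target_density`` (segments/mm^3).
    Segment lengths follow the minimum-image convention.
    """
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")
    if target_density <= 0:
        raise ValueError("target_density must be positive")
    diameter_law = diameter_law or DiameterLaw()
    rng = np.random.default_rng(seed)

    volume_mm3 = (edge_length / 1000.0) ** 3
    target_count = int(round(target_density * volume_mm3))
    if target_count < 1:
        raise ValueError("target density yields no segments for this cube size")

    # lattice size: aim for a mean degree ~3.3 (capillary-like)
    n = max(2, int(round((2.0 * target_count / 3.3) ** (1.0 / 3.0))))
    while 3 * n**3 < target_count:
        n += 1
    while n > 2 and n**3 - 1 > target_count:
        n -= 1
    if 3 * n**3 < target_count or n**3 - 1 > target_count:
        raise RuntimeError(
            f"target density {target_density}/mm^3 unattainable with the "
            f"lattice construction (count {target_count}, lattice {n})"
        )

    spacing = edge_length / n
    idx = np.indices((n, n, n)).reshape(3, -1).T  # (n^3, 3)
    pos = (idx + 0.5) * spacing
    pos = pos + rng.uniform(-0.22 * spacing, 0.22 * spacing, size=pos.shape)
    pos = np.mod(pos, edge_length)

    def node_id(i, j, k):
        return (i * n + j) * n + k

    edges = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                a = node_id(i, j, k)
                edges.append((a, node_id((i + 1) % n, j, k)))
                edges.append((a, node_id(i, (j + 1) % n, k)))
                edges.append((a, node_id(i, j, (k + 1) % n)))
    edges = np.array(edges, dtype=np.int64)

    # wrap vector of each candidate edge (lattice wrap is +1 by construction
    # for edges leaving the high face)
    nbr = idx[edges[:, 1]] - idx[edges[:, 0]]
    wrap_axes = nbr < 0  # (n_edges, 3) True where the edge wraps around

    keep = _prune_to_count(edges, wrap_axes, n**3, target_count, rng)
    seg_nodes = edges[keep]

    d = pos[seg_nodes[:, 1]] - pos[seg_nodes[:, 0]]
    d -= edge_length * np.round(d / edge_length)
    lengths = np.linalg.norm(d, axis=1)
    diameters = diameter_law.sample(rng, len(seg_nodes))

    return VesselGraph(
        node_xyz=pos,
        seg_nodes=seg_nodes,
        diameters=diameters,
        lengths=lengths,
        kinds=np.array(["capillary"] * len(seg_nodes), dtype=object),
        inlet=None,
        box=np.array([edge_length] * 3),
        periodic=True,
        meta={"seed": int(seed), "lattice_n": n, "target_density": target_density},
    )


#: number of cubes stacked into a column; pruning preserves connectivity of
#: the stacked finite network, where lateral wrap edges become boundary
#: stubs and carry no connectivity
_STACK_FOR_CONNECTIVITY = 4


def _prune_to_count(edges, wrap_axes, n_nodes, target, rng):
    """Boolean keep-mask removing random edges down to ``target``.

    Every node keeps degree >= 2 in the periodic cube, and the finite
    stacked column implied by the kept edges (within-copy edges plus
    pure-z wrap links between consecutive copies) stays connected.
    """
    n_edges = len(edges)
    if target > n_edges:
        raise RuntimeError(
            f"target segment count {target} exceeds lattice capacity {n_edges}"
        )
    ns = _STACK_FOR_CONNECTIVITY
    lateral = wrap_axes[:, 0] | wrap_axes[:, 1]
    pure_z = wrap_axes[:, 2] & ~lateral

    def column_links(e):
        """Column adjacency links contributed by cube edge e."""
        a, b = edges[e]
        out = []
        if lateral[e]:
            return out
        if pure_z[e]:
            # a sits on the high-z side; continuation reaches b one copy down
            for k in range(ns - 1):
                out.append((k * n_nodes + a, (k + 1) * n_nodes + b))
        else:
            for k in range(ns):
                out.append((k * n_nodes + a, k * n_nodes + b))
        return out

    adj: list[set[int]] = [set() for _ in range(ns * n_nodes)]
    for e in range(n_edges):
        for u, v in column_links(e):
            adj[u].add(v)
            adj[v].add(u)

    def connected() -> bool:
        seen = np.zeros(ns * n_nodes, dtype=bool)
        stack = [0]
        seen[0] = True
        count = 1
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    count += 1
                    stack.append(v)
        return count == ns * n_nodes

    if not connected():
        raise RuntimeError("full lattice column is disconnected (lattice too small)")

    keep = np.ones(n_edges, dtype=bool)
    degree = np.bincount(edges.ravel(), minlength=n_nodes)
    n_current = n_edges
    order = rng.permutation(n_edges)
    progress = True
    while n_current > target and progress:
        progress = False
        for e in order:
            if n_current <= target:
                break
            if not keep[e]:
                continue
            a, b = edges[e]
            if degree[a] <= 2 or degree[b] <= 2:
                continue
            links = column_links(e)
            for u, v in links:
                adj[u].discard(v)
                adj[v].discard(u)
            if links and not connected():
                for u, v in links:
                    adj[u].add(v)
                    adj[v].add(u)
                continue
            keep[e] = False
            degree[a] -= 1
            degree[b] -= 1
            n_current -= 1
            progress = True
    if n_current != target:
        raise RuntimeError(
            "target segment density unattainable: pruning stalled at "
            f"{n_current} segments (target {target})"
        )
    return keep


# ----------------------------------------------------------------------
# penetrating arteriole
def generate_arteriole_tree(
    depth: float = 1400.0,
    inlet_diameter: float | None = None,
    branching: BranchingSpec | None = None,
    seed: int = 0,
) -> VesselGraph:
    """Generate a stochastic penetrating-arteriole tree rooted at (0, 0, 0).

    The tree descends from the cortical surface with side branches leaving
    the trunk at random depths; trunk diameters decrease strictly from the
    inlet and fall below the 25 um bead size after the drawn number of
    supra-threshold branch points, so every tree presents 6-15 distinct
    bead trapping sites (n_supra_branches + 1).
    """
    spec = branching or BranchingSpec()
    rng = np.random.default_rng(seed)
    if depth <= 0:
        raise ValueError("depth must be positive")
    d0 = float(inlet_diameter) if inlet_diameter is not None else rng.uniform(29.0, 33.0)
    if d0 <= BEAD_DIAMETER:
        raise ValueError(
            f"inlet diameter {d0} um must exceed the bead size {BEAD_DIAMETER} um"
        )

    nodes = [np.array([0.0, 0.0, 0.0])]
    segs: list[tuple[int, int]] = []
    diam: list[float] = []
    kinds: list[str] = []

    lo, hi = spec.n_supra_branches
    n_b = int(rng.integers(lo, hi + 1))

    # supra-threshold branch points spread between the first-branch depth
    # and the depth where the trunk crosses the bead size
    z0 = rng.uniform(*spec.first_branch_depth)
    z_cross = min(rng.uniform(*spec.trunk_cross_depth), depth - 100.0)
    z_cross = max(z_cross, z0 + 50.0)
    if n_b > 0:
        # branches shed roughly evenly along the supra-threshold trunk,
        # starting right at the first-branch depth (the shallow cortex is
        # supplied by the first offshoots) and ending at the crossing
        if n_b == 1:
            frac = np.array([1.0])
        else:
            frac = (np.arange(n_b) + rng.uniform(-0.3, 0.3, n_b)) / (n_b - 1)
            frac = np.clip(np.sort(frac), 0.0, 1.0)
            frac[0], frac[-1] = 0.0, 1.0
        branch_z = list(z0 + (z_cross - z0) * frac)
    else:
        branch_z = []

    # trunk run-boundary diameters: the run ending at branch point k+1 tapers
    # from D[k] to D[k+1]; D falls linearly from the inlet to exactly 25 um at
    # the last supra-threshold branch, so no trunk segment above it is below
    # the bead size and the first sub-25 um segment lies just past it
    if n_b > 0:
        D = [BEAD_DIAMETER + (d0 - BEAD_DIAMETER) * (1.0 - k / n_b)
             for k in range(n_b + 1)]
    else:
        D = [d0]

    def add_chain(start_idx, start_pos, direction, total_len, seg_len, d_start, d_end, kind):
        """Straight-ish chain of segments; returns final node index."""
        n_seg = max(1, int(round(total_len / seg_len)))
        cur = start_idx
        pos = start_pos.copy()
        for i in range(n_seg):
            frac0, frac1 = i / n_seg, (i + 1) / n_seg
            step = direction * (total_len / n_seg)
            if kind == "arteriole" and abs(direction[2]) > 0.9:
                step = step + np.array(
                    [rng.uniform(-spec.trunk_wobble, spec.trunk_wobble),
                     rng.uniform(-spec.trunk_wobble, spec.trunk_wobble), 0.0]
                )
            pos = pos + step
            nodes.append(pos.copy())
            nxt = len(nodes) - 1
            segs.append((cur, nxt))
            diam.append(d_start + (d_end - d_start) * (frac0 + frac1) / 2.0)
            kinds.append(kind)
            cur = nxt
        return cur

    def reflect_lateral(pos):
        """Fold positions back inside the lateral territory."""
        hw = spec.lateral_halfwidth
        out = pos.copy()
        for ax in (0, 1):
            if abs(out[ax]) > hw:
                out[ax] = np.sign(out[ax]) * (2 * hw - abs(out[ax]))
        out[2] = max(out[2], 5.0)  # never poke above the cortical surface
        return out

    def add_leaf_twig(start_idx, start_pos, d):
        """Short lateral offshoot ending in a terminal leaf."""
        azim = rng.uniform(0, 2 * np.pi)
        step = np.array([np.cos(azim), np.sin(azim), rng.uniform(-0.3, 0.8)])
        step /= np.linalg.norm(step)
        pos = reflect_lateral(start_pos + step * rng.uniform(30.0, 50.0))
        nodes.append(pos.copy())
        nxt = len(nodes) - 1
        segs.append((start_idx, nxt))
        diam.append(max(d, spec.leaf_diameter))
        kinds.append("arteriole")
        return nxt

    def add_side_branch(start_idx, start_pos, d_side, descent_hint=None):
        """Descending secondary branch: an oblique elbow followed by a
        near-vertical run that sheds leaf twigs -- delivery stays close to
        the column axis (with face-outlet boundaries, peripheral delivery
        would short-circuit straight out of the column) while the branch's
        territory spans a tall slab of cortex.  ``descent_hint`` couples
        the run length to the local branch spacing so supply covers every
        depth regardless of how many branches a tree drew."""
        azim = rng.uniform(0, 2 * np.pi)
        polar = np.deg2rad(rng.uniform(*spec.side_polar_deg))
        direction = np.array(
            [np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim),
             np.cos(polar)]
        )
        seg_len = rng.uniform(*spec.side_segment_length)
        # oblique elbow
        cur, pos = start_idx, start_pos.copy()
        d_elbow = max(d_side * 0.93, spec.leaf_diameter)
        pos = reflect_lateral(pos + direction * seg_len)
        nodes.append(pos.copy())
        cur_new = len(nodes) - 1
        segs.append((cur, cur_new))
        diam.append((d_side + d_elbow) / 2.0)
        kinds.append("arteriole")
        cur = cur_new
        # descending run shedding leaf twigs
        if descent_hint is None:
            descent_hint = rng.uniform(*spec.side_total_length) * 0.6
        descent = max(descent_hint * rng.uniform(1.0, 1.5), 60.0)
        n_desc = max(1, int(round(descent / 80.0)))
        d_here = d_elbow
        d_leafend = spec.leaf_diameter
        for i in range(n_desc):
            step = np.array([rng.uniform(-15, 15), rng.uniform(-15, 15),
                             descent / n_desc])
            pos = reflect_lateral(pos + step)
            nodes.append(pos.copy())
            nxt = len(nodes) - 1
            segs.append((cur, nxt))
            d_next = d_elbow + (d_leafend - d_elbow) * (i + 1) / n_desc
            diam.append((d_here + d_next) / 2.0)
            kinds.append("arteriole")
            d_here = d_next
            cur = nxt
            if d_here > spec.leaf_diameter + 0.5:
                add_leaf_twig(cur, pos, max(d_here * 0.8, spec.leaf_diameter))

    # build trunk run by run
    m = spec.murray_exponent
    cur = 0
    pos = nodes[0]
    prev_z = 0.0
    down = np.array([0.0, 0.0, 1.0])
    for k, bz in enumerate(branch_z):
        run = bz - prev_z
        if run > 1.0:
            cur = add_chain(cur, nodes[cur], down, run, spec.trunk_segment_length,
                            D[k], D[k + 1], "arteriole")
        # Murray-law side diameter from the trunk step at this branch point
        d_side = (max(D[k] ** m - D[k + 1] ** m, 1.0)) ** (1.0 / m)
        d_side = min(d_side, D[k + 1] - 0.5)  # strictly thinner than the trunk it leaves
        d_side = max(d_side, spec.leaf_diameter + 1.0)
        gap = (branch_z[k + 1] - bz) if k + 1 < len(branch_z) else \
            spec.sub25_twig_spacing
        add_side_branch(cur, nodes[cur], d_side, descent_hint=max(gap, 60.0))
        prev_z = bz

    # sub-threshold terminal trunk: keeps descending and shedding
    # (shadowed) offshoots so the deep half of the column is fed by the
    # trunk -- occluding the first sub-25 um trunk segment starves it
    remaining = depth - prev_z
    if remaining > 1.0:
        start_d = spec.sub25_trunk_diameter if n_b > 0 else d0
        n_twig = max(0, int(remaining / spec.sub25_twig_spacing) - 1)
        z_twigs = [prev_z + (i + 1) * remaining / (n_twig + 1)
                   for i in range(n_twig)]
        d_here, z_here = start_d, prev_z
        d_bottom = min(spec.deep_trunk_bottom_diameter, start_d - 0.5)
        for zt in z_twigs:
            d_next = start_d + (d_bottom - start_d) * (zt - prev_z) / remaining
            cur = add_chain(cur, nodes[cur], down, zt - z_here,
                            spec.trunk_segment_length, d_here, d_next,
                            "arteriole")
            if d_next > spec.leaf_diameter + 1.5 and d_here < BEAD_DIAMETER:
                # offshoots only below the bead-size crossing: any sub-25 um
                # branch off a supra-threshold trunk would be a trap site
                m = spec.murray_exponent
                d_twig = max((max(d_here**m - d_next**m, 1.0)) ** (1.0 / m),
                             spec.leaf_diameter + 0.5)
                add_side_branch(cur, nodes[cur], min(d_twig, d_next - 0.2),
                                descent_hint=spec.sub25_twig_spacing)
            d_here, z_here = d_next, zt
        if depth - z_here > 1.0:
            add_chain(cur, nodes[cur], down, depth - z_here,
                      spec.trunk_segment_length, d_here, d_bottom, "arteriole")

    node_xyz = np.array(nodes)
    seg_nodes = np.array(segs, dtype=np.int64)
    lengths = np.linalg.norm(
        node_xyz[seg_nodes[:, 1]] - node_xyz[seg_nodes[:, 0]], axis=1
    )
    g = VesselGraph(
        node_xyz=node_xyz,
        seg_nodes=seg_nodes,
        diameters=np.array(diam),
        lengths=lengths,
        kinds=np.array(kinds, dtype=object),
        inlet=0,
        box=None,
        periodic=False,
        meta={"seed": int(seed), "n_supra_branches": n_b, "inlet_diameter": d0},
    )
    if not np.any(g.diameters < BEAD_DIAMETER):
        raise RuntimeError("arteriole tree never tapers below the bead size")
    return g


# ----------------------------------------------------------------------
# assembly
def assemble_column(
    arteriole: VesselGraph,
    cube: VesselGraph,
    n_stack: int = 4,
) -> VesselGraph:
    """Assemble a cortical column from a periodic capillary cube and a
    penetrating arteriole tree.

    ``n_stack`` copies of the cube are stacked in depth; periodic capillary
    segments become straight inter-copy segments (z) or are cut at the box
    faces into boundary stubs (lateral and outer z faces).  The arteriole is
    translated to the lateral centre, trimmed at the faces, and each of its
    terminals is joined to the closest capillary node by a connector segment
    carrying the terminal's diameter.
    """
    if not cube.periodic or cube.box is None:
        raise ValueError("cube must be a periodic capillary cube")
    edge = float(cube.box[0])
    box = np.array([edge, edge, edge * n_stack])

    n = cube.n_nodes
    node_xyz = [
        cube.node_xyz + np.array([0.0, 0.0, edge * k]) for k in range(n_stack)
    ]
    node_xyz = list(np.concatenate(node_xyz, axis=0))
    segs: list[tuple[int, int]] = []
    diams: list[float] = []
    lens: list[float] = []
    kinds: list[str] = []

    delta = cube.node_xyz[cube.seg_nodes[:, 1]] - cube.node_xyz[cube.seg_nodes[:, 0]]
    # wrap vector w such that (pos_b + w*edge) is the straight continuation of a
    wrap = -np.round(delta / edge).astype(int)

    def add_seg(a, b, d, L, kind):
        segs.append((a, b))
        diams.append(d)
        lens.append(L)
        kinds.append(kind)

    def first_exit(p, q):
        """First box-exit parameter t in (0, 1] along p -> q, or None."""
        t_exit = np.inf
        for ax in range(3):
            dv = q[ax] - p[ax]
            if dv > 0 and q[ax] > box[ax]:
                t_exit = min(t_exit, (box[ax] - p[ax]) / dv)
            elif dv < 0 and q[ax] < 0.0:
                t_exit = min(t_exit, (0.0 - p[ax]) / dv)
        return None if not np.isfinite(t_exit) else t_exit

    def add_stub(idx_inside, p_inside, p_target, d, kind):
        t = first_exit(p_inside, p_target)
        if t is None or t <= 1e-9:
            return
        exit_pt = p_inside + t * (p_target - p_inside)
        exit_pt = np.clip(exit_pt, 0.0, box)  # land exactly on the face
        node_xyz.append(exit_pt)
        j = len(node_xyz) - 1
        add_seg(idx_inside, j, d, float(np.linalg.norm(exit_pt - p_inside)), kind)

    for e, ((a, b), w) in enumerate(zip(cube.seg_nodes, wrap)):
        d = float(cube.diameters[e])
        pa, pb = cube.node_xyz[a], cube.node_xyz[b]
        if w[2] < 0:  # orient so any z wrap points downward
            a, b, pa, pb, w = b, a, pb, pa, -w
        pure_z = w[2] == 1 and w[0] == 0 and w[1] == 0
        for k in range(n_stack):
            off = np.array([0.0, 0.0, edge * k])
            A = pa + off
            # unwrapped continuation of a: b shifted by the wrap vector
            B = pb + w * edge + off
            ia, ib = k * n + a, k * n + b
            if (w == 0).all():
                add_seg(ia, ib, d, float(np.linalg.norm(B - A)), "capillary")
            elif pure_z:
                if k < n_stack - 1:
                    add_seg(ia, (k + 1) * n + b, d, float(np.linalg.norm(B - A)),
                            "capillary")
                else:
                    add_stub(ia, A, B, d, "capillary")
                if k == 0:
                    # partner stub entering through the top face
                    A2 = pa - w * edge + off
                    B2 = pb + off
                    add_stub(ib, B2, A2, d, "capillary")
            else:
                add_stub(ia, A, B, d, "capillary")
                A2 = pa - w * edge + off
                B2 = pb + off
                add_stub(ib, B2, A2, d, "capillary")

    n_capillary_nodes = len(node_xyz)

    # ---- arteriole: translate to centre, trim at faces, walk from root
    if arteriole.inlet is None:
        raise ValueError("arteriole has no inlet")
    shift = np.array([box[0] / 2.0, box[1] / 2.0, 0.0]) - arteriole.node_xyz[arteriole.inlet]
    art_xyz = arteriole.node_xyz + shift
    inside = np.all((art_xyz >= 0) & (art_xyz <= box), axis=1)
    if not inside[arteriole.inlet]:
        raise ValueError("arteriole root does not lie on the top face inside the box")

    adj = arteriole.adjacency()
    art_map: dict[int, int] = {}

    def get_art_node(i):
        if i not in art_map:
            node_xyz.append(art_xyz[i].copy())
            art_map[i] = len(node_xyz) - 1
        return art_map[i]

    terminals: list[tuple[int, float]] = []  # (column node idx, diameter)
    root = arteriole.inlet
    visited = {root}
    stack = [root]
    degree_in_col: dict[int, int] = {}
    while stack:
        u = stack.pop()
        for s, v in adj[u]:
            if v in visited:
                continue
            visited.add(v)
            d = float(arteriole.diameters[s])
            iu = get_art_node(u)
            if inside[v]:
                iv = get_art_node(v)
                add_seg(iu, iv, d, float(np.linalg.norm(art_xyz[v] - art_xyz[u])),
                        "arteriole")
                degree_in_col[iu] = degree_in_col.get(iu, 0) + 1
                degree_in_col[iv] = degree_in_col.get(iv, 0) + 1
                stack.append(v)
            else:
                # cut at the face; downstream subtree is discarded
                t = first_exit(art_xyz[u], art_xyz[v])
                if t is None or t <= 1e-9:
                    continue
                cut = np.clip(art_xyz[u] + t * (art_xyz[v] - art_xyz[u]), 0.0, box)
                node_xyz.append(cut)
                ic = len(node_xyz) - 1
                add_seg(iu, ic, d, float(np.linalg.norm(cut - art_xyz[u])), "arteriole")
                degree_in_col[iu] = degree_in_col.get(iu, 0) + 1
                degree_in_col[ic] = 1
                terminals.append((ic, d))

    # leaves of the retained tree (degree 1, not the root)
    root_idx = get_art_node(root)
    seg_arr = np.array(segs, dtype=np.int64)
    kind_arr = np.array(kinds, dtype=object)
    art_degree: dict[int, int] = {}
    for (u, v), kd in zip(seg_arr, kind_arr):
        if kd == "arteriole":
            art_degree[u] = art_degree.get(u, 0) + 1
            art_degree[v] = art_degree.get(v, 0) + 1
    terminal_ids = {t for t, _ in terminals}
    term_diam = dict(terminals)
    for (u, v), kd, d in zip(seg_arr, kind_arr, diams):
        if kd != "arteriole":
            continue
        for idx in (u, v):
            if idx != root_idx and art_degree.get(idx, 0) == 1 and idx not in terminal_ids:
                terminal_ids.add(idx)
                term_diam[idx] = d

    # connectors: every arteriole terminal joins the closest capillary node
    cap_tree = cKDTree(np.array(node_xyz[:n_capillary_nodes]))
    for t in sorted(terminal_ids):
        p = node_xyz[t]
        _, j = cap_tree.query(p)
        L = float(np.linalg.norm(np.array(node_xyz[int(j)]) - p))
        if L <= 1e-9:
            continue
        add_seg(t, int(j), term_diam[t], L, "connector")

    col = VesselGraph(
        node_xyz=np.array(node_xyz),
        seg_nodes=np.array(segs, dtype=np.int64),
        diameters=np.array(diams),
        lengths=np.array(lens),
        kinds=np.array(kinds, dtype=object),
        inlet=root_idx,
        box=box,
        periodic=False,
        meta={
            "cube_seed": cube.meta.get("seed"),
            "arteriole_seed": arteriole.meta.get("seed"),
            "n_stack": n_stack,
        },
    )
    if not col.is_connected():
        raise RuntimeError("assembled column is disconnected")
    return col


def generate_column(seed: int, box=COLUMN_BOX, cube_density: float = DEFAULT_CUBE_DENSITY,
                    diameter_law: DiameterLaw | None = None,
                    branching: BranchingSpec | None = None) -> VesselGraph:
    """Convenience wrapper: one default column from a single seed."""
    rng = np.random.default_rng(seed)
    cube_seed, art_seed = rng.integers(0, 2**31 - 1, size=2)
    cube = generate_capillary_cube(box[0], cube_density, diameter_law, int(cube_seed))
    art = generate_arteriole_tree(depth=box[2] - 100.0, branching=branching,
                                  seed=int(art_seed))
    return assemble_column(art, cube, n_stack=int(round(box[2] / box[0])))


# ----------------------------------------------------------------------
# statistics
@dataclass
class ColumnStats:
    """Geometric summary of a column."""

    surface_density_per_mm2: float
    vessel_density_per_mm3: float
    volume_fraction: float

    def __post_init__(self):
        if not (0.0 <= self.volume_fraction < 1.0):
            raise ValueError("volume fraction outside (0, 1)")


def network_stats(column: VesselGraph) -> ColumnStats:
    """Surface density of arterioles, vessel density and volume fraction."""
    if column.box is None:
        raise ValueError("column has no bounding box")
    area_mm2 = (column.box[0] / 1000.0) * (column.box[1] / 1000.0)
    vol_mm3 = float(np.prod(column.box)) * UM3_TO_MM3
    n_arterioles = 1 if column.inlet is not None else 0
    if column.n_segments == 0:
        return ColumnStats(n_arterioles / area_mm2, 0.0, 0.0)
    seg_vol_um3 = float(np.sum(np.pi * column.radii**2 * column.lengths))
    return ColumnStats(
        surface_density_per_mm2=n_arterioles / area_mm2,
        vessel_density_per_mm3=column.n_segments / vol_mm3,
        volume_fraction=seg_vol_um3 * UM3_TO_MM3 / vol_mm3,
    )


def bead_volume_arithmetic(
    bead_density_per_mm3: float,
    bead_diameter_um: float,
    territory_volume_ml: float,
    reference_thrombus_ml: float,
) -> tuple[float, float, float]:
    """Worked bead-load arithmetic.

    Returns (volume fraction of beads per unit tissue, total bead volume in
    the territory in mL, and that volume as a percentage of a reference
    thrombus volume).
    """
    for v in (bead_density_per_mm3, bead_diameter_um, territory_volume_ml,
              reference_thrombus_ml):
        if v <= 0:
            raise ValueError("all inputs must be positive")
    bead_vol_mm3 = (np.pi / 6.0) * (bead_diameter_um**3) * UM3_TO_MM3
    fraction = bead_density_per_mm3 * bead_vol_mm3  # mL beads / mL tissue
    total_ml = fraction * territory_volume_ml
    percent = 100.0 * total_ml / reference_thrombus_ml
    return fraction, total_ml, percent
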