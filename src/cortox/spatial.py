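"""3D spatial statistics linking microspheres and hypoxic tissue.

Two analyses, applied identically to simulated columns and to segmented
experimental-style data:

* pixel-based Gx function: the empirical cumulative distribution of the
  Euclidean distance from every in-domain hypoxic voxel centre to its
  nearest microsphere;
* hypoxic intensity: the hypoxic volume fraction inside spheres of
  increasing radius (50-500 um, step 50) centred on a microsphere, with a
  type A (decreasing 50->100 um slope; local hypoxia) / type B (increasing;
  distal hypoxia) classification and a local/no-local subtype by the
  presence of hypoxic voxels within 100 um.

Monte-Carlo control points drawn uniformly over the domain at the observed
bead density provide the randomness reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: standard hypoxic-intensity radius grid, um
INTENSITY_RADII = tuple(float(r) for r in range(50, 501, 50))
#: Gx reporting grid: 0-1000 um in 10 um bins
GX_BIN_UM = 10.0
GX_MAX_UM = 1000.0


@dataclass
class PointSet:
    """Labelled 3D points (um): microsphere centres or MC controls."""

    xyz: np.ndarray
    label: str = "bead"

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)

    @property
    def n(self) -> int:
        return len(self.xyz)

    @classmethod
    def from_csv(cls, path, label="bead") -> "PointSet":
        df = pd.read_csv(path)
        if len(df) == 0:
            return cls(np.empty((0, 3)), label)
        return cls(df[["x_um", "y_um", "z_um"]].to_numpy(), label)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.xyz, columns=["x_um", "y_um", "z_um"]).assign(
            label=self.label
        ).to_csv(path, index=False)


@dataclass
class GxCurve:
    """Cumulative fraction of hypoxic-voxel-to-nearest-bead distances."""

    distance_um: np.ndarray
    fraction: np.ndarray
    n_voxels: int
    empty: bool = False

    def crossing(self, level: float) -> float:
        """First grid distance at which the curve reaches ``level``
        (NaN if never)."""
        ix = np.nonzero(self.fraction >= level)[0]
        return float(self.distance_um[ix[0]]) if len(ix) else float("nan")


@dataclass
class HypoxicIntensityCurve:
    radius_um: np.ndarray
    fraction: np.ndarray  # NaN where no in-domain voxel falls in the sphere
    centre_xyz: np.ndarray | None = None


def voxel_centers(shape, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    axes = [origin[i] + (np.arange(shape[i]) + 0.5) * spacing[i] for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def pixel_gx(
    hypoxic: np.ndarray,
    points: PointSet,
    domain: np.ndarray | None = None,
    baseline: np.ndarray | None = None,
    spacing=(15.0, 15.0, 15.0),
    origin=(0.0, 0.0, 0.0),
    bin_um: float = GX_BIN_UM,
    max_um: float = GX_MAX_UM,
) -> GxCurve:
    """Pixel-based Gx function on a voxel grid.

    Voxels outside the domain and voxels hypoxic at baseline (healthy
    state) are excluded; distances run from voxel centres to the nearest
    point, honouring anisotropic spacing.
    """
    if points.n == 0:
        raise ValueError("pixel_gx requires at least one point")
    hypoxic = np.asarray(hypoxic, dtype=bool)
    mask = hypoxic.copy()
    if domain is not None:
        mask &= np.asarray(domain, dtype=bool)
    if baseline is not None:
        mask &= ~np.asarray(baseline, dtype=bool)
    grid = np.arange(0.0, max_um + bin_um / 2, bin_um)
    if not mask.any():
        return GxCurve(grid, np.zeros_like(grid), 0, empty=True)
    centers = voxel_centers(mask.shape, spacing, origin)[mask.ravel()]
    d, _ = cKDTree(points.xyz).query(centers)
    frac = np.searchsorted(np.sort(d), grid, side="right") / len(d)
    return GxCurve(grid, frac, int(len(d)))


def gx_from_distances(distances, bin_um=GX_BIN_UM, max_um=GX_MAX_UM) -> GxCurve:
    """Gx curve from pooled nearest-bead distances."""
    d = np.sort(np.asarray(distances, dtype=float))
    grid = np.arange(0.0, max_um + bin_um / 2, bin_um)
    if len(d) == 0:
        return GxCurve(grid, np.zeros_like(grid), 0, empty=True)
    frac = np.searchsorted(d, grid, side="right") / len(d)
    return GxCurve(grid, frac, int(len(d)))


def nearest_point_distances(
    hypoxic, points: PointSet, domain=None, baseline=None,
    spacing=(15.0, 15.0, 15.0), origin=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Distances feeding the Gx curve (used for pooling across scenarios)."""
    if points.n == 0:
        raise ValueError("requires at least one point")
    mask = np.asarray(hypoxic, dtype=bool).copy()
    if domain is not None:
        mask &= np.asarray(domain, dtype=bool)
    if baseline is not None:
        mask &= ~np.asarray(baseline, dtype=bool)
    if not mask.any():
        return np.empty(0)
    centers = voxel_centers(mask.shape, spacing, origin)[mask.ravel()]
    d, _ = cKDTree(points.xyz).query(centers)
    return d


def hypoxic_intensity(
    hypoxic: np.ndarray,
    centre_xyz,
    domain: np.ndarray | None = None,
    spacing=(15.0, 15.0, 15.0),
    origin=(0.0, 0.0, 0.0),
    radii=INTENSITY_RADII,
) -> HypoxicIntensityCurve:
    """Hypoxic volume fraction in spheres around one microsphere.

    At each radius the fraction counts in-domain hypoxic voxel centres over
    all in-domain voxel centres within the sphere; radii whose sphere holds
    no in-domain voxel yield NaN (reported missing, not zero).
    """
    hypoxic = np.asarray(hypoxic, dtype=bool)
    dom = (np.ones_like(hypoxic, dtype=bool) if domain is None
           else np.asarray(domain, dtype=bool))
    centre = np.asarray(centre_xyz, dtype=float)
    centers = voxel_centers(hypoxic.shape, spacing, origin)
    d = np.linalg.norm(centers - centre, axis=1)
    radii = np.asarray(radii, dtype=float)
    frac = np.full(len(radii), np.nan)
    dom_flat = dom.ravel()
    hyp_flat = (hypoxic & dom).ravel()
    for i, r in enumerate(radii):
        inside = d <= r
        denom = int(np.count_nonzero(inside & dom_flat))
        if denom:
            frac[i] = np.count_nonzero(inside & hyp_flat) / denom
    return HypoxicIntensityCurve(radii, frac, centre)


def classify_intensity(curve: HypoxicIntensityCurve) -> tuple[str, str]:
    """(type, subtype) of a hypoxic-intensity curve.

    Type A: fraction falls from 50 to 100 um (or full hypoxia within
    100 um); type B: it rises (or no hypoxia within 100 um); an exact tie
    with partial hypoxia counts as B (the residual class).  Subtype is
    'local' iff any hypoxic voxel lies within 100 um.
    """
    radii = list(curve.radius_um)
    if 50.0 not in radii or 100.0 not in radii:
        raise ValueError("curve lacks the 50/100 um radii")
    f50 = curve.fraction[radii.index(50.0)]
    f100 = curve.fraction[radii.index(100.0)]
    if np.isnan(f50) or np.isnan(f100):
        raise ValueError("missing fraction at 50 or 100 um")
    local = "local" if f100 > 0 else "no-local"
    if f50 == 1.0 and f100 == 1.0:
        return "A", local
    if f50 == 0.0 and f100 == 0.0:
        return "B", local
    if f100 < f50:
        return "A", local
    return "B", local


@dataclass
class ColumnAggregate:
    gx: GxCurve
    intensity: HypoxicIntensityCurve
    type_counts: dict = field(default_factory=dict)


def aggregate_column(
    distances_per_scenario: list,
    intensity_curves: list,
    bin_um: float = GX_BIN_UM,
    max_um: float = GX_MAX_UM,
) -> ColumnAggregate:
    """Column-level aggregate over equally probable blockage scenarios.

    Gx pools every scenario's voxel-to-bead distances before forming the
    cumulative curve; the intensity is the unweighted mean of the scenario
    curves (NaN-aware); type counts tally the per-scenario classification.
    """
    if not intensity_curves:
        raise ValueError("no scenarios to aggregate")
    pooled = (np.concatenate([np.asarray(d, dtype=float) for d in distances_per_scenario])
              if distances_per_scenario else np.empty(0))
    gx = gx_from_distances(pooled, bin_um, max_um)
    radii = intensity_curves[0].radius_um
    stack = np.vstack([c.fraction for c in intensity_curves])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    counts: dict[str, int] = {}
    for c in intensity_curves:
        t, sub = classify_intensity(c)
        counts[t] = counts.get(t, 0) + 1
        counts[f"{t}/{sub}"] = counts.get(f"{t}/{sub}", 0) + 1
    return ColumnAggregate(
        gx=gx,
        intensity=HypoxicIntensityCurve(np.asarray(radii, dtype=float), mean),
        type_counts=counts,
    )


def monte_carlo_controls(
    domain: np.ndarray,
    density_per_mm3: float,
    n_replicates: int,
    seed: int,
    spacing=(15.0, 15.0, 15.0),
    origin=(0.0, 0.0, 0.0),
) -> list[PointSet]:
    """Uniform random control points over the in-domain voxels.

    The per-replicate count is round(density x in-domain volume); points
    land uniformly inside randomly chosen in-domain voxels.
    """
    if density_per_mm3 <= 0:
        raise ValueError("density must be positive")
    dom = np.asarray(domain, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    vol_mm3 = float(dom.sum()) * float(np.prod(spacing)) * 1e-9
    count = int(round(density_per_mm3 * vol_mm3))
    centers = voxel_centers(dom.shape, spacing, origin)[dom.ravel()]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        ix = rng.integers(0, len(centers), size=count)
        jitter = rng.uniform(-0.5, 0.5, size=(count, 3)) * spacing
        out.append(PointSet(centers[ix] + jitter, label="control"))
    return out


def curves_to_frame(curves: dict[str, GxCurve | HypoxicIntensityCurve]
                    ) -> pd.DataFrame:
    """Tidy long-format table of named curves (for CSV export)."""
    rows = []
    for name, c in curves.items():
        if isinstance(c, GxCurve):
            xs, ys, kind = c.distance_um, c.fraction, "gx"
        else:
            xs, ys, kind = c.radius_um, c.fraction, "intensity"
        for x, y in zip(xs, ys):
            rows.append({"curve": name, "kind": kind, "x_um": x, "value": y})
    return pd.DataFrame(rows)
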