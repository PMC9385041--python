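"""Experimental-style segmented data: ingestion and synthetic fixtures.

The imaging arm of the analysis works on binary maximum-intensity-
projection (MIP) masks of 50 um coronal sections at 3.033 um xy pixels,
exported per section, plus microsphere centre coordinates.  For the
distance analyses each section stack is downsampled to
15.165 x 15.165 x 50 um^3 voxels (5 x 5 pixel pooling), with each
section's content placed at its slab centre.

Because no real data ships with the package, a synthetic-experiment
generator plants hypoxia blobs at recorded displacements from beads
(plus optional unrelated background blobs) so the full pipeline is
testable against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .spatial import PointSet

DEFAULT_PIXEL_UM = 3.033
DEFAULT_SECTION_UM = 50.0
POOL = 5  # 5x5 pixel pooling -> 15.165 um analysis voxels


@dataclass
class SectionStack:
    """Ordered binary MIP sections plus tissue-domain masks.

    ``hypoxia`` and ``tissue`` are (n_sections, ny_px, nx_px) boolean
    arrays; section k's content sits at z = (k + 1/2) * section_um.
    """

    hypoxia: np.ndarray
    tissue: np.ndarray
    pixel_um: float = DEFAULT_PIXEL_UM
    section_um: float = DEFAULT_SECTION_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.hypoxia = np.asarray(self.hypoxia, dtype=bool)
        self.tissue = np.asarray(self.tissue, dtype=bool)
        if self.hypoxia.shape != self.tissue.shape:
            raise ValueError("hypoxia and tissue stacks differ in shape")
        if self.hypoxia.ndim != 3:
            raise ValueError("expected a (sections, y, x) stack")
        # pixels outside the tissue mask carry no signal
        dropped = int(np.count_nonzero(self.hypoxia & ~self.tissue))
        if dropped:
            self.meta["pixels_outside_tissue_dropped"] = dropped
            self.hypoxia &= self.tissue

    @property
    def n_sections(self) -> int:
        return self.hypoxia.shape[0]

    def z_centers(self) -> np.ndarray:
        return (np.arange(self.n_sections) + 0.5) * self.section_um

    # ---- IO ----------------------------------------------------------
    def write(self, directory: str | Path, prefix: str = "stack") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(directory / f"{prefix}_hypoxia.tif",
                         self.hypoxia.astype(np.uint8) * 255,
                         photometric="minisblack")
        tifffile.imwrite(directory / f"{prefix}_tissue.tif",
                         self.tissue.astype(np.uint8) * 255,
                         photometric="minisblack")
        header = {
            "schema": "cortox.sectionstack.v1",
            "pixel_um": self.pixel_um,
            "section_um": self.section_um,
            "n_sections": self.n_sections,
            "meta": self.meta,
        }
        (directory / f"{prefix}_header.json").write_text(json.dumps(header, indent=1))

    @classmethod
    def read(cls, directory: str | Path, prefix: str = "stack") -> "SectionStack":
        directory = Path(directory)
        header = json.loads((directory / f"{prefix}_header.json").read_text())
        hyp = tifffile.imread(directory / f"{prefix}_hypoxia.tif") > 0
        tis = tifffile.imread(directory / f"{prefix}_tissue.tif") > 0
        if hyp.ndim == 2:
            hyp = hyp[None]
            tis = tis[None]
        return cls(hyp, tis, header["pixel_um"], header["section_um"],
                   header.get("meta", {}))


def load_stack(hypoxia_files, tissue_files, pixel_um=DEFAULT_PIXEL_UM,
               section_um=DEFAULT_SECTION_UM) -> SectionStack:
    """Assemble a stack from per-section binary TIFF files (in z order)."""
    hyp = [tifffile.imread(f) > 0 for f in hypoxia_files]
    tis = [tifffile.imread(f) > 0 for f in tissue_files]
    shapes = {a.shape for a in hyp} | {a.shape for a in tis}
    if len(shapes) != 1:
        raise ValueError(f"sections differ in shape: {sorted(shapes)}")
    return SectionStack(np.stack(hyp), np.stack(tis), pixel_um, section_um)


def downsample_to_analysis_grid(stack: SectionStack, pool: int = POOL
                                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pool each section's pixels into analysis voxels.

    Returns (hypoxia mask, domain mask, spacing_um, origin_um) with arrays
    indexed (x, y, z) to match the simulation grids.  A voxel is hypoxic
    iff at least half of its in-tissue pixels are hypoxic; it belongs to
    the domain iff at least half of its block is tissue.  Trailing pixels
    that do not fill a block are discarded.
    """
    if pool <= 0 or int(pool) != pool:
        raise ValueError("pooling factor must be a positive integer")
    nz, ny, nx = stack.hypoxia.shape
    my, mx = ny // pool, nx // pool
    if my == 0 or mx == 0:
        raise ValueError("stack smaller than one pooling block")
    hyp = stack.hypoxia[:, : my * pool, : mx * pool].reshape(nz, my, pool, mx, pool)
    tis = stack.tissue[:, : my * pool, : mx * pool].reshape(nz, my, pool, mx, pool)
    tis_count = tis.sum(axis=(2, 4))
    hyp_count = (hyp & tis).sum(axis=(2, 4))
    domain = tis_count * 2 >= pool * pool
    with np.errstate(invalid="ignore"):
        hyp_vox = np.zeros_like(domain)
        nonzero = tis_count > 0
        hyp_vox[nonzero] = hyp_count[nonzero] * 2 >= tis_count[nonzero]
    hyp_vox &= domain
    # reorder (z, y, x) -> (x, y, z)
    hyp_xyz = np.transpose(hyp_vox, (2, 1, 0))
    dom_xyz = np.transpose(domain, (2, 1, 0))
    spacing = np.array([stack.pixel_um * pool, stack.pixel_um * pool,
                        stack.section_um])
    origin = np.zeros(3)
    return hyp_xyz, dom_xyz, spacing, origin


def load_beads(csv_path, domain=None, spacing=None, origin=(0, 0, 0)
               ) -> tuple[PointSet, pd.DataFrame]:
    """Bead centres from CSV (columns x_um, y_um, z_um).

    If a domain mask is given, out-of-domain beads are rejected and
    returned in the report frame.
    """
    df = pd.read_csv(csv_path)
    if len(df) == 0:
        return PointSet(np.empty((0, 3))), pd.DataFrame(columns=["x_um", "y_um", "z_um", "reason"])
    pts = df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if domain is None:
        return PointSet(pts), pd.DataFrame(columns=["x_um", "y_um", "z_um", "reason"])
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    idx = np.floor((pts - origin) / spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(domain.shape)), axis=1)
    inside = ok.copy()
    inside[ok] = domain[tuple(idx[ok].T)]
    rejected = df.loc[~inside].assign(reason="outside tissue domain")
    return PointSet(pts[inside]), rejected


# ----------------------------------------------------------------------
# synthetic experiment fixtures
@dataclass
class SyntheticExperimentSpec:
    """Ground-truth recipe for a synthetic segmented data set.

    Hypoxia blobs (spheres of ``blob_radius_um``) are planted at
    ``displacement_um`` from each bead, in a uniformly random in-plane
    direction; ``background_blobs`` additional blobs are unrelated to any
    bead.  ``displacement_um`` may be a scalar or a (low, high) range.
    """

    n_beads: int = 8
    field_um: float = 2000.0  # lateral extent of the tissue region
    n_sections: int = 10
    blob_radius_um: float = 24.0
    displacement_um: float | tuple = 300.0
    background_blobs: int = 0
    pixel_um: float = DEFAULT_PIXEL_UM
    section_um: float = DEFAULT_SECTION_UM
    tissue_margin_px: int = 4  # pixels shaved off the field edge


def generate_synthetic_experiment(
    spec: SyntheticExperimentSpec | None = None,
    seed: int = 0,
):
    """Synthetic bead/hypoxia data with a recorded truth.

    Returns (SectionStack, PointSet of beads, truth dict).  Bead z sits at
    a section centre so the planted in-plane displacement is exactly the
    voxel-measured bead-blob distance; blobs that would leave the tissue
    are clipped and logged in the truth record.
    """
    spec = spec or SyntheticExperimentSpec()
    rng = np.random.default_rng(seed)
    npx = int(round(spec.field_um / spec.pixel_um))
    tissue = np.zeros((spec.n_sections, npx, npx), dtype=bool)
    m = spec.tissue_margin_px
    tissue[:, m:-m, m:-m] = True
    hyp = np.zeros_like(tissue)

    margin = spec.blob_radius_um + 10.0
    lo = margin + m * spec.pixel_um
    hi = spec.field_um - lo
    if isinstance(spec.displacement_um, (tuple, list)):
        d_max = float(max(spec.displacement_um))
    else:
        d_max = float(spec.displacement_um)
    # beads keep displacement clearance from the edges so planted blobs
    # are never clipped by the field boundary
    lo_b, hi_b = lo + d_max, hi - d_max
    if lo_b >= hi_b:
        raise ValueError("field too small for the requested displacement")
    beads = np.column_stack([
        rng.uniform(lo_b, hi_b, spec.n_beads),
        rng.uniform(lo_b, hi_b, spec.n_beads),
        (rng.integers(0, spec.n_sections, spec.n_beads) + 0.5) * spec.section_um,
    ])

    yy, xx = np.mgrid[0:npx, 0:npx]
    px_x = (xx + 0.5) * spec.pixel_um
    px_y = (yy + 0.5) * spec.pixel_um

    def paint_blob(cx, cy, section, radius):
        disk = (px_x - cx) ** 2 + (px_y - cy) ** 2 <= radius**2
        clipped = int(np.count_nonzero(disk & ~tissue[section]))
        hyp[section] |= disk & tissue[section]
        return clipped

    truth = {"displacements_um": [], "bead_xyz_um": beads.tolist(),
             "clipped_px": 0, "background_xyz_um": []}
    for bx, by, bz in beads:
        if isinstance(spec.displacement_um, (tuple, list)):
            disp = rng.uniform(*spec.displacement_um)
        else:
            disp = float(spec.displacement_um)
        theta = rng.uniform(0, 2 * np.pi)
        cx, cy = bx + disp * np.cos(theta), by + disp * np.sin(theta)
        cx = float(np.clip(cx, lo, hi))
        cy = float(np.clip(cy, lo, hi))
        section = int(bz / spec.section_um)
        truth["clipped_px"] += paint_blob(cx, cy, section, spec.blob_radius_um)
        truth["displacements_um"].append(
            float(np.hypot(cx - bx, cy - by)))
    for _ in range(spec.background_blobs):
        cx, cy = rng.uniform(lo, hi, 2)
        section = int(rng.integers(0, spec.n_sections))
        truth["clipped_px"] += paint_blob(cx, cy, section, spec.blob_radius_um)
        truth["background_xyz_um"].append(
            [float(cx), float(cy), (section + 0.5) * spec.section_um])

    stack = SectionStack(hyp, tissue, spec.pixel_um, spec.section_um,
                         meta={"seed": int(seed), "synthetic": True})
    return stack, PointSet(beads), truth
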