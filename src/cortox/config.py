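"""Run configuration: YAML-backed parameter bundle for the pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .column import (BEAD_DIAMETER, BranchingSpec, COLUMN_BOX,
                     DEFAULT_CUBE_DENSITY, DiameterLaw)
from .flow import HemoParams
from .oxygen import OxyParams
from .spatial import GX_BIN_UM, GX_MAX_UM, INTENSITY_RADII


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the model's study conditions."""

    n_columns: int = 10
    seed: int = 0
    box_um: tuple = COLUMN_BOX
    cube_density: float = DEFAULT_CUBE_DENSITY
    diameter_law: DiameterLaw = field(default_factory=DiameterLaw)
    branching: BranchingSpec = field(default_factory=BranchingSpec)
    hemo: HemoParams = field(default_factory=HemoParams)
    oxy: OxyParams = field(default_factory=OxyParams)
    bead_diameter_um: float = BEAD_DIAMETER
    intensity_radii: tuple = INTENSITY_RADII
    gx_bin_um: float = GX_BIN_UM
    gx_max_um: float = GX_MAX_UM
    outdir: str = "cortox_out"

    def column_seeds(self):
        import numpy as np

        rng = np.random.default_rng(self.seed)
        return [int(s) for s in rng.integers(0, 2**31 - 1, size=self.n_columns)]

    # ---- YAML round trip ---------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "diameter_law" in kw and isinstance(kw["diameter_law"], dict):
            kw["diameter_law"] = DiameterLaw(**kw["diameter_law"])
        if "branching" in kw and isinstance(kw["branching"], dict):
            b = {k: tuple(v) if isinstance(v, list) else v
                 for k, v in kw["branching"].items()}
            kw["branching"] = BranchingSpec(**b)
        if "hemo" in kw and isinstance(kw["hemo"], dict):
            kw["hemo"] = HemoParams(**kw["hemo"])
        if "oxy" in kw and isinstance(kw["oxy"], dict):
            kw["oxy"] = OxyParams(**kw["oxy"])
        for name in ("box_um", "intensity_radii"):
            if name in kw and isinstance(kw[name], list):
                kw[name] = tuple(kw[name])
        return cls(**kw)
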