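"""Run configuration: one structured file drives the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .dlnm import CrossbasisSpec
from .simulate import SimConfig


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    crossbasis: CrossbasisSpec = field(default_factory=CrossbasisSpec)
    cr_threshold: float = 0.1
    outdir: str = "heatrisk-run"
    seed: int = None  # overrides sim.seed when given

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.sim.seed = int(self.seed)
        if self.cr_threshold < 0:
            raise ValueError("cr_threshold must be non-negative")

    def to_dict(self) -> dict:
        d = {"sim": asdict(self.sim), "crossbasis": asdict(self.crossbasis),
             "cr_threshold": self.cr_threshold, "outdir": self.outdir}
        d["sim"]["lag_kernel"] = np.asarray(self.sim.lag_kernel).tolist()
        for key in ("years", "season_months", "grid_shape"):
            d["sim"][key] = list(d["sim"][key])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim_d = dict(d.get("sim", {}))
        for key in ("years", "season_months", "grid_shape"):
            if key in sim_d:
                sim_d[key] = tuple(sim_d[key])
        if sim_d.get("lag_kernel") is not None:
            sim_d["lag_kernel"] = np.asarray(sim_d["lag_kernel"], dtype=float)
        known = {f.name for f in fields(SimConfig)}
        unknown = set(sim_d) - known
        if unknown:
            raise ValueError(f"unknown sim config fields: {sorted(unknown)}")
        return cls(
            sim=SimConfig(**sim_d),
            crossbasis=CrossbasisSpec(**d.get("crossbasis", {})),
            cr_threshold=float(d.get("cr_threshold", 0.1)),
            outdir=d.get("outdir", "heatrisk-run"),
            seed=d.get("seed"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
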