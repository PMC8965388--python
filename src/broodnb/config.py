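"""Run configuration: YAML-backed parameter blocks with paper-default values."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .mixture import MCMCSettings
from .qc import QCThresholds


@dataclass
class SibshipParams:
    error_rate: float = 0.001
    fs_threshold: float = 0.0
    hs_threshold: float = 5.0
    min_loci: int = 50
    bootstrap_B: int = 100
    run_length: str = "medium"    # medium: 2 refinement passes; long: 4
    compute_support: bool = False

    @property
    def max_passes(self) -> int:
        return {"medium": 2, "long": 4}.get(self.run_length, 2)


@dataclass
class MixtureParams:
    k_max: int = 10
    cutoff: float = 0.035
    birth_rate: float = 1.0
    min_n: int = 50               # below this, skip mixture models (single cohort)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)


@dataclass
class ReconcileParams:
    relatedness: str = "cluster"  # or "fullsib"
    length_bands: dict[int, tuple[float, float]] = field(default_factory=dict)
    events: list[dict] = field(default_factory=list)


@dataclass
class EffsizeParams:
    pcrit: float = 0.05
    bootstrap_B: int = 1000
    n_perm: int = 100


@dataclass
class RunConfig:
    vcf: str = ""
    individuals: str = ""
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    qc: QCThresholds = field(default_factory=QCThresholds)
    sibship: SibshipParams = field(default_factory=SibshipParams)
    mixture: MixtureParams = field(default_factory=MixtureParams)
    reconcile: ReconcileParams = field(default_factory=ReconcileParams)
    effsize: EffsizeParams = field(default_factory=EffsizeParams)

    def module_seeds(self) -> dict[str, int]:
        """Fan the global seed out deterministically to per-module seeds."""
        ss = np.random.SeedSequence(self.seed)
        names = ["panel", "sibship", "mixture", "effsize"]
        states = ss.generate_state(len(names))
        return {n: int(s) for n, s in zip(names, states)}

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("vcf", "individuals", "out_dir", "seed", "log_level"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "qc" in raw:
            cfg.qc = QCThresholds(**raw["qc"])
        if "sibship" in raw:
            cfg.sibship = SibshipParams(**raw["sibship"])
        if "mixture" in raw:
            block = dict(raw["mixture"])
            mc = block.pop("mcmc", None)
            cfg.mixture = MixtureParams(**block)
            if mc:
                cfg.mixture.mcmc = MCMCSettings(**mc)
        if "reconcile" in raw:
            block = dict(raw["reconcile"])
            bands = {int(k): tuple(v)
                     for k, v in (block.pop("length_bands", {}) or {}).items()}
            cfg.reconcile = ReconcileParams(length_bands=bands, **block)
        if "effsize" in raw:
            cfg.effsize = EffsizeParams(**raw["effsize"])
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
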