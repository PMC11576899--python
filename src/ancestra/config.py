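"""Run configuration: one home for every tunable, with YAML round-trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .demography import DemographyModel, Pulse
from .simulate import SimScenario

__all__ = ["RunConfig", "load_config", "save_config", "derive_seed"]


@dataclass
class RunConfig:
    """All pipeline tunables in one place.

    Thresholds follow the study defaults: full-sibling kinship window
    [0.177, 0.354], BH FDR 0.05, TAGR window 20 kb, at least 10 reference
    calls per ancestry per locus, and the WHG/EEF genome-wide covA pair as
    structure covariates (any pair spans the two degrees of freedom).
    """

    seed: int = 1
    out_dir: str = "results"
    min_calls: int = 10
    tau: float | None = None  # ascertainment threshold; None = h2/(2 n_causal)
    fdr_q: float = 0.05
    kinship_bounds: tuple = (0.177, 0.354)
    tagr_window_bp: int = 20_000
    gw_cova_pair: tuple = ("WHG", "EEF")
    scenario: dict = field(default_factory=dict)  # SimScenario overrides

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kinship_bounds"] = list(self.kinship_bounds)
        d["gw_cova_pair"] = list(self.gw_cova_pair)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def build_scenario(self, **overrides) -> SimScenario:
        params = dict(self.scenario)
        params.update(overrides)
        params.setdefault("seed", self.seed)
        scale = params.pop("scale", None)
        dem = params.pop("demography", None)
        if isinstance(dem, dict):
            pulses = dem.pop("pulses", None)
            if pulses is not None:
                dem["pulses"] = tuple(Pulse(*p) for p in pulses)
            params["demography"] = DemographyModel(**dem)
        elif dem is not None:
            params["demography"] = dem
        scen = SimScenario(**params)
        if scale:
            scen = scen.scaled(int(scale))
        return scen


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "kinship_bounds" in raw:
        raw["kinship_bounds"] = tuple(raw["kinship_bounds"])
    if "gw_cova_pair" in raw:
        raw["gw_cova_pair"] = tuple(raw["gw_cova_pair"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def derive_seed(master: int, stage: str, replicate: int = 0) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}:{replicate}".encode()).digest()
    return int(np.frombuffer(digest[:8], dtype=np.uint64)[0] % (2**31 - 1)) + 1
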