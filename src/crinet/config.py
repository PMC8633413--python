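"""Pipeline configuration and run manifests.

``PipelineConfig`` gathers every stage's tunable settings under one object
that round-trips losslessly through YAML or JSON; unknown keys are rejected
by name.  ``RunManifest`` records what a pipeline run produced so the run is
reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field

import yaml

from .errors import InvalidInputError


@dataclass
class SimulateConfig:
    n: int = 66
    p: int = 100
    h2: float = 0.05
    prop_testcross: float = 94591 / 156362
    causal_index: int = 0
    causal_segregation: str = "testcross"
    effect_fraction: float = 0.10
    t_start: float = 1.0
    t_end: float = 14.0


@dataclass
class MappingConfig:
    alpha: float = 0.05
    rk4_step: float = 0.01
    threshold_policy: str = "bonferroni"   # or "permutation"
    n_permutations: int = 100
    run_subtests: bool = False
    expected_frequencies: bool = False     # Mendelian instead of observed n_j/n


@dataclass
class ClusteringConfig:
    L_min: int = 1
    L_max: int = 6
    criterion: str = "BIC"
    lop_order: int = 4
    max_iter: int = 500
    tol: float = 1e-6
    n_restarts: int = 5


@dataclass
class NetworkConfig:
    smooth_order: int = 4
    decomp_order: int = 3
    n_dense: int = 100
    selector: str = "lasso_pr2"
    target: str = "derivative"
    pr2_threshold: float = 0.7
    max_in_degree: int | None = None
    weight_floor: float = 1e-8


@dataclass
class PowerConfig:
    sample_sizes: list = field(default_factory=lambda: [66, 100, 200])
    heritabilities: list = field(default_factory=lambda: [0.05, 0.1])
    replicates: int = 50
    p_markers: int = 100


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "crinet_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    power: PowerConfig = field(default_factory=PowerConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, val in data.items():
            if key not in sections:
                raise InvalidInputError(f"unknown configuration key {key!r}")
            f = sections[key]
            if dataclasses.is_dataclass(f.type) or f.name in (
                    "simulate", "mapping", "clustering", "network", "power"):
                sub_cls = {"simulate": SimulateConfig, "mapping": MappingConfig,
                           "clustering": ClusteringConfig,
                           "network": NetworkConfig,
                           "power": PowerConfig}[f.name]
                valid = {sf.name for sf in dataclasses.fields(sub_cls)}
                unknown = set(val) - valid
                if unknown:
                    raise InvalidInputError(
                        f"unknown configuration key {key}.{sorted(unknown)[0]!r}")
                kwargs[key] = sub_cls(**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            text = fh.read()
        if str(path).endswith(".json"):
            data = json.loads(text) if text.strip() else {}
        else:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise InvalidInputError("configuration must be a mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    stage: str
    config: dict
    version: str = "0.1.0"
    started: float = field(default_factory=time.time)
    finished: float | None = None
    outputs: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add_output(self, path) -> None:
        p = str(path)
        if p not in self.outputs:
            self.outputs.append(p)

    def close(self, path) -> None:
        self.finished = time.time()
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
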