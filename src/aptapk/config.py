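"""Run configuration: schema-validated YAML/JSON with a content hash.

Every pipeline run logs the fully resolved configuration and embeds its
hash plus the seed in output artifacts, so any result can be traced back
to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved settings for simulation, fitting and diagnostics.

    ``design`` and ``population`` hold keyword overrides for
    :class:`~aptapk.simulate.StudyDesign` and
    :class:`~aptapk.pk.PopPKParams.reference`; ``omega_cl`` and ``b`` are
    the generating between-animal SD (log CL) and residual SD (log scale).
    """

    structure: str = "two_compartment"
    bloq_policy: str = "discard"
    init: dict | None = None
    fix: dict | None = None
    optimizer_tol: float = 1e-8
    maxiter: int = 500
    seed: int = 0
    n_sim_vpc: int = 500
    n_sim_npde: int = 1000
    design: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    omega_cl: float = 0.2174
    b: float = 0.27

    def __post_init__(self) -> None:
        if self.structure not in ("one_compartment", "two_compartment",
                                  "one_cpt", "two_cpt"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.bloq_policy not in ("discard", "censored"):
            raise ValueError(f"unknown bloq_policy {self.bloq_policy!r}")
        if self.omega_cl < 0 or self.b < 0:
            raise ValueError("omega_cl and b must be non-negative")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) \
                else json.load(fh)
        raw = raw or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
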