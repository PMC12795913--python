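"""Study configuration: YAML round-trip, hashing, and seed derivation.

A :class:`RunConfig` bundles everything needed to reproduce a run: the
device, population, both procedure configurations, the study design,
the direct generative model, and the master seed.  Seeds are derived
hierarchically (master -> participant -> condition) via numpy
``SeedSequence`` spawning, so any single condition can be re-run in
isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Any, Dict, Optional

import yaml

from .bekesy import BekesyConfig
from .observer import LatencyModel, PopulationModel
from .staircase import StaircaseConfig
from .study import (
    CALIBRATED_CONDITION_MEANS,
    GenerativeLMMConfig,
    StudyDesign,
)
from .units import DeviceModel


@dataclass
class RunConfig:
    """Composite configuration for one reproducible run."""

    device: DeviceModel
    population: PopulationModel
    bekesy: BekesyConfig = field(default_factory=BekesyConfig)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    design: StudyDesign = field(default_factory=StudyDesign)
    generative: GenerativeLMMConfig = field(default_factory=GenerativeLMMConfig)
    seed: int = 0

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> Dict[str, Any]:
        d: Dict[str, Any] = {
            "device": asdict(self.device),
            "population": asdict(self.population),
            "bekesy": asdict(self.bekesy),
            "staircase": asdict(self.staircase),
            "design": asdict(self.design),
            "generative": asdict(self.generative),
            "seed": self.seed,
        }
        # mapping keys must be YAML/JSON-friendly
        d["population"]["condition_means"] = {
            f"{f}:{loc}": v for (f, loc), v in self.population.condition_means.items()
        }
        if self.device.ceiling_g is not None:
            d["device"]["ceiling_g"] = {str(k): v for k, v in self.device.ceiling_g.items()}
        d["device"].pop("constants", None)
        d["device"]["one_g"] = self.device.constants.one_g
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "RunConfig":
        from .units import UnitConstants

        dev = dict(d["device"])
        constants = UnitConstants(one_g=dev.pop("one_g", UnitConstants().one_g))
        if dev.get("ceiling_g") is not None:
            dev["ceiling_g"] = {float(k): float(v) for k, v in dev["ceiling_g"].items()}
        device = DeviceModel(constants=constants, **dev)

        pop = dict(d["population"])
        means = {}
        for key, v in pop.pop("condition_means").items():
            f, loc = key.split(":")
            means[(float(f), loc)] = float(v)
        latency = LatencyModel(**pop.pop("latency"))
        population = PopulationModel(condition_means=means, latency=latency, **pop)

        return cls(
            device=device,
            population=population,
            bekesy=BekesyConfig(**d.get("bekesy", {})),
            staircase=StaircaseConfig(**d.get("staircase", {})),
            design=StudyDesign(**{**d.get("design", {}),
                                  **({"frequencies": tuple(d["design"]["frequencies"]),
                                      "locations": tuple(d["design"]["locations"]),
                                      "methods": tuple(d["design"]["methods"])}
                                     if "design" in d else {})}),
            generative=GenerativeLMMConfig(**d.get("generative", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (incl. seed)."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # -- presets ----------------------------------------------------------
    @classmethod
    def default(cls, seed: int = 0) -> "RunConfig":
        """The study-calibrated preset: 30 participants, 6 conditions, 2 methods."""
        from .study import default_population, default_study_device

        return cls(
            device=default_study_device(),
            population=default_population(),
            seed=seed,
        )

    @classmethod
    def deterministic_demo(cls, seed: int = 0) -> "RunConfig":
        """Hand-traceable preset: step observers, identity-dB device, no latency."""
        from .observer import DETERMINISTIC_STEP
        from .units import identity_db_device

        pop = PopulationModel(
            condition_means={(250.0, "index"): 12.0},
            tau_between=0.0,
            form=DETERMINISTIC_STEP,
            guess_rate=0.0,
            lapse_rate=0.0,
            latency=LatencyModel(kind="zero"),
        )
        return cls(
            device=identity_db_device(),
            population=pop,
            design=StudyDesign(n_participants=1, frequencies=(250.0,),
                               locations=("index",), n_male=1),
            seed=seed,
        )


def spawn_condition_seed(master_seed: int, participant_index: int, condition_index: int):
    """Derive an isolated SeedSequence for one participant-condition cell."""
    import numpy as np

    return np.random.SeedSequence(master_seed,
                                  spawn_key=(participant_index, condition_index))


__all__ = ["RunConfig", "spawn_condition_seed", "CALIBRATED_CONDITION_MEANS"]
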