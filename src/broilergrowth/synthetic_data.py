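"""Seeded simulator of flock weighing data, plus packaged reference fixtures.

The simulator emulates the study design behind the reference dataset: a
flock of male broilers weighed weekly from hatch (week 0) through week 6.
Each bird follows a smooth sigmoidal trajectory from one of the five growth
families; biological heterogeneity enters through a per-bird asymptotic
weight ``A_i = A (1 + asymptote_cv * z_i)``, and each weighing carries
multiplicative measurement noise ``(1 + noise_cv * eps)`` — constant-CV
error is the realistic default when weights span ~50 g to ~2200 g. Weights
are truncated below at 1 g so extreme noise draws at hatch cannot produce a
nonpositive weight. An additive-noise variant (fixed SD in grams) is
available for textbook OLS recovery experiments.

Only the seven observed weekly mean weights of the study flock are published;
they ship here as a packaged fixture together with the study's reported
growth-model parameters and its printed hinge-spline model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .fitting import GrowthDataset, GrowthRecord
from .growth_models import ModelFamily, ModelParameters, evaluate
from .mars import MarsModel

__all__ = [
    "SimulationScenario",
    "simulate",
    "table3_observed",
    "table1_parameters",
    "printed_mars_model",
]

#: Floor applied to every simulated weight (g).
MIN_WEIGHT_G = 1.0


@dataclass(frozen=True)
class SimulationScenario:
    """Everything needed to regenerate one synthetic flock, reproducibly.

    Parameters
    ----------
    params
        Mean-trajectory parameters (the family travels with them).
    n_birds
        Flock size (>= 1).
    ages
        Weighing ages in weeks, sorted, non-negative.
    asymptote_cv
        Relative SD of the per-bird asymptote ``A_i`` (0 = identical birds).
    noise_cv
        Relative SD of multiplicative measurement error per weighing.
    seed
        Seed of the generator; identical scenarios produce identical data.
    additive_sd_g
        When set, replaces the multiplicative noise with additive Gaussian
        noise of this SD in grams (``noise_cv`` is then ignored).
    """

    params: ModelParameters
    n_birds: int = 192
    ages: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    asymptote_cv: float = 0.08
    noise_cv: float = 0.05
    seed: int = 0
    additive_sd_g: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", tuple(float(a) for a in self.ages))
        if self.n_birds < 1:
            raise ValueError("n_birds must be >= 1")
        if self.asymptote_cv < 0 or self.noise_cv < 0:
            raise ValueError("asymptote_cv and noise_cv must be >= 0")
        if any(a < 0 for a in self.ages) or list(self.ages) != sorted(self.ages):
            raise ValueError("ages must be sorted and non-negative")

    @property
    def family(self) -> ModelFamily:
        return self.params.family

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "n_birds": self.n_birds,
            "ages": list(self.ages),
            "asymptote_cv": self.asymptote_cv,
            "noise_cv": self.noise_cv,
            "seed": self.seed,
            "additive_sd_g": self.additive_sd_g,
        }

    @classmethod
    def from_dict(cls, doc) -> "SimulationScenario":
        return cls(
            params=ModelParameters.from_dict(doc["params"]),
            n_birds=int(doc.get("n_birds", 192)),
            ages=tuple(doc.get("ages", (0, 1, 2, 3, 4, 5, 6))),
            asymptote_cv=float(doc.get("asymptote_cv", 0.08)),
            noise_cv=float(doc.get("noise_cv", 0.05)),
            seed=int(doc.get("seed", 0)),
            additive_sd_g=doc.get("additive_sd_g"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationScenario":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def simulate(scenario: SimulationScenario) -> GrowthDataset:
    """Generate one flock dataset; a pure function of the scenario."""
    rng = np.random.default_rng(scenario.seed)
    ages = np.asarray(scenario.ages)
    records = []
    width = len(str(scenario.n_birds))
    for i in range(scenario.n_birds):
        a_i = scenario.params.A * (1.0 + scenario.asymptote_cv * rng.standard_normal())
        a_i = max(a_i, 1e-6 * scenario.params.A)
        curve = np.asarray(
            evaluate(dataclasses.replace(scenario.params, A=a_i), ages), dtype=float
        )
        eps = rng.standard_normal(ages.size)
        if scenario.additive_sd_g is not None:
            w = curve + scenario.additive_sd_g * eps
        else:
            w = curve * (1.0 + scenario.noise_cv * eps)
        w = np.maximum(w, MIN_WEIGHT_G)
        bird = f"bird_{i + 1:0{width}d}"
        records.extend(GrowthRecord(bird, float(t), float(v)) for t, v in zip(ages, w))
    return GrowthDataset(
        records=tuple(records),
        label=f"simulated {scenario.family.value} flock (seed={scenario.seed})",
    )


def _data_path(name: str):
    return resources.files("broilergrowth.data").joinpath(name)


def table3_observed() -> GrowthDataset:
    """The seven observed weekly mean weights of the study flock (g)."""
    with resources.as_file(_data_path("table3_observed.csv")) as path:
        return GrowthDataset.from_csv(path, label="observed weekly means")


def table1_parameters() -> dict[ModelFamily, ModelParameters]:
    """The study's reported growth-model parameters, keyed by family.

    These are evaluation inputs (the per-bird data they were estimated from
    is unpublished), useful for computing curves, inflection points and
    prediction columns.
    """
    doc = json.loads(_data_path("table1_parameters.json").read_text())
    return {ModelFamily(name): ModelParameters.from_dict(p) for name, p in doc.items()}


def printed_mars_model() -> MarsModel:
    """The study's printed hinge-spline model for weight vs age."""
    return MarsModel.from_dict(json.loads(_data_path("mars_printed_model.json").read_text()))
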