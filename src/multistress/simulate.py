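"""Synthetic full-factorial multi-stressor acute-toxicity experiments.

The generator emulates the laboratory design of the motivating *Gammarus
pulex* study: nine clothianidin concentrations (0, 0.01, 0.1, 1, 10, 100,
215, 465, 1000 µg/L) x three prochloraz levels (0, 1, 10 µg/L) x three
temperatures (16, 19, 22 °C) x two population classes.  Each class pools
several stream populations (four reference and eight agricultural by
default) contributing twelve animals per treatment each, split over three
replicate vessels of four — so class-level curves rest on 48 and 96
animals per treatment, as when survival is averaged per group across
streams.  Each treatment's
expected survival follows the forward stress addition model: the
population's log-logistic clothianidin curve is converted to General-Stress,
the configured true stresses of prochloraz, warming and (for agricultural
populations under co-stress) adaptation cost are added, and the sum is
transformed back to survival.  Immobile counts are binomial.

The configured true curves and stresses are returned as a ground-truth
sidecar so that recovery tests can compare estimates against them.  They
are fixture choices for a realistic experiment, not estimates of any real
population's latent parameters.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from typing import Mapping

import numpy as np
import pandas as pd

from .doseresponse import ll5_effect
from .exceptions import ValidationError
from .sam import StressCapacityDistribution

DEFAULT_DOSES = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0, 215.0, 465.0, 1000.0)
DEFAULT_PROCHLORAZ = (0.0, 1.0, 10.0)
DEFAULT_TEMPERATURES = (16.0, 19.0, 22.0)


@dataclasses.dataclass
class PopulationTruth:
    """True clothianidin curve of one population class at 16 °C."""

    ec50: float
    slope_b: float = 2.0
    lower_c: float = 0.02
    upper_d: float = 1.0
    asymmetry_f: float = 1.0


@dataclasses.dataclass
class SyntheticConfig:
    """Complete description of a simulated experiment.

    True stress magnitudes are chosen so that a default run spans the weak-
    to-strong synergism range seen in comparable laboratory studies; they
    are design fixtures, labelled as such in the sidecar.
    """

    doses: tuple = DEFAULT_DOSES
    prochloraz_levels: tuple = DEFAULT_PROCHLORAZ
    temperatures: tuple = DEFAULT_TEMPERATURES
    populations: Mapping[str, PopulationTruth] = dataclasses.field(
        default_factory=lambda: {
            "reference": PopulationTruth(ec50=67.0),
            "agricultural": PopulationTruth(ec50=148.0),
        })
    stress_prochloraz: Mapping[float, float] = dataclasses.field(
        default_factory=lambda: {0.0: 0.0, 1.0: 0.04, 10.0: 0.10})
    stress_temperature: Mapping[float, float] = dataclasses.field(
        default_factory=lambda: {16.0: 0.0, 19.0: 0.15, 22.0: 0.18})
    stress_adaptation: float = 0.07
    n_per_treatment: int = 12
    n_replicates: int = 3
    n_streams: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"reference": 4, "agricultural": 8})
    capacity_alpha: float = 3.2
    capacity_beta: float = 3.2
    seed: int = 0

    def __post_init__(self):
        if self.n_per_treatment < 1 or self.n_replicates < 1:
            raise ValidationError("n_per_treatment and n_replicates must be >= 1")
        if self.n_per_treatment % self.n_replicates:
            raise ValidationError(
                "n_per_treatment must divide evenly into n_replicates vessels")
        for level, s in {**self.stress_prochloraz, **self.stress_temperature}.items():
            if s < 0:
                raise ValidationError(f"true stress for level {level} must be >= 0")
        if self.stress_adaptation < 0:
            raise ValidationError("stress_adaptation must be >= 0")
        for name, pop in self.populations.items():
            if pop.ec50 <= 0:
                raise ValidationError(f"population {name}: ec50 must be > 0")
            if self.n_streams.get(name, 1) < 1:
                raise ValidationError(f"n_streams for {name} must be >= 1")
        missing = set(self.prochloraz_levels) - set(self.stress_prochloraz)
        if missing:
            raise ValidationError(
                f"no true prochloraz stress configured for level(s) {sorted(missing)}")
        missing = set(self.temperatures) - set(self.stress_temperature)
        if missing:
            raise ValidationError(
                f"no true temperature stress configured for {sorted(missing)}")

    @property
    def capacity(self) -> StressCapacityDistribution:
        return StressCapacityDistribution(self.capacity_alpha, self.capacity_beta)


def expected_survival(config: SyntheticConfig, population: str,
                      temperature: float, prochloraz: float, dose) -> np.ndarray:
    """Closed-form forward-model survival for one cell (no sampling).

    Reduces exactly to the bare log-logistic survival when all configured
    stresses are zero.
    """
    pop = config.populations[population]
    dist = config.capacity
    surv_tox = 1.0 - ll5_effect(dose, pop.slope_b, pop.lower_c, pop.upper_d,
                                pop.ec50, pop.asymmetry_f)
    s_env = (config.stress_prochloraz[prochloraz]
             + config.stress_temperature[temperature])
    co_stressed = prochloraz > 0 or temperature > min(config.temperatures)
    if population == "agricultural" and co_stressed:
        s_env += config.stress_adaptation
    return dist.survival(dist.stress(surv_tox) + s_env)


def _cell_rng(seed: int, key: str) -> np.random.Generator:
    """Independent substream per cell, stable under grid changes: the cell
    key is hashed so adding a condition does not shift other cells' draws."""
    digest = zlib.crc32(key.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


def generate_experiment(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate the full factorial and return (trial table, ground truth).

    The table has one row per stream population and replicate vessel;
    identical seeds give identical tables.  The sidecar carries the true
    curves, stresses and closed-form expected survival per treatment.
    """
    per_rep = config.n_per_treatment // config.n_replicates
    rows = []
    truth_cells = []
    for population in config.populations:
        streams = config.n_streams.get(population, 1)
        for temp in config.temperatures:
            for proch in config.prochloraz_levels:
                for dose in config.doses:
                    surv = float(expected_survival(config, population, temp,
                                                   proch, dose))
                    p_immobile = 1.0 - surv
                    for stream in range(1, streams + 1):
                        rng = _cell_rng(
                            config.seed,
                            f"{population}|{stream}|{temp}|{proch}|{dose}")
                        ks = rng.binomial(per_rep, p_immobile,
                                          size=config.n_replicates)
                        for rep, k in enumerate(ks, start=1):
                            rows.append({
                                "clothianidin_conc": dose,
                                "prochloraz_conc": proch,
                                "temperature": temp,
                                "population": population,
                                "n_exposed": per_rep,
                                "n_immobile": int(k),
                                "stream": stream,
                                "replicate": rep,
                                "duration_h": 48,
                            })
                    truth_cells.append({
                        "population": population, "temperature": temp,
                        "prochloraz": proch, "dose": dose,
                        "expected_survival": surv,
                    })
    table = pd.DataFrame(rows)
    truth = {
        "note": "synthetic ground truth (design fixture, not field estimates)",
        "populations": {k: dataclasses.asdict(v)
                        for k, v in config.populations.items()},
        "stress_prochloraz": dict(config.stress_prochloraz),
        "stress_temperature": dict(config.stress_temperature),
        "stress_adaptation": config.stress_adaptation,
        "n_streams": dict(config.n_streams),
        "capacity": {"alpha": config.capacity_alpha, "beta": config.capacity_beta},
        "seed": config.seed,
        "expected_survival": truth_cells,
    }
    return table, truth


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def generate_site_table(n_sites: int, tu_range=(-4.8, -0.8), noise_sd: float = 0.05,
                        seed: int = 0, slope: float = -0.12,
                        intercept: float = 0.2) -> pd.DataFrame:
    """Synthetic site table of (log TU_max, community index) pairs.

    The community index is linear in log TU plus Gaussian noise — a fixture
    for the generic site-level regression utility.
    """
    if n_sites < 3:
        raise ValidationError("need at least 3 sites")
    rng = np.random.default_rng(seed)
    tu = np.sort(rng.uniform(*tu_range, size=n_sites))
    index = intercept + slope * tu + rng.normal(0.0, noise_sd, size=n_sites)
    return pd.DataFrame({"site_id": [f"S{i:02d}" for i in range(n_sites)],
                         "log_tu_max": tu, "community_index": index})
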