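"""Synthetic ground-truth scenarios for end-to-end testing.

Real long-term lake monitoring series of the kind this tool targets are not
redistributable, so every other module is exercised on synthetic data whose
shape mimics them: a deterministic process-based truth simulated on a dense
daily grid, observation-level Gaussian noise (standard deviation expressed
as a fraction of the trajectory's standard deviation), smooth periodic
exogenous forcings, and contiguous train / validation / test splits in
temporal order (year-like splits for the aquatic scenario).

Two ready-made scenario families are provided:

* :func:`make_predator_prey` — the two-population oscillatory system from
  the packaged Predator-Prey library, observed on both state variables;
* :func:`make_aquatic_style` — a single-ODE phytoplankton-biomass system
  driven by temperature-like and light-like sinusoidal forcings with a
  365-day period, sampled daily over one simulated year per split.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import TimeSeriesDataset, Trajectory, simulate
from .knowledge_library import Library, parse_library
from .model_space import (
    IncompleteModel,
    compile_to_odes,
    enumerate_structures,
    parse_incomplete_model,
)


class ScenarioError(ValueError):
    pass


def packaged_text(name: str) -> str:
    return importlib.resources.files("pbme.data").joinpath(name).read_text()


@dataclass
class SyntheticScenario:
    """A ground-truth model plus observation and split settings."""

    incomplete: IncompleteModel
    true_structure: str  # structure key, e.g. "growth=ExponentialGrowth;..."
    true_params: dict[str, float]
    init: dict[str, float]
    t_start: float = 0.0
    t_stop: float = 100.0
    step: float = 1.0  # sampling step in days
    noise_sigma: float = 0.05  # fraction of the trajectory's std dev
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    forcings: dict[str, object] = field(default_factory=dict)  # name -> f(t)
    obs_clip: tuple[float, float] | None = None  # detection-limit clipping

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ScenarioError("noise_sigma must be >= 0")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9 or any(f <= 0 for f in self.split_fractions):
            raise ScenarioError("split fractions must be positive and sum to 1")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_stop + self.step / 2, self.step)


@dataclass
class SyntheticData:
    """Generated observations plus the stored truth for recovery tests."""

    scenario: SyntheticScenario
    splits: dict[str, TimeSeriesDataset]  # train / validation / test
    truth: Trajectory  # noiseless simulation on the full grid

    def __getitem__(self, role: str) -> TimeSeriesDataset:
        return self.splits[role]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for role, ds in self.splits.items():
            ds.to_csv(out / f"{role}.csv")
        manifest = {
            "true_structure": self.scenario.true_structure,
            "true_params": self.scenario.true_params,
            "init": self.scenario.init,
            "noise_sigma": self.scenario.noise_sigma,
            "seed": self.scenario.seed,
        }
        (out / "truth.json").write_text(json.dumps(manifest, indent=2) + "\n")


def generate(sc: SyntheticScenario, lib: Library) -> SyntheticData:
    """Simulate the truth, add seeded observation noise, emit labeled splits."""
    structures = {s.key: s for s in enumerate_structures(lib, sc.incomplete)}
    if sc.true_structure not in structures:
        raise ScenarioError(
            f"true structure {sc.true_structure!r} is not in the candidate space "
            f"({sorted(structures)})"
        )
    system = compile_to_odes(lib, structures[sc.true_structure])
    times = sc.times

    frame = pd.DataFrame({"t": times})
    for name in system.exog_vars:
        if name not in sc.forcings:
            raise ScenarioError(f"no forcing provided for exogenous variable {name!r}")
        frame[name] = np.asarray([sc.forcings[name](t) for t in times], dtype=float)
    carrier = TimeSeriesDataset(frame.copy(), endogenous=(), exogenous=tuple(system.exog_vars))

    truth = simulate(system, sc.true_params, carrier, init=sc.init)
    if not truth.ok:
        raise ScenarioError("truth simulation failed; adjust the scenario")

    rng = np.random.default_rng(sc.seed)
    for v in system.state_vars:
        clean = truth[v]
        sigma = sc.noise_sigma * float(np.std(clean))
        noisy = clean + rng.normal(0.0, sigma, size=len(times)) if sigma > 0 else clean
        if sc.obs_clip is not None and sigma > 0:
            noisy = np.clip(noisy, *sc.obs_clip)
        frame[v] = noisy

    n = len(times)
    n_train = int(round(sc.split_fractions[0] * n))
    n_val = int(round(sc.split_fractions[1] * n))
    edges = [0, n_train, n_train + n_val, n]
    splits = {}
    for role, lo, hi in zip(("train", "validation", "test"), edges[:-1], edges[1:]):
        splits[role] = TimeSeriesDataset(
            frame.iloc[lo:hi].reset_index(drop=True),
            endogenous=tuple(system.state_vars),
            exogenous=tuple(system.exog_vars),
            role=role,
        )
    return SyntheticData(sc, splits, truth)


# ---------------------------------------------------------------------------
# predator-prey scenario (two coupled state variables, no forcings)
# ---------------------------------------------------------------------------

PREDATOR_PREY_TRUTH = "growth=ExponentialGrowth;predator_prey=UnsaturatedPP;decay=Decay"
PREDATOR_PREY_PARAMS = {
    "growth.gR": 0.8,
    "predator_prey.iR": 0.4,
    "predator_prey.eF": 0.5,
    "decay.dR": 0.6,
}


def make_predator_prey(seed: int = 0, noise_sigma: float = 0.05) -> tuple[Library, SyntheticScenario]:
    """Oscillatory two-population scenario on the packaged library.

    The truth is the exponential-growth / unsaturated-interaction candidate
    with in-range parameters around a stable cycle (prey equilibrium 3,
    predator equilibrium 2), observed daily over 100 days.
    """
    lib = parse_library(packaged_text("predator_prey.pbl"))
    inc = parse_incomplete_model(packaged_text("predator_prey.pbm"))
    sc = SyntheticScenario(
        incomplete=inc,
        true_structure=PREDATOR_PREY_TRUTH,
        true_params=dict(PREDATOR_PREY_PARAMS),
        init={"prey.d": 3.5, "predator.d": 1.5},
        t_start=0.0,
        t_stop=100.0,
        step=1.0,
        noise_sigma=noise_sigma,
        split_fractions=(0.6, 0.2, 0.2),
        seed=seed,
    )
    return lib, sc


# ---------------------------------------------------------------------------
# aquatic-style scenario (single ODE + two seasonal forcings)
# ---------------------------------------------------------------------------

AQUATIC_LIBRARY = """
template entity Phytoplankton {
  vars: biomass {aggregation: sum, unit: "mg/l", range: <0, 100>};
}
template entity EnvironmentalFactor {
  vars: level {aggregation: sum, unit: "", range: <0, 50>};
}
template process Growth(p: Phytoplankton, temp: EnvironmentalFactor, light: EnvironmentalFactor) {
  consts: maxGrowth {range: <0, 2>};
}
template process UnlimitedGrowth : Growth {
  equations: td(p.biomass) = maxGrowth * 0.05 * temp.level * light.level * p.biomass;
}
template process LimitedGrowth : Growth {
  consts: capacity {range: <1, 100>};
  equations: td(p.biomass) = maxGrowth * 0.05 * temp.level * light.level * p.biomass * (1 - p.biomass / capacity);
}
template process Loss(p: Phytoplankton, temp: EnvironmentalFactor) {
  consts: lossRate {range: <0, 2>};
}
template process LinearLoss : Loss {
  equations: td(p.biomass) = -lossRate * p.biomass;
}
template process TemperatureLoss : Loss {
  equations: td(p.biomass) = -lossRate * 0.05 * temp.level * p.biomass;
}
"""

AQUATIC_INCOMPLETE = """
incomplete model AquaticPhytoplankton {
  entity phyto : Phytoplankton;
  entity temp : EnvironmentalFactor exogenous;
  entity light : EnvironmentalFactor exogenous;
  process growth : Growth(p = phyto, temp = temp, light = light);
  process loss : Loss(p = phyto, temp = temp);
}
"""

AQUATIC_TRUTH = "growth=LimitedGrowth;loss=TemperatureLoss"
AQUATIC_PARAMS = {"growth.maxGrowth": 0.8, "growth.capacity": 40.0, "loss.lossRate": 0.3}
YEAR = 365.0


def _temperature(t: float) -> float:
    """Water temperature (deg C), peaking in late July."""
    return 12.0 + 8.0 * np.sin(2 * np.pi * (t - 110.0) / YEAR)


def _light(t: float) -> float:
    """Normalized global solar radiation, peaking near the solstice.

    The winter floor of 0.2 keeps a background biomass over winter, as real
    lakes retain a residual phytoplankton stock year-round.
    """
    return 0.575 + 0.375 * np.sin(2 * np.pi * (t - 80.0) / YEAR)


def make_aquatic_style(seed: int = 0, noise_sigma: float = 0.05) -> tuple[Library, SyntheticScenario]:
    """Single-ODE phytoplankton scenario with seasonal forcings.

    One endogenous variable (phytoplankton biomass) governed by one of four
    candidate growth/loss structure combinations, driven by temperature-like
    and light-like sinusoids with a 365-day period, sampled daily over three
    simulated years: one year each for training, validation and testing.
    """
    lib = parse_library(AQUATIC_LIBRARY)
    inc = parse_incomplete_model(AQUATIC_INCOMPLETE)
    sc = SyntheticScenario(
        incomplete=inc,
        true_structure=AQUATIC_TRUTH,
        true_params=dict(AQUATIC_PARAMS),
        init={"phyto.biomass": 2.0},
        t_start=0.0,
        t_stop=3 * YEAR - 1,
        step=1.0,
        noise_sigma=noise_sigma,
        split_fractions=(1 / 3, 1 / 3, 1 / 3),
        seed=seed,
        forcings={"temp.level": _temperature, "light.level": _light},
        # winter biomass sits near zero; measurements below the instrument's
        # detection limit are reported at the limit, never negative
        obs_clip=(0.05, 100.0),
    )
    return lib, sc
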