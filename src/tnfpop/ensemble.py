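"""Heterogeneous cell populations and ground-truth validation fixtures.

Cell-to-cell variability is modeled deterministically: each cell of the
ensemble is the nominal ODE model with every distributed protein production
rate scaled by an independently drawn lognormal multiplier.  The lognormal
spread parameter defaults to σ = 0.148 on the natural-log scale, and the
distribution's location is shifted so that the multiplier's MEAN is exactly
one (μ_log = −σ²/2), i.e. the population averages to the nominal cell.  A
median-centered convention (μ_log = 0) and a log10 reading of σ are
available as switches; at σ = 0.148 the two centerings differ by ~1%.

The module also builds the toy fixtures used to validate the estimators
without the full signaling model: a death-timer network with a closed-form
time of death (elasticity exactly −1), a synthetic receptor/inhibitor
network, and a regression-stage dataset generator with known slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import Reaction, ReactionNetwork, Species

__all__ = [
    "CellParameterSet",
    "EnsembleSpec",
    "sample_population",
    "population_frame",
    "population_from_frame",
    "make_toy_timer",
    "make_toy_receptor_model",
    "generate_tod_dataset",
]


@dataclass(frozen=True)
class CellParameterSet:
    """Per-cell multipliers of the distributed production rates.

    Multipliers are dimensionless and relative to the nominal value; the
    nominal cell is the all-ones multiplier set.
    """

    multipliers: dict[str, float]

    def __post_init__(self):
        bad = {k: v for k, v in self.multipliers.items() if not v > 0}
        if bad:
            raise ValueError(f"multipliers must be > 0, got {bad}")

    @classmethod
    def nominal(cls, parameter_ids) -> "CellParameterSet":
        return cls({pid: 1.0 for pid in parameter_ids})

    def __getitem__(self, pid: str) -> float:
        return self.multipliers[pid]


@dataclass(frozen=True)
class EnsembleSpec:
    """Configuration of one heterogeneous population.

    ``sigma`` is the standard deviation of the log-multiplier (natural log
    by default).  ``centering`` selects where the lognormal is anchored:
    "mean" keeps the multiplier's expected value at 1, "median" keeps its
    median at 1.
    """

    n_cells: int = 2500
    sigma: float = 0.148
    seed: int = 0
    distributed_ids: tuple[str, ...] = ()
    centering: str = "mean"
    log_base: str = "e"  # "e" or "10": the scale on which sigma is read

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.centering not in ("mean", "median"):
            raise ValueError("centering must be 'mean' or 'median'")
        if self.log_base not in ("e", "10"):
            raise ValueError("log_base must be 'e' or '10'")

    @property
    def sigma_ln(self) -> float:
        """sigma expressed on the natural-log scale."""
        return self.sigma if self.log_base == "e" else self.sigma * math.log(10)


def sample_population(spec: EnsembleSpec) -> list[CellParameterSet]:
    """Draw a reproducible lognormal population of cell parameter sets.

    One RNG stream per population; draws are laid out cell-major with
    parameters in ``distributed_ids`` order, so the sample is independent of
    any execution parallelism downstream.
    """
    ids = list(spec.distributed_ids)
    if not ids:
        raise ValueError("spec.distributed_ids is empty: nothing to distribute")
    sigma = spec.sigma_ln
    mu = -0.5 * sigma**2 if spec.centering == "mean" else 0.0
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_cells, len(ids)))
    mult = np.exp(mu + sigma * z)
    return [
        CellParameterSet(dict(zip(ids, row))) for row in mult
    ]


def population_frame(population: list[CellParameterSet]) -> pd.DataFrame:
    """One row per cell, one column per distributed parameter id."""
    if not population:
        return pd.DataFrame()
    ids = list(population[0].multipliers)
    frame = pd.DataFrame(
        [[c.multipliers[pid] for pid in ids] for c in population], columns=ids
    )
    frame.index.name = "cell_index"
    return frame


def population_from_frame(frame: pd.DataFrame) -> list[CellParameterSet]:
    return [CellParameterSet(dict(zip(frame.columns, row))) for row in frame.to_numpy()]


# ---------------------------------------------------------------------------
# toy fixtures
# ---------------------------------------------------------------------------


def make_toy_timer(k: float = 1.0, theta: float = 5.0, with_inert: bool = False) -> ReactionNetwork:
    """One-species death timer: dX/dt = k, death when X reaches theta.

    The closed-form time of death is theta / (m·k) for a production
    multiplier m, so the log-log elasticity of the time of death with
    respect to the production rate is exactly −1 — the ground truth against
    which the population and nominal sensitivity estimators are validated.

    With ``with_inert`` a second, decoupled production reaction (species Y,
    rate k_y) is added whose multiplier has no influence on the time of
    death: a zero-slope control parameter.
    """
    if k <= 0 or theta <= 0:
        raise ValueError("k and theta must be > 0")
    species = [Species("X", "death marker", 0.0, "cell")]
    reactions = [Reaction("prod_X", "production of X", {}, {"X": 1}, "k_x")]
    parameters = {"k_x": float(k)}
    if with_inert:
        species.append(Species("Y", "inert bystander", 0.0, "cell"))
        reactions.append(Reaction("prod_Y", "production of Y", {}, {"Y": 1}, "k_y"))
        parameters["k_y"] = 1.0
    net = ReactionNetwork(
        species=species,
        reactions=reactions,
        parameters=parameters,
        compartments={"cell": 1.0},
        production_rate_ids=["k_x"] + (["k_y"] if with_inert else []),
        metadata={
            "death_readout": {"type": "species_threshold", "species": "X", "threshold": float(theta)},
            "needs_equilibration": False,
            "time_unit": "hour",
        },
    )
    net.validate()
    return net


def make_toy_receptor_model(
    k_on: float = 10.0,
    k_off: float = 1.0,
    r_total: float = 1.0,
    k_x: float = 1.0,
    k_i: float = 1.0,
    d_i: float = 1.0,
    k_q: float = 1.0,
    theta: float = 0.35,
    tnf_units_per_ng_ml: float = 0.1,
) -> ReactionNetwork:
    """Synthetic receptor/inhibitor network for protocol- and knockout-level tests.

    A deliberately small stand-in (built and labelled synthetic) with the
    qualitative anatomy of the TNF-R1 system: ligand binds a receptor
    (TNF + R -> C, reversible), the complex drives production of a death
    marker X, and a constitutively produced protector Inh clears X.  Death
    is declared when X reaches ``theta``.

    Distributed production rates: ``k_x`` (pro-death, negative time-of-death
    elasticity) and ``k_i`` (protective, positive elasticity).  Knocking out
    ``prod_Inh`` removes the survival arm — the analogue of the NF-κB
    knockout.  At TNF = 0 the steady state is C = 0, Inh = k_i/d_i, X = 0:
    no death-marker activity before stimulation.
    """
    species = [
        Species("TNF", "free TNF", 0.0, "cell"),
        Species("R", "receptor", float(r_total), "cell"),
        Species("C", "TNF:receptor complex", 0.0, "cell"),
        Species("Inh", "protective inhibitor", 0.0, "cell"),
        Species("X", "death marker", 0.0, "cell"),
    ]
    reactions = [
        Reaction("bind", "TNF binding", {"TNF": 1, "R": 1}, {"C": 1}, "k_on*TNF*R"),
        Reaction("unbind", "complex dissociation", {"C": 1}, {"TNF": 1, "R": 1}, "k_off*C"),
        Reaction(
            "prod_X", "complex-driven death-marker production", {}, {"X": 1},
            "k_x*C", modifiers=["C"],
        ),
        Reaction("prod_Inh", "protector production", {}, {"Inh": 1}, "k_i"),
        Reaction("deg_Inh", "protector turnover", {"Inh": 1}, {}, "d_i*Inh"),
        Reaction(
            "clear_X", "protector-mediated clearance", {"X": 1}, {},
            "k_q*Inh*X", modifiers=["Inh"],
        ),
    ]
    parameters = {
        "k_on": float(k_on),
        "k_off": float(k_off),
        "k_x": float(k_x),
        "k_i": float(k_i),
        "d_i": float(d_i),
        "k_q": float(k_q),
    }
    net = ReactionNetwork(
        species=species,
        reactions=reactions,
        parameters=parameters,
        compartments={"cell": 1.0},
        production_rate_ids=["k_x", "k_i"],
        metadata={
            "death_readout": {"type": "species_threshold", "species": "X", "threshold": float(theta)},
            "tnf_species_id": "TNF",
            "tnf_units_per_ng_ml": float(tnf_units_per_ng_ml),
            "needs_equilibration": True,
            # species that must be inactive at the unstimulated steady state,
            # each measured against a reference nominal amount (the analogue
            # of "no activated caspases" against the procaspase pool)
            "no_activity_species": [
                {"species": "C", "reference": "R"},
                {"species": "X", "reference": "R"},
            ],
            "time_unit": "hour",
        },
    )
    net.validate()
    return net


def generate_tod_dataset(
    slope: float,
    intercept: float,
    noise_sd: float,
    n: int,
    censor_fraction: float = 0.0,
    seed: int = 0,
    sigma_x: float = 0.148,
) -> pd.DataFrame:
    """Regression-stage fixture with known ground truth.

    log(ToD) = intercept + slope·log(multiplier) + Normal(0, noise_sd), with
    multipliers drawn lognormally (mean 1, log-sd ``sigma_x``) and a random
    fraction of cells marked censored.  Columns: ``multiplier``, ``tod_h``,
    ``censored``.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= censor_fraction < 1:
        raise ValueError("censor_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    log_m = -0.5 * sigma_x**2 + sigma_x * rng.standard_normal(n)
    log_tod = intercept + slope * log_m + noise_sd * rng.standard_normal(n)
    censored = np.zeros(n, dtype=bool)
    n_cens = int(round(censor_fraction * n))
    if n_cens:
        censored[rng.choice(n, size=n_cens, replace=False)] = True
    return pd.DataFrame(
        {
            "multiplier": np.exp(log_m),
            "tod_h": np.exp(log_tod),
            "censored": censored,
        }
    )
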