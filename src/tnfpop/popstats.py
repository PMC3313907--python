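"""Fate-distribution summaries and wild-type vs knockout comparisons.

The heterogeneity analysis compares a wild-type population with an
in-silico knockout population built from the SAME sampled multipliers
(common random numbers), so every difference is attributable to the zeroed
reaction, not to sampling noise.  Reported metrics follow the convention of
the knockout comparison table:

* death rate — fraction of cells dying before the censor horizon; deltas
  as percentage points (KO − WT, ×100);
* median time of death — over dying cells; deltas as relative percent
  change (KO − WT)/WT × 100;
* relative std — the heterogeneity metric: sample standard deviation of
  the time of death over dying cells divided by its mean (a coefficient of
  variation; a median normalizer is available as a switch); deltas as
  relative percent change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ensemble import EnsembleSpec, sample_population
from .network import ReactionNetwork, apply_knockout
from .simulate import (
    CellFate,
    SolverSettings,
    equilibrate,
    simulate_population,
    viability_curve,
)
from .stimulation import StimulusProtocol

__all__ = [
    "PopulationSummary",
    "ComparisonRecord",
    "summarize",
    "compare_populations",
    "knockout_experiment",
]


@dataclass
class PopulationSummary:
    """Descriptive statistics of one population's fates.

    Time-of-death statistics are over dying cells only; with no dying
    cells they are flagged undefined (``tod_defined = False``) rather than
    silently zero.  Quartiles use linear interpolation; whiskers extend to
    the most extreme datum within 1.5 × IQR of the box.
    """

    n: int
    n_dying: int
    death_rate: float
    tod_defined: bool
    median_tod_h: float = math.nan
    mean_tod_h: float = math.nan
    relative_std: float = math.nan
    q1_h: float = math.nan
    q3_h: float = math.nan
    whisker_low_h: float = math.nan
    whisker_high_h: float = math.nan
    outliers_h: list[float] = field(default_factory=list)
    relative_std_normalizer: str = "mean"


def summarize(
    fates: list[CellFate], relative_std_normalizer: str = "mean"
) -> PopulationSummary:
    """Summarize a fate list: death rate over all cells, ToD stats over dying ones."""
    if not fates:
        raise ValueError("fate list is empty")
    if relative_std_normalizer not in ("mean", "median"):
        raise ValueError("relative_std_normalizer must be 'mean' or 'median'")
    tods = np.array([f.time_of_death_h for f in fates if f.died], dtype=float)
    n, n_dying = len(fates), tods.size
    summary = PopulationSummary(
        n=n,
        n_dying=n_dying,
        death_rate=n_dying / n,
        tod_defined=n_dying > 0,
        relative_std_normalizer=relative_std_normalizer,
    )
    if n_dying == 0:
        return summary
    summary.median_tod_h = float(np.median(tods))
    summary.mean_tod_h = float(np.mean(tods))
    if n_dying > 1:
        sd = float(np.std(tods, ddof=1))
        center = summary.mean_tod_h if relative_std_normalizer == "mean" else summary.median_tod_h
        summary.relative_std = sd / center
    q1, q3 = np.quantile(tods, [0.25, 0.75])  # type-7 linear interpolation
    iqr = q3 - q1
    in_lo = tods[tods >= q1 - 1.5 * iqr]
    in_hi = tods[tods <= q3 + 1.5 * iqr]
    summary.q1_h, summary.q3_h = float(q1), float(q3)
    summary.whisker_low_h = float(in_lo.min())
    summary.whisker_high_h = float(in_hi.max())
    summary.outliers_h = sorted(
        float(t) for t in tods if t < summary.whisker_low_h or t > summary.whisker_high_h
    )
    return summary


@dataclass
class ComparisonRecord:
    """Knockout-minus-wild-type deltas for one protocol and dose.

    ``delta_death_rate_pp`` is in percentage points; the other two deltas
    are relative percent change.  ``delta_death_rate_pct`` (relative) is
    also stored so either convention can be compared.
    """

    protocol_label: str
    dose_ng_ml: float
    mode: str
    delta_death_rate_pp: float
    delta_death_rate_pct: float
    delta_median_tod_pct: float
    delta_relative_std_pct: float
    wt: PopulationSummary | None = None
    ko: PopulationSummary | None = None


def compare_populations(
    wt: PopulationSummary,
    ko: PopulationSummary,
    protocol: StimulusProtocol | None = None,
) -> ComparisonRecord:
    """KO − WT deltas; ToD-based deltas are undefined (NaN) if either side is."""
    d_rate_pp = (ko.death_rate - wt.death_rate) * 100.0
    d_rate_pct = (
        (ko.death_rate - wt.death_rate) / wt.death_rate * 100.0
        if wt.death_rate > 0
        else math.nan
    )
    if wt.tod_defined and ko.tod_defined:
        d_median = (ko.median_tod_h - wt.median_tod_h) / wt.median_tod_h * 100.0
        if np.isfinite(wt.relative_std) and np.isfinite(ko.relative_std) and wt.relative_std > 0:
            d_std = (ko.relative_std - wt.relative_std) / wt.relative_std * 100.0
        else:
            d_std = math.nan
    else:
        d_median = math.nan
        d_std = math.nan
    return ComparisonRecord(
        protocol_label=protocol.label if protocol else "",
        dose_ng_ml=protocol.dose_ng_ml if protocol else math.nan,
        mode=protocol.mode if protocol else "",
        delta_death_rate_pp=d_rate_pp,
        delta_death_rate_pct=d_rate_pct,
        delta_median_tod_pct=d_median,
        delta_relative_std_pct=d_std,
        wt=wt,
        ko=ko,
    )


def knockout_experiment(
    network: ReactionNetwork,
    knockout_reaction_id: str,
    protocols: list[StimulusProtocol],
    spec: EnsembleSpec,
    settings: SolverSettings = SolverSettings(),
    viability_grid=None,
    relative_std_normalizer: str = "mean",
) -> tuple[list[ComparisonRecord], dict]:
    """Paired WT/KO runs over a protocol grid with common random numbers.

    One population is sampled once from ``spec`` and reused for the
    wild-type network and its knockout under every protocol, isolating the
    knocked-out reaction's effect.  Returns the comparison records and a
    dict of viability curves keyed by (dose, mode, genotype).
    """
    spec = EnsembleSpec(
        n_cells=spec.n_cells,
        sigma=spec.sigma,
        seed=spec.seed,
        distributed_ids=tuple(spec.distributed_ids) or tuple(network.production_rate_ids),
        centering=spec.centering,
        log_base=spec.log_base,
    )
    population = sample_population(spec)
    ko_network = apply_knockout(network, knockout_reaction_id)
    # the unstimulated steady state does not depend on the protocol:
    # equilibrate each cell once per genotype and reuse across conditions
    resting_states = {
        "wt": [equilibrate(network, cell, settings) for cell in population],
        "ko": [equilibrate(ko_network, cell, settings) for cell in population],
    }
    records = []
    curves = {}
    for protocol in protocols:
        if viability_grid is None:
            grid = np.linspace(0.0, protocol.horizon_hours, 101)
        else:
            grid = np.asarray(viability_grid, dtype=float)
        summaries = {}
        for genotype, net in (("wt", network), ("ko", ko_network)):
            result = simulate_population(
                net, population, protocol, settings,
                initial_states=resting_states[genotype],
            )
            summaries[genotype] = summarize(result.fates, relative_std_normalizer)
            curves[(protocol.dose_ng_ml, protocol.mode, genotype)] = (
                grid,
                viability_curve(result.fates, grid),
            )
        records.append(compare_populations(summaries["wt"], summaries["ko"], protocol))
    return records, curves
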