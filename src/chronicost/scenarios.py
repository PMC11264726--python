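"""Scenario definitions and the end-to-end projection pipeline.

Sixteen deterministic scenarios vary the epidemiological trends (annual
proportional changes in incidence and mortality rate ratio), the
demographic variant and the annual excess-cost growth rate:

=======  ==========  ==============  =========  ======  ====================
id       variant     incidence/yr    MRR/yr     growth  note
=======  ==========  ==============  =========  ======  ====================
1        G2L2W2            0          -2%        0      base case
2..5     G2L2W2       +1/-1/+2/-2%    -2%        0      incidence band
6, 7     G2L2W2          +5/-5%       -2%        0      extreme incidence
8        G2L2W2            -           -         0      constant prevalence
9, 10    G2L2W2            0          -2%       1%/5%   cost growth
11, 12   W1 / W3           0          -2%        0      low/high migration
13       G1L2W2            0          -2%        0      low fertility
14, 15   L1 / L3           0          -2%        0      life expectancy band
16       G2L2W2           +1%         -2%        1%     most probable
=======  ==========  ==============  =========  ======  ====================

Scenarios 2-5 and 11-15 are configurable defaults; 1, 6-10 and 16 are
pinned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cost_model import (
    aggregate_pac,
    baseline_per_capita,
    cost_ratio,
    compute_pac,
    extrapolate_national,
    per_capita_surfaces,
    total_costs,
    total_excess_costs,
    totals_frame,
)
from .grids import BASE_YEAR, END_YEAR, SEXES, TYPES, YEARS
from .prevalence_projection import (
    PrevalenceSurface,
    RateSurface,
    apply_trend,
    case_counts,
    constant_prevalence_surface,
    solve_idm_pde,
)
from .synthetic_data import (
    AggregatedCostTable,
    EpiInputs,
    PopulationProjection,
    VARIANTS,
    default_base_population,
    generate_cost_table,
    generate_epi_inputs,
    generate_population,
    mortality_surface,
)

__all__ = [
    "ScenarioSpec",
    "PipelineInputs",
    "ProjectionResult",
    "build_scenarios",
    "default_inputs",
    "run_scenario",
    "percent_change",
]

BASELINE_VARIANT = "G2L2W2"


@dataclass(frozen=True)
class ScenarioSpec:
    id: int
    name: str = ""
    demographic_variant: str = BASELINE_VARIANT
    incidence_trend: float = 0.0
    mrr_trend: float = 0.0
    cost_growth: float = 0.0
    constant_prevalence: bool = False

    def __post_init__(self):
        if not 1 <= self.id <= 16:
            raise ValueError("scenario id must be in 1..16")
        for name in ("incidence_trend", "mrr_trend"):
            if 1.0 + getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must exceed -1")
        if self.cost_growth <= -1.0:
            raise ValueError("cost_growth must exceed -1")
        if self.constant_prevalence and (self.incidence_trend or self.mrr_trend):
            raise ValueError("constant-prevalence scenario cannot carry epi trends")


def _default_scenarios() -> list[ScenarioSpec]:
    s = ScenarioSpec
    return [
        s(1, "base case", mrr_trend=-0.02),
        s(2, "incidence +1%", incidence_trend=0.01, mrr_trend=-0.02),
        s(3, "incidence -1%", incidence_trend=-0.01, mrr_trend=-0.02),
        s(4, "incidence +2%", incidence_trend=0.02, mrr_trend=-0.02),
        s(5, "incidence -2%", incidence_trend=-0.02, mrr_trend=-0.02),
        s(6, "incidence +5%", incidence_trend=0.05, mrr_trend=-0.02),
        s(7, "incidence -5%", incidence_trend=-0.05, mrr_trend=-0.02),
        s(8, "constant prevalence", constant_prevalence=True),
        s(9, "cost growth 1%", mrr_trend=-0.02, cost_growth=0.01),
        s(10, "cost growth 5%", mrr_trend=-0.02, cost_growth=0.05),
        s(11, "low migration", demographic_variant="G2L2W1", mrr_trend=-0.02),
        s(12, "high migration", demographic_variant="G2L2W3", mrr_trend=-0.02),
        s(13, "low fertility", demographic_variant="G1L2W2", mrr_trend=-0.02),
        s(14, "lower life expectancy", demographic_variant="G2L1W2", mrr_trend=-0.02),
        s(15, "higher life expectancy", demographic_variant="G2L3W2", mrr_trend=-0.02),
        s(16, "most probable", incidence_trend=0.01, mrr_trend=-0.02, cost_growth=0.01),
    ]


def build_scenarios(config: dict | None = None) -> list[ScenarioSpec]:
    """The 16-scenario table, optionally overriding the configurable ones.

    ``config`` maps scenario id (int) to a dict of ScenarioSpec field
    overrides, e.g. ``{2: {"incidence_trend": 0.015}}``.
    """
    specs = _default_scenarios()
    if config:
        by_id = {s.id: s for s in specs}
        for sid, overrides in config.items():
            sid = int(sid)
            if sid not in by_id:
                raise ValueError(f"unknown scenario id {sid}")
            by_id[sid] = replace(by_id[sid], **overrides)
        specs = [by_id[i] for i in sorted(by_id)]
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scenario ids")
    return specs


@dataclass
class PipelineInputs:
    """Everything a scenario run consumes, on the common grid."""

    populations: dict[str, PopulationProjection]
    mortality: dict[str, np.ndarray]  # variant -> (sex, age, year) general mortality
    epi: EpiInputs
    cost_table: AggregatedCostTable
    sample_fraction: float = 0.068
    pde_step: float = 0.25


def default_inputs(
    seed: int = 2010,
    variants: list[str] | None = None,
    **kwargs,
) -> PipelineInputs:
    """Fully synthetic default inputs for the requested demographic variants."""
    variant_ids = variants or list(VARIANTS)
    base = default_base_population()
    populations = {}
    mortality = {}
    for vid in variant_ids:
        params = VARIANTS[vid]
        populations[vid] = generate_population(params, base, seed)
        mortality[vid] = mortality_surface(params)
    epi = generate_epi_inputs(seed=seed, population=base)
    table = generate_cost_table(epi=epi, pop=populations[variant_ids[0]], seed=seed)
    return PipelineInputs(populations, mortality, epi, table, **kwargs)


@dataclass
class ProjectionResult:
    """All projection outputs of one scenario."""

    scenario: ScenarioSpec
    prevalence: PrevalenceSurface
    counts: dict[str, np.ndarray]  # type -> (sex, age, year)
    totals: dict[str, np.ndarray]  # diagnosis -> (sex, year) euro
    excess: dict[str, np.ndarray]  # type -> (sex, year) euro
    ratio: dict[str, np.ndarray]  # type -> (sex, age, year)
    pac: dict[str, np.ndarray]  # type -> (sex, age, year)
    frame: pd.DataFrame  # tidy (year, type, sex) table
    aggregate: pd.DataFrame  # per (year, type): aggregate PAC + national euro

    def annual_totals(self, diabetes_type: str) -> np.ndarray:
        """Total annual costs summed over sexes, shape (year,)."""
        return self.totals[diabetes_type].sum(axis=0)


def run_scenario(spec: ScenarioSpec, inputs: PipelineInputs) -> ProjectionResult:
    """Execute the full pipeline for one scenario.

    Order: trend application -> PDE prevalence projection (or constant
    prevalence) -> case counts -> per capita growth projection -> totals,
    excess, cost ratios, PAC and national extrapolation.
    """
    if spec.demographic_variant not in inputs.populations:
        raise ValueError(f"no population for variant {spec.demographic_variant!r}")
    pop = inputs.populations[spec.demographic_variant]
    epi = inputs.epi

    if spec.constant_prevalence:
        prev = PrevalenceSurface(
            {d: constant_prevalence_surface(epi.prevalence0[d]) for d in TYPES}
        )
    else:
        mort = RateSurface(inputs.mortality[spec.demographic_variant])
        surfaces = {}
        for d in TYPES:
            inc = apply_trend(epi.incidence[d], spec.incidence_trend)
            mrr = apply_trend(epi.mrr[d], spec.mrr_trend, floor=1.0)
            surfaces[d] = solve_idm_pde(
                epi.prevalence0[d], inc, mort, mrr, step=inputs.pde_step
            )
        prev = PrevalenceSurface(surfaces)

    counts = case_counts(prev, pop.counts)
    profile = baseline_per_capita(inputs.cost_table)
    percap = per_capita_surfaces(profile, spec.cost_growth)
    totals = total_costs(prev, pop.counts, percap)
    excess_surf = {d: percap[d] - percap["none"] for d in TYPES}
    excess = total_excess_costs(prev, pop.counts, excess_surf)
    ratio = {d: cost_ratio(percap[d], profile.curves["none"]) for d in TYPES}
    pac = {d: compute_pac(prev.values[d], ratio[d]) for d in TYPES}

    agg_rows = []
    for d in TYPES:
        pac_t = aggregate_pac(prev, pop.counts, percap, d)
        national_total = (pop.counts * percap["none"]).sum(axis=(0, 1)) + excess[d].sum(axis=0)
        sample_total = national_total * inputs.sample_fraction
        extrap = extrapolate_national(pac_t, sample_total, inputs.sample_fraction)
        for yi, year in enumerate(YEARS):
            agg_rows.append(
                {
                    "year": int(year),
                    "type": d,
                    "aggregate_pac": pac_t[yi],
                    "national_total_eur": extrap["national_total"][yi],
                    "attributable_eur": extrap["attributable"][yi],
                }
            )
    frame = totals_frame(totals, excess, counts)
    frame.insert(0, "scenario_id", spec.id)
    aggregate = pd.DataFrame(agg_rows)
    aggregate.insert(0, "scenario_id", spec.id)
    return ProjectionResult(spec, prev, counts, totals, excess, ratio, pac, frame, aggregate)


def percent_change(
    result: ProjectionResult,
    from_year: int = BASE_YEAR,
    to_year: int = END_YEAR,
) -> dict[str, float]:
    """Percent change of total annual costs per type between two years."""
    out = {}
    for d in TYPES:
        totals = result.annual_totals(d)
        start = totals[int(from_year) - BASE_YEAR]
        end = totals[int(to_year) - BASE_YEAR]
        if start == 0:
            raise ValueError("zero baseline total")
        out[d] = 100.0 * (end - start) / start
    return out
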