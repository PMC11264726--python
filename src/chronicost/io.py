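"""CSV interchange schemas.

All pipeline artifacts are plain CSV: euro amounts with 2 decimals,
proportions and rates with 6 significant decimals, one fully-crossed row
per grid cell.  Readers validate grid completeness and rebuild the dense
arrays used internally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import AGES, N_AGES, N_SEXES, N_YEARS, SEXES, TYPES, YEARS
from .synthetic_data.costs import COLUMNS as COST_COLUMNS, AggregatedCostTable
from .synthetic_data.demography import PopulationProjection
from .synthetic_data.epidemiology import EpiInputs

EURO_FMT = "%.2f"
RATE_FMT = "%.6g"


def write_population(pop: PopulationProjection, path) -> None:
    rows = []
    for si, sex in enumerate(SEXES):
        for age in AGES:
            for yi, year in enumerate(YEARS):
                rows.append((int(age), sex, int(year), pop.counts[si, age, yi]))
    pd.DataFrame(rows, columns=["age", "sex", "year", "count"]).to_csv(
        path, index=False, float_format="%.3f"
    )


def read_population(path, variant_id: str = "") -> PopulationProjection:
    df = pd.read_csv(path)
    counts = np.zeros((N_SEXES, N_AGES, N_YEARS))
    if len(df) != N_SEXES * N_AGES * N_YEARS:
        raise ValueError(f"{path}: incomplete population grid")
    si = df["sex"].map({s: i for i, s in enumerate(SEXES)}).to_numpy()
    counts[si, df["age"].to_numpy(), df["year"].to_numpy() - YEARS[0]] = df["count"].to_numpy()
    return PopulationProjection(counts, variant_id=variant_id)


def write_rate_surface(values: np.ndarray, path, value_name: str = "rate") -> None:
    """(sex, age, year) surface to long CSV."""
    rows = []
    for si, sex in enumerate(SEXES):
        for age in AGES:
            for yi, year in enumerate(YEARS):
                rows.append((int(age), sex, int(year), values[si, age, yi]))
    pd.DataFrame(rows, columns=["age", "sex", "year", value_name]).to_csv(
        path, index=False, float_format=RATE_FMT
    )


def read_rate_surface(path, value_name: str = "rate") -> np.ndarray:
    df = pd.read_csv(path)
    if len(df) != N_SEXES * N_AGES * N_YEARS:
        raise ValueError(f"{path}: incomplete rate grid")
    out = np.zeros((N_SEXES, N_AGES, N_YEARS))
    si = df["sex"].map({s: i for i, s in enumerate(SEXES)}).to_numpy()
    out[si, df["age"].to_numpy(), df["year"].to_numpy() - YEARS[0]] = df[value_name].to_numpy()
    return out


def write_epi(epi: EpiInputs, path) -> None:
    """Base-year epi grids: age, sex, type, prevalence0, incidence, mrr, mortality."""
    rows = []
    for d in TYPES:
        for si, sex in enumerate(SEXES):
            for age in AGES:
                rows.append(
                    (
                        int(age),
                        sex,
                        d,
                        epi.prevalence0[d][si, age],
                        epi.incidence[d][si, age],
                        epi.mrr[d][si, age],
                        epi.mortality_general[si, age],
                    )
                )
    pd.DataFrame(
        rows,
        columns=["age", "sex", "type", "prevalence0", "incidence", "mrr", "mortality_general"],
    ).to_csv(path, index=False, float_format=RATE_FMT)


def read_epi(path) -> EpiInputs:
    df = pd.read_csv(path)
    if len(df) != len(TYPES) * N_SEXES * N_AGES:
        raise ValueError(f"{path}: incomplete epi grid")
    prev, inc, mrr = {}, {}, {}
    mort = np.zeros((N_SEXES, N_AGES))
    for d in TYPES:
        prev[d] = np.zeros((N_SEXES, N_AGES))
        inc[d] = np.zeros((N_SEXES, N_AGES))
        mrr[d] = np.zeros((N_SEXES, N_AGES))
    for _, row in df.iterrows():
        si = SEXES.index(row["sex"])
        a = int(row["age"])
        d = row["type"]
        prev[d][si, a] = row["prevalence0"]
        inc[d][si, a] = row["incidence"]
        mrr[d][si, a] = row["mrr"]
        mort[si, a] = row["mortality_general"]
    return EpiInputs(prev, inc, mort, mrr)


def write_cost_table(table: AggregatedCostTable, path) -> None:
    table.frame.to_csv(path, index=False, float_format=EURO_FMT)


def read_cost_table(path) -> AggregatedCostTable:
    df = pd.read_csv(path)
    missing = set(COST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return AggregatedCostTable(df)


def write_prevalence(values: dict[str, np.ndarray], path) -> None:
    """Prevalence surfaces p(age, sex, type, year) to long CSV."""
    rows = []
    for d, surf in values.items():
        for si, sex in enumerate(SEXES):
            for age in AGES:
                for yi, year in enumerate(YEARS):
                    rows.append((int(age), sex, d, int(year), surf[si, age, yi]))
    pd.DataFrame(rows, columns=["age", "sex", "type", "year", "p"]).to_csv(
        path, index=False, float_format="%.6f"
    )
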