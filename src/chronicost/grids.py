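"""Common axis definitions shared by every pipeline stage.

All surfaces in this package are dense numpy arrays laid out as
``(sex, age, year)`` with the axes below.  Sex index 0 is male, 1 is
female; ages are single years 0..100; calendar years run 2010..2040.
"""

from __future__ import annotations

import numpy as np

BASE_YEAR = 2010
END_YEAR = 2040

AGES = np.arange(101)
N_AGES = AGES.size

YEARS = np.arange(BASE_YEAR, END_YEAR + 1)
N_YEARS = YEARS.size

SEXES = ("male", "female")
N_SEXES = len(SEXES)

TYPES = ("T1", "T2")
DIAGNOSES = ("T1", "T2", "none")

EXPENDITURE_FIELDS = (
    "physicians",
    "dentists",
    "pharmacies",
    "hospitals",
    "sick_benefits",
    "others",
)

#: 22 five-year claims age groups. The nominal claims dialect runs
#: 0-4, 5-9, ..., 100-104, 105+; the modelling range stops at age 100,
#: so the open-ended 105+ group is structurally empty here.
AGE_GROUPS = tuple((5 * i, 5 * i + 4) for i in range(21)) + ((105, 109),)
N_AGE_GROUPS = len(AGE_GROUPS)


def sex_index(sex: str) -> int:
    try:
        return SEXES.index(sex)
    except ValueError:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}") from None


def year_index(year: int) -> int:
    if not BASE_YEAR <= year <= END_YEAR:
        raise ValueError(f"year {year} outside {BASE_YEAR}..{END_YEAR}")
    return int(year) - BASE_YEAR


def age_group_of(age: int) -> int:
    """Claims age-group index for a single-year age (0..100)."""
    if not 0 <= age <= 100:
        raise ValueError(f"age {age} outside 0..100")
    return min(age // 5, N_AGE_GROUPS - 1)
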