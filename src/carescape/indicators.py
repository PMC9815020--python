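"""Registry of the 17 tertiary indicators of elderly-care-institution development.

The indicator system has three primary dimensions — facility construction,
nursing staff and service recipients — refined into secondary groups and 17
tertiary indicators: 6 quantity indicators (counts, floor area, beds, staff,
residents, mean days of stay) and 11 proportional indicators (percentages of
the staff or resident population). Declaration order below is the canonical
table order used everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "Indicator",
    "INDICATORS",
    "INDICATOR_IDS",
    "QUANTITY_IDS",
    "PROPORTION_IDS",
    "REGIONS",
    "AREAS",
    "YEARS",
    "by_id",
]

REGIONS = ("Northeast", "Eastern", "Central", "Western")
AREAS = ("urban", "rural")
#: study window of the yearbook panel
YEARS = tuple(range(2010, 2017))


@dataclass(frozen=True)
class Indicator:
    """One tertiary indicator and its place in the aggregation tree."""

    id: str
    label: str
    kind: str  # "quantity" | "proportion"
    unit: str
    primary: str
    secondary: str
    #: within-group redistribution share for the three proportional groups
    #: whose secondary weight (3/17) is split unevenly; None = plain 1/17
    share: Fraction | None = None


_F = Fraction

INDICATORS: tuple[Indicator, ...] = (
    Indicator("n_institutions", "Number of elderly care institutions",
              "quantity", "institutions",
              "facilities", "n_institutions"),
    Indicator("floor_area", "GFA of elderly care facilities",
              "quantity", "10^4 m^2",
              "facilities", "floor_area"),
    Indicator("beds_year_end", "Number of beds at end of year",
              "quantity", "10^4 beds",
              "facilities", "beds_year_end"),
    Indicator("staff_year_end", "Number of employees at end of year",
              "quantity", "10^4 persons",
              "nursing_staff", "staff_year_end"),
    Indicator("pct_female_caregivers", "Proportion of female caregivers",
              "proportion", "%",
              "nursing_staff", "gender_structure"),
    Indicator("pct_university_educated", "Percentage of university education",
              "proportion", "%",
              "nursing_staff", "education_level"),
    Indicator("pct_age_35_under", "Proportion of persons aged 35 and under",
              "proportion", "%",
              "nursing_staff", "age_structure", _F(1, 2)),
    Indicator("pct_age_36_55", "Proportion of persons aged 36-55 years",
              "proportion", "%",
              "nursing_staff", "age_structure", _F(3, 10)),
    Indicator("pct_age_56_over", "Proportion of persons aged 56 and over",
              "proportion", "%",
              "nursing_staff", "age_structure", _F(1, 5)),
    Indicator("avg_days_in_care",
              "Average number of days in elderly care institution per year",
              "quantity", "days",
              "service_users", "admission"),
    Indicator("residents_year_end",
              "Number of people in elderly care institution at the end of the year",
              "quantity", "10^4 persons",
              "service_users", "admission"),
    Indicator("pct_beneficiaries", "Proportion of beneficiaries",
              "proportion", "%",
              "service_users", "resident_nature", _F(1, 5)),
    Indicator("pct_three_noes", "Proportion of \"three noughts\"",
              "proportion", "%",
              "service_users", "resident_nature", _F(3, 10)),
    Indicator("pct_self_financing", "Proportion of self-financing staff",
              "proportion", "%",
              "service_users", "resident_nature", _F(1, 2)),
    Indicator("pct_fully_self_care", "Proportion of fully self-care workers",
              "proportion", "%",
              "service_users", "self_care_ability", _F(1, 5)),
    Indicator("pct_semi_self_care", "Proportion of semi-self-care persons",
              "proportion", "%",
              "service_users", "self_care_ability", _F(7, 20)),
    Indicator("pct_cannot_self_care",
              "Proportion of people who cannot care for themselves",
              "proportion", "%",
              "service_users", "self_care_ability", _F(9, 20)),
)

INDICATOR_IDS: tuple[str, ...] = tuple(ind.id for ind in INDICATORS)
QUANTITY_IDS: tuple[str, ...] = tuple(
    ind.id for ind in INDICATORS if ind.kind == "quantity")
PROPORTION_IDS: tuple[str, ...] = tuple(
    ind.id for ind in INDICATORS if ind.kind == "proportion")

_BY_ID = {ind.id: ind for ind in INDICATORS}


def by_id(indicator_id: str) -> Indicator:
    """Look up an indicator by its canonical id."""
    try:
        return _BY_ID[indicator_id]
    except KeyError:
        raise KeyError(f"unknown indicator id: {indicator_id!r}") from None
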