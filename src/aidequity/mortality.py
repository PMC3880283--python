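"""Under-5 mortality from complete birth histories.

The estimator counts, for every (country, calendar year, wealth quintile)
cell, the survey-weighted number of under-5 deaths and the survey-weighted
child-years lived by under-5 children during the 120-month recall window
preceding each interview; the cell rate is deaths per 1,000 child-years.

Month conventions (all months are century month codes):

* a child contributes exposure for calendar months ``m`` with
  ``birth_month <= m < min(birth_month + 60, death_month, interview_month)``
  and ``m >= interview_month - window_months`` — the interview month itself
  and the death month contribute no exposure ("full months lived", death at
  month start);
* ``death_month = birth_month + age_at_death_months``; the death is counted
  in the calendar year of the death month only if that month lies inside the
  window and the age at death is below 60 months;
* months are bucketed into calendar years by their own year.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from aidequity.exceptions import ConfigurationError
from aidequity.months import cmc_year, year_start_cmc
from aidequity.wealth_index import weighted_quantile

logger = logging.getLogger(__name__)


def child_exposure_by_year(
    birth_month: int,
    died: bool,
    age_at_death_months: int | None,
    interview_month: int,
    window_months: int = 120,
) -> tuple[dict[int, int], int | None]:
    """Exposure months per calendar year for one child, plus its death year.

    Reference (scalar) implementation of the exposure rules; the table-level
    aggregation is vectorized but must agree with this month arithmetic
    exactly.  Returns ``({year: months}, death_year_or_None)``.
    """
    if birth_month > interview_month:
        raise ConfigurationError("birth_month after interview_month")
    if died and age_at_death_months is not None and age_at_death_months >= 60:
        raise ConfigurationError(
            f"age at death {age_at_death_months} >= 60 months violates the under-5 definition"
        )
    window_start = interview_month - window_months
    end = min(birth_month + 60, interview_month)
    death_month = None
    if died:
        if age_at_death_months is None or age_at_death_months < 0:
            raise ConfigurationError("died child lacks age_at_death_months")
        death_month = birth_month + age_at_death_months
        end = min(end, death_month)
    start = max(birth_month, window_start)

    exposure: dict[int, int] = {}
    for m in range(start, end):
        y = cmc_year(m)
        exposure[y] = exposure.get(y, 0) + 1
    death_year = None
    if (
        death_month is not None
        and age_at_death_months < 60
        and window_start <= death_month < interview_month
    ):
        death_year = int(cmc_year(death_month))
    return exposure, death_year


def _exposure_table(
    births: pd.DataFrame, interview_month: np.ndarray, window_months: int
) -> pd.DataFrame:
    """Vectorized per-(child, calendar year) exposure months and death flags."""
    birth = births["birth_month"].to_numpy()
    died = births["died"].to_numpy().astype(bool)
    age = births["age_at_death_months"].to_numpy()

    window_start = interview_month - window_months
    end = np.minimum(birth + 60, interview_month)
    death_month = np.where(died, birth + age, np.iinfo(np.int64).max)
    end = np.minimum(end, death_month)
    start = np.maximum(birth, window_start)

    death_counted = died & (age < 60) & (death_month >= window_start) & (
        death_month < interview_month
    )
    death_year = np.where(death_counted, cmc_year(np.minimum(death_month, 10**7)), -1)

    y_lo = int(cmc_year(start.min()))
    y_hi = int(max(cmc_year(np.maximum(start, end - 1).max()), death_year.max()))
    frames = []
    idx = np.arange(len(births))
    for year in range(y_lo, y_hi + 1):
        ys = year_start_cmc(year)
        months = np.clip(np.minimum(end, ys + 12) - np.maximum(start, ys), 0, 12)
        mask = (months > 0) | (death_year == year)
        if not mask.any():
            continue
        frames.append(
            pd.DataFrame(
                {
                    "child_idx": idx[mask],
                    "year": year,
                    "months": months[mask],
                    "death": (death_year[mask] == year).astype(np.int64),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["child_idx", "year", "months", "death"])
    return pd.concat(frames, ignore_index=True)


def aggregate_cells(
    births: pd.DataFrame,
    households: pd.DataFrame,
    window_months: int = 120,
) -> pd.DataFrame:
    """Survey-weighted deaths, exposure and rates per (country, year, quintile).

    ``households`` must carry ``household_id``, ``country_id``, ``survey_id``,
    ``interview_month``, ``survey_weight`` and an assigned ``quintile``.
    Records with age at death >= 60 months violate the under-5 definition and
    are rejected with a logged count.  Overlapping surveys from one country
    pool into the same cells (weighted union), preserving the
    deaths/exposure definition of the rate.  Median mother education is the
    weighted median per (country, quintile, survey), carried to that survey's
    years (exposure-weighted average where surveys overlap).
    """
    hh_cols = ["household_id", "country_id", "survey_id", "interview_month", "survey_weight", "quintile"]
    missing = [c for c in hh_cols if c not in households.columns]
    if missing:
        raise ConfigurationError(f"household table lacks columns: {missing}")
    merged = births.merge(households[hh_cols], on="household_id", how="left")
    orphans = merged["country_id"].isna()
    if orphans.any():
        ids = merged.loc[orphans, "household_id"].unique()[:10].tolist()
        raise ConfigurationError(
            f"{int(orphans.sum())} births reference unknown households, e.g. {ids}"
        )
    over5 = merged["died"].astype(bool) & (merged["age_at_death_months"] >= 60)
    if over5.any():
        logger.warning(
            "rejected %d birth records with age at death >= 60 months", int(over5.sum())
        )
        merged = merged.loc[~over5].reset_index(drop=True)

    expo = _exposure_table(merged, merged["interview_month"].to_numpy(), window_months)
    expo = expo.join(
        merged[["country_id", "survey_id", "quintile", "survey_weight", "mother_education_years"]],
        on="child_idx",
    )
    expo["w_months"] = expo["months"] * expo["survey_weight"]
    expo["w_deaths"] = expo["death"] * expo["survey_weight"]

    keys = ["country_id", "year", "quintile"]
    cells = (
        expo.groupby(keys, as_index=False)
        .agg(
            deaths=("w_deaths", "sum"),
            w_months=("w_months", "sum"),
            n_children_unweighted=("child_idx", "nunique"),
        )
        .assign(child_years=lambda d: d["w_months"] / 12.0)
        .drop(columns="w_months")
    )
    cells = cells[cells["child_years"] > 0].reset_index(drop=True)
    cells["mortality_rate"] = 1000.0 * cells["deaths"] / cells["child_years"]

    # Weighted median education per (country, quintile, survey): one value per
    # contributing mother-child record, weighted by survey weight.
    edu = (
        merged.groupby(["country_id", "quintile", "survey_id"])
        .apply(
            lambda g: weighted_quantile(
                g["mother_education_years"], g["survey_weight"], 0.5
            ),
            include_groups=False,
        )
        .rename("median_mother_education")
        .reset_index()
    )
    expo_s = (
        expo.groupby(["country_id", "year", "quintile", "survey_id"], as_index=False)[
            "w_months"
        ].sum()
        .merge(edu, on=["country_id", "quintile", "survey_id"])
    )
    cell_edu = (
        expo_s.assign(num=lambda d: d["w_months"] * d["median_mother_education"])
        .groupby(keys, as_index=False)[["num", "w_months"]]
        .sum()
        .assign(median_mother_education=lambda d: d["num"] / d["w_months"])
        .loc[:, keys + ["median_mother_education"]]
    )
    cells = cells.merge(cell_edu, on=keys, how="left")
    return cells[
        keys
        + ["deaths", "child_years", "mortality_rate", "median_mother_education", "n_children_unweighted"]
    ]


def period_summary(
    cells: pd.DataFrame,
    period_a: tuple[int, int],
    period_b: tuple[int, int],
) -> pd.DataFrame:
    """Per-quintile period rates, absolute decline and percent decline.

    Period rates are exposure-weighted (total deaths over total child-years
    within the period), not averages of annual rates.  Percent decline is
    ``100 * (rate_a - rate_b) / rate_a`` and is missing when ``rate_a`` is 0.
    """

    def period_rates(period):
        lo, hi = period
        sub = cells[(cells["year"] >= lo) & (cells["year"] <= hi)]
        if sub.empty:
            raise ConfigurationError(f"no cells in period {period}")
        g = sub.groupby("quintile")[["deaths", "child_years"]].sum()
        return 1000.0 * g["deaths"] / g["child_years"], g["child_years"]

    rate_a, expo_a = period_rates(period_a)
    rate_b, expo_b = period_rates(period_b)
    out = pd.DataFrame(
        {
            "rate_a": rate_a,
            "exposure_a": expo_a,
            "rate_b": rate_b,
            "exposure_b": expo_b,
        }
    )
    out["absolute_decline"] = out["rate_a"] - out["rate_b"]
    out["pct_decline"] = np.where(
        out["rate_a"] > 0, 100.0 * out["absolute_decline"] / out["rate_a"], np.nan
    )
    return out.reset_index()
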