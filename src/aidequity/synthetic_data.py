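"""DHS-like synthetic survey microdata with known mortality and wealth truth.

The generator emulates the logical tables of a pooled multi-country household
survey study: a household table with asset indicators and survey weights, a
complete-birth-history table with month-granular survival information, and a
country-year panel of health aid and covariates.  All "truth" (asset
gradients, baseline hazards by wealth quintile, the aid-by-wealth interaction
on mortality) is held in :class:`~aidequity.config.GeneratorConfig`, so every
downstream stage — wealth index, rate estimation, panel regression — can be
tested for parameter recovery without any external data.

Conventions
-----------
* Months are DHS century month codes (see :mod:`aidequity.months`).
* Interviews are dated January following the survey year, so the 120-month
  recall window covers exactly the ten calendar years ending with the survey
  year.
* Quintile 1 is the wealthiest, quintile 5 the poorest.
* Child survival is simulated month by month: in each lived month a child
  dies with probability ``rate(country, year, quintile) / 12000`` where the
  rate is in deaths per 1,000 child-years; aid enters that rate with a
  one-year lag (configurable) so that the generator's estimand matches the
  default regression specification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from aidequity.config import ASSET_COLUMNS, GeneratorConfig, config_to_yaml
from aidequity.exceptions import ConfigurationError, GenerationError
from aidequity.months import cmc, cmc_year

# Independent RNG streams per operation so each table is reproducible on its
# own, regardless of which other generator calls precede it.
_STREAM_COUNTRY = 0
_STREAM_PANEL = 1
_STREAM_HOUSEHOLDS = 2
_STREAM_BIRTHS = 3


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def country_ids(config: GeneratorConfig) -> list[str]:
    return [f"C{i:02d}" for i in range(config.n_countries)]


def country_attributes(config: GeneratorConfig) -> pd.DataFrame:
    """Time-invariant country draws shared by all generator operations.

    One row per country: population, per-series aid level and trend,
    education base, government-spending and urbanization trajectories, and
    the country mortality shift.
    """
    config.validate()
    rng = _rng(config, _STREAM_COUNTRY)
    n = config.n_countries
    cov = config.covariate_params
    attrs = pd.DataFrame({"country_id": country_ids(config)})
    attrs["population"] = rng.uniform(1e6, 5e7, n)
    for name in sorted(config.aid_series_params):
        params = config.aid_series_params[name]
        attrs[f"{name}_level"] = rng.uniform(*params.level_range, n)
        attrs[f"{name}_trend"] = rng.uniform(*params.trend_range, n)
    attrs["edu_base"] = rng.uniform(*cov.education_country_range, n)
    attrs["govt_level"] = rng.uniform(*cov.govt_level_range, n)
    attrs["govt_trend"] = rng.uniform(*cov.govt_trend_range, n)
    attrs["urban_level"] = rng.uniform(*cov.urban_level_range, n)
    attrs["urban_trend"] = rng.uniform(*cov.urban_trend_range, n)
    attrs["country_shift"] = rng.normal(0.0, config.country_shift_sd, n)
    return attrs


def panel_year_range(config: GeneratorConfig) -> tuple[int, int]:
    """Panel years, extended 3 years before the study range for lag variants."""
    y0, y1 = config.years
    return y0 - 3, y1


def generate_country_panel(config: GeneratorConfig) -> pd.DataFrame:
    """Country-year panel of aid per capita and covariates.

    Returns one row per (country, year) over the configured range extended
    back 3 years (so lags 0..3 never lose observations to the panel edge),
    with columns ``total_aid_pc``, ``malaria_aid_pc``, ``govt_health_pc``,
    ``urban_share``.  Deterministic for a fixed config.
    """
    config.validate()
    attrs = country_attributes(config)
    rng = _rng(config, _STREAM_PANEL)
    y0, y1 = panel_year_range(config)
    years = np.arange(y0, y1 + 1)
    n, t = config.n_countries, len(years)
    cov = config.covariate_params

    rel = years - config.years[0]  # trend origin at the study start year
    rows = {
        "country_id": np.repeat(attrs["country_id"].to_numpy(), t),
        "year": np.tile(years, n),
    }
    for name in sorted(config.aid_series_params):
        params = config.aid_series_params[name]
        level = attrs[f"{name}_level"].to_numpy()[:, None]
        trend = attrs[f"{name}_trend"].to_numpy()[:, None]
        noise = rng.normal(0.0, params.noise_sd, (n, t)) if params.noise_sd else 0.0
        series = np.maximum(0.0, level + trend * rel[None, :] + noise)
        rows[f"{name}_aid_pc"] = series.ravel()
    govt = (
        attrs["govt_level"].to_numpy()[:, None]
        + attrs["govt_trend"].to_numpy()[:, None] * rel[None, :]
        + rng.normal(0.0, cov.govt_noise_sd, (n, t))
    )
    rows["govt_health_pc"] = np.maximum(0.0, govt).ravel()
    urban = (
        attrs["urban_level"].to_numpy()[:, None]
        + attrs["urban_trend"].to_numpy()[:, None] * rel[None, :]
        + rng.normal(0.0, cov.urban_noise_sd, (n, t))
    )
    rows["urban_share"] = np.clip(urban, 0.0, 1.0).ravel()
    panel = pd.DataFrame(rows)
    return panel[
        ["country_id", "year", "total_aid_pc", "malaria_aid_pc", "govt_health_pc", "urban_share"]
    ]


def latent_quintile(z: np.ndarray, sd: float) -> np.ndarray:
    """Quintile of latent wealth using theoretical normal cutpoints (1 = wealthiest)."""
    cuts = sd * norm.ppf([0.2, 0.4, 0.6, 0.8])
    return 5 - np.searchsorted(cuts, z, side="right")


def generate_households(config: GeneratorConfig) -> pd.DataFrame:
    """Household table: assets, weights and (generator-internal) latent wealth.

    Each binary asset is drawn Bernoulli(logistic(intercept + slope * z))
    with z ~ Normal(0, latent_wealth_sd), so ownership probability is
    non-decreasing in latent wealth for every asset (slopes are validated to
    be non-negative).  ``population_share_weight`` is the survey's share of
    the pooled national population divided equally over its households.
    """
    config.validate()
    attrs = country_attributes(config)
    rng = _rng(config, _STREAM_HOUSEHOLDS)
    n_hh = config.households_per_survey
    total_pop = float(attrs["population"].sum()) * len(config.survey_years)

    frames = []
    hh_base = 0
    for ci, cid in enumerate(country_ids(config)):
        pop = float(attrs.loc[ci, "population"])
        for sy in config.survey_years:
            z = rng.normal(0.0, config.latent_wealth_sd, n_hh)
            hh = pd.DataFrame(
                {
                    "household_id": np.arange(hh_base, hh_base + n_hh),
                    "survey_id": f"{cid}-{sy}",
                    "country_id": cid,
                    "survey_year": sy,
                    # January after the survey year: the recall window is the
                    # ten calendar years ending with survey_year.
                    "interview_month": cmc(sy + 1, 1),
                    "survey_weight": rng.lognormal(0.0, 0.2, n_hh),
                    "population_share_weight": (pop / total_pop) / n_hh,
                }
            )
            hh_base += n_hh
            for asset in ASSET_COLUMNS:
                a, b = config.asset_loadings[asset]
                hh[asset] = (rng.random(n_hh) < expit(a + b * z)).astype(np.int64)
            ri, rs, rsd = config.rooms_per_person
            hh["rooms_per_person"] = np.maximum(
                0.02, ri + rs * z + rng.normal(0.0, rsd, n_hh)
            )
            hh["latent_wealth"] = z
            frames.append(hh)
    households = pd.concat(frames, ignore_index=True)
    households["latent_quintile"] = latent_quintile(
        households["latent_wealth"].to_numpy(), config.latent_wealth_sd
    )
    return households


def expected_cell_rates(config: GeneratorConfig, panel: pd.DataFrame) -> pd.DataFrame:
    """Expected mortality rate per (country, year, quintile), the generator truth.

    Linear form::

        rate = 12000*h_q + shift_c + trend*(year-y0) + (gamma + delta_q)*aid_lagged

    Proportional form replaces the additive aid/country/year terms with the
    same terms on log(rate).  Rates are floored at 0.
    """
    config.validate()
    attrs = country_attributes(config)
    aid_col = f"{config.effect_aid}_aid_pc"
    wide = panel.pivot(index="country_id", columns="year", values=aid_col)
    wide = wide.reindex(attrs["country_id"])
    years = np.asarray(sorted(panel["year"].unique()))
    y0, y1 = config.years
    out_years = np.arange(y0, y1 + 1)
    lag_years = out_years - config.gen_aid_lag
    if lag_years.min() < years.min():
        raise ConfigurationError(
            f"panel starts {years.min()} but lag {config.gen_aid_lag} needs {lag_years.min()}"
        )
    aid_lagged = wide[lag_years].to_numpy()  # (n_countries, n_years)
    base = 12000.0 * np.asarray(config.baseline_hazard)  # (5,)
    effect = config.aid_main_effect + np.asarray(config.interaction_truth)  # (5,)
    shift = attrs["country_shift"].to_numpy()[:, None, None]
    trend = config.year_rate_trend * (out_years - y0)[None, :, None]
    aid_term = aid_lagged[:, :, None] * effect[None, None, :]
    if config.aid_effect_form == "linear":
        rate = base[None, None, :] + shift + trend + aid_term
    else:
        rate = base[None, None, :] * np.exp(shift + trend + aid_term)
    rate = np.maximum(rate, 0.0)
    n, t = aid_lagged.shape
    return pd.DataFrame(
        {
            "country_id": np.repeat(attrs["country_id"].to_numpy(), t * 5),
            "year": np.tile(np.repeat(out_years, 5), n),
            "quintile": np.tile(np.arange(1, 6), n * t),
            "expected_rate": rate.ravel(),
        }
    )


def _rate_array(config: GeneratorConfig, panel: pd.DataFrame):
    """Expected rates as an array R[country, year - y0, quintile] plus its y0."""
    truth = expected_cell_rates(config, panel)
    y0, y1 = config.years
    n, t = config.n_countries, y1 - y0 + 1
    rate = truth["expected_rate"].to_numpy().reshape(n, t, 5)
    return rate, y0


def generate_birth_histories(
    households: pd.DataFrame,
    panel: pd.DataFrame,
    config: GeneratorConfig,
    chunk_size: int = 250_000,
) -> pd.DataFrame:
    """Complete birth histories for the households, simulated month by month.

    Births are placed uniformly over each survey's 120-month recall window,
    with a Poisson number of births per household whose mean depends on the
    latent wealth quintile (poorer households have more births).  Each child's
    monthly death probability is the generator's expected cell rate divided
    by 12,000; the first month whose Bernoulli draw fires before age 60 and
    before the interview is recorded as the death month.
    """
    config.validate()
    rng = _rng(config, _STREAM_BIRTHS)
    rate, y0 = _rate_array(config, panel)
    hazard = rate / 12000.0
    if (hazard > 1.0).any():
        ci, yi, qi = np.argwhere(hazard > 1.0)[0]
        raise GenerationError(
            f"monthly hazard exceeds 1 in cell (country={country_ids(config)[ci]}, "
            f"year={y0 + yi}, quintile={qi + 1})"
        )
    attrs = country_attributes(config)
    edu_base = dict(zip(attrs["country_id"], attrs["edu_base"]))
    cidx = {cid: i for i, cid in enumerate(country_ids(config))}
    unknown = set(households["country_id"]) - set(cidx)
    if unknown:
        raise ConfigurationError(f"households reference unknown countries: {sorted(unknown)}")
    min_window_year = int(households["survey_year"].min()) - 9
    if min_window_year < y0:
        raise ConfigurationError(
            f"recall window starts {min_window_year}, before the panel's first "
            f"study year {y0}"
        )

    fert = np.asarray(config.fertility_per_quintile)
    offsets = np.asarray(config.covariate_params.education_quintile_offsets)
    hq = households["latent_quintile"].to_numpy()
    n_births = rng.poisson(fert[hq - 1])
    mother_edu = np.maximum(
        0,
        np.rint(
            np.asarray([edu_base[c] for c in households["country_id"]])
            + offsets[hq - 1]
            + rng.normal(0.0, config.covariate_params.education_noise_sd, len(households))
        ),
    ).astype(np.int64)

    rep = np.repeat(np.arange(len(households)), n_births)
    interview = households["interview_month"].to_numpy()[rep]
    ccode = np.asarray([cidx[c] for c in households["country_id"]])[rep]
    quint = hq[rep]
    birth_month = rng.integers(interview - 120, interview)  # uniform over the window

    n_children = len(rep)
    died = np.zeros(n_children, dtype=bool)
    age_death = np.zeros(n_children, dtype=np.int64)
    ages = np.arange(60)
    n_years = hazard.shape[1]
    for lo in range(0, n_children, chunk_size):
        hi = min(lo + chunk_size, n_children)
        month = birth_month[lo:hi, None] + ages[None, :]
        yr_idx = np.clip(cmc_year(month) - y0, 0, n_years - 1)
        h = hazard[ccode[lo:hi, None], yr_idx, quint[lo:hi, None] - 1]
        fire = rng.random((hi - lo, 60)) < h
        fire &= month < interview[lo:hi, None]  # censored at interview
        any_death = fire.any(axis=1)
        died[lo:hi] = any_death
        age_death[lo:hi] = np.where(any_death, fire.argmax(axis=1), 0)

    births = pd.DataFrame(
        {
            "child_id": np.arange(n_children),
            "household_id": households["household_id"].to_numpy()[rep],
            "mother_education_years": mother_edu[rep],
            "birth_month": birth_month,
            "died": died.astype(np.int64),
            "age_at_death_months": np.where(died, age_death, -1),
        }
    )
    return births


def write_tables(
    out_dir,
    households: pd.DataFrame,
    births: pd.DataFrame,
    panel: pd.DataFrame,
    config: GeneratorConfig | None = None,
) -> dict[str, str]:
    """Write the three delimited text tables (and a config echo) to ``out_dir``.

    Latent-wealth columns are withheld from the household table: the analysis
    must recover wealth from assets, exactly as with real survey data.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    public = households.drop(columns=["latent_wealth", "latent_quintile"], errors="ignore")
    for name, df in (
        ("households", public),
        ("births", births),
        ("country_panel", panel),
    ):
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")
        paths[name] = str(path)
    if config is not None:
        path = out / "generator_config.yaml"
        path.write_text(config_to_yaml(config), encoding="utf-8")
        paths["config"] = str(path)
    return paths
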