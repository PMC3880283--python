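"""Configuration objects for the generator, the panel model and pipeline runs.

All simulation truth lives in :class:`GeneratorConfig`; a fixed config
(including its seed) fully determines every synthetic table the package
writes.  Wealth quintiles are labelled 1 = wealthiest .. 5 = poorest
throughout the package, and quintile 1 is the reference stratum of the
regression model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from aidequity.exceptions import ConfigurationError

#: Binary asset/service indicators of the wealth index, in canonical order.
ASSET_COLUMNS = (
    "water_improved",
    "sanitation_improved",
    "finished_floor",
    "electricity",
    "radio",
    "television",
    "phone",
    "refrigerator",
    "motorcycle",
    "car",
)

#: Continuous wealth-index variable.
ROOMS_COLUMN = "rooms_per_person"

#: All wealth-index variables in model order.
INDEX_COLUMNS = ASSET_COLUMNS + (ROOMS_COLUMN,)

QUINTILES = (1, 2, 3, 4, 5)  # 1 = wealthiest, 5 = poorest


def _default_asset_loadings() -> dict[str, tuple[float, float]]:
    # (intercept, slope) of a logistic ownership model on latent wealth z,
    # chosen so that quintile ownership shares resemble observed DHS
    # gradients (electricity near 0% among the poorest and near 100% among
    # the wealthiest, car rare everywhere but concentrated at the top, ...).
    return {
        "water_improved": (0.3, 1.2),
        "sanitation_improved": (-0.5, 1.5),
        "finished_floor": (-0.5, 2.0),
        "electricity": (0.75, 3.9),
        "radio": (0.6, 1.0),
        "television": (-1.0, 2.5),
        "phone": (-0.8, 2.0),
        "refrigerator": (-1.8, 3.6),
        "motorcycle": (-1.8, 1.2),
        "car": (-3.3, 1.9),
    }


@dataclass(frozen=True)
class AidSeriesParams:
    """Country aid trajectories: level + trend * (year - y0) + noise, floored at 0.

    Levels and trends are drawn once per country from uniform ranges, in
    constant-2010 USD per capita (trend per year).
    """

    level_range: tuple[float, float] = (1.0, 12.0)
    trend_range: tuple[float, float] = (0.0, 1.0)
    noise_sd: float = 0.8

    def validate(self, name: str) -> None:
        lo, hi = self.level_range
        tlo, thi = self.trend_range
        if lo < 0 or hi < lo:
            raise ConfigurationError(f"{name}: level_range must be 0 <= lo <= hi")
        if tlo < 0 or thi < tlo:
            raise ConfigurationError(f"{name}: trend_range must be 0 <= lo <= hi")
        if self.noise_sd < 0:
            raise ConfigurationError(f"{name}: noise_sd must be >= 0")


@dataclass(frozen=True)
class CovariateParams:
    """Distributions of the non-aid covariates (no causal role in the generator)."""

    education_country_range: tuple[float, float] = (1.0, 6.0)
    #: additive offset per quintile, q1 (wealthiest) first
    education_quintile_offsets: tuple[float, ...] = (4.0, 2.5, 1.5, 0.5, 0.0)
    education_noise_sd: float = 2.0
    govt_level_range: tuple[float, float] = (5.0, 50.0)
    govt_trend_range: tuple[float, float] = (0.0, 2.0)
    govt_noise_sd: float = 1.0
    urban_level_range: tuple[float, float] = (0.10, 0.60)
    urban_trend_range: tuple[float, float] = (0.0, 0.010)
    urban_noise_sd: float = 0.005


@dataclass(frozen=True)
class GeneratorConfig:
    """All simulation truth for a DHS-like multi-country synthetic study.

    Mortality truth is expressed on the cell-rate scale (deaths per 1,000
    child-years).  Under the default ``aid_effect_form="linear"`` the expected
    rate of a (country, year, quintile) cell is::

        rate = 12000 * baseline_hazard[q] + country_shift + year_rate_trend * (year - y0)
               + (aid_main_effect + interaction_truth[q]) * aid[year - gen_aid_lag]

    and the per-month death probability is ``rate / 12000``.  Under
    ``aid_effect_form="proportional"`` the aid and country/year terms act on
    ``log(rate)`` instead, so ``interaction_truth`` is in natural-log points
    per aid dollar (a semi-elasticity).
    """

    n_countries: int = 30
    years: tuple[int, int] = (1993, 2012)
    survey_years: tuple[int, ...] = (2002, 2012)
    households_per_survey: int = 600
    latent_wealth_sd: float = 1.0
    asset_loadings: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_asset_loadings
    )
    #: rooms-per-person model: (intercept, slope on latent wealth, noise sd)
    rooms_per_person: tuple[float, float, float] = (0.55, 0.12, 0.25)
    #: monthly under-5 death probability per quintile, q1 (wealthiest) first
    baseline_hazard: tuple[float, ...] = tuple(
        r / 12000.0 for r in (7.9, 13.6, 23.2, 34.3, 36.9)
    )
    #: aid main effect (reference-stratum slope), rate units per aid dollar
    aid_main_effect: float = 0.34
    #: per-quintile aid interaction vs the wealthiest, q1 first (must be 0)
    interaction_truth: tuple[float, ...] = (0.0, 0.01, -0.23, -0.51, -0.57)
    #: "linear" (additive on the rate) or "proportional" (additive on log rate)
    aid_effect_form: str = "linear"
    #: which aid series drives mortality: "total" or "malaria"
    effect_aid: str = "total"
    #: years of lag between disbursement and mortality effect in the generator
    gen_aid_lag: int = 1
    #: Poisson mean births per household over the recall window, q1 first
    fertility_per_quintile: tuple[float, ...] = (0.9, 1.1, 1.3, 1.6, 1.9)
    #: sd of time-invariant country mortality shifts (rate units, or log points
    #: under the proportional form)
    country_shift_sd: float = 2.0
    #: common secular trend in the rate per calendar year (same units)
    year_rate_trend: float = -0.15
    aid_series_params: Mapping[str, AidSeriesParams] = field(
        default_factory=lambda: {
            "total": AidSeriesParams((1.0, 12.0), (0.0, 1.0), 0.8),
            "malaria": AidSeriesParams((0.1, 1.5), (0.0, 0.15), 0.15),
        }
    )
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> "GeneratorConfig":
        y0, y1 = self.years
        if y1 < y0:
            raise ConfigurationError(f"empty year range {self.years}")
        if self.n_countries < 1:
            raise ConfigurationError("n_countries must be >= 1")
        if not self.survey_years:
            raise ConfigurationError("at least one survey year is required")
        for sy in self.survey_years:
            if not y0 <= sy <= y1:
                raise ConfigurationError(f"survey year {sy} outside {self.years}")
        if self.households_per_survey < 1:
            raise ConfigurationError("households_per_survey must be >= 1")
        if self.latent_wealth_sd <= 0:
            raise ConfigurationError("latent_wealth_sd must be > 0")
        if len(self.baseline_hazard) != 5 or len(self.interaction_truth) != 5:
            raise ConfigurationError("baseline_hazard and interaction_truth need 5 entries")
        for q, h in zip(QUINTILES, self.baseline_hazard):
            if not 0.0 <= h <= 1.0:
                raise ConfigurationError(f"baseline hazard for quintile {q} not in [0,1]")
        if self.interaction_truth[0] != 0.0:
            raise ConfigurationError("interaction_truth[0] (reference quintile) must be 0")
        if self.aid_effect_form not in ("linear", "proportional"):
            raise ConfigurationError(f"unknown aid_effect_form {self.aid_effect_form!r}")
        if self.effect_aid not in self.aid_series_params:
            raise ConfigurationError(f"no aid series named {self.effect_aid!r}")
        if self.gen_aid_lag < 0:
            raise ConfigurationError("gen_aid_lag must be >= 0")
        missing = [a for a in ASSET_COLUMNS if a not in self.asset_loadings]
        if missing:
            raise ConfigurationError(f"asset_loadings missing: {missing}")
        for name, (_, slope) in self.asset_loadings.items():
            if slope < 0:
                raise ConfigurationError(
                    f"asset {name!r} has negative slope {slope}; ownership must be "
                    "non-decreasing in latent wealth"
                )
        if self.rooms_per_person[1] < 0 or self.rooms_per_person[2] < 0:
            raise ConfigurationError("rooms_per_person slope and sd must be >= 0")
        if len(self.fertility_per_quintile) != 5 or min(self.fertility_per_quintile) < 0:
            raise ConfigurationError("fertility_per_quintile needs 5 non-negative entries")
        for name, params in self.aid_series_params.items():
            params.validate(name)
        return self

    @property
    def surveys_per_country(self) -> int:
        return len(self.survey_years)

    def replace(self, **kwargs: Any) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class FEModelSpec:
    """Specification of the two-way fixed-effects interaction regression."""

    outcome_transform: str = "identity"  # "identity" | "log"
    aid_variable: str = "total"  # "total" | "malaria"
    aid_lag: int = 1
    include_ldv: bool = False
    reference_quintile: int = 1
    covariates: tuple[str, ...] = (
        "median_mother_education",
        "govt_health_pc",
        "urban_share",
    )
    cluster_by: str = "country_id"
    exposure_weighted: bool = False

    def validate(self) -> "FEModelSpec":
        if self.outcome_transform not in ("identity", "log"):
            raise ConfigurationError(f"unknown transform {self.outcome_transform!r}")
        if self.aid_variable not in ("total", "malaria"):
            raise ConfigurationError(f"unknown aid variable {self.aid_variable!r}")
        if self.aid_lag < 0:
            raise ConfigurationError("aid_lag must be >= 0")
        if self.reference_quintile != 1:
            raise ConfigurationError("the wealthiest quintile (1) is the reference")
        return self

    def replace(self, **kwargs: Any) -> "FEModelSpec":
        return dataclasses.replace(self, **kwargs)

    @property
    def aid_column(self) -> str:
        return {"total": "total_aid_pc", "malaria": "malaria_aid_pc"}[self.aid_variable]


@dataclass
class RunConfig:
    """End-to-end pipeline run: generator truth, model spec and report options."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: FEModelSpec = field(default_factory=FEModelSpec)
    period_a: tuple[int, int] = (1993, 2000)
    period_b: tuple[int, int] = (2005, 2012)
    smoothing_degree: int = 6
    smoothing_bandwidth: float | None = None  # None -> leave-one-out CV
    stages: tuple[str, ...] = ("generate", "index", "rates", "fit", "report")

    def validate(self) -> "RunConfig":
        self.generator.validate()
        self.model.validate()
        known = {"generate", "index", "rates", "fit", "report"}
        unknown = set(self.stages) - known
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        if self.smoothing_bandwidth is not None and self.smoothing_bandwidth <= 0:
            raise ConfigurationError("smoothing bandwidth must be > 0")
        return self


# -- YAML round-trip --------------------------------------------------------

def _as_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    return obj


def config_to_yaml(config: RunConfig | GeneratorConfig) -> str:
    return yaml.safe_dump(_as_plain(config), sort_keys=False)


def _tupled(d: Mapping[str, Any], keys: tuple[str, ...]) -> dict[str, Any]:
    out = dict(d)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(
                tuple(v) if isinstance(v, list) else v for v in out[k]
            )
    return out


def generator_config_from_dict(d: Mapping[str, Any]) -> GeneratorConfig:
    d = _tupled(
        d,
        (
            "years",
            "survey_years",
            "baseline_hazard",
            "interaction_truth",
            "fertility_per_quintile",
            "rooms_per_person",
        ),
    )
    if "asset_loadings" in d:
        d["asset_loadings"] = {k: tuple(v) for k, v in d["asset_loadings"].items()}
    if "aid_series_params" in d:
        d["aid_series_params"] = {
            k: AidSeriesParams(
                tuple(v["level_range"]), tuple(v["trend_range"]), v["noise_sd"]
            )
            if isinstance(v, Mapping)
            else v
            for k, v in d["aid_series_params"].items()
        }
    if "covariate_params" in d and isinstance(d["covariate_params"], Mapping):
        cp = _tupled(
            d["covariate_params"],
            (
                "education_country_range",
                "education_quintile_offsets",
                "govt_level_range",
                "govt_trend_range",
                "urban_level_range",
                "urban_trend_range",
            ),
        )
        d["covariate_params"] = CovariateParams(**cp)
    return GeneratorConfig(**d).validate()


def run_config_from_yaml(text: str) -> RunConfig:
    raw = yaml.safe_load(text) or {}
    kwargs: dict[str, Any] = {}
    if "generator" in raw:
        kwargs["generator"] = generator_config_from_dict(raw["generator"])
    if "model" in raw:
        m = _tupled(raw["model"], ("covariates",))
        kwargs["model"] = FEModelSpec(**m).validate()
    for key in ("period_a", "period_b"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    for key in ("smoothing_degree", "smoothing_bandwidth"):
        if key in raw:
            kwargs[key] = raw[key]
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    return RunConfig(**kwargs).validate()
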