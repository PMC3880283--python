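"""Fixed-effects estimator: oracles, clustered inference, variants."""

import numpy as np
import pandas as pd
import pytest

from aidequity.config import FEModelSpec, GeneratorConfig
from aidequity.exceptions import CollinearityError, ConfigurationError
from aidequity.mortality import aggregate_cells
from aidequity.panel_fe import Design, build_design, fit_model, fit_within, variant_sweep
from aidequity.synthetic_data import (
    generate_birth_histories,
    generate_country_panel,
    generate_households,
)


def _toy_cells(countries, years, quintiles, rate_fn, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for c in countries:
        for y in years:
            for q in quintiles:
                rows.append(
                    {
                        "country_id": c,
                        "year": y,
                        "quintile": q,
                        "deaths": 1.0,
                        "child_years": 100.0,
                        "mortality_rate": rate_fn(c, y, q, rng),
                        "median_mother_education": 5.0 + q,
                        "n_children_unweighted": 50,
                    }
                )
    return pd.DataFrame(rows)


def _toy_panel(countries, years, aid_fn):
    rows = []
    for c in countries:
        for y in years:
            rows.append(
                {
                    "country_id": c,
                    "year": y,
                    "total_aid_pc": aid_fn(c, y),
                    "malaria_aid_pc": 0.3 * aid_fn(c, y),
                    "govt_health_pc": 10.0 + y - min(years),
                    "urban_share": 0.3,
                }
            )
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_lag_drops_first_panel_year(self):
        cells = _toy_cells("AB", [2000, 2001, 2002], range(1, 6),
                           lambda c, y, q, r: 10.0 + q + r.normal())
        panel = _toy_panel("AB", [2000, 2001, 2002], lambda c, y: y - 1999.0)
        design = build_design(cells, panel, FEModelSpec(aid_lag=1))
        assert design.n_obs == 2 * 2 * 5
        assert design.n_dropped_missing_aid == 10

    def test_log_spec_observation_count_with_zero_cells(self):
        # 3,199 cells of which exactly 89 have zero rates -> log keeps 3,110
        countries = [f"c{i}" for i in range(31)]
        years = list(range(1991, 2012))  # 21 years
        cells = _toy_cells(countries, years, range(1, 6),
                           lambda c, y, q, r: 10.0 + q + r.random()).iloc[:3199].copy()
        cells.loc[cells.index[:89], "mortality_rate"] = 0.0
        panel = _toy_panel(countries, range(1990, 2012), lambda c, y: 1.0 + 0.1 * (y - 1990))
        identity = build_design(cells, panel, FEModelSpec())
        log = build_design(cells, panel, FEModelSpec(outcome_transform="log"))
        assert identity.n_obs == 3199
        assert log.n_obs == 3110
        assert log.n_dropped_zero_rate == 89

    def test_ldv_drops_rows_without_prior_cell(self):
        countries = "AB"
        years = [2000, 2001, 2002, 2003]
        cells = _toy_cells(countries, years, range(1, 6),
                           lambda c, y, q, r: 10.0 + q + r.normal())
        # remove 2001 cells for country A: 2001 and 2002 rows of A lose support
        cells = cells[~((cells.country_id == "A") & (cells.year == 2001))]
        panel = _toy_panel(countries, range(1999, 2004), lambda c, y: float(y - 1999))
        base = build_design(cells, panel, FEModelSpec())
        ldv = build_design(cells, panel, FEModelSpec(include_ldv=True))
        # oracle row count by set arithmetic
        have = {(c, y, q) for c, y, q in
                cells[["country_id", "year", "quintile"]].itertuples(index=False)}
        expected = sum(1 for (c, y, q) in have if (c, y - 1, q) in have)
        assert ldv.n_obs == expected
        assert base.n_obs - ldv.n_obs == ldv.n_dropped_missing_ldv

    def test_all_zero_rates_under_log_raises(self):
        cells = _toy_cells("AB", [2000, 2001], range(1, 6), lambda c, y, q, r: 0.0)
        panel = _toy_panel("AB", [1999, 2000, 2001], lambda c, y: 1.0)
        with pytest.raises(ConfigurationError, match="zero mortality"):
            build_design(cells, panel, FEModelSpec(outcome_transform="log"))


class TestFitWithin:
    def test_matches_normal_equations_oracle_on_12_row_panel(self):
        # 2 countries x 2 years x 3 quintiles, solved independently from the
        # normal equations on a hand-assembled matrix
        cells = _toy_cells("AB", [2001, 2002], [1, 2, 3],
                           lambda c, y, q, r: 10 + 2 * q + (y - 2001) + r.normal())
        panel = _toy_panel("AB", [2000, 2001, 2002],
                          lambda c, y: (y - 2000.0) * (1.0 if c == "A" else 2.0))
        spec = FEModelSpec(covariates=())
        design = build_design(cells, panel, spec)
        fit = fit_within(design, spec)

        d = cells.sort_values(["country_id", "year", "quintile"]).reset_index(drop=True)
        aid = d.apply(lambda row: (row.year - 1 - 2000.0) * (1.0 if row.country_id == "A" else 2.0), axis=1)
        X = np.column_stack(
            [
                (d.quintile == 2).astype(float),
                (d.quintile == 3).astype(float),
                aid,
                (d.quintile == 2) * aid,
                (d.quintile == 3) * aid,
                np.ones(len(d)),
                (d.country_id == "B").astype(float),
                (d.year == 2002).astype(float),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ d.mortality_rate.to_numpy())
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_singleton_clusters_equal_hc1(self):
        rng = np.random.default_rng(7)
        n, k = 60, 3
        X = pd.DataFrame(rng.normal(size=(n, k)), columns=["a", "b", "c"])
        X["const"] = 1.0
        y = pd.Series(X["a"].to_numpy() - 2 * X["b"].to_numpy() + rng.normal(size=n))
        design = Design(X=X, y=y, clusters=np.arange(n))
        fit = fit_within(design)
        sm = pytest.importorskip("statsmodels.api")
        res = sm.OLS(y.to_numpy(), X.to_numpy()).fit(cov_type="HC1")
        assert np.allclose(fit.se.to_numpy(), res.bse, rtol=1e-10)

    def test_clustered_se_match_statsmodels(self, small_data):
        panel, households, births = small_data
        hh = households.assign(quintile=households["latent_quintile"])
        cells = aggregate_cells(births, hh)
        spec = FEModelSpec()
        design = build_design(cells, panel, spec)
        fit = fit_within(design, spec)
        sm = pytest.importorskip("statsmodels.api")
        res = sm.OLS(design.y.to_numpy(), design.X.to_numpy()).fit(
            cov_type="cluster", cov_kwds={"groups": design.clusters}, use_t=True
        )
        assert np.allclose(fit.params.to_numpy(), res.params, rtol=1e-9)
        assert np.allclose(fit.se.to_numpy(), res.bse, rtol=1e-8)
        assert np.allclose(fit.pvalues.to_numpy(), res.pvalues, rtol=1e-6)

    def test_dummy_fit_equals_two_way_demeaning(self):
        # on a balanced panel the explicit-dummy fit must equal OLS on
        # within-transformed data (x - x̄_c - x̄_t + x̄)
        cells = _toy_cells("ABCDE", range(2001, 2007), range(1, 6),
                           lambda c, y, q, r: 20.0 + 2 * q + r.normal(0, 2), seed=3)
        panel = _toy_panel("ABCDE", range(2000, 2007),
                          lambda c, y: (y - 2000.0) * (ord(c) - 64) / 3.0)
        spec = FEModelSpec(covariates=())
        design = build_design(cells, panel, spec)
        fit = fit_within(design, spec)

        d = cells.sort_values(["country_id", "year", "quintile"]).reset_index(drop=True)
        non_fe = [c for c in design.X.columns
                  if not c.startswith(("country_", "year_")) and c != "const"]
        frame = design.X[non_fe].copy()
        frame["y"] = design.y.to_numpy()
        frame["country"] = d["country_id"].to_numpy()
        frame["year"] = d["year"].to_numpy()

        def demean(col):
            x = frame[col]
            return (x - frame.groupby("country")[col].transform("mean")
                    - frame.groupby("year")[col].transform("mean") + x.mean())

        Xd = np.column_stack([demean(c) for c in non_fe])
        yd = demean("y").to_numpy()
        beta = np.linalg.lstsq(Xd, yd, rcond=None)[0]
        assert np.allclose(fit.params[non_fe].to_numpy(), beta, atol=1e-8)

    def test_frisch_waugh_partialling(self, small_data):
        panel, households, births = small_data
        hh = households.assign(quintile=households["latent_quintile"])
        cells = aggregate_cells(births, hh)
        spec = FEModelSpec()
        design = build_design(cells, panel, spec)
        fit = fit_within(design, spec)
        target = [c for c in design.X.columns if c.startswith("aid_x_")]
        others = [c for c in design.X.columns if c not in target]
        X1 = design.X[target].to_numpy()
        X2 = design.X[others].to_numpy()
        y = design.y.to_numpy()
        resid = lambda M, v: v - M @ np.linalg.lstsq(M, v, rcond=None)[0]
        X1r = np.column_stack([resid(X2, X1[:, j]) for j in range(X1.shape[1])])
        yr = resid(X2, y)
        beta1 = np.linalg.lstsq(X1r, yr, rcond=None)[0]
        assert np.allclose(fit.params[target].to_numpy(), beta1, atol=1e-8)

    def test_single_cluster_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "const": 1.0})
        design = Design(X=X, y=pd.Series([1.0, 2, 3, 4]), clusters=np.zeros(4))
        with pytest.raises(ConfigurationError, match="single cluster"):
            fit_within(design)

    def test_collinearity_named(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=30), "const": 1.0})
        X["a_copy"] = X["a"]
        design = Design(X=X, y=pd.Series(rng.normal(size=30)), clusters=np.arange(30) % 3)
        with pytest.raises(CollinearityError, match="a"):
            fit_within(design)


class TestVariants:
    def test_true_lag_has_largest_interaction(self):
        # serially-uncorrelated aid sharply separates the lags: the fitted
        # |delta_5| must peak at the generator's lag (1) on average
        from aidequity.config import AidSeriesParams

        deltas = {lag: [] for lag in (0, 1, 2, 3)}
        for r in range(20):
            cfg = GeneratorConfig(
                n_countries=10,
                households_per_survey=1200,
                aid_series_params={
                    "total": AidSeriesParams((6.0, 6.0), (0.0, 0.0), 2.0),
                    "malaria": AidSeriesParams((0.1, 1.0), (0.0, 0.1), 0.1),
                },
                seed=700 + r,
            )
            panel = generate_country_panel(cfg)
            hh = generate_households(cfg)
            births = generate_birth_histories(hh, panel, cfg)
            cells = aggregate_cells(births, hh.assign(quintile=hh.latent_quintile))
            sweep = variant_sweep(cells, panel, FEModelSpec(),
                                  transforms=("identity",), aid_variables=("total",),
                                  ldv_options=(False,))
            for _, row in sweep.iterrows():
                deltas[row["aid_lag"]].append(row["delta_q5"])
        means = {lag: np.mean(v) for lag, v in deltas.items()}
        # truth is -0.57 at lag 1 and ~0 at the other lags under white-noise aid
        assert means[1] == min(means.values())
        assert abs(means[1]) == max(abs(m) for m in means.values())

    def test_identity_and_log_sign_pattern_on_noise_free_data(self):
        slopes = {1: 0.0, 2: -0.05, 3: -0.2, 4: -0.4, 5: -0.5}
        aid_fn = lambda c, y: (y - 1999.0) * (ord(c) - 64) / 2.0
        cells = _toy_cells("ABC", range(2000, 2006), range(1, 6),
                           lambda c, y, q, r: 40.0 + 2 * q + slopes[q] * aid_fn(c, y - 1))
        panel = _toy_panel("ABC", range(1999, 2006), aid_fn)
        sweep = variant_sweep(cells, panel, FEModelSpec(covariates=()),
                              lags=(1,), aid_variables=("total",), ldv_options=(False,))
        ident = sweep[sweep.outcome_transform == "identity"].iloc[0]
        log = sweep[sweep.outcome_transform == "log"].iloc[0]
        for q in (3, 4, 5):
            assert np.sign(ident[f"delta_q{q}"]) == np.sign(log[f"delta_q{q}"]) == -1

    def test_ldv_coefficient_near_zero_for_white_noise(self):
        rng = np.random.default_rng(11)
        cells = _toy_cells([f"c{i}" for i in range(10)], range(2000, 2010), range(1, 6),
                           lambda c, y, q, r: 30.0 + r.normal(0, 3))
        panel = _toy_panel([f"c{i}" for i in range(10)], range(1999, 2010),
                          lambda c, y: rng.random() * 3)
        fit = fit_model(cells, panel, FEModelSpec(include_ldv=True, covariates=()))
        assert abs(fit.params["ldv"]) < 3 * fit.se["ldv"] + 0.1

    def test_sweep_records_failures_and_continues(self):
        cells = _toy_cells("AB", [2000, 2001], range(1, 6), lambda c, y, q, r: 0.0)
        panel = _toy_panel("AB", [1999, 2000, 2001], lambda c, y: 1.0)
        sweep = variant_sweep(cells, panel, FEModelSpec(covariates=()),
                              lags=(1,), aid_variables=("total",))
        assert sweep["error"].notna().any()  # log variants fail on all-zero rates
        assert len(sweep) == 4  # identity/log x ldv on/off

    def test_report_formatting_smoke(self, small_data):
        panel, households, births = small_data
        hh = households.assign(quintile=households["latent_quintile"])
        cells = aggregate_cells(births, hh)
        fit = fit_model(cells, panel, FEModelSpec())
        text = fit.format_report()
        assert "Wealth*aid" in text and "Observations" in text
        table = fit.coefficient_table()
        assert {"term", "estimate", "se", "p"} <= set(table.columns)
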