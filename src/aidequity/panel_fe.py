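"""Two-way fixed-effects interaction regression with clustered inference.

The model regresses the cell mortality rate (or its natural log) on wealth
quintile dummies, lagged health aid per capita, aid-by-quintile interactions,
covariates (median maternal education, government health spending per capita,
urbanization share), and country and year fixed effects::

    M_ctq = sum_q beta_q W_q + gamma A_{c,t-lag}
            + sum_q delta_q (W_q * A_{c,t-lag})
            + theta E_cq + phi G_ct + psi U_ct + alpha_c + tau_t + eps_ctq

with the wealthiest quintile (q = 1) as the reference stratum.  The
interaction coefficients delta_q are the quantities of interest: the extra
change in mortality per aid dollar in quintile q relative to the wealthiest.

Estimation is ordinary least squares with the fixed effects entered as
explicit dummies; inference uses the cluster-robust (sandwich) covariance
grouped by country with the finite-sample factor G/(G-1) * (N-1)/(N-K) and
t(G-1) reference distribution, matching the convention of standard
econometric software.  The estimator is implemented here from first
principles; external packages appear only as cross-checks in the test suite.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from aidequity.config import FEModelSpec
from aidequity.exceptions import CollinearityError, ConfigurationError

logger = logging.getLogger(__name__)

QUINTILE_DUMMIES = ("q2", "q3", "q4", "q5")
INTERACTIONS = ("aid_x_q2", "aid_x_q3", "aid_x_q4", "aid_x_q5")


@dataclass
class Design:
    """Assembled regression inputs: one row per surviving cell."""

    X: pd.DataFrame
    y: pd.Series
    clusters: np.ndarray
    weights: np.ndarray | None = None
    n_dropped_missing_aid: int = 0
    n_dropped_zero_rate: int = 0
    n_dropped_missing_ldv: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.y)


@dataclass
class FEFit:
    """Fitted two-way FE model: coefficients, clustered SEs and metadata."""

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    n_obs: int
    r_squared: float
    df_inference: int  # G - 1
    n_clusters: int
    spec: FEModelSpec | None = None

    @property
    def beta_quintile(self) -> dict[int, float]:
        return {int(q[1]): float(self.params[q]) for q in QUINTILE_DUMMIES if q in self.params.index}

    @property
    def gamma_aid(self) -> float:
        return float(self.params["aid"])

    @property
    def delta_interaction(self) -> dict[int, float]:
        return {int(t[-1]): float(self.params[t]) for t in INTERACTIONS if t in self.params.index}

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        half = stats.t.ppf(0.5 + level / 2.0, self.df_inference) * self.se
        return pd.DataFrame({"lo": self.params - half, "hi": self.params + half})

    def coefficient_table(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {"estimate": self.params, "se": self.se, "p": self.pvalues}
        )
        tab.index.name = "term"
        tab["n_obs"] = self.n_obs
        tab["r2"] = self.r_squared
        return tab.reset_index()

    def format_report(self) -> str:
        """Plain-text summary in the layout of a published regression table."""
        is_log = self.spec is not None and self.spec.outcome_transform == "log"

        def cell(term):
            b, s, p = self.params[term], self.se[term], self.pvalues[term]
            if is_log:
                # semi-elasticity reading: 100*coef is % mortality per dollar
                return f"{100 * b:8.2f}%  {100 * s:.2f} (p={p:.3f})  [exp-1: {100 * (np.exp(b) - 1):.2f}%]"
            return f"{b:8.3f}   {s:.3f} (p={p:.3f})"

        lines = [
            "Two-way fixed-effects regression of under-5 mortality",
            f"outcome: {'log rate' if is_log else 'rate per 1,000 child-years'}"
            + (f", aid: {self.spec.aid_variable}, lag {self.spec.aid_lag}" if self.spec else ""),
            "",
            "Wealth quintile (vs 1 - wealthiest):",
        ]
        for q in QUINTILE_DUMMIES:
            if q not in self.params.index:
                continue
            label = f"  {q[1]}" + (" - poorest" if q == "q5" else "")
            lines.append(f"{label:24s}{cell(q)}")
        lines.append(f"{'Aid':24s}{cell('aid')}")
        lines.append("Wealth*aid (vs 1 - wealthiest):")
        for t in INTERACTIONS:
            if t not in self.params.index:
                continue
            label = f"  {t[-1]}" + (" - poorest" if t.endswith('5') else "")
            lines.append(f"{label:24s}{cell(t)}")
        for term, label in (
            ("median_mother_education", "Maternal education"),
            ("govt_health_pc", "Gov't health spending"),
            ("urban_share", "Urbanization"),
        ):
            if term in self.params.index:
                lines.append(f"{label:24s}{cell(term)}")
        if "ldv" in self.params.index:
            lines.append(f"{'Lagged outcome':24s}{cell('ldv')}")
        lines.append("")
        lines.append(f"Observations            {self.n_obs}")
        lines.append(f"R^2                     {self.r_squared:.2f}")
        lines.append(f"Clusters (countries)    {self.n_clusters}")
        return "\n".join(lines)


def build_design(
    cells: pd.DataFrame, panel: pd.DataFrame, spec: FEModelSpec
) -> Design:
    """Assemble the design matrix, outcome and cluster ids for one model spec.

    Rows are (country, year, quintile) cells.  Cells whose lagged aid year is
    missing from the panel are dropped with a logged count; the log transform
    additionally drops zero-rate cells; the lagged-dependent-variable variant
    drops cells without a previous-year cell for the same (country, quintile).
    """
    spec.validate()
    d = cells.copy()
    d["lag_year"] = d["year"] - spec.aid_lag
    aid = panel[["country_id", "year", spec.aid_column]].rename(
        columns={"year": "lag_year", spec.aid_column: "aid"}
    )
    d = d.merge(aid, on=["country_id", "lag_year"], how="left")
    covs = [c for c in ("govt_health_pc", "urban_share") if c in spec.covariates]
    if covs:
        d = d.merge(panel[["country_id", "year"] + covs], on=["country_id", "year"], how="left")
    n0 = len(d)
    d = d.dropna(subset=["aid"] + covs)
    n_dropped_aid = n0 - len(d)
    if n_dropped_aid:
        logger.info("dropped %d cells with missing lagged aid/covariates", n_dropped_aid)

    n_dropped_zero = 0
    if spec.outcome_transform == "log":
        zero = d["mortality_rate"] <= 0
        n_dropped_zero = int(zero.sum())
        d = d.loc[~zero]
        if d.empty:
            raise ConfigurationError("all cells have zero mortality under the log transform")
        d["outcome"] = np.log(d["mortality_rate"])
    else:
        d["outcome"] = d["mortality_rate"]

    n_dropped_ldv = 0
    if spec.include_ldv:
        prev = d[["country_id", "quintile", "year", "outcome"]].copy()
        prev["year"] += 1
        prev = prev.rename(columns={"outcome": "ldv"})
        d = d.merge(prev, on=["country_id", "quintile", "year"], how="left")
        n1 = len(d)
        d = d.dropna(subset=["ldv"])
        n_dropped_ldv = n1 - len(d)

    d = d.sort_values(["country_id", "year", "quintile"]).reset_index(drop=True)
    quintiles = [q for q in sorted(d["quintile"].unique()) if q != spec.reference_quintile]
    X = pd.DataFrame(index=d.index)
    for q in quintiles:
        X[f"q{q}"] = (d["quintile"] == q).astype(float)
    X["aid"] = d["aid"]
    for q in quintiles:
        X[f"aid_x_q{q}"] = X[f"q{q}"] * d["aid"]
    for cov in spec.covariates:
        if cov == "median_mother_education":
            X[cov] = d["median_mother_education"]
        elif cov in d.columns:
            X[cov] = d[cov]
    if spec.include_ldv:
        X["ldv"] = d["ldv"]
    X["const"] = 1.0
    for cid in sorted(d["country_id"].unique())[1:]:
        X[f"country_{cid}"] = (d["country_id"] == cid).astype(float)
    for year in sorted(d["year"].unique())[1:]:
        X[f"year_{year}"] = (d["year"] == year).astype(float)

    weights = d["child_years"].to_numpy() if spec.exposure_weighted and "child_years" in d else None
    return Design(
        X=X,
        y=d["outcome"].rename("outcome"),
        clusters=d[spec.cluster_by].to_numpy(),
        weights=weights,
        n_dropped_missing_aid=n_dropped_aid,
        n_dropped_zero_rate=n_dropped_zero,
        n_dropped_missing_ldv=n_dropped_ldv,
    )


def _collinear_columns(X: np.ndarray, names, tol: float = 1e-8) -> list[str]:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    bad = diag < tol * diag[0]
    return [names[piv[i]] for i in np.nonzero(bad)[0]]


def fit_within(design: Design, spec: FEModelSpec | None = None) -> FEFit:
    """OLS with explicit fixed-effect dummies and country-clustered covariance.

    The sandwich covariance is
    ``V = (X'X)^-1 (sum_c X_c' e_c e_c' X_c) (X'X)^-1`` scaled by
    ``G/(G-1) * (N-1)/(N-K)``; p-values use t with G-1 degrees of freedom.
    Raises :class:`CollinearityError` naming the redundant columns on rank
    deficiency, and errors out with a single cluster.
    """
    X = design.X.to_numpy(dtype=float)
    y = design.y.to_numpy(dtype=float)
    names = list(design.X.columns)
    if design.weights is not None:
        sw = np.sqrt(design.weights)
        X = X * sw[:, None]
        y = y * sw
    n, k = X.shape
    groups = pd.unique(design.clusters)
    G = len(groups)
    if G < 2:
        raise ConfigurationError("clustered variance undefined with a single cluster")
    if n <= k:
        raise ConfigurationError(f"{n} observations cannot identify {k} coefficients")
    if np.linalg.matrix_rank(X) < k:
        raise CollinearityError(_collinear_columns(X, names))

    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    XtX_inv = np.linalg.inv(XtX)

    meat = np.zeros((k, k))
    for g in groups:
        idx = design.clusters == g
        s = X[idx].T @ resid[idx]
        meat += np.outer(s, s)
    correction = (G / (G - 1)) * ((n - 1) / (n - k))
    V = correction * XtX_inv @ meat @ XtX_inv
    se = np.sqrt(np.diag(V))
    tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), G - 1)

    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else np.nan
    return FEFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        cov=pd.DataFrame(V, index=names, columns=names),
        n_obs=n,
        r_squared=r2,
        df_inference=G - 1,
        n_clusters=G,
        spec=spec,
    )


def fit_model(cells: pd.DataFrame, panel: pd.DataFrame, spec: FEModelSpec) -> FEFit:
    """Convenience wrapper: :func:`build_design` then :func:`fit_within`."""
    return fit_within(build_design(cells, panel, spec), spec)


def variant_sweep(
    cells: pd.DataFrame,
    panel: pd.DataFrame,
    base_spec: FEModelSpec | None = None,
    lags: tuple[int, ...] = (0, 1, 2, 3),
    transforms: tuple[str, ...] = ("identity", "log"),
    aid_variables: tuple[str, ...] = ("total", "malaria"),
    ldv_options: tuple[bool, ...] = (False, True),
) -> pd.DataFrame:
    """Robustness sweep over lag, transform, aid series and LDV inclusion.

    Returns one row per fitted variant with the interaction estimates and
    clustered SEs; variants that fail record the error and the sweep
    continues.
    """
    base_spec = base_spec or FEModelSpec()
    rows = []
    for lag, transform, aid_var, ldv in itertools.product(
        lags, transforms, aid_variables, ldv_options
    ):
        spec = base_spec.replace(
            aid_lag=lag, outcome_transform=transform, aid_variable=aid_var, include_ldv=ldv
        )
        row = {
            "aid_lag": lag,
            "outcome_transform": transform,
            "aid_variable": aid_var,
            "include_ldv": ldv,
        }
        try:
            fit = fit_model(cells, panel, spec)
        except Exception as exc:  # recorded, sweep continues
            row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
            continue
        row["error"] = None
        row["n_obs"] = fit.n_obs
        row["r2"] = fit.r_squared
        row["gamma_aid"] = fit.gamma_aid
        for q, v in fit.delta_interaction.items():
            row[f"delta_q{q}"] = v
            row[f"se_q{q}"] = float(fit.se[f"aid_x_q{q}"])
        rows.append(row)
    return pd.DataFrame(rows)
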