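"""Pooled absolute wealth index from household assets.

The index is the first principal component of the weighted correlation-scale
covariance of the asset indicators plus rooms-per-person, computed on all
surveys pooled so that scores are comparable across countries.  Two features
mirror standard pooled-survey practice:

* households are weighted by the share of the pooled national population the
  survey represents, so uniquely large surveys do not dominate the loadings;
* per-year weighted means of the standardized variables are removed before
  the eigen-decomposition ("year effects"), absorbing common secular drift in
  asset ownership over the survey period.

Scores are sign-normalized to increase with wealth (positive electricity
loading) and households are assigned to weighted quintiles, labelled
1 = wealthiest .. 5 = poorest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aidequity.config import INDEX_COLUMNS
from aidequity.exceptions import ConfigurationError

logger = logging.getLogger(__name__)


def weighted_quantile(values, weights, probs):
    """Type-1 (lower) weighted quantiles: smallest v with F(v) >= p."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cdf = np.cumsum(w) / w.sum()
    idx = np.searchsorted(cdf, np.atleast_1d(probs) - 1e-12, side="left")
    out = v[np.minimum(idx, len(v) - 1)]
    return out if np.ndim(probs) else float(out[0])


@dataclass
class WealthIndexModel:
    """Fitted pooled wealth index: everything needed to score new households."""

    variables: tuple[str, ...]
    asset_means: np.ndarray
    asset_sds: np.ndarray
    year_effects: dict[int, np.ndarray]  # per survey year, per-variable adjustment
    loadings: np.ndarray
    explained_variance_share: float
    quintile_cutpoints: np.ndarray  # 4 ascending score cutpoints (20/40/60/80)

    # -- scoring ------------------------------------------------------------
    def adjusted(self, households: pd.DataFrame) -> np.ndarray:
        X = households.loc[:, list(self.variables)].to_numpy(dtype=float)
        Z = (X - self.asset_means) / self.asset_sds
        if self.year_effects:
            years = households["survey_year"].to_numpy()
            for year, eff in self.year_effects.items():
                Z[years == year] -= eff
        return Z

    def score(self, households: pd.DataFrame) -> np.ndarray:
        return self.adjusted(households) @ self.loadings

    def assign_quintile(self, scores: np.ndarray) -> np.ndarray:
        # Ties at a cutpoint go to the poorer quintile (side="left").
        k = np.searchsorted(self.quintile_cutpoints, scores, side="left")
        return 5 - k

    # -- plain-text serialization -------------------------------------------
    def to_text(self) -> str:
        lines = ["# aidequity wealth index model v1"]
        lines.append("variables\t" + "\t".join(self.variables))
        for name, arr in (
            ("asset_means", self.asset_means),
            ("asset_sds", self.asset_sds),
            ("loadings", self.loadings),
            ("quintile_cutpoints", self.quintile_cutpoints),
        ):
            lines.append(name + "\t" + "\t".join(repr(float(v)) for v in arr))
        lines.append(f"explained_variance_share\t{self.explained_variance_share!r}")
        for year in sorted(self.year_effects):
            lines.append(
                f"year_effect:{year}\t"
                + "\t".join(repr(float(v)) for v in self.year_effects[year])
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "WealthIndexModel":
        fields: dict[str, list[str]] = {}
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            key, *vals = line.split("\t")
            fields[key] = vals
        year_effects = {
            int(k.split(":", 1)[1]): np.array([float(v) for v in vals])
            for k, vals in fields.items()
            if k.startswith("year_effect:")
        }
        return cls(
            variables=tuple(fields["variables"]),
            asset_means=np.array([float(v) for v in fields["asset_means"]]),
            asset_sds=np.array([float(v) for v in fields["asset_sds"]]),
            year_effects=year_effects,
            loadings=np.array([float(v) for v in fields["loadings"]]),
            explained_variance_share=float(fields["explained_variance_share"][0]),
            quintile_cutpoints=np.array(
                [float(v) for v in fields["quintile_cutpoints"]]
            ),
        )


def fit_wealth_index(
    households: pd.DataFrame,
    variables: tuple[str, ...] = INDEX_COLUMNS,
    weight_col: str = "population_share_weight",
    year_effects: bool = True,
) -> WealthIndexModel:
    """Fit the pooled weighted first-principal-component wealth index.

    Variables are standardized by their weighted mean and SD (so the
    decomposition is on the weighted correlation matrix), per-year weighted
    means are removed when ``year_effects`` is enabled, and the first
    eigenvector of the weighted covariance of the adjusted variables gives
    the loadings.  Raises on zero-variance variables and on tables with
    fewer households than variables.
    """
    variables = tuple(variables)
    if len(households) < len(variables):
        raise ConfigurationError(
            f"{len(households)} households < {len(variables)} index variables"
        )
    complete = households.dropna(subset=list(variables))
    if len(complete) < len(households):
        logger.info(
            "wealth index: excluded %d households with incomplete asset data",
            len(households) - len(complete),
        )
    X = complete.loc[:, list(variables)].to_numpy(dtype=float)
    w = complete[weight_col].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ConfigurationError("weights must be positive")
    wn = w / w.sum()
    means = wn @ X
    sds = np.sqrt(wn @ (X - means) ** 2)
    zero = [
        v
        for v, s, m in zip(variables, sds, means)
        if s <= 1e-12 * max(1.0, abs(m))
    ]
    if zero:
        raise ConfigurationError(f"zero weighted variance in: {', '.join(zero)}")
    Z = (X - means) / sds

    effects: dict[int, np.ndarray] = {}
    if year_effects:
        years = complete["survey_year"].to_numpy()
        for year in np.unique(years):
            mask = years == year
            eff = (wn[mask] @ Z[mask]) / wn[mask].sum()
            effects[int(year)] = eff
            Z[mask] -= eff

    cov = (Z * wn[:, None]).T @ Z  # weighted covariance of adjusted variables
    eigvals, eigvecs = np.linalg.eigh(cov)
    loadings = eigvecs[:, -1]
    evs = float(eigvals[-1] / eigvals.sum())
    # Sign normalization: the score must increase with wealth.
    elec = variables.index("electricity") if "electricity" in variables else None
    orient = loadings[elec] if elec is not None else loadings.sum()
    if orient < 0:
        loadings = -loadings

    scores = Z @ loadings
    cuts = weighted_quantile(scores, w, [0.2, 0.4, 0.6, 0.8])
    if not np.all(np.diff(cuts) > 0):
        # can only happen when the score distribution is heavily discrete;
        # tied cutpoints still assign deterministically (ties go poorer)
        logger.warning("quintile cutpoints are not strictly ascending: %s", cuts)
    return WealthIndexModel(
        variables=variables,
        asset_means=means,
        asset_sds=sds,
        year_effects=effects,
        loadings=loadings,
        explained_variance_share=evs,
        quintile_cutpoints=np.asarray(cuts, dtype=float),
    )


def score_and_assign_quintiles(
    model: WealthIndexModel, households: pd.DataFrame
) -> pd.DataFrame:
    """Score households with a fitted model and assign wealth quintiles.

    Households missing any index variable are excluded with a logged count.
    Returns columns ``household_id``, ``wealth_score``, ``quintile``.
    """
    missing = [v for v in model.variables if v not in households.columns]
    if missing:
        raise ConfigurationError(f"household table lacks index variables: {missing}")
    complete = households.dropna(subset=list(model.variables))
    n_dropped = len(households) - len(complete)
    if n_dropped:
        logger.info("scoring: excluded %d households with incomplete asset data", n_dropped)
    scores = model.score(complete)
    return pd.DataFrame(
        {
            "household_id": complete["household_id"].to_numpy(),
            "wealth_score": scores,
            "quintile": model.assign_quintile(scores),
        }
    )


def tabulate_assets_by_quintile(
    scored: pd.DataFrame,
    households: pd.DataFrame,
    weight_col: str = "survey_weight",
) -> pd.DataFrame:
    """Weighted asset-ownership shares (%) and mean rooms-per-person by quintile.

    Mirrors a sample-description table: one row per reported variable, one
    column per quintile from poorest to wealthiest.
    """
    merged = scored.merge(households, on="household_id", how="left", validate="1:1")
    if merged[weight_col].isna().any():
        raise ConfigurationError("scored households missing from the household table")
    rows = {}
    g = merged.groupby("quintile")
    wsum = g[weight_col].sum()
    rows["n_households"] = g.size()
    for asset in [v for v in INDEX_COLUMNS if v != "rooms_per_person"]:
        if asset not in merged.columns:
            continue
        num = merged[asset] * merged[weight_col]
        rows[asset] = 100.0 * num.groupby(merged["quintile"]).sum() / wsum
    if "rooms_per_person" in merged.columns:
        num = merged["rooms_per_person"] * merged[weight_col]
        rows["rooms_per_person_mean"] = num.groupby(merged["quintile"]).sum() / wsum
    table = pd.DataFrame(rows).T
    # poorest .. wealthiest ordering of columns (5 .. 1)
    return table.loc[:, sorted(table.columns, reverse=True)]
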