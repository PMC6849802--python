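"""Year x land-use and Year x temperature interaction models.

The central question these models answer: does the amount of
high-intensity land around a monitoring site change the *rate* at which
its cold-associated (low-STI) or warm-associated (high-STI) assemblage is
changing? The response is assemblage total abundance; fixed effects are
Year (centred, continuous), high-intensity proportion of the buffer,
centred site mean annual temperature, and the two interactions with Year;
random intercepts for Site, Year and 50-km grid.

Because the right land-use definition and buffer radius are not known a
priori, the full grid of high-intensity combinations x radii is fitted and
ranked by AIC ("scale of effect" selection). Variance explained is
partitioned with the Nakagawa-Schielzeth marginal/conditional R-squared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landcover import RADII_M, HighIntensityCombo
from .mixedmodels import FitResult, RandomTerm, fit_poisson_mixed
from .trends import _poisson_response, _with_grid50

logger = logging.getLogger(__name__)

__all__ = ["InteractionFit", "fit_interaction", "select_best", "r2_nakagawa", "aic"]


@dataclass
class InteractionFit:
    """A fitted interaction model plus its land-use context and R-squared."""

    fit: FitResult
    combo: HighIntensityCombo
    radius: float
    assemblage: str
    marginal_r2: float
    conditional_r2: float

    @property
    def interaction_landuse(self) -> tuple[float, float, float, float]:
        """(coef, se, z, p) of the Year x land-use interaction."""
        t = "year_c:landuse"
        return (
            float(self.fit.params[t]),
            float(self.fit.bse[t]),
            float(self.fit.zvalues[t]),
            float(self.fit.pvalues[t]),
        )

    @property
    def interaction_temperature(self) -> tuple[float, float, float, float]:
        t = "year_c:temp_c"
        return (
            float(self.fit.params[t]),
            float(self.fit.bse[t]),
            float(self.fit.zvalues[t]),
            float(self.fit.pvalues[t]),
        )


def _site_covariates(
    index_records: pd.DataFrame,
    buffer_metrics: pd.DataFrame,
    temperature: pd.DataFrame,
    combo: HighIntensityCombo,
    radius: float,
) -> tuple[pd.Series, pd.Series]:
    """Per-site land-use proportion and recording-period mean temperature."""
    sites = index_records["site_id"].unique()
    col = f"prop_{combo.label}"
    sel = buffer_metrics[buffer_metrics["radius"] == radius]
    if col not in buffer_metrics.columns:
        raise KeyError(f"buffer metrics lack column {col!r}")
    landuse = sel.set_index("site_id")[col]
    missing = [s for s in sites if s not in landuse.index]
    if missing:
        raise ValueError(f"no buffer metrics at radius {radius} for sites: {missing}")
    temp = temperature.merge(
        index_records[["site_id", "year"]].drop_duplicates(), on=["site_id", "year"]
    )
    site_temp = temp.groupby("site_id")["temperature"].mean()
    missing_t = [s for s in sites if s not in site_temp.index]
    if missing_t:
        raise ValueError(f"no temperature overlap with recorded years for sites: {missing_t}")
    return landuse.loc[sites], site_temp.loc[sites]


def fit_interaction(
    index_records: pd.DataFrame,
    buffer_metrics: pd.DataFrame,
    temperature: pd.DataFrame,
    assemblage: str,
    combo: HighIntensityCombo,
    radius: float,
    site_table: pd.DataFrame | None = None,
    theta0=None,
) -> InteractionFit:
    """Fit one Year x land-use x temperature interaction model.

    Land use enters as the proportion of the buffer (in [0, 1], so the
    interaction coefficient is log-abundance per year per unit
    proportion); temperature as the site mean over its recorded years,
    centred (per year per deg C).
    """
    df = _with_grid50(index_records, site_table)
    landuse, site_temp = _site_covariates(index_records, buffer_metrics, temperature, combo, radius)
    y = _poisson_response(df[f"abundance_{assemblage}"], f"{assemblage} abundance")
    year_c = (df["year"] - df["year"].mean()).to_numpy(dtype=float)
    H = landuse.loc[df["site_id"]].to_numpy(dtype=float)
    T = site_temp.loc[df["site_id"]].to_numpy(dtype=float)
    T = T - T.mean()
    X = pd.DataFrame(
        {
            "Intercept": np.ones(len(df)),
            "year_c": year_c,
            "landuse": H,
            "temp_c": T,
            "year_c:landuse": year_c * H,
            "year_c:temp_c": year_c * T,
        }
    )
    terms = [
        RandomTerm.from_labels("site", df["site_id"]),
        RandomTerm.from_labels("year", df["year"]),
        RandomTerm.from_labels("grid50", df["grid50"]),
    ]
    fit = fit_poisson_mixed(y, X, terms, theta0=theta0)
    marginal, conditional = r2_nakagawa(fit, X, terms)
    return InteractionFit(
        fit=fit,
        combo=combo,
        radius=float(radius),
        assemblage=assemblage,
        marginal_r2=marginal,
        conditional_r2=conditional,
    )


def _combo_complexity(combo: HighIntensityCombo) -> tuple:
    return (len(combo.categories), combo.include_sea, combo.code)


def select_best(
    index_records: pd.DataFrame,
    buffer_metrics: pd.DataFrame,
    temperature: pd.DataFrame,
    assemblage: str,
    combos: list[HighIntensityCombo] | None = None,
    radii=RADII_M,
    site_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, InteractionFit | None]:
    """Fit the full combo x radius grid and rank by AIC.

    Returns the selection table (one row per cell, with ``delta_aic``
    relative to the best converged fit; ties broken toward the simpler
    combination then the smaller radius) and the best fit itself.
    Non-converged cells are flagged and excluded from the ranking.
    """
    combos = HighIntensityCombo.all_combos() if combos is None else combos
    rows = []
    fits: dict[tuple[str, float], InteractionFit] = {}
    theta0 = None
    for combo in combos:
        for radius in radii:
            res = fit_interaction(
                index_records, buffer_metrics, temperature, assemblage,
                combo, radius, site_table=site_table, theta0=theta0,
            )
            if res.fit.converged:
                theta0 = np.log(np.sqrt(np.maximum(
                    [res.fit.vc[t] for t in ("site", "year", "grid50")], 1e-8
                )))
            coef, se, z, p = res.interaction_landuse
            rows.append(
                {
                    "combo": combo.code,
                    "include_sea": combo.include_sea,
                    "radius": float(radius),
                    "aic": res.fit.aic,
                    "loglik": res.fit.loglik,
                    "converged": res.fit.converged,
                    "interaction_landuse": coef,
                    "interaction_landuse_z": z,
                    "marginal_r2": res.marginal_r2,
                    "conditional_r2": res.conditional_r2,
                }
            )
            fits[(combo.label, float(radius))] = res
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    best = None
    if not ok.empty:
        order = sorted(
            ok.index,
            key=lambda i: (
                round(ok.loc[i, "aic"], 10),
                _combo_complexity(
                    HighIntensityCombo(ok.loc[i, "combo"], bool(ok.loc[i, "include_sea"]))
                ),
                ok.loc[i, "radius"],
            ),
        )
        best_row = table.loc[order[0]]
        label = best_row["combo"] + ("+sea" if best_row["include_sea"] else "")
        best = fits[(label, best_row["radius"])]
        table["delta_aic"] = table["aic"] - best_row["aic"]
        table.loc[~table["converged"], "delta_aic"] = np.nan
    else:
        table["delta_aic"] = np.nan
        logger.warning("no converged fits in the selection grid")
    return table.reset_index(drop=True), best


def r2_nakagawa(
    fit: FitResult, X: pd.DataFrame, terms: list[RandomTerm] | None = None
) -> tuple[float, float]:
    """Marginal and conditional R-squared of a mixed model.

    marginal = var_fixed / (var_fixed + var_random + var_additive);
    conditional adds var_random to the numerator. For gaussian models the
    additive variance is the residual variance; for Poisson log-link
    models it is the lognormal approximation ``ln(1 + 1/lambda_bar)`` with
    ``lambda_bar`` the fitted rate at centred covariates
    (``exp(Intercept)``). Random slopes contribute their variance times
    the mean squared slope covariate.
    """
    if not fit.converged:
        raise ValueError("cannot partition variance of a non-converged fit")
    pred = X.to_numpy(dtype=float) @ fit.params.to_numpy()
    var_fixed = float(np.var(pred))
    var_random = 0.0
    for name, v in fit.vc.items():
        weight = 1.0
        if terms is not None:
            match = [t for t in terms if t.name == name]
            if match and match[0].values is not None:
                weight = float(np.mean(match[0].values ** 2))
        var_random += v * weight
    if fit.family == "gaussian":
        var_add = fit.scale
    elif fit.family == "poisson":
        lam = float(np.exp(fit.params.get("Intercept", fit.params.iloc[0])))
        var_add = float(np.log1p(1.0 / lam))
    else:
        raise ValueError(f"unsupported family {fit.family!r}")
    denom = var_fixed + var_random + var_add
    return var_fixed / denom, (var_fixed + var_random) / denom


def aic(fit: FitResult) -> float:
    """Akaike information criterion: 2k - 2 loglik.

    k counts fixed coefficients plus variance components (plus the
    residual variance for gaussian fits). Only valid for ML fits; a REML
    fit would make fixed-structure comparisons invalid and is rejected.
    """
    if "reml" in fit.method.lower():
        raise ValueError("AIC comparison requires an ML fit, not REML")
    return fit.aic
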