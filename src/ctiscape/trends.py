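"""Temporal trend models for CTI, assemblages, species and sites.

All mixed models share the random structure the monitoring analysis
settled on: crossed random intercepts for Site, Year (categorical) and the
50-km grid cell, plus (for community-level responses) a random Year slope
within Site. Year enters fixed effects centred; coefficients are per
calendar year. Estimation is ML throughout so likelihood-ratio tests and
AIC comparisons are valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2 as chi2_dist

from .mixedmodels import FitResult, RandomTerm, fit_gaussian_mixed, fit_poisson_mixed

logger = logging.getLogger(__name__)

__all__ = [
    "grid50_assign",
    "fit_cti_trend",
    "fit_assemblage_trend",
    "fit_species_trend",
    "fit_site_trend",
    "site_trend_table",
    "likelihood_ratio_test",
    "trend_correlogram",
    "CorrelogramResult",
]


def grid50_assign(easting: float, northing: float) -> str:
    """50-km national-grid cell id of a projected coordinate (metres)."""
    if easting < 0 or northing < 0:
        raise ValueError(f"coordinates must be non-negative, got ({easting}, {northing})")
    return f"E{int(easting // 50000)}N{int(northing // 50000)}"


def _with_grid50(records: pd.DataFrame, site_table: pd.DataFrame | None) -> pd.DataFrame:
    df = records.copy()
    if "easting" not in df.columns:
        if site_table is None:
            raise ValueError("need site coordinates (pass site_table) for the 50-km grid term")
        df = df.merge(site_table[["site_id", "easting", "northing"]], on="site_id", how="left")
        if df["easting"].isna().any():
            missing = sorted(df.loc[df["easting"].isna(), "site_id"].unique())
            raise ValueError(f"sites missing from site_table: {missing}")
    df["grid50"] = [grid50_assign(e, n) for e, n in zip(df["easting"], df["northing"])]
    return df


def _standard_terms(df: pd.DataFrame, year_c: np.ndarray, random_slope: bool) -> list[RandomTerm]:
    terms = [
        RandomTerm.from_labels("site", df["site_id"]),
        RandomTerm.from_labels("year", df["year"]),
        RandomTerm.from_labels("grid50", df["grid50"]),
    ]
    if random_slope:
        terms.append(RandomTerm.from_labels("site_slope", df["site_id"], values=year_c))
    return terms


def fit_cti_trend(
    index_records: pd.DataFrame,
    site_table: pd.DataFrame | None = None,
    random_slope: bool = True,
    lrt: bool = True,
    theta0=None,
    reml: bool = False,
) -> tuple[FitResult, tuple[float, int, float] | None]:
    """Gaussian mixed model ``CTI ~ year`` with the standard random structure.

    Returns the fit (slope in deg C per year under ``year_c``) and, when
    ``lrt`` is requested, the likelihood-ratio test of the fixed Year
    effect against the same model without it. The LRT pair is always ML;
    ``reml=True`` (for interval estimation only) excludes the LRT.
    """
    if reml and lrt:
        raise ValueError("likelihood-ratio testing requires ML; call with lrt=False for REML")
    df = _with_grid50(index_records, site_table)
    if df["site_id"].nunique() < 2 or df["year"].nunique() < 3:
        raise ValueError("need at least 2 sites and 3 years to fit a CTI trend")
    year_c = (df["year"] - df["year"].mean()).to_numpy(dtype=float)
    X = pd.DataFrame({"Intercept": np.ones(len(df)), "year_c": year_c})
    terms = _standard_terms(df, year_c, random_slope)
    full = fit_gaussian_mixed(df["cti"].to_numpy(), X, terms, theta0=theta0, reml=reml)
    if not full.converged:
        logger.warning("CTI trend model did not converge cleanly: %s", full.message)
    test = None
    if lrt:
        reduced = fit_gaussian_mixed(df["cti"].to_numpy(), X[["Intercept"]], terms)
        test = likelihood_ratio_test(full, reduced)
    return full, test


def _poisson_response(values: pd.Series, what: str) -> np.ndarray:
    y = values.to_numpy(dtype=float)
    if np.all(y == 0):
        raise ValueError(f"all-zero {what} series cannot be modelled")
    rounded = np.round(y)  # banker's rounding, half to even
    if not np.allclose(y, rounded):
        logger.warning("%s: non-integer values rounded half-to-even for the Poisson family", what)
    return rounded


def fit_assemblage_trend(
    index_records: pd.DataFrame,
    assemblage: str,
    response: str = "total_abundance",
    site_table: pd.DataFrame | None = None,
    random_slope: bool = True,
    theta0=None,
) -> FitResult:
    """Poisson GLMM trend in assemblage total abundance or richness.

    ``index_records`` is the per-site-year community table (columns
    ``abundance_<g>`` / ``richness_<g>``). The slope is the log change per
    year in the chosen response of the chosen STI-quartile assemblage.
    """
    col = {"total_abundance": f"abundance_{assemblage}", "richness": f"richness_{assemblage}"}
    if response not in col:
        raise ValueError(f"response must be one of {sorted(col)}")
    df = _with_grid50(index_records, site_table)
    y = _poisson_response(df[col[response]], f"{assemblage} {response}")
    year_c = (df["year"] - df["year"].mean()).to_numpy(dtype=float)
    X = pd.DataFrame({"Intercept": np.ones(len(df)), "year_c": year_c})
    terms = _standard_terms(df, year_c, random_slope)
    fit = fit_poisson_mixed(y, X, terms, theta0=theta0)
    if not fit.converged:
        logger.warning("assemblage trend (%s, %s) convergence flagged", assemblage, response)
    return fit


@dataclass
class SpeciesTrend:
    species_id: str
    coefficient: float
    se: float
    z: float
    n_sites: int
    n_years: int
    single_site: bool = False


def fit_species_trend(
    abundance_table: pd.DataFrame, species_id: str
) -> SpeciesTrend | None:
    """Per-species abundance trend: Poisson GLMM with a Site random intercept.

    The z value (slope / SE) approximates the species' contribution to its
    assemblage trend. Species observed at a single site fall back to a
    plain Poisson regression (flagged); species with fewer than 2 sites'
    *and* 3 years' data are skipped with a log message.
    """
    df = abundance_table[
        (abundance_table["species_id"] == species_id) & abundance_table["index_available"]
    ]
    n_sites = df["site_id"].nunique()
    n_years = df["year"].nunique()
    if n_years < 3 or len(df) < 4:
        logger.info("skipping species %s: insufficient data (%d sites, %d years)",
                    species_id, n_sites, n_years)
        return None
    y = _poisson_response(df["abundance"], f"species {species_id}")
    year_c = (df["year"] - df["year"].mean()).to_numpy(dtype=float)
    X = pd.DataFrame({"Intercept": np.ones(len(df)), "year_c": year_c})
    single = n_sites < 2
    terms = [] if single else [RandomTerm.from_labels("site", df["site_id"])]
    fit = fit_poisson_mixed(y, X, terms)
    coef = float(fit.params["year_c"])
    se = float(fit.bse["year_c"])
    return SpeciesTrend(
        species_id=species_id,
        coefficient=coef,
        se=se,
        z=coef / se,
        n_sites=n_sites,
        n_years=n_years,
        single_site=single,
    )


def fit_site_trend(
    index_records: pd.DataFrame,
    site_id: str,
    assemblage: str,
    min_years: int = 6,
) -> dict | None:
    """Quasipoisson trend in one site's assemblage total abundance.

    A plain GLM per site with a free dispersion parameter (Pearson
    chi-square / df) absorbing overdispersion. Sites with fewer than
    ``min_years`` distinct years are skipped with a log message. The slope
    is scale-equivariant: multiplying all counts by a constant changes
    neither the slope nor its z value.
    """
    df = index_records[index_records["site_id"] == site_id]
    if df["year"].nunique() < min_years:
        logger.info("skipping site %s: fewer than %d years", site_id, min_years)
        return None
    y = _poisson_response(df[f"abundance_{assemblage}"], f"site {site_id} {assemblage}")
    year_c = (df["year"] - df["year"].mean()).to_numpy(dtype=float)
    X = sm.add_constant(pd.DataFrame({"year_c": year_c}))
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit(scale="X2")
    return {
        "site_id": site_id,
        "assemblage": assemblage,
        "slope": float(res.params["year_c"]),
        "se": float(res.bse["year_c"]),
        "dispersion": float(res.scale),
        "n_years": int(df["year"].nunique()),
    }


def site_trend_table(
    index_records: pd.DataFrame, assemblage: str, min_years: int = 6
) -> pd.DataFrame:
    """Per-site quasipoisson slopes for one assemblage (scatter-plot data)."""
    rows = []
    for site in index_records["site_id"].unique():
        res = fit_site_trend(index_records, site, assemblage, min_years=min_years)
        if res is not None:
            rows.append(res)
    return pd.DataFrame(rows)


def likelihood_ratio_test(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """LRT of two nested ML fits on the same data: (chi2, df, p)."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("LRT requires fits on identical data (n_obs differ)")
    if full.family != reduced.family:
        raise ValueError("LRT requires the same response family")
    df = full.k_params - reduced.k_params
    if df <= 0:
        raise ValueError("models are not nested (no extra parameters in the full model)")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return chi2, df, float(chi2_dist.sf(chi2, df))


@dataclass
class CorrelogramResult:
    """Distance-binned Moran's I of per-site trend slopes."""

    bin_mid_km: np.ndarray
    morans_i: np.ndarray
    n_pairs: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def trend_correlogram(
    slopes,
    coordinates,
    n_bins: int = 8,
    n_permutations: int = 199,
    seed: int = 0,
) -> CorrelogramResult:
    """Spatial autocorrelation of site-level slopes, binned Moran's I.

    Distance classes are equal-width up to half the maximum inter-site
    distance; the confidence band is the 2.5-97.5% envelope of Moran's I
    under random permutation of slopes across sites. (A binned Moran's I
    with a permutation envelope serves the same detection purpose as a
    spline correlogram with far less machinery.)
    """
    z = np.asarray(slopes, dtype=float)
    xy = np.asarray(coordinates, dtype=float)
    if len(z) < 10:
        raise ValueError("need at least 10 sites for a correlogram")
    if np.allclose(z, z[0]):
        raise ValueError("all slopes identical: Moran's I undefined")
    z = z - z.mean()
    denom = float(z @ z)
    n = len(z)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, k=1)
    dmax = d[iu].max() / 2.0
    edges = np.linspace(0.0, dmax, n_bins + 1)
    which = np.digitize(d[iu], edges) - 1

    def morans(zv):
        zc = zv - zv.mean()
        cross = zc[iu[0]] * zc[iu[1]]
        out = np.full(n_bins, np.nan)
        for b in range(n_bins):
            m = which == b
            w = m.sum()
            if w:
                out[b] = (n / (2.0 * w)) * (2.0 * cross[m].sum()) / float(zc @ zc)
        return out

    obs = morans(z)
    rng = np.random.default_rng(seed)
    sims = np.array([morans(rng.permutation(z)) for _ in range(n_permutations)])
    lower = np.nanpercentile(sims, 2.5, axis=0)
    upper = np.nanpercentile(sims, 97.5, axis=0)
    n_pairs = np.array([(which == b).sum() for b in range(n_bins)])
    return CorrelogramResult(
        bin_mid_km=(edges[:-1] + edges[1:]) / 2.0 / 1000.0,
        morans_i=obs,
        n_pairs=n_pairs,
        lower=lower,
        upper=upper,
    )
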