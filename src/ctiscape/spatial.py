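"""Spatial variation of CTI with local land use, and back-calculation.

If CTI varies across space with habitat composition, an observed temporal
CTI trend could in principle be produced by habitat change alone. The
spatial model regresses site-year CTI on five land-use percentage covers
in the 0.5-km buffer (arable, improved grassland, urban/suburban,
broadleaved woodland, low-intensity grassland) plus easting and northing,
with Site / Year / 50-km-grid random intercepts. Its coefficients are
then inverted: how much would a cover have to change to account for the
cumulative CTI change implied by the fitted annual trend?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixedmodels import FitResult, RandomTerm, fit_gaussian_mixed
from .trends import _with_grid50

__all__ = [
    "SPATIAL_COVARIATES",
    "fit_spatial_cti",
    "cumulative_cti_change",
    "required_cover_change",
    "RequiredChange",
]

#: habitat covers entering the spatial model, as buffer-metric columns
SPATIAL_COVARIATES = {
    "arable": ("arable",),
    "urban_suburban": ("urban_suburban",),
    "woodland_broadleaf": ("woodland_broadleaf",),
    # grassland split depends on the improved-grassland variant
}


def _grassland_split(variant: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(improved, low-intensity) grassland category sets for IG1/IG2."""
    if variant == "IG1":
        return ("grassland_generic", "grassland_lowland_meadow"), ("grassland_calcareous",)
    if variant == "IG2":
        return ("grassland_generic",), ("grassland_calcareous", "grassland_lowland_meadow")
    raise ValueError(f"unknown grassland variant {variant!r}")


def spatial_design(
    index_records: pd.DataFrame,
    buffer_metrics: pd.DataFrame,
    site_table: pd.DataFrame,
    variant: str = "IG1",
    radius: float = 500.0,
) -> pd.DataFrame:
    """Merge CTI records with % covers at the smallest radius.

    Covers are percentages of the buffer (0-100); easting/northing in km
    so coefficients stay readable.
    """
    improved, low_int = _grassland_split(variant)
    sel = buffer_metrics[buffer_metrics["radius"] == radius].set_index("site_id")
    missing = set(index_records["site_id"]) - set(sel.index)
    if missing:
        raise ValueError(f"no buffer metrics at {radius} m for sites: {sorted(missing)}")
    covers = pd.DataFrame(index=sel.index)
    covers["arable_pct"] = sel["prop_arable"] * 100.0
    covers["urban_pct"] = sel["prop_urban_suburban"] * 100.0
    covers["woodland_pct"] = sel["prop_woodland_broadleaf"] * 100.0
    covers["improved_grassland_pct"] = sum(sel[f"prop_{c}"] for c in improved) * 100.0
    covers["low_intensity_grassland_pct"] = sum(sel[f"prop_{c}"] for c in low_int) * 100.0
    df = index_records.merge(covers, left_on="site_id", right_index=True)
    df = df.merge(site_table[["site_id", "easting", "northing"]], on="site_id", how="left")
    return df


HABITAT_TERMS = (
    "arable_pct",
    "improved_grassland_pct",
    "urban_pct",
    "woodland_pct",
    "low_intensity_grassland_pct",
)


def fit_spatial_cti(
    index_records: pd.DataFrame,
    buffer_metrics: pd.DataFrame,
    site_table: pd.DataFrame,
    variant: str = "IG1",
    radius: float = 500.0,
) -> FitResult:
    """Gaussian mixed model: CTI ~ five % covers + easting + northing.

    Coefficients are deg C per percentage point of cover. Raises if the
    habitat covariates are (near-)collinear or constant across sites.
    """
    df = spatial_design(index_records, buffer_metrics, site_table, variant, radius)
    df = _with_grid50(df, None)
    X = pd.DataFrame({"Intercept": np.ones(len(df))})
    for term in HABITAT_TERMS:
        X[term] = df[term].to_numpy()
    X["easting_km"] = df["easting"].to_numpy() / 1000.0
    X["northing_km"] = df["northing"].to_numpy() / 1000.0
    spread = X[list(HABITAT_TERMS)].std()
    flat = spread[spread < 1e-9].index.tolist()
    if flat:
        raise ValueError(f"habitat covers constant across sites: {flat}")
    centred = X.iloc[:, 1:] - X.iloc[:, 1:].mean()
    scaled = centred / centred.std()
    cond = np.linalg.cond(scaled.to_numpy())
    if cond > 1e8:
        corr = scaled.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(
            f"collinear habitat covariates (condition number {cond:.2g}); worst pair: {worst}"
        )
    terms = [
        RandomTerm.from_labels("site", df["site_id"]),
        RandomTerm.from_labels("year", df["year"]),
        RandomTerm.from_labels("grid50", df["grid50"]),
    ]
    return fit_gaussian_mixed(df["cti"].to_numpy(), X, terms)


def cumulative_cti_change(annual_coefficient: float, first_year: int, last_year: int) -> float:
    """Total CTI change implied by an annual trend over a monitoring span."""
    span = last_year - first_year
    if span <= 0:
        raise ValueError(f"last_year must exceed first_year (span {span})")
    return annual_coefficient * span


@dataclass
class RequiredChange:
    """Cover change needed for habitat alone to explain a CTI change."""

    habitat: str
    delta_cti: float
    beta: float  # deg C per unit proportion of cover
    required_change: float  # proportion points
    current_cover: float
    feasible: bool

    @property
    def required_change_pct(self) -> float:
        return self.required_change * 100.0


def required_cover_change(
    delta_cti: float,
    beta: float,
    current_cover: float = 0.0,
    habitat: str = "",
) -> RequiredChange:
    """Invert a spatial CTI-habitat slope: required_change = delta_cti / beta.

    ``beta`` is in deg C per unit proportion (a percentage-point
    coefficient times 100). Feasibility requires the implied final cover
    to stay inside [0, 1]. Only single-habitat solutions are computed;
    combinations of habitats trade off linearly and are left to the
    reader.
    """
    if abs(beta) <= 1e-9:
        raise ValueError("uninformative coefficient: |beta| is effectively zero")
    required = delta_cti / beta
    final = current_cover + required
    return RequiredChange(
        habitat=habitat,
        delta_cti=delta_cti,
        beta=beta,
        required_change=required,
        current_cover=current_cover,
        feasible=bool(0.0 <= final <= 1.0),
    )
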