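"""Input readers, run configuration, temperature handling and orchestration.

Input formats are deliberately plain: delimited text tables for species
temperature indices, abundance indices, sites and temperatures, and an
ESRI ASCII grid for land cover. ``run_pipeline`` chains every analysis
stage — filters, community indices, trend models, interaction/selection
models, the spatial CTI model and the habitat back-calculation — into one
deterministic, seeded run whose outputs all carry the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import indices, spatial, trends
from .interactions import select_best
from .landcover import RADII_M, HighIntensityCombo, metrics_for_all_sites, read_ascii_grid

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    abundance_path: str
    sti_path: str
    sites_path: str
    landcover_path: str
    temperature_path: str
    output_dir: str
    taxon: str = "synthetic"
    min_species: int = 10
    min_coverage: float = 0.75
    min_years: int = 6
    quartile_scope: str = "full"  # or "filtered"
    combo_codes: list = field(default_factory=lambda: list(HighIntensityCombo.all_combos()))
    radii: list = field(default_factory=lambda: list(RADII_M))
    grassland_variant: str = "IG1"
    temperature_mode: str = "site-mean"  # or "site-year"
    species_exclusions: list = field(default_factory=list)
    drop_missing_sti: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.quartile_scope not in {"full", "filtered"}:
            raise ValueError("quartile_scope must be 'full' or 'filtered'")
        if self.temperature_mode not in {"site-mean", "site-year"}:
            raise ValueError("temperature_mode must be 'site-mean' or 'site-year'")
        if self.grassland_variant not in {"IG1", "IG2"}:
            raise ValueError("grassland_variant must be 'IG1' or 'IG2'")
        combos = []
        for c in self.combo_codes:
            if isinstance(c, HighIntensityCombo):
                combos.append(c)
            elif isinstance(c, str):
                code, _, sea = c.partition("+sea")
                combos.append(HighIntensityCombo(code.rstrip("+"), sea != "" or c.endswith("+sea")))
            else:
                raise ValueError(f"bad combo entry {c!r}")
        self.combo_codes = combos

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        payload = {k: (v if not isinstance(v, list) else [str(x) for x in v])
                   for k, v in asdict(self).items()}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class ValidationError(ValueError):
    pass


def read_sti_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("species_id", "sti"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if df["species_id"].duplicated().any():
        dup = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise ValidationError(f"{path}: duplicate species ids {dup}")
    if not np.isfinite(df["sti"]).all():
        raise ValidationError(f"{path}: non-finite STI values")
    return df[["species_id", "sti"]]


def read_abundance_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str, "species_id": str})
    needed = ["site_id", "year", "species_id", "abundance", "index_available"]
    for col in needed:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    df["index_available"] = df["index_available"].astype(bool)
    bad = df.index[df["index_available"] & df["abundance"].isna()]
    if len(bad):
        raise ValidationError(
            f"{path}: abundance missing but index_available=True at data rows "
            f"{[int(i) + 2 for i in bad[:10]]}"
        )
    neg = df.index[df["abundance"] < 0]
    if len(neg):
        raise ValidationError(
            f"{path}: negative abundance at data rows {[int(i) + 2 for i in neg[:10]]}"
        )
    dup = df.duplicated(["site_id", "year", "species_id"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate (site, year, species) at data rows "
            f"{[int(i) + 2 for i in df.index[dup][:10]]}"
        )
    return df[needed]


def read_site_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str})
    for col in ("site_id", "easting", "northing"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    if df["site_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate site ids")
    return df


def read_temperature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str})
    month_cols = [c for c in df.columns if c.startswith("month_")]
    if "temperature" not in df.columns:
        if len(month_cols) != 12:
            raise ValidationError(
                f"{path}: need a 'temperature' column or 12 month_* columns"
            )
        df["temperature"] = df[month_cols].apply(
            lambda row: annual_mean_temperature(row.to_numpy()), axis=1
        )
    if df.duplicated(["site_id", "year"]).any():
        raise ValidationError(f"{path}: duplicate (site, year) rows")
    return df[["site_id", "year", "temperature"]]


def annual_mean_temperature(monthly) -> float:
    """Unweighted mean of 12 monthly mean temperatures (deg C)."""
    m = np.asarray(monthly, dtype=float)
    if m.shape != (12,):
        raise ValueError(f"need exactly 12 monthly values, got shape {m.shape}")
    if not np.isfinite(m).all():
        raise ValueError("monthly temperatures contain non-finite values")
    return float(m.mean())


def site_mean_temperature(temperature_table: pd.DataFrame, site_id, recorded_years) -> float:
    """Mean annual temperature of one site over its recorded years only."""
    years = set(recorded_years)
    sel = temperature_table[
        (temperature_table["site_id"] == site_id)
        & temperature_table["year"].isin(years)
    ]
    if sel.empty:
        raise ValueError(f"site {site_id}: no temperature overlap with recorded years")
    return float(sel["temperature"].mean())


@dataclass
class Dataset:
    abundance: pd.DataFrame
    sti: pd.DataFrame
    sites: pd.DataFrame
    temperature: pd.DataFrame
    grid: object
    validation: list[str] = field(default_factory=list)


def read_inputs(config: RunConfig) -> Dataset:
    """Read and cross-validate every input file."""
    abundance = read_abundance_table(config.abundance_path)
    sti = read_sti_table(config.sti_path)
    sites = read_site_table(config.sites_path)
    temperature = read_temperature_table(config.temperature_path)
    grid = read_ascii_grid(config.landcover_path)
    report: list[str] = []
    orphan = sorted(set(abundance["species_id"]) - set(sti["species_id"]))
    if orphan:
        msg = f"species in abundance but not in STI table: {orphan}"
        report.append(msg)
        if not config.drop_missing_sti:
            raise ValidationError(msg)
        logger.warning("%s (dropped)", msg)
    orphan_sites = sorted(set(abundance["site_id"]) - set(sites["site_id"]))
    if orphan_sites:
        raise ValidationError(f"sites in abundance but not in site table: {orphan_sites}")
    logger.info(
        "inputs: %d abundance rows, %d species, %d sites, %d temperature rows, grid %s",
        len(abundance), len(sti), len(sites), len(temperature), grid.shape,
    )
    return Dataset(abundance, sti, sites, temperature, grid, report)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Returns a dict of the in-memory artefacts; delimited-text copies and a
    markdown report land in ``config.output_dir``, all stamped with the
    config hash and seed.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.hash(), "seed": config.seed}
    artefacts: dict = {"stamp": stamp}
    t0 = time.time()

    def stage(name):
        logger.info("stage %-14s t=%.1fs", name, time.time() - t0)

    try:
        stage("read")
        data = read_inputs(config)
        abundance = data.abundance
        if config.species_exclusions:
            before = len(abundance)
            abundance = abundance[~abundance["species_id"].isin(config.species_exclusions)]
            logger.info("excluded %d rows of %d for %d species",
                        before - len(abundance), before, len(config.species_exclusions))

        stage("filters")
        filtered = indices.filter_site_years(abundance, config.min_species, config.min_coverage)
        filtered = indices.filter_sites(filtered, config.min_years)
        sti_scope = data.sti if config.quartile_scope == "full" else data.sti[
            data.sti["species_id"].isin(filtered["species_id"].unique())
        ]
        labelled = indices.assign_assemblages(sti_scope)

        stage("indices")
        community = indices.community_index_table(
            filtered, labelled, drop_missing_sti=config.drop_missing_sti
        )
        artefacts["community"] = community

        stage("trends")
        cti_fit, cti_lrt = trends.fit_cti_trend(community, data.sites)
        assemblage_fits = {}
        for g in indices.ASSEMBLAGES:
            assemblage_fits[g] = {
                resp: trends.fit_assemblage_trend(community, g, resp, data.sites)
                for resp in ("total_abundance", "richness")
            }
        artefacts["cti_fit"], artefacts["cti_lrt"] = cti_fit, cti_lrt
        artefacts["assemblage_fits"] = assemblage_fits

        stage("landcover")
        metrics = metrics_for_all_sites(
            data.grid,
            data.sites[data.sites["site_id"].isin(community["site_id"].unique())],
            radii=config.radii,
            combos=config.combo_codes,
        )
        artefacts["buffer_metrics"] = metrics

        stage("interactions")
        selections = {}
        for g in ("low", "high"):
            table, best = select_best(
                community, metrics, data.temperature, g,
                combos=config.combo_codes, radii=config.radii, site_table=data.sites,
            )
            selections[g] = {"table": table, "best": best}
        artefacts["selections"] = selections

        stage("spatial")
        spatial_fit = spatial.fit_spatial_cti(
            community, metrics, data.sites, variant=config.grassland_variant
        )
        artefacts["spatial_fit"] = spatial_fit
        years = community["year"]
        delta = spatial.cumulative_cti_change(
            float(cti_fit.params["year_c"]), int(years.min()), int(years.max())
        )
        required = []
        for term in spatial.HABITAT_TERMS:
            beta_pct = float(spatial_fit.params[term])
            beta_prop = beta_pct * 100.0  # per unit proportion
            if abs(beta_prop) > 1e-9:
                required.append(spatial.required_cover_change(delta, beta_prop, habitat=term))
        artefacts["cumulative_cti_change"] = delta
        artefacts["required_changes"] = required

        stage("site-trends")
        site_slopes = {
            g: trends.site_trend_table(community, g, min_years=config.min_years)
            for g in ("low", "high")
        }
        artefacts["site_trends"] = site_slopes
        # Fig.3-shaped scatter: per-site slope vs high-intensity proportion
        best_low = selections["low"]["best"]
        if best_low is not None and not site_slopes["low"].empty:
            col = f"prop_{best_low.combo.label}"
            sel_metrics = metrics[metrics["radius"] == best_low.radius]
            artefacts["slope_vs_landuse"] = site_slopes["low"].merge(
                sel_metrics[["site_id", col]], on="site_id"
            ).rename(columns={col: "high_intensity_proportion"})

        stage("correlogram")
        slopes_low = site_slopes["low"]
        correlogram = None
        if len(slopes_low) >= 10 and slopes_low["slope"].nunique() > 1:
            coords = data.sites.set_index("site_id").loc[
                slopes_low["site_id"], ["easting", "northing"]
            ].to_numpy()
            correlogram = trends.trend_correlogram(
                slopes_low["slope"].to_numpy(), coords, seed=config.seed
            )
        artefacts["correlogram"] = correlogram

        stage("species-trends")
        species_rows = []
        for sp in sorted(filtered["species_id"].unique()):
            res = trends.fit_species_trend(filtered, sp)
            if res is not None:
                species_rows.append(res.__dict__)
        artefacts["species_trends"] = pd.DataFrame(species_rows)

        stage("write")
        _write_outputs(config, artefacts, out_dir)
    except Exception:
        (out_dir / "FAILED").write_text(
            f"pipeline failed; partial outputs retained. {stamp}\n"
        )
        raise
    return artefacts


def _fit_block(name, fit) -> str:
    lines = [f"### {name}", "", "term\testimate\tse\tz\tp"]
    frame = fit.summary_frame()
    for term, row in frame.iterrows():
        lines.append(
            f"{term}\t{row['estimate']:.5g}\t{row['se']:.3g}\t{row['z']:.3g}\t{row['p']:.3g}"
        )
    vc = ", ".join(f"{k}={v:.4g}" for k, v in fit.vc.items())
    lines.append(f"variance components: {vc}; loglik {fit.loglik:.2f}; AIC {fit.aic:.2f}")
    if fit.singular:
        lines.append("note: at least one variance component at the boundary (singular fit)")
    lines.append("")
    return "\n".join(lines)


def _write_outputs(config: RunConfig, artefacts: dict, out_dir: Path) -> None:
    stamp = artefacts["stamp"]
    artefacts["community"].to_csv(out_dir / "community_indices.csv", index=False)
    artefacts["buffer_metrics"].to_csv(out_dir / "buffer_metrics.csv", index=False)
    for g, sel in artefacts["selections"].items():
        sel["table"].to_csv(out_dir / f"selection_{g}.csv", index=False)
    for g, tab in artefacts["site_trends"].items():
        tab.to_csv(out_dir / f"site_trends_{g}.csv", index=False)
    if not artefacts["species_trends"].empty:
        artefacts["species_trends"].to_csv(out_dir / "species_trends.csv", index=False)
    if artefacts.get("slope_vs_landuse") is not None:
        artefacts["slope_vs_landuse"].to_csv(out_dir / "slope_vs_landuse.csv", index=False)
    corr = artefacts.get("correlogram")
    if corr is not None:
        pd.DataFrame(
            {
                "distance_km": corr.bin_mid_km,
                "morans_i": corr.morans_i,
                "n_pairs": corr.n_pairs,
                "envelope_lower": corr.lower,
                "envelope_upper": corr.upper,
            }
        ).to_csv(out_dir / "trend_correlogram.csv", index=False)

    lines = [
        f"# Community change report ({config.taxon})",
        "",
        f"config hash {stamp['config_hash']}, seed {stamp['seed']}",
        "",
        "## CTI trend",
        "",
        _fit_block("CTI ~ year (gaussian mixed model)", artefacts["cti_fit"]),
    ]
    if artefacts["cti_lrt"] is not None:
        chi2, df, p = artefacts["cti_lrt"]
        lines.append(f"Year effect LRT: chi2={chi2:.2f}, df={df}, p={p:.3g}")
    lines += ["", "## Assemblage trends", ""]
    for g, fits in artefacts["assemblage_fits"].items():
        for resp, fit in fits.items():
            slope = fit.params["year_c"]
            se = fit.bse["year_c"]
            z = slope / se
            lines.append(f"- {g} {resp}: {slope:+.4f} +/- {se:.4f} (z={z:.2f})")
    lines += ["", "## Land-use interaction models", ""]
    for g, sel in artefacts["selections"].items():
        best = sel["best"]
        if best is None:
            lines.append(f"- {g}: no converged fits")
            continue
        coef, se, z, p = best.interaction_landuse
        ct, cse, cz, cp = best.interaction_temperature
        lines.append(
            f"- {g}-STI best model: {best.combo.label} at {best.radius/1000:g} km; "
            f"Year x land-use {coef:+.3f} +/- {se:.3f} (z={z:.2f}, p={p:.3g}); "
            f"Year x temperature {ct:+.3f} +/- {cse:.3f} (z={cz:.2f}, p={cp:.3g}); "
            f"R2 marginal {best.marginal_r2:.2f} conditional {best.conditional_r2:.2f}"
        )
    lines += ["", "## Spatial CTI model", "", _fit_block("CTI ~ habitat covers", artefacts["spatial_fit"])]
    lines.append(
        f"cumulative CTI change over the record: {artefacts['cumulative_cti_change']:+.3f} deg C"
    )
    for rc in artefacts["required_changes"]:
        lines.append(
            f"- {rc.habitat}: required change {rc.required_change_pct:+.1f} percentage points "
            f"({'feasible' if rc.feasible else 'not feasible'})"
        )
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
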