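"""Seeded synthetic monitoring data with the structure the analysis assumes.

The generator is the testbed for the whole pipeline: it produces a species
pool with species temperature indices (STIs), a smoothed-noise categorical
landscape with monitoring sites embedded in it, site-year mean
temperatures, and overdispersed count data whose log expectation follows
the same model family the pipeline fits::

    log mu[i, s, t] = a_i + u_s + v_t + w_g(s)
                      + (beta_g(i) + delta_g(i) * H_s + gamma_g(i) * Tc_s
                         + slope_noise_s) * (t - t_bar)

with ``a_i`` species intercepts, crossed site / year / 50-km-grid random
effects, ``H_s`` the proportion of high-intensity land in a buffer around
site ``s``, ``Tc_s`` the centred site mean temperature, and per-assemblage
trend (``beta``), land-use-interaction (``delta``) and
temperature-interaction (``gamma``) coefficients. Year effects are shared
across sites and species (common weather shocks). Counts are Poisson, or
gamma-mixed Poisson (negative binomial) when ``overdispersion > 0``.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import indices
from .landcover import (
    CATEGORIES,
    DEFAULT_CODES,
    HighIntensityCombo,
    LandCoverGrid,
    buffer_cover,
    write_ascii_grid,
)

ASSEMBLAGES = indices.ASSEMBLAGES


def _per_assemblage(value) -> dict[str, float]:
    if isinstance(value, dict):
        missing = set(ASSEMBLAGES) - set(value)
        if missing:
            raise ValueError(f"per-assemblage dict missing {sorted(missing)}")
        return {g: float(value[g]) for g in ASSEMBLAGES}
    return {g: float(value) for g in ASSEMBLAGES}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate a bird-scheme study.

    Trend defaults are the bird assemblage abundance trends of the source
    monitoring analysis (log-abundance per year); land-use and temperature
    interactions default to zero and are switched on per scenario.
    """

    seed: int = 0
    n_species: int = 60
    n_sites: int = 150
    year_start: int = 1990
    year_end: int = 2014
    # species pool
    sti_mean: float = 10.5
    sti_sd: float = 1.5
    baseline_log_abundance_mean: float = 2.0
    baseline_log_abundance_sd: float = 0.7
    # per-assemblage dynamics (log-abundance / yr and interactions)
    trend: dict = field(
        default_factory=lambda: {
            "low": -0.025,
            "medium_low": 0.006,
            "medium_high": 0.010,
            "high": -0.013,
        }
    )
    landuse_interaction: dict = field(default_factory=lambda: dict.fromkeys(ASSEMBLAGES, 0.0))
    temperature_interaction: dict = field(default_factory=lambda: dict.fromkeys(ASSEMBLAGES, 0.0))
    # variance components (log scale)
    sigma_site: float = 0.5
    sigma_year: float = 0.08
    sigma_grid: float = 0.2
    sigma_slope: float = 0.004
    overdispersion: float = 0.0
    # observation model
    p_missing_index: float = 0.05
    p_unsurveyed_year: float = 0.10
    # landscape
    cell_size: float = 100.0
    site_spacing: float = 8000.0
    site_jitter: float = 0.3
    blur_sigma_m: float = 800.0
    category_targets: dict = field(
        default_factory=lambda: {
            "arable": 0.30,
            "urban_suburban": 0.12,
            "grassland_generic": 0.18,
            "grassland_calcareous": 0.04,
            "grassland_lowland_meadow": 0.04,
            "woodland_broadleaf": 0.17,
            "sea": 0.0,
            "other": 0.15,
        }
    )
    landuse_combo: str = "A+U"
    landuse_combo_sea: bool = False
    landuse_radius: float = 2000.0
    # temperature field
    temp_mean: float = 9.5
    temp_gradient_per_100km: float = -1.5
    temp_site_sd: float = 0.4
    temp_year_sd: float = 0.5
    temp_noise_sd: float = 0.15

    def __post_init__(self):
        if self.year_end <= self.year_start:
            raise ValueError("year_end must exceed year_start")
        for name in (
            "sti_sd", "baseline_log_abundance_sd", "sigma_site", "sigma_year",
            "sigma_grid", "sigma_slope", "overdispersion",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_missing_index", "p_unsurveyed_year"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        self.trend = _per_assemblage(self.trend)
        self.landuse_interaction = _per_assemblage(self.landuse_interaction)
        self.temperature_interaction = _per_assemblage(self.temperature_interaction)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def combo(self) -> HighIntensityCombo:
        return HighIntensityCombo(self.landuse_combo, self.landuse_combo_sea)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))

    def _rngs(self, n: int = 6) -> list[np.random.Generator]:
        seqs = np.random.SeedSequence(self.seed).spawn(n)
        return [np.random.default_rng(s) for s in seqs]


@dataclass
class SyntheticDataset:
    """All tables of one synthetic study, referentially consistent."""

    config: SimulationConfig
    sti_table: pd.DataFrame
    species_params: pd.DataFrame
    site_table: pd.DataFrame
    grid: LandCoverGrid
    temperature_table: pd.DataFrame
    abundance_table: pd.DataFrame
    landuse_proportion: pd.Series  # per site, at config combo/radius


def generate_species_pool(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Species pool: STI values, quartile assemblage labels, intercepts.

    STIs are normal(sti_mean, sti_sd); assemblages come from the
    rank-based quartile split; per-species baseline log abundances are
    normal(baseline mean, sd).
    """
    if config.n_species < 4:
        raise ValueError("need at least 4 species")
    rng = rng or config._rngs()[0]
    ids = [f"sp{i:03d}" for i in range(config.n_species)]
    sti = rng.normal(config.sti_mean, config.sti_sd, config.n_species)
    table = pd.DataFrame({"species_id": ids, "sti": sti})
    table = indices.assign_assemblages(table)
    table["baseline_log_abundance"] = rng.normal(
        config.baseline_log_abundance_mean,
        config.baseline_log_abundance_sd,
        config.n_species,
    )
    return table


def _site_layout(config: SimulationConfig, rng) -> pd.DataFrame:
    margin = 10000.0 + 2 * config.cell_size
    ncols = int(np.ceil(np.sqrt(config.n_sites)))
    nrows = int(np.ceil(config.n_sites / ncols))
    jit = config.site_jitter * config.site_spacing
    e = margin + (np.arange(ncols) + 0.5) * config.site_spacing
    n = margin + (np.arange(nrows) + 0.5) * config.site_spacing
    ee, nn = np.meshgrid(e, n)
    pts = np.column_stack([ee.ravel(), nn.ravel()])[: config.n_sites]
    pts += rng.uniform(-jit, jit, size=pts.shape)
    return pd.DataFrame(
        {
            "site_id": [f"S{i:04d}" for i in range(config.n_sites)],
            "easting": pts[:, 0],
            "northing": pts[:, 1],
        }
    )


def generate_landscape(
    config: SimulationConfig, rng=None
) -> tuple[LandCoverGrid, pd.DataFrame]:
    """Clumped categorical landscape plus embedded monitoring sites.

    Independent white-noise fields (one per category with positive target
    proportion) are Gaussian-blurred and combined by offset-shifted argmax;
    the offsets are calibrated iteratively so realized grid-wide category
    proportions land within ~0.02 of the configured targets. Every site's
    10-km buffer fits inside the grid by construction.
    """
    rng = rng or config._rngs()[1]
    sites = _site_layout(config, rng)
    margin = 10000.0 + 2 * config.cell_size
    width = sites["easting"].max() + margin
    height = sites["northing"].max() + margin
    ncols = int(np.ceil(width / config.cell_size))
    nrows = int(np.ceil(height / config.cell_size))
    targets = {k: v for k, v in config.category_targets.items() if v > 0}
    bad = set(config.category_targets) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories in targets: {sorted(bad)}")
    total = sum(targets.values())
    targets = {k: v / total for k, v in targets.items()}
    names = list(targets)
    if len(names) == 1:
        values = np.full((nrows, ncols), DEFAULT_CODES[names[0]], dtype=np.int16)
        grid = LandCoverGrid(values, cell_size=config.cell_size)
        return grid, sites
    sigma_cells = config.blur_sigma_m / config.cell_size
    fields = np.empty((len(names), nrows, ncols), dtype=np.float32)
    for k in range(len(names)):
        f = ndimage.gaussian_filter(
            rng.standard_normal((nrows, ncols)).astype(np.float32), sigma_cells
        )
        fields[k] = (f - f.mean()) / (f.std() + 1e-12)
    offsets = np.zeros(len(names), dtype=np.float32)
    target_vec = np.array([targets[k] for k in names])
    # calibrate offsets on a strided subsample, then label at full resolution
    sub = fields[:, ::3, ::3].reshape(len(names), -1)
    for _ in range(80):
        cat_sub = np.argmax(sub + offsets[:, None], axis=0)
        props = np.bincount(cat_sub, minlength=len(names)) / cat_sub.size
        if np.abs(props - target_vec).max() < 0.015:
            break
        offsets -= 0.8 * np.log((props + 1e-4) / (target_vec + 1e-4)).astype(np.float32)
        offsets = offsets - offsets.mean()
    cat = np.argmax(fields + offsets[:, None, None], axis=0)
    code_of = np.array([DEFAULT_CODES[name] for name in names], dtype=np.int16)
    grid = LandCoverGrid(code_of[cat], cell_size=config.cell_size)
    return grid, sites


def generate_temperature(
    config: SimulationConfig, site_table: pd.DataFrame, rng=None
) -> pd.DataFrame:
    """Site-year mean annual temperatures (deg C).

    A north-south gradient plus site-level noise gives persistent spatial
    contrast; shared annual anomalies plus site-year noise give the
    interannual signal.
    """
    rng = rng or config._rngs()[2]
    years = config.years
    nn = site_table["northing"].to_numpy()
    site_mean = (
        config.temp_mean
        + config.temp_gradient_per_100km * (nn - nn.mean()) / 1e5
        + rng.normal(0.0, config.temp_site_sd, len(site_table))
    )
    anomaly = rng.normal(0.0, config.temp_year_sd, len(years))
    noise = rng.normal(0.0, config.temp_noise_sd, (len(site_table), len(years)))
    temp = site_mean[:, None] + anomaly[None, :] + noise
    out = pd.DataFrame(
        {
            "site_id": np.repeat(site_table["site_id"].to_numpy(), len(years)),
            "year": np.tile(years, len(site_table)),
            "temperature": temp.ravel(),
        }
    )
    return out


def landuse_at_sites(
    config: SimulationConfig, grid: LandCoverGrid, site_table: pd.DataFrame
) -> pd.Series:
    """Proportion of the configured high-intensity combo in each site's buffer."""
    combo_cats = list(config.combo.categories)
    props = []
    for row in site_table.itertuples(index=False):
        cover = buffer_cover(grid, (row.easting, row.northing), config.landuse_radius)
        props.append(float(cover.loc[combo_cats, "proportion"].sum()))
    return pd.Series(props, index=site_table["site_id"].to_numpy(), name="landuse")


def simulate_abundances(
    config: SimulationConfig,
    species: pd.DataFrame,
    site_table: pd.DataFrame,
    landuse: pd.Series,
    temperature: pd.DataFrame,
    rng=None,
) -> pd.DataFrame:
    """Draw the species x site x year count array and return it long-form.

    Only records with a positive count appear (a species is "present" when
    counted); ``index_available`` starts True everywhere and is degraded by
    :func:`apply_observation_model`.
    """
    rng = rng or config._rngs()[3]
    years = config.years
    tc = years - years.mean()
    n_sp, n_si, n_y = len(species), len(site_table), len(years)

    from .trends import grid50_assign  # local import to avoid cycle at import time

    a = species["baseline_log_abundance"].to_numpy()
    beta = species["assemblage"].map(config.trend).to_numpy(dtype=float)
    delta = species["assemblage"].map(config.landuse_interaction).to_numpy(dtype=float)
    gamma = species["assemblage"].map(config.temperature_interaction).to_numpy(dtype=float)

    H = landuse.loc[site_table["site_id"]].to_numpy(dtype=float)
    t_site = temperature.groupby("site_id")["temperature"].mean()
    Tc = t_site.loc[site_table["site_id"]].to_numpy() - t_site.mean()

    u = rng.normal(0.0, config.sigma_site, n_si)
    v = rng.normal(0.0, config.sigma_year, n_y)
    cells = [grid50_assign(e, n) for e, n in zip(site_table["easting"], site_table["northing"])]
    uniq = sorted(set(cells))
    w_cell = dict(zip(uniq, rng.normal(0.0, config.sigma_grid, len(uniq))))
    w = np.array([w_cell[c] for c in cells])
    slope_noise = rng.normal(0.0, config.sigma_slope, n_si)

    slope = beta[:, None] + delta[:, None] * H[None, :] + gamma[:, None] * Tc[None, :]
    slope = slope + slope_noise[None, :]
    log_mu = (
        a[:, None, None]
        + (u + w)[None, :, None]
        + v[None, None, :]
        + slope[:, :, None] * tc[None, None, :]
    )
    if not np.isfinite(log_mu).all():
        raise FloatingPointError("non-finite linear predictor in abundance simulation")
    mu = np.exp(np.clip(log_mu, -30.0, 30.0))
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        mu = mu * rng.gamma(shape, config.overdispersion, size=mu.shape)
    counts = rng.poisson(mu)

    sp_idx, si_idx, y_idx = np.nonzero(counts)
    table = pd.DataFrame(
        {
            "site_id": site_table["site_id"].to_numpy()[si_idx],
            "year": years[y_idx],
            "species_id": species["species_id"].to_numpy()[sp_idx],
            "abundance": counts[sp_idx, si_idx, y_idx].astype(float),
            "index_available": True,
        }
    )
    return table.sort_values(["site_id", "year", "species_id"]).reset_index(drop=True)


def apply_observation_model(
    abundance_table: pd.DataFrame, config: SimulationConfig, rng=None
) -> pd.DataFrame:
    """Impose survey gaps and missing indices.

    Whole site-years vanish with probability ``p_unsurveyed_year``;
    surviving records lose their index (abundance becomes unknown, species
    stays present) with probability ``p_missing_index``.
    """
    rng = rng or config._rngs()[4]
    table = abundance_table.copy()
    if config.p_unsurveyed_year > 0:
        site_years = table[["site_id", "year"]].drop_duplicates().reset_index(drop=True)
        drop = rng.random(len(site_years)) < config.p_unsurveyed_year
        dropped = set(map(tuple, site_years[drop].to_numpy()))
        if dropped:
            mask = [
                (s, y) not in dropped
                for s, y in zip(table["site_id"], table["year"])
            ]
            table = table[mask].reset_index(drop=True)
    if config.p_missing_index > 0:
        miss = rng.random(len(table)) < config.p_missing_index
        table.loc[miss, "index_available"] = False
        table.loc[miss, "abundance"] = np.nan
    return table


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage in order; fully deterministic given the seed."""
    rngs = config._rngs()
    species = generate_species_pool(config, rngs[0])
    grid, sites = generate_landscape(config, rngs[1])
    temperature = generate_temperature(config, sites, rngs[2])
    landuse = landuse_at_sites(config, grid, sites)
    abundance = simulate_abundances(config, species, sites, landuse, temperature, rngs[3])
    abundance = apply_observation_model(abundance, config, rngs[4])
    sti_table = species[["species_id", "sti", "assemblage"]].copy()
    return SyntheticDataset(
        config=config,
        sti_table=sti_table,
        species_params=species,
        site_table=sites,
        grid=grid,
        temperature_table=temperature,
        abundance_table=abundance,
        landuse_proportion=landuse,
    )


def simulate_cti_series(
    config: SimulationConfig,
    cti_trend: float = 0.0046,
    cti_mean: float = 10.5,
    sigma_site: float = 0.3,
    sigma_year: float = 0.02,
    sigma_grid: float = 0.1,
    sigma_slope: float = 0.001,
    sigma_resid: float = 0.05,
) -> pd.DataFrame:
    """Gaussian generative twin of the CTI trend model, with known slope.

    Used for parameter-recovery checks of the linear mixed model: the
    community generator's CTI slope is emergent, whereas here the annual
    CTI trend (default the bird-scheme value of 0.0046 deg C per year) is
    an explicit parameter. Noise defaults mirror the reported uncertainty
    scale of the monitoring analysis (slope SE around 0.0007).
    """
    rngs = config._rngs()
    rng = rngs[5]
    sites = _site_layout(config, rngs[1])
    years = config.years
    tc = years - years.mean()
    n_si, n_y = len(sites), len(years)

    from .trends import grid50_assign

    u = rng.normal(0.0, sigma_site, n_si)
    v = rng.normal(0.0, sigma_year, n_y)
    cells = [grid50_assign(e, n) for e, n in zip(sites["easting"], sites["northing"])]
    uniq = sorted(set(cells))
    w_cell = dict(zip(uniq, rng.normal(0.0, sigma_grid, len(uniq))))
    w = np.array([w_cell[c] for c in cells])
    s = rng.normal(0.0, sigma_slope, n_si)
    cti = (
        cti_mean
        + (u + w)[:, None]
        + v[None, :]
        + (cti_trend + s[:, None]) * tc[None, :]
        + rng.normal(0.0, sigma_resid, (n_si, n_y))
    )
    out = pd.DataFrame(
        {
            "site_id": np.repeat(sites["site_id"].to_numpy(), n_y),
            "year": np.tile(years, n_si),
            "cti": cti.ravel(),
        }
    )
    return out.merge(sites, on="site_id")


def write_fixture(dataset: SyntheticDataset, directory) -> dict[str, Path]:
    """Write every pipeline input file plus a true-parameter manifest.

    Formats are exactly what the readers consume: delimited text tables
    and an ESRI ASCII land-cover grid. Round-trips losslessly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "sti": directory / "sti.csv",
        "abundance": directory / "abundance.csv",
        "sites": directory / "sites.csv",
        "temperature": directory / "temperature.csv",
        "landcover": directory / "landcover.asc",
        "manifest": directory / "manifest.yaml",
    }
    dataset.sti_table[["species_id", "sti"]].to_csv(paths["sti"], index=False)
    ab = dataset.abundance_table.copy()
    ab["abundance"] = ab["abundance"].map(lambda x: "" if pd.isna(x) else f"{x:.6g}")
    ab.to_csv(paths["abundance"], index=False)
    dataset.site_table.to_csv(paths["sites"], index=False, float_format="%.3f")
    dataset.temperature_table.to_csv(paths["temperature"], index=False, float_format="%.6g")
    write_ascii_grid(dataset.grid, paths["landcover"])
    manifest = {
        "seed": dataset.config.seed,
        "true_parameters": asdict(dataset.config),
        "n_species": int(len(dataset.sti_table)),
        "n_sites": int(len(dataset.site_table)),
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths
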