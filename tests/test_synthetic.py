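"""Generator properties: determinism, analytic means, landscape targets."""

import numpy as np
import pandas as pd
import pytest

from ctiscape import indices
from ctiscape.landcover import buffer_cover
from ctiscape.synthetic import (
    SimulationConfig,
    apply_observation_model,
    generate_landscape,
    generate_species_pool,
    simulate_abundances,
    simulate_dataset,
    write_fixture,
)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(year_start=2000, year_end=2000)
        with pytest.raises(ValueError):
            SimulationConfig(sigma_site=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(p_missing_index=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(trend={"low": 0.1})  # missing assemblages


class TestSpeciesPool:
    def test_deterministic(self):
        a = generate_species_pool(SimulationConfig(seed=5))
        b = generate_species_pool(SimulationConfig(seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_sti_sd_propagates(self):
        with pytest.raises(ValueError):
            generate_species_pool(SimulationConfig(seed=1, sti_sd=0.0))

    def test_clt_bound_on_mean_sti(self):
        cfg = SimulationConfig(seed=2, n_species=1000, sti_mean=10.0, sti_sd=2.0)
        pool = generate_species_pool(cfg)
        assert pool["sti"].mean() == pytest.approx(10.0, abs=0.2)  # 3 sigma / sqrt(n)

    def test_assemblages_assigned(self):
        pool = generate_species_pool(SimulationConfig(seed=3, n_species=60))
        sizes = pool["assemblage"].value_counts()
        assert sizes.sum() == 60 and sizes.max() - sizes.min() <= 1


class TestLandscape:
    def test_single_category_grid(self):
        cfg = SimulationConfig(
            seed=4, n_sites=4, category_targets={"arable": 1.0}, cell_size=200.0
        )
        grid, sites = generate_landscape(cfg)
        assert (grid.values == grid.codes["arable"]).all()
        cover = buffer_cover(
            grid, (sites.loc[0, "easting"], sites.loc[0, "northing"]), 500.0
        )
        assert cover.loc["arable", "proportion"] == 1.0

    def test_two_category_proportions_near_targets(self):
        cfg = SimulationConfig(
            seed=5,
            n_sites=9,
            cell_size=200.0,
            category_targets={"arable": 0.5, "woodland_broadleaf": 0.5},
        )
        grid, _ = generate_landscape(cfg)
        prop_arable = (grid.values == grid.codes["arable"]).mean()
        assert prop_arable == pytest.approx(0.5, abs=0.05)

    def test_deterministic_raster(self):
        cfg = SimulationConfig(seed=6, n_sites=9, cell_size=200.0)
        g1, s1 = generate_landscape(cfg)
        g2, s2 = generate_landscape(cfg)
        np.testing.assert_array_equal(g1.values, g2.values)
        pd.testing.assert_frame_equal(s1, s2)

    def test_sites_fit_largest_buffer(self):
        cfg = SimulationConfig(seed=7, n_sites=16, cell_size=200.0)
        grid, sites = generate_landscape(cfg)
        for row in sites.itertuples(index=False):
            buffer_cover(grid, (row.easting, row.northing), 10000.0)  # must not raise

    def test_high_intensity_span_identifiable(self):
        """0.5-km high-intensity proportions should span [0.1, 0.9] across sites."""
        cfg = SimulationConfig(seed=8, n_sites=100, cell_size=100.0)
        grid, sites = generate_landscape(cfg)
        cats = list(cfg.combo.categories)
        props = []
        for row in sites.itertuples(index=False):
            cover = buffer_cover(grid, (row.easting, row.northing), 500.0)
            props.append(float(cover.loc[cats, "proportion"].sum()))
        assert min(props) <= 0.1
        assert max(props) >= 0.9


def _two_site_setup(n_years=11, **overrides):
    cfg = SimulationConfig(
        seed=9,
        n_species=8,
        n_sites=2,
        year_start=2000,
        year_end=2000 + n_years - 1,
        baseline_log_abundance_mean=4.0,
        baseline_log_abundance_sd=0.0,
        sigma_site=0.0,
        sigma_year=0.0,
        sigma_grid=0.0,
        sigma_slope=0.0,
        p_missing_index=0.0,
        p_unsurveyed_year=0.0,
        trend=dict.fromkeys(indices.ASSEMBLAGES, 0.0),
        **overrides,
    )
    species = generate_species_pool(cfg)
    sites = pd.DataFrame(
        {"site_id": ["A", "B"], "easting": [20000.0, 30000.0], "northing": [20000.0, 30000.0]}
    )
    landuse = pd.Series([0.0, 1.0], index=["A", "B"])
    temperature = pd.DataFrame(
        {
            "site_id": np.repeat(["A", "B"], n_years),
            "year": np.tile(cfg.years, 2),
            "temperature": 9.0,
        }
    )
    return cfg, species, sites, landuse, temperature


class TestSimulateAbundances:
    def test_constant_regime_matches_analytic_mean(self):
        cfg, species, sites, landuse, temperature = _two_site_setup(n_years=40)
        table = simulate_abundances(cfg, species, sites, landuse, temperature)
        per_cell = 2 * len(cfg.years)
        for sp, a in zip(species["species_id"], species["baseline_log_abundance"]):
            total = table.loc[table["species_id"] == sp, "abundance"].sum()
            mean = total / per_cell
            expect = np.exp(a)
            # Poisson mean over 80 cells: 4 sigma MC band
            assert mean == pytest.approx(expect, abs=4 * np.sqrt(expect / per_cell))

    def test_landuse_contrast_shifts_log_trend(self):
        cfg, species, sites, landuse, temperature = _two_site_setup(
            landuse_interaction={"low": -0.5, "medium_low": 0.0, "medium_high": 0.0, "high": 0.0},
        )
        table = simulate_abundances(cfg, species, sites, landuse, temperature)
        low_sp = set(species.loc[species["assemblage"] == "low", "species_id"])
        tc = cfg.years - cfg.years.mean()
        slopes = {}
        for site in ("A", "B"):
            sel = table[(table["site_id"] == site) & table["species_id"].isin(low_sp)]
            totals = sel.groupby("year")["abundance"].sum().reindex(cfg.years).fillna(0.5)
            slopes[site] = np.polyfit(tc, np.log(totals), 1)[0]
        assert slopes["B"] - slopes["A"] == pytest.approx(-0.5, abs=0.03)

    def test_seeded_counts_identical(self):
        cfg, species, sites, landuse, temperature = _two_site_setup()
        rng1 = np.random.default_rng(123)
        rng2 = np.random.default_rng(123)
        a = simulate_abundances(cfg, species, sites, landuse, temperature, rng1)
        b = simulate_abundances(cfg, species, sites, landuse, temperature, rng2)
        pd.testing.assert_frame_equal(a, b)

    def test_overdispersion_inflates_variance(self):
        base = _two_site_setup(n_years=40)
        cfg0 = base[0]
        cfg1 = SimulationConfig(**{**cfg0.__dict__, "overdispersion": 1.0})
        _, species, sites, landuse, temperature = base
        t0 = simulate_abundances(cfg0, species, sites, landuse, temperature)
        t1 = simulate_abundances(cfg1, species, sites, landuse, temperature)
        v0 = t0.groupby("species_id")["abundance"].var().mean()
        v1 = t1.groupby("species_id")["abundance"].var().mean()
        assert v1 > 3 * v0


class TestObservationModel:
    def test_zero_probabilities_identity(self):
        cfg, species, sites, landuse, temperature = _two_site_setup()
        table = simulate_abundances(cfg, species, sites, landuse, temperature)
        out = apply_observation_model(table, cfg)
        pd.testing.assert_frame_equal(out, table)

    def test_all_indices_missing_fails_coverage_filter(self):
        cfg, species, sites, landuse, temperature = _two_site_setup()
        cfg = SimulationConfig(**{**cfg.__dict__, "p_missing_index": 1.0})
        table = simulate_abundances(cfg, species, sites, landuse, temperature)
        out = apply_observation_model(table, cfg)
        assert (~out["index_available"]).all()
        kept = indices.filter_site_years(out, min_species=1, min_coverage=0.75)
        assert kept.empty

    def test_unsurveyed_fraction_within_binomial_bound(self):
        cfg = SimulationConfig(
            seed=11, n_species=10, n_sites=200, year_start=1990, year_end=2019,
            p_unsurveyed_year=0.2, p_missing_index=0.0, cell_size=300.0,
            baseline_log_abundance_mean=3.0,
        )
        ds = simulate_dataset(cfg)
        n_total = 200 * 30
        survived = len(ds.abundance_table[["site_id", "year"]].drop_duplicates())
        expect = 0.8 * n_total
        half_width = 2.576 * np.sqrt(n_total * 0.2 * 0.8)
        assert abs(survived - expect) <= half_width


class TestFixtureRoundTrip:
    def test_full_dataset_deterministic(self, small_config, small_dataset):
        again = simulate_dataset(small_config)
        pd.testing.assert_frame_equal(again.abundance_table, small_dataset.abundance_table)
        pd.testing.assert_frame_equal(again.sti_table, small_dataset.sti_table)
        np.testing.assert_array_equal(again.grid.values, small_dataset.grid.values)

    def test_write_read_write_byte_identical(self, small_dataset, tmp_path):
        d1 = tmp_path / "one"
        d2 = tmp_path / "two"
        paths1 = write_fixture(small_dataset, d1)
        from ctiscape.io import (
            read_abundance_table,
            read_site_table,
            read_sti_table,
            read_temperature_table,
        )
        from ctiscape.landcover import read_ascii_grid

        back = simulate_dataset(small_dataset.config)
        back.abundance_table = read_abundance_table(paths1["abundance"])
        back.sti_table = back.sti_table.merge(read_sti_table(paths1["sti"]))[
            ["species_id", "sti", "assemblage"]
        ]
        back.site_table = read_site_table(paths1["sites"])
        back.temperature_table = read_temperature_table(paths1["temperature"])
        back.grid = read_ascii_grid(paths1["landcover"])
        paths2 = write_fixture(back, d2)
        for key in ("abundance", "sites", "landcover"):
            assert paths1[key].read_bytes() == paths2[key].read_bytes(), key

    def test_manifest_records_seed_and_parameters(self, small_dataset, tmp_path):
        import yaml

        paths = write_fixture(small_dataset, tmp_path)
        manifest = yaml.safe_load(paths["manifest"].read_text())
        assert manifest["seed"] == small_dataset.config.seed
        assert manifest["true_parameters"]["trend"]["low"] == pytest.approx(-0.025)
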