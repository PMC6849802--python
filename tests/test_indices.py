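"""CTI, quartile assemblages and inclusion filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctiscape import indices
from ctiscape.indices import (
    ASSEMBLAGES,
    MissingStiError,
    NoCommunityError,
    assemblage_metrics,
    assign_assemblages,
    community_index_table,
    compute_cti,
    filter_site_years,
    filter_sites,
)
from conftest import make_abundance


def brute_force_cti(abundances: dict, sti: dict) -> float:
    num = den = 0.0
    for sp, n in abundances.items():
        if n > 0:
            num += n * sti[sp]
            den += n
    return num / den


class TestComputeCti:
    @pytest.mark.parametrize(
        "abundances, sti, expected",
        [
            ({"a": 5.0}, {"a": 10.2}, 10.2),
            ({"a": 2.0, "b": 2.0, "c": 2.0}, {"a": 8.0, "b": 10.0, "c": 12.0}, 10.0),
            ({"a": 3.0, "b": 1.0}, {"a": 8.0, "b": 12.0}, 9.0),
        ],
    )
    def test_weighted_mean(self, abundances, sti, expected):
        assert compute_cti(abundances, pd.Series(sti)) == pytest.approx(expected, abs=1e-12)

    def test_zero_abundance_contributes_nothing(self):
        sti = pd.Series({"a": 8.0, "b": 12.0, "c": 99.0})
        assert compute_cti({"a": 3.0, "b": 1.0, "c": 0.0}, sti) == pytest.approx(9.0)

    def test_empty_community_raises(self):
        with pytest.raises(NoCommunityError):
            compute_cti({"a": 0.0}, pd.Series({"a": 8.0}))

    def test_missing_sti_raises_by_default_drops_under_option(self):
        sti = pd.Series({"a": 8.0})
        with pytest.raises(MissingStiError):
            compute_cti({"a": 1.0, "zz": 1.0}, sti)
        assert compute_cti({"a": 1.0, "zz": 1.0}, sti, drop_missing_sti=True) == 8.0

    @given(
        data=st.lists(
            st.tuples(
                st.floats(min_value=0.01, max_value=1e4),
                st.floats(min_value=-5.0, max_value=25.0),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        abundances = {f"s{i}": a for i, (a, _) in enumerate(data)}
        sti = {f"s{i}": t for i, (_, t) in enumerate(data)}
        expected = brute_force_cti(abundances, sti)
        assert compute_cti(abundances, pd.Series(sti)) == pytest.approx(expected, abs=1e-12)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_abundance_scaling_invariance(self, scale):
        ab = {"a": 3.0, "b": 1.0, "c": 0.5}
        sti = pd.Series({"a": 8.0, "b": 12.0, "c": 10.0})
        base = compute_cti(ab, sti)
        scaled = compute_cti({k: v * scale for k, v in ab.items()}, sti)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_adding_species_at_cti_leaves_cti_unchanged(self):
        ab = {"a": 3.0, "b": 1.0}
        sti = {"a": 8.0, "b": 12.0}
        base = compute_cti(ab, pd.Series(sti))
        sti["new"] = base
        ab["new"] = 7.0
        assert compute_cti(ab, pd.Series(sti)) == pytest.approx(base, rel=1e-12)

    def test_cti_bounded_by_sti_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(2, 15)
            ab = {f"s{i}": float(rng.gamma(2.0)) + 0.01 for i in range(n)}
            sti = {f"s{i}": float(rng.normal(10, 3)) for i in range(n)}
            cti = compute_cti(ab, pd.Series(sti))
            assert min(sti.values()) <= cti <= max(sti.values())


class TestAssignAssemblages:
    def test_exact_quarters(self, toy_sti):
        out = assign_assemblages(toy_sti)
        by = out.set_index("species_id")["assemblage"]
        assert list(by[["s1", "s2"]]) == ["low", "low"]
        assert list(by[["s3", "s4"]]) == ["medium_low", "medium_low"]
        assert list(by[["s5", "s6"]]) == ["medium_high", "medium_high"]
        assert list(by[["s7", "s8"]]) == ["high", "high"]

    @pytest.mark.parametrize("n", [4, 5, 7, 60, 63, 114])
    def test_balanced_partition_oracle(self, n):
        """Group sizes must match the integer partition of n into 4 ranks."""
        rng = np.random.default_rng(n)
        table = pd.DataFrame(
            {"species_id": [f"s{i:03d}" for i in range(n)], "sti": rng.normal(10, 2, n)}
        )
        out = assign_assemblages(table)
        sizes = out["assemblage"].value_counts()
        # oracle: cut points of ranks 1..n at quarter boundaries
        expected = np.diff([round(n * k / 4) for k in range(5)])
        assert sorted(sizes) == sorted(expected)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == n

    def test_rank_order_respected(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {"species_id": [f"s{i}" for i in range(40)], "sti": rng.normal(10, 2, 40)}
        )
        out = assign_assemblages(table).sort_values("sti")
        seen = [g for g in out["assemblage"]]
        order = {g: i for i, g in enumerate(ASSEMBLAGES)}
        ranks = [order[g] for g in seen]
        assert ranks == sorted(ranks)

    def test_tie_at_median_deterministic(self):
        table = pd.DataFrame(
            {
                "species_id": ["d", "c", "b", "a", "f", "e", "h", "g"],
                "sti": [10.0, 10.0, 10.0, 10.0, 10.0, 10.0, 12.0, 8.0],
            }
        )
        first = assign_assemblages(table)
        second = assign_assemblages(table)
        pd.testing.assert_frame_equal(first, second)
        # ties broken by species_id: 'a' sorts before 'f' among the tied block
        by = first.set_index("species_id")["assemblage"]
        assert by["g"] == "low" and by["h"] == "high"

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError):
            assign_assemblages(
                pd.DataFrame({"species_id": ["a", "b", "c"], "sti": [1.0, 2.0, 3.0]})
            )
        with pytest.raises(ValueError):
            assign_assemblages(
                pd.DataFrame({"species_id": list("abcd"), "sti": [5.0] * 4})
            )


class TestAssemblageMetrics:
    def test_one_species_per_assemblage(self, toy_sti):
        labelled = assign_assemblages(toy_sti)
        ab = {"s1": 2.0, "s3": 3.0, "s5": 4.0, "s7": 5.0}
        out = assemblage_metrics(ab, labelled)
        assert list(out["total_abundance"]) == [2.0, 3.0, 4.0, 5.0]
        assert list(out["richness"]) == [1, 1, 1, 1]

    def test_all_in_one_assemblage_conservation(self, toy_sti):
        labelled = assign_assemblages(toy_sti)
        out = assemblage_metrics({"s1": 1.0, "s2": 2.0}, labelled)
        assert out.loc["low", "total_abundance"] == 3.0
        assert out.loc["low", "richness"] == 2
        for g in ("medium_low", "medium_high", "high"):
            assert out.loc[g, "total_abundance"] == 0.0
            assert out.loc[g, "richness"] == 0

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(1)
        n = 20
        table = pd.DataFrame(
            {"species_id": [f"s{i:02d}" for i in range(n)], "sti": rng.normal(10, 2, n)}
        )
        labelled = assign_assemblages(table)
        ab = {f"s{i:02d}": float(rng.gamma(2.0)) for i in range(n)}
        out = assemblage_metrics(ab, labelled)
        # independent oracle: explicit loop over species
        lab = labelled.set_index("species_id")["assemblage"]
        for g in ASSEMBLAGES:
            total = sum(v for k, v in ab.items() if lab[k] == g and v > 0)
            rich = sum(1 for k, v in ab.items() if lab[k] == g and v > 0)
            assert out.loc[g, "total_abundance"] == pytest.approx(total, rel=1e-12)
            assert out.loc[g, "richness"] == rich
        assert out["total_abundance"].sum() == pytest.approx(sum(ab.values()), rel=1e-12)


class TestFilters:
    def _toy(self):
        rows = []
        # site A, year 2000: 9 species all indexed -> too few species
        rows += [("A", 2000, f"s{i}", 1.0, True) for i in range(9)]
        # site A, year 2001: 12 species, 9 indexed -> coverage exactly 0.75, dropped
        rows += [("A", 2001, f"s{i}", 1.0, True) for i in range(9)]
        rows += [("A", 2001, f"s{i}", np.nan, False) for i in range(9, 12)]
        # site A, year 2002: 12 species, 10 indexed -> coverage 0.833, kept
        rows += [("A", 2002, f"s{i}", 1.0, True) for i in range(10)]
        rows += [("A", 2002, f"s{i}", np.nan, False) for i in range(10, 12)]
        return make_abundance(rows)

    def test_site_year_rules(self):
        out = filter_site_years(self._toy())
        kept = set(map(tuple, out[["site_id", "year"]].drop_duplicates().to_numpy()))
        assert kept == {("A", 2002)}

    def test_site_year_filter_idempotent(self):
        once = filter_site_years(self._toy())
        twice = filter_site_years(once)
        pd.testing.assert_frame_equal(once, twice)

    @pytest.mark.parametrize("n_years, kept", [(5, False), (6, True)])
    def test_min_years_boundary(self, n_years, kept):
        rows = [
            ("B", 2000 + t, f"s{i}", 1.0, True)
            for t in range(n_years)
            for i in range(12)
        ]
        out = filter_sites(filter_site_years(make_abundance(rows)))
        assert ("B" in set(out["site_id"])) is kept

    def test_filter_sites_idempotent(self):
        rows = [
            ("C", 2000 + t, f"s{i}", 1.0, True) for t in range(8) for i in range(15)
        ]
        table = filter_site_years(make_abundance(rows))
        once = filter_sites(table)
        pd.testing.assert_frame_equal(filter_sites(once), once)


class TestCommunityIndexTable:
    def test_matches_per_community_oracle(self):
        rng = np.random.default_rng(5)
        n_sp = 12
        sti = pd.DataFrame(
            {"species_id": [f"s{i:02d}" for i in range(n_sp)], "sti": rng.normal(10, 2, n_sp)}
        )
        labelled = assign_assemblages(sti)
        rows = []
        for site in ("X", "Y"):
            for year in (2000, 2001):
                for i in range(n_sp):
                    if rng.random() < 0.7:
                        rows.append((site, year, f"s{i:02d}", float(rng.gamma(2.0)), True))
        table = make_abundance(rows)
        out = community_index_table(table, labelled).set_index(["site_id", "year"])
        for (site, year), grp in table.groupby(["site_id", "year"]):
            ab = grp.set_index("species_id")["abundance"]
            expected_cti = compute_cti(ab, labelled.set_index("species_id")["sti"])
            assert out.loc[(site, year), "cti"] == pytest.approx(expected_cti, abs=1e-12)
            metrics = assemblage_metrics(ab, labelled)
            for g in ASSEMBLAGES:
                assert out.loc[(site, year), f"abundance_{g}"] == pytest.approx(
                    metrics.loc[g, "total_abundance"]
                )
                assert out.loc[(site, year), f"richness_{g}"] == metrics.loc[g, "richness"]

    def test_assemblage_sums_conserve_totals(self, small_dataset):
        community = community_index_table(
            small_dataset.abundance_table, small_dataset.sti_table
        )
        ab = small_dataset.abundance_table
        pos = ab[ab["index_available"] & (ab["abundance"] > 0)]
        totals = pos.groupby(["site_id", "year"])["abundance"].sum()
        got = community.set_index(["site_id", "year"])[
            [f"abundance_{g}" for g in ASSEMBLAGES]
        ].sum(axis=1)
        pd.testing.assert_series_equal(
            got.sort_index(), totals.sort_index(), check_names=False
        )

    def test_unindexed_species_count_toward_presence_not_cti(self):
        sti = assign_assemblages(
            pd.DataFrame({"species_id": list("abcd"), "sti": [1.0, 2.0, 3.0, 4.0]})
        )
        rows = [
            ("S", 2000, "a", 2.0, True),
            ("S", 2000, "b", np.nan, False),
            ("S", 2000, "c", 1.0, True),
        ]
        out = community_index_table(make_abundance(rows), sti)
        assert out.loc[0, "n_species_present"] == 3
        assert out.loc[0, "index_coverage"] == pytest.approx(2 / 3)
        assert out.loc[0, "cti"] == pytest.approx((2 * 1 + 1 * 3) / 3)
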