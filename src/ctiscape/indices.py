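"""Community temperature index (CTI) and STI-quartile assemblage metrics.

The CTI of one site-year is the mean species temperature index (STI) of the
species present, weighted by their relative abundance; it rises when
warm-associated species gain relative weight. To see *which* species drive
a CTI change, the species pool is ranked by STI and split into four
contiguous quartile assemblages (low, medium-low, medium-high, high STI),
and total abundance and species richness are tracked per assemblage.

Inclusion filters mirror standard monitoring-scheme practice: a site-year
is used only if at least ``min_species`` species are present and an
abundance index is available for strictly more than ``min_coverage`` of
them; sites then need at least ``min_years`` surviving years.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ASSEMBLAGES = ("low", "medium_low", "medium_high", "high")

#: column schema of an abundance table
ABUNDANCE_COLUMNS = ["site_id", "year", "species_id", "abundance", "index_available"]


class NoCommunityError(ValueError):
    """Raised when a site-year has no species with positive abundance."""


class MissingStiError(KeyError):
    """Raised when a species with positive abundance has no STI value."""


def _positive_abundances(
    abundances: pd.Series, sti: pd.Series, drop_missing_sti: bool
) -> tuple[np.ndarray, np.ndarray]:
    ab = abundances[abundances > 0]
    if ab.empty:
        raise NoCommunityError("no species with positive abundance")
    missing = ab.index.difference(sti.index)
    if len(missing) > 0:
        if not drop_missing_sti:
            raise MissingStiError(
                f"species with positive abundance lack an STI: {sorted(missing)}"
            )
        logger.warning("dropping %d species without STI: %s", len(missing), sorted(missing))
        ab = ab.drop(missing)
        if ab.empty:
            raise NoCommunityError("all positively-abundant species lacked an STI")
    return ab.to_numpy(dtype=float), sti.loc[ab.index].to_numpy(dtype=float)


def compute_cti(abundances, sti_table, drop_missing_sti: bool = False) -> float:
    """Abundance-weighted mean STI of the species present in one site-year.

    Parameters
    ----------
    abundances
        Mapping or Series ``species_id -> abundance`` for a single
        site-year. Species with zero or unknown abundance contribute
        nothing.
    sti_table
        Series ``species_id -> STI`` (degrees C), or a DataFrame with
        ``species_id`` and ``sti`` columns.
    drop_missing_sti
        If True, species lacking an STI are dropped with a logged warning
        instead of raising.
    """
    sti = _sti_series(sti_table)
    ab = pd.Series(abundances, dtype=float)
    w, s = _positive_abundances(ab, sti, drop_missing_sti)
    return float(np.average(s, weights=w))


def _sti_series(sti_table) -> pd.Series:
    if isinstance(sti_table, pd.DataFrame):
        return sti_table.set_index("species_id")["sti"] if "species_id" in sti_table else sti_table["sti"]
    return pd.Series(sti_table, dtype=float)


def assign_assemblages(sti_table: pd.DataFrame) -> pd.DataFrame:
    """Rank species by STI and split the pool into four quartile groups.

    The split is rank-based: species are stable-sorted by (STI,
    species_id) and cut at the 25/50/75% rank boundaries into four
    contiguous groups whose sizes differ by at most one, so re-running is
    bit-identical even under STI ties.

    Returns a copy of the table with an ``assemblage`` column holding one
    of ``low``, ``medium_low``, ``medium_high``, ``high``.
    """
    table = sti_table.copy()
    if "species_id" not in table or "sti" not in table:
        raise ValueError("sti_table needs 'species_id' and 'sti' columns")
    n = len(table)
    if n < 4:
        raise ValueError(f"need at least 4 species to form quartile assemblages, got {n}")
    if not np.isfinite(table["sti"]).all():
        raise ValueError("all STI values must be finite")
    if table["species_id"].duplicated().any():
        raise ValueError("duplicate species_id in STI table")
    if table["sti"].nunique() == 1:
        raise ValueError("all STI values identical: quartile assemblages are degenerate")
    order = table.sort_values(["sti", "species_id"], kind="stable").index
    # ranks 1..n; group g holds ranks in (g*n/4, (g+1)*n/4]
    bounds = [int(round(n * k / 4.0)) for k in range(5)]
    labels = pd.Series(index=table.index, dtype=object)
    for g, name in enumerate(ASSEMBLAGES):
        labels.loc[order[bounds[g] : bounds[g + 1]]] = name
    table["assemblage"] = pd.Categorical(labels, categories=list(ASSEMBLAGES))
    return table


def assemblage_metrics(abundances, labelled_sti: pd.DataFrame, drop_missing_sti: bool = False) -> pd.DataFrame:
    """Total abundance and species richness per STI-quartile assemblage.

    Richness counts species with positive abundance. Assemblages with no
    species present report (0, 0); the four rows always sum to community
    totals.
    """
    if "assemblage" not in labelled_sti:
        raise ValueError("sti_table has no assemblage labels; run assign_assemblages first")
    sti = labelled_sti.set_index("species_id") if "species_id" in labelled_sti else labelled_sti
    ab = pd.Series(abundances, dtype=float)
    w, _ = _positive_abundances(ab, sti["sti"], drop_missing_sti)
    ab = ab[ab > 0]
    ab = ab[ab.index.isin(sti.index)]
    groups = sti.loc[ab.index, "assemblage"]
    out = pd.DataFrame(index=pd.Index(ASSEMBLAGES, name="assemblage"))
    totals = ab.groupby(groups, observed=False).sum()
    richness = ab.groupby(groups, observed=False).size()
    out["total_abundance"] = totals.reindex(ASSEMBLAGES).fillna(0.0)
    out["richness"] = richness.reindex(ASSEMBLAGES).fillna(0).astype(int)
    return out


def community_index_table(
    abundance_table: pd.DataFrame,
    labelled_sti: pd.DataFrame,
    drop_missing_sti: bool = False,
) -> pd.DataFrame:
    """Per site-year CTI plus per-assemblage totals and richness.

    One row per (site, year) with columns ``cti``, ``n_species_present``,
    ``index_coverage`` and ``abundance_<g>`` / ``richness_<g>`` for each of
    the four assemblages. Only records with an available index contribute
    abundance; present-but-unindexed species count toward presence and
    coverage only.
    """
    sti = labelled_sti.set_index("species_id") if "species_id" in labelled_sti else labelled_sti
    if "assemblage" not in sti:
        raise ValueError("sti_table has no assemblage labels; run assign_assemblages first")
    df = abundance_table.merge(
        sti[["sti", "assemblage"]], left_on="species_id", right_index=True, how="left"
    )
    pos = df[df["index_available"] & (df["abundance"] > 0)]
    orphans = pos.loc[pos["sti"].isna(), "species_id"].unique()
    if len(orphans):
        if not drop_missing_sti:
            raise MissingStiError(
                f"species with positive abundance lack an STI: {sorted(orphans)}"
            )
        logger.warning("dropping %d species without STI: %s", len(orphans), sorted(orphans))
        pos = pos[pos["sti"].notna()]
    keys = ["site_id", "year"]
    grp_all = df.groupby(keys)
    present = grp_all["species_id"].nunique()
    coverage = grp_all["index_available"].mean()
    gp = pos.groupby(keys)
    weighted = (pos["abundance"] * pos["sti"]).groupby([pos["site_id"], pos["year"]]).sum()
    cti = weighted / gp["abundance"].sum()
    totals = pos.pivot_table(
        index=keys, columns="assemblage", values="abundance", aggfunc="sum", observed=False
    ).reindex(columns=list(ASSEMBLAGES)).fillna(0.0)
    richness = pos.pivot_table(
        index=keys, columns="assemblage", values="abundance", aggfunc="count", observed=False
    ).reindex(columns=list(ASSEMBLAGES)).fillna(0).astype(int)
    out = pd.DataFrame(index=cti.index)
    out["cti"] = cti
    out["n_species_present"] = present.loc[out.index]
    out["index_coverage"] = coverage.loc[out.index]
    for g in ASSEMBLAGES:
        out[f"abundance_{g}"] = totals[g]
        out[f"richness_{g}"] = richness[g]
    out.index.names = keys
    return out.reset_index()


def filter_site_years(
    table: pd.DataFrame, min_species: int = 10, min_coverage: float = 0.75
) -> pd.DataFrame:
    """Keep site-years with >= min_species present and coverage strictly above min_coverage.

    Coverage is the fraction of present species whose abundance index is
    available; the strict inequality means a site-year with coverage
    exactly at the threshold is dropped.
    """
    grouped = table.groupby(["site_id", "year"])
    present = grouped["species_id"].nunique()
    covered = grouped["index_available"].mean()
    keep = present.index[(present >= min_species) & (covered > min_coverage)]
    before = len(present)
    out = table[table.set_index(["site_id", "year"]).index.isin(keep)].reset_index(drop=True)
    logger.info("filter_site_years: kept %d of %d site-years", len(keep), before)
    return out


def filter_sites(table: pd.DataFrame, min_years: int = 6) -> pd.DataFrame:
    """Keep sites with at least ``min_years`` distinct surviving years.

    Apply after :func:`filter_site_years`. The default of 6 keeps sites
    with more than five years' data.
    """
    years = table.groupby("site_id")["year"].nunique()
    keep = years.index[years >= min_years]
    logger.info("filter_sites: kept %d of %d sites", len(keep), len(years))
    return table[table["site_id"].isin(keep)].reset_index(drop=True)
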