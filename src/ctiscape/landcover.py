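"""Land-cover composition in circular buffers around monitoring sites.

Works on a single categorical raster (projected easting/northing metres,
lower-left origin) holding the eight cover classes the analysis needs:
arable, urban/suburban, three grassland classes (generic improved,
calcareous, lowland meadow), broadleaved woodland, sea and other.
"High-intensity" land use is a combination of arable (A), urban (U) and an
improved-grassland definition:

* ``IG1`` — total grassland minus calcareous grassland,
* ``IG2`` — additionally minus lowland meadows,

optionally counting sea as hostile too, giving 6 x 2 = 12 combinations,
each evaluated at buffer radii of 0.5, 2, 5 and 10 km.

Cell membership uses the standard zonal convention: a cell belongs to the
buffer iff its centre lies within the radius (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CATEGORIES = (
    "arable",
    "urban_suburban",
    "grassland_generic",
    "grassland_calcareous",
    "grassland_lowland_meadow",
    "woodland_broadleaf",
    "sea",
    "other",
)
DEFAULT_CODES = {name: i + 1 for i, name in enumerate(CATEGORIES)}

RADII_M = (500.0, 2000.0, 5000.0, 10000.0)

COMBO_CODES = ("A", "A+IG1", "A+IG2", "A+U", "A+U+IG1", "A+U+IG2")

_COMBO_CATEGORIES = {
    "A": ("arable",),
    "A+IG1": ("arable", "grassland_generic", "grassland_lowland_meadow"),
    "A+IG2": ("arable", "grassland_generic"),
    "A+U": ("arable", "urban_suburban"),
    "A+U+IG1": ("arable", "urban_suburban", "grassland_generic", "grassland_lowland_meadow"),
    "A+U+IG2": ("arable", "urban_suburban", "grassland_generic"),
}


@dataclass(frozen=True)
class HighIntensityCombo:
    """One of the 6 x 2 definitions of high-intensity land use."""

    code: str
    include_sea: bool = False

    def __post_init__(self):
        if self.code not in COMBO_CODES:
            raise ValueError(f"unknown combo code {self.code!r}; valid: {COMBO_CODES}")

    @property
    def categories(self) -> tuple[str, ...]:
        cats = _COMBO_CATEGORIES[self.code]
        return cats + ("sea",) if self.include_sea else cats

    @property
    def label(self) -> str:
        return self.code + ("+sea" if self.include_sea else "")

    @classmethod
    def all_combos(cls, include_sea_variants: bool = True) -> list["HighIntensityCombo"]:
        combos = [cls(c, False) for c in COMBO_CODES]
        if include_sea_variants:
            combos += [cls(c, True) for c in COMBO_CODES]
        return combos


@dataclass
class LandCoverGrid:
    """Categorical raster with integer codes per cell.

    ``values[row, col]`` with row 0 at the *top* of the grid (northing
    decreasing with row index, the usual raster layout); ``origin`` is the
    lower-left corner. Cell (col, row-from-bottom) centre sits at
    ``origin + (col + 0.5, row + 0.5) * cell_size``.
    """

    values: np.ndarray
    cell_size: float = 25.0
    origin: tuple[float, float] = (0.0, 0.0)
    codes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CODES))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in map units."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncols * self.cell_size, y0 + nrows * self.cell_size)

    def category_of(self, code: int) -> str:
        inv = {v: k for k, v in self.codes.items()}
        return inv[code]


def read_ascii_grid(path, codes: dict[str, int] | None = None) -> LandCoverGrid:
    """Read an ESRI ASCII grid (integer category codes)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key!r}")
    values = np.loadtxt(lines[i:], dtype=int)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data shape {values.shape} does not match header")
    return LandCoverGrid(
        values=values,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        codes=dict(codes or DEFAULT_CODES),
    )


def write_ascii_grid(grid: LandCoverGrid, path) -> None:
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write("NODATA_value -9999\n")
        np.savetxt(fh, grid.values, fmt="%d")


class BufferOutsideGridError(ValueError):
    pass


def buffer_cover(
    grid: LandCoverGrid, centroid: tuple[float, float], radius: float
) -> pd.DataFrame:
    """Per-category area (km^2) and proportion in a circular buffer.

    The buffer must lie fully within the grid. Returns one row per
    category present in the grid's code table, with zero rows included, so
    proportions always sum to 1.
    """
    cx, cy = centroid
    xmin, ymin, xmax, ymax = grid.extent
    if cx - radius < xmin or cx + radius > xmax or cy - radius < ymin or cy + radius > ymax:
        raise BufferOutsideGridError(
            f"buffer of radius {radius} m at ({cx}, {cy}) exceeds grid extent {grid.extent}"
        )
    cs = grid.cell_size
    nrows, ncols = grid.shape
    # columns/rows whose centres could fall within the radius
    c0 = max(int(np.floor((cx - radius - xmin) / cs - 0.5)), 0)
    c1 = min(int(np.ceil((cx + radius - xmin) / cs - 0.5)) + 1, ncols)
    r0b = max(int(np.floor((cy - radius - ymin) / cs - 0.5)), 0)
    r1b = min(int(np.ceil((cy + radius - ymin) / cs - 0.5)) + 1, nrows)
    xs = xmin + (np.arange(c0, c1) + 0.5) * cs
    ys = ymin + (np.arange(r0b, r1b) + 0.5) * cs
    dx2 = (xs - cx) ** 2
    dy2 = (ys - cy) ** 2
    inside = dy2[:, None] + dx2[None, :] <= radius * radius
    # rows-from-bottom -> array row index (top-down layout)
    block = grid.values[nrows - r1b : nrows - r0b][::-1]
    cells = block[:, c0:c1][inside]
    counts = np.bincount(cells, minlength=max(grid.codes.values()) + 1)
    total = int(inside.sum())
    if total == 0:
        raise BufferOutsideGridError("buffer contains no cell centres")
    cell_area_km2 = (cs / 1000.0) ** 2
    rows = []
    for name, code in grid.codes.items():
        k = counts[code] if code < len(counts) else 0
        rows.append(
            {
                "category": name,
                "area_km2": k * cell_area_km2,
                "proportion": k / total,
            }
        )
    out = pd.DataFrame(rows).set_index("category")
    out.attrs["buffer_area_km2"] = total * cell_area_km2
    out.attrs["n_cells"] = total
    return out


def improved_grassland_area(cover: pd.DataFrame, variant: str) -> float:
    """Improved-grassland area (km^2) under definition IG1 or IG2.

    IG1 = total grassland minus calcareous = generic + lowland meadow;
    IG2 = additionally minus lowland meadows = generic only.
    """
    if variant == "IG1":
        return float(
            cover.loc["grassland_generic", "area_km2"]
            + cover.loc["grassland_lowland_meadow", "area_km2"]
        )
    if variant == "IG2":
        return float(cover.loc["grassland_generic", "area_km2"])
    raise ValueError(f"unknown improved-grassland variant {variant!r}")


def high_intensity_area(
    cover: pd.DataFrame, combo: HighIntensityCombo
) -> tuple[float, float]:
    """(area km^2, proportion of buffer) of a high-intensity combination."""
    area = float(cover.loc[list(combo.categories), "area_km2"].sum())
    buffer_area = float(cover.attrs.get("buffer_area_km2", cover["area_km2"].sum()))
    return area, area / buffer_area


def metrics_for_all_sites(
    grid: LandCoverGrid,
    site_table: pd.DataFrame,
    radii=RADII_M,
    combos: list[HighIntensityCombo] | None = None,
) -> pd.DataFrame:
    """Buffer metrics for every site x radius.

    One row per (site, radius), with per-category proportions
    (``prop_<category>``) and, for every combination, the high-intensity
    area (``area_<label>``) and buffer proportion (``prop_<label>``).
    Errors are aggregated so one bad site reports all failures at once.
    """
    combos = HighIntensityCombo.all_combos() if combos is None else combos
    rows = []
    failures = []
    for site in site_table.itertuples(index=False):
        for radius in radii:
            try:
                cover = buffer_cover(grid, (site.easting, site.northing), radius)
            except BufferOutsideGridError as exc:
                failures.append(f"site {site.site_id} radius {radius}: {exc}")
                continue
            row = {
                "site_id": site.site_id,
                "radius": radius,
                "buffer_area_km2": cover.attrs["buffer_area_km2"],
            }
            for cat in cover.index:
                row[f"prop_{cat}"] = cover.loc[cat, "proportion"]
            for combo in combos:
                area, prop = high_intensity_area(cover, combo)
                row[f"area_{combo.label}"] = area
                row[f"prop_{combo.label}"] = prop
            rows.append(row)
    if failures:
        raise BufferOutsideGridError("; ".join(failures))
    return pd.DataFrame(rows).sort_values(["site_id", "radius"]).reset_index(drop=True)
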