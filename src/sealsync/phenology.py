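"""Sea-ice phenology covariates and their principal-component reduction.

Daily gridded sea-ice concentration (SIC, percent) over a small polygon is
reduced, season by season, to ten covariates describing the seasonal ice
cycle: days of advance and retreat, season duration, persistence, the days
and values of the extrema of ice *extent* (area of cells at >= 15 %
concentration) and ice *area* (concentration-weighted area).  A season runs
from calendar day 46 (Feb 15, near the mean extent minimum) to day 410/411
of the following year.  The covariate table is then decorrelated with a PCA
on the correlation matrix.

Threshold conventions: all 15 % comparisons are inclusive (>= 15), including
the advance rule; polygon-level presence is the area-weighted mean
concentration >= 15 %.  Both are configurable via ``SIC_THRESHOLD``
arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIC_THRESHOLD = 15.0
ADVANCE_RUN_DAYS = 5
EARTH_RADIUS_KM = 6371.0
SEASON_START_DOY = 46  # Feb 15 (non-leap): climatological extent minimum

#: fixed column order of the covariate table
COVARIATE_COLUMNS = [
    "advance_day",
    "retreat_day",
    "duration_days",
    "persistence_pct",
    "day_min_extent",
    "day_max_extent",
    "day_min_area",
    "day_max_area",
    "min_extent_km2",
    "max_extent_km2",
]


def cell_areas_km2(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Spherical-rectangle cell areas (km^2) for a regular lat/lon grid.

    ``lat``/``lon`` are cell-center coordinates in degrees; spacing is taken
    from the grid itself (must be regular).
    """
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    dlat = np.abs(np.diff(lat)).mean() if lat.size > 1 else 0.25
    dlon = np.abs(np.diff(lon)).mean() if lon.size > 1 else 0.25
    phi1 = np.radians(lat - dlat / 2.0)
    phi2 = np.radians(lat + dlat / 2.0)
    band = EARTH_RADIUS_KM**2 * np.radians(dlon) * (np.sin(phi2) - np.sin(phi1))
    return np.abs(np.repeat(band[:, None], lon.size, axis=1))


@dataclass
class SICGrid:
    """Daily SIC percent on a regular lat/lon grid.

    ``sic`` has shape (time, nlat, nlon); values outside [0, 100] are clipped
    on construction with a logged warning; NaN marks missing cells.
    """

    dates: np.ndarray  # datetime64[D], strictly increasing, daily
    lat: np.ndarray
    lon: np.ndarray
    sic: np.ndarray
    cell_area: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.sic = np.asarray(self.sic, float)
        step = np.diff(self.dates).astype(int)
        if self.dates.size > 1 and not np.all(step == 1):
            raise ValueError("SICGrid dates must be strictly increasing and daily")
        with np.errstate(invalid="ignore"):
            bad = (self.sic < 0) | (self.sic > 100)
        if np.any(bad):
            logger.warning("clipping %d SIC values outside [0, 100]", int(bad.sum()))
            self.sic = np.clip(self.sic, 0.0, 100.0)
        if self.cell_area is None:
            self.cell_area = cell_areas_km2(self.lat, self.lon)

    @property
    def total_area_km2(self) -> float:
        return float(np.sum(self.cell_area))

    def day_fields(self) -> np.ndarray:
        """(time, ncell) view of the concentration fields."""
        return self.sic.reshape(self.sic.shape[0], -1)


@dataclass(frozen=True)
class SeasonWindow:
    """One annual ice season: day 46 of ``label_year`` up to day 45/46 of the
    next year (the 46..410/411 day-of-year axis)."""

    label_year: int

    @property
    def start_date(self) -> np.datetime64:
        return np.datetime64(f"{self.label_year}-01-01") + (SEASON_START_DOY - 1)

    @property
    def end_date(self) -> np.datetime64:
        """Exclusive end: start of the next season."""
        return SeasonWindow(self.label_year + 1).start_date

    @property
    def n_days(self) -> int:
        return int((self.end_date - self.start_date).astype(int))

    def window_day_to_doy(self, wday: int) -> int:
        """1-based window day -> the standard day-of-year axis (46..410/411)."""
        return SEASON_START_DOY - 1 + wday


@dataclass
class IceSeasonMetrics:
    """The ten per-season covariates (window-day units for day metrics)."""

    label_year: int
    advance_day: int
    retreat_day: int
    duration_days: int
    persistence_pct: float
    day_min_extent: int
    day_max_extent: int
    day_min_area: int
    day_max_area: int
    min_extent_km2: float
    max_extent_km2: float
    iceless: bool = False

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in COVARIATE_COLUMNS}


def daily_extent(sic_field: np.ndarray, cell_area: np.ndarray,
                 threshold: float = SIC_THRESHOLD) -> float:
    """Ice extent (km^2): total area of cells at >= ``threshold`` percent.

    All-missing fields propagate NaN (the day is excluded from extrema).
    """
    sic_field = np.asarray(sic_field, float).ravel()
    area = np.asarray(cell_area, float).ravel()
    valid = np.isfinite(sic_field)
    if not valid.any():
        return float("nan")
    return float(np.sum(area[valid] * (sic_field[valid] >= threshold)))


def daily_area(sic_field: np.ndarray, cell_area: np.ndarray) -> float:
    """Ice area (km^2): concentration-weighted sum of cell areas."""
    sic_field = np.asarray(sic_field, float).ravel()
    area = np.asarray(cell_area, float).ravel()
    valid = np.isfinite(sic_field)
    if not valid.any():
        return float("nan")
    return float(np.sum(area[valid] * sic_field[valid] / 100.0))


def regional_presence(sic_field: np.ndarray, cell_area: np.ndarray,
                      threshold: float = SIC_THRESHOLD) -> bool:
    """Polygon-level ice presence: area-weighted mean SIC >= threshold."""
    sic_field = np.asarray(sic_field, float).ravel()
    area = np.asarray(cell_area, float).ravel()
    valid = np.isfinite(sic_field)
    if not valid.any():
        return False
    mean = np.sum(area[valid] * sic_field[valid]) / np.sum(area[valid])
    return bool(mean >= threshold)


def _interpolate_gaps(x: np.ndarray, max_gap: int = 2) -> np.ndarray:
    """Linear interpolation of interior NaN runs of length <= max_gap."""
    x = np.asarray(x, float).copy()
    isnan = ~np.isfinite(x)
    if not isnan.any():
        return x
    idx = np.arange(x.size)
    runs = []
    start = None
    for i, m in enumerate(isnan):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, x.size))
    for a, b in runs:
        if a == 0 or b == x.size:
            raise ValueError("missing days at the season boundary cannot be interpolated")
        if b - a > max_gap:
            raise ValueError(f"gap of {b - a} days exceeds the {max_gap}-day interpolation limit")
    x[isnan] = np.interp(idx[isnan], idx[~isnan], x[~isnan])
    return x


def _first_run_start(mask: np.ndarray, run: int) -> int | None:
    """0-based start of the first run of >= ``run`` consecutive True."""
    if run <= 1:
        hits = np.flatnonzero(mask)
        return int(hits[0]) if hits.size else None
    m = mask.astype(int)
    csum = np.convolve(m, np.ones(run, int), mode="valid")
    hits = np.flatnonzero(csum == run)
    return int(hits[0]) if hits.size else None


def season_metrics(presence: np.ndarray, extent: np.ndarray, area: np.ndarray,
                   label_year: int, run_days: int = ADVANCE_RUN_DAYS) -> IceSeasonMetrics:
    """Ten covariates from daily polygon presence/extent/area over a window.

    * advance: first day of the first run of >= ``run_days`` consecutive
      presence days;
    * retreat: day after the last presence day (first day below threshold
      until the end of the window);
    * saturated seasons (ice never absent) pin advance/retreat to the window
      limits; iceless seasons set advance = retreat = window end, duration 0
      and persistence 0;
    * extrema days are 1-based window days of the first day attaining the
      extremum, NaN days excluded.
    """
    presence = np.asarray(presence, bool)
    extent = _interpolate_gaps(np.asarray(extent, float))
    area = _interpolate_gaps(np.asarray(area, float))
    n = presence.size
    if extent.size != n or area.size != n:
        raise ValueError("presence/extent/area lengths differ")

    ice_total = int(presence.sum())
    if ice_total == 0:
        advance = retreat = n
        duration = 0
        persistence = 0.0
        iceless = True
    else:
        start = _first_run_start(presence, run_days)
        if start is None:
            # presence occurs but never for run_days in a row: no established
            # advance; treat as iceless by the same degenerate-input rule
            advance = retreat = n
            duration = 0
            persistence = 0.0
            iceless = True
        else:
            advance = start + 1  # 1-based window day
            last = int(np.flatnonzero(presence)[-1])
            retreat = min(last + 2, n)  # day after the last ice day, capped
            if presence.all():
                advance, retreat = 1, n
            duration = retreat - advance
            ice_days = int(presence[advance - 1:retreat - 1].sum())
            persistence = 100.0 * ice_days / duration if duration > 0 else 0.0
            iceless = False

    def _first_extremum(x: np.ndarray, which: str) -> tuple[int, float]:
        valid = np.isfinite(x)
        if not valid.any():
            raise ValueError("no valid days for extremum search")
        v = np.nanmin(x) if which == "min" else np.nanmax(x)
        day = int(np.flatnonzero(valid & (x == v))[0]) + 1
        return day, float(v)

    day_min_ext, min_ext = _first_extremum(extent, "min")
    day_max_ext, max_ext = _first_extremum(extent, "max")
    day_min_area, _ = _first_extremum(area, "min")
    day_max_area, _ = _first_extremum(area, "max")

    return IceSeasonMetrics(
        label_year=label_year,
        advance_day=int(advance),
        retreat_day=int(retreat),
        duration_days=int(duration),
        persistence_pct=float(persistence),
        day_min_extent=day_min_ext,
        day_max_extent=day_max_ext,
        day_min_area=day_min_area,
        day_max_area=day_max_area,
        min_extent_km2=min_ext,
        max_extent_km2=max_ext,
        iceless=iceless,
    )


def season_series(grid: SICGrid, window: SeasonWindow,
                  threshold: float = SIC_THRESHOLD):
    """Daily (presence, extent, area) series for one season window."""
    sel = (grid.dates >= window.start_date) & (grid.dates < window.end_date)
    if sel.sum() < window.n_days:
        raise ValueError(f"season {window.label_year}: incomplete daily coverage")
    fields = grid.day_fields()[sel]
    area_flat = grid.cell_area.ravel()
    extent = np.array([daily_extent(f, area_flat, threshold) for f in fields])
    area = np.array([daily_area(f, area_flat) for f in fields])
    pres = np.array([regional_presence(f, area_flat, threshold) for f in fields])
    return pres, extent, area


def build_covariate_table(grid: SICGrid, label_years=None,
                          threshold: float = SIC_THRESHOLD) -> pd.DataFrame:
    """Season x 10 covariate table, one row per label year.

    Seasons without full daily coverage become rows of NaN (logged) so the
    year axis stays contiguous; PCA later drops them.
    """
    if label_years is None:
        years = np.unique(grid.dates.astype("datetime64[Y]").astype(int) + 1970)
        label_years = [int(y) for y in years
                       if SeasonWindow(int(y)).start_date >= grid.dates[0]
                       and SeasonWindow(int(y)).end_date <= grid.dates[-1] + 1]
    rows = []
    for year in label_years:
        window = SeasonWindow(int(year))
        try:
            pres, extent, area = season_series(grid, window, threshold)
            rows.append(season_metrics(pres, extent, area, int(year)).as_row())
        except ValueError as err:
            logger.warning("season %d skipped: %s", year, err)
            rows.append({k: np.nan for k in COVARIATE_COLUMNS})
    table = pd.DataFrame(rows, index=pd.Index(label_years, name="season"))
    return table[COVARIATE_COLUMNS]


@dataclass
class PCAResult:
    loadings: pd.DataFrame       # variable x component
    scores: pd.DataFrame         # season x component
    var_explained: np.ndarray    # fraction per component, non-increasing
    mean: pd.Series
    sd: pd.Series

    def project(self, table: pd.DataFrame) -> pd.DataFrame:
        """Project new seasons with the stored standardization."""
        z = (table[self.mean.index] - self.mean) / self.sd
        return z @ self.loadings


def pca(table: pd.DataFrame) -> PCAResult:
    """PCA of the correlation matrix of the covariate table.

    Rows with any missing value are dropped (logged).  Scores are the
    standardized data projected on the eigenvectors; the sign of each
    loading vector is fixed so its largest-magnitude element is positive.
    """
    complete = table.dropna()
    dropped = len(table) - len(complete)
    if dropped:
        logger.info("pca: dropping %d incomplete season rows", dropped)
    if len(complete) < 2:
        raise ValueError("pca needs at least 2 complete rows")
    mean = complete.mean()
    sd = complete.std(ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        raise ValueError(f"constant column(s): {list(constant)}")
    z = ((complete - mean) / sd).to_numpy()
    n = z.shape[0]
    # SVD of the standardized data: eigenvectors of the correlation matrix
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    eigvals = s**2 / (n - 1)
    load = vt.T
    flip = np.sign(load[np.abs(load).argmax(axis=0), np.arange(load.shape[1])])
    flip[flip == 0] = 1.0
    load = load * flip
    comp = [f"PC{i + 1}" for i in range(load.shape[1])]
    loadings = pd.DataFrame(load, index=complete.columns, columns=comp)
    scores = pd.DataFrame(z @ load, index=complete.index, columns=comp)
    return PCAResult(
        loadings=loadings,
        scores=scores,
        var_explained=eigvals / eigvals.sum(),
        mean=mean,
        sd=sd,
    )
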