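"""Sediment-core dating and annual scale-accumulation series.

Sediment subsamples carrying lepidopteran (moth) scale counts are dated with
the constant-rate-of-supply (CRS) ²¹⁰Pb model, t(z) = λ⁻¹ ln(I₀ / I(z)),
where I(z) is the unsupported ²¹⁰Pb inventory below depth z and λ the ²¹⁰Pb
decay constant (half-life 22.3 yr).  Dated subsamples are then spread onto a
calendar-year grid by proportional overlap weighting, conserving the total
scale count, to give a scales·cm⁻²·yr⁻¹ accumulation series comparable with
annual tree-ring records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PB210_HALF_LIFE",
    "PB210_LAMBDA",
    "PbProfile",
    "AgeDepthModel",
    "ScaleRecord",
    "AnnualSeries",
    "fit_crs",
    "annualize_scales",
    "composite_scale_mean",
]

PB210_HALF_LIFE = 22.3  # years
PB210_LAMBDA = np.log(2.0) / PB210_HALF_LIFE  # yr^-1


@dataclass
class PbProfile:
    """Contiguous depth intervals with unsupported ²¹⁰Pb and cumulative dry mass.

    ``cum_dry_mass`` is the cumulative dry mass (g cm⁻²) at the *bottom* of
    each interval; ``activity`` is the interval-mean unsupported activity in
    Bq kg⁻¹.
    """

    top_depth: np.ndarray  # cm
    bottom_depth: np.ndarray  # cm
    activity: np.ndarray  # Bq/kg unsupported
    cum_dry_mass: np.ndarray  # g/cm^2 at bottom of interval

    def __post_init__(self) -> None:
        self.top_depth = np.asarray(self.top_depth, dtype=float)
        self.bottom_depth = np.asarray(self.bottom_depth, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.cum_dry_mass = np.asarray(self.cum_dry_mass, dtype=float)
        if not (
            self.top_depth.shape
            == self.bottom_depth.shape
            == self.activity.shape
            == self.cum_dry_mass.shape
        ):
            raise ValueError("profile arrays must share one shape")
        if np.any(self.bottom_depth <= self.top_depth):
            raise ValueError("need top < bottom per interval")
        if np.any(np.diff(self.top_depth) <= 0):
            raise ValueError("depths must strictly increase")
        if np.any(self.activity < 0):
            raise ValueError("activities must be >= 0")
        if np.any(np.diff(self.cum_dry_mass) <= 0):
            raise ValueError("cumulative dry mass must increase")

    @property
    def mass_increment(self) -> np.ndarray:
        """Dry mass per interval (g cm⁻²)."""
        prev = np.concatenate(([0.0], self.cum_dry_mass[:-1]))
        return self.cum_dry_mass - prev

    @classmethod
    def from_csv(cls, path) -> "PbProfile":
        df = pd.read_csv(path)
        return cls(
            top_depth=df["top_depth_cm"].to_numpy(),
            bottom_depth=df["bottom_depth_cm"].to_numpy(),
            activity=df["activity_Bq_kg"].to_numpy(),
            cum_dry_mass=df["dry_mass_g_cm2"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "top_depth_cm": self.top_depth,
                "bottom_depth_cm": self.bottom_depth,
                "activity_Bq_kg": self.activity,
                "dry_mass_g_cm2": self.cum_dry_mass,
            }
        ).to_csv(path, index=False)


@dataclass
class AgeDepthModel:
    """CRS ages (years before coring) at interval boundary depths."""

    boundary_depth: np.ndarray  # cm, starts at core top
    age: np.ndarray  # yr before coring at each boundary, age[0] = 0
    coring_year: int
    lambda_: float = PB210_LAMBDA

    def __post_init__(self) -> None:
        self.boundary_depth = np.asarray(self.boundary_depth, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        if np.any(np.diff(self.age) <= 0):
            raise ValueError("CRS ages must strictly increase with depth")

    def age_at(self, depth) -> np.ndarray:
        """Piecewise-linear age (yr before coring) at arbitrary depth."""
        return np.interp(depth, self.boundary_depth, self.age)

    def year_at(self, depth) -> np.ndarray:
        return self.coring_year - self.age_at(depth)


@dataclass
class ScaleRecord:
    """Lepidopteran scale counts per sediment subsample."""

    top_depth: np.ndarray  # cm
    bottom_depth: np.ndarray  # cm
    count: np.ndarray  # scales
    area: np.ndarray  # cm^2 sampled
    site_id: str = ""

    def __post_init__(self) -> None:
        self.top_depth = np.asarray(self.top_depth, dtype=float)
        self.bottom_depth = np.asarray(self.bottom_depth, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        self.area = np.broadcast_to(np.asarray(self.area, dtype=float), self.count.shape).copy()
        if np.any(self.count < 0):
            raise ValueError("scale counts must be >= 0")
        if np.any(self.bottom_depth <= self.top_depth):
            raise ValueError("need top < bottom per subsample")

    @classmethod
    def from_csv(cls, path, site_id: str = "") -> "ScaleRecord":
        df = pd.read_csv(path)
        return cls(
            top_depth=df["top_depth_cm"].to_numpy(),
            bottom_depth=df["bottom_depth_cm"].to_numpy(),
            count=df["scale_count"].to_numpy(),
            area=df["area_cm2"].to_numpy(),
            site_id=site_id,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "top_depth_cm": self.top_depth,
                "bottom_depth_cm": self.bottom_depth,
                "scale_count": self.count,
                "area_cm2": self.area,
            }
        ).to_csv(path, index=False)


@dataclass
class AnnualSeries:
    """Gap-free annual series: consecutive integer years -> value."""

    first_year: int
    values: np.ndarray
    units: str = ""
    site_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)):
            raise ValueError("annual series may not contain missing values")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.values.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.values.size - 1

    def window(self, y0: int, y1: int) -> "AnnualSeries":
        """Inclusive year window [y0, y1]."""
        i0 = max(y0, self.first_year) - self.first_year
        i1 = min(y1, self.last_year) - self.first_year + 1
        if i1 <= i0:
            raise ValueError("window does not intersect series span")
        return AnnualSeries(self.first_year + i0, self.values[i0:i1], self.units, self.site_id)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.years, name=self.site_id or self.units)

    def to_csv(self, path) -> None:
        pd.DataFrame({"year": self.years, "value": self.values}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, units: str = "", site_id: str = "") -> "AnnualSeries":
        df = pd.read_csv(path)
        years = df["year"].to_numpy(dtype=int)
        if np.any(np.diff(years) != 1):
            raise ValueError("annual CSV must have consecutive years")
        return cls(int(years[0]), df["value"].to_numpy(), units, site_id)


# ---------------------------------------------------------------------------
# CRS dating
# ---------------------------------------------------------------------------


def estimate_supported(profile: PbProfile, frac_of_surface: float = 0.05) -> float:
    """Supported (background) ²¹⁰Pb from the deep plateau.

    Mean activity of intervals below the first depth at which activity drops
    under ``frac_of_surface`` of the surface activity; 0 when no plateau is
    reached (the profile is then taken as already background-corrected).
    """
    surface = profile.activity[0]
    low = profile.activity < frac_of_surface * surface
    if not np.any(low):
        return 0.0
    return float(np.mean(profile.activity[low]))


def fit_crs(
    profile: PbProfile,
    coring_year: int,
    supported: float | None = 0.0,
    max_age: float = 150.0,
) -> AgeDepthModel:
    """Fit the constant-rate-of-supply ²¹⁰Pb age model.

    Parameters
    ----------
    profile
        Depth intervals with (unsupported, unless `supported` is used)
        activity and cumulative dry mass.
    coring_year
        Calendar year of core collection (age zero).
    supported
        Background activity to subtract (Bq kg⁻¹); ``None`` triggers
        plateau-based estimation, 0 assumes the profile is already
        unsupported-only.
    max_age
        Ages are clipped at this horizon: below the depth where the residual
        inventory reaches I₀·exp(−λ·max_age) the model stops being datable.
    """
    if profile.activity.size < 3:
        raise ValueError("CRS needs at least 3 intervals")
    if supported is None:
        supported = estimate_supported(profile)
    unsupp = profile.activity - supported
    # interval inventory: interval-mean activity times interval dry mass
    inv = np.clip(unsupp, 0.0, None) * profile.mass_increment
    total = float(np.sum(inv))
    if total <= 0:
        raise ValueError("non-positive total unsupported inventory")
    # inventory remaining below each interval boundary (top of core first)
    below = total - np.concatenate(([0.0], np.cumsum(inv)))
    floor = total * np.exp(-PB210_LAMBDA * max_age)
    datable = below > floor
    if np.any(unsupp[datable[1:]] <= 0):
        raise ValueError(
            "non-positive unsupported activity above the background horizon; "
            "inventory is incomplete"
        )
    ages = np.where(datable, np.log(total / np.maximum(below, floor)) / PB210_LAMBDA, max_age)
    # drop duplicate clipped tail so ages strictly increase
    boundaries = np.concatenate(([profile.top_depth[0]], profile.bottom_depth))
    keep = np.concatenate(([True], np.diff(ages) > 0))
    return AgeDepthModel(
        boundary_depth=boundaries[keep], age=ages[keep], coring_year=coring_year
    )


# ---------------------------------------------------------------------------
# Annualization
# ---------------------------------------------------------------------------


def annualize_scales(record: ScaleRecord, model: AgeDepthModel) -> AnnualSeries:
    """Proportional-overlap interpolation of subsample accumulations to years.

    Each dated subsample has an accumulation rate count/(area·span) in
    scales·cm⁻²·yr⁻¹ over its calendar span; each calendar year [y, y+1)
    receives the overlap-weighted sum of the rates of the subsamples covering
    it.  When the subsample spans tile the record the total scale count is
    conserved exactly.
    """
    year_top = model.year_at(record.top_depth)
    year_bot = model.year_at(record.bottom_depth)
    # deeper sediment is older: bottom year < top year
    start = np.minimum(year_top, year_bot)
    end = np.maximum(year_top, year_bot)
    span = end - start
    if np.any(span <= 0):
        raise ValueError("subsample with non-positive year span")
    order = np.argsort(start)
    if np.any(start[order][1:] - end[order][:-1] > 1e-9):
        raise ValueError("gap in dated subsample spans; age model broken")
    rate = record.count / (record.area * span)  # scales cm^-2 yr^-1

    y0 = int(np.floor(start.min()))
    y1 = int(np.ceil(end.max()))
    years = np.arange(y0, y1)
    values = np.zeros(years.size)
    for s, e, r in zip(start, end, rate):
        lo = np.maximum(years, s)
        hi = np.minimum(years + 1, e)
        overlap = np.clip(hi - lo, 0.0, None)
        values += overlap * r
    # trim partially covered edge years so every reported year is fully dated
    cover = np.zeros(years.size)
    for s, e in zip(start, end):
        cover += np.clip(np.minimum(years + 1, e) - np.maximum(years, s), 0.0, None)
    full = cover > 1.0 - 1e-6
    if not np.any(full):
        raise ValueError("no calendar year fully covered by dated subsamples")
    i0, i1 = np.argmax(full), years.size - np.argmax(full[::-1])
    return AnnualSeries(
        first_year=int(years[i0]),
        values=values[i0:i1],
        units="scales cm^-2 yr^-1",
        site_id=record.site_id,
    )


def composite_scale_mean(series: list[AnnualSeries]) -> AnnualSeries:
    """Per-year arithmetic mean over the sites with data that year."""
    if len(series) < 2:
        raise ValueError("composite needs at least 2 series")
    df = pd.concat([s.to_series() for s in series], axis=1).sort_index()
    if df.dropna(how="all").empty:
        raise ValueError("series do not overlap")
    mean = df.mean(axis=1)
    years = mean.index.to_numpy(dtype=int)
    if np.any(np.diff(years) != 1):  # spans are contiguous by construction
        raise ValueError("composite year coverage has gaps")
    return AnnualSeries(int(years[0]), mean.to_numpy(), units=series[0].units, site_id="composite")
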