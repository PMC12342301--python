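"""Tree-ring series, detrending, and site chronology statistics.

Dated ring-width series are detrended with a cubic smoothing spline whose
frequency response is 50% at a chosen wavelength (60 yr by default), divided
through to give dimensionless ring-width indices (RWI), and averaged into a
site chronology with Tukey's biweight robust mean.  Chronology reliability is
quantified by the mean inter-series correlation r-bar, the expressed
population signal (EPS) and the subsample signal strength (SSS); EPS-guided
"chronology stripping" greedily drops series whose removal raises EPS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import curve_fit

__all__ = [
    "TreeRingSeries",
    "RwiSeries",
    "SiteChronology",
    "read_rwl",
    "write_rwl",
    "detrend_spline",
    "biweight_mean",
    "interseries_correlation",
    "build_chronology",
    "eps",
    "sss",
    "strip_chronology",
    "composite_rwi",
]

WHITE_SPRUCE = "white spruce"
BLACK_SPRUCE = "black spruce"


@dataclass
class TreeRingSeries:
    """One dated, measured radius: consecutive annual ring widths in mm."""

    tree_id: str
    first_year: int
    widths: np.ndarray
    site_id: str = ""
    species: str = WHITE_SPRUCE

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size == 0:
            raise ValueError("widths must be a non-empty 1-d array")
        if np.any(self.widths <= 0):
            raise ValueError(f"{self.tree_id}: ring widths must be > 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.widths.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.widths.size - 1


@dataclass
class RwiSeries:
    """Detrended, standardized ring-width index (dimensionless, mean ~ 1)."""

    tree_id: str
    first_year: int
    index: np.ndarray
    site_id: str = ""
    species: str = WHITE_SPRUCE

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=float)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.index.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.index.size - 1

    def to_series(self) -> pd.Series:
        return pd.Series(self.index, index=self.years, name=self.tree_id)


@dataclass
class SiteChronology:
    """Mean site index with replication and signal-strength statistics."""

    years: np.ndarray
    index: np.ndarray
    sample_depth: np.ndarray
    rbar: float
    eps: float
    sss: np.ndarray
    tree_ids: list[str] = field(default_factory=list)
    site_id: str = ""
    species: str = WHITE_SPRUCE

    def value_at(self, years: np.ndarray) -> np.ndarray:
        s = pd.Series(self.index, index=self.years)
        return s.reindex(np.asarray(years)).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "index": self.index,
                "depth": self.sample_depth,
                "sss": self.sss,
            }
        )


# ---------------------------------------------------------------------------
# Tucson / RWL format
# ---------------------------------------------------------------------------

# Terminator sentinel encodes the measurement unit: 999 -> 0.01 mm, -9999 -> 0.001 mm.
_UNIT_BY_STOP = {999: 0.01, -9999: 0.001}


def read_rwl(path, site_id: str = "", species: str = WHITE_SPRUCE) -> list[TreeRingSeries]:
    """Read a Tucson (decadal) ring-width file.

    Values are converted to mm according to the series terminator flag
    (``999`` = hundredths of mm, ``-9999`` = thousandths).
    """
    chunks: dict[str, list[tuple[int, list[int]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            sid = raw[:8].strip()
            rest = raw[8:].split()
            if not sid or len(rest) < 2:
                raise ValueError(f"{path}:{lineno}: malformed decade row")
            try:
                decade = int(rest[0])
                vals = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed decade row ({exc})") from None
            chunks.setdefault(sid, []).append((decade, vals))
            if sid not in order:
                order.append(sid)

    out = []
    for sid in order:
        rows = sorted(chunks[sid])
        values: list[int] = []
        first_year = rows[0][0]
        for _, vals in rows:
            values.extend(vals)
        # the sentinel is the trailing value only: 999 (and, rarely, -9999)
        # are legitimate widths elsewhere in the series
        if not values or values[-1] not in _UNIT_BY_STOP:
            raise ValueError(f"{path}: series {sid} lacks a 999/-9999 terminator")
        unit = _UNIT_BY_STOP[values[-1]]
        values = values[:-1]
        out.append(
            TreeRingSeries(
                tree_id=sid,
                first_year=first_year,
                widths=np.asarray(values, dtype=float) * unit,
                site_id=site_id,
                species=species,
            )
        )
    return out


def write_rwl(path, series: list[TreeRingSeries], unit: float = 0.01) -> None:
    """Write Tucson decadal rows; ``unit`` selects the precision/terminator."""
    stop = {0.01: 999, 0.001: -9999}[unit]
    with open(path, "w") as fh:
        for s in series:
            ints = np.rint(s.widths / unit).astype(int)
            # widths are positive; keep at least one unit so round-trip stays valid
            ints = np.maximum(ints, 1)
            year = s.first_year
            vals = list(ints) + [stop]
            while vals:
                row_end = (year // 10) * 10 + 10  # next decade boundary
                take = min(len(vals), row_end - year)
                row = vals[:take]
                vals = vals[take:]
                fh.write(f"{s.tree_id:<8}{year:4d}" + "".join(f"{v:6d}" for v in row) + "\n")
                year += take


# ---------------------------------------------------------------------------
# Detrending
# ---------------------------------------------------------------------------


def _spline_lambda(wavelength: float) -> float:
    # Second-derivative-penalty smoothing spline has amplitude response
    # 1 / (1 + lam * (2*pi*f)^4); 50% response at f = 1/wavelength gives:
    return (wavelength / (2.0 * np.pi)) ** 4


def _negexp_fit(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    def model(t, a, b, c):
        return a * np.exp(-b * t) + c

    try:
        p0 = (max(y[0] - y[-1], 1e-3), 0.02, max(y[-1], 1e-3))
        popt, _ = curve_fit(model, t, y, p0=p0, maxfev=5000)
        fit = model(t, *popt)
        if np.all(fit > 0) and popt[1] >= 0:
            return fit
    except RuntimeError:
        pass
    # fall back to the horizontal mean when the negexp is degenerate
    return np.full_like(y, float(np.mean(y)))


def detrend_spline(series: TreeRingSeries, wavelength: float = 60.0) -> RwiSeries:
    """Detrend by ratio against a smoothing spline (50% response at `wavelength`).

    Series shorter than half the wavelength are detrended with a fitted
    negative exponential instead, which avoids overfitting very short series.
    """
    y = series.widths
    t = np.arange(y.size, dtype=float)
    if y.size < wavelength / 2.0:
        fit = _negexp_fit(t, y)
    else:
        spl = make_smoothing_spline(t, y, lam=_spline_lambda(wavelength))
        fit = spl(t)
    if np.any(fit <= 0):
        raise ValueError(f"{series.tree_id}: nonpositive fitted growth curve")
    return RwiSeries(
        tree_id=series.tree_id,
        first_year=series.first_year,
        index=y / fit,
        site_id=series.site_id,
        species=series.species,
    )


# ---------------------------------------------------------------------------
# Chronology statistics
# ---------------------------------------------------------------------------


def biweight_mean(x: np.ndarray, c: float = 9.0) -> float:
    """Tukey's biweight robust mean (median start, MAD scale)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan
    med = np.median(x)
    s = np.median(np.abs(x - med))
    if s == 0:
        return float(med)
    u = (x - med) / (c * s)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return float(np.sum(w * x) / np.sum(w))


def _align(series: list[RwiSeries]) -> pd.DataFrame:
    return pd.concat([s.to_series() for s in series], axis=1).sort_index()


def interseries_correlation(series: list[RwiSeries], min_overlap: int = 30) -> float:
    """Mean pairwise Pearson correlation (r-bar) over pairwise-complete overlaps.

    Pairs with fewer than `min_overlap` common years are excluded.
    """
    df = _align(series)
    corr = df.corr(min_periods=min_overlap).to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    vals = corr[iu]
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else np.nan


def eps(rbar: float, n: int) -> float:
    """Expressed population signal: EPS = n*rbar / (1 + (n-1)*rbar)."""
    if n < 2:
        raise ValueError("EPS requires n >= 2 series")
    if rbar < 0:
        warnings.warn("negative r-bar clamped to 0 for EPS", stacklevel=2)
        rbar = 0.0
    return n * rbar / (1.0 + (n - 1) * rbar)


def sss(rbar: float, n_sub: int, n_total: int) -> float:
    """Subsample signal strength for n_sub of n_total series."""
    if not (1 <= n_sub <= n_total):
        raise ValueError("require 1 <= n_sub <= n_total")
    if rbar < 0:
        warnings.warn("negative r-bar clamped to 0 for SSS", stacklevel=2)
        rbar = 0.0
    return (n_sub * (1.0 + (n_total - 1) * rbar)) / (n_total * (1.0 + (n_sub - 1) * rbar))


def build_chronology(
    series: list[RwiSeries],
    site_id: str = "",
    robust: bool = True,
    min_overlap: int = 30,
) -> SiteChronology:
    """Average RWI series into a site chronology (biweight mean by default)."""
    if len(series) < 2:
        raise ValueError("need at least 2 series to build a chronology")
    df = _align(series)
    if df.dropna(how="all").empty or df.notna().sum(axis=1).max() < 2:
        raise ValueError("series do not overlap")
    if robust:
        index = df.apply(lambda row: biweight_mean(row.to_numpy()), axis=1)
    else:
        index = df.mean(axis=1)
    depth = df.notna().sum(axis=1).to_numpy()
    rbar = interseries_correlation(series, min_overlap=min_overlap)
    n = len(series)
    rbar_for_stats = max(rbar, 0.0) if np.isfinite(rbar) else 0.0
    sss_year = np.array(
        [sss(rbar_for_stats, int(d), n) if d >= 1 else np.nan for d in depth]
    )
    return SiteChronology(
        years=df.index.to_numpy(),
        index=index.to_numpy(),
        sample_depth=depth,
        rbar=rbar,
        eps=eps(rbar_for_stats, n),
        sss=sss_year,
        tree_ids=[s.tree_id for s in series],
        site_id=site_id,
        species=series[0].species,
    )


def _eps_over_period(series: list[RwiSeries], period: tuple[int, int], min_overlap: int) -> float:
    y0, y1 = period
    clipped = []
    for s in series:
        sr = s.to_series().loc[y0:y1].dropna()
        if sr.size >= min_overlap:
            clipped.append(
                RwiSeries(s.tree_id, int(sr.index[0]), sr.to_numpy(), s.site_id, s.species)
            )
    if len(clipped) < 2:
        return -np.inf
    rbar = interseries_correlation(clipped, min_overlap=min_overlap)
    if not np.isfinite(rbar):
        return -np.inf
    return eps(max(rbar, 0.0), len(clipped))


def strip_chronology(
    series: list[RwiSeries],
    period: tuple[int, int] = (1900, 2019),
    site_id: str = "",
    min_overlap: int = 30,
) -> SiteChronology:
    """Greedy leave-one-out EPS maximisation over the target period.

    At each step the series whose removal most increases EPS is dropped;
    the loop stops when no single removal improves EPS (ties keep the longer
    series, i.e. remove the shorter one).
    """
    if len(series) < 3:
        raise ValueError("chronology stripping needs at least 3 series")
    kept = list(series)
    current = _eps_over_period(kept, period, min_overlap)
    while len(kept) > 2:
        best_gain, victim = 0.0, None
        for i, s in enumerate(kept):
            trial = kept[:i] + kept[i + 1 :]
            e = _eps_over_period(trial, period, min_overlap)
            gain = e - current
            better = gain > best_gain + 1e-12
            tie = abs(gain - best_gain) <= 1e-12 and victim is not None
            if better or (tie and gain > 0 and s.index.size < kept[victim].index.size):
                best_gain, victim = gain, i
        if victim is None or best_gain <= 0:
            break
        current += best_gain
        kept.pop(victim)
    if len(kept) < 2:
        raise ValueError("stripping left fewer than 2 series")
    return build_chronology(kept, site_id=site_id, min_overlap=min_overlap)


def composite_rwi(
    series_by_site: dict[str, list[RwiSeries]],
    species: str,
    min_overlap: int = 30,
) -> SiteChronology:
    """Pool standardized series from several same-species sites."""
    pooled: list[RwiSeries] = []
    for site, group in series_by_site.items():
        for s in group:
            if s.species != species:
                raise ValueError(
                    f"composite restricted to {species!r}; {site}/{s.tree_id} is {s.species!r}"
                )
            pooled.append(s)
    chron = build_chronology(pooled, site_id=f"composite-{species}", min_overlap=min_overlap)
    chron.species = species
    return chron
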