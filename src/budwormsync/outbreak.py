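"""Growth-suppression index and defoliation/outbreak detection.

The tree-level growth suppression index follows the host/non-host correction
GSI_i = H_i − (NH_i − NH_m)·(σ_H/σ_NH); with no non-host chronology available
the index is simply the standardized host series, GSI_i = H_i.  Its
standardized form nGSI (mean 0, sd 1) drives defoliation-event detection:
an event is a sustained run of below-average growth (>= `duration_years`
consecutive negative years) reaching at least `max_reduction` standard
deviations at its deepest point, with optional bridging of events separated
by short recoveries and relaxed handling of runs truncated by the series end.
Site-level records report mean GSI and the percentage of recording trees
inside an event each year ("percent affected").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dendro import RwiSeries, SiteChronology

__all__ = [
    "GsiSeries",
    "DefoliationEvent",
    "DefoliationParams",
    "OutbreakRecord",
    "compute_gsi",
    "detect_defoliation",
    "outbreak_metrics",
    "composite_outbreak",
]


@dataclass
class GsiSeries:
    tree_id: str
    first_year: int
    gsi: np.ndarray
    ngsi: np.ndarray
    site_id: str = ""
    species: str = ""

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.gsi.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.gsi.size - 1


@dataclass
class DefoliationEvent:
    tree_id: str
    start_year: int
    end_year: int
    min_ngsi: float
    bridged: bool = False
    series_end: bool = False

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("event end before start")

    @property
    def duration(self) -> int:
        return self.end_year - self.start_year + 1

    def covers(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


@dataclass
class DefoliationParams:
    """Detection thresholds (documented defaults of the defoliation method)."""

    duration_years: int = 8
    max_reduction: float = -1.28  # standard-deviation units
    bridge_events: bool = True
    series_end_events: bool = True


@dataclass
class OutbreakRecord:
    site_id: str
    years: np.ndarray
    mean_gsi: np.ndarray
    perc_affected: np.ndarray  # 0..100
    n_series: np.ndarray
    outbreak_flag: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "mean_gsi": self.mean_gsi,
                "perc_affected": self.perc_affected,
                "n_series": self.n_series,
                "outbreak_flag": self.outbreak_flag,
            }
        )


def compute_gsi(host: RwiSeries, nonhost: SiteChronology | None = None) -> GsiSeries:
    """Tree-level growth suppression index, optionally non-host corrected."""
    h = host.index
    if nonhost is None:
        gsi = h.copy()
    else:
        nh = nonhost.value_at(host.years)
        if np.any(~np.isfinite(nh)):
            raise ValueError("non-host chronology does not cover the host span")
        sd_nh = float(np.std(nh, ddof=1))
        if sd_nh == 0:
            raise ValueError("non-host chronology has zero variance")
        sd_h = float(np.std(h, ddof=1))
        gsi = h - (nh - float(np.mean(nh))) * (sd_h / sd_nh)
    sd = float(np.std(gsi, ddof=1))
    if sd == 0:
        # a perfectly corrected (constant) index carries no deviations
        ngsi = np.zeros_like(gsi)
    else:
        ngsi = (gsi - float(np.mean(gsi))) / sd
    return GsiSeries(
        tree_id=host.tree_id,
        first_year=host.first_year,
        gsi=gsi,
        ngsi=ngsi,
        site_id=host.site_id,
        species=host.species,
    )


def _negative_runs(ngsi: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of strictly negative values as (start, stop) index pairs."""
    neg = ngsi < 0
    runs = []
    i = 0
    n = neg.size
    while i < n:
        if neg[i]:
            j = i
            while j + 1 < n and neg[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def detect_defoliation(
    tree: GsiSeries, params: DefoliationParams | None = None
) -> list[DefoliationEvent]:
    """Detect defoliation events on a standardized (nGSI) series.

    A qualifying run has >= duration_years consecutive negative years and at
    least one year at or below max_reduction.  With series_end_events a
    terminal run reaching max_reduction qualifies regardless of duration;
    with bridge_events, qualifying runs separated only by sub-duration gaps
    are merged into one event.
    """
    p = params or DefoliationParams()
    x = tree.ngsi
    n = x.size
    runs = _negative_runs(x)

    qualifying: list[tuple[int, int, bool]] = []  # (start, stop, series_end_flag)
    for i, j in runs:
        deep = np.min(x[i : j + 1]) <= p.max_reduction
        long_enough = (j - i + 1) >= p.duration_years
        at_end = j == n - 1
        if long_enough and deep:
            qualifying.append((i, j, False))
        elif p.series_end_events and at_end and deep:
            qualifying.append((i, j, True))

    if not qualifying:
        return []

    merged: list[list] = []
    for i, j, end_flag in qualifying:
        if (
            p.bridge_events
            and merged
            and (i - merged[-1][1] - 1) < p.duration_years
        ):
            merged[-1][1] = j
            merged[-1][2] = merged[-1][2] or end_flag
            merged[-1][3] = True  # bridged
        else:
            merged.append([i, j, end_flag, False])

    return [
        DefoliationEvent(
            tree_id=tree.tree_id,
            start_year=tree.first_year + i,
            end_year=tree.first_year + j,
            min_ngsi=float(np.min(x[i : j + 1])),
            bridged=bridged,
            series_end=end_flag,
        )
        for i, j, end_flag, bridged in merged
    ]


def outbreak_metrics(
    trees: list[tuple[GsiSeries, list[DefoliationEvent]]],
    min_perc: float = 25.0,
    min_series: int = 3,
    site_id: str = "",
) -> OutbreakRecord:
    """Site-level mean GSI, percent affected and outbreak-year flags."""
    if not trees:
        raise ValueError("need at least one tree")
    y0 = min(t.first_year for t, _ in trees)
    y1 = max(t.last_year for t, _ in trees)
    years = np.arange(y0, y1 + 1)
    gsi_sum = np.zeros(years.size)
    n_rec = np.zeros(years.size, dtype=int)
    n_def = np.zeros(years.size, dtype=int)
    for tree, events in trees:
        sl = slice(tree.first_year - y0, tree.last_year - y0 + 1)
        gsi_sum[sl] += tree.gsi
        n_rec[sl] += 1
        for ev in events:
            a = max(ev.start_year, y0) - y0
            b = min(ev.end_year, y1) - y0
            n_def[a : b + 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_gsi = np.where(n_rec > 0, gsi_sum / np.maximum(n_rec, 1), np.nan)
        perc = np.where(n_rec > 0, 100.0 * n_def / np.maximum(n_rec, 1), np.nan)
    flag = (perc >= min_perc) & (n_rec >= min_series)
    return OutbreakRecord(
        site_id=site_id,
        years=years,
        mean_gsi=mean_gsi,
        perc_affected=perc,
        n_series=n_rec,
        outbreak_flag=flag,
    )


def composite_outbreak(
    trees_by_site: dict[str, list[tuple[GsiSeries, list[DefoliationEvent]]]],
    species: str,
    min_perc: float = 25.0,
    min_series: int = 3,
) -> OutbreakRecord:
    """Pool trees across same-species sites and recompute outbreak metrics."""
    pooled: list[tuple[GsiSeries, list[DefoliationEvent]]] = []
    for site, group in trees_by_site.items():
        for tree, events in group:
            if tree.species and tree.species != species:
                raise ValueError(
                    f"composite restricted to {species!r}; {site}/{tree.tree_id} "
                    f"is {tree.species!r}"
                )
            pooled.append((tree, events))
    return outbreak_metrics(
        pooled, min_perc=min_perc, min_series=min_series, site_id=f"composite-{species}"
    )
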