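"""Circular phase statistics and proxy agreement classification.

Phase angles pooled from significant zones of a cross-wavelet or coherence
spectrum summarize whether two proxies move in-phase (mean phase near 0) or
anti-phase (near π).  Because larger moth populations *suppress* tree growth,
the sedimentary scale record agrees with the mean growth-suppression index
when the two are anti-phase, but agrees with the percent-affected record
when in-phase.  The continuous circular mean is collapsed to a binary
agreement/disagreement call by the sign of its cosine (nearest hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wavelet import WaveletProduct

__all__ = [
    "WINDOWS",
    "SCALES_VS_GSI",
    "SCALES_VS_PCT",
    "PhaseSummary",
    "AgreementCall",
    "circular_mean_sd",
    "xwt_zone",
    "wtc_zone",
    "phase_stats",
    "classify_agreement",
]

# inclusive calendar windows: full study period and the three 20th-century
# spruce budworm outbreaks
WINDOWS: dict[str, tuple[int, int]] = {
    "All": (1900, 2019),
    "O3": (1912, 1929),
    "O2": (1946, 1959),
    "O1": (1975, 1992),
}

SCALES_VS_GSI = "scales~GSI"
SCALES_VS_PCT = "scales~pctAff"


@dataclass
class PhaseSummary:
    comparison: str  # SCALES_VS_GSI | SCALES_VS_PCT
    zone_type: str  # 'xwt-significant' | 'wtc-r2'
    window: str  # key of WINDOWS
    mean: float  # circular mean, radians in (-pi, pi]
    sd: float  # circular standard deviation, radians
    n: int  # cells pooled


@dataclass
class AgreementCall:
    site: str
    comparison: str
    analysis: str  # 'cross-wavelet' | 'coherence'
    window: str
    call: str  # 'A' | 'D' | '-'
    mean_phase: float | None = None
    sd_phase: float | None = None
    n_cells: int = 0


def circular_mean_sd(phases: np.ndarray) -> tuple[float, float, float]:
    """Circular mean, SD = sqrt(-2 ln R̄) and mean resultant length R̄."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("no phases to average")
    c, s = np.mean(np.cos(phases)), np.mean(np.sin(phases))
    rbar = float(np.hypot(c, s))
    mean = float(np.arctan2(s, c))
    sd = float(np.sqrt(-2.0 * np.log(max(rbar, 1e-300))))
    return mean, sd, rbar


def xwt_zone(product: WaveletProduct, restrict_coi: bool = True) -> np.ndarray:
    """Zone of significant overlapping cross power (ratio > 1), inside COI."""
    if product.signif_ratio is None:
        raise ValueError("product lacks a significance ratio")
    zone = product.signif_ratio > 1.0
    if restrict_coi:
        zone &= product.inside_coi()
    return zone


def wtc_zone(
    product: WaveletProduct, r2_threshold: float = 0.80, restrict_coi: bool = True
) -> np.ndarray:
    """Zone of high coherence (R² >= threshold), inside COI."""
    zone = product.power >= r2_threshold
    if restrict_coi:
        zone &= product.inside_coi()
    return zone


def phase_stats(
    product: WaveletProduct,
    zone: np.ndarray,
    window: str = "All",
    comparison: str = SCALES_VS_GSI,
    zone_type: str = "xwt-significant",
) -> PhaseSummary | None:
    """Circular mean/SD of phases in `zone` ∩ calendar `window`; None if empty."""
    if product.phase is None:
        raise ValueError("product carries no phase field")
    y0, y1 = WINDOWS[window]
    mask = zone & product.year_mask(y0, y1)[None, :]
    phases = product.phase[mask]
    if phases.size == 0:
        return None
    mean, sd, _ = circular_mean_sd(phases)
    return PhaseSummary(
        comparison=comparison,
        zone_type=zone_type,
        window=window,
        mean=mean,
        sd=sd,
        n=int(phases.size),
    )


def classify_agreement(
    summary: PhaseSummary | None,
    site: str = "",
    analysis: str = "cross-wavelet",
    comparison: str | None = None,
    window: str | None = None,
) -> AgreementCall:
    """Collapse a circular mean phase to an A/D call; '-' for an empty zone.

    scales~GSI agrees when anti-phase (cos(mean) < 0): abundant moths, and
    hence scales, coincide with suppressed growth.  scales~pctAff agrees when
    in-phase (cos(mean) > 0).
    """
    if summary is None:
        return AgreementCall(
            site=site,
            comparison=comparison or "",
            analysis=analysis,
            window=window or "",
            call="-",
        )
    anti = np.cos(summary.mean) < 0
    if summary.comparison == SCALES_VS_GSI:
        call = "A" if anti else "D"
    elif summary.comparison == SCALES_VS_PCT:
        call = "D" if anti else "A"
    else:
        raise ValueError(f"unknown comparison {summary.comparison!r}")
    return AgreementCall(
        site=site,
        comparison=summary.comparison,
        analysis=analysis,
        window=summary.window,
        call=call,
        mean_phase=summary.mean,
        sd_phase=summary.sd,
        n_cells=summary.n,
    )


def calls_to_frame(calls: list[AgreementCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site": [c.site for c in calls],
            "comparison": [c.comparison for c in calls],
            "analysis": [c.analysis for c in calls],
            "window": [c.window for c in calls],
            "call": [c.call for c in calls],
            "mean_phase": [c.mean_phase for c in calls],
            "sd_phase": [c.sd_phase for c in calls],
            "n_cells": [c.n_cells for c in calls],
        }
    )
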