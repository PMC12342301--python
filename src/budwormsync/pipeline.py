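"""End-to-end per-site and per-species-composite orchestration.

`run_site` executes the full chain for one site: read ring widths -> detrend
-> EPS-guided stripping -> GSI / defoliation / outbreak metrics -> CRS dating
-> annualized scale accumulation -> optional outlier imputation -> GAM
smoothing -> CWT (+AR(1) significance) -> XWT and WTC against both tree-ring
variables -> circular phase statistics per outbreak window -> A/D agreement
calls.  `run_composite` pools same-species sites and repeats the comparison
on the composite records.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dendro, outbreak, sediment, smoothing, synchrony, wavelet

__all__ = ["SiteManifest", "SiteResult", "RunReport", "run_site", "run_composite", "run_all"]


@dataclass
class SiteManifest:
    site_id: str
    species: str
    rwl: str
    scales_csv: str
    pb_csv: str
    coring_year: int
    impute_years: list[int] = field(default_factory=list)
    window: tuple[int, int] = (1900, 2019)
    supported_pb: float | None = 0.0  # None -> plateau auto-detection

    @classmethod
    def from_dict(cls, d: dict) -> "SiteManifest":
        known = {k: d[k] for k in (
            "site_id", "species", "rwl", "scales_csv", "pb_csv", "coring_year"
        )}
        return cls(
            **known,
            impute_years=list(d.get("impute_years", [])),
            window=tuple(d.get("window", (1900, 2019))),
            supported_pb=d.get("supported_pb", 0.0),
        )

    def validate(self) -> None:
        for p in (self.rwl, self.scales_csv, self.pb_csv):
            if not Path(p).exists():
                raise FileNotFoundError(p)


@dataclass
class SiteResult:
    site_id: str
    species: str
    chronology: dendro.SiteChronology
    outbreak_record: outbreak.OutbreakRecord
    scales_annual: sediment.AnnualSeries
    smoothed: dict[str, smoothing.SmoothedSeries]
    cwt: dict[str, wavelet.WaveletProduct]
    xwt: dict[str, wavelet.WaveletProduct]
    wtc: dict[str, wavelet.WaveletProduct]
    calls: list[synchrony.AgreementCall]
    phase_summaries: list[synchrony.PhaseSummary | None]

    def summary_dict(self) -> dict:
        sss_ok = self.chronology.years[self.chronology.sss > 0.85]
        return {
            "site_id": self.site_id,
            "species": self.species,
            "n_trees": len(self.chronology.tree_ids),
            "rbar": round(float(self.chronology.rbar), 4),
            "eps": round(float(self.chronology.eps), 4),
            "sss_above_0.85": [int(sss_ok.min()), int(sss_ok.max())] if sss_ok.size else None,
            "calls": [
                {
                    "comparison": c.comparison,
                    "analysis": c.analysis,
                    "window": c.window,
                    "call": c.call,
                    "mean_phase": None if c.mean_phase is None else round(c.mean_phase, 4),
                    "n_cells": c.n_cells,
                }
                for c in self.calls
            ],
        }


@dataclass
class RunReport:
    sites: dict[str, dict] = field(default_factory=dict)
    composites: dict[str, dict] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    parameters: dict = field(default_factory=dict)

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "parameters": self.parameters,
                "sites": self.sites,
                "composites": self.composites,
                "errors": self.errors,
            },
            sort_keys=True,
            **kw,
        )

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _compare_proxies(
    scales_ann: sediment.AnnualSeries,
    gsi_ann: sediment.AnnualSeries,
    pct_ann: sediment.AnnualSeries,
    site_id: str,
    seed: int,
    n_mc: int = 1000,
    impute: list[int] | None = None,
):
    """Shared tail of the pipeline: GAM -> CWT/XWT/WTC -> phases -> calls."""
    if impute:
        gsi_ann = smoothing.impute_years(gsi_ann, impute)
    smoothed = {
        "scales": smoothing.gam_smooth(scales_ann),
        "gsi": smoothing.gam_smooth(gsi_ann),
        "pct": smoothing.gam_smooth(pct_ann),
    }
    cwts = {}
    for name, sm in smoothed.items():
        prod = wavelet.cwt_morlet(sm.series)
        wavelet.ar1_significance(prod)
        cwts[name] = prod

    comparisons = {
        synchrony.SCALES_VS_GSI: "gsi",
        synchrony.SCALES_VS_PCT: "pct",
    }
    xwts, wtcs, calls, summaries = {}, {}, [], []
    for comp, key in comparisons.items():
        xp = wavelet.xwt(cwts["scales"], cwts[key])
        wp = wavelet.wtc(cwts["scales"], cwts[key], n_mc=n_mc, seed=seed)
        xwts[comp], wtcs[comp] = xp, wp
        for analysis, prod, zone, ztype in (
            ("cross-wavelet", xp, synchrony.xwt_zone(xp), "xwt-significant"),
            ("coherence", wp, synchrony.wtc_zone(wp), "wtc-r2"),
        ):
            for window in synchrony.WINDOWS:
                summ = synchrony.phase_stats(
                    prod, zone, window=window, comparison=comp, zone_type=ztype
                )
                summaries.append(summ)
                calls.append(
                    synchrony.classify_agreement(
                        summ, site=site_id, analysis=analysis,
                        comparison=comp, window=window,
                    )
                )
    return smoothed, cwts, xwts, wtcs, calls, summaries


def _annual_from_outbreak(
    rec: outbreak.OutbreakRecord, attr: str, units: str, window: tuple[int, int]
) -> sediment.AnnualSeries:
    ok = rec.n_series >= 1
    years = rec.years[ok]
    vals = getattr(rec, attr)[ok]
    ser = sediment.AnnualSeries(int(years[0]), vals, units=units, site_id=rec.site_id)
    return ser.window(*window)


def run_site(
    manifest: SiteManifest,
    seed: int = 0,
    n_mc: int = 1000,
    defol_params: outbreak.DefoliationParams | None = None,
) -> SiteResult:
    """Execute the full two-proxy analysis for one site."""
    manifest.validate()
    trees = dendro.read_rwl(manifest.rwl, site_id=manifest.site_id, species=manifest.species)
    rwi = [dendro.detrend_spline(t) for t in trees]
    chron = dendro.strip_chronology(rwi, period=manifest.window, site_id=manifest.site_id)
    kept = [s for s in rwi if s.tree_id in chron.tree_ids]

    gsi_trees = []
    for s in kept:
        g = outbreak.compute_gsi(s, nonhost=None)
        gsi_trees.append((g, outbreak.detect_defoliation(g, defol_params)))
    rec = outbreak.outbreak_metrics(gsi_trees, site_id=manifest.site_id)

    profile = sediment.PbProfile.from_csv(manifest.pb_csv)
    model = sediment.fit_crs(profile, manifest.coring_year, supported=manifest.supported_pb)
    record = sediment.ScaleRecord.from_csv(manifest.scales_csv, site_id=manifest.site_id)
    scales_ann = sediment.annualize_scales(record, model)

    y0 = max(manifest.window[0], scales_ann.first_year, int(rec.years[rec.n_series >= 1].min()))
    y1 = min(manifest.window[1], scales_ann.last_year, int(rec.years[rec.n_series >= 1].max()))
    window = (y0, y1)
    scales_ann = scales_ann.window(*window)
    gsi_ann = _annual_from_outbreak(rec, "mean_gsi", "mean GSI", window)
    pct_ann = _annual_from_outbreak(rec, "perc_affected", "percent affected", window)

    smoothed, cwts, xwts, wtcs, calls, summaries = _compare_proxies(
        scales_ann, gsi_ann, pct_ann, manifest.site_id, seed,
        n_mc=n_mc, impute=manifest.impute_years,
    )
    return SiteResult(
        site_id=manifest.site_id,
        species=manifest.species,
        chronology=chron,
        outbreak_record=rec,
        scales_annual=scales_ann,
        smoothed=smoothed,
        cwt=cwts,
        xwt=xwts,
        wtc=wtcs,
        calls=calls,
        phase_summaries=summaries,
    )


def run_composite(
    manifests: list[SiteManifest],
    species: str,
    seed: int = 0,
    n_mc: int = 1000,
    defol_params: outbreak.DefoliationParams | None = None,
) -> SiteResult:
    """Pool >=2 same-species sites and run the comparison on composites."""
    group = sorted(
        (m for m in manifests if m.species == species), key=lambda m: m.site_id
    )
    if len(group) < 2:
        raise ValueError(f"species {species!r} has fewer than 2 sites")
    rwi_by_site: dict[str, list[dendro.RwiSeries]] = {}
    trees_by_site: dict[str, list] = {}
    annual_by_site: list[sediment.AnnualSeries] = []
    window = group[0].window
    for m in group:
        m.validate()
        trees = dendro.read_rwl(m.rwl, site_id=m.site_id, species=m.species)
        rwi = [dendro.detrend_spline(t) for t in trees]
        rwi_by_site[m.site_id] = rwi
        gsis = []
        for s in rwi:
            g = outbreak.compute_gsi(s, nonhost=None)
            gsis.append((g, outbreak.detect_defoliation(g, defol_params)))
        trees_by_site[m.site_id] = gsis
        profile = sediment.PbProfile.from_csv(m.pb_csv)
        model = sediment.fit_crs(profile, m.coring_year, supported=m.supported_pb)
        record = sediment.ScaleRecord.from_csv(m.scales_csv, site_id=m.site_id)
        annual_by_site.append(sediment.annualize_scales(record, model))

    chron = dendro.composite_rwi(rwi_by_site, species)
    rec = outbreak.composite_outbreak(trees_by_site, species)
    scales_ann = sediment.composite_scale_mean(annual_by_site)

    y0 = max(window[0], scales_ann.first_year, int(rec.years[rec.n_series >= 1].min()))
    y1 = min(window[1], scales_ann.last_year, int(rec.years[rec.n_series >= 1].max()))
    scales_ann = scales_ann.window(y0, y1)
    gsi_ann = _annual_from_outbreak(rec, "mean_gsi", "mean GSI", (y0, y1))
    pct_ann = _annual_from_outbreak(rec, "perc_affected", "percent affected", (y0, y1))

    site_id = f"composite-{species.replace(' ', '-')}"
    smoothed, cwts, xwts, wtcs, calls, summaries = _compare_proxies(
        scales_ann, gsi_ann, pct_ann, site_id, seed, n_mc=n_mc
    )
    return SiteResult(
        site_id=site_id,
        species=species,
        chronology=chron,
        outbreak_record=rec,
        scales_annual=scales_ann,
        smoothed=smoothed,
        cwt=cwts,
        xwt=xwts,
        wtc=wtcs,
        calls=calls,
        phase_summaries=summaries,
    )


def run_all(config_path, seed: int | None = None, n_mc: int | None = None) -> RunReport:
    """Run every configured site, then species composites with >=2 sites.

    The YAML config holds global parameters (`seed`, `n_mc`) and a `sites`
    list of manifest mappings.  A failing site is logged and skipped; other
    sites continue.
    """
    cfg = yaml.safe_load(Path(config_path).read_text())
    seed = int(cfg.get("seed", 0)) if seed is None else seed
    n_mc = int(cfg.get("n_mc", 1000)) if n_mc is None else n_mc
    manifests = [SiteManifest.from_dict(d) for d in cfg["sites"]]
    report = RunReport(seed=seed, parameters={"n_mc": n_mc})
    ok: list[SiteManifest] = []
    for m in manifests:
        try:
            res = run_site(m, seed=seed, n_mc=n_mc)
        except Exception as exc:  # noqa: BLE001 - other sites continue
            report.errors[m.site_id] = f"{type(exc).__name__}: {exc}"
            continue
        report.sites[m.site_id] = res.summary_dict()
        ok.append(m)
    for species in sorted({m.species for m in ok}):
        if sum(m.species == species for m in ok) < 2:
            continue
        try:
            res = run_composite(ok, species, seed=seed, n_mc=n_mc)
        except Exception as exc:  # noqa: BLE001
            report.errors[f"composite-{species}"] = f"{type(exc).__name__}: {exc}"
            continue
        report.composites[species] = res.summary_dict()
    return report
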