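"""Coupled synthetic site data with known outbreak ground truth.

One quasi-periodic outbreak forcing (a rectified sinusoid with a ~30-40 yr
return interval plus AR(1) noise) drives both proxies the analysis compares:

* tree rings: a negative-exponential age trend multiplied by lagged growth
  suppression (each tree responds 2-4 yr after the moth population rises)
  and lognormal noise;
* lake sediment: moth-scale deposition proportional to the adult population,
  Poisson-sampled per year, integrated into variable-thickness subsamples,
  with a constant-flux ²¹⁰Pb profile consistent with the (optionally
  jittered) subsample ages.

Everything is deterministic given the config seed, so downstream stages can
be tested against the designed coupling (recovery tests).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .dendro import WHITE_SPRUCE, TreeRingSeries, write_rwl
from .sediment import PB210_LAMBDA, AnnualSeries, PbProfile, ScaleRecord

__all__ = [
    "SyntheticSiteConfig",
    "SyntheticTruth",
    "SedimentSim",
    "simulate_population",
    "simulate_tree_rings",
    "simulate_sediment",
    "write_site",
]


@dataclass
class SyntheticSiteConfig:
    """Generation parameters for one synthetic lake + stand.

    Defaults encode the study conditions the analysis assumes: a ~32-yr
    outbreak return interval with ~14-yr episodes, half of the growth removed
    at outbreak peak, a 2-4 yr tree response lag, and sediment subsamples
    integrating a few years each.
    """

    site_id: str = "synth"
    species: str = WHITE_SPRUCE
    n_trees: int = 25
    start_year: int = 1900
    end_year: int = 2019
    outbreak_period: float = 32.0  # yr between outbreak onsets
    outbreak_duration: float = 14.0  # yr above threshold per episode
    suppression_depth: float = 0.5  # fraction of growth removed at peak
    response_lags: tuple[int, ...] = (2, 3, 4)  # per-tree lag draw
    ar1_coeff: float = 0.3  # lag-1 autocorrelation of forcing noise
    noise_sd: float = 0.15  # marginal sd of forcing noise and tree noise
    scale_yield: float = 50.0  # scales cm^-2 yr^-1 at peak population
    scale_background: float = 2.0  # scales cm^-2 yr^-1 baseline deposition
    sample_area_cm2: float = 30.0  # subsample area (gravity-core cross-section)
    sample_thickness_years: float = 3.0  # yr of deposition per subsample
    sedimentation_cm_yr: float = 0.2  # linear sedimentation rate
    dry_mass_rate: float = 0.03  # g cm^-2 yr^-1 dry-mass accumulation
    pb_surface_activity: float = 500.0  # Bq/kg unsupported at the surface
    dating_jitter_sd: float = 0.0  # yr, perturbation of subsample ages
    outbreak_threshold: float = 0.25  # population level defining outbreak years
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if not 0.0 <= self.suppression_depth < 1.0:
            raise ValueError("suppression_depth must be in [0, 1)")
        if not 0.0 <= self.ar1_coeff < 1.0:
            raise ValueError("ar1_coeff must be in [0, 1)")
        if self.outbreak_duration >= self.outbreak_period:
            raise ValueError("outbreak_duration must be shorter than outbreak_period")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class SyntheticTruth:
    """Ground truth: relative adult-moth abundance and outbreak years."""

    population: AnnualSeries  # dimensionless >= 0, peak ~ 1
    outbreak_years: frozenset[int]
    config: SyntheticSiteConfig = field(repr=False, default=None)

    def population_at(self, year: int) -> float:
        """Abundance at `year`; zero outside the simulated span."""
        if year < self.population.first_year or year > self.population.last_year:
            return 0.0
        return float(self.population.values[year - self.population.first_year])


@dataclass
class SedimentSim:
    """Sediment simulation output plus the realized annual flux (truth)."""

    record: ScaleRecord
    pb_profile: PbProfile
    flux: AnnualSeries  # realized scales cm^-2 yr^-1, after Poisson sampling


def simulate_population(config: SyntheticSiteConfig) -> SyntheticTruth:
    """Quasi-periodic outbreak forcing: rectified sinusoid + AR(1) noise.

    The rectification constant is chosen so that, without noise, the
    population sits at or above `outbreak_threshold` for exactly
    `outbreak_duration` (D) years out of each `outbreak_period` (P); the
    forcing peaks at 1 and is floored at 0.
    """
    years = np.arange(config.start_year, config.end_year + 1)
    p, d = config.outbreak_period, config.outbreak_duration
    theta = config.outbreak_threshold
    # sin >= c + theta*(1-c) must last D years: c = (cos(pi D/P) - theta)/(1-theta)
    c = (np.cos(np.pi * d / p) - theta) / (1.0 - theta)
    raw = np.sin(2.0 * np.pi * (years - config.start_year) / p)
    base = np.clip((raw - c) / (1.0 - c), 0.0, None)
    rng = config.rng(0)
    a, sd = config.ar1_coeff, config.noise_sd
    if sd > 0:
        innov_sd = sd * np.sqrt(1.0 - a * a)
        noise = np.empty(years.size)
        noise[0] = rng.normal(0.0, sd)
        eps = rng.normal(0.0, innov_sd, size=years.size)
        for i in range(1, years.size):
            noise[i] = a * noise[i - 1] + eps[i]
    else:
        noise = np.zeros(years.size)
    pop = np.clip(base + noise, 0.0, None)
    outbreak = frozenset(int(y) for y, v in zip(years, pop) if v >= config.outbreak_threshold)
    return SyntheticTruth(
        population=AnnualSeries(int(years[0]), pop, units="relative abundance",
                                site_id=config.site_id),
        outbreak_years=outbreak,
        config=config,
    )


def simulate_tree_rings(
    truth: SyntheticTruth, config: SyntheticSiteConfig
) -> list[TreeRingSeries]:
    """Ring widths: negexp age trend x lagged suppression x lognormal noise."""
    rng = config.rng(1)
    trees = []
    for i in range(config.n_trees):
        lag = int(rng.choice(config.response_lags))
        germination = config.start_year - int(rng.integers(30, 61))
        years = np.arange(germination, config.end_year + 1)
        age = years - germination
        w0 = rng.uniform(1.5, 3.0)  # juvenile width, mm
        floor = rng.uniform(0.3, 0.6)  # mature asymptote, mm
        tau = rng.uniform(60.0, 120.0)
        trend = (w0 - floor) * np.exp(-age / tau) + floor
        pop_lagged = np.array([truth.population_at(int(y) - lag) for y in years])
        suppression = 1.0 - config.suppression_depth * np.clip(pop_lagged, 0.0, 1.0)
        if config.noise_sd > 0:
            # mean-one lognormal noise
            noise = np.exp(rng.normal(0.0, config.noise_sd, size=years.size)
                           - 0.5 * config.noise_sd**2)
        else:
            noise = np.ones(years.size)
        trees.append(
            TreeRingSeries(
                tree_id=f"{config.site_id.upper()[:4]}{i + 1:03d}",
                first_year=int(years[0]),
                widths=trend * suppression * noise,
                site_id=config.site_id,
                species=config.species,
            )
        )
    return trees


def simulate_sediment(truth: SyntheticTruth, config: SyntheticSiteConfig) -> SedimentSim:
    """Scale deposition binned into subsamples plus a consistent ²¹⁰Pb profile.

    Annual scale counts are Poisson around area x (background + yield x
    population) and then split across subsamples by exact year overlap, so the
    total count in the record equals the sum of realized annual fluxes x area.
    The ²¹⁰Pb interval activities are constructed from the (jittered) boundary
    ages under constant ²¹⁰Pb flux, with the deepest interval absorbing the
    full residual inventory so that a CRS fit recovers the boundary ages.
    """
    cfg = config
    coring_year = cfg.end_year + 1  # core collected just after the last full year
    years = truth.population.years
    expected = cfg.sample_area_cm2 * (
        cfg.scale_background + cfg.scale_yield * np.clip(truth.population.values, 0.0, None)
    )
    rng = cfg.rng(2)
    annual_counts = (
        rng.poisson(expected).astype(float) if cfg.noise_sd > 0 else expected
    )
    flux = AnnualSeries(
        int(years[0]),
        annual_counts / cfg.sample_area_cm2,
        units="scales cm^-2 yr^-1",
        site_id=cfg.site_id,
    )

    # subsample boundaries in years-before-coring; deposition year y covers
    # ages [coring_year - y - 1, coring_year - y)
    total_span = float(coring_year - cfg.start_year)
    n_samp = int(np.ceil(total_span / cfg.sample_thickness_years))
    bounds = np.minimum(np.arange(n_samp + 1) * cfg.sample_thickness_years, total_span)

    jittered = bounds.copy()
    if cfg.dating_jitter_sd > 0:
        jittered[1:] += rng.normal(0.0, cfg.dating_jitter_sd, size=n_samp)
        jittered = np.maximum.accumulate(jittered)
        jittered[1:] = np.maximum(jittered[1:], jittered[:-1] + 0.1)

    # distribute annual counts over subsamples by overlap with true spans
    age_top = coring_year - (years + 1).astype(float)  # age of the young edge of year y
    counts = np.zeros(n_samp)
    for k in range(n_samp):
        lo, hi = bounds[k], bounds[k + 1]
        overlap = np.clip(np.minimum(age_top + 1.0, hi) - np.maximum(age_top, lo), 0.0, None)
        counts[k] = float(np.sum(overlap * annual_counts))
    depth_top = bounds[:-1] * cfg.sedimentation_cm_yr
    depth_bot = bounds[1:] * cfg.sedimentation_cm_yr
    record = ScaleRecord(
        top_depth=depth_top,
        bottom_depth=depth_bot,
        count=counts,
        area=np.full(n_samp, cfg.sample_area_cm2),
        site_id=cfg.site_id,
    )

    # Pb profile on the jittered age grid, extended to ~8 half-lives so the
    # unsupported inventory is essentially complete
    deep_ages = np.arange(
        jittered[-1] + cfg.sample_thickness_years, 180.0, cfg.sample_thickness_years
    )
    pb_ages = np.concatenate((jittered, deep_ages))
    c0 = cfg.pb_surface_activity / 1000.0  # Bq/g
    i0 = c0 * cfg.dry_mass_rate / PB210_LAMBDA  # Bq/cm^2 total unsupported inventory
    inv_at = i0 * np.exp(-PB210_LAMBDA * pb_ages)
    dm = cfg.dry_mass_rate * np.diff(pb_ages)
    act = (inv_at[:-1] - inv_at[1:]) / dm * 1000.0  # Bq/kg interval means
    act[-1] = inv_at[-2] / dm[-1] * 1000.0  # deepest interval holds the tail
    pb = PbProfile(
        top_depth=pb_ages[:-1] * cfg.sedimentation_cm_yr,
        bottom_depth=pb_ages[1:] * cfg.sedimentation_cm_yr,
        activity=act,
        cum_dry_mass=np.cumsum(dm),
    )
    return SedimentSim(record=record, pb_profile=pb, flux=flux)


def write_site(directory, config: SyntheticSiteConfig) -> dict:
    """Simulate one site and write RWL + CSV files and a truth sidecar.

    Returns a manifest dict (paths and metadata) suitable for the pipeline.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth = simulate_population(config)
    trees = simulate_tree_rings(truth, config)
    sed = simulate_sediment(truth, config)

    rwl = directory / f"{config.site_id}.rwl"
    scales_csv = directory / f"{config.site_id}_scales.csv"
    pb_csv = directory / f"{config.site_id}_pb210.csv"
    truth_json = directory / f"{config.site_id}_truth.json"

    write_rwl(rwl, trees, unit=0.001)
    sed.record.to_csv(scales_csv)
    sed.pb_profile.to_csv(pb_csv)
    truth_json.write_text(
        json.dumps(
            {
                "config": asdict(config),
                "population": {
                    "first_year": truth.population.first_year,
                    "values": truth.population.values.tolist(),
                },
                "outbreak_years": sorted(truth.outbreak_years),
                "annual_flux": {
                    "first_year": sed.flux.first_year,
                    "values": sed.flux.values.tolist(),
                },
            },
            indent=1,
        )
    )
    return {
        "site_id": config.site_id,
        "species": config.species,
        "rwl": str(rwl),
        "scales_csv": str(scales_csv),
        "pb_csv": str(pb_csv),
        "coring_year": config.end_year + 1,
        "truth_json": str(truth_json),
    }
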