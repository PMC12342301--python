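# budwormsync

Two-proxy reconstruction of eastern spruce budworm (*Choristoneura
fumiferana*) outbreaks, for paleoecologists and dendrochronologists who want
to compare **sedimentary lepidopteran scale accumulations** with **tree-ring
growth suppression** at the same site.

Adult budworm moths are covered in chitinous wing scales that settle into
lake sediments within the deposition year, so the scale count per cm² per
year tracks local adult-moth biomass. Host trees (white and black spruce)
record the same outbreaks indirectly: larval defoliation suppresses ring
growth with a 2–4 yr lag. This package builds both records and asks whether
— and with what phase relationship — they tell the same story.

## What it computes

**Tree-ring record.** Ring-width series (Tucson/RWL format) are detrended by
ratio against a cubic smoothing spline with a 50% frequency response at 60 yr,
averaged into a site chronology with Tukey's biweight robust mean, and
screened by EPS-guided chronology stripping. Reliability statistics:

    EPS = n·r̄ / (1 + (n−1)·r̄)        SSS = n_s(1 + (N−1)r̄) / N(1 + (n_s−1)r̄)

with r̄ the mean inter-series correlation. The tree-level growth suppression
index is the host/non-host corrected index

    GSI_i = H_i − (NH_i − NH_m)·(σ_H/σ_NH)

falling back to GSI_i = H_i when no non-host chronology exists. Defoliation
events are sustained runs (≥ 8 yr) of below-average standardized growth
reaching −1.28 sd, with bridging and series-end relaxations; "percent
affected" is the share of recording trees inside an event each year.

**Sediment record.** Subsamples are dated with the constant-rate-of-supply
²¹⁰Pb model, t(z) = λ⁻¹·ln(I₀/I(z)) with λ = ln 2 / 22.3 yr⁻¹, and scale
counts are spread onto calendar years by proportional-overlap weighting that
conserves the total count.

**Synchrony.** Annual series are GAM-smoothed (penalized cubic regression
spline, REML), then compared with Morlet continuous, cross (XWT) and
coherence (WTC) wavelet transforms — χ² test against an AR(1) red-noise
background for CWT/XWT, 1000 Monte Carlo AR(1) surrogate pairs for the WTC
level. Phases pooled from significant zones (inside the cone of influence)
give a circular mean/SD per outbreak window (O1 1975–1992, O2 1946–1959,
O3 1912–1929, All 1900–2019), collapsed to Agreement/Disagreement calls:
scales vs. GSI agree when **anti-phase** (more moths, less growth); scales
vs. percent affected agree when **in-phase**.

A synthetic-data module generates coupled site datasets (tree rings, scale
record, ²¹⁰Pb profile) from a known quasi-periodic outbreak forcing, so the
whole pipeline is testable against ground truth.

## Worked example

```python
import tempfile
from budwormsync import synthetic, pipeline

cfg = synthetic.SyntheticSiteConfig(site_id="demo", seed=1)   # 25 trees, 1900-2019
with tempfile.TemporaryDirectory() as d:
    manifest = synthetic.write_site(d, cfg)
    res = pipeline.run_site(pipeline.SiteManifest.from_dict(manifest),
                            seed=1, n_mc=1000)

c = res.chronology
print(f"chronology: n={len(c.tree_ids)} rbar={c.rbar:.3f} EPS={c.eps:.3f}")
for call in res.calls:
    if call.window == "All":
        print(call.analysis, call.comparison, call.call,
              f"mean phase {call.mean_phase:+.2f} rad")
```

prints

```
chronology: n=25 rbar=0.560 EPS=0.970
cross-wavelet scales~GSI     A  mean phase -2.26 rad
coherence     scales~GSI     A  mean phase -2.44 rad
cross-wavelet scales~pctAff  A  mean phase +0.96 rad
coherence     scales~pctAff  A  mean phase +0.76 rad
```

The EPS of 0.97 (25 trees, r̄ = 0.56) marks a well-replicated chronology.
Both analyses classify scales~GSI as Agreement with a mean phase in the
anti-phase hemisphere (≈ ±π offset by the 2–4 yr response lag), and
scales~pctAff as Agreement in the in-phase hemisphere — exactly the coupling
the generator built in.

The same run is available from a shell:

```sh
budwormsync simulate --out site/ --site-id demo --seed 1
budwormsync run-all --config config.yaml --out report.json
```

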