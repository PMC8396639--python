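# voltipy

Voltinism inference from opportunistic citizen-science butterfly records.

Many butterflies are shifting from one generation per year (univoltine) to
two (bivoltine) as climates warm. Detecting that shift from mass
citizen-science portals is not straightforward: the records carry no
explicit search effort, observers differ wildly in activity, and the
tell-tale signal — a third autumn flight peak — could equally be worn adults
re-appearing after a summer rest. `voltipy` implements an analysis chain
that settles the question from four independent angles, with the peacock
butterfly (*Aglais io*) as the motivating case:

1. **Effort-corrected abundance phenology.** Search effort is proxied by
   *proven day-grid-visits*: one observer reporting ≥1 record (any taxon,
   absences included) from one 100 m grid cell on one day, restricted to
   proficient observers (≥50 butterfly records of ≥10 species per year).
   The daily index is *n*ₐ/*V* (target adults per day-grid-visit); the
   weekly index averages the three best days of each ISO week to damp
   weather-driven detectability swings.
2. **Flight-peak segmentation.** Each year's weekly series is split into
   spring / first / second generation windows (smoothed local maxima,
   valley-split boundaries). A generation's size is its *performance
   index*: the sum of weekly indices over its window (area under the
   flight curve). A year is classified univoltine (<15% third-peak share),
   partially bivoltine (15–25%) or bivoltine (>25%).
3. **Wing wear and reproduction phenology.** Weekly proportions of four
   ordinal wear classes (immaculate → heavily worn) reveal waves of fresh
   emergences; egg/caterpillar records cluster in two lagged cycles whose
   median dates sit ~10 weeks apart.
4. **Between-year regression.** OLS fits of next-spring abundance on the
   two prior generations, spring(*t*+1) ~ gen1(*t*) + gen2(*t*), identify
   which generation stocks the overwintering population.

A synthetic observation-process generator (`voltipy.simulate`) produces
portal-style records with known latent structure — Gaussian-mixture flight
curves, Poisson detection under weather suppression, proficient/casual
observer mixes, exponential wear aging, lagged reproduction — so every
estimate above can be tested as a ground-truth recovery problem.

## Worked example

```python
import voltipy as v

cfg = v.SyntheticConfig(years=tuple(range(2009, 2021)), seed=2)
sim = v.simulate(cfg)                      # portal-style RecordSet + truth
model = v.VoltinismAnalysis(sim.records, cfg.target_taxon, cfg.butterfly_taxa)
res = model.fit()
print(res.summary())
```

```
Voltinism analysis summary
==========================
Target taxon:       Aglais io
Years analysed:     12

Mean generation AUC index (area under weekly curve):
  spring      5.346
  gen1       11.027
  gen2       10.981
  gen1 vs spring: +106.3%   gen2 vs gen1:   -0.4%

Per-year third-peak proportion and regime:
  2009  p=0.418  bivoltine
  ...
  2020  p=0.280  bivoltine

Next-spring coupling (OLS):
  simple_gen2  R²=0.950  p=3.595e-07  n=11
  simple_gen1  R²=0.034  p=0.5877  n=11
  multiple     R²=0.952  p=5.49e-06  n=11

Mean gap between caterpillar-peak medians: 70.2 days (n=12 years)
```

Every simulated year is classified bivoltine (third-peak share 0.28–0.58,
all above the 25% threshold); next-spring abundance is explained almost
entirely by the previous autumn generation (R² = 0.95) and essentially not
at all by the early-summer one (R² = 0.03) — the generator couples spring
to the autumn generation through winter survival, and the regression stage
recovers exactly that structure. The two caterpillar cohorts sit 70 days
apart, matching the configured 10-week spacing of the reproduction cycles.

The same pipeline is available from a shell:

```bash
voltipy run --seed 2 --out out/        # simulate + full analysis + report
voltipy simulate --seed 2 --out data/  # stage-by-stage instead:
voltipy index --obs data/observations.csv --taxa-config data/taxa.yaml --out weekly.csv
voltipy phenology --weekly weekly.csv --out-generations gen.csv --out-voltinism volt.csv
voltipy regress --generations gen.csv --out regression.json
voltipy report out/
```

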