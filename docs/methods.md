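# Methods

This note documents the models and procedures implemented in `voltipy`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Effort correction

Opportunistic portal records confound abundance with search effort. The
package's effort unit is the *proven day-grid-visit*: one observer having
reported at least one record — of any taxon, absence records included —
from one hectare (100 m × 100 m) grid cell on one day. Grid cells are
opaque identifiers; only distinct-cell counts matter, so no geodesy is
implemented.

Only *proficient* observers contribute to effort and, by default, to the
abundance numerator: observers with at least `min_records = 50` butterfly
records of at least `min_species = 10` butterfly species in a given
calendar year. The filter is applied per year — an observer can qualify in
some years only. Absence records of butterfly taxa count toward the record
threshold, since they document search activity as directly as presences.

Two points the effort definition leaves open are both configurable:

* **Cell counting across observers.** The default counts distinct cells
  *per observer* and sums over observers (two observers in the same cell
  on the same day contribute 2 visits), reading the effort sum as a
  per-observer quantity; `union_cells=True` switches to the per-day union.
* **Numerator restriction.** By default only selected observers' target
  records enter the daily index, mirroring the denominators; the
  unrestricted variant is available.

The daily abundance index is (target adults reported) / (day-grid-visits),
*undefined* — not zero — on days with zero effort. The numerator sums the
`count` fields (individuals), not record rows. Weekly indices average the
three highest defined daily indices per ISO week, because day-to-day
weather swings detectability far more than true abundance; weeks with only
one or two defined days use what is available and flag `n_days_used`.
Same-day repeat counts by one observer in one cell are summed, not maxed.
ISO week 53 is folded into week 52 everywhere.

## Flight-peak segmentation and voltinism

The weekly series of a year is smoothed with a centred 3-week moving
average; local maxima with prominence ≥10% of the annual maximum are peak
candidates (the three highest are kept when more are found). Boundaries
between consecutive peaks are the minimum-index week of the raw series
between them; the valley week belongs to the earlier generation, ties go
to the earlier week. When fewer than three maxima separate, fixed fallback
windows (weeks 9–24, 25–33, 34–48) are used and recorded in the output.
Years with fewer than 20 defined weeks are refused. These settings are the
package's own — flight peaks in the source data are an empirical
observation, not a formal model — and all are configurable
(`SegmentationOptions`).

A generation's performance index is the sum of weekly indices across its
window (undefined weeks contribute 0 and are tallied); `peak_week` is the
argmax with ties to the earliest week. The third peak's share *p* of the
annual total classifies the year: univoltine (*p* < 0.15), partial
bivoltinism (0.15 ≤ *p* ≤ 0.25), bivoltine (*p* > 0.25). For historical
data predating effort-corrected indices, the same thresholds are applied
to raw record shares per window, with years under 30 records flagged
insufficient.

## Wing wear

Photo-scored adults carry an ordinal wear class 1–4 (immaculate, slightly,
moderately, heavily worn). Weekly class counts are pooled across years;
the sparse season tails (weeks <10 and >44) are lumped into bins 8 and 46,
conserving totals. *Wear progression* summarises aging speed as the OLS
slope of the weekly mean wear score (classes as 1–4 integers) against
week — a package-defined diagnostic chosen for its simplicity; because
class 4 is a ceiling, the slope is informative only across the rising part
of a cohort's window, and the recommended comparison windows start just
before each generation's peak.

The photo-representativeness diagnostic reports weekly
photos-per-reported-individual rates and the photographed class mix, plus
a chi-square test of homogeneous photo propensity across classes for the
simulation setting where per-class availability is known exactly.

## Reproduction timing

Immature-stage phenology counts *records* (each record weight 1 regardless
of its count field), since opportunistic reporting of clutch or brood
sizes is far noisier than the fact of a record. Caterpillar records of a
year are split at the minimum-count week inside a valley-search window
(default weeks 28–32); the per-peak median record date uses the lower
median for even counts (ties resolve to the earlier date). The per-year
gap is the difference between the two medians in days, and the cross-year
mean is unweighted — years with many records do not dominate. The shift of
the second reproduction period is the OLS slope of its median week against
year (negative = earlier). Eggs after week 36 and caterpillars from week
40 (October) onward are tallied as indications of third-cycle attempts.
Pupae are only counted; they are far too rare to peak-detect.

## Next-spring regression

Generation AUC indices are aligned into a lag-1 table (complete
consecutive-year pairs only; ≥4 required). Ordinary least squares is fit
for the multiple model spring(*t*+1) ~ gen1(*t*) + gen2(*t*), the two
simple one-predictor models, and the within-year pairs
gen1(*t*) ~ spring(*t*) and gen2(*t*) ~ gen1(*t*). Per-fit R² and p-values
are reported (slope t-tests for simple fits, the F-test for the multiple
fit) — the simple fits are reported alongside the multiple model because
per-generation R² can be read either way. With ~11 pairs no
autocorrelation correction is applied. Fits are delegated to statsmodels
OLS; a predictor with zero variance is flagged `degenerate`, and condition
numbers above 10⁸ are warned about but still reported.

## The synthetic observation process

The generator defines the study conditions for every recovery test. Its
defaults, chosen once:

* **Flight curve**: Gaussian mixture on week number with peaks at weeks
  16, 27 and 37 (spring, early summer, autumn; the last 8–10 weeks after
  the second), common sd 2.0 weeks, amplitudes 1 : 1.83 : 2.25 in units of
  expected detectable adults per day-grid-visit at peak. Equal widths make
  the amplitude ratios equal the AUC ratios, so the generation-size
  contrasts (+83%, +23%) are exactly encoded. Amplitude 0 and 1–3
  generations are allowed; per-year amplitude overrides pin exact
  proportions for recovery tests.
* **Between-year structure**: gen1 and gen2 amplitudes vary log-normally
  (sd 0.35) and independently — within-year couplings are deliberately
  weak, matching the observation that generations within a year connect
  through a long chain of life-cycle risks. Next year's spring AUC equals
  `winter_survival` × this year's gen2 AUC × (1 + ε), ε ~ N(0, 0.10):
  only winter mortality separates the autumn generation from next spring.
  The default survival 1/2.25 ≈ 0.44 keeps expected within-year ratios at
  1 : 1.83 : 2.25 while encoding the coupling the regression stage is
  meant to find. The 0.35 and 0.10 dispersions are free parameters (no
  source quantifies them); 0.35 gives year-to-year third-vs-second-peak
  ratios spanning roughly 45–330%, comparable to reported spreads.
* **Observers**: 25 observers, 80% proficient (5 outings/week, ~5 cells
  per outing — ≈500 proficient day-grid-visits per week, the scale used in
  the recovery criteria), 20% casual (1.5 outings/week, small species
  repertoire) so the proficiency filter has something to reject. Bycatch
  of 16 butterfly and 4 non-butterfly taxa exercises the filter and the
  any-taxon effort rule. Every visited (observer, day, cell) emits at
  least one record — detection, absence (p = 0.15 on empty visits) or
  bycatch — so effort is exactly reconstructible; this is a deliberate
  idealisation (real observers do not report from every visited cell).
* **Detection**: Poisson per day-grid-visit with mean = latent abundance ×
  weather factor; each day is independently "bad" with p = 0.3, multiplying
  means by 0.2. This is what makes the three-best-days rule matter.
  Observer skill does not affect detection, only visit counts.
* **Wing wear**: individuals emerge in their generation's Gaussian wave
  and age through classes 1→2→3→4 with exponential (memoryless) residence
  times — no wear kinetics are documented anywhere, so the simplest
  process is used. Defaults: 6 days per class in spring, 12 in summer, 18
  in autumn (wear fastest in spring); the default preset enforces that
  ordering. Overwintered spring adults re-appear in a mixed condition
  (class probabilities 0.4/0.3/0.2/0.1); new generations emerge
  immaculate. Photos are taken at an age uniform over a 28-day adult
  lifespan, with optional per-class photo propensities and label
  confusion (both off by default). ~400 photos/year, split by generation
  share.
* **Reproduction**: egg records lag the adult peaks by 2 weeks,
  caterpillars by 7 weeks (spring cycle) and 6 weeks (summer cycle) — the
  longer spring lag reflects slower development in cooler weather and
  places the caterpillar-peak medians 10 weeks (70 days) apart. ~6 egg,
  ~240 caterpillar and ~5 pupa records/year, 10% fewer in the second
  cycle; a trickle of week-37+ eggs and October caterpillars emulates
  third-cycle attempts. An optional second-cycle timing drift (weeks/year)
  supports trend-recovery tests. Records attach to scheduled visits so
  effort stays conserved.

What the generator does *not* emulate: spatial autocorrelation, migration
or altitudinal movement, observer-specific detection skill, fuzzy
duplicate submissions, and reporting rates that vary with abundance
itself. Passing recovery tests therefore show that the estimators invert
the assumed observation process correctly — not that real portal data obey
that process.

## Numerical and interface choices

* CSV throughout: comma-separated, UTF-8, ISO-8601 dates, missing values
  as empty cells; reals written with 12 significant digits; rejected input
  rows are returned with reasons, never silently dropped, and
  accepted + rejected always equals rows read.
* Deduplication is exact-row only.
* Determinism: a fixed `(config, seed)` yields byte-identical outputs; the
  seed is split into independent streams for latents, visit schedules,
  detections and wear.
* Problem sizes in the test suite and acceptance script (one- to
  twenty-year simulations, ~500 proficient visits/week, 10-seed
  replicates) were chosen as the smallest scales at which the recovery
  tolerances are comfortably meaningful.
* The pipeline facade (`VoltinismAnalysis.fit()` →
  `VoltinismResults.summary()`) skips years the segmentation refuses and
  reports them; the regression stage is omitted (not failed) when fewer
  than 4 consecutive-year pairs survive.

## Known limitations

* The segmentation is a heuristic; with heavily overlapping peaks the
  valley-split windows bias adjacent generation AUCs toward each other by
  a few percent (visible in the recovery tests' tolerance).
* Wear-progression slopes saturate at class 4; comparisons are only valid
  over matched, pre-saturation windows.
* The proficiency filter uses calendar years while the weekly index uses
  ISO years; records in the few boundary days around New Year can fall
  under different year labels in the two stages.
* Historical raw-record shares and index-based shares are compared on the
  same thresholds, but the two bases are not strictly commensurable; the
  `basis` field keeps them distinguishable.
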