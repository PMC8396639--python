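"""Synthetic portal-style record generator with known latent structure.

Every downstream stage of the analysis (effort correction, flight-peak
segmentation, wear phenology, reproduction timing, spring-coupling
regression) estimates something. This module generates observation records
whose ground truth is known exactly, so each stage can be tested as a
recovery problem.

The data-generating model, briefly:

* **Flight curve** — a Gaussian mixture on ISO week number, one component
  per generation (defaults: spring ≈ week 16, first new generation ≈ week
  27, second new generation ≈ week 37, 8-10 weeks later). Per-year
  multipliers vary the new generations log-normally; next year's spring
  amplitude is coupled to this year's autumn (gen2) AUC through a winter
  survival factor — the latent structure the regression stage is meant to
  detect.
* **Observation process** — observers plan weekly outings covering several
  hectare cells; every visited (observer, day, cell) leaves at least one
  record, so search effort can be reconstructed from the records alone.
  Detected adults per day-grid-visit are Poisson with mean proportional to
  the latent abundance; independently "bad weather" days suppress the mean,
  which is what motivates the three-best-days weekly index. A mix of
  proficient and casual observers straddles the proficiency filter; bycatch
  of other butterfly and non-butterfly taxa exercises it.
* **Wing wear** — simulated adults age through the four wear classes with
  exponential (memoryless) residence times whose means differ by season:
  wear accumulates fastest in spring, slower in summer, slowest in autumn.
  Overwintered spring adults re-appear in a mix of conditions; new
  generations emerge immaculate.
* **Reproduction** — egg and caterpillar records cluster around the adult
  flight peaks with configurable lags; the caterpillar peaks of the two
  cycles sit ~10 weeks apart by default. Pupae are rare. A trickle of
  late-season eggs/caterpillars emulates occasional third-cycle attempts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .records import OBS_COLUMNS, RecordSet, WEAR_COLUMNS
from .phenology import classify_voltinism
from .weeks import N_WEEKS, week_start

SQRT_2PI = math.sqrt(2.0 * math.pi)
SEASONS = ("spring", "summer", "autumn")
GEN_NAMES = ("spring", "gen1", "gen2")


# --------------------------------------------------------------------------
# configuration dataclasses

@dataclass(frozen=True)
class GenerationPeak:
    mean_week: float
    sd_weeks: float
    amplitude: float  # expected detectable adults per day-grid-visit at peak


@dataclass
class SeasonModel:
    """Gaussian-mixture flight curve, one component per generation."""

    peaks: tuple[GenerationPeak, ...] = (
        GenerationPeak(16.0, 2.0, 1.0),
        GenerationPeak(27.0, 2.0, 1.83),
        GenerationPeak(37.0, 2.0, 2.25),
    )

    def __post_init__(self) -> None:
        n = len(self.peaks)
        if n not in (1, 2, 3):
            raise ConfigError(f"n_generations must be 1, 2 or 3, got {n}")
        means = [p.mean_week for p in self.peaks]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ConfigError("generation mean weeks must be strictly increasing")
        for p in self.peaks:
            if p.sd_weeks <= 0 or p.amplitude < 0:
                raise ConfigError("sd_weeks must be > 0 and amplitude >= 0")

    @property
    def n_generations(self) -> int:
        return len(self.peaks)


@dataclass
class ObserverModel:
    """Who goes out, how often, and how much trace they leave."""

    n_observers: int = 25
    proficient_fraction: float = 0.8
    outings_per_week: float = 5.0          # proficient observers
    cells_per_outing: float = 5.0          # mean cells covered per outing
    casual_outings_per_week: float = 1.5
    casual_cells_per_outing: float = 2.0
    n_cells: int = 400                     # size of the shared cell pool
    bad_day_prob: float = 0.3              # weather suppression
    bad_day_factor: float = 0.2
    absence_prob: float = 0.15             # chance a zero-detection visit logs an absence
    bycatch_rate: float = 1.0              # mean non-target records per visit
    n_butterfly_bycatch: int = 16          # butterfly species known to proficients
    n_other_taxa: int = 4
    casual_pool_species: int = 4           # butterflies known to casual observers

    def __post_init__(self) -> None:
        if not (0.0 <= self.proficient_fraction <= 1.0):
            raise ConfigError("proficient_fraction must be in [0, 1]")
        for name in ("outings_per_week", "cells_per_outing",
                     "casual_outings_per_week", "casual_cells_per_outing",
                     "bycatch_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class WearModel:
    """Exponential aging through wear classes 1 -> 2 -> 3 -> 4.

    ``residence_days[season]`` are the mean residence times in classes 1-3;
    class 4 is absorbing. With ``enforce_season_ordering`` (the default,
    seasonally ordered preset) spring wear must be at least as fast as
    summer, summer at least as fast as autumn.
    """

    residence_days: dict = field(default_factory=lambda: {
        "spring": (6.0, 6.0, 6.0),
        "summer": (12.0, 12.0, 12.0),
        "autumn": (18.0, 18.0, 18.0),
    })
    photos_per_year: float = 400.0
    adult_lifespan_days: float = 28.0      # photo age ~ Uniform(0, lifespan)
    photo_propensity: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    spring_initial_class_probs: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    label_confusion: float = 0.0           # chance a label shifts one class
    enforce_season_ordering: bool = True

    def __post_init__(self) -> None:
        for season in SEASONS:
            if season not in self.residence_days:
                raise ConfigError(f"residence_days missing season '{season}'")
            if any(t <= 0 for t in self.residence_days[season]):
                raise ConfigError("residence times must be positive")
        if self.enforce_season_ordering:
            sp, su, au = (np.asarray(self.residence_days[s]) for s in SEASONS)
            if not (np.all(sp <= su) and np.all(su <= au)):
                raise ConfigError(
                    "seasonally ordered preset needs wear rates spring >= summer >= autumn "
                    "(residence times spring <= summer <= autumn)")


@dataclass
class ReproductionModel:
    """Lagged reproduction records around the first two adult peaks."""

    egg_lag_weeks: tuple[float, float] = (2.0, 2.0)
    cat_lag_weeks: tuple[float, float] = (7.0, 6.0)
    egg_disp_weeks: tuple[float, float] = (1.2, 1.5)
    cat_disp_weeks: tuple[float, float] = (1.5, 2.0)
    eggs_per_year: float = 6.0
    caterpillars_per_year: float = 240.0
    pupae_per_year: float = 5.0
    second_cycle_fraction: float = 0.474   # ~10% fewer records in cycle 2
    third_cycle_egg_rate: float = 0.5      # stray eggs ~ week 37-38
    late_caterpillar_rate: float = 2.75    # caterpillars from October on
    timing_drift_weeks_per_year: float = 0.0  # second-cycle shift (negative = earlier)

    def __post_init__(self) -> None:
        for e, c in zip(self.egg_lag_weeks, self.cat_lag_weeks):
            if e <= 0 or c <= 0:
                raise ConfigError("reproduction lags must be positive")
            if c <= e:
                raise ConfigError("caterpillar lag must exceed egg lag")


@dataclass
class SyntheticConfig:
    """Full generator configuration. Fixed seed -> byte-identical output."""

    season: SeasonModel = field(default_factory=SeasonModel)
    observers: ObserverModel = field(default_factory=ObserverModel)
    wear: WearModel = field(default_factory=WearModel)
    reproduction: ReproductionModel = field(default_factory=ReproductionModel)
    years: tuple[int, ...] = tuple(range(2009, 2021))
    seed: int = 0
    year_sd: float = 0.35            # lognormal sd of gen1/gen2 year multipliers
    winter_survival: float = 1.0 / 2.25  # spring AUC(t+1) = ws * gen2 AUC(t) * (1+eps)
    winter_noise_sd: float = 0.10
    amplitude_overrides: dict | None = None  # year -> per-generation amplitudes
    target_taxon: str = "Aglais io"

    @property
    def butterfly_taxa(self) -> list[str]:
        n = self.observers.n_butterfly_bycatch
        return [self.target_taxon] + [f"butterfly_{i + 1:02d}" for i in range(n)]


def config_to_yaml(config: SyntheticConfig, path) -> None:
    d = asdict(config)
    d["season"]["peaks"] = [list(asdict(p).values()) for p in config.season.peaks]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> SyntheticConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    known = {"season", "observers", "wear", "reproduction", "years", "seed",
             "year_sd", "winter_survival", "winter_noise_sd",
             "amplitude_overrides", "target_taxon"}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(d)
    if "season" in d:
        peaks = tuple(GenerationPeak(*p) for p in d["season"]["peaks"])
        kwargs["season"] = SeasonModel(peaks=peaks)
    for key, cls in (("observers", ObserverModel), ("wear", WearModel),
                     ("reproduction", ReproductionModel)):
        if key in d:
            sub = dict(d[key])
            for name, val in sub.items():
                if isinstance(val, list):
                    sub[name] = tuple(val)
                if isinstance(val, dict):
                    sub[name] = {k: tuple(v) for k, v in val.items()}
            kwargs[key] = cls(**sub)
    if "years" in d:
        kwargs["years"] = tuple(d["years"])
    return SyntheticConfig(**kwargs)


# --------------------------------------------------------------------------
# latent layer

def _rngs(config: SyntheticConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


def year_amplitudes(config: SyntheticConfig) -> pd.DataFrame:
    """Per-year true peak amplitudes (columns amp_spring, amp_gen1, amp_gen2).

    Generations absent from the SeasonModel get amplitude 0. The first
    listed year uses the base spring amplitude; later years couple spring to
    the previous year's gen2 AUC via ``winter_survival`` (years are treated
    as consecutive seasons).
    """
    rng = _rngs(config)[0]
    peaks = config.season.peaks
    n_gen = len(peaks)
    rows = []
    prev_gen2_auc = None
    for year in config.years:
        over = (config.amplitude_overrides or {}).get(year)
        if over is not None:
            amps = list(over) + [0.0] * (3 - len(over))
        else:
            amps = [0.0, 0.0, 0.0]
            # spring: coupled to last year's autumn generation where possible
            if prev_gen2_auc is not None and n_gen == 3:
                noise = 1.0 + rng.normal(0.0, config.winter_noise_sd)
                auc = max(config.winter_survival * prev_gen2_auc * noise, 1e-9)
                amps[0] = auc / (peaks[0].sd_weeks * SQRT_2PI)
            else:
                amps[0] = peaks[0].amplitude * rng.lognormal(0.0, config.year_sd)
            for g in range(1, n_gen):
                amps[g] = peaks[g].amplitude * rng.lognormal(0.0, config.year_sd)
        rows.append({"year": year, "amp_spring": amps[0],
                     "amp_gen1": amps[1], "amp_gen2": amps[2]})
        if n_gen == 3:
            prev_gen2_auc = rows[-1]["amp_gen2"] * peaks[2].sd_weeks * SQRT_2PI
    return pd.DataFrame(rows)


def simulate_latent_abundance(config: SyntheticConfig) -> pd.DataFrame:
    """True relative abundance per (year, week) and generation.

    ``abundance_<gen>`` columns give each Gaussian component evaluated on the
    week grid; ``total`` is their sum (the expected detectable adults per
    day-grid-visit on a good-weather day).
    """
    amps = year_amplitudes(config)
    weeks = np.arange(1, N_WEEKS + 1, dtype=float)
    frames = []
    for row in amps.itertuples(index=False):
        data = {"year": row.year, "week": weeks.astype(int)}
        total = np.zeros_like(weeks)
        for g, gen in enumerate(GEN_NAMES):
            if g < len(config.season.peaks):
                p = config.season.peaks[g]
                amp = getattr(row, f"amp_{gen}")
                comp = amp * np.exp(-((weeks - p.mean_week) ** 2) / (2 * p.sd_weeks ** 2))
            else:
                comp = np.zeros_like(weeks)
            data[f"abundance_{gen}"] = comp
            total += comp
        data["total"] = total
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def truth_report(config: SyntheticConfig) -> pd.DataFrame:
    """Ground truth per year: generation AUCs, third-peak proportion, regime."""
    amps = year_amplitudes(config)
    peaks = config.season.peaks
    rows = []
    for row in amps.itertuples(index=False):
        aucs = []
        for g, gen in enumerate(GEN_NAMES):
            if g < len(peaks):
                aucs.append(getattr(row, f"amp_{gen}") * peaks[g].sd_weeks * SQRT_2PI)
            else:
                aucs.append(0.0)
        total = sum(aucs)
        p = aucs[2] / total if total > 0 else 0.0
        rows.append({"year": row.year,
                     "auc_spring": aucs[0], "auc_gen1": aucs[1], "auc_gen2": aucs[2],
                     "proportion_third_peak": p, "regime": classify_voltinism(p),
                     "winter_survival": config.winter_survival})
    return pd.DataFrame(rows)


def truth_generation_table(config: SyntheticConfig) -> pd.DataFrame:
    """Lag-1 spring-coupling table built from the latent truth (no observation noise)."""
    t = truth_report(config).set_index("year")
    out = pd.DataFrame({
        "year": t.index,
        "spring": t["auc_spring"].to_numpy(),
        "gen1": t["auc_gen1"].to_numpy(),
        "gen2": t["auc_gen2"].to_numpy(),
        "spring_next": t["auc_spring"].reindex(t.index + 1).to_numpy(),
    })
    return out.dropna().reset_index(drop=True)


# --------------------------------------------------------------------------
# wear aging (shared with the representativeness power tests)

def age_wear_cohort(
    ages_days: np.ndarray,
    residence_days: tuple[float, float, float],
    rng: np.random.Generator,
    initial_classes: np.ndarray | None = None,
) -> np.ndarray:
    """Wear class of each individual after aging for ``ages_days``.

    Individuals start in ``initial_classes`` (default all 1) and advance
    through classes with independent exponential residence times; class 4 is
    absorbing.
    """
    n = len(ages_days)
    if initial_classes is None:
        initial_classes = np.ones(n, dtype=int)
    res = np.column_stack([rng.exponential(m, size=n) for m in residence_days])
    classes = initial_classes.copy()
    for start in (1, 2, 3):
        mask = initial_classes == start
        if not mask.any():
            continue
        # time to leave each remaining class, cumulative from the start class
        cum = np.cumsum(res[mask][:, start - 1:], axis=1)
        classes[mask] = start + (ages_days[mask, None] >= cum).sum(axis=1)
    return np.minimum(classes, 4)


def simulate_photo_sample(
    n_individuals: int,
    residence_days: tuple[float, float, float],
    photo_propensity: tuple[float, float, float, float],
    rng: np.random.Generator,
    adult_lifespan_days: float = 28.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(available_by_class, photographed_by_class) for one simulated cohort.

    Used to study the photo-representativeness chi-square test where the
    true per-class photo propensities are known.
    """
    ages = rng.uniform(0.0, adult_lifespan_days, size=n_individuals)
    classes = age_wear_cohort(ages, residence_days, rng)
    avail = np.bincount(classes, minlength=5)[1:]
    prop = np.asarray(photo_propensity, dtype=float)
    keep = rng.random(n_individuals) < prop[classes - 1] / prop.max()
    photo = np.bincount(classes[keep], minlength=5)[1:]
    return avail, photo


# --------------------------------------------------------------------------
# observation process

@dataclass
class SimulationOutput:
    """Records plus the internals needed for ground-truth recovery tests."""

    records: RecordSet
    visits: pd.DataFrame        # deduplicated (observer, date, cell) schedule
    truth: pd.DataFrame         # per-year latent truth
    wear_truth: pd.DataFrame    # per (year, season): class availability vs photos


def _visit_schedule(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    om = config.observers
    if om.n_observers == 0:
        import logging
        logging.getLogger(__name__).warning("simulate: zero observers configured")
        return pd.DataFrame(columns=["observer_id", "proficient", "year", "week",
                                     "date", "grid_cell"])
    n_prof = int(round(om.n_observers * om.proficient_fraction))
    observer_ids = np.array([f"obs_{i:03d}" for i in range(om.n_observers)])
    proficient = np.arange(om.n_observers) < n_prof

    frames = []
    for year in config.years:
        monday_w1 = np.datetime64(week_start(year, 1))
        for prof in (True, False):
            ids = observer_ids[proficient == prof]
            if not len(ids):
                continue
            rate = om.outings_per_week if prof else om.casual_outings_per_week
            cmean = om.cells_per_outing if prof else om.casual_cells_per_outing
            n_out = rng.poisson(rate, size=(len(ids), N_WEEKS))
            total = int(n_out.sum())
            if total == 0:
                continue
            obs_idx = np.repeat(np.repeat(np.arange(len(ids)), N_WEEKS), n_out.ravel())
            week = np.repeat(np.tile(np.arange(1, N_WEEKS + 1), len(ids)), n_out.ravel())
            day = rng.integers(0, 7, size=total)
            n_cells = 1 + rng.poisson(max(cmean - 1.0, 0.0), size=total)
            rows = int(n_cells.sum())
            cell = rng.integers(0, om.n_cells, size=rows)
            frames.append(pd.DataFrame({
                "observer_id": np.repeat(ids[obs_idx], n_cells),
                "proficient": prof,
                "year": year,
                "week": np.repeat(week, n_cells),
                "date": monday_w1 + np.repeat((week - 1) * 7 + day, n_cells)
                .astype("timedelta64[D]"),
                "grid_cell": np.char.add("cell_", np.char.zfill(
                    cell.astype(str), 4)),
            }))
    if not frames:
        return pd.DataFrame(columns=["observer_id", "proficient", "year", "week",
                                     "date", "grid_cell"])
    visits = pd.concat(frames, ignore_index=True)
    visits["date"] = pd.to_datetime(visits["date"])
    visits = visits.drop_duplicates(subset=["observer_id", "date", "grid_cell"],
                                    ignore_index=True)
    return visits.sort_values(["date", "observer_id", "grid_cell"],
                              ignore_index=True)


def _bycatch_taxa(pool_idx: np.ndarray, proficient: np.ndarray,
                  om: ObserverModel) -> np.ndarray:
    """Map per-record pool indices to taxon names given observer proficiency."""
    n_bf = om.n_butterfly_bycatch
    taxa = np.empty(len(pool_idx), dtype=object)
    is_bf = proficient & (pool_idx < n_bf) | (~proficient)
    bf_idx = np.where(proficient, pool_idx, pool_idx % max(om.casual_pool_species, 1))
    taxa[is_bf] = np.char.add("butterfly_",
                              np.char.zfill((bf_idx[is_bf] + 1).astype(str), 2))
    other = ~is_bf
    taxa[other] = np.char.add("other_",
                              np.char.zfill((pool_idx[other] - n_bf + 1).astype(str), 2))
    return taxa


def simulate(config: SyntheticConfig) -> SimulationOutput:
    """Run the full observation-process simulation."""
    rng_latent, rng_visits, rng_rec, rng_wear = _rngs(config)

    latent = simulate_latent_abundance(config)
    truth = truth_report(config)
    abundance = latent.set_index(["year", "week"])["total"]

    visits = _visit_schedule(config, rng_visits)
    om = config.observers
    obs_frames = []

    if len(visits):
        # weather: each calendar day independently bad
        dates = pd.Series(sorted(visits["date"].unique()))
        bad = rng_rec.random(len(dates)) < om.bad_day_prob
        factor = pd.Series(np.where(bad, om.bad_day_factor, 1.0), index=dates)

        lam = (abundance.reindex(
            pd.MultiIndex.from_frame(visits[["year", "week"]])).to_numpy()
            * factor.reindex(visits["date"]).to_numpy())
        counts = rng_rec.poisson(lam)
        absent = (counts == 0) & (rng_rec.random(len(visits)) < om.absence_prob)
        bycatch = rng_rec.poisson(om.bycatch_rate, size=len(visits))
        forced = (counts == 0) & ~absent & (bycatch == 0)
        bycatch[forced] = 1

        present = counts > 0
        obs_frames.append(pd.DataFrame({
            "observer_id": visits.loc[present, "observer_id"],
            "date": visits.loc[present, "date"],
            "grid_cell": visits.loc[present, "grid_cell"],
            "taxon": config.target_taxon, "life_stage": "adult",
            "count": counts[present], "is_absence": False}))
        obs_frames.append(pd.DataFrame({
            "observer_id": visits.loc[absent, "observer_id"],
            "date": visits.loc[absent, "date"],
            "grid_cell": visits.loc[absent, "grid_cell"],
            "taxon": config.target_taxon, "life_stage": "adult",
            "count": 0, "is_absence": True}))

        rep = visits.loc[np.repeat(visits.index.to_numpy(), bycatch)]
        pool_size = np.where(rep["proficient"], om.n_butterfly_bycatch + om.n_other_taxa,
                             max(om.casual_pool_species, 1))
        pool_idx = rng_rec.integers(0, pool_size)
        obs_frames.append(pd.DataFrame({
            "observer_id": rep["observer_id"].to_numpy(),
            "date": rep["date"].to_numpy(),
            "grid_cell": rep["grid_cell"].to_numpy(),
            "taxon": _bycatch_taxa(pool_idx, rep["proficient"].to_numpy(), om),
            "life_stage": "adult", "count": 1, "is_absence": False}))

        obs_frames.append(_reproduction_records(config, visits, rng_rec))

    wear_df, wear_truth = _wear_records(config, rng_wear)

    obs = pd.concat([f for f in obs_frames if len(f)], ignore_index=True) \
        if obs_frames else pd.DataFrame(columns=OBS_COLUMNS)
    obs = obs.reindex(columns=OBS_COLUMNS)
    if len(obs):
        obs["count"] = obs["count"].astype(np.int64)
        obs["is_absence"] = obs["is_absence"].astype(bool)
        obs = obs.sort_values(OBS_COLUMNS, ignore_index=True)

    # per-year day-grid-visit tallies for conservation checks
    if len(visits):
        tallies = visits.groupby("year").size().rename("n_day_grid_visits")
        prof_tallies = (visits[visits["proficient"]].groupby("year").size()
                        .rename("n_day_grid_visits_proficient"))
        truth = truth.merge(tallies, on="year", how="left") \
                     .merge(prof_tallies, on="year", how="left")

    records = RecordSet(observations=obs, wear=wear_df,
                        provenance={"generator": "voltipy.simulate",
                                    "seed": config.seed,
                                    "years": list(config.years)})
    return SimulationOutput(records=records, visits=visits, truth=truth,
                            wear_truth=wear_truth)


def simulate_records(config: SyntheticConfig) -> RecordSet:
    """Portal-style RecordSet only (see :func:`simulate` for the full output)."""
    return simulate(config).records


def _attach_to_visits(weeks: np.ndarray, year: int, visits: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Pick one scheduled visit per requested week (nearest week with visits)."""
    vy = visits[visits["year"] == year]
    if not len(vy):
        return vy
    have = np.sort(vy["week"].unique())
    idx_by_week = {w: vy.index[vy["week"] == w].to_numpy() for w in have}
    chosen = []
    for w in weeks:
        nearest = have[np.argmin(np.abs(have - w))]
        pool = idx_by_week[nearest]
        chosen.append(pool[rng.integers(0, len(pool))])
    return vy.loc[chosen]


def _reproduction_records(config: SyntheticConfig, visits: pd.DataFrame,
                          rng: np.random.Generator) -> pd.DataFrame:
    rm = config.reproduction
    peaks = config.season.peaks
    n_cycles = min(len(peaks), 2)
    frac = [1.0 - rm.second_cycle_fraction, rm.second_cycle_fraction][:n_cycles]
    if n_cycles == 1:
        frac = [1.0]

    rows = []
    for year in config.years:
        drift = rm.timing_drift_weeks_per_year * (year - config.years[0])
        for cyc in range(n_cycles):
            mean_wk = peaks[cyc].mean_week + (drift if cyc == 1 else 0.0)
            stages = (
                ("egg", rm.eggs_per_year, rm.egg_lag_weeks[cyc], rm.egg_disp_weeks[cyc]),
                ("caterpillar", rm.caterpillars_per_year, rm.cat_lag_weeks[cyc],
                 rm.cat_disp_weeks[cyc]),
                ("pupa", rm.pupae_per_year, rm.cat_lag_weeks[cyc] + 2.5, 1.5),
            )
            for stage, rate, lag, disp in stages:
                n = rng.poisson(rate * frac[cyc])
                if n == 0:
                    continue
                wk = np.clip(np.rint(rng.normal(mean_wk + lag, disp, size=n)),
                             1, N_WEEKS).astype(int)
                rows.append((year, stage, wk))
        # occasional third-cycle attempts
        n3 = rng.poisson(rm.third_cycle_egg_rate)
        if n3:
            wk = np.clip(np.rint(rng.normal(37.5, 0.8, size=n3)), 37, N_WEEKS).astype(int)
            rows.append((year, "egg", wk))
        nl = rng.poisson(rm.late_caterpillar_rate)
        if nl:
            wk = np.clip(np.rint(rng.normal(41.5, 1.5, size=nl)), 40, 48).astype(int)
            rows.append((year, "caterpillar", wk))

    frames = []
    for year, stage, wk in rows:
        host = _attach_to_visits(wk, year, visits, rng)
        if not len(host):
            continue
        if stage == "egg":
            count = rng.integers(1, 41, size=len(host))
        elif stage == "caterpillar":
            count = 1 + rng.poisson(8, size=len(host))
        else:
            count = np.ones(len(host), dtype=int)
        frames.append(pd.DataFrame({
            "observer_id": host["observer_id"].to_numpy(),
            "date": host["date"].to_numpy(),
            "grid_cell": host["grid_cell"].to_numpy(),
            "taxon": config.target_taxon, "life_stage": stage,
            "count": count, "is_absence": False}))
    if not frames:
        return pd.DataFrame(columns=OBS_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _wear_records(config: SyntheticConfig,
                  rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    wm = config.wear
    peaks = config.season.peaks
    amps = year_amplitudes(config)
    frames, truth_rows = [], []
    counter = 0
    for row in amps.itertuples(index=False):
        aucs = np.array([getattr(row, f"amp_{g}", 0.0)
                         * (peaks[i].sd_weeks if i < len(peaks) else 0.0)
                         for i, g in enumerate(GEN_NAMES)])
        if aucs.sum() <= 0:
            continue
        shares = aucs / aucs.sum()
        for g, (gen, season) in enumerate(zip(GEN_NAMES, SEASONS)):
            if g >= len(peaks) or shares[g] <= 0:
                continue
            n = rng.poisson(wm.photos_per_year * shares[g])
            if n == 0:
                continue
            em_week = rng.normal(peaks[g].mean_week, peaks[g].sd_weeks, size=n)
            em_day = (np.clip(em_week, 1, N_WEEKS) - 1) * 7 + rng.integers(0, 7, size=n)
            ages = rng.uniform(0.0, wm.adult_lifespan_days, size=n)
            if g == 0:
                probs = np.asarray(wm.spring_initial_class_probs, dtype=float)
                init = rng.choice(np.arange(1, len(probs) + 1), size=n,
                                  p=probs / probs.sum())
            else:
                init = np.ones(n, dtype=int)
            classes = age_wear_cohort(ages, wm.residence_days[season], rng,
                                      initial_classes=init)
            if wm.label_confusion > 0:
                flip = rng.random(n) < wm.label_confusion
                shift = rng.choice([-1, 1], size=n)
                classes = np.where(flip, np.clip(classes + shift, 1, 4), classes)
            prop = np.asarray(wm.photo_propensity, dtype=float)
            keep = rng.random(n) < prop[classes - 1] / prop.max()

            avail = np.bincount(classes, minlength=5)[1:]
            photo = np.bincount(classes[keep], minlength=5)[1:]
            truth_rows.append({"year": row.year, "season": season,
                               **{f"avail_c{k}": int(avail[k - 1]) for k in (1, 2, 3, 4)},
                               **{f"photo_c{k}": int(photo[k - 1]) for k in (1, 2, 3, 4)}})

            monday_w1 = np.datetime64(week_start(row.year, 1))
            photo_dates = monday_w1 + (em_day[keep] + ages[keep]).astype(
                "timedelta64[D]")
            ids = [f"photo_{counter + i:06d}" for i in range(int(keep.sum()))]
            counter += int(keep.sum())
            frames.append(pd.DataFrame({"source_id": ids,
                                        "date": pd.to_datetime(photo_dates),
                                        "wear_class": classes[keep]}))
    wear = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=WEAR_COLUMNS))
    wear = wear.reindex(columns=WEAR_COLUMNS)
    if len(wear):
        wear = wear.sort_values(["date", "source_id"], ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return wear, truth
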