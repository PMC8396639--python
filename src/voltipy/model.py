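"""Model/Results facade over the full voltinism analysis.

`VoltinismAnalysis` is constructed from a :class:`~voltipy.records.RecordSet`
(or CSV paths) plus the taxa configuration; :meth:`VoltinismAnalysis.fit`
chains effort correction -> weekly index -> flight-peak segmentation ->
generation AUCs -> voltinism classification -> spring-coupling regression,
plus the wear and reproduction phenologies when those records are present,
and returns a :class:`VoltinismResults` carrying every stage's table and a
``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import effort, phenology, reproduction, wear as wear_mod
from .exceptions import InsufficientDataError
from .records import RecordSet, read_observations, read_wear_labels
from .regression import RegressionResultSet, build_generation_table, fit_spring_models

logger = logging.getLogger(__name__)


@dataclass
class AnalysisOptions:
    """Tunable settings of the analysis chain, with the defaults used throughout."""

    min_records: int = 50           # proficiency: butterfly records per year
    min_species: int = 10           # proficiency: butterfly species per year
    union_cells: bool = False       # effort: per-observer cell sums (default) vs union
    restrict_numerator: bool = True
    n_best_days: int = 3
    segmentation: phenology.SegmentationOptions = field(
        default_factory=phenology.SegmentationOptions)
    valley_window: tuple[int, int] = reproduction.DEFAULT_VALLEY_WINDOW
    min_caterpillar_records: int = 10
    min_year_records: int = 30      # historical-series sufficiency threshold


class VoltinismAnalysis:
    """The full citizen-science voltinism analysis as a fittable model."""

    def __init__(self, records: RecordSet, target_taxon: str,
                 butterfly_taxa: list[str],
                 options: AnalysisOptions | None = None) -> None:
        self.records = records
        self.target_taxon = target_taxon
        self.butterfly_taxa = list(butterfly_taxa)
        self.options = options or AnalysisOptions()

    @classmethod
    def from_csv(cls, observations_path, target_taxon: str,
                 butterfly_taxa: list[str], wear_path=None,
                 options: AnalysisOptions | None = None) -> "VoltinismAnalysis":
        rs = read_observations(observations_path)
        if wear_path is not None:
            rs.wear = read_wear_labels(wear_path).records
        return cls(rs, target_taxon, butterfly_taxa, options)

    def fit(self) -> "VoltinismResults":
        opt = self.options
        weekly = effort.weekly_index_pipeline(
            self.records, self.target_taxon, self.butterfly_taxa,
            min_records=opt.min_records, min_species=opt.min_species,
            union_cells=opt.union_cells,
            restrict_numerator=opt.restrict_numerator,
            n_best_days=opt.n_best_days)

        gen_frames, volt_rows, skipped = [], [], []
        for year in sorted(weekly["year"].unique()):
            try:
                summaries, volt = phenology.analyse_year(weekly, int(year),
                                                         opt.segmentation)
            except InsufficientDataError as exc:
                skipped.append((int(year), str(exc)))
                continue
            gen_frames.append(summaries)
            volt_rows.append(volt)
        generations = (pd.concat(gen_frames, ignore_index=True) if gen_frames
                       else pd.DataFrame())
        voltinism = pd.DataFrame(volt_rows)

        regression = None
        if len(generations):
            try:
                table = build_generation_table(generations)
                regression = fit_spring_models(table)
            except InsufficientDataError as exc:
                logger.info("regression skipped: %s", exc)

        wear_table = None
        if len(self.records.wear):
            wear_table = wear_mod.weekly_wear_table(self.records.wear)

        stage_counts = reproduction.stage_weekly_counts(self.records,
                                                        self.target_taxon)
        cat_peaks = reproduction.caterpillar_peak_table(
            self.records, self.target_taxon,
            valley_window=opt.valley_window,
            min_records=opt.min_caterpillar_records)

        return VoltinismResults(
            model=self, weekly_index=weekly, generations=generations,
            voltinism=voltinism, regression=regression, wear_table=wear_table,
            stage_counts=stage_counts, caterpillar_peaks=cat_peaks,
            skipped_years=skipped)


@dataclass
class VoltinismResults:
    """Fitted tables of every stage of the voltinism analysis."""

    model: VoltinismAnalysis
    weekly_index: pd.DataFrame
    generations: pd.DataFrame
    voltinism: pd.DataFrame
    regression: RegressionResultSet | None
    wear_table: pd.DataFrame | None
    stage_counts: pd.DataFrame
    caterpillar_peaks: pd.DataFrame
    skipped_years: list = field(default_factory=list)

    # -- derived summaries -------------------------------------------------
    def mean_generation_aucs(self) -> pd.Series:
        """Mean AUC index per generation across analysed years."""
        return self.generations.groupby("generation")["auc_index"].mean() \
            .reindex(list(phenology.GENERATIONS))

    def percent_larger_gen1_vs_spring(self) -> float:
        m = self.mean_generation_aucs()
        return phenology.percent_larger(m["spring"], m["gen1"])

    def percent_larger_gen2_vs_gen1(self) -> float:
        m = self.mean_generation_aucs()
        return phenology.percent_larger(m["gen1"], m["gen2"])

    def mean_caterpillar_gap_days(self) -> float:
        return reproduction.mean_peak_gap(self.caterpillar_peaks)

    def summary(self) -> str:
        lines = ["Voltinism analysis summary", "=" * 26]
        lines.append(f"Target taxon:       {self.model.target_taxon}")
        lines.append(f"Years analysed:     {len(self.voltinism)}"
                     + (f" ({len(self.skipped_years)} skipped)" if self.skipped_years else ""))
        if len(self.generations):
            m = self.mean_generation_aucs()
            lines.append("")
            lines.append("Mean generation AUC index (area under weekly curve):")
            for gen in phenology.GENERATIONS:
                lines.append(f"  {gen:<8s} {m[gen]:8.3f}")
            lines.append(f"  gen1 vs spring: {self.percent_larger_gen1_vs_spring():+6.1f}%"
                         f"   gen2 vs gen1: {self.percent_larger_gen2_vs_gen1():+6.1f}%")
        if len(self.voltinism):
            lines.append("")
            lines.append("Per-year third-peak proportion and regime:")
            for row in self.voltinism.itertuples(index=False):
                lines.append(f"  {row.year}  p={row.proportion_third_peak:5.3f}"
                             f"  {row.regime}")
        if self.regression is not None:
            lines.append("")
            lines.append("Next-spring coupling (OLS):")
            for name in ("simple_gen2", "simple_gen1", "multiple"):
                f = self.regression[name]
                lines.append(f"  {name:<12s} R²={f.r_squared:5.3f}  "
                             f"p={f.p_value:.4g}  n={f.n}")
        if len(self.caterpillar_peaks):
            try:
                gap = self.mean_caterpillar_gap_days()
                lines.append("")
                lines.append(f"Mean gap between caterpillar-peak medians: {gap:.1f} days"
                             f" (n={int(self.caterpillar_peaks['gap_days'].notna().sum())} years)")
            except InsufficientDataError:
                pass
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot_flight_curve(self, ax=None):
        """Weekly abundance index per year, with generation windows shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for year, sub in self.weekly_index.groupby("year"):
            ax.plot(sub["week"], sub["index"], alpha=0.6, label=str(year))
        ax.set_xlabel("ISO week")
        ax.set_ylabel("abundance index (adults / day-grid-visit)")
        ax.legend(fontsize="x-small", ncol=2)
        return ax

    def plot_wear_phenology(self, ax=None):
        """Stacked weekly wear-class proportions."""
        import matplotlib.pyplot as plt

        if self.wear_table is None:
            raise InsufficientDataError("no wear records were supplied")
        if ax is None:
            _, ax = plt.subplots()
        bottom = None
        for k in (1, 2, 3, 4):
            vals = self.wear_table[f"p{k}"]
            ax.bar(self.wear_table["week"], vals, bottom=bottom,
                   label=f"class {k}")
            bottom = vals if bottom is None else bottom + vals
        ax.set_xlabel("ISO week")
        ax.set_ylabel("proportion of photographed adults")
        ax.legend()
        return ax
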