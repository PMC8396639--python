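import numpy as np
import pandas as pd
import pytest

import voltipy as v
from voltipy.exceptions import ConfigError
from voltipy.simulate import (GenerationPeak, SQRT_2PI, age_wear_cohort,
                              truth_generation_table, year_amplitudes)


def _season(*peaks):
    return v.SeasonModel(peaks=tuple(GenerationPeak(*p) for p in peaks))


def _fixed_cfg(amps=(1.0, 1.83, 2.25), years=(2020,), **kw):
    over = {y: amps for y in years}
    return v.SyntheticConfig(years=years, amplitude_overrides=over, **kw)


class TestLatentAbundance:
    def test_single_peak_zero_beyond_six_sd(self):
        cfg = _fixed_cfg(amps=(1.0, 0.0, 0.0))
        latent = v.simulate_latent_abundance(cfg)
        far = latent[np.abs(latent["week"] - 16) > 12]  # 6 sd at sd=2
        assert (far["total"] < 1e-8).all()
        at_peak = latent.loc[latent["week"] == 16, "total"].iloc[0]
        assert at_peak == pytest.approx(1.0, abs=1e-6)

    def test_component_value_at_mean_equals_amplitude(self):
        cfg = _fixed_cfg()
        latent = v.simulate_latent_abundance(cfg)
        row = latent[latent["week"] == 37].iloc[0]
        assert row["abundance_gen2"] == pytest.approx(2.25)

    def test_auc_ratios_match_numerical_integration_oracle(self):
        """Closed-form Gaussian AUCs agree with numerical integration of the curve."""
        cfg = _fixed_cfg()
        truth = v.truth_report(cfg).iloc[0]
        # independent oracle: integrate each component on a fine week grid
        w = np.linspace(-20, 80, 200001)
        for gen, (mean, amp) in [("spring", (16, 1.0)), ("gen1", (27, 1.83)),
                                 ("gen2", (37, 2.25))]:
            numeric = np.trapezoid(amp * np.exp(-((w - mean) ** 2) / (2 * 4.0)), w)
            assert truth[f"auc_{gen}"] == pytest.approx(numeric, rel=1e-6)
        assert truth["auc_gen1"] / truth["auc_spring"] == pytest.approx(1.83)
        assert truth["auc_gen2"] / truth["auc_spring"] == pytest.approx(2.25)

    def test_generation_count_validated(self):
        with pytest.raises(ConfigError):
            _season((10, 2, 1), (20, 2, 1), (30, 2, 1), (40, 2, 1))
        with pytest.raises(ConfigError):
            _season((20, 2, 1), (10, 2, 1))  # means not increasing


class TestTruthReport:
    def test_one_generation_proportion_zero(self):
        cfg = v.SyntheticConfig(season=_season((16, 2, 1.0)), years=(2020,))
        t = v.truth_report(cfg)
        assert (t["proportion_third_peak"] == 0).all()
        assert (t["regime"] == "univoltine").all()

    def test_equal_sd_arithmetic(self):
        t = v.truth_report(_fixed_cfg(amps=(1.0, 1.0, 2.0))).iloc[0]
        assert t["proportion_third_peak"] == pytest.approx(0.5)
        assert t["regime"] == "bivoltine"

    def test_regime_threshold(self):
        t = v.truth_report(_fixed_cfg(amps=(1.0, 1.0, 0.7))).iloc[0]
        assert t["proportion_third_peak"] == pytest.approx(0.7 / 2.7)
        assert t["regime"] == "bivoltine"  # 0.259 > 0.25

    def test_doubling_amplitudes_leaves_proportion_invariant(self):
        t1 = v.truth_report(_fixed_cfg(amps=(1.0, 1.83, 2.25))).iloc[0]
        t2 = v.truth_report(_fixed_cfg(amps=(2.0, 3.66, 4.5))).iloc[0]
        assert t1["proportion_third_peak"] == pytest.approx(
            t2["proportion_third_peak"])

    def test_spring_coupled_to_previous_gen2(self):
        cfg = v.SyntheticConfig(years=tuple(range(2009, 2021)), seed=5,
                                winter_noise_sd=0.0)
        t = v.truth_report(cfg)
        ratio = t["auc_spring"].to_numpy()[1:] / t["auc_gen2"].to_numpy()[:-1]
        assert ratio == pytest.approx(np.full(11, cfg.winter_survival))
        table = truth_generation_table(cfg)
        assert len(table) == 11
        assert table["spring_next"].to_numpy() == pytest.approx(
            cfg.winter_survival * table["gen2"].to_numpy())


class TestSimulateRecords:
    def test_determinism_same_seed_identical(self):
        cfg = v.SyntheticConfig(years=(2020,), seed=11)
        a, b = v.simulate(cfg), v.simulate(v.SyntheticConfig(years=(2020,), seed=11))
        pd.testing.assert_frame_equal(a.records.observations, b.records.observations)
        pd.testing.assert_frame_equal(a.records.wear, b.records.wear)
        pd.testing.assert_frame_equal(a.visits, b.visits)

    def test_different_seed_differs(self):
        a = v.simulate_records(v.SyntheticConfig(years=(2020,), seed=1))
        b = v.simulate_records(v.SyntheticConfig(years=(2020,), seed=2))
        assert not a.observations.equals(b.observations)

    def test_amplitude_doubling_doubles_detections(self):
        """Poisson mean linearity: x2 amplitude with the same visit schedule."""
        cfg1 = _fixed_cfg(amps=(1.0, 1.83, 2.25), seed=3)
        cfg2 = _fixed_cfg(amps=(2.0, 3.66, 4.5), seed=3)
        s1, s2 = v.simulate(cfg1), v.simulate(cfg2)
        pd.testing.assert_frame_equal(s1.visits, s2.visits)  # effort held fixed

        def total_adults(sim):
            o = sim.records.observations
            tgt = o[(o["taxon"] == "Aglais io") & (o["life_stage"] == "adult")]
            return tgt["count"].sum()

        ratio = total_adults(s2) / total_adults(s1)
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_effort_conservation_against_visit_schedule(self):
        """Every visit leaves >=1 record, so recomputed effort equals the schedule."""
        cfg = v.SyntheticConfig(years=(2020,), seed=4)
        sim = v.simulate(cfg)
        obs = sim.records.observations
        everyone = {yr: set(obs["observer_id"].unique())
                    for yr in obs["date"].dt.year.unique()}
        from voltipy.effort import compute_daily_effort
        eff = compute_daily_effort(sim.records, everyone)
        assert eff["day_grid_visits"].sum() == len(sim.visits)
        tally = sim.visits.groupby("date").size()
        merged = eff.set_index("date")["day_grid_visits"]
        assert merged.equals(tally.reindex(merged.index))

    def test_zero_observers_empty_recordset(self):
        cfg = v.SyntheticConfig(
            years=(2020,), observers=v.ObserverModel(n_observers=0),
            wear=v.WearModel(photos_per_year=0))
        rs = v.simulate_records(cfg)
        assert len(rs.observations) == 0

    def test_proficiency_mix_straddles_filter(self):
        from voltipy.effort import select_proficient_observers
        cfg = v.SyntheticConfig(years=(2020,), seed=9)
        rs = v.simulate_records(cfg)
        sel = select_proficient_observers(rs, cfg.butterfly_taxa)
        n_sel = len(sel.get(2020, set()))
        assert 0 < n_sel < cfg.observers.n_observers


class TestWearAging:
    def test_infinite_residence_keeps_class_one(self):
        rng = np.random.default_rng(0)
        classes = age_wear_cohort(np.full(500, 30.0), (1e12, 1e12, 1e12), rng)
        assert (classes == 1).all()

    def test_old_individuals_fully_worn(self):
        rng = np.random.default_rng(0)
        classes = age_wear_cohort(np.full(500, 1e9), (5.0, 5.0, 5.0), rng)
        assert (classes == 4).all()

    def test_initial_class_respected(self):
        rng = np.random.default_rng(0)
        init = np.array([1, 2, 3, 4] * 100)
        classes = age_wear_cohort(np.zeros(400), (5.0, 5.0, 5.0), rng, init)
        assert (classes == init).all()

    def test_season_ordering_enforced_by_default(self):
        with pytest.raises(ConfigError):
            v.WearModel(residence_days={"spring": (10, 10, 10),
                                        "summer": (5, 5, 5),
                                        "autumn": (18, 18, 18)})


def test_config_yaml_round_trip(tmp_path):
    from voltipy.simulate import config_from_yaml, config_to_yaml
    cfg = v.SyntheticConfig(years=(2019, 2020), seed=42, year_sd=0.2)
    path = tmp_path / "cfg.yaml"
    config_to_yaml(cfg, path)
    back = config_from_yaml(path)
    assert back.years == (2019, 2020) and back.seed == 42
    assert back.season.peaks == cfg.season.peaks
    pd.testing.assert_frame_equal(v.truth_report(back), v.truth_report(cfg))


def test_unknown_yaml_keys_rejected(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("seed: 1\nbogus_key: 2\n")
    from voltipy.simulate import config_from_yaml
    with pytest.raises(ConfigError, match="bogus_key"):
        config_from_yaml(path)
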