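"""Forward simulator: determinism, validity, conservation, recovery."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from cryotrace import (
    CoolingExperiment,
    NoiseModel,
    default_truth,
    reference_site_summary,
    simulate,
)
from cryotrace.errors import ConfigError
from cryotrace.synthetic import SiteTruth


class TestDefaultTruth:
    def test_reference_rates_match_published_site_means(self):
        truth = default_truth()
        ref = reference_site_summary().set_index("parameter")
        by_name = {s.name: s for s in truth.sites}
        for param in ("respiration", "growth", "label_respiration", "label_mbc"):
            assert by_name["agricultural"].rate_11[param] == pytest.approx(
                ref.loc[param, "agricultural_mean"]
            )
            assert by_name["forest"].rate_11[param] == pytest.approx(
                ref.loc[param, "forest_mean"]
            )

    def test_site_respiration_contrast(self):
        truth = default_truth()
        by_name = {s.name: s for s in truth.sites}
        ratio = (
            by_name["forest"].rate_11["respiration"]
            / by_name["agricultural"].rate_11["respiration"]
        )
        assert round(ratio, 1) == 8.1

    def test_cooling_response_of_respiration(self):
        truth = default_truth()
        agri = next(s for s in truth.sites if s.name == "agricultural")
        assert agri.rr42["respiration"] == pytest.approx(3.30)

    def test_all_simplices_valid(self):
        for site in default_truth().sites:
            assert sum(site.group_biomass.values()) == pytest.approx(1.0)
            for simplex in site.label_groups.values():
                assert sum(simplex.values()) == pytest.approx(1.0)
                assert all(v >= 0 for v in simplex.values())

    def test_invalid_simplex_rejected(self):
        agri = next(s for s in default_truth().sites if s.name == "agricultural")
        with pytest.raises(ConfigError):
            dataclasses.replace(
                agri, group_biomass={"bacterial": 0.8, "fungal": 0.4, "general": 0.0}
            )


class TestSimulate:
    def test_same_seed_same_tables(self):
        truth = default_truth()
        a = simulate(truth, 123)
        b = simulate(truth, 123)
        for name in a.tables:
            pd.testing.assert_frame_equal(a.tables[name], b.tables[name])

    def test_different_seed_different_noise(self):
        truth = default_truth()
        a = simulate(truth, 1).tables["headspace"]
        b = simulate(truth, 2).tables["headspace"]
        assert not np.allclose(a["co2_ppm_t1"], b["co2_ppm_t1"])

    def test_tables_referentially_consistent(self, zero_noise_experiment):
        meta_ids = set(zero_noise_experiment.tables["sample_meta"]["sample_id"])
        for name in ("headspace", "fumigation", "plfa"):
            assert set(zero_noise_experiment.tables[name]["sample_id"]) <= meta_ids

    def test_label_and_control_arms_generated_for_every_vial(self, zero_noise_experiment):
        meta = zero_noise_experiment.tables["sample_meta"]
        o18 = meta[meta["assay"] == "18O"]
        counts = o18.groupby(["site", "plot", "temperature_c", "window_h", "amendment"])[
            "label_arm"
        ].nunique()
        assert (counts == 2).all()


class TestZeroNoiseInversion:
    def test_pipeline_recovers_every_true_value(self, zero_noise_experiment, zero_noise_results):
        """Exact inversion of the generative model at zero noise."""
        summary = zero_noise_results.summary_table
        truth = zero_noise_experiment.truth_values
        merged = summary.merge(
            truth,
            on=["site", "temperature_c", "window_h", "amendment", "parameter"],
            suffixes=("", "_true"),
        )
        # every truth row must be matched by a pipeline estimate
        assert len(merged) == len(truth)
        rel = np.abs(merged["mean"] - merged["value"]) / np.maximum(
            np.abs(merged["value"]), 1e-12
        )
        assert rel.max() < 1e-6
        assert (merged["se"].abs() < 1e-9 * merged["value"].abs().clip(lower=1)).all()

    def test_label_mass_conservation(self, zero_noise_results, zero_noise_experiment):
        """Respired + biomass + residual extractable label <= dose."""
        doses = {s.name: s.glucose_dose_ug_per_g for s in
                 zero_noise_experiment.truth.sites}
        ps = zero_noise_results.per_sample
        wide = ps[ps["amendment"] == "glucose"].pivot_table(
            index=["site", "plot", "temperature_c", "window_h"],
            columns="parameter",
            values="value",
        ).reset_index()
        duration = 42.0
        recovered = (
            wide["label_respiration"] * duration / 1000.0
            + wide["label_mbc"] * duration / 1000.0
            + wide["label_eoc"]
        )
        added = wide["site"].map(doses)
        assert (recovered <= added * (1 + 1e-6)).all()

    def test_rr_increases_with_respiration_q_factor(self):
        truth = default_truth().zero_noise()
        sites = []
        for s in truth.sites:
            rr42 = dict(s.rr42)
            rr42["respiration"] *= 1.5
            sites.append(dataclasses.replace(s, rr42=rr42))
        steeper = dataclasses.replace(truth, sites=tuple(sites))
        base_rr = _respiration_rr(simulate(truth, 5))
        steep_rr = _respiration_rr(simulate(steeper, 5))
        assert (steep_rr > base_rr).all()


def _respiration_rr(exp):
    res = CoolingExperiment.from_tables(exp.tables).fit()
    rr = res.response_ratios
    sel = rr[(rr["parameter"] == "respiration") & (rr["window_h"] == 42.0)]
    return sel.set_index(["site", "plot", "amendment"])["rr"]


class TestRecoveryUnderNoise:
    def test_replicate_means_converge_to_truth(self):
        """Instrument noise only, 100 plots: respiration means within 2%.

        Growth inherits the sampling noise of the fumigation-difference MBC
        (the flush is a small difference of two noisy extracts), so it is
        checked for statistical consistency (within 3 SE) rather than a
        fixed percentage.
        """
        truth = dataclasses.replace(
            default_truth(),
            n_plots=100,
            noise=NoiseModel(
                cv_gas=0.03,
                cv_extract=0.05,
                sd_at_percent=0.0,
                cv_area=0.0,
                plot_cv=0.0,
            ),
        )
        exp = simulate(truth, 42)
        res = CoolingExperiment.from_tables(exp.tables).fit()
        merged = res.summary_table.merge(
            exp.truth_values,
            on=["site", "temperature_c", "window_h", "amendment", "parameter"],
            suffixes=("", "_true"),
        )
        ref = merged[
            (merged["temperature_c"] == 11.0)
            & (merged["window_h"] == 42.0)
            & (merged["amendment"] == "glucose")
        ].set_index(["site", "parameter"])
        for site in ("agricultural", "forest"):
            resp = ref.loc[(site, "respiration")]
            assert abs(resp["mean"] - resp["value"]) / resp["value"] < 0.02
            for param in ("growth", "mbc"):
                row = ref.loc[(site, param)]
                assert abs(row["mean"] - row["value"]) < 3.0 * row["se"]
            cue_row = ref.loc[(site, "cue")]
            assert abs(cue_row["mean"] - cue_row["value"]) < 0.02
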