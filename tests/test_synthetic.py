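"""Generator contracts: determinism, zero-noise exactness, magnitudes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from matbgc.spectra import PiecewiseSpectrum
from matbgc.synthetic import (
    PowerLawSensor,
    ScenarioConfig,
    gen_core_35s,
    gen_filter_sequence,
    gen_incubation,
    gen_light_log,
    gen_solidphase,
)


@pytest.mark.parametrize(
    "generator",
    [gen_light_log, gen_filter_sequence, gen_incubation, gen_core_35s,
     gen_solidphase],
)
def test_seed_determinism(config, generator):
    """Identical seed and config give bit-identical tables."""
    a, b = generator(config), generator(config)
    for field in a.__dataclass_fields__:
        va, vb = getattr(a, field), getattr(b, field)
        if isinstance(va, pd.DataFrame):
            pd.testing.assert_frame_equal(va, vb)


def test_generators_use_independent_streams(config):
    """One generator's draws do not depend on another having run."""
    first = gen_incubation(config)
    gen_core_35s(config)  # interleave another generator
    second = gen_incubation(config)
    pd.testing.assert_frame_equal(first.samples, second.samples)


class TestLightLog:
    def test_proportional_law_gives_proportional_signal(self, quiet_config):
        cfg = dataclasses.replace(
            quiet_config,
            sensor=PowerLawSensor(amplitudes=(0.5,), exponent=1.0,
                                  signal_max=1e12),
        )
        log = gen_light_log(cfg)
        np.testing.assert_allclose(
            log.samples["signal"], log.truth["irradiance"] / 0.5, rtol=1e-12
        )

    def test_wall_irradiance_within_observed_low_light_range(self, config):
        """Default wall-mooring truth stays inside the measured
        0.021-0.084 μmol photons m⁻² s⁻¹ window."""
        log = gen_light_log(config)
        wall = log.truth.loc[log.truth["phase"] == "wall", "irradiance"]
        assert 0.021 <= wall.min() and wall.max() <= 0.084

    def test_center_irradiance_anchor(self, quiet_config):
        log = gen_light_log(quiet_config)
        descent = log.truth[log.truth["phase"] == "descent"]
        at_30 = descent.iloc[(descent["depth"] - 30.0).abs().argmin()]
        # nearest sample sits a few cm off 30 m at the 1 s sampling step
        assert at_30["irradiance"] == pytest.approx(0.27, rel=0.01)

    def test_par_masked_below_floor(self, config):
        log = gen_light_log(config)
        joined = log.samples.assign(truth=log.truth["irradiance"])
        assert joined.loc[joined["truth"] < config.par_floor, "par"].isna().all()
        assert joined.loc[joined["truth"] >= config.par_floor, "par"].notna().all()

    def test_non_monotone_sensor_law_rejected(self):
        with pytest.raises(ValueError, match="non-monotone"):
            PowerLawSensor(exponent=-1.0)
        with pytest.raises(ValueError, match="non-monotone"):
            PowerLawSensor(amplitudes=(1.0, -2.0))


class TestFilterSequence:
    def test_flat_spectrum_longpass_proportion(self, quiet_config):
        """Flat 200-700 nm spectrum, transmission 1: a 400 nm longpass
        keeps 300/500 = 0.6 of the unfiltered reading."""
        flat = PiecewiseSpectrum(np.array([200.0, 700.0]), np.array([1.0]))
        cfg = dataclasses.replace(quiet_config, spectrum=flat,
                                  filter_transmission=1.0)
        steps = gen_filter_sequence(cfg).steps
        unfiltered = steps.loc[steps["cutoff"].isna(), "reading"].iloc[0]
        at_400 = steps.loc[steps["cutoff"] == 400.0, "reading"].iloc[0]
        assert at_400 == pytest.approx(0.6 * unfiltered, rel=1e-12)

    def test_default_truth_fractions(self, config):
        truth = gen_filter_sequence(config).truth
        frac = dict(zip(truth["band"], truth["fraction"]))
        assert frac["<400"] == pytest.approx(0.64, abs=1e-12)
        assert frac["475-530"] == pytest.approx(0.21, abs=1e-12)
        assert frac["590-645"] == 0.0 and frac[">645"] == 0.0

    def test_decreasing_cutoffs_rejected(self, config):
        cfg = dataclasses.replace(config, filter_cutoffs=(475.0, 400.0))
        with pytest.raises(ValueError, match="increasing"):
            gen_filter_sequence(cfg)


class TestIncubation:
    def test_zero_rate_no_noise_gives_natural_abundance(self, quiet_config):
        cfg = dataclasses.replace(
            quiet_config, true_per_cell_rate=0.0,
            true_per_cell_rate_acetate=0.0,
        )
        samples = gen_incubation(cfg).samples
        np.testing.assert_allclose(
            samples["ratio_13c_12c"], cfg.natural_ratio, rtol=1e-12
        )

    def test_default_vial_rate_matches_study_scale(self, quiet_config):
        truth = gen_incubation(quiet_config).truth
        assert truth["DIC"]["true_vial_rate_light"] == pytest.approx(
            0.83, abs=0.005
        )

    def test_negative_noise_sd_rejected(self, config):
        bad = config.with_noise(ratio=-0.1)
        with pytest.raises(ValueError, match="negative noise sd"):
            gen_incubation(bad)


class TestTracerCores:
    def test_zero_rate_no_noise_gives_zero_tris(self, quiet_config):
        cfg = dataclasses.replace(
            quiet_config, true_srr_profile=((0.0, 0.0), (5.0, 0.0)),
            blank_dpm_mean=0.0,
        )
        cores = gen_core_35s(cfg)
        assert (cores.samples["a_tris"] == 0).all()
        assert (cores.blanks["blank"] == 0).all()

    def test_true_rates_within_reported_span(self, config):
        truth = gen_core_35s(config).truth
        assert truth["rate"].min() >= 0.0
        assert truth["rate"].max() <= 99.2

    def test_excessive_turnover_rejected(self, quiet_config):
        cfg = dataclasses.replace(
            quiet_config,
            true_srr_profile=((0.0, 1e9), (5.0, 1e9)),
        )
        with pytest.raises(ValueError, match="turnover"):
            gen_core_35s(cfg)

    def test_turnover_warning_above_linearity_threshold(self, quiet_config):
        cfg = dataclasses.replace(
            quiet_config,
            true_srr_profile=((0.0, 12000.0), (5.0, 12000.0)),
        )
        with pytest.warns(UserWarning, match="turnover"):
            gen_core_35s(cfg)


class TestSolidPhase:
    def test_no_noise_flat_profiles_equal_truth(self, quiet_config):
        flat = {
            "avs": ((0.0, 0.1), (4.0, 0.1)),
            "crs": ((0.0, 10.0), (4.0, 10.0)),
            "s0": ((0.0, 0.5), (4.0, 0.5)),
            "dith_fe": ((0.0, 8.0), (4.0, 8.0)),
            "so4_porewater": ((0.0, 28000.0), (4.0, 28000.0)),
        }
        cfg = dataclasses.replace(quiet_config, pool_profiles=flat)
        result = gen_solidphase(cfg)
        pd.testing.assert_frame_equal(result.samples, result.truth)
        assert (result.truth["crs"] == 10.0).all()

    def test_default_s0_enriched_at_surface(self, quiet_config):
        truth = gen_solidphase(quiet_config).truth
        top = truth[truth["depth_bottom"] <= 0.25]["s0"].mean()
        deep = truth[truth["depth_top"] >= 0.5]["s0"].mean()
        assert top == pytest.approx(0.12, abs=0.01)
        assert deep == pytest.approx(0.02, abs=0.005)

    def test_crs_below_s0_rejected(self, quiet_config):
        bad = dict(quiet_config.pool_profiles)
        bad["crs"] = ((0.0, 0.01), (4.0, 0.01))
        cfg = dataclasses.replace(quiet_config, pool_profiles=bad)
        with pytest.raises(ValueError, match="CRS"):
            gen_solidphase(cfg)
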