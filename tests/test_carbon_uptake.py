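"""Uptake-rate chain: labeling, rate fitting, extrapolations."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from matbgc.carbon_uptake import (
    MOLAR_MASS_C,
    NATURAL_13C_RATIO,
    CellModel,
    LabelSpec,
    absorptive_area,
    areal_rate,
    atom_fraction,
    derive_uptake,
    estimate_cell_count,
    labeling_fraction,
    per_cell_rate,
    quantum_yield,
    ratio_from_atom_fraction,
    sulfide_equivalent,
    uptake_rate,
)
from matbgc.synthetic import gen_incubation


class TestLabelingFraction:
    def test_singly_labeled_acetate_is_half(self):
        spec = LabelSpec(substrate="acetate", labeled_positions=1,
                         total_positions=2, ambient_conc=0.0)
        assert labeling_fraction(spec) == 0.5

    def test_dic_mole_balance(self):
        """73.8 nmol label into 100 μmol/L ambient DIC in 6 mL:
        73.8 / (73.8 + 600) by direct mole balance."""
        spec = LabelSpec(substrate="DIC", label_added=73.8,
                         ambient_conc=100.0, vial_volume=6.0)
        assert labeling_fraction(spec) == pytest.approx(73.8 / 673.8, rel=1e-12)

    def test_monotone_decreasing_in_ambient(self):
        fracs = [
            labeling_fraction(LabelSpec(ambient_conc=c))
            for c in (0.0, 10.0, 1e3, 1e9)
        ]
        assert all(a > b for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] < 1e-4


def _series(slope_nmol_h, frac, hours=(0.0, 24.0, 60.0), total_ug=11.83,
            natural=NATURAL_13C_RATIO, dark_slope=0.0):
    """Exact linear excess-13C construction (the textbook inverse of the
    estimator): excess(t) = slope x t nmol 13C per vial."""
    total_nmol = total_ug / MOLAR_MASS_C * 1e3
    x_na = natural / (1 + natural)
    rows = [
        {"condition": "natural_abundance", "light_hours": np.nan,
         "ratio_13c_12c": natural, "total_c": total_ug}
        for _ in range(3)
    ]
    for cond, s in (("light", slope_nmol_h), ("dark", dark_slope)):
        for t in hours:
            x = x_na + s * t / total_nmol
            rows.append({
                "condition": "t0" if t == 0 else cond,
                "light_hours": t,
                "ratio_13c_12c": x / (1 - x),
                "total_c": total_ug,
            })
    return pd.DataFrame(rows).drop_duplicates(
        subset=["condition", "light_hours", "ratio_13c_12c"]
    )


class TestUptakeRate:
    def test_flat_ratios_give_zero_rate(self):
        rates = uptake_rate(_series(0.0, 0.105), frac=0.105)
        assert rates.light == pytest.approx(0.0, abs=1e-12)
        assert rates.dark == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_excess_recovers_vial_rate(self):
        """Excess 13C of 0.08715 nmol/h at labeling 0.105 is a vial rate
        of 0.83 nmol C vial-1 h-1."""
        rates = uptake_rate(_series(0.08715, 0.105), frac=0.105)
        assert rates.light == pytest.approx(0.83, rel=1e-10)

    def test_rate_inversely_proportional_to_labeling(self):
        series = _series(0.08715, 0.105)
        assert uptake_rate(series, 0.105).light == pytest.approx(
            2 * uptake_rate(series, 0.21).light, rel=1e-12
        )

    def test_single_timepoint_errors(self):
        series = _series(0.1, 0.5, hours=(24.0,))
        series = series[series["condition"] != "t0"]
        with pytest.raises(ValueError, match="time points"):
            uptake_rate(series, 0.5)

    def test_missing_baseline_errors(self):
        series = _series(0.1, 0.5)
        series = series[series["condition"] != "natural_abundance"]
        with pytest.raises(ValueError, match="natural"):
            uptake_rate(series, 0.5)

    def test_negative_slope_warned_not_clamped(self):
        series = _series(-0.01, 0.105)
        with pytest.warns(UserWarning, match="negative"):
            rates = uptake_rate(series, 0.105)
        assert rates.light < 0


class TestCellCount:
    def test_literature_cell_carbon_and_count(self):
        """r = 0.6125 μm at 106 fg C μm-3 is ~102 fg C per cell, so
        11.83 μg net filter C is ~1.16e8 cells."""
        model = CellModel()
        assert model.carbon_per_cell_fg == pytest.approx(102.0, abs=0.05)
        cells = estimate_cell_count(11.83 + 2.0, 2.0, model)
        assert cells == pytest.approx(1.16e8, rel=0.001)

    def test_zero_net_carbon_zero_cells(self):
        assert estimate_cell_count(2.0, 2.0) == 0.0

    def test_blank_exceeding_total_errors(self):
        with pytest.raises(ValueError, match="below blank"):
            estimate_cell_count(1.0, 2.0)


class TestExtrapolations:
    def test_per_cell_round_trip(self):
        rate = per_cell_rate(0.83, 1.16e8)
        assert rate * 1.16e8 == pytest.approx(0.83, rel=1e-12)
        with pytest.raises(ValueError):
            per_cell_rate(0.83, 0.0)

    def test_areal_monolayer_extrapolation(self):
        """7.1e-9 nmol/cell/h over a gapless monolayer of 0.6125 μm
        disks for 24 h/d gives ~14.5 nmol C cm-2 d-1."""
        assert areal_rate(7.1e-9) == pytest.approx(14.5, rel=0.01)
        assert areal_rate(0.0) == 0.0

    def test_areal_scales_inverse_square_radius(self):
        small = CellModel(radius=0.30625)
        assert areal_rate(1e-9, small) == pytest.approx(
            4 * areal_rate(1e-9), rel=1e-12
        )

    def test_sulfide_equivalent_is_exactly_double(self):
        assert sulfide_equivalent(14.5) == 29.0
        x = 0.123456
        assert sulfide_equivalent(x) == 2 * x

    def test_absorptive_area_linear(self):
        area = absorptive_area(1.16e8)
        assert area == pytest.approx(0.719, abs=2e-3)
        assert absorptive_area(0.0) == 0.0
        assert absorptive_area(2.32e8) == pytest.approx(2 * area, rel=1e-12)


class TestQuantumYield:
    def test_study_scale_chain(self):
        """0.83 nmol/h against 21% of 0.27 μmol photons m-2 s-1 on
        0.716 cm2 of absorbing cell surface is a yield near 0.056."""
        qy = quantum_yield(0.83, 0.21, 0.27, 0.716)
        assert qy == pytest.approx(0.0568, abs=0.0005)

    def test_zero_rate_zero_yield(self):
        assert quantum_yield(0.0, 0.21, 0.27, 0.716) == 0.0

    def test_doubling_irradiance_halves_yield(self):
        qy1 = quantum_yield(0.83, 0.21, 0.27, 0.716)
        qy2 = quantum_yield(0.83, 0.21, 0.54, 0.716)
        assert qy1 == pytest.approx(2 * qy2, rel=1e-12)

    def test_zero_photon_delivery_errors(self):
        with pytest.raises(ValueError, match="delivery"):
            quantum_yield(0.83, 0.0, 0.27, 0.716)

    def test_dimensional_round_trip(self):
        """Multiplying the yield back by the photon delivery recovers the
        vial rate (independent unit check)."""
        band, irr, area, rate = 0.21, 0.27, 0.716, 0.83
        qy = quantum_yield(rate, band, irr, area)
        delivery_nmol_h = band * irr * (area * 1e-4) * 3600 * 1e3
        assert qy * delivery_nmol_h == pytest.approx(rate, rel=1e-12)


class TestFullChainOnSyntheticData:
    def test_zero_noise_recovers_per_cell_rate_exactly(self, quiet_config):
        incub = gen_incubation(quiet_config)
        truth = incub.truth["DIC"]
        sub = incub.samples[incub.samples["treatment"] == "DIC"]
        rates = uptake_rate(sub, truth["labeling_fraction"])
        result = derive_uptake(rates, quiet_config.blank_carbon_ug,
                               quiet_config.cell_model)
        assert result.per_cell_rate == pytest.approx(
            truth["true_per_cell_rate"], rel=1e-8
        )
        assert result.cells_per_vial == pytest.approx(
            truth["cells_per_vial"], rel=1e-8
        )

    def test_acetate_rate_recovered_and_much_smaller(self, quiet_config):
        incub = gen_incubation(quiet_config)
        truth = incub.truth["acetate"]
        sub = incub.samples[incub.samples["treatment"] == "acetate"]
        rates = uptake_rate(sub, truth["labeling_fraction"])
        assert rates.light == pytest.approx(
            truth["true_vial_rate_light"], rel=1e-8
        )
        assert rates.light < 0.1 * incub.truth["DIC"]["true_vial_rate_light"]

    def test_scaling_commutes_through_chain(self, quiet_config):
        """Doubling the true per-cell rate doubles both the areal and the
        sulfide-equivalent outputs."""
        results = []
        for scale in (1.0, 2.0):
            cfg = dataclasses.replace(
                quiet_config,
                true_per_cell_rate=quiet_config.true_per_cell_rate * scale,
            )
            incub = gen_incubation(cfg)
            sub = incub.samples[incub.samples["treatment"] == "DIC"]
            rates = uptake_rate(sub, incub.truth["DIC"]["labeling_fraction"])
            results.append(derive_uptake(rates, cfg.blank_carbon_ug,
                                         cfg.cell_model))
        assert results[1].areal_rate == pytest.approx(
            2 * results[0].areal_rate, rel=1e-9
        )
        assert results[1].sulfide_equiv == pytest.approx(
            2 * results[0].sulfide_equiv, rel=1e-9
        )


def test_atom_fraction_ratio_inverse():
    r = np.array([0.0, 0.011, 0.5, 3.0])
    np.testing.assert_allclose(
        ratio_from_atom_fraction(atom_fraction(r)), r, rtol=1e-12
    )
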