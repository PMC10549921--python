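"""Thyroid homeostasis parameter computation (SPINA-GT / SPINA-GD)."""

import numpy as np
import pandas as pd
import pytest

from thyrobmd import (
    DEFAULT_CONSTANTS,
    HormonePanel,
    SpinaCalculator,
    SpinaConstants,
    attach_spina,
    spina_gd,
    spina_gt,
    spina_panel,
)
from thyrobmd.spina import _t3_binding_factor, _t4_binding_factor

import oracles


class TestEquations:
    def test_binding_factors_exact(self):
        assert _t4_binding_factor(DEFAULT_CONSTANTS) == pytest.approx(6901.0, abs=0)
        assert _t3_binding_factor(DEFAULT_CONSTANTS) == pytest.approx(601.0, abs=0)

    def test_median_male_panel_values(self):
        # median male TSH/fT4/fT3: 1.87 mIU/L, 16.84 pmol/L, 4.76 pmol/L
        assert spina_gt(1.87, 16.84) == pytest.approx(3.158, rel=5e-4)
        assert spina_gd(16.84, 4.76) == pytest.approx(26.14, rel=5e-4)

    def test_agrees_with_independent_transcription(self, rng):
        for _ in range(100):
            tsh = rng.uniform(0.27, 4.2)
            ft4 = rng.uniform(12, 22)
            ft3 = rng.uniform(3.1, 6.8)
            assert spina_gt(tsh, ft4) == pytest.approx(
                oracles.spina_gt_direct(tsh, ft4), rel=1e-10
            )
            assert spina_gd(ft4, ft3) == pytest.approx(
                oracles.spina_gd_direct(ft4, ft3), rel=1e-10
            )

    def test_gt_linear_in_ft4_and_decreasing_in_tsh(self, rng):
        for _ in range(20):
            tsh = rng.uniform(0.1, 10)
            ft4 = rng.uniform(1, 40)
            assert spina_gt(tsh, 2 * ft4) == pytest.approx(
                2 * spina_gt(tsh, ft4), rel=1e-12
            )
            assert spina_gt(tsh * 1.5, ft4) < spina_gt(tsh, ft4)

    def test_gd_linear_in_ft3_and_decreasing_in_ft4(self, rng):
        for _ in range(20):
            ft4 = rng.uniform(5, 40)
            ft3 = rng.uniform(1, 10)
            assert spina_gd(ft4, 2 * ft3) == pytest.approx(
                2 * spina_gd(ft4, ft3), rel=1e-12
            )
            assert spina_gd(ft4 * 1.5, ft3) < spina_gd(ft4, ft3)

    def test_gt_saturation_in_tsh(self):
        # gt*tsh/(DT+tsh) approaches a constant as tsh grows
        vals = [
            spina_gt(tsh, 16.0) * tsh / (DEFAULT_CONSTANTS.d_t + tsh)
            for tsh in (1e2, 1e4, 1e6)
        ]
        assert vals[0] == pytest.approx(vals[2], rel=1e-9)

    def test_zero_hormone_gives_zero(self):
        assert spina_gt(1.5, 0.0) == 0.0
        assert spina_gd(16.0, 0.0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            spina_gt(0.0, 16.0)
        with pytest.raises(ValueError):
            spina_gt(-1.0, 16.0)
        with pytest.raises(ValueError):
            spina_gt(1.5, -1.0)
        with pytest.raises(ValueError):
            spina_gd(0.0, 4.0)
        with pytest.raises(ValueError):
            spina_gd(16.0, -1.0)

    def test_central_panels_inside_printed_reference_ranges(self):
        # interquartile hormone grid -> GT within 1.4-8.7 pmol/s,
        # GD within 20-60 nmol/s
        for tsh in np.linspace(1.02, 2.70, 7):
            for ft4 in np.linspace(15.37, 19.09, 7):
                assert 1.4 <= spina_gt(tsh, ft4) <= 8.7
        for ft4 in np.linspace(15.37, 19.09, 7):
            for ft3 in np.linspace(4.295, 5.29, 7):
                assert 20 <= spina_gd(ft4, ft3) <= 60


class TestPanel:
    def test_full_panel(self):
        res = spina_panel(HormonePanel(tsh=1.87, ft4=16.84, ft3=4.76))
        assert res.gt == pytest.approx(3.158, rel=5e-4)
        assert res.gd == pytest.approx(26.14, rel=5e-4)

    @pytest.mark.parametrize(
        "panel, gt_missing, gd_missing",
        [
            (HormonePanel(ft4=16.84, ft3=4.76), True, False),
            (HormonePanel(tsh=1.87, ft3=4.76), True, True),
            (HormonePanel(tsh=1.87, ft4=16.84), False, True),
            (HormonePanel(), True, True),
            (HormonePanel(tsh=1.87, ft4=0.0, ft3=4.76), False, True),
        ],
    )
    def test_missingness_propagates(self, panel, gt_missing, gd_missing):
        res = spina_panel(panel)
        assert (res.gt is None) == gt_missing
        assert (res.gd is None) == gd_missing

    def test_negative_hormone_rejected(self):
        with pytest.raises(ValueError):
            HormonePanel(tsh=-0.1)


class TestConstants:
    def test_defaults_positive_and_overridable(self):
        c = DEFAULT_CONSTANTS.replace(d_t=3.0)
        assert c.d_t == 3.0 and DEFAULT_CONSTANTS.d_t == 2.75

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            SpinaConstants(alpha_t=0.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            SpinaConstants.from_dict({"alpha_t": 0.1, "bogus": 1.0})

    def test_beta_corr_carried_but_inert(self):
        # beta_corr is documented as unused by the two equations
        altered = DEFAULT_CONSTANTS.replace(beta_corr=99.0)
        assert spina_gt(1.87, 16.84, altered) == spina_gt(1.87, 16.84)
        assert spina_gd(16.84, 4.76, altered) == spina_gd(16.84, 4.76)


class TestFrameInterface:
    def test_attach_spina_handles_missing_rows(self):
        frame = pd.DataFrame(
            {
                "tsh": [1.87, np.nan, 2.0, 0.0],
                "ft4": [16.84, 16.0, np.nan, 15.0],
                "ft3": [4.76, 4.0, 4.5, np.nan],
            }
        )
        out = attach_spina(frame)
        assert out["spina_gt"].notna().tolist() == [True, False, False, False]
        assert out["spina_gd"].notna().tolist() == [True, True, False, False]
        assert out.loc[0, "spina_gt"] == pytest.approx(3.158, rel=5e-4)

    def test_transformer_roundtrip_and_params(self):
        frame = pd.DataFrame({"tsh": [1.8], "ft4": [16.0], "ft3": [4.5]})
        calc = SpinaCalculator()
        out = calc.fit_transform(frame)
        assert {"spina_gt", "spina_gd"} <= set(out.columns)
        # sklearn param interface
        assert "constants" in calc.get_params()

    def test_transformer_requires_hormone_columns(self):
        with pytest.raises(ValueError):
            SpinaCalculator().fit(pd.DataFrame({"tsh": [1.0]}))
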