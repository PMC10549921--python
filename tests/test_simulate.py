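"""Synthetic cohort generator: calibration, reproducibility, links."""

import numpy as np
import pytest

from thyrobmd import (
    DoseSpec,
    LinkSpec,
    LognormalSpec,
    NormalSpec,
    SyntheticConfig,
    generate_cohort,
    generate_quantal,
)
from thyrobmd.constants import REFERENCE_RANGES
from thyrobmd.families import get_family


class TestMarginalSpecs:
    def test_lognormal_quartile_parameterization(self):
        spec = LognormalSpec(median=8.278, p25=2.902, p75=14.20)
        dist = spec.frozen()
        assert dist.median() == pytest.approx(8.278, rel=1e-9)
        # quartile ratio is honoured exactly by the two-parameter family
        q25, q75 = dist.ppf([0.25, 0.75])
        assert q75 / q25 == pytest.approx(14.20 / 2.902, rel=1e-9)

    def test_invalid_quartile_order_rejected(self):
        with pytest.raises(ValueError):
            LognormalSpec(median=5.0, p25=6.0, p75=7.0)
        with pytest.raises(ValueError):
            NormalSpec(median=5.0, p25=5.0, p75=4.0)

    def test_normal_spec_truncated_at_zero(self):
        spec = NormalSpec(median=15.63, p25=5.718, p75=18.46)
        samples = spec.frozen().rvs(size=2000, random_state=1)
        assert (samples > 0).all()


class TestGenerateCohort:
    def test_reproducible_and_seed_sensitive(self):
        config = SyntheticConfig(n_male=40, n_female=40)
        a = generate_cohort(config, seed=5)
        b = generate_cohort(config, seed=5)
        c = generate_cohort(config, seed=6)
        assert a.equals(b)
        assert not a.equals(c)

    def test_structure_and_bounds(self):
        config = SyntheticConfig(n_male=30, n_female=20)
        cohort = generate_cohort(config, seed=1)
        assert len(cohort) == 50
        assert (cohort["sex"] == "M").sum() == 30
        assert cohort["ni"].gt(0).all()
        assert cohort["age"].between(18, 94).all()
        assert set(cohort["group"]) <= {"healthy", "unhealthy"}
        assert cohort["id"].is_unique

    def test_quartile_calibration_at_large_n(self):
        config = SyntheticConfig(n_male=10000, n_female=0, missingness={})
        cohort = generate_cohort(config, seed=2)
        ni = cohort["ni"]
        assert ni.median() == pytest.approx(8.278, rel=0.05)
        q25, q75 = ni.quantile([0.25, 0.75])
        assert q75 / q25 == pytest.approx(14.20 / 2.902, rel=0.05)
        # hormone marginal: median of male fT4 target
        assert cohort["ft4"].median() == pytest.approx(16.84, rel=0.05)

    def test_no_missingness_when_disabled(self):
        config = SyntheticConfig(n_male=50, n_female=50, missingness={})
        cohort = generate_cohort(config, seed=3)
        assert not cohort[["tsh", "ft4", "ft3", "t4", "t3"]].isna().any().any()

    def test_default_missingness_rates_near_targets(self):
        config = SyntheticConfig(n_male=5000, n_female=0)
        cohort = generate_cohort(config, seed=4)
        assert cohort["ft4"].isna().mean() == pytest.approx(32 / 217, abs=0.02)

    def test_link_induces_monotone_outlier_fraction(self):
        link = LinkSpec(endpoint="ft3", background=0.05, bmd=3.0)
        config = SyntheticConfig(
            n_male=4000, n_female=0, missingness={}, links=(link,)
        )
        cohort = generate_cohort(config, seed=6)
        low, high = REFERENCE_RANGES["ft3"]
        out = ((cohort["ft3"] < low) | (cohort["ft3"] > high)).to_numpy(float)
        deciles = np.array_split(out[np.argsort(cohort["ni"].to_numpy())], 10)
        rates = [chunk.mean() for chunk in deciles]
        assert rates[-1] > rates[0] + 0.2
        # first and last decile bracket the configured background/saturation
        assert rates[0] < 0.15

    def test_link_values_consistent_with_indicators(self):
        # the continuous draw must land in the region its indicator says
        link = LinkSpec(endpoint="t3", background=0.5, bmd=1.0)
        config = SyntheticConfig(n_male=500, n_female=0, missingness={},
                                 links=(link,))
        cohort = generate_cohort(config, seed=7)
        low, high = REFERENCE_RANGES["t3"]
        out_frac = (~cohort["t3"].between(low, high)).mean()
        # high background + low BMD: most subjects outside the range
        assert out_frac > 0.5

    def test_link_rejected_on_derived_endpoint(self):
        with pytest.raises(ValueError):
            LinkSpec(endpoint="spina_gt")

    def test_invalid_missingness_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(missingness={"M": {"tsh": 1.0}})


class TestGenerateQuantal:
    @pytest.mark.parametrize("family", ["log_logistic", "log_probit", "weibull"])
    def test_link_true_bmd_closed_form(self, family):
        link = LinkSpec(endpoint="ft3", family=family, background=0.05,
                        bmd=5.0, bmr=0.10)
        # at the true BMD, extra risk equals the configured BMR
        p = float(link.prob(5.0))
        assert p == pytest.approx(0.05 + 0.10 * 0.95, abs=1e-9)

    def test_outcome_rate_matches_model_mean(self):
        link = LinkSpec(endpoint="ft3", background=0.05, bmd=5.0)
        d, y = generate_quantal(8000, DoseSpec(), link=link, seed=9)
        expected = get_family(link.family).prob(link.params, d).mean()
        assert y.mean() == pytest.approx(expected, abs=0.02)

    def test_flat_curve_rate(self):
        d, y = generate_quantal(
            5000, DoseSpec(kind="log_uniform", low=0.1, high=10),
            family="background", params=[0.3], seed=10,
        )
        assert y.mean() == pytest.approx(0.3, abs=0.03)

    def test_reproducible(self):
        link = LinkSpec(endpoint="ft3", bmd=5.0)
        d1, y1 = generate_quantal(100, DoseSpec(), link=link, seed=11)
        d2, y2 = generate_quantal(100, DoseSpec(), link=link, seed=11)
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_array_equal(y1, y2)

    def test_requires_params_or_link(self):
        with pytest.raises(ValueError):
            generate_quantal(10, DoseSpec(), seed=1)
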