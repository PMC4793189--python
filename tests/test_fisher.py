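"""Fisher z machinery and the end-to-end percentage-change test."""

import math

import numpy as np
import pytest

from pctchange import (
    GeneratorSpec,
    NullBasis,
    conventional_test,
    fisher_z,
    fisher_z_test,
    generate_paired_sample,
)
from pctchange import test_from_summary as from_summary
from pctchange import test_percentage_change as pct_change_test


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_value(self):
        assert fisher_z(0.63) == pytest.approx(math.atanh(0.63))
        assert fisher_z(0.63) == pytest.approx(0.7414, abs=5e-5)

    def test_odd_symmetry(self):
        assert fisher_z(-0.354) == pytest.approx(-fisher_z(0.354))

    @pytest.mark.parametrize("r", [-1.0, 1.0, 1.5])
    def test_domain_error(self, r):
        with pytest.raises(ValueError):
            fisher_z(r)


class TestFisherZTest:
    def test_periodontal_example_statistics(self):
        """Observed 0.354 vs null 0.63 at n = 47: z about -2.46, P 0.014."""
        rho0 = math.sqrt((1 - 0.207) / 2)
        z, p = fisher_z_test(0.354, rho0, 47)
        assert z == pytest.approx(-2.46, abs=0.01)
        assert p == pytest.approx(0.014, abs=0.001)

    def test_cd4_example_statistics(self):
        """Observed 0.711 vs null 0.508 at n = 100: z about 3.24, P 0.001."""
        rho0 = math.sqrt((1 - 0.484) / 2)
        z, p = fisher_z_test(0.711, rho0, 100)
        assert z == pytest.approx(3.24, abs=0.01)
        assert p == pytest.approx(0.001, abs=0.0005)

    def test_null_equals_observed_gives_unit_p(self):
        z, p = fisher_z_test(0.5, 0.5, 30)
        assert z == 0.0
        assert p == 1.0

    def test_antisymmetry_in_arguments(self):
        z1, _ = fisher_z_test(0.3, 0.6, 50)
        z2, _ = fisher_z_test(0.6, 0.3, 50)
        assert z1 == pytest.approx(-z2)

    def test_z_grows_with_n(self):
        zs = [abs(fisher_z_test(0.3, 0.6, n)[0]) for n in (10, 50, 200, 1000)]
        assert zs == sorted(zs)

    def test_p_monotone_in_abs_z_and_matches_one_sided_doubling(self):
        from scipy import stats
        z, p = fisher_z_test(0.3, 0.6, 50)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)))
        _, p_weak = fisher_z_test(0.35, 0.6, 50)
        assert p_weak > p

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="insufficient|n >= 4"):
            fisher_z_test(0.3, 0.5, 3)


class TestSummaryInterface:
    def test_example1_both_methods(self):
        appr = from_summary(0.354, 0.207, 47)
        conv = from_summary(0.354, 0.207, 47, method="conventional")
        # both reject at the 5% level but with opposite readings
        assert appr.reject and conv.reject
        assert appr.z_stat < 0 < conv.z_stat
        assert "less percentage change" in appr.direction
        assert "greater percentage change" in conv.direction
        assert conv.p_two_sided == pytest.approx(0.015, abs=0.002)
        assert conv.null.basis is NullBasis.CONVENTIONAL_ZERO

    def test_example2_both_methods(self):
        appr = from_summary(0.711, 0.484, 100)
        conv = from_summary(0.711, 0.484, 100, method="conventional")
        assert appr.p_two_sided == pytest.approx(0.001, abs=0.0005)
        assert conv.p_two_sided < 0.001
        assert appr.z_stat > 0

    def test_zero_observed_conventional(self):
        res = from_summary(0.0, 0.3, 50, method="conventional")
        assert res.z_stat == 0.0
        assert res.p_two_sided == 1.0
        assert not res.reject

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            from_summary(0.3, 0.2, 30, method="bayes")


class TestEndToEnd:
    def test_proportional_sample_short_circuits(self, bp_prop):
        res = pct_change_test(bp_prop)
        assert res.proportional
        assert not res.reject
        assert res.r_obs is None
        assert "proportionality" in res.direction
        conv = conventional_test(bp_prop)
        assert conv.proportional and not conv.reject

    def test_heterogeneous_toy_runs_fully(self, bp_het):
        res = pct_change_test(bp_het)
        assert not res.proportional
        assert res.k == pytest.approx(1.9, abs=0.05)
        assert res.null.basis is NullBasis.APPROPRIATE_K1
        assert 0.0 <= res.p_two_sided <= 1.0
        assert res.reject == (res.p_two_sided < res.alpha)

    def test_rho0_override(self, bp_het):
        res = pct_change_test(bp_het, rho0_override=0.2)
        assert res.null.rho0 == 0.2

    @pytest.mark.parametrize("r_xy,seed0", [(0.207, 0), (0.99, 10_000)])
    def test_null_calibration_under_h0(self, r_xy, seed0):
        """Under the exact k = 1 null the appropriate test is never
        anti-conservative, and reaches the nominal 5% as the pre/post
        correlation approaches 1 (the regime of error-free repeated
        measurements).  At moderate r_xy it is conservative: rho0 is
        derived from the sample r_xy, which co-varies with the observed
        coupled correlation and absorbs part of its sampling noise."""
        reps = 2000
        rejections = 0
        for i in range(reps):
            sample = generate_paired_sample(GeneratorSpec(
                n=100, target_r_xy=r_xy, target_k=1.0, seed=seed0 + i))
            if pct_change_test(sample, alpha=0.05).reject:
                rejections += 1
        rate = rejections / reps
        # 3 binomial SEs around 0.05 at 2000 reps is about +-0.015
        assert rate <= 0.05 + 0.015
        if r_xy > 0.9:
            assert rate == pytest.approx(0.05, abs=0.015)
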