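"""MR estimator correctness against closed forms and independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from lipomr import mr_core, synthetic
from lipomr.containers import ConfigurationError, DataError, LDMatrix

from conftest import make_panel


class TestWaldRatio:
    def test_direct_division(self):
        est = mr_core.wald_ratio(bx=0.2, sex=0.01, by=0.1, sey=0.05)
        assert est.theta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.25)
        assert est.ci_low < est.theta < est.ci_high

    def test_null_numerator(self):
        est = mr_core.wald_ratio(bx=0.2, sex=0.01, by=0.0, sey=1.0)
        assert est.theta == 0.0 and est.pvalue == pytest.approx(1.0)

    def test_zero_denominator_errors(self):
        with pytest.raises(DataError):
            mr_core.wald_ratio(bx=0.0, sex=0.01, by=0.1, sey=0.05)


def _random_panel(rng, J=5, theta=0.4):
    bx = rng.normal(0.1, 0.04, size=J)
    sey = rng.uniform(0.02, 0.1, size=J)
    by = theta * bx + rng.normal(0, sey)
    return make_panel(bx, 0.01, by, sey)


class TestIVW:
    def test_single_variant_reduces_to_wald(self):
        panel = make_panel([0.2], 0.01, [0.1], [0.05])
        est = mr_core.ivw(panel, effects="fixed")
        wald = mr_core.wald_ratio(0.2, 0.01, 0.1, 0.05)
        assert est.theta == pytest.approx(wald.theta)
        assert est.se == pytest.approx(wald.se)

    def test_identity_ld_matches_textbook_formula(self, rng):
        panel = _random_panel(rng, J=5)
        bx, by, sey = panel.bX[:, 0], panel.bY, panel.seY
        theta_ref = np.sum(bx * by / sey**2) / np.sum(bx**2 / sey**2)
        se_ref = 1.0 / np.sqrt(np.sum(bx**2 / sey**2))
        est = mr_core.ivw(panel, effects="fixed")
        assert est.theta == pytest.approx(theta_ref, abs=1e-12)
        assert est.se == pytest.approx(se_ref, abs=1e-12)

    def test_explicit_identity_ld_equals_no_ld(self, rng):
        panel = _random_panel(rng, J=7)
        ld = LDMatrix.identity(panel.variant_ids)
        e1 = mr_core.ivw(panel, ld=None, effects="fixed")
        e2 = mr_core.ivw(panel, ld=ld, effects="fixed")
        assert e1.theta == pytest.approx(e2.theta, abs=1e-10)
        assert e1.se == pytest.approx(e2.se, abs=1e-10)

    def test_gls_matches_statsmodels_oracle(self, rng):
        """With correlated instruments, GLS-IVW equals an independent
        generalized-least-squares fit of bY on bX through the origin."""
        J = 6
        panel = _random_panel(rng, J=J)
        A = rng.normal(size=(J, J + 3))
        R = np.corrcoef(A)
        ld = LDMatrix(panel.variant_ids, R)
        omega = ld.r * np.outer(panel.seY, panel.seY)
        oracle = sm.GLS(panel.bY, panel.bX, sigma=omega).fit()
        est = mr_core.ivw(panel, ld=ld, effects="fixed")
        assert est.theta == pytest.approx(oracle.params[0], abs=1e-10)
        # statsmodels scales the coefficient covariance by the estimated
        # residual variance; fixed-effects IVW fixes it at 1
        se_unit_scale = oracle.bse[0] / np.sqrt(oracle.scale)
        assert est.se == pytest.approx(se_unit_scale, abs=1e-10)

    def test_duplicated_variant_with_unit_correlation_is_redundant(self, rng):
        """A variant duplicated with r = 1 (ridged to PSD) adds no
        information: the estimate matches the single-copy panel."""
        panel = _random_panel(rng, J=4)
        dup = make_panel(
            np.r_[panel.bX[:, 0], panel.bX[0, 0]], 0.01,
            np.r_[panel.bY, panel.bY[0]], np.r_[panel.seY, panel.seY[0]],
        )
        R = np.eye(5)
        R[0, 4] = R[4, 0] = 1.0
        ld = LDMatrix(dup.variant_ids, R)  # load-time ridge makes it PSD
        e_single = mr_core.ivw(panel, effects="fixed")
        e_dup = mr_core.ivw(dup, ld=ld, effects="fixed")
        assert e_dup.theta == pytest.approx(e_single.theta, rel=1e-3)

    def test_random_effects_se_at_least_fixed(self, rng):
        for _ in range(10):
            panel = _random_panel(rng, J=8)
            ef = mr_core.ivw(panel, effects="fixed")
            er = mr_core.ivw(panel, effects="random")
            assert er.se >= ef.se
            assert er.theta == pytest.approx(ef.theta)

    def test_scale_equivariance(self, rng):
        panel = _random_panel(rng, J=6)
        c = 2.5
        scaled = make_panel(panel.bX * c, panel.seX * c, panel.bY, panel.seY)
        assert mr_core.ivw(scaled, effects="fixed").theta == pytest.approx(
            mr_core.ivw(panel, effects="fixed").theta / c
        )

    def test_sign_equivariance(self, rng):
        panel = _random_panel(rng, J=6)
        neg = make_panel(panel.bX, panel.seX, -panel.bY, panel.seY)
        assert mr_core.ivw(neg, effects="fixed").theta == pytest.approx(
            -mr_core.ivw(panel, effects="fixed").theta
        )

    def test_random_effects_needs_two_variants(self):
        panel = make_panel([0.2], 0.01, [0.1], [0.05])
        with pytest.raises(ConfigurationError):
            mr_core.ivw(panel, effects="random")


class TestEgger:
    def _oriented_panel(self, rng, J=30, theta=0.4, c=0.0):
        bx = np.abs(rng.normal(0.1, 0.04, size=J))
        sey = np.full(J, 0.02)
        by = theta * bx + c + rng.normal(0, sey)
        return make_panel(bx, 0.01, by, sey)

    def test_no_pleiotropy_intercept_near_zero(self, rng):
        panel = self._oriented_panel(rng)
        est = mr_core.mr_egger(panel)
        assert abs(est.egger_intercept) < 3 * est.egger_intercept_se

    def test_constant_pleiotropy_shifts_intercept_not_slope(self, rng):
        """Adding a constant c to every outcome association moves the Egger
        intercept by exactly c and leaves the slope unchanged."""
        rng2 = np.random.default_rng(7)
        bx = np.abs(rng2.normal(0.1, 0.04, size=25))
        sey = np.full(25, 0.02)
        by = 0.4 * bx + rng2.normal(0, sey)
        c = 0.02
        clean = mr_core.mr_egger(make_panel(bx, 0.01, by, sey))
        shifted = mr_core.mr_egger(make_panel(bx, 0.01, by + c, sey))
        assert shifted.egger_intercept - clean.egger_intercept == pytest.approx(c, abs=1e-12)
        assert shifted.theta == pytest.approx(clean.theta, abs=1e-12)

    def test_collinear_design_is_degenerate(self):
        panel = make_panel([0.1, 0.1, 0.1], 0.01, [0.1, 0.2, 0.3], [0.05] * 3)
        with pytest.raises(DataError):
            mr_core.mr_egger(panel)

    def test_requires_three_variants(self):
        panel = make_panel([0.1, 0.2], 0.01, [0.1, 0.2], [0.05] * 2)
        with pytest.raises(ConfigurationError):
            mr_core.mr_egger(panel)

    def test_orientation_invariance(self, rng):
        """Flipping the allele coding of any row (bx and by jointly) does
        not change the Egger fit."""
        panel = self._oriented_panel(rng, J=12)
        flip = np.where(rng.random(12) < 0.5, -1.0, 1.0)
        flipped = make_panel(panel.bX * flip[:, None], panel.seX,
                             panel.bY * flip, panel.seY)
        e1, e2 = mr_core.mr_egger(panel), mr_core.mr_egger(flipped)
        assert e1.theta == pytest.approx(e2.theta, abs=1e-12)
        assert e1.egger_intercept == pytest.approx(e2.egger_intercept, abs=1e-12)


class TestMVMR:
    def test_k1_reduces_to_ivw(self, rng):
        panel = _random_panel(rng, J=6)
        mv = mr_core.mvmr(panel, effects="fixed")
        assert len(mv) == 1
        assert mv[0].theta == pytest.approx(mr_core.ivw(panel, effects="fixed").theta)

    def test_zero_column_flagged_infinite_variance(self, rng):
        J = 10
        bx = np.column_stack([rng.normal(0.1, 0.03, J), np.zeros(J)])
        panel = make_panel(bx, 0.01, rng.normal(0, 0.05, J), np.full(J, 0.05))
        mv = mr_core.mvmr(panel)
        assert mv[1].theta == 0.0 and np.isinf(mv[1].se) and mv[1].degenerate

    def test_parameter_recovery_two_exposures(self):
        """theta = (0.5, 0) at high instrument strength: both direct effects
        recovered within 3 SE."""
        cfg = synthetic.SyntheticConfig(
            exposures=["E1", "E2"], n_latent_factors=2,
            causal_set={"E1": 0.5}, seed=42,
        )
        panel, _, truth = synthetic.simulate_panel(cfg)
        mv = mr_core.mvmr(panel, effects="fixed")
        for est, true in zip(mv, truth.theta_true):
            assert abs(est.theta - true) < 3 * est.se

    def test_collinear_exposures_error_names_pair(self, rng):
        J = 10
        x = rng.normal(0.1, 0.03, J)
        bx = np.column_stack([x, x * 1.0000001])
        panel = make_panel(bx, 0.01, rng.normal(0, 0.05, J), np.full(J, 0.05),
                           exposures=["A", "B"])
        with pytest.raises(DataError, match="A.*B"):
            mr_core.mvmr(panel)

    def test_requires_more_variants_than_exposures(self, rng):
        bx = rng.normal(0.1, 0.03, size=(2, 2))
        panel = make_panel(bx, 0.01, [0.1, 0.2], [0.05, 0.05])
        with pytest.raises(ConfigurationError):
            mr_core.mvmr(panel)


class TestAlgebraicProperties:
    """Estimator identities over hypothesis-generated panels."""

    from hypothesis import given, settings, strategies as st

    @given(
        theta=st.floats(-2, 2),
        c=st.floats(0.1, 10),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_joint_scale_and_sign_equivariance(self, theta, c, seed):
        r = np.random.default_rng(seed)
        J = 6
        bx = r.normal(0.1, 0.05, J)
        bx[np.abs(bx) < 1e-3] = 1e-3
        sey = r.uniform(0.02, 0.1, J)
        by = theta * bx + r.normal(0, sey)
        base = mr_core.ivw(make_panel(bx, 0.01, by, sey), effects="fixed")
        scaled = mr_core.ivw(make_panel(bx * c, 0.01 * c, -by, sey), effects="fixed")
        assert scaled.theta == pytest.approx(-base.theta / c, rel=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_wald_ratio_is_ivw_fixed_at_j1(self, seed):
        r = np.random.default_rng(seed)
        bx = float(r.normal(0.2, 0.05)) or 0.1
        by, sey = float(r.normal()), float(r.uniform(0.01, 1))
        est = mr_core.ivw(make_panel([bx], 0.01, [by], [sey]), effects="fixed")
        wald = mr_core.wald_ratio(bx, 0.01, by, sey)
        assert est.theta == pytest.approx(wald.theta)
        assert est.se == pytest.approx(wald.se)
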