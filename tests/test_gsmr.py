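"""GSMR estimator: ratio estimates, V matrix, GLS, comparators, helpers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gsmrkit import (
    GsmrOptions,
    LDMatrix,
    SimConfig,
    aggregate_effect,
    bonferroni_threshold,
    build_V,
    bxy_per_snp,
    estimate_egger,
    estimate_ivw,
    gls_estimate,
    harmonized_from_truth,
    ld_matrix_from_config,
    logor_to_or,
    make_truth,
    or_to_logor,
    run_bidirectional,
    run_gsmr,
    sample_sumstats_direct,
)
from gsmrkit.gsmr import GsmrError, InsufficientInstrumentsError
from gsmrkit.sumstats import HarmonizedInstrumentSet

from conftest import make_dataset


def make_inst(bzx, se_zx, bzy, se_zy, snp_ids=None, p_zx=None):
    import pandas as pd

    m = len(bzx)
    snp_ids = snp_ids or [f"rs{i + 1}" for i in range(m)]
    bzx = np.asarray(bzx, float)
    se_zx = np.asarray(se_zx, float)
    if p_zx is None:
        p_zx = 2 * stats.norm.sf(np.abs(bzx / se_zx))
    tbl = pd.DataFrame(
        {
            "snp_id": snp_ids, "chrom": "1", "bp": range(1, m + 1),
            "effect_allele": "A", "eaf": 0.3,
            "bzx": bzx, "se_bzx": se_zx, "p_zx": p_zx,
            "bzy": np.asarray(bzy, float), "se_bzy": np.asarray(se_zy, float),
            "p_zy": 0.5, "n_x": 50000.0, "n_y": 50000.0,
        }
    )
    return HarmonizedInstrumentSet(tbl)


def diag_var_literal(bzx, se_zx, bzy, se_zy):
    """The literal diagonal-V factorization (undefined at bzy = 0)."""
    bxy = bzy / bzx
    return bxy**2 * (se_zx**2 / bzx**2 + se_zy**2 / bzy**2 - se_zx**4 / bzx**4)


def offdiag_literal(bzx_i, se_zx_i, bzx_j, se_zx_j, se_zy_i, se_zy_j, bxy_i, bxy_j, r):
    """Term-by-term evaluation of the off-diagonal covariance formula."""
    t1 = r * math.sqrt(se_zy_i**2 * se_zy_j**2) / (bzx_i * bzx_j)
    t2 = bxy_i * bxy_j * (
        r * math.sqrt(se_zx_i**2 * se_zx_j**2) / (bzx_i * bzx_j)
        - (se_zx_i**2 * se_zx_j**2) / (bzx_i**2 * bzx_j**2)
    )
    return t1 + t2


class TestBxyPerSnp:
    def test_worked_example(self):
        inst = make_inst([0.1], [0.01], [0.05], [0.01])
        est = bxy_per_snp(inst)
        assert est.bxy[0] == pytest.approx(0.5)
        assert est.var_bxy[0] == pytest.approx(0.012475)

    def test_zero_numerator_stable_form(self):
        inst = make_inst([0.1], [0.01], [0.0], [0.01])
        est = bxy_per_snp(inst)
        assert est.bxy[0] == 0.0
        assert est.var_bxy[0] == pytest.approx(0.01**2 / 0.1**2)

    def test_scale_equivariance_of_outcome(self):
        inst1 = make_inst([0.1], [0.0001], [0.05], [0.01])
        inst2 = make_inst([0.1], [0.0001], [0.05 * 3], [0.01 * 3])
        e1, e2 = bxy_per_snp(inst1), bxy_per_snp(inst2)
        assert e2.bxy[0] == pytest.approx(3 * e1.bxy[0])
        # se_zx ~ 0, so sqrt(var) scales with |c| to first order
        assert math.sqrt(e2.var_bxy[0]) == pytest.approx(3 * math.sqrt(e1.var_bxy[0]), rel=1e-3)

    def test_zero_bzx_is_degenerate(self):
        inst = make_inst([0.0], [0.01], [0.05], [0.01], snp_ids=["rsBad"])
        with pytest.raises(GsmrError, match="rsBad"):
            bxy_per_snp(inst)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        bzx=st.floats(0.02, 1.0), se_zx=st.floats(1e-4, 0.003),
        bzy=st.floats(-0.5, 0.5), se_zy=st.floats(1e-4, 0.1),
    )
    def test_stable_form_equals_literal_factorization(self, bzx, se_zx, bzy, se_zy):
        if abs(bzy) < 1e-6:
            bzy = 0.1
        est = bxy_per_snp(make_inst([bzx], [se_zx], [bzy], [se_zy]))
        assert est.var_bxy[0] == pytest.approx(
            diag_var_literal(bzx, se_zx, bzy, se_zy), rel=1e-9
        )


class TestBuildV:
    def test_singleton(self):
        inst = make_inst([0.1], [0.01], [0.05], [0.01])
        est = bxy_per_snp(inst)
        V = build_V(inst, est, None)
        assert V.shape == (1, 1)
        assert V[0, 0] == pytest.approx(est.var_bxy[0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        bzx=st.floats(0.05, 1.0), se_zx=st.floats(1e-4, 0.005),
        bzy=st.floats(-0.5, 0.5).filter(lambda v: abs(v) > 1e-3),
        se_zy=st.floats(1e-4, 0.1),
    )
    def test_offdiagonal_reduces_to_diagonal_at_self_pair(self, bzx, se_zx, bzy, se_zy):
        """Setting i = j and r = 1 in the covariance reproduces the variance."""
        bxy = bzy / bzx
        off = offdiag_literal(bzx, se_zx, bzx, se_zx, se_zy, se_zy, bxy, bxy, 1.0)
        assert off == pytest.approx(diag_var_literal(bzx, se_zx, bzy, se_zy), rel=1e-9)

    def test_two_snp_term_by_term_oracle(self):
        bzx = [0.12, 0.07]
        se_zx = [0.008, 0.009]
        bzy = [0.05, 0.02]
        se_zy = [0.01, 0.012]
        r = 0.2
        inst = make_inst(bzx, se_zx, bzy, se_zy)
        est = bxy_per_snp(inst)
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, r], [r, 1.0]]))
        V = build_V(inst, est, ld)
        expected = offdiag_literal(
            bzx[0], se_zx[0], bzx[1], se_zx[1], se_zy[0], se_zy[1],
            bzy[0] / bzx[0], bzy[1] / bzx[1], r,
        )
        assert V[0, 1] == pytest.approx(expected, rel=1e-12)
        assert V[1, 0] == V[0, 1]
        np.testing.assert_allclose(np.diag(V), est.var_bxy)

    def test_near_singular_condition_reported(self):
        inst = make_inst([0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.01, 0.01])
        est = bxy_per_snp(inst)
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.999999], [0.999999, 1.0]]))
        with pytest.raises(GsmrError, match="condition"):
            build_V(inst, est, ld, condition_limit=1e6)


class TestGlsEstimate:
    def test_single_snp_reduces_to_ratio(self):
        inst = make_inst([0.1], [0.01], [0.05], [0.01])
        est = bxy_per_snp(inst)
        V = build_V(inst, est, None)
        b, se, chi2, p = gls_estimate(est, V)
        assert b == pytest.approx(0.5)
        assert se == pytest.approx(math.sqrt(0.012475))

    def test_diagonal_oracle(self):
        from gsmrkit.gsmr import BxyEstimates

        est = BxyEstimates(["a", "b"], np.array([0.2, 0.4]), np.array([0.01, 0.04]))
        b, se, chi2, p = gls_estimate(est, np.diag(est.var_bxy))
        assert b == pytest.approx(0.24)
        assert se == pytest.approx(1 / math.sqrt(125))
        assert chi2 == pytest.approx(7.2)
        assert p == pytest.approx(stats.chi2.sf(7.2, 1))

    def test_diagonal_equals_inverse_variance_mean(self, rng):
        from gsmrkit.gsmr import BxyEstimates

        for _ in range(50):
            m = int(rng.integers(1, 20))
            bxy = rng.normal(0, 1, m)
            var = rng.uniform(0.01, 2.0, m)
            est = BxyEstimates([f"s{i}" for i in range(m)], bxy, var)
            b, se, chi2, p = gls_estimate(est, np.diag(var))
            w = 1 / var
            assert b == pytest.approx(np.sum(w * bxy) / np.sum(w), rel=1e-10)
            assert se == pytest.approx(1 / math.sqrt(np.sum(w)), rel=1e-10)

    def test_constant_ratios_returned_unchanged(self, rng):
        from gsmrkit.gsmr import BxyEstimates

        m = 6
        A = rng.normal(size=(m, m))
        V = A @ A.T + m * np.eye(m)
        est = BxyEstimates([f"s{i}" for i in range(m)], np.full(m, 0.37), np.diag(V))
        b, *_ = gls_estimate(est, V)
        assert b == pytest.approx(0.37, rel=1e-10)

    def test_chi2_matches_ratio_of_estimate_to_se(self):
        from gsmrkit.gsmr import BxyEstimates

        est = BxyEstimates(["a", "b"], np.array([0.1, 0.3]), np.array([0.02, 0.05]))
        b, se, chi2, p = gls_estimate(est, np.diag(est.var_bxy))
        assert chi2 == pytest.approx((b / se) ** 2)

    def test_indefinite_v_rejected(self):
        from gsmrkit.gsmr import BxyEstimates

        est = BxyEstimates(["a", "b"], np.array([0.1, 0.3]), np.array([1.0, 1.0]))
        V = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(GsmrError):
            gls_estimate(est, V)


class TestInterpretation:
    def test_logor_identity_and_worked_examples(self):
        assert logor_to_or(0.0) == 1.0
        assert logor_to_or(0.41) == pytest.approx(1.51, abs=0.005)
        assert logor_to_or(-0.21) == pytest.approx(0.81, abs=0.005)
        assert or_to_logor(logor_to_or(0.3)) == pytest.approx(0.3)

    def test_aggregate_effect_examples(self):
        assert aggregate_effect([0.5, -0.5], [0.0, 0.0]) == 1.0
        assert aggregate_effect([1.01, -0.17], [1, 1]) == pytest.approx(2.3, abs=0.05)
        assert aggregate_effect([0.41, 0.47, 0.14, 0.48], [1, 1, 1, 1]) == pytest.approx(
            4.5, abs=0.05
        )
        with pytest.raises(GsmrError):
            aggregate_effect([0.1, 0.2], [1.0])

    def test_bonferroni_thresholds(self):
        assert bonferroni_threshold(0.05, 231) == pytest.approx(2.2e-4, rel=0.05)
        assert bonferroni_threshold(0.05, 66) == pytest.approx(7.6e-4, rel=0.05)
        assert bonferroni_threshold(0.05, 42) == pytest.approx(1.2e-3, rel=0.05)
        assert bonferroni_threshold(0.05, 1) == 0.05
        with pytest.raises(GsmrError):
            bonferroni_threshold(1.5, 10)
        with pytest.raises(GsmrError):
            bonferroni_threshold(0.05, 0)


class TestComparators:
    def test_exact_line_through_origin(self):
        inst = make_inst([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.01, 0.02])
        b, se, p = estimate_ivw(inst)
        assert b == pytest.approx(0.5, rel=1e-10)

    def test_normal_equations_oracle(self, rng):
        m = 5
        bzx = rng.uniform(0.05, 0.3, m) * rng.choice([-1, 1], m)
        se_zx = rng.uniform(0.005, 0.02, m)
        bzy = rng.normal(0.02, 0.05, m)
        se_zy = rng.uniform(0.005, 0.03, m)
        inst = make_inst(bzx, se_zx, bzy, se_zy)
        # orientation: flip so bzx > 0
        sign = np.where(bzx < 0, -1.0, 1.0)
        x, y, w = sign * bzx, sign * bzy, 1 / se_zy**2
        # IVW: zero-intercept weighted LS, fixed-effect SE
        slope_ivw = np.sum(w * x * y) / np.sum(w * x * x)
        se_ivw = 1 / math.sqrt(np.sum(w * x * x))
        b, se, p = estimate_ivw(inst)
        assert b == pytest.approx(slope_ivw, rel=1e-10)
        assert se == pytest.approx(se_ivw, rel=1e-10)
        # Egger: weighted LS with intercept via normal equations
        X = np.column_stack([np.ones(m), x])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        slope, slope_se, intercept, intercept_p = estimate_egger(inst)
        assert intercept == pytest.approx(beta[0], rel=1e-8)
        assert slope == pytest.approx(beta[1], rel=1e-8)

    def test_insufficient_instruments(self):
        inst1 = make_inst([0.1], [0.01], [0.05], [0.01])
        with pytest.raises(GsmrError):
            estimate_ivw(inst1)
        inst2 = make_inst([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(GsmrError):
            estimate_egger(inst2)

    def test_egger_intercept_calibrated_without_pleiotropy(self):
        """With no pleiotropy the Egger intercept is null ~95% of the time."""
        hits = 0
        reps = 100
        for k in range(reps):
            cfg = SimConfig(m=40, b_xy_true=0.2, seed=90_000 + k)
            truth = make_truth(cfg)
            inst = harmonized_from_truth(
                truth, None, 50_000, 50_000, seed=91_000 + k, selection="true"
            )
            *_, intercept_p = estimate_egger(inst)
            hits += intercept_p >= 0.05
        assert hits / reps > 0.88


class TestRunGsmr:
    def test_too_few_instruments_guard(self):
        cfg = SimConfig(m=5, b_xy_true=0.3, seed=1)
        truth = make_truth(cfg)
        exp, out = sample_sumstats_direct(truth, None, 50_000, 50_000, seed=2)
        with pytest.raises(InsufficientInstrumentsError):
            run_gsmr(exp, out, None)

    def test_recovery_within_two_se(self):
        cfg = SimConfig(m=50, b_xy_true=0.3, seed=21)
        truth = make_truth(cfg)
        ld = ld_matrix_from_config(truth)
        exp, out = sample_sumstats_direct(truth, ld, 50_000, 50_000, seed=22)
        res = run_gsmr(exp, out, ld)
        assert abs(res.bxy_hat - 0.3) < 2 * res.se
        assert res.chi2 == pytest.approx((res.bxy_hat / res.se) ** 2, rel=1e-9)
        assert res.n_instruments_used == res.n_instruments_input - len(
            res.flagged_pleiotropic
        )

    def test_outcome_recoding_leaves_estimate_invariant(self):
        """Flipping the outcome's allele coding must not change the estimate."""
        cfg = SimConfig(m=30, b_xy_true=0.2, seed=31)
        truth = make_truth(cfg)
        exp, out = sample_sumstats_direct(truth, None, 50_000, 50_000, seed=32)
        res1 = run_gsmr(exp, out, None)
        flipped = out.table.copy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        flipped[["effect_allele", "other_allele"]] = flipped[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        from gsmrkit import SummaryDataset

        out2 = SummaryDataset("outcome", "quantitative", flipped)
        res2 = run_gsmr(exp, out2, None)
        assert res2.bxy_hat == pytest.approx(res1.bxy_hat, rel=1e-12)
        assert res2.se == pytest.approx(res1.se, rel=1e-12)

    def test_bidirectional_swap_symmetry(self):
        cfg = SimConfig(m=40, m_outcome=40, b_xy_true=0.3, per_snp_h2_outcome=0.001,
                        seed=41)
        truth = make_truth(cfg)
        exp, out = sample_sumstats_direct(truth, None, 50_000, 50_000, seed=42)
        opts = GsmrOptions(force=True)
        f1, r1 = run_bidirectional(exp, out, None, opts)
        f2, r2 = run_bidirectional(out, exp, None, opts)
        assert f1.bxy_hat == pytest.approx(r2.bxy_hat)
        assert r1.bxy_hat == pytest.approx(f2.bxy_hat)

    def test_pure_forward_effect_gives_null_reverse(self):
        """x -> y only: the reverse direction should usually be null."""
        nulls = 0
        reps = 40
        for k in range(reps):
            cfg = SimConfig(
                m=40, m_outcome=40, b_xy_true=0.3, reverse_b=0.0,
                per_snp_h2_outcome=0.001, seed=95_000 + k,
            )
            truth = make_truth(cfg)
            exp, out = sample_sumstats_direct(truth, None, 50_000, 50_000, seed=96_000 + k)
            _, rev = run_bidirectional(exp, out, None, GsmrOptions(force=True))
            nulls += rev.pval >= 0.05
        assert nulls / reps >= 0.9

    def test_opposite_sign_bidirectional_recovered(self):
        cfg = SimConfig(
            m=40, m_outcome=40, b_xy_true=0.3, reverse_b=-0.05,
            per_snp_h2_outcome=0.002, seed=97,
        )
        truth = make_truth(cfg)
        exp, out = sample_sumstats_direct(truth, None, 100_000, 100_000, seed=98)
        fwd, rev = run_bidirectional(exp, out, None, GsmrOptions(force=True))
        assert fwd.bxy_hat > 0
        assert rev.bxy_hat < 0
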