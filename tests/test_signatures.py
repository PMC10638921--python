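import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from sigbench import (
    GeneExpressionMatrix,
    MethodParams,
    filter_low_expression,
    register_external_method,
    signature_characteristic_direction,
    signature_logfc,
    signature_modz,
    signature_ranksum,
    signature_welch_t,
)
from sigbench.signatures import Signature, compute_signature


def _matrix(arr, kind="counts", genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i}" for i in range(1, arr.shape[0] + 1)]
    samples = samples or (
        [f"T{i}" for i in range(1, arr.shape[1] // 2 + 1)]
        + [f"C{i}" for i in range(1, arr.shape[1] - arr.shape[1] // 2 + 1)]
    )
    return GeneExpressionMatrix(
        values=pd.DataFrame(arr, index=genes, columns=samples), value_kind=kind
    )


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        m = _matrix(np.vstack([np.zeros(8), np.full(8, 100.0)]))
        out = filter_low_expression(m, (4, 4))
        assert out.gene_ids == ["G2"]

    def test_high_count_gene_retained(self):
        m = _matrix(np.full((1, 8), 100.0))
        assert filter_low_expression(m, (4, 4)).n_genes == 1

    def test_matches_brute_force_rule(self):
        # keep iff count >= 10 in >= min(group sizes) samples AND total >= 15
        rng = np.random.default_rng(3)
        arr = rng.integers(0, 30, size=(25, 8)).astype(float)
        m = _matrix(arr)
        out = filter_low_expression(m, (4, 4))
        expected = [
            g
            for g, row in zip(m.gene_ids, arr)
            if sum(1 for v in row if v >= 10) >= 4 and sum(row) >= 15
        ]
        assert out.gene_ids == expected

    def test_order_preserved(self):
        arr = np.full((5, 8), 100.0)
        m = _matrix(arr)
        assert filter_low_expression(m, (4, 4)).gene_ids == m.gene_ids

    def test_all_filtered_is_error(self):
        m = _matrix(np.ones((3, 8)))
        with pytest.raises(ValueError, match="all genes"):
            filter_low_expression(m, (4, 4))


class TestLogFC:
    def test_signed_log_mean_difference(self):
        m = _matrix([[2.0, 2.0, 1.0, 1.0]], kind="signed_log")
        sig = signature_logfc(m, ["T1", "T2"], ["C1", "C2"])
        assert sig.coefficient["G1"] == pytest.approx(1.0)
        assert sig.ranking_key == "abs_coefficient_desc"
        assert sig.p_value is None

    def test_counts_pseudocount_formula(self):
        # log2(7+1) - log2(3+1) = 1
        m = _matrix([[7.0, 7.0, 3.0, 3.0]])
        sig = signature_logfc(m, ["T1", "T2"], ["C1", "C2"])
        assert sig.coefficient["G1"] == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        m = _matrix(np.tile([[5.0, 9.0]], (3, 2)).reshape(3, 4))
        sig = signature_logfc(m, ["T1", "T2"], ["C1", "C2"])
        # columns repeat (5,9,5,9): groups T=(5,9), C=(5,9) identical
        assert np.allclose(sig.coefficient, 0.0)

    def test_invariant_to_appending_constant_gene(self):
        rng = np.random.default_rng(1)
        arr = rng.poisson(40, size=(6, 8)).astype(float)
        base = signature_logfc(_matrix(arr), [f"T{i}" for i in range(1, 5)],
                               [f"C{i}" for i in range(1, 5)])
        arr2 = np.vstack([arr, np.full(8, 1000.0)])
        ext = signature_logfc(_matrix(arr2), [f"T{i}" for i in range(1, 5)],
                              [f"C{i}" for i in range(1, 5)])
        assert np.allclose(ext.coefficient.to_numpy()[:6], base.coefficient.to_numpy())


class TestWelchT:
    def test_hand_computed_statistic(self):
        m = _matrix([[4.0, 5.0, 6.0, 1.0, 2.0, 3.0]], kind="signed_log",
                    samples=["T1", "T2", "T3", "C1", "C2", "C3"])
        sig = signature_welch_t(m, ["T1", "T2", "T3"], ["C1", "C2", "C3"])
        assert sig.coefficient["G1"] == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), abs=1e-9)

    def test_zero_variance_gene_gets_p_one(self):
        m = _matrix([[5.0] * 8], kind="signed_log")
        sig = signature_welch_t(m, [f"T{i}" for i in range(1, 5)],
                                [f"C{i}" for i in range(1, 5)])
        assert sig.coefficient["G1"] == 0.0
        assert sig.p_value["G1"] == 1.0

    def test_p_matches_distribution_function_oracle(self):
        # Welch statistic + Satterthwaite dof + Student-t survival function,
        # evaluated independently of the scipy test routine
        rng = np.random.default_rng(11)
        for _ in range(50):
            n1, n2 = rng.integers(2, 7, size=2)
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 2, n2)
            v1, v2 = x.var(ddof=1) / n1, y.var(ddof=1) / n2
            t = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
            dof = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
            expected_p = 2 * (1 - special.stdtr(dof, abs(t)))
            arr = np.concatenate([x, y])[None, :]
            samples = [f"T{i}" for i in range(n1)] + [f"C{i}" for i in range(n2)]
            m = _matrix(arr, kind="signed_log", samples=samples)
            sig = signature_welch_t(m, samples[:n1], samples[n1:])
            assert sig.p_value["G1"] == pytest.approx(expected_p, abs=1e-9)
            assert sig.coefficient["G1"] == pytest.approx(t, abs=1e-9)

    def test_equal_var_flag_gives_pooled_t(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(3, 7))[None, 0:1].reshape(1, -1)
        arr = rng.normal(size=(1, 7))
        samples = ["T1", "T2", "T3", "C1", "C2", "C3", "C4"]
        m = _matrix(arr, kind="signed_log", samples=samples)
        sig = signature_welch_t(m, samples[:3], samples[3:],
                                MethodParams(equal_var=True))
        t_ref, p_ref = stats.ttest_ind(arr[0, :3], arr[0, 3:], equal_var=True)
        assert sig.coefficient["G1"] == pytest.approx(t_ref)
        assert sig.p_value["G1"] == pytest.approx(p_ref)


class TestRankSum:
    def test_complete_separation_is_extremal(self):
        # among all tie-free 5v5 configurations, full separation has max |z|, min p
        sep = np.concatenate([np.arange(6, 11), np.arange(1, 6)])[None, :].astype(float)
        samples = [f"T{i}" for i in range(5)] + [f"C{i}" for i in range(5)]
        m = _matrix(sep, kind="signed_log", samples=samples)
        sig = signature_ranksum(m, samples[:5], samples[5:])
        rng = np.random.default_rng(2)
        for _ in range(20):
            vals = rng.permutation(np.arange(1.0, 11.0))[None, :]
            other = signature_ranksum(
                _matrix(vals, kind="signed_log", samples=samples),
                samples[:5], samples[5:],
            )
            assert abs(sig.coefficient["G1"]) >= abs(other.coefficient["G1"])
            assert sig.p_value["G1"] <= other.p_value["G1"]

    def test_identical_groups_z_zero_p_one(self):
        m = _matrix([[3.0] * 8], kind="signed_log")
        sig = signature_ranksum(m, [f"T{i}" for i in range(1, 5)],
                                [f"C{i}" for i in range(1, 5)])
        assert sig.coefficient["G1"] == 0.0
        assert sig.p_value["G1"] == 1.0

    def test_p_matches_full_permutation_enumeration(self):
        # exact null for 3 vs 3: enumerate all C(6,3) group assignments
        rng = np.random.default_rng(9)
        samples = ["T1", "T2", "T3", "C1", "C2", "C3"]
        for _ in range(10):
            vals = rng.normal(size=6)
            if len(np.unique(vals)) < 6:
                continue
            m = _matrix(vals[None, :], kind="signed_log", samples=samples)
            sig = signature_ranksum(m, samples[:3], samples[3:])
            ranks = stats.rankdata(vals)
            w_obs = ranks[:3].sum()
            mu = 3 * 7 / 2.0
            ws = [
                ranks[list(combo)].sum()
                for combo in itertools.combinations(range(6), 3)
            ]
            p_exact = np.mean([abs(w - mu) >= abs(w_obs - mu) - 1e-12 for w in ws])
            assert sig.p_value["G1"] == pytest.approx(p_exact, abs=1e-9)


def _dense_chdir(xt, xc, gamma):
    """Dense regularized-LDA solve: the independent small-p oracle."""
    p = xt.shape[0]
    n = xt.shape[1] + xc.shape[1]
    zt = xt - xt.mean(axis=1, keepdims=True)
    zc = xc - xc.mean(axis=1, keepdims=True)
    pooled = (zt @ zt.T + zc @ zc.T) / (n - 2)
    sigma = gamma * pooled + (1 - gamma) * (np.trace(pooled) / p) * np.eye(p)
    b = np.linalg.solve(sigma, xt.mean(axis=1) - xc.mean(axis=1))
    return b / np.linalg.norm(b)


class TestCharacteristicDirection:
    def test_unit_norm_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for p, n1, n2 in [(5, 3, 3), (200, 4, 4), (1000, 3, 17)]:
            arr = rng.normal(size=(p, n1 + n2))
            arr[:10, :n1] += 2.0
            samples = [f"T{i}" for i in range(n1)] + [f"C{i}" for i in range(n2)]
            m = _matrix(arr, kind="signed_log", samples=samples)
            sig = signature_characteristic_direction(m, samples[:n1], samples[n1:])
            assert np.linalg.norm(sig.coefficient) == pytest.approx(1.0, abs=1e-10)

    def test_agrees_with_dense_solve(self):
        rng = np.random.default_rng(8)
        for p, n1, n2 in [(4, 3, 3), (6, 4, 4), (10, 5, 3)]:
            xt = rng.normal(1.0, 1.0, size=(p, n1))
            xc = rng.normal(0.0, 1.0, size=(p, n2))
            expected = _dense_chdir(xt, xc, gamma=0.5)
            samples = [f"T{i}" for i in range(n1)] + [f"C{i}" for i in range(n2)]
            m = _matrix(np.hstack([xt, xc]), kind="signed_log", samples=samples)
            sig = signature_characteristic_direction(m, samples[:n1], samples[n1:])
            got = sig.coefficient.to_numpy()
            if np.dot(got, expected) < 0:
                expected = -expected  # same direction up to the (fixed) sign
            assert np.allclose(got, expected, atol=1e-8)

    def test_discriminative_gene_outscores_noise_gene(self):
        wins = 0
        n_trials = 200
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            g1 = np.concatenate([rng.normal(3, 0.5, 4), rng.normal(0, 0.5, 4)])
            g2 = rng.normal(0, 1, 8)
            samples = [f"T{i}" for i in range(4)] + [f"C{i}" for i in range(4)]
            m = _matrix(np.vstack([g1, g2]), kind="signed_log", samples=samples)
            sig = signature_characteristic_direction(m, samples[:4], samples[4:])
            if abs(sig.coefficient["G1"]) > abs(sig.coefficient["G2"]):
                wins += 1
        assert wins >= 0.95 * n_trials

    def test_positive_means_higher_in_treatment(self):
        samples = [f"T{i}" for i in range(4)] + [f"C{i}" for i in range(4)]
        arr = np.vstack(
            [np.concatenate([np.full(4, 5.0), np.full(4, 0.0)]) + np.linspace(0, 0.1, 8),
             np.linspace(0, 1, 8)]
        )
        m = _matrix(arr, kind="signed_log", samples=samples)
        sig = signature_characteristic_direction(m, samples[:4], samples[4:])
        assert sig.coefficient["G1"] > 0

    def test_degenerate_comparison_is_error(self):
        m = _matrix(np.full((3, 8), 2.0), kind="signed_log")
        with pytest.raises(ValueError, match="degenerate"):
            signature_characteristic_direction(
                m, [f"T{i}" for i in range(1, 5)], [f"C{i}" for i in range(1, 5)]
            )


def _sig_from(vec, genes):
    return Signature(
        coefficient=pd.Series(vec, index=genes),
        method="logfc",
        ranking_key="abs_coefficient_desc",
    )


class TestModz:
    def test_two_replicates_is_elementwise_mean(self):
        genes = [f"G{i}" for i in range(10)]
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        out = signature_modz([_sig_from(a, genes), _sig_from(b, genes)])
        assert np.allclose(out.coefficient, (a + b) / 2)

    def test_identical_replicates_idempotent(self):
        genes = [f"G{i}" for i in range(8)]
        a = np.arange(8.0)
        out = signature_modz([_sig_from(a, genes)] * 4)
        assert np.allclose(out.coefficient, a)

    def test_single_replicate_identity(self):
        genes = ["G1", "G2"]
        out = signature_modz([_sig_from(np.array([1.0, -2.0]), genes)])
        assert np.allclose(out.coefficient, [1.0, -2.0])

    def test_weights_match_spearman_formula(self):
        genes = [f"G{i}" for i in range(30)]
        rng = np.random.default_rng(6)
        base = rng.normal(size=30)
        reps = [base + rng.normal(0, s, 30) for s in (0.1, 0.5, 2.0)]
        # independent evaluation of the stated weight formula
        rho = np.array(
            [
                [stats.spearmanr(reps[i], reps[j]).statistic for j in range(3)]
                for i in range(3)
            ]
        )
        raw = np.array([(rho[i].sum() - 1.0) / 2 for i in range(3)])
        raw = np.maximum(raw, 0.01)
        expected_w = raw / raw.sum()
        expected = np.column_stack(reps) @ expected_w
        out = signature_modz([_sig_from(r, genes) for r in reps])
        assert np.allclose(out.coefficient, expected, atol=1e-12)

    def test_mismatched_universe_is_error(self):
        a = _sig_from(np.ones(3), ["G1", "G2", "G3"])
        b = _sig_from(np.ones(3), ["G1", "G2", "G4"])
        with pytest.raises(ValueError, match="mismatched"):
            signature_modz([a, b])


@pytest.mark.parametrize("method", ["logfc", "welch_t", "ranksum", "chdir"])
def test_antisymmetric_under_group_swap(method):
    rng = np.random.default_rng(13)
    arr = rng.normal(size=(20, 8))
    arr[:5, :4] += 1.5
    samples = [f"T{i}" for i in range(4)] + [f"C{i}" for i in range(4)]
    m = _matrix(arr, kind="signed_log", samples=samples)
    fwd = compute_signature(method, m, samples[:4], samples[4:])
    rev = compute_signature(method, m, samples[4:], samples[:4])
    assert np.allclose(fwd.coefficient, -rev.coefficient, atol=1e-9)
    if fwd.p_value is not None:
        assert np.allclose(fwd.p_value, rev.p_value, atol=1e-12)


def test_welch_p_uniform_under_null():
    # pure-noise data: p-values indistinguishable from U(0,1) at 10,000 genes
    rng = np.random.default_rng(21)
    arr = rng.normal(size=(10000, 8))
    samples = [f"T{i}" for i in range(4)] + [f"C{i}" for i in range(4)]
    m = _matrix(arr, kind="signed_log", samples=samples)
    sig = signature_welch_t(m, samples[:4], samples[4:])
    ks = stats.kstest(sig.p_value.to_numpy(), "uniform").statistic
    assert ks < 0.05


class TestExternalMethods:
    def test_registered_stub_is_callable(self, toy_counts, groups):
        handle = register_external_method(
            "stub", lambda m, t, c, p: signature_logfc(m, t, c, p)
        )
        assert handle == "external:stub"
        sig = compute_signature(handle, toy_counts, *groups)
        ref = signature_logfc(toy_counts, *groups)
        assert np.allclose(sig.coefficient, ref.coefficient)

    def test_counts_only_adapter_refuses_signed_input(self, groups):
        handle = register_external_method(
            "countsonly",
            lambda m, t, c, p: signature_logfc(m, t, c, p),
            counts_only=True,
        )
        m = _matrix(np.random.default_rng(0).normal(size=(3, 8)), kind="signed_log")
        with pytest.raises(ValueError, match="signed"):
            compute_signature(handle, m, *groups)

    def test_unregistered_name_is_error(self, toy_counts, groups):
        with pytest.raises(KeyError, match="unknown method"):
            compute_signature("external:nope", toy_counts, *groups)

    def test_malformed_output_rejected(self, toy_counts, groups):
        handle = register_external_method("bad", lambda m, t, c, p: "not a signature")
        with pytest.raises(ValueError, match="non-Signature"):
            compute_signature(handle, toy_counts, *groups)
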