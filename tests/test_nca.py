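"""NCA: identifiability criteria, reduction, recovery and normalization."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import coldnet as cn
from coldnet.exceptions import (
    DegenerateTFError,
    FormatError,
    NotIdentifiableError,
)
from coldnet.nca import normalize


def _block_pattern(genes_per_tf: int, n_tfs: int) -> cn.ConnectivityPattern:
    """Disjoint gene blocks: trivially identifiable."""
    n = genes_per_tf * n_tfs
    support = np.zeros((n, n_tfs), dtype=int)
    for j in range(n_tfs):
        support[j * genes_per_tf:(j + 1) * genes_per_tf, j] = 1
    return cn.ConnectivityPattern(
        gene_ids=[f"g{i}" for i in range(n)],
        tf_ids=[f"tf{j}" for j in range(n_tfs)],
        support=support,
    )


# ---------------------------------------------------------------------------
# patterns and criteria
# ---------------------------------------------------------------------------


def test_pattern_invariants_enforced():
    with pytest.raises(FormatError):  # all-zero row
        cn.ConnectivityPattern(["g1", "g2"], ["t"], np.array([[1], [0]]))
    with pytest.raises(FormatError):  # more TFs than genes
        cn.ConnectivityPattern(["g1"], ["t1", "t2"], np.array([[1, 1]]))


def test_criteria_block_pattern_passes():
    rep = cn.check_nca_criteria(_block_pattern(3, 2), n_conditions=4, seed=0)
    assert rep.criterion_a and rep.criterion_b and rep.criterion_c
    assert rep.overall_pass


def test_criteria_structural_rank_deficiency_fails_a():
    # two TFs supported only on the same single gene: their columns are
    # generically proportional, so the pattern cannot reach full rank
    support = np.array([[1, 1, 1], [1, 0, 0], [1, 0, 0]])
    z0 = cn.ConnectivityPattern(["g0", "g1", "g2"], ["t0", "t1", "t2"], support)
    rep = cn.check_nca_criteria(z0, n_conditions=5, seed=0)
    assert not rep.criterion_a


def test_criteria_removal_rule_fails_b():
    # removing t0 removes every gene, leaving t1 with no support
    support = np.array([[1, 0], [1, 1], [1, 1]])
    z0 = cn.ConnectivityPattern(["g0", "g1", "g2"], ["t0", "t1"], support)
    rep = cn.check_nca_criteria(z0, n_conditions=5, seed=0)
    assert rep.criterion_a
    assert not rep.criterion_b and "t0" in rep.failing_tfs


def test_criteria_condition_count_fails_c():
    # the study-scale configuration: 178 TFs against 10 conditions cannot
    # give the activity matrix full row rank
    z0 = _block_pattern(2, 178)
    rep = cn.check_nca_criteria(z0, n_conditions=10, seed=0)
    assert rep.criterion_a and rep.criterion_b
    assert not rep.criterion_c and not rep.overall_pass


def test_reduce_already_compliant_unchanged():
    z0 = _block_pattern(3, 3)
    reduced, log = cn.reduce_to_compliant(z0, n_conditions=6, seed=0)
    assert log == []
    assert (reduced.support == z0.support).all()


def test_reduce_dimensional_violation_drops_exact_count():
    z0 = _block_pattern(4, 5)
    reduced, log = cn.reduce_to_compliant(z0, n_conditions=3, seed=0)
    assert len(log) == 2 and reduced.n_tfs == 3
    assert all(entry["reason"] == "criterion_c" for entry in log)


def test_reduce_random_patterns_always_end_compliant():
    for seed in range(20):
        z0, _ = cn.generate_connectivity(50, 8, out_degree=10, seed=seed)
        reduced, _ = cn.reduce_to_compliant(z0, n_conditions=10, seed=seed)
        assert cn.check_nca_criteria(reduced, 10, seed=seed).overall_pass


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------


def test_noiseless_recovery(compliant_truth):
    truth, expr = compliant_truth
    dec = cn.decompose(expr, truth.connectivity, tol=1e-12, n_restarts=3, seed=0)
    scale = np.linalg.norm(expr.values.to_numpy())
    assert dec.final_residual < 1e-8 * scale
    T_true = truth.activities.to_numpy()
    for j in range(T_true.shape[0]):
        r = np.corrcoef(dec.T[j], T_true[j])[0, 1]
        assert abs(r) >= 0.999


def test_support_constraint_exact(compliant_truth):
    truth, expr = compliant_truth
    dec = cn.decompose(expr, truth.connectivity, n_restarts=2, seed=0)
    outside = dec.C[truth.connectivity.support == 0]
    assert (outside == 0).all()


def test_residual_history_monotone(compliant_truth):
    truth, expr = compliant_truth
    noisy = expr.values + np.random.default_rng(1).normal(
        0, 0.5, size=expr.values.shape
    )
    dec = cn.decompose(noisy, truth.connectivity, n_restarts=2, seed=0)
    hist = np.asarray(dec.residual_history)
    assert (np.diff(hist) <= 1e-9 * hist[:-1] + 1e-12).all()


def test_rank_one_fit_matches_svd_oracle():
    rng = np.random.default_rng(2)
    E = rng.normal(size=(10, 6))
    z0 = cn.ConnectivityPattern(
        [f"g{i}" for i in range(10)], ["tf0"], np.ones((10, 1), dtype=int)
    )
    dec = cn.decompose(E, z0, tol=1e-14, max_iter=2000, n_restarts=3, seed=0)
    U, s, Vt = np.linalg.svd(E)
    best_rank1 = s[0] * np.outer(U[:, 0], Vt[0])
    # the fitted residual equals the optimal rank-1 residual sqrt(sum s_i^2, i>1)
    assert dec.final_residual == pytest.approx(
        np.sqrt((s[1:] ** 2).sum()), abs=1e-10
    )
    # and the factor product matches the truncated SVD (the residual-change
    # stop leaves a slightly larger angle error than residual error)
    np.testing.assert_allclose(dec.C @ dec.T, best_rank1, atol=1e-5)


def test_zero_expression_fits_immediately():
    z0 = _block_pattern(3, 2)
    dec = cn.decompose(np.zeros((6, 4)), z0, seed=0)
    assert dec.final_residual == 0.0 and dec.n_iter == 1
    assert (dec.C @ dec.T == 0).all()


def test_strict_mode_refuses_noncompliant():
    z0 = _block_pattern(2, 5)  # L=5 > M=3 violates criterion (c)
    E = np.random.default_rng(3).normal(size=(10, 3))
    with pytest.raises(NotIdentifiableError):
        cn.decompose(E, z0, seed=0)
    with pytest.warns(UserWarning):
        dec = cn.decompose(E, z0, seed=0, strict=False)
    assert not dec.identifiable


def test_scaling_ambiguity_resolved_across_seeds(compliant_truth):
    """Two runs from different initializations agree after normalization."""
    truth, expr = compliant_truth
    a = cn.decompose(expr, truth.connectivity, tol=1e-13, n_restarts=2, seed=0)
    b = cn.decompose(expr, truth.connectivity, tol=1e-13, n_restarts=2, seed=99)
    np.testing.assert_allclose(a.C, b.C, rtol=1e-6, atol=1e-8)
    np.testing.assert_allclose(a.T, b.T, rtol=1e-6, atol=1e-8)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _unnormalized_dec(compliant_truth):
    truth, expr = compliant_truth
    C = truth.control_strengths * 3.0
    T = truth.activities.to_numpy() / 3.0
    return cn.NCADecomposition(
        control_strengths=pd.DataFrame(
            C, index=truth.connectivity.gene_ids, columns=truth.connectivity.tf_ids
        ),
        activities=pd.DataFrame(
            T, index=truth.connectivity.tf_ids, columns=truth.activities.columns
        ),
        residual_history=[0.0],
        scale_record={},
        converged=True,
        n_iter=1,
    )


def test_normalize_preserves_product_and_is_idempotent(compliant_truth):
    dec = _unnormalized_dec(compliant_truth)
    product = dec.C @ dec.T
    norm1 = normalize(dec)
    np.testing.assert_allclose(
        norm1.C @ norm1.T, product, atol=1e-10 * np.linalg.norm(product)
    )
    np.testing.assert_allclose(np.linalg.norm(norm1.C, axis=0), 1.0, atol=1e-12)
    # largest-|entry| of each column is positive
    for j in range(norm1.C.shape[1]):
        col = norm1.C[:, j]
        assert col[np.argmax(np.abs(col))] > 0
    norm2 = normalize(norm1)
    np.testing.assert_allclose(norm2.C, norm1.C, atol=1e-14)
    np.testing.assert_allclose(norm2.T, norm1.T, atol=1e-14)


def test_normalize_rejects_zero_column(compliant_truth):
    dec = _unnormalized_dec(compliant_truth)
    dec.control_strengths.iloc[:, 2] = 0.0
    with pytest.raises(DegenerateTFError):
        normalize(dec)


# ---------------------------------------------------------------------------
# estimator interface
# ---------------------------------------------------------------------------


def test_estimator_sklearn_conventions(compliant_truth):
    truth, expr = compliant_truth
    est = cn.NetworkComponentAnalysis(
        connectivity=truth.connectivity, n_restarts=2, random_state=0
    )
    C = est.fit_transform(expr.values)
    assert C.shape == (50, 5)
    assert est.activities_.shape == (5, 12)
    assert est.components_ is est.activities_
    params = est.get_params()
    assert params["n_restarts"] == 2
    cloned = clone(est)
    C2 = cloned.fit_transform(expr.values)
    np.testing.assert_allclose(C, C2)
    # transform solves the same constrained row problem on seen data
    np.testing.assert_allclose(est.transform(expr.values), C, atol=1e-8)
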