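"""Network reconstruction: correlation calling, thresholds, activity calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import coldnet as cn
from coldnet.exceptions import InputError, ParameterError
from coldnet.network import classify_tf_correlations


def _frames(A, E, conds=None):
    conds = conds or [f"c{i}" for i in range(A.shape[1])]
    acts = pd.DataFrame(A, index=[f"tf{i}" for i in range(A.shape[0])],
                        columns=conds)
    expr = pd.DataFrame(E, index=[f"g{i}" for i in range(E.shape[0])],
                        columns=conds)
    return acts, expr


def test_correlation_exact_copies():
    rng = np.random.default_rng(0)
    a = rng.normal(size=10)
    acts, expr = _frames(a[None, :], np.vstack([a, -a]))
    cand = cn.correlate_tf_targets(acts, expr)
    by_target = cand.set_index("target")
    assert by_target.loc["g0", "r"] == pytest.approx(1.0)
    assert by_target.loc["g1", "r"] == pytest.approx(-1.0)
    assert (by_target["p"] <= 1e-12).all()


def test_correlation_matches_pointwise_oracle():
    rng = np.random.default_rng(1)
    A = rng.normal(size=(4, 12))
    E = rng.normal(size=(20, 12))
    acts, expr = _frames(A, E)
    cand = cn.correlate_tf_targets(acts, expr).set_index(["tf", "target"])
    for i in range(4):
        for j in range(20):
            r_o, p_o = stats.pearsonr(A[i], E[j])
            row = cand.loc[(f"tf{i}", f"g{j}")]
            assert row["r"] == pytest.approx(r_o, abs=1e-12)
            assert row["p"] == pytest.approx(p_o, rel=1e-9)


def test_correlation_preconditions_and_skips():
    acts, expr = _frames(np.ones((1, 2)), np.ones((1, 2)))
    with pytest.raises(InputError):
        cn.correlate_tf_targets(acts, expr)
    rng = np.random.default_rng(2)
    A = rng.normal(size=(2, 8))
    E = rng.normal(size=(3, 8))
    E[1] = 5.0  # constant expression row: correlation undefined
    acts, expr = _frames(A, E)
    cand = cn.correlate_tf_targets(acts, expr)
    assert "g1" not in set(cand["target"])
    assert any(s.get("target") == "g1" for s in cand.attrs["skipped"])


def test_build_network_threshold_rule():
    cand = pd.DataFrame(
        {"tf": ["a", "a", "a"], "target": ["g1", "g2", "g3"],
         "r": [0.9, -0.85, 0.5], "p": [0.01] * 3}
    )
    net = cn.build_network(cand, r_threshold=0.8)
    assert net.n_edges == 2
    assert net.n_activations == 1 and net.n_repressions == 1
    assert "g3" not in net.nodes  # below-threshold gene absent from network
    exact = cn.build_network(
        pd.DataFrame({"tf": ["a", "a"], "target": ["g1", "g2"],
                      "r": [1.0, 0.999], "p": [0, 0]}),
        r_threshold=1.0,
    )
    assert exact.n_edges == 1
    with pytest.raises(ParameterError):
        cn.build_network(cand, r_threshold=1.5)


def test_edge_count_monotone_in_threshold():
    rng = np.random.default_rng(3)
    cand = pd.DataFrame(
        {"tf": ["t"] * 200, "target": [f"g{i}" for i in range(200)],
         "r": rng.uniform(-1, 1, 200), "p": rng.uniform(0, 1, 200)}
    )
    counts = [cn.build_network(cand, thr).n_edges
              for thr in (0.2, 0.5, 0.8, 0.95)]
    assert counts == sorted(counts, reverse=True)
    net = cn.build_network(cand, 0.5)
    assert net.n_activations + net.n_repressions == net.n_edges


def test_noiseless_sign_recovery_is_exact():
    """Single-regulator genes: the TFA-target correlation sign equals the
    control-strength sign, and every true edge survives the 0.8 cut."""
    pattern, strengths = cn.generate_connectivity(
        40, 4, out_degree=10, sign_fraction_negative=0.4, seed=4
    )
    assert (pattern.support.sum(axis=1) == 1).all()  # partition by construction
    acts = cn.generate_activities(4, 10, seed=4, tf_ids=pattern.tf_ids)
    truth = cn.GroundTruth(connectivity=pattern, control_strengths=strengths,
                           activities=acts, noise_sd=0.0, seed=4)
    expr = cn.simulate_expression(truth)
    cand = cn.correlate_tf_targets(acts, expr.values, pairs="z0_only", z0=pattern)
    net = cn.build_network(cand, r_threshold=0.8)
    assert net.n_edges == pattern.n_edges
    merged = net.edges.set_index(["tf", "target"])
    for i, g in enumerate(pattern.gene_ids):
        j = int(np.argmax(pattern.support[i]))
        expected = "activation" if strengths[i, j] > 0 else "repression"
        assert merged.loc[(pattern.tf_ids[j], g), "sign"] == expected


def test_classify_tf_correlation_boundaries():
    rng = np.random.default_rng(5)
    a = rng.normal(size=10)
    assert cn.classify_tf_correlation(a, a) == "positive"
    assert cn.classify_tf_correlation(a, -a) == "negative"
    # r == cut exactly is "low" (strict inequality)
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 3.0, 2.0, 4.0])  # r = 0.8
    r = np.corrcoef(x, y)[0, 1]
    assert cn.classify_tf_correlation(x, y, cut=r) == "low"
    with pytest.raises(InputError):
        cn.classify_tf_correlation(np.ones(5), a[:5])


def test_classify_tf_correlations_table():
    rng = np.random.default_rng(6)
    a = rng.normal(size=10)
    acts = pd.DataFrame([a, a], index=["tf0", "tf1"],
                        columns=[f"c{i}" for i in range(10)])
    expr = pd.DataFrame([a * 2], index=["tf0"], columns=acts.columns)
    out = classify_tf_correlations(acts, expr)
    assert out.loc["tf0", "class"] == "positive"
    assert out.loc["tf1", "class"] == "undefined"  # no expression row


def test_call_active_ecotypes_spike_and_constant():
    conds = [f"e{i}" for i in range(10)]
    spike = np.zeros(10)
    spike[4] = 3.0
    acts = pd.DataFrame([spike, np.ones(10)], index=["tf0", "tf1"],
                        columns=conds)
    calls = cn.call_active_ecotypes(acts, z_cut=1.0)
    assert calls.active["tf0"] == ("e4",)
    assert calls.is_specific("tf0")
    assert calls.active["tf1"] == () and "tf1" in calls.skipped


def test_block_truth_recovered_from_noisy_activities():
    """TFs active in known ecotype blocks are recalled at z >= 1."""
    correct = total = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        blocks = {j: sorted(rng.choice(10, size=1, replace=False).tolist())
                  for j in range(6)}
        acts = cn.generate_activities(
            6, 10, model="ecotype_blocks", seed=seed, blocks=blocks,
            delta=2.0, background_sd=0.3,
        )
        calls = cn.call_active_ecotypes(acts, z_cut=1.0)
        names = list(acts.columns)
        for j in range(6):
            expected = tuple(names[c] for c in blocks[j])
            total += 1
            if calls.active[acts.index[j]] == expected:
                correct += 1
    assert correct / total >= 0.9
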