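"""Differential expression: test calibration, set algebra, clustering, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import coldnet as cn
from coldnet.exceptions import DesignError, InputError


def _make_expr(values: np.ndarray, ecotypes, n_reps=3):
    """genes x (ecotypes * 2 treatments * reps) matrix with metadata."""
    cols, meta = [], []
    for eco in ecotypes:
        for tr in ("control", "cold"):
            for rep in range(1, n_reps + 1):
                s = f"{eco}.{tr}.{rep}"
                cols.append(s)
                meta.append((s, eco, tr, rep))
    values = pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])], columns=cols
    )
    metadata = pd.DataFrame(
        meta, columns=["sample", "ecotype", "treatment", "replicate"]
    ).set_index("sample")
    return cn.ExpressionMatrix(values=values, metadata=metadata)


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------


def test_ttest_degenerate_constant_groups():
    vals = np.ones((1, 6))
    expr = _make_expr(vals, ["Cvi"])
    res = cn.ttest_per_gene(expr, "Cvi")
    assert res["log2fc"].iloc[0] == 0.0
    assert res["t_p"].iloc[0] == 1.0


def test_ttest_large_shift_tiny_jitter():
    rng = np.random.default_rng(0)
    ctrl = rng.normal(0, 1e-6, size=3)
    cold = 2 + rng.normal(0, 1e-6, size=3)
    vals = np.concatenate([ctrl, cold])[None, :]
    expr = _make_expr(vals, ["Cvi"])
    res = cn.ttest_per_gene(expr, "Cvi")
    assert res["t_p"].iloc[0] < 1e-6
    assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-5)


def test_ttest_requires_two_replicates():
    expr, _ = cn.simulate_ecotype_experiment(n_ecotypes=2, n_genes=5, seed=1)
    sub = cn.ExpressionMatrix(
        values=expr.values.drop(columns=["Cvi.cold.2", "Cvi.cold.3"]),
        metadata=expr.metadata.drop(["Cvi.cold.2", "Cvi.cold.3"]),
    )
    with pytest.raises(DesignError):
        cn.ttest_per_gene(sub, "Cvi")


def test_ttest_false_positive_rate_on_nulls():
    """Raw p < 0.01 should reject about 1% of truly null genes."""
    rejections = total = 0
    for seed in range(10):
        expr, _ = cn.simulate_ecotype_experiment(
            n_ecotypes=3, n_genes=2000, de_fraction=0.0, seed=seed
        )
        for eco in expr.ecotypes:
            p = cn.ttest_per_gene(expr, eco)["t_p"]
            rejections += int((p < 0.01).sum())
            total += len(p)
    rate = rejections / total
    assert 0.005 <= rate <= 0.02


# ---------------------------------------------------------------------------
# ANOVA interaction
# ---------------------------------------------------------------------------


def test_anova_matches_statsmodels_oracle():
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rng = np.random.default_rng(3)
    vals = rng.normal(size=(5, 4 * 2 * 3))
    expr = _make_expr(vals, ["A", "B", "C", "D"])
    mine = cn.anova_interaction(expr)
    md = expr.metadata
    for g in expr.gene_ids:
        df = pd.DataFrame(
            {
                "y": expr.values.loc[g].to_numpy(),
                "eco": md["ecotype"].to_numpy(),
                "treat": md["treatment"].to_numpy(),
            }
        )
        fit = ols("y ~ C(eco) * C(treat)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        expected = table.loc["C(eco):C(treat)", "PR(>F)"]
        assert mine[g] == pytest.approx(expected, rel=1e-8)


def test_anova_additive_shift_has_no_interaction():
    # exactly additive cell means (ecotype effect + identical treatment
    # shift + a common replicate pattern): the interaction sum of squares
    # vanishes, so p is 1 by construction
    eco_effect = {"A": 0.0, "B": 1.0, "C": -0.5}
    rep_jitter = [0.02, -0.01, 0.04]
    vals = []
    for eco in ["A", "B", "C"]:
        for tr in ("control", "cold"):
            for rep in range(3):
                vals.append(
                    eco_effect[eco] + (3.0 if tr == "cold" else 0.0)
                    + rep_jitter[rep]
                )
    expr = _make_expr(np.array(vals)[None, :], ["A", "B", "C"])
    assert cn.anova_interaction(expr).iloc[0] > 0.99


def test_anova_single_ecotype_effect_detected():
    rng = np.random.default_rng(5)
    vals = rng.normal(0, 0.1, size=(1, 3 * 2 * 3))
    expr0 = _make_expr(vals.copy(), ["A", "B", "C"])
    df = pd.DataFrame(vals, columns=expr0.sample_ids)
    df[["A.cold.1", "A.cold.2", "A.cold.3"]] += 3.0
    expr = _make_expr(df.to_numpy(), ["A", "B", "C"])
    assert cn.anova_interaction(expr).iloc[0] < 0.001


def test_anova_rejects_unbalanced_design():
    expr, _ = cn.simulate_ecotype_experiment(n_ecotypes=2, n_genes=5, seed=6)
    sub = cn.ExpressionMatrix(
        values=expr.values.drop(columns=["Cvi.cold.3"]),
        metadata=expr.metadata.drop(["Cvi.cold.3"]),
    )
    with pytest.raises(DesignError):
        cn.anova_interaction(sub)


# ---------------------------------------------------------------------------
# DE sets, core selection
# ---------------------------------------------------------------------------


def _de_result(p, fc, ecotypes):
    genes = [f"g{i}" for i in range(p.shape[0])]
    return cn.DEResult(
        t_p=pd.DataFrame(p, index=genes, columns=ecotypes),
        log2fc=pd.DataFrame(fc, index=genes, columns=ecotypes),
        interaction_p=None,
        alpha=0.01,
    )


def test_call_de_sets_partitions():
    p = np.array([[0.001, 0.5], [0.5, 0.002], [0.001, 0.001], [0.9, 0.9]])
    fc = np.array([[1, 0.1], [-0.2, -1], [2, 2], [0, 0]])
    sets = cn.call_de_sets(_de_result(p, fc, ["A", "B"]))
    assert sets.union == ["g0", "g1", "g2"]
    assert sets.unique["A"] == ["g0"] and sets.unique["B"] == ["g1"]
    assert "g2" not in sets.unique["A"] + sets.unique["B"]
    assert sets.up["A"] == ["g0", "g2"] and sets.down["B"] == ["g1"]
    # table partitions are consistent
    row = sets.table.loc["A"]
    assert row["total"] == row["total_up"] + row["total_down"]
    assert sets.unique_fraction == pytest.approx(2 / 3)


def test_select_core_transcripts_filter_and_rank():
    p = np.array(
        [[0.001, 0.5, 0.5],
         [0.002, 0.003, 0.5],
         [0.004, 0.001, 0.5],
         [0.005, 0.006, 0.007],
         [0.9, 0.001, 0.9]]
    )
    fc = np.zeros_like(p)
    de = _de_result(p, fc, ["A", "B", "C"])
    sel = cn.select_core_transcripts(de, min_ecotypes=2, max_n=10, tf_list={"g1"})
    assert set(sel.core) == {"g1", "g2", "g3"}  # membership >= 2
    sel2 = cn.select_core_transcripts(de, min_ecotypes=2, max_n=2, tf_list={"g1"})
    assert set(sel2.core) == {"g2", "g1"}  # two smallest best-p values
    assert sel.tfs == ["g1"] and set(sel.tfs) | set(sel.targets) == set(sel.core)


def test_unique_fraction_recovered_from_simulation():
    expr, truth = cn.simulate_ecotype_experiment(
        n_ecotypes=10, n_genes=3000, de_fraction=0.2, effect_size=2.0,
        noise_sd=0.3, unique_fraction=0.75, seed=7,
    )
    de = cn.de_analysis(expr, with_anova=False)
    sets = cn.call_de_sets(de)
    assert sets.unique_fraction == pytest.approx(0.75, abs=0.05)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def test_cluster_identical_columns_merge_first_with_full_support():
    rng = np.random.default_rng(8)
    x = rng.normal(size=200)
    fc = pd.DataFrame(
        {"A": x, "B": x, "C": rng.normal(size=200)}
    )
    res = cn.cluster_ecotypes(fc, n_boot=100, seed=0)
    first = res.clades[0]
    assert first == frozenset({"A", "B"})
    assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert res.support[0] == pytest.approx(1.0)
    assert ((res.support >= 0) & (res.support <= 1)).all()


def test_cluster_anticorrelated_joins_last():
    rng = np.random.default_rng(9)
    x = rng.normal(size=300)
    fc = pd.DataFrame(
        {
            "A": x + rng.normal(0, 0.01, 300),
            "B": x + rng.normal(0, 0.01, 300),
            "C": -x + rng.normal(0, 0.01, 300),
        }
    )
    res = cn.cluster_ecotypes(fc, n_boot=10, seed=0)
    assert res.clades[0] == frozenset({"A", "B"})


def test_cluster_constant_column_rejected():
    fc = pd.DataFrame({"A": [1.0, 2.0], "B": [1.0, 1.0], "C": [0.0, 1.0]})
    with pytest.raises(InputError, match="B"):
        cn.cluster_ecotypes(fc, n_boot=5, seed=0)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def test_hypergeometric_closed_forms():
    universe = {f"g{i}" for i in range(10)}
    term = {f"g{i}" for i in range(5)}
    res = cn.enrich_hypergeometric(term, {"t1": term}, universe)
    # drawing all 5 annotated genes in a query of 5 from 10: 1 / C(10,5)
    assert res.loc["t1", "p_raw"] == pytest.approx(1 / comb(10, 5, exact=True))
    # saturated case: query == term == universe
    res2 = cn.enrich_hypergeometric(universe, {"all": universe}, universe)
    assert res2.loc["all", "p_raw"] == pytest.approx(1.0)


def test_enrichment_correction_invariants():
    rng = np.random.default_rng(10)
    universe = {f"g{i}" for i in range(50)}
    annotation = {
        f"t{j}": set(rng.choice(sorted(universe), size=8, replace=False))
        for j in range(6)
    }
    query = set(rng.choice(sorted(universe), size=12, replace=False))
    for correction in ("bonferroni", "bh"):
        res = cn.enrich_hypergeometric(query, annotation, universe,
                                       correction=correction)
        assert (res["p_adj"] >= res["p_raw"] - 1e-15).all()
        assert (res["p_adj"] <= 1.0).all()
    with pytest.raises(InputError):
        cn.enrich_hypergeometric({"zz"}, annotation, universe)
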