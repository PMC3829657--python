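"""Differential-expression calling and downstream gene-set summaries.

Per ecotype, cold-responsive genes are called by a two-sample t-test on
log2 values between treated and control replicates (raw p < alpha, no
multiple-testing correction, matching the conventional microarray
workflow this pipeline emulates). Genotype-dependent responses are
flagged by the genotype x treatment interaction term of a balanced
two-way fixed-effects ANOVA. Gene sets are then partitioned into
per-ecotype, ecotype-unique and up/down lists; a core transcript set
(significant in >= ``min_ecotypes`` ecotypes, ranked by best p) feeds
the network stage; hierarchical clustering with bootstrap support and a
hypergeometric over-representation test cover the descriptive summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .exceptions import DesignError, InputError, ParameterError
from .io import ExpressionMatrix

__all__ = [
    "DEResult",
    "DESets",
    "CoreSelection",
    "ClusterResult",
    "ttest_per_gene",
    "anova_interaction",
    "de_analysis",
    "call_de_sets",
    "select_core_transcripts",
    "cluster_ecotypes",
    "enrich_hypergeometric",
]


# ---------------------------------------------------------------------------
# Per-gene tests
# ---------------------------------------------------------------------------


def _group_arrays(
    expr: ExpressionMatrix, ecotype: str
) -> tuple[np.ndarray, np.ndarray]:
    control = expr.samples_for(ecotype, "control")
    cold = expr.samples_for(ecotype, "cold")
    if len(control) < 2 or len(cold) < 2:
        raise DesignError(
            f"ecotype {ecotype!r} has {len(control)} control / {len(cold)} cold "
            "replicates; need >= 2 in each group"
        )
    return (
        expr.values[cold].to_numpy(dtype=float),
        expr.values[control].to_numpy(dtype=float),
    )


def ttest_per_gene(
    expr: ExpressionMatrix, ecotype: str, equal_var: bool = True
) -> pd.DataFrame:
    """Two-sided two-sample t-test, cold vs control, for one ecotype.

    Returns a DataFrame indexed by gene with ``t_p`` and ``log2fc``
    (treatment mean minus control mean). The pooled-variance (Student)
    form is the default; ``equal_var=False`` switches to Welch.

    Degenerate convention: if both groups have zero variance, p is 1 for
    equal means and 0 otherwise.
    """
    treat, ctrl = _group_arrays(expr, ecotype)
    log2fc = treat.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(treat, ctrl, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    both_const = (treat.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    p[both_const & (log2fc == 0)] = 1.0
    p[both_const & (log2fc != 0)] = 0.0
    return pd.DataFrame({"t_p": p, "log2fc": log2fc}, index=expr.gene_ids)


def anova_interaction(expr: ExpressionMatrix) -> pd.Series:
    """Genotype x treatment interaction p-value per gene (two-way ANOVA).

    Requires a balanced design: every (ecotype, treatment) cell present
    with the same number (>= 2) of replicates. The fixed-effects sums of
    squares are computed in closed form (on a balanced design the type-I,
    II and III decompositions coincide), vectorized across genes.
    """
    if expr.metadata is None:
        raise DesignError("ANOVA needs sample metadata")
    ecotypes = expr.ecotypes
    if len(ecotypes) < 2:
        raise DesignError("ANOVA needs at least 2 ecotypes")
    cells: dict[tuple[str, str], list[str]] = {}
    sizes = set()
    for eco in ecotypes:
        for tr in ("control", "cold"):
            s = expr.samples_for(eco, tr)
            if not s:
                raise DesignError(f"empty design cell ({eco!r}, {tr!r})")
            cells[(eco, tr)] = s
            sizes.add(len(s))
    if len(sizes) != 1:
        raise DesignError(f"unbalanced design: cell sizes {sorted(sizes)}")
    r = sizes.pop()
    if r < 2:
        raise DesignError("need >= 2 replicates per design cell")

    a, b = len(ecotypes), 2
    n_genes = expr.n_genes
    # Y: genes x a x b x r
    Y = np.empty((n_genes, a, b, r))
    for i, eco in enumerate(ecotypes):
        for j, tr in enumerate(("control", "cold")):
            Y[:, i, j, :] = expr.values[cells[(eco, tr)]].to_numpy()
    cell_mean = Y.mean(axis=3)  # genes x a x b
    a_mean = cell_mean.mean(axis=2)  # genes x a
    b_mean = cell_mean.mean(axis=1)  # genes x b
    grand = cell_mean.mean(axis=(1, 2))  # genes
    inter = (
        cell_mean
        - a_mean[:, :, None]
        - b_mean[:, None, :]
        + grand[:, None, None]
    )
    ss_int = r * (inter**2).sum(axis=(1, 2))
    ss_err = ((Y - cell_mean[:, :, :, None]) ** 2).sum(axis=(1, 2, 3))
    df_int = (a - 1) * (b - 1)
    df_err = a * b * (r - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_int / df_int) / (ss_err / df_err)
        p = stats.f.sf(F, df_int, df_err)
    zero_err = ss_err == 0
    p[zero_err & (ss_int == 0)] = 1.0
    p[zero_err & (ss_int > 0)] = 0.0
    return pd.Series(p, index=expr.gene_ids, name="interaction_p")


@dataclass
class DEResult:
    """Per-gene, per-ecotype DE statistics at a significance level alpha."""

    t_p: pd.DataFrame  # genes x ecotypes
    log2fc: pd.DataFrame  # genes x ecotypes
    interaction_p: pd.Series | None
    alpha: float = 0.01

    @property
    def calls(self) -> pd.DataFrame:
        return self.t_p < self.alpha

    @property
    def membership(self) -> pd.Series:
        """Number of ecotypes in which each gene is called."""
        return self.calls.sum(axis=1)

    @property
    def ecotypes(self) -> list[str]:
        return list(self.t_p.columns)


def de_analysis(
    expr: ExpressionMatrix,
    alpha: float = 0.01,
    equal_var: bool = True,
    with_anova: bool = True,
) -> DEResult:
    """Run the t-test per ecotype (and the interaction ANOVA) on a dataset."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    ecotypes = expr.ecotypes
    ps, fcs = {}, {}
    for eco in ecotypes:
        res = ttest_per_gene(expr, eco, equal_var=equal_var)
        ps[eco] = res["t_p"]
        fcs[eco] = res["log2fc"]
    interaction = anova_interaction(expr) if with_anova and len(ecotypes) > 1 else None
    return DEResult(
        t_p=pd.DataFrame(ps)[ecotypes],
        log2fc=pd.DataFrame(fcs)[ecotypes],
        interaction_p=interaction,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Set construction
# ---------------------------------------------------------------------------


@dataclass
class DESets:
    union: list[str]
    per_ecotype: dict[str, list[str]]
    unique: dict[str, list[str]]
    up: dict[str, list[str]]
    down: dict[str, list[str]]
    table: pd.DataFrame  # per-ecotype counts, Total/Up/Down x all/unique

    @property
    def unique_fraction(self) -> float:
        """Fraction of the union called in exactly one ecotype."""
        n_unique = sum(len(v) for v in self.unique.values())
        return n_unique / len(self.union) if self.union else float("nan")


def call_de_sets(de: DEResult, alpha: float | None = None) -> DESets:
    """Partition DE calls into union / per-ecotype / unique / up / down lists."""
    if alpha is not None:
        de = DEResult(
            t_p=de.t_p, log2fc=de.log2fc, interaction_p=de.interaction_p, alpha=alpha
        )
    calls = de.calls
    membership = de.membership
    union = list(calls.index[membership >= 1])
    per_ecotype, unique, up, down = {}, {}, {}, {}
    rows = []
    for eco in de.ecotypes:
        called = calls[eco]
        genes = list(calls.index[called])
        per_ecotype[eco] = genes
        uniq_mask = called & (membership == 1)
        unique[eco] = list(calls.index[uniq_mask])
        up_mask = called & (de.log2fc[eco] > 0)
        down_mask = called & (de.log2fc[eco] < 0)
        up[eco] = list(calls.index[up_mask])
        down[eco] = list(calls.index[down_mask])
        rows.append(
            {
                "ecotype": eco,
                "total": int(called.sum()),
                "total_up": int(up_mask.sum()),
                "total_down": int(down_mask.sum()),
                "unique_total": int(uniq_mask.sum()),
                "unique_up": int((uniq_mask & up_mask).sum()),
                "unique_down": int((uniq_mask & down_mask).sum()),
            }
        )
    table = pd.DataFrame(rows).set_index("ecotype")
    return DESets(
        union=union, per_ecotype=per_ecotype, unique=unique, up=up, down=down,
        table=table,
    )


@dataclass
class CoreSelection:
    core: list[str]
    tfs: list[str]
    targets: list[str]
    best_p: pd.Series = field(repr=False, default=None)


def select_core_transcripts(
    de: DEResult,
    min_ecotypes: int = 2,
    max_n: int = 1509,
    tf_list: set | None = None,
    rank_by: str = "min_p",
) -> CoreSelection:
    """Select the core transcript set for network reconstruction.

    Keeps genes called in at least ``min_ecotypes`` ecotypes, ranks them
    (``min_p``: smallest best p-value across ecotypes; ``max_fc``:
    largest absolute fold-change) and truncates to ``max_n``; the
    survivors are partitioned into TFs and target genes by ``tf_list``.
    """
    if len(de.ecotypes) < min_ecotypes:
        raise DesignError(
            f"only {len(de.ecotypes)} ecotypes present; min_ecotypes={min_ecotypes}"
        )
    tf_list = set() if tf_list is None else {str(t) for t in tf_list}
    eligible = de.membership[de.membership >= min_ecotypes].index
    best_p = de.t_p.loc[eligible].min(axis=1)
    if rank_by == "min_p":
        order = best_p.sort_values(kind="mergesort")
        ranked = list(order.index)
    elif rank_by == "max_fc":
        score = de.log2fc.loc[eligible].abs().max(axis=1)
        ranked = list(score.sort_values(ascending=False, kind="mergesort").index)
    else:
        raise ParameterError(f"unknown ranking {rank_by!r}")
    core = ranked[:max_n]
    tfs = [g for g in core if g in tf_list]
    targets = [g for g in core if g not in tf_list]
    return CoreSelection(core=core, tfs=tfs, targets=targets, best_p=best_p)


# ---------------------------------------------------------------------------
# Clustering with bootstrap support
# ---------------------------------------------------------------------------


def _correlation_distance(fold_changes: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(fold_changes, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def _clades(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    """Leaf set of each internal node, in linkage-matrix row order."""
    n = len(labels)
    sets: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for k, (a, b) in enumerate(Z[:, :2].astype(int)):
        merged = sets[a] | sets[b]
        sets[n + k] = merged
        out.append(merged)
    return out


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    support: np.ndarray  # per internal node, linkage row order
    clades: list[frozenset]


def cluster_ecotypes(
    fold_changes: pd.DataFrame,
    n_boot: int = 10000,
    seed: int = 0,
) -> ClusterResult:
    """UPGMA clustering of ecotype columns on Pearson-correlation distance.

    Distance is 1 - r between fold-change columns; linkage is average
    (UPGMA). Bootstrap support resamples genes with replacement ``n_boot``
    times and reports, per internal node, the fraction of replicate trees
    containing the same leaf set.
    """
    if fold_changes.shape[1] < 3:
        raise InputError("need at least 3 ecotype columns to cluster")
    stds = fold_changes.std(axis=0, ddof=0)
    if (stds == 0).any():
        eco = stds.index[stds == 0][0]
        raise InputError(
            f"ecotype {eco!r} has constant fold-changes; correlation undefined"
        )
    X = fold_changes.to_numpy(dtype=float)
    labels = list(fold_changes.columns)
    Z = linkage(squareform(_correlation_distance(X), checks=False), method="average")
    clades = _clades(Z, labels)
    counts = np.zeros(len(clades))
    rng = np.random.default_rng(seed)
    n_genes = X.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, size=n_genes)
        Xb = X[idx]
        if (Xb.std(axis=0) == 0).any():
            continue  # degenerate resample carries no topology information
        Zb = linkage(
            squareform(_correlation_distance(Xb), checks=False), method="average"
        )
        boot_clades = set(_clades(Zb, labels))
        for i, clade in enumerate(clades):
            if clade in boot_clades:
                counts[i] += 1
    support = counts / n_boot if n_boot > 0 else np.full(len(clades), np.nan)
    return ClusterResult(linkage=Z, labels=labels, support=support, clades=clades)


# ---------------------------------------------------------------------------
# Over-representation
# ---------------------------------------------------------------------------


def enrich_hypergeometric(
    query,
    annotation: dict,
    universe,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    For each term with annotated set of size K (after intersecting with
    the universe of size N_u), a query of size n and overlap k, the raw
    p-value is P(X >= k) under sampling without replacement. Correction:
    Bonferroni (default, min(1, p * n_terms)) or Benjamini-Hochberg.
    """
    query = {str(g) for g in query}
    universe = {str(g) for g in universe}
    outside = query - universe
    if outside:
        raise InputError(f"query genes outside universe: {sorted(outside)[:5]}")
    if correction not in ("bonferroni", "bh"):
        raise ParameterError(f"unknown correction {correction!r}")
    N_u, n = len(universe), len(query)
    rows = []
    for term in sorted(annotation):
        term_set = {str(g) for g in annotation[term]} & universe
        K = len(term_set)
        k = len(term_set & query)
        p_raw = float(stats.hypergeom.sf(k - 1, N_u, K, n)) if K else 1.0
        rows.append({"term": term, "k": k, "K": K, "n": n, "N_u": N_u, "p_raw": p_raw})
    out = pd.DataFrame(rows).set_index("term")
    if len(out) == 0:
        out["p_adj"] = []
        return out
    if correction == "bonferroni":
        out["p_adj"] = np.minimum(1.0, out["p_raw"] * len(out))
    else:
        out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
    return out
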