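"""Ground-truth simulators for every stage of the pipeline.

The generators emulate the structure of a multi-ecotype cold-stress
microarray study: 10 ecotypes x {control, cold} x 3 biological
replicates, a subset of genes truly differentially expressed per ecotype
(75% of them in exactly one ecotype), and condition-level log
fold-changes produced by the log-linear TF-activity model
``logE = CS . logTFA`` plus Gaussian noise. A single-hit mutation
simulator supplies alignments with a known number of segregating sites
for the polymorphism statistics.

Reproducibility: every generator takes one integer ``seed``; internal
sub-streams are derived as ``default_rng([seed, stream])`` so adding a
draw to one stream never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import AlignedSequences, ExpressionMatrix
from .nca import ConnectivityPattern

__all__ = [
    "ARABIDOPSIS_ECOTYPES",
    "GroundTruth",
    "generate_connectivity",
    "generate_activities",
    "simulate_expression",
    "simulate_ecotype_experiment",
    "simulate_regulatory_experiment",
    "simulate_alignment",
]

#: The ten wild ecotypes of the emulated study design, south to north.
ARABIDOPSIS_ECOTYPES = (
    "Cvi", "Kas-1", "Kyo-2", "Sha", "Col-0", "Kond", "C24", "Ler", "An-1", "Eri",
)


def ecotype_names(n: int) -> list[str]:
    if n <= len(ARABIDOPSIS_ECOTYPES):
        return list(ARABIDOPSIS_ECOTYPES[:n])
    extra = [f"Eco{i:02d}" for i in range(len(ARABIDOPSIS_ECOTYPES), n)]
    return list(ARABIDOPSIS_ECOTYPES) + extra


@dataclass
class GroundTruth:
    """Everything a downstream test needs to score recovery."""

    connectivity: ConnectivityPattern | None = None
    control_strengths: np.ndarray | None = None  # N x L, support == connectivity
    activities: pd.DataFrame | None = None  # TFs x conditions
    noise_sd: float = 0.0
    de_labels: pd.DataFrame | None = None  # genes x ecotypes, bool
    de_signs: pd.DataFrame | None = None  # genes x ecotypes, {-1, 0, +1}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control_strengths is not None and self.connectivity is not None:
            cs = np.asarray(self.control_strengths, dtype=float)
            if cs.shape != self.connectivity.support.shape:
                raise ParameterError("control_strengths shape differs from support")
            if ((cs != 0) != (self.connectivity.support != 0)).any():
                raise ParameterError(
                    "control_strengths support differs from connectivity support"
                )
            self.control_strengths = cs
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


def generate_connectivity(
    n_genes: int,
    n_tfs: int,
    out_degree: int | tuple = 5,
    sign_fraction_negative: float = 0.3,
    seed: int = 0,
    gene_prefix: str = "G",
    tf_prefix: str = "TF",
) -> tuple[ConnectivityPattern, np.ndarray]:
    """Random bipartite connectivity plus true control strengths.

    Every TF regulates exactly its out-degree of genes and every gene is
    regulated by at least one TF. ``out_degree`` is an int (same for all
    TFs) or ``("uniform", lo, hi)`` for per-TF degrees. Nonzero strengths
    have magnitude Uniform[0.5, 2] and are negative with probability
    ``sign_fraction_negative``.
    """
    if n_genes < n_tfs:
        raise ParameterError("need n_genes >= n_tfs")
    if not 0 <= sign_fraction_negative <= 1:
        raise ParameterError("sign_fraction_negative must be in [0, 1]")
    rng = np.random.default_rng([seed, 0])
    if isinstance(out_degree, tuple):
        kind, lo, hi = out_degree
        if kind != "uniform" or lo < 1 or hi < lo:
            raise ParameterError(f"bad out_degree spec {out_degree!r}")
        if hi > n_genes:
            raise ParameterError("out_degree upper bound exceeds n_genes")
        degrees = rng.integers(lo, hi + 1, size=n_tfs)
    else:
        if out_degree < 1 or out_degree > n_genes:
            raise ParameterError(
                f"out_degree {out_degree} infeasible for {n_genes} genes"
            )
        degrees = np.full(n_tfs, int(out_degree))
    if degrees.sum() < n_genes:
        raise ParameterError(
            f"total out-degree {degrees.sum()} cannot cover {n_genes} genes"
        )

    # Deal every gene one regulator first (guaranteeing coverage), then
    # fill each TF's remaining capacity with distinct extra genes.
    support = np.zeros((n_genes, n_tfs), dtype=np.int8)
    slot_cols = np.repeat(np.arange(n_tfs), degrees)
    rng.shuffle(slot_cols)
    gene_order = rng.permutation(n_genes)
    for g, j in zip(gene_order, slot_cols[:n_genes]):
        support[g, j] = 1
    for j in range(n_tfs):
        deficit = int(degrees[j] - support[:, j].sum())
        if deficit > 0:
            pool = np.flatnonzero(support[:, j] == 0)
            extra = rng.choice(pool, size=deficit, replace=False)
            support[extra, j] = 1

    magnitudes = rng.uniform(0.5, 2.0, size=int(support.sum()))
    neg = rng.random(int(support.sum())) < sign_fraction_negative
    strengths = np.zeros_like(support, dtype=float)
    strengths[support.astype(bool)] = magnitudes * np.where(neg, -1.0, 1.0)

    width_g = max(4, len(str(n_genes)))
    width_t = max(2, len(str(n_tfs)))
    pattern = ConnectivityPattern(
        gene_ids=[f"{gene_prefix}{i:0{width_g}d}" for i in range(n_genes)],
        tf_ids=[f"{tf_prefix}{j:0{width_t}d}" for j in range(n_tfs)],
        support=support,
        signs=np.sign(strengths).astype(np.int8),
    )
    return pattern, strengths


# ---------------------------------------------------------------------------
# Activities and expression
# ---------------------------------------------------------------------------


def generate_activities(
    n_tfs: int,
    n_conditions: int,
    model: str = "iid_normal",
    seed: int = 0,
    blocks: dict | None = None,
    delta: float = 2.0,
    background_sd: float = 0.3,
    tf_ids=None,
    condition_ids=None,
) -> pd.DataFrame:
    """Latent log-activity matrix T (TFs x conditions).

    ``iid_normal`` draws entries from Normal(0, 1). ``ecotype_blocks``
    draws a Normal(0, background_sd) background and adds ``delta`` to
    each TF's activity in its block of conditions (``blocks`` maps TF
    index or id -> iterable of condition indices or names), mimicking
    TFs highly active in one or a few ecotypes.
    """
    if n_conditions < 2:
        raise ParameterError("need at least 2 conditions")
    if tf_ids is None:
        tf_ids = [f"TF{j:02d}" for j in range(n_tfs)]
    if condition_ids is None:
        condition_ids = ecotype_names(n_conditions)
    rng = np.random.default_rng([seed, 1])
    if model == "iid_normal":
        vals = rng.standard_normal((n_tfs, n_conditions))
    elif model == "ecotype_blocks":
        if not blocks:
            raise ParameterError("model='ecotype_blocks' requires a block spec")
        vals = rng.normal(0.0, background_sd, size=(n_tfs, n_conditions))
        tf_pos = {t: i for i, t in enumerate(tf_ids)}
        cond_pos = {c: i for i, c in enumerate(condition_ids)}
        for tf, conds in blocks.items():
            i = tf_pos[tf] if isinstance(tf, str) else int(tf)
            for c in conds:
                j = cond_pos[c] if isinstance(c, str) else int(c)
                vals[i, j] += delta
    else:
        raise ParameterError(f"unknown activity model {model!r}")
    return pd.DataFrame(vals, index=list(tf_ids), columns=list(condition_ids))


def simulate_expression(truth: GroundTruth) -> ExpressionMatrix:
    """Condition-level expression from the forward model C T + noise.

    With ``noise_sd == 0`` the values are exactly the matrix product.
    """
    if truth.control_strengths is None or truth.activities is None:
        raise ParameterError("truth must carry control_strengths and activities")
    C = np.asarray(truth.control_strengths, dtype=float)
    T = truth.activities.to_numpy()
    if C.shape[1] != T.shape[0]:
        raise ParameterError(
            f"dimension mismatch: C is {C.shape}, T is {T.shape}"
        )
    rng = np.random.default_rng([truth.seed, 2])
    vals = C @ T
    if truth.noise_sd > 0:
        vals = vals + rng.normal(0.0, truth.noise_sd, size=vals.shape)
    gene_ids = (
        truth.connectivity.gene_ids
        if truth.connectivity is not None
        else [f"G{i:04d}" for i in range(C.shape[0])]
    )
    return ExpressionMatrix(
        values=pd.DataFrame(
            vals, index=gene_ids, columns=list(truth.activities.columns)
        )
    )


# ---------------------------------------------------------------------------
# Replicate-level experiment
# ---------------------------------------------------------------------------


def _replicate_frame(
    fc: pd.DataFrame,
    n_replicates: int,
    noise_sd: float,
    baseline_mean: float,
    baseline_sd: float,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Expand a genes x ecotypes fold-change matrix into replicate samples.

    Control replicates are baseline + noise; cold replicates additionally
    carry the gene's fold-change for that ecotype.
    """
    genes = list(fc.index)
    ecotypes = list(fc.columns)
    baseline = rng.normal(baseline_mean, baseline_sd, size=len(genes))
    cols, meta = [], []
    data = []
    for eco in ecotypes:
        for treatment in ("control", "cold"):
            shift = fc[eco].to_numpy() if treatment == "cold" else 0.0
            for rep in range(1, n_replicates + 1):
                sample = f"{eco}.{treatment}.{rep}"
                cols.append(sample)
                meta.append((sample, eco, treatment, rep))
                data.append(
                    baseline + shift + rng.normal(0.0, noise_sd, size=len(genes))
                )
    values = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    metadata = pd.DataFrame(
        meta, columns=["sample", "ecotype", "treatment", "replicate"]
    ).set_index("sample")
    return ExpressionMatrix(values=values, metadata=metadata)


def simulate_ecotype_experiment(
    n_ecotypes: int = 10,
    n_replicates: int = 3,
    n_genes: int = 2000,
    de_fraction: float = 0.1,
    effect_size: float = 2.0,
    noise_sd: float = 0.3,
    unique_fraction: float = 0.75,
    seed: int = 0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Replicate-level multi-ecotype experiment with known DE labels.

    ``de_fraction`` of genes respond to cold in at least one ecotype;
    responders are shifted by +/- ``effect_size`` (log2 units) in the
    treated samples of their ecotypes. ``unique_fraction`` of responders
    are assigned to exactly one ecotype; the rest to 2-4 ecotypes.
    """
    if n_replicates < 2:
        raise ParameterError("need at least 2 replicates per group")
    if not 0 <= de_fraction <= 1:
        raise ParameterError("de_fraction must be in [0, 1]")
    if not 0 <= unique_fraction <= 1:
        raise ParameterError("unique_fraction must be in [0, 1]")
    rng = np.random.default_rng([seed, 3])
    genes = [f"G{i:05d}" for i in range(n_genes)]
    ecotypes = ecotype_names(n_ecotypes)
    labels = pd.DataFrame(False, index=genes, columns=ecotypes)
    signs = pd.DataFrame(0, index=genes, columns=ecotypes, dtype=np.int8)

    n_de = int(round(de_fraction * n_genes))
    de_genes = rng.choice(n_genes, size=n_de, replace=False)
    for g in de_genes:
        if rng.random() < unique_fraction:
            members = [int(rng.integers(n_ecotypes))]
        else:
            k = int(rng.integers(2, min(4, n_ecotypes) + 1))
            members = rng.choice(n_ecotypes, size=k, replace=False).tolist()
        sign = 1 if rng.random() < 0.5 else -1
        for e in members:
            labels.iat[int(g), int(e)] = True
            signs.iat[int(g), int(e)] = sign

    fc = signs.astype(float) * effect_size
    expr = _replicate_frame(
        fc, n_replicates, noise_sd, baseline_mean, baseline_sd, rng
    )
    truth = GroundTruth(
        noise_sd=noise_sd, de_labels=labels, de_signs=signs, seed=seed
    )
    return expr, truth


def simulate_regulatory_experiment(
    n_target_genes: int = 192,
    n_tfs: int = 8,
    n_ecotypes: int = 10,
    n_replicates: int = 3,
    out_degree: int = 25,
    sign_fraction_negative: float = 0.3,
    activity_delta: float = 2.0,
    activity_background_sd: float = 0.3,
    noise_sd: float = 0.3,
    seed: int = 0,
    de_threshold: float = 0.5,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Full forward model behind the end-to-end pipeline.

    A random connectivity pattern drives target-gene fold-changes through
    C T; each TF is highly active (+``activity_delta``) in a random block
    of 1-3 ecotypes. TF genes themselves appear in the expression matrix
    with fold-changes tracking their own activity, so that
    expression-activity correlation is well defined. Replicate-level
    samples add Normal(0, noise_sd) noise around per-gene baselines.
    """
    if n_ecotypes < n_tfs:
        raise ParameterError(
            "need n_ecotypes >= n_tfs so the activity matrix can have full row rank"
        )
    rng = np.random.default_rng([seed, 4])
    pattern, strengths = generate_connectivity(
        n_target_genes,
        n_tfs,
        out_degree=out_degree,
        sign_fraction_negative=sign_fraction_negative,
        seed=seed,
    )
    blocks = {
        j: rng.choice(n_ecotypes, size=int(rng.integers(1, 4)), replace=False).tolist()
        for j in range(n_tfs)
    }
    activities = generate_activities(
        n_tfs,
        n_ecotypes,
        model="ecotype_blocks",
        seed=seed,
        blocks=blocks,
        delta=activity_delta,
        background_sd=activity_background_sd,
        tf_ids=pattern.tf_ids,
    )
    target_fc = pd.DataFrame(
        strengths @ activities.to_numpy(),
        index=pattern.gene_ids,
        columns=activities.columns,
    )
    # TF transcripts track their own activity (unit coefficient).
    tf_fc = activities.copy()
    fc = pd.concat([tf_fc, target_fc])
    expr = _replicate_frame(fc, n_replicates, noise_sd, 8.0, 1.5, rng)
    labels = fc.abs() >= de_threshold
    truth = GroundTruth(
        connectivity=pattern,
        control_strengths=strengths,
        activities=activities,
        noise_sd=noise_sd,
        de_labels=labels,
        de_signs=np.sign(fc).astype(np.int8),
        seed=seed,
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_alignment(
    n_seqs: int,
    length: int,
    n_mutations: int,
    seed: int = 0,
    gap_columns=None,
) -> AlignedSequences:
    """Alignment with exactly ``n_mutations`` segregating sites.

    One random ancestral sequence is copied to all sequences; each
    mutation picks a distinct column and flips it to a different base in
    a random nonempty proper subset of sequences (single-hit mutations,
    so segregating-site count equals ``n_mutations``). ``gap_columns``
    optionally lists columns where one random sequence receives a gap,
    for testing the complete-column filter.
    """
    if n_seqs < 2:
        raise ParameterError("need at least 2 sequences")
    if n_mutations > length:
        raise ParameterError(
            f"cannot place {n_mutations} mutations in {length} columns"
        )
    rng = np.random.default_rng([seed, 5])
    ancestral = rng.choice(_BASES, size=length)
    arr = np.tile(ancestral, (n_seqs, 1))
    sites = rng.choice(length, size=n_mutations, replace=False)
    for col in sites:
        k = int(rng.integers(1, n_seqs))  # nonempty proper subset
        carriers = rng.choice(n_seqs, size=k, replace=False)
        alternatives = _BASES[_BASES != ancestral[col]]
        arr[carriers, col] = rng.choice(alternatives)
    if gap_columns is not None:
        for col in gap_columns:
            if not 0 <= col < length:
                raise ParameterError(f"gap column {col} outside alignment")
            arr[int(rng.integers(n_seqs)), col] = "-"
    ids = [f"seq{i:03d}" for i in range(n_seqs)]
    return AlignedSequences.from_array(ids, arr)
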