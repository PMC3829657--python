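"""Regulatory-network reconstruction from inferred TF activities.

Edges are called by Pearson correlation between a TF's inferred activity
profile and a gene's expression profile across conditions: pairs with
|r| >= 0.8 (inclusive) enter the network, positive correlations labelled
activation and negative ones repression. A separate classification
relates each TF's activity to its *own* transcript's expression
(positive / negative / low at |r| > 0.5, strict), and per-ecotype
activity calls flag TFs whose standardized activity exceeds a z-score
cut in one or more ecotypes — TFs active in exactly one ecotype are
"ecotype-specific".

All of this is invariant to the diagonal scaling ambiguity of the NCA
decomposition up to sign: rescaling an activity row leaves |r| unchanged,
and a sign flip flips the edge sign together with the activity's sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError, ParameterError
from .io import RegulatoryNetwork, sign_label
from .nca import ConnectivityPattern

__all__ = [
    "correlate_tf_targets",
    "build_network",
    "classify_tf_correlation",
    "classify_tf_correlations",
    "call_active_ecotypes",
    "ActivityCalls",
]


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows, scale to unit norm; returns (scaled, zero-variance mask)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return Xc / safe[:, None], zero


def _pearson_p(r: np.ndarray, m: int) -> np.ndarray:
    """Two-sided p from the t transform of r with m - 2 degrees of freedom."""
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.clip(1.0 - r**2, 0.0, None)
        t = r * np.sqrt((m - 2) / np.where(denom == 0, np.inf, denom))
        p = 2.0 * stats.t.sf(np.abs(t), m - 2)
    p[denom == 0] = 0.0  # |r| == 1 exactly
    return p


def correlate_tf_targets(
    activities: pd.DataFrame,
    expression: pd.DataFrame,
    pairs: str = "all",
    z0: ConnectivityPattern | None = None,
    exclude_self: bool = True,
) -> pd.DataFrame:
    """Pearson r (and p) between every TF activity row and gene expression row.

    ``activities`` is TFs x conditions, ``expression`` genes x conditions
    with identical condition columns. ``pairs="all"`` evaluates every
    TF x gene pair; ``"z0_only"`` restricts to the support of ``z0``.
    Zero-variance rows cannot be correlated; their pairs are skipped and
    recorded in ``result.attrs["skipped"]``. Self pairs (TF id == gene
    id) are dropped unless ``exclude_self=False``.
    """
    if list(activities.columns) != list(expression.columns):
        raise InputError("activities and expression must share condition order")
    m = activities.shape[1]
    if m < 3:
        raise InputError(f"need >= 3 conditions to correlate; got {m}")
    if pairs not in ("all", "z0_only"):
        raise ParameterError(f"unknown pairs mode {pairs!r}")
    if pairs == "z0_only" and z0 is None:
        raise ParameterError("pairs='z0_only' requires a connectivity pattern")

    A, zero_a = _standardize_rows(activities.to_numpy(dtype=float))
    E, zero_e = _standardize_rows(expression.to_numpy(dtype=float))
    R = np.clip(A @ E.T, -1.0, 1.0)  # TFs x genes
    P = _pearson_p(R, m)

    tf_ids = list(activities.index)
    gene_ids = list(expression.index)
    mask = np.ones_like(R, dtype=bool)
    if pairs == "z0_only":
        sup = z0.to_frame()
        mask &= False
        tf_pos = {t: i for i, t in enumerate(tf_ids)}
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        for g in sup.index:
            for t in sup.columns:
                if sup.loc[g, t] and t in tf_pos and g in gene_pos:
                    mask[tf_pos[t], gene_pos[g]] = True
    skipped = []
    for i in np.flatnonzero(zero_a):
        skipped.append({"tf": tf_ids[i], "reason": "zero-variance activity"})
        mask[i, :] = False
    for j in np.flatnonzero(zero_e):
        skipped.append({"target": gene_ids[j], "reason": "zero-variance expression"})
        mask[:, j] = False
    if exclude_self:
        gene_pos = {g: j for j, g in enumerate(gene_ids)}
        for i, t in enumerate(tf_ids):
            if t in gene_pos:
                mask[i, gene_pos[t]] = False

    ti, gi = np.nonzero(mask)
    out = pd.DataFrame(
        {
            "tf": [tf_ids[i] for i in ti],
            "target": [gene_ids[j] for j in gi],
            "r": R[ti, gi],
            "p": P[ti, gi],
        }
    )
    out.attrs["skipped"] = skipped
    return out


def build_network(
    candidates: pd.DataFrame, r_threshold: float = 0.8
) -> RegulatoryNetwork:
    """Threshold candidate correlations into a signed regulatory network.

    Keeps pairs with |r| >= ``r_threshold`` (inclusive); the sign label is
    activation for r > 0 and repression for r < 0. Genes whose every
    candidate falls below the threshold are absent from the network, so
    the node count can be smaller than the input gene count.
    """
    if not 0 < r_threshold <= 1:
        raise ParameterError(f"r_threshold {r_threshold} outside (0, 1]")
    kept = candidates[candidates["r"].abs() >= r_threshold].copy()
    kept["sign"] = kept["r"].map(sign_label)
    return RegulatoryNetwork(edges=kept.reset_index(drop=True))


def classify_tf_correlation(activity, expression_row, cut: float = 0.5) -> str:
    """Relate a TF's activity profile to its own expression profile.

    Returns ``"positive"`` (r > cut), ``"negative"`` (r < -cut) or
    ``"low"`` (|r| <= cut, strict boundaries).
    """
    a = np.asarray(activity, dtype=float)
    e = np.asarray(expression_row, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise InputError("activity and expression profiles must match in length")
    if a.size < 3:
        raise InputError("need >= 3 conditions")
    if a.std() == 0 or e.std() == 0:
        raise InputError("zero-variance profile; correlation undefined")
    r = float(np.corrcoef(a, e)[0, 1])
    if r > cut:
        return "positive"
    if r < -cut:
        return "negative"
    return "low"


def classify_tf_correlations(
    activities: pd.DataFrame, expression: pd.DataFrame, cut: float = 0.5
) -> pd.DataFrame:
    """Vector form of :func:`classify_tf_correlation` for all fitted TFs.

    TFs without an expression row, or with a constant profile, get class
    ``"undefined"``.
    """
    rows = []
    for tf in activities.index:
        if tf not in expression.index:
            rows.append({"tf": tf, "r": np.nan, "class": "undefined"})
            continue
        a = activities.loc[tf].to_numpy(dtype=float)
        e = expression.loc[tf].to_numpy(dtype=float)
        if a.std() == 0 or e.std() == 0:
            rows.append({"tf": tf, "r": np.nan, "class": "undefined"})
            continue
        r = float(np.corrcoef(a, e)[0, 1])
        cls = "positive" if r > cut else "negative" if r < -cut else "low"
        rows.append({"tf": tf, "r": r, "class": cls})
    return pd.DataFrame(rows).set_index("tf")


@dataclass
class ActivityCalls:
    """Per-TF active-ecotype sets from standardized activity profiles."""

    active: dict[str, tuple[str, ...]]
    ecotype_specific: list[str]
    skipped: list[str] = field(default_factory=list)

    def is_specific(self, tf: str) -> bool:
        return tf in self.ecotype_specific


def call_active_ecotypes(
    activities: pd.DataFrame, z_cut: float = 1.0
) -> ActivityCalls:
    """Call the ecotypes in which each TF is highly active.

    Each activity row is standardized to mean 0, sd 1 (sample sd) across
    conditions; an ecotype is called active when the standardized
    activity is >= ``z_cut``. TFs active in exactly one ecotype are
    flagged ecotype-specific. Constant rows yield no calls.
    """
    if activities.shape[1] < 3:
        raise InputError("need >= 3 conditions")
    active: dict[str, tuple[str, ...]] = {}
    specific: list[str] = []
    skipped: list[str] = []
    conditions = list(activities.columns)
    for tf in activities.index:
        row = activities.loc[tf].to_numpy(dtype=float)
        sd = row.std(ddof=1)
        if sd == 0:
            active[tf] = ()
            skipped.append(tf)
            continue
        z = (row - row.mean()) / sd
        called = tuple(c for c, zi in zip(conditions, z) if zi >= z_cut)
        active[tf] = called
        if len(called) == 1:
            specific.append(tf)
    return ActivityCalls(active=active, ecotype_specific=specific, skipped=skipped)
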