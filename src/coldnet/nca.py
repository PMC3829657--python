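"""Network Component Analysis (NCA).

NCA decomposes a genes x conditions expression matrix ``E`` (log scale)
into a control-strength matrix ``C`` and a hidden transcription-factor
activity matrix ``T``::

    E ~= C @ T,   support(C) <= support(Z0)

where ``Z0`` is a known candidate connectivity pattern saying which TF is
allowed to influence which gene. Minimizing ||E - C T||_F under the
support constraint is solved by a two-step (alternating) least-squares
scheme: holding T fixed, every gene row of C is an ordinary least-squares
problem restricted to that row's allowed TFs; holding C fixed, T is a
single least-squares solve. Each half step is an exact minimization, so
the Frobenius residual is non-increasing.

The decomposition is unique only up to a diagonal rescaling C S, S^-1 T
when Z0 satisfies the NCA identifiability criteria:

(a) C is generically full column rank;
(b) removing any one TF together with all genes it regulates leaves a
    pattern that is still generically full column rank;
(c) T has full row rank, which requires at least as many conditions as
    TFs (M >= L).

:func:`normalize` fixes the diagonal ambiguity by scaling each column of
C to unit Euclidean norm with its largest-magnitude entry positive.

The estimator :class:`NetworkComponentAnalysis` follows scikit-learn
decomposition conventions (compare ``sklearn.decomposition.NMF``): rows
of ``X`` are genes, columns are conditions, ``fit_transform`` returns C
and ``activities_`` (= ``components_``) holds T.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    DegenerateTFError,
    FormatError,
    InputError,
    IrreducibleError,
    NotIdentifiableError,
    ParameterError,
)

__all__ = [
    "ConnectivityPattern",
    "CriteriaReport",
    "NCADecomposition",
    "NetworkComponentAnalysis",
    "check_nca_criteria",
    "reduce_to_compliant",
    "decompose",
    "normalize",
]


# ---------------------------------------------------------------------------
# Connectivity patterns
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityPattern:
    """Binary N x L support saying which TF may regulate which gene.

    ``signs`` optionally carries prior regulation signs in {-1, 0, +1}
    with the same support.
    """

    gene_ids: list[str]
    tf_ids: list[str]
    support: np.ndarray
    signs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.tf_ids = [str(t) for t in self.tf_ids]
        s = np.asarray(self.support)
        if s.shape != (len(self.gene_ids), len(self.tf_ids)):
            raise FormatError(
                f"support shape {s.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.tf_ids)} TFs)"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids in connectivity pattern")
        if len(set(self.tf_ids)) != len(self.tf_ids):
            raise FormatError("duplicate TF ids in connectivity pattern")
        s = (s != 0).astype(np.int8)
        if (s.sum(axis=1) == 0).any():
            gene = self.gene_ids[int(np.argmax(s.sum(axis=1) == 0))]
            raise FormatError(f"gene {gene!r} has no candidate regulator")
        if (s.sum(axis=0) == 0).any():
            tf = self.tf_ids[int(np.argmax(s.sum(axis=0) == 0))]
            raise FormatError(f"TF {tf!r} regulates no gene")
        if s.shape[0] < s.shape[1]:
            raise FormatError(
                f"pattern has more TFs ({s.shape[1]}) than genes ({s.shape[0]})"
            )
        self.support = s
        if self.signs is not None:
            sg = np.asarray(self.signs)
            if sg.shape != s.shape:
                raise FormatError("signs shape differs from support shape")
            if ((sg != 0) != (s != 0)).any():
                raise FormatError("signs support differs from connectivity support")
            self.signs = sg.astype(np.int8)

    @property
    def n_genes(self) -> int:
        return self.support.shape[0]

    @property
    def n_tfs(self) -> int:
        return self.support.shape[1]

    @property
    def n_edges(self) -> int:
        return int(self.support.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.support, index=self.gene_ids, columns=self.tf_ids)

    def restrict(self, gene_ids=None, tf_ids=None) -> "ConnectivityPattern":
        """Sub-pattern on the given genes/TFs; drops rows and columns left
        empty by the restriction."""
        df = self.to_frame()
        if gene_ids is not None:
            keep = [g for g in self.gene_ids if g in set(gene_ids)]
            df = df.loc[keep]
        if tf_ids is not None:
            keep = [t for t in self.tf_ids if t in set(tf_ids)]
            df = df[keep]
        df = df.loc[df.sum(axis=1) > 0, df.sum(axis=0) > 0]
        if df.empty:
            raise InputError("restriction leaves an empty connectivity pattern")
        return ConnectivityPattern(
            gene_ids=list(df.index), tf_ids=list(df.columns), support=df.to_numpy()
        )


# ---------------------------------------------------------------------------
# Identifiability criteria
# ---------------------------------------------------------------------------


@dataclass
class CriteriaReport:
    """Outcome of the three NCA identifiability checks."""

    criterion_a: bool
    criterion_b: bool
    criterion_c: bool
    failing_tfs: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        return self.criterion_a and self.criterion_b and self.criterion_c


def _generic_rank(support: np.ndarray, rng: np.random.Generator, n_trials: int) -> int:
    """Generic rank of a support pattern.

    The rank of a matrix with the given zero pattern and otherwise generic
    entries equals, with probability 1, the maximum rank over random
    instantiations; a handful of trials makes a false negative vanishingly
    unlikely.
    """
    if support.size == 0:
        return 0
    best = 0
    full = min(support.shape)
    for _ in range(n_trials):
        vals = support * rng.standard_normal(support.shape)
        best = max(best, int(np.linalg.matrix_rank(vals)))
        if best == full:
            break
    return best


def check_nca_criteria(
    z0: ConnectivityPattern,
    n_conditions: int,
    n_trials: int = 5,
    seed: int = 0,
) -> CriteriaReport:
    """Evaluate the three NCA identifiability criteria for a pattern.

    (a) generic full column rank of C; (b) rank preserved when any single
    TF is removed together with every gene it regulates; (c) the
    dimensional requirement n_conditions >= L for T to have full row rank.
    """
    rng = np.random.default_rng(seed)
    s = z0.support
    L = z0.n_tfs
    rank_a = _generic_rank(s, rng, n_trials)
    crit_a = rank_a == L

    failing: list[str] = []
    ranks_b: dict[str, int] = {}
    for j, tf in enumerate(z0.tf_ids):
        keep_rows = s[:, j] == 0
        sub = np.delete(s[keep_rows], j, axis=1)
        r = _generic_rank(sub, rng, n_trials)
        ranks_b[tf] = r
        if r < L - 1:
            failing.append(tf)
    crit_b = not failing
    crit_c = n_conditions >= L
    return CriteriaReport(
        criterion_a=crit_a,
        criterion_b=crit_b,
        criterion_c=crit_c,
        failing_tfs=failing,
        details={"rank_a": rank_a, "ranks_after_removal": ranks_b, "L": L,
                 "n_conditions": n_conditions},
    )


def reduce_to_compliant(
    z0: ConnectivityPattern,
    n_conditions: int,
    seed: int = 0,
    n_trials: int = 5,
) -> tuple[ConnectivityPattern, list[dict]]:
    """Greedily remove TFs until the pattern satisfies all three criteria.

    While the criteria fail: a criterion-(c) violation drops the TF with
    the lowest support count (ties broken lexicographically); an (a)/(b)
    violation drops the lowest-support TF among those flagged as failing.
    Genes left without any regulator are dropped alongside. Raises
    :class:`IrreducibleError` if the pattern empties out.
    """
    current = z0
    log: list[dict] = []
    step = 0
    while True:
        report = check_nca_criteria(current, n_conditions, n_trials=n_trials,
                                    seed=seed + step)
        if report.overall_pass:
            return current, log
        if not report.criterion_c:
            candidates = list(current.tf_ids)
            reason = "criterion_c"
        else:
            candidates = report.failing_tfs or list(current.tf_ids)
            reason = "criterion_a" if not report.criterion_a else "criterion_b"
        counts = current.to_frame().sum(axis=0)
        drop = min(candidates, key=lambda t: (counts[t], t))
        keep_tfs = [t for t in current.tf_ids if t != drop]
        if not keep_tfs:
            raise IrreducibleError(
                f"reduction emptied the pattern; removal log: {log + [drop]}"
            )
        df = current.to_frame()[keep_tfs]
        dropped_genes = list(df.index[df.sum(axis=1) == 0])
        df = df.loc[df.sum(axis=1) > 0]
        if df.empty or df.shape[0] < df.shape[1]:
            raise IrreducibleError(
                f"reduction left an infeasible pattern after removing {drop!r}"
            )
        log.append({"tf": drop, "reason": reason, "genes_dropped": dropped_genes})
        current = ConnectivityPattern(
            gene_ids=list(df.index), tf_ids=list(df.columns), support=df.to_numpy()
        )
        step += 1


# ---------------------------------------------------------------------------
# Decomposition result container
# ---------------------------------------------------------------------------


@dataclass
class NCADecomposition:
    """Result of an NCA fit: E ~= C T with support(C) <= Z0."""

    control_strengths: pd.DataFrame  # genes x TFs
    activities: pd.DataFrame  # TFs x conditions
    residual_history: list[float]
    scale_record: dict  # {"norms": ..., "signs": ...} applied by normalize
    converged: bool
    n_iter: int
    identifiable: bool = True
    rank_deficient_rows: list[str] = field(default_factory=list)

    @property
    def C(self) -> np.ndarray:
        return self.control_strengths.to_numpy()

    @property
    def T(self) -> np.ndarray:
        return self.activities.to_numpy()

    @property
    def final_residual(self) -> float:
        return self.residual_history[-1]


def _normalize_arrays(
    C: np.ndarray, T: np.ndarray, tf_ids: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unit-norm columns of C, largest-|entry| positive; T rescaled inversely."""
    norms = np.linalg.norm(C, axis=0)
    if (norms == 0).any():
        tf = tf_ids[int(np.argmax(norms == 0))]
        raise DegenerateTFError(f"TF {tf!r} has an all-zero control-strength column")
    signs = np.empty(C.shape[1])
    for j in range(C.shape[1]):
        signs[j] = 1.0 if C[np.argmax(np.abs(C[:, j])), j] >= 0 else -1.0
    scale = norms * signs
    return C / scale, T * scale[:, None], norms, signs


def normalize(dec: NCADecomposition) -> NCADecomposition:
    """Resolve the diagonal scaling ambiguity C S, S^-1 T.

    Each column of C is scaled to unit Euclidean norm with its
    largest-magnitude entry positive; the reciprocal scale is applied to
    the matching row of T, so the product C T is unchanged to machine
    precision. Idempotent.
    """
    C, T, norms, signs = _normalize_arrays(
        dec.C.copy(), dec.T.copy(), list(dec.control_strengths.columns)
    )
    return NCADecomposition(
        control_strengths=pd.DataFrame(
            C, index=dec.control_strengths.index, columns=dec.control_strengths.columns
        ),
        activities=pd.DataFrame(
            T, index=dec.activities.index, columns=dec.activities.columns
        ),
        residual_history=list(dec.residual_history),
        scale_record={
            "norms": norms * np.asarray(dec.scale_record.get("norms", 1.0)),
            "signs": signs * np.asarray(dec.scale_record.get("signs", 1.0)),
        },
        converged=dec.converged,
        n_iter=dec.n_iter,
        identifiable=dec.identifiable,
        rank_deficient_rows=list(dec.rank_deficient_rows),
    )


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class NetworkComponentAnalysis(TransformerMixin, BaseEstimator):
    """Constrained matrix decomposition E ~= C T with known support.

    Parameters
    ----------
    connectivity : ConnectivityPattern
        The candidate TF -> gene support Z0. Row order of ``X`` must match
        ``connectivity.gene_ids`` (DataFrames are reindexed by gene id).
    tol : float
        Convergence threshold on the relative change of the Frobenius
        residual between full iterations.
    max_iter : int
        Maximum alternating-least-squares iterations per restart.
    n_restarts : int
        Independent random initializations of T; the solution with the
        smallest final residual is kept.
    strict : bool
        If True (default) refuse to fit a pattern failing the NCA
        identifiability criteria; if False, warn and proceed, stamping
        ``identifiable_ = False``.
    random_state : int or None
        Seed for initialization (and the criteria check's generic-rank
        instantiations).

    Attributes
    ----------
    control_strengths_ : ndarray (n_genes, n_tfs)
        Normalized C; zeros outside the support are exact.
    activities_ : ndarray (n_tfs, n_conditions)
        Normalized T. Also exposed as ``components_``.
    residual_history_ : list of float
        Frobenius residual after each full iteration (best restart).
    converged_, n_iter_, identifiable_ : fit diagnostics.
    """

    def __init__(
        self,
        connectivity: ConnectivityPattern | None = None,
        tol: float = 1e-6,
        max_iter: int = 500,
        n_restarts: int = 10,
        strict: bool = True,
        random_state: int | None = None,
    ):
        self.connectivity = connectivity
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.strict = strict
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _validate_input(self, X) -> np.ndarray:
        z0 = self.connectivity
        if z0 is None:
            raise ParameterError("connectivity pattern is required")
        if isinstance(X, pd.DataFrame):
            missing = set(z0.gene_ids) - set(X.index)
            if missing:
                raise InputError(
                    f"expression matrix lacks genes from Z0: {sorted(missing)[:5]}"
                )
            X = X.loc[z0.gene_ids]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != z0.n_genes:
            raise InputError(
                f"expression shape {X.shape} does not match "
                f"{z0.n_genes} genes in Z0"
            )
        if not np.isfinite(X).all():
            raise InputError("expression matrix contains non-finite values")
        return X

    @staticmethod
    def _support_groups(support: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Group gene rows sharing the same support mask (batched solves)."""
        groups: dict[bytes, list[int]] = {}
        mask = support.astype(bool)
        for i in range(support.shape[0]):
            groups.setdefault(mask[i].tobytes(), []).append(i)
        out = []
        for key, rows in groups.items():
            m = np.frombuffer(key, dtype=bool)
            out.append((np.flatnonzero(m), np.asarray(rows)))
        return out

    def _solve_C(
        self,
        E: np.ndarray,
        T: np.ndarray,
        groups,
        deficient: set[int],
    ) -> np.ndarray:
        """Row-wise least squares for C given T, restricted to the support."""
        L = T.shape[0]
        C = np.zeros((E.shape[0], L))
        for cols, rows in groups:
            Tm = T[cols]  # k x M
            G = Tm @ Tm.T
            B = Tm @ E[rows].T  # k x n_rows
            try:
                coeff = np.linalg.solve(G, B)
                # guard against ill-conditioned but non-singular Gram matrices
                if not np.isfinite(coeff).all():
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                coeff = np.linalg.lstsq(Tm.T, E[rows].T, rcond=None)[0]
                deficient.update(int(r) for r in rows)
            C[np.ix_(rows, cols)] = coeff.T
        return C

    def _als(self, E, support, groups, rng):
        """One restart of two-step least squares; returns (C, T, history, ...)."""
        L, M = support.shape[1], E.shape[1]
        T = rng.standard_normal((L, M))
        history: list[float] = []
        deficient: set[int] = set()
        converged = False
        scale = np.linalg.norm(E)
        for _ in range(self.max_iter):
            C = self._solve_C(E, T, groups, deficient)
            T = np.linalg.lstsq(C, E, rcond=None)[0]
            res = float(np.linalg.norm(E - C @ T))
            history.append(res)
            if len(history) > 1:
                prev = history[-2]
                if abs(prev - res) <= self.tol * max(prev, 1e-30):
                    converged = True
                    break
            if res <= 1e-15 * max(scale, 1e-30):
                converged = True
                break
        return C, T, history, converged, deficient

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        z0 = self.connectivity
        E = self._validate_input(X)
        report = check_nca_criteria(
            z0, n_conditions=E.shape[1], seed=0 if self.random_state is None
            else int(self.random_state)
        )
        self.criteria_report_ = report
        if not report.overall_pass:
            msg = (
                "connectivity pattern fails NCA identifiability criteria "
                f"(a={report.criterion_a}, b={report.criterion_b}, "
                f"c={report.criterion_c}; failing TFs: {report.failing_tfs[:5]})"
            )
            if self.strict:
                raise NotIdentifiableError(msg + "; use strict=False to proceed")
            warnings.warn(msg + "; result is not identifiable", stacklevel=2)
        self.identifiable_ = report.overall_pass

        groups = self._support_groups(z0.support)
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_restarts)):
            C, T, history, converged, deficient = self._als(
                E, z0.support, groups, rng
            )
            if best is None or history[-1] < best[2][-1]:
                best = (C, T, history, converged, deficient)
        C, T, history, converged, deficient = best

        self.scale_record_ = {"norms": np.ones(z0.n_tfs), "signs": np.ones(z0.n_tfs)}
        if (np.linalg.norm(C, axis=0) > 0).all():
            C, T, norms, signs = _normalize_arrays(C, T, z0.tf_ids)
            self.scale_record_ = {"norms": norms, "signs": signs}
        else:
            warnings.warn(
                "zero control-strength column; skipping scale normalization",
                stacklevel=2,
            )
        self.control_strengths_ = C
        self.activities_ = T
        self.components_ = T
        self.residual_history_ = history
        self.converged_ = converged
        self.n_iter_ = len(history)
        self.rank_deficient_rows_ = sorted(
            z0.gene_ids[i] for i in deficient
        )
        self.gene_ids_ = list(z0.gene_ids)
        self.tf_ids_ = list(z0.tf_ids)
        return C

    def transform(self, X) -> np.ndarray:
        """Project new gene rows onto the fitted activities (support-constrained)."""
        if not hasattr(self, "activities_"):
            raise InputError("estimator is not fitted")
        E = self._validate_input(X)
        groups = self._support_groups(self.connectivity.support)
        return self._solve_C(E, self.activities_, groups, set())

    def to_decomposition(self, condition_ids=None) -> NCADecomposition:
        """Package fitted attributes as an :class:`NCADecomposition`."""
        if not hasattr(self, "activities_"):
            raise InputError("estimator is not fitted")
        if condition_ids is None:
            condition_ids = [f"cond{i}" for i in range(self.activities_.shape[1])]
        return NCADecomposition(
            control_strengths=pd.DataFrame(
                self.control_strengths_, index=self.gene_ids_, columns=self.tf_ids_
            ),
            activities=pd.DataFrame(
                self.activities_, index=self.tf_ids_, columns=list(condition_ids)
            ),
            residual_history=list(self.residual_history_),
            scale_record=dict(self.scale_record_),
            converged=self.converged_,
            n_iter=self.n_iter_,
            identifiable=self.identifiable_,
            rank_deficient_rows=list(self.rank_deficient_rows_),
        )


def decompose(
    e,
    z0: ConnectivityPattern,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
    seed: int = 0,
    strict: bool = True,
) -> NCADecomposition:
    """Functional wrapper around :class:`NetworkComponentAnalysis`.

    ``e`` may be an :class:`~coldnet.io.ExpressionMatrix`, a DataFrame or
    an array whose rows follow ``z0.gene_ids``.
    """
    from .io import ExpressionMatrix

    if isinstance(e, ExpressionMatrix):
        X = e.values
    else:
        X = e
    est = NetworkComponentAnalysis(
        connectivity=z0,
        tol=tol,
        max_iter=max_iter,
        n_restarts=n_restarts,
        strict=strict,
        random_state=seed,
    )
    est.fit(X)
    cond = list(X.columns) if isinstance(X, pd.DataFrame) else None
    return est.to_decomposition(condition_ids=cond)
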