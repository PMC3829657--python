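"""Nucleotide polymorphism statistics: segregating sites, pi, Tajima's D.

Tajima's D contrasts two estimators of the population mutation rate
theta: the mean number of pairwise differences pi and Watterson's
S / a1, where S is the segregating-site count and a1 = sum_{i=1}^{n-1} 1/i.
Under the neutral equilibrium model both estimate the same quantity, so

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1))

is centred near zero; negative D indicates an excess of rare, recent
alleles, positive D an excess of intermediate-frequency alleles. The
variance coefficients depend on the sample size n alone:

    a1 = sum 1/i,  a2 = sum 1/i^2            (i = 1 .. n-1)
    b1 = (n+1) / (3(n-1)),  b2 = 2(n^2+n+3) / (9n(n-1))
    c1 = b1 - 1/a1,  c2 = b2 - (n+2)/(a1 n) + a2/a1^2
    e1 = c1/a1,  e2 = c2 / (a1^2 + a2)

Columns containing gaps, missing data or any ambiguity code are removed
before computing statistics (:func:`filter_complete_columns`); only pure
A/C/G/T columns are analyzed. With S = 0 the statistic is undefined and
reported as NaN with an explicit status, never silently zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InputError
from .io import AlignedSequences

__all__ = [
    "PolymorphismStats",
    "filter_complete_columns",
    "segregating_sites",
    "pairwise_pi",
    "tajima_coefficients",
    "tajimas_d",
    "analyze_alignment",
]

_NUCLEOTIDES = frozenset("ACGT")


def filter_complete_columns(
    aln: AlignedSequences,
) -> tuple[AlignedSequences, list[int]]:
    """Drop every column containing a gap, N or other non-ACGT symbol.

    Returns the filtered alignment and the (original) indices of removed
    columns, order preserved.
    """
    arr = aln.to_array()
    keep = np.array(
        [all(c in _NUCLEOTIDES for c in arr[:, j]) for j in range(arr.shape[1])]
    )
    removed = [int(j) for j in np.flatnonzero(~keep)]
    if not keep.any():
        raise InputError("no complete columns remain after filtering")
    return AlignedSequences.from_array(aln.seq_ids, arr[:, keep]), removed


def segregating_sites(aln: AlignedSequences) -> int:
    """Number of columns with more than one nucleotide state."""
    arr = aln.to_array()
    return int(sum((arr[:, j] != arr[0, j]).any() for j in range(arr.shape[1])))


def pairwise_pi(aln: AlignedSequences) -> float:
    """Mean pairwise differences over all unordered sequence pairs.

    Computed per alignment (sum over sites), not per site. Counting per
    column: a column with base counts c_b contributes
    C(n,2) - sum_b C(c_b,2) differing pairs.
    """
    arr = aln.to_array()
    n = arr.shape[0]
    n_pairs = n * (n - 1) // 2
    total = 0
    for j in range(arr.shape[1]):
        _, counts = np.unique(arr[:, j], return_counts=True)
        same = int((counts * (counts - 1) // 2).sum())
        total += n_pairs - same
    return total / n_pairs


def tajima_coefficients(n: int) -> dict[str, float]:
    """The sample-size-dependent constants of Tajima's D (n >= 2)."""
    if n < 2:
        raise InputError("coefficients require n >= 2")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


@dataclass
class PolymorphismStats:
    n: int
    L_sites: int
    S_seg: int
    pi: float
    theta_w: float
    coefficients: dict[str, float]
    D: float
    status: str  # "ok" or "undefined_no_segregating_sites"

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "L_sites": self.L_sites,
            "S_seg": self.S_seg,
            "pi": self.pi,
            "theta_w": self.theta_w,
            "D": self.D,
            "status": self.status,
        }
        d.update(self.coefficients)
        return d


def tajimas_d(aln: AlignedSequences, per_site: bool = False) -> PolymorphismStats:
    """Full polymorphism statistics for a complete-column alignment.

    ``per_site=True`` additionally divides pi and theta_w by the number of
    analyzed columns (D itself is scale-free and unaffected). With no
    segregating site the denominator vanishes; D is NaN and ``status``
    says why.
    """
    n = aln.n
    if n < 4:
        warnings.warn(
            f"Tajima's D with n={n} sequences is poorly calibrated; n >= 4 "
            "is recommended",
            stacklevel=2,
        )
    S = segregating_sites(aln)
    pi = pairwise_pi(aln)
    coeff = tajima_coefficients(n)
    theta_w = S / coeff["a1"]
    if S == 0:
        D = float("nan")
        status = "undefined_no_segregating_sites"
    else:
        var = coeff["e1"] * S + coeff["e2"] * S * (S - 1)
        if var <= 0:
            # for n < 4 the variance coefficients vanish identically
            D = float("nan")
            status = "undefined_zero_variance"
        else:
            D = (pi - theta_w) / np.sqrt(var)
            status = "ok"
    L = aln.length
    if per_site:
        pi, theta_w = pi / L, theta_w / L
    return PolymorphismStats(
        n=n, L_sites=L, S_seg=S, pi=pi, theta_w=theta_w,
        coefficients=coeff, D=float(D), status=status,
    )


def analyze_alignment(
    aln: AlignedSequences, per_site: bool = False
) -> tuple[PolymorphismStats, list[int]]:
    """Filter incomplete columns, then compute the full statistics."""
    filtered, removed = filter_complete_columns(aln)
    return tajimas_d(filtered, per_site=per_site), removed
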