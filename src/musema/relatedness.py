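"""Numerator (A), origin-generation (A_k) and mutational (M) relationship
matrices, plus a Monte-Carlo gene-dropping oracle.

A scales additive genetic variance present in the pedigree base; A_k scales
the variance contributed by mutations that arose in generation-k
individuals; and the mutational relationship matrix is their sum over
origin generations from the earliest to the second-to-last generation t,

    M = sum_{k} A_k,

so that in the animal model V_A,0 = A * sigma^2_a and V_M = M * sigma^2_m.

The A_k recursion treats generation-k individuals as mutually unrelated,
non-inbred carriers of that generation's new mutational variance.  For
descendants the individual-level recursion needs, besides the matrix, the
summed variance T_i of an individual's two haplotype values (T = 1 for all
individuals in ordinary A, but decays toward the origin cohort's
contribution in A_k):

    A_k[i, j] = (A_k[sire_i, j] + A_k[dam_i, j]) / 2        (j born earlier)
    A_k[i, i] = T_sire/2 + T_dam/2 + A_k[sire_i, dam_i] / 2
    T_i       = (T_sire + T_dam) / 2

which is exact under Mendelian gene dropping (verified against the
Monte-Carlo oracle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from musema.pedigree import Pedigree


@dataclass
class RelationshipMatrix:
    """Symmetric expected-covariance scaler over an ordered set of
    individuals.  ``role`` is "A", "M", "A_k" or "oracle"."""

    individual_ids: list[str]
    values: np.ndarray
    role: str
    se: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")

    def loc(self, i: str, j: str) -> float:
        a = self.individual_ids.index(i)
        b = self.individual_ids.index(j)
        return float(self.values[a, b])

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        pos = [self.individual_ids.index(i) for i in ids]
        idx = np.ix_(pos, pos)
        return RelationshipMatrix(list(ids), self.values[idx], self.role,
                                  None if self.se is None else self.se[idx])


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders (individuals without recorded parents) form the base:
    diagonal 1, mutually unrelated.  A_ii = 1 + F_i.
    """
    n = len(ped)
    parents = ped.parent_positions()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = parents[i]
        if s < 0:
            A[i, i] = 1.0
        else:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[:i, i] = A[i, :i]
            A[i, i] = 1.0 + 0.5 * A[s, d]
    return RelationshipMatrix(ped.ids, A, "A")


def _origin_matrix(ped: Pedigree, origin: set[int]) -> np.ndarray:
    """Covariance scaler for alleles originating as new mutations in the
    stated origin generations (one unit of variance added per individual
    per origin generation it belongs to)."""
    n = len(ped)
    parents = ped.parent_positions()
    gens = ped.generations()
    A = np.zeros((n, n))
    T = np.zeros(n)  # summed variance of the two haplotype values
    for i in range(n):
        s, d = parents[i]
        if s >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[:i, i] = A[i, :i]
            A[i, i] = 0.5 * (T[s] + T[d]) + 0.5 * A[s, d]
            T[i] = 0.5 * (T[s] + T[d])
        if int(gens[i]) in origin:
            A[i, i] += 1.0
            T[i] += 1.0
    return A


def build_A_k(ped: Pedigree, k: int) -> RelationshipMatrix:
    """Relationship matrix for mutations originating in generation-k
    individuals.

    Individuals born before generation k have zero rows and columns;
    generation-k individuals are the base (diagonal 1, mutually unrelated);
    later individuals follow the haplotype-variance recursion.
    """
    gens = ped.generations()
    t = int(gens.max()) - 1
    lo = int(gens.min())
    if not (lo <= k <= t):
        raise ValueError(f"origin generation {k} outside [{lo}, {t}]")
    return RelationshipMatrix(ped.ids, _origin_matrix(ped, {k}), "A_k")


def build_M(ped: Pedigree, include_burnin: bool = True) -> RelationshipMatrix:
    """Mutational relationship matrix: elementwise sum of A_k over origin
    generations k from the earliest generation (or 0 when
    ``include_burnin`` is False) to the second-to-last generation t.

    Mutations arising in the final generation contribute no between-line
    information and are excluded (the sum stops at t).
    """
    gens = ped.generations()
    t = int(gens.max()) - 1
    lo = int(gens.min()) if include_burnin else 0
    if t < lo:
        raise ValueError("pedigree needs at least 2 generations for M")
    n = len(ped)
    M = np.zeros((n, n))
    for k in range(lo, t + 1):
        M += _origin_matrix(ped, {k})
    return RelationshipMatrix(ped.ids, M, "M")


def gene_drop_oracle(ped: Pedigree, origin_generations: Iterable[int],
                     n_reps: int, seed: int) -> RelationshipMatrix:
    """Monte-Carlo estimate of the expected-covariance matrix from
    unit-variance variants seeded in the stated origin generations and
    transmitted by Mendelian segregation.

    Each individual in an origin generation receives independent fresh
    effects of variance 1/2 on each of its two haplotypes (one unit of new
    variance in total); every transmission passes one of the parent's two
    haplotype values at random.  The returned matrix is the empirical
    second-moment matrix across ``n_reps`` independent drops, with
    per-entry Monte-Carlo standard errors in ``.se``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    origin = {int(g) for g in origin_generations}
    rng = np.random.default_rng(seed)
    n = len(ped)
    parents = ped.parent_positions()
    gens = ped.generations()

    # haplotype values: shape (n, 2, n_reps)
    hap = np.zeros((n, 2, n_reps), dtype=np.float64)
    for i in range(n):
        s, d = parents[i]
        if s >= 0:
            pick_s = rng.integers(0, 2, size=n_reps)
            pick_d = rng.integers(0, 2, size=n_reps)
            hap[i, 0] = hap[s, pick_s, np.arange(n_reps)]
            hap[i, 1] = hap[d, pick_d, np.arange(n_reps)]
        if int(gens[i]) in origin:
            hap[i] += rng.normal(0.0, np.sqrt(0.5), size=(2, n_reps))

    X = hap.sum(axis=1)                      # genotypic values, (n, n_reps)
    est = (X @ X.T) / n_reps                 # true means are zero
    sq = X * X
    second = (sq @ sq.T) / n_reps
    var = np.maximum(second - est * est, 0.0)
    se = np.sqrt(var / n_reps)
    return RelationshipMatrix(ped.ids, est, "oracle", se=se)
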