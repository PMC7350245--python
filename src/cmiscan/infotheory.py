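"""Plug-in entropy, mutual information, and the two-locus extractor.

All quantities use natural logarithms (nats) and maximum-likelihood
("plug-in") cell probabilities with the convention 0·log 0 = 0; no bias
correction is applied.  For a balanced two-population sample the label
entropy H(y) = ln 2 ≈ 0.6931 nats is the ceiling of every score here,
which is what makes the conventional flagging threshold θ = 0.693
interpretable: a pair of loci attains it only when the two-locus
genotype perfectly determines the population.

The extractor is the joint mutual information I(y; (x1, x2)) between the
population label y and the composite genotype at two adjacent loci.  By
the chain rule it decomposes as

    I(y; x1, x2) = I(y; x1 | x2) + I(y; x2),

and both routes are implemented independently (``mi_extractor`` via the
composite variable; ``conditional_mi`` via the explicit triple sum), so
the identity doubles as an internal consistency check.

Significance is assessed against a label-permutation null: population
labels are shuffled against the fixed genotype columns.  The Monte Carlo
p-value carries the add-one correction p = (1 + #{null ≥ obs}) / (1 + B);
for small samples an exact mode enumerates all C(n, n_A) balanced label
assignments instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple, Union

import numpy as np
from scipy.special import xlogy

_CLAMP = 1e-12

CountsLike = Union[Sequence[float], np.ndarray, Mapping[object, float]]


@dataclass
class JointCountTable:
    """A named-axis contingency table of non-negative integer counts."""

    counts: np.ndarray
    axes: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != len(self.axes):
            raise ValueError("axes do not match table dimensionality")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("count table is empty")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_vectors(cls, axes: Tuple[str, ...], *vectors: Sequence[int]) -> "JointCountTable":
        """Tabulate aligned categorical code vectors into a joint table."""
        if len(vectors) != len(axes):
            raise ValueError("one vector per axis required")
        arrs = [np.asarray(v, dtype=np.int64) for v in vectors]
        shape = tuple(int(a.max()) + 1 for a in arrs)
        flat = np.ravel_multi_index(arrs, shape)
        counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
        return cls(counts=counts.astype(float), axes=axes)


def _as_counts(counts: CountsLike) -> np.ndarray:
    if isinstance(counts, Mapping):
        arr = np.asarray(list(counts.values()), dtype=float)
    else:
        arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.sum() <= 0:
        raise ValueError("counts sum to zero")
    return arr


def entropy(counts: CountsLike) -> float:
    """Plug-in Shannon entropy H = −Σ p ln p in nats."""
    arr = _as_counts(counts).ravel()
    n = arr.sum()
    return float(math.log(n) - xlogy(arr, arr).sum() / n)


def _table(joint: Union[JointCountTable, np.ndarray], ndim: int) -> np.ndarray:
    arr = joint.counts if isinstance(joint, JointCountTable) else np.asarray(joint, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"expected a {ndim}-axis count table, got {arr.ndim} axes")
    if (arr < 0).any() or arr.sum() <= 0:
        raise ValueError("invalid count table")
    return arr


def mutual_information(joint: Union[JointCountTable, np.ndarray]) -> float:
    """I(x; y) = Σ p(x,y) ln[p(x,y) / (p(x) p(y))] from a two-axis count table."""
    c = _table(joint, 2)
    n = c.sum()
    cx = c.sum(axis=1, keepdims=True)
    cy = c.sum(axis=0, keepdims=True)
    # Σ (c/n) ln(c n / (cx cy)); xlogy keeps empty cells at exactly 0.
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c > 0, c * n / (cx * cy), 1.0)
    val = float(xlogy(c, ratio).sum() / n)
    return 0.0 if -_CLAMP < val < 0 else val


def conditional_mi(joint: Union[JointCountTable, np.ndarray]) -> float:
    """I(y; x1 | x2) from a three-axis (y, x1, x2) count table.

    Direct triple sum Σ p(y,s1,s2) ln[ p(s2) p(y,s1,s2) / (p(y,s2) p(s1,s2)) ].
    """
    c = _table(joint, 3)
    n = c.sum()
    c_s2 = c.sum(axis=(0, 1))[None, None, :]
    c_y_s2 = c.sum(axis=1)[:, None, :]
    c_s1_s2 = c.sum(axis=0)[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c > 0, (c_s2 * c) / (c_y_s2 * c_s1_s2), 1.0)
    val = float(xlogy(c, ratio).sum() / n)
    return 0.0 if -_CLAMP < val < 0 else max(val, 0.0)


def mi_extractor(joint: Union[JointCountTable, np.ndarray]) -> float:
    """I(y; (x1, x2)) — the two-locus extractor, for a binary y axis.

    Computed as plain mutual information between y and the composite
    variable (x1, x2); by the chain rule it equals
    conditional_mi(y; x1 | x2) + I(y; x2).
    """
    c = _table(joint, 3)
    if c.shape[0] != 2:
        raise ValueError(f"extractor requires a binary first (population) axis, got {c.shape[0]} levels")
    return mutual_information(c.reshape(2, -1))


def extractor_from_vectors(
    y: Sequence[int], x1: Sequence[int], x2: Sequence[int]
) -> float:
    """Extractor value straight from aligned per-sample code vectors."""
    joint = JointCountTable.from_vectors(("y", "x1", "x2"), y, x1, x2)
    if joint.counts.shape[0] != 2:
        raise ValueError("y must take exactly the codes {0, 1}")
    return mi_extractor(joint)


@dataclass
class CmiScore:
    """Extractor value and permutation significance for one adjacent pair."""

    pair: Tuple[int, int]
    value_nats: float
    p_value: float
    n_permutations: int
    exact_null: bool


def _binary_mi_rows(counts_a: np.ndarray, counts_b: np.ndarray) -> np.ndarray:
    """Row-wise MI between a binary label and a categorical variable.

    counts_a/counts_b: (rows, classes) counts of each class within label
    0 and label 1.  Vectorized over rows (one row per permutation).
    """
    n_a = counts_a.sum(axis=1, keepdims=True)
    n_b = counts_b.sum(axis=1, keepdims=True)
    tot = counts_a + counts_b
    n = n_a + n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        ra = np.where(counts_a > 0, counts_a * n / (n_a * tot), 1.0)
        rb = np.where(counts_b > 0, counts_b * n / (n_b * tot), 1.0)
    return (xlogy(counts_a, ra).sum(axis=1) + xlogy(counts_b, rb).sum(axis=1)) / n[:, 0]


def _composite_onehot(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """One-hot (n, m) indicator of the composite (x1, x2) class per sample."""
    comp = x1.astype(np.int64) * (int(x2.max()) + 1) + x2.astype(np.int64)
    _, dense = np.unique(comp, return_inverse=True)
    m = int(dense.max()) + 1
    onehot = np.zeros((comp.size, m))
    onehot[np.arange(comp.size), dense] = 1.0
    return onehot


MAX_EXACT_ASSIGNMENTS = 200_000


def permutation_pvalue(
    observed_nats: float,
    y_labels: Sequence[int],
    x1_vector: Sequence[int],
    x2_vector: Sequence[int],
    n_perm: int = 9_999,
    seed: Union[int, np.random.Generator, None] = None,
    exact: bool = False,
) -> Tuple[float, bool]:
    """Label-permutation p-value for an observed extractor score.

    Monte Carlo mode: p = (1 + #{null ≥ obs}) / (1 + n_perm).  Exact mode
    enumerates every balanced label assignment C(n, n_A) (the true one
    included) and reports the tail fraction; it refuses when the number
    of assignments exceeds ``MAX_EXACT_ASSIGNMENTS``.
    """
    y = np.asarray(y_labels, dtype=np.int8)
    x1 = np.asarray(x1_vector, dtype=np.int64)
    x2 = np.asarray(x2_vector, dtype=np.int64)
    if not (y.shape == x1.shape == x2.shape):
        raise ValueError("y, x1, x2 must be aligned vectors")
    if set(np.unique(y).tolist()) - {0, 1}:
        raise ValueError("y labels must be coded 0/1")
    n = y.size
    onehot = _composite_onehot(x1, x2)
    class_totals = onehot.sum(axis=0)
    threshold = observed_nats - _CLAMP

    if exact:
        n_a = int((y == 0).sum())
        n_combos = math.comb(n, n_a)
        if n_combos > MAX_EXACT_ASSIGNMENTS:
            raise ValueError(
                f"exact null would enumerate C({n},{n_a}) = {n_combos} assignments; "
                f"use Monte-Carlo (exact=False)"
            )
        member = np.zeros((n_combos, n))
        for r, combo in enumerate(itertools.combinations(range(n), n_a)):
            member[r, list(combo)] = 1.0
        counts_a = member @ onehot
        null = _binary_mi_rows(counts_a, class_totals[None, :] - counts_a)
        p = float((null >= threshold).sum() / n_combos)
        return p, True

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = rng.permuted(np.tile(y, (n_perm, 1)), axis=1)
    member = (perms == 0).astype(float)
    counts_a = member @ onehot
    null = _binary_mi_rows(counts_a, class_totals[None, :] - counts_a)
    exceed = int((null >= threshold).sum())
    return (1.0 + exceed) / (1.0 + n_perm), False


def score_pair(
    y: Sequence[int],
    x1: Sequence[int],
    x2: Sequence[int],
    pair: Tuple[int, int],
    n_perm: int = 9_999,
    seed: Union[int, np.random.Generator, None] = None,
    exact: bool = False,
) -> CmiScore:
    """Extractor value plus permutation p-value for one adjacent pair."""
    value = extractor_from_vectors(y, x1, x2)
    p, exact_null = permutation_pvalue(value, y, x1, x2, n_perm=n_perm, seed=seed, exact=exact)
    n_used = math.comb(len(list(y)), int((np.asarray(y) == 0).sum())) if exact_null else n_perm
    return CmiScore(pair=pair, value_nats=value, p_value=p, n_permutations=n_used, exact_null=exact_null)
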