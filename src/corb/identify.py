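"""Analytical identification of oblique multidimensional Rasch models.

A completely oblique D-dimensional dichotomous Rasch model is identified
when a reduced design matrix ``A'`` can be constructed that pins down the
vector of per-dimension additive constants.  The procedure partitions item
parameters into D disjoint sets, designates one dropped parameter per set
(re-expressed as the negative sum of its set-mates; a singleton's parameter
is anchored at zero), and forms the D-by-D matrix ``C`` whose i-th row is
the column sum of the scoring matrix ``B`` over set i.  The model is
identified for that partition iff ``det(C) != 0``; since the constants
vector solves the homogeneous system ``C c = 0``, a nonsingular ``C``
forces ``c = 0``.

Because each row of ``C`` lies in the row space of ``B``, a nonsingular
``C`` exists iff ``B`` has full column rank, and singleton sets suffice to
witness it.  The ``rank`` method uses this equivalence; the ``brute_force``
method searches all singleton-set partitions and serves as an independent
oracle on small structures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .structures import (
    DesignMatrix,
    LoadingStructure,
    ScoringMatrix,
    StructureError,
    gsm_scoring_matrix,
)

__all__ = [
    "ItemPartition",
    "IdentificationReport",
    "IdentificationError",
    "cmatrix",
    "check_identification",
    "reduced_design_matrix",
    "gsm_identification_suite",
    "DET_TOL",
]

#: Tolerance on |det C|.  C is integer-valued for 0/1/-1 scoring, where the
#: determinant is computed exactly; the tolerance only guards float paths.
DET_TOL = 1e-9


class IdentificationError(ValueError):
    """Partition or structure unusable for identification."""


@dataclass
class ItemPartition:
    """D disjoint non-empty item sets with one dropped item each.

    ``sets`` holds 0-based item indices; the sets need not cover all items.
    The dropped item's parameter is re-expressed as the negative sum of its
    set-mates (anchored at zero for a singleton set).
    """

    sets: list[list[int]]
    dropped: list[int] | None = None

    def __post_init__(self):
        self.sets = [sorted(int(i) for i in s) for s in self.sets]
        if any(len(s) == 0 for s in self.sets):
            raise IdentificationError("partition sets must be non-empty")
        flat = [i for s in self.sets for i in s]
        if len(flat) != len(set(flat)):
            raise IdentificationError("partition sets must be pairwise disjoint")
        if self.dropped is None:
            self.dropped = [s[-1] for s in self.sets]
        self.dropped = [int(t) for t in self.dropped]
        if len(self.dropped) != len(self.sets):
            raise IdentificationError("one dropped item per set is required")
        for s, t in zip(self.sets, self.dropped):
            if t not in s:
                raise IdentificationError(f"dropped item {t} is not in its set {s}")

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @classmethod
    def singletons(cls, items) -> "ItemPartition":
        return cls([[int(i)] for i in items])


@dataclass
class IdentificationReport:
    identified: bool
    rankB: int
    D: int
    n_items: int
    method: str
    partition: ItemPartition | None = None
    C: np.ndarray | None = None
    detC: float | None = None
    A_reduced: DesignMatrix | None = None
    reason: str = ""
    dimension_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-ready report; item indices are reported 1-based."""
        out = {
            "identified": bool(self.identified),
            "rankB": int(self.rankB),
            "D": int(self.D),
            "n_items": int(self.n_items),
            "method": self.method,
            "reason": self.reason,
        }
        if self.partition is not None:
            out["partition_sets"] = [[i + 1 for i in s] for s in self.partition.sets]
            out["dropped_items"] = [t + 1 for t in self.partition.dropped]
        if self.C is not None:
            out["C"] = np.asarray(self.C).tolist()
            out["detC"] = float(self.detC)
        return out


def _det(C: np.ndarray) -> float:
    """Determinant, exact for integer-valued matrices."""
    if np.allclose(C, np.round(C)):
        M = np.round(C).astype(object)  # arbitrary-precision integer Bareiss
        n = M.shape[0]
        M = [[int(M[i, j]) for j in range(n)] for i in range(n)]
        sign, prev = 1, 1
        for k in range(n - 1):
            if M[k][k] == 0:
                swap = next((r for r in range(k + 1, n) if M[r][k] != 0), None)
                if swap is None:
                    return 0.0
                M[k], M[swap] = M[swap], M[k]
                sign = -sign
            for i in range(k + 1, n):
                for j in range(k + 1, n):
                    M[i][j] = (M[i][j] * M[k][k] - M[i][k] * M[k][j]) // prev
            prev = M[k][k]
        return float(sign * M[n - 1][n - 1])
    return float(np.linalg.det(C))


def cmatrix(B: ScoringMatrix | np.ndarray, partition: ItemPartition) -> np.ndarray:
    """Set-sum matrix ``C``: row i is the column sum of ``B`` over set i."""
    Bm = B.B if isinstance(B, ScoringMatrix) else np.asarray(B, dtype=float)
    n = Bm.shape[0]
    for s in partition.sets:
        if any(not (0 <= i < n) for i in s):
            raise IdentificationError(f"item index out of range in set {s}")
    return np.vstack([Bm[s].sum(axis=0) for s in partition.sets])


def reduced_design_matrix(
    B: ScoringMatrix | np.ndarray, partition: ItemPartition
) -> DesignMatrix:
    """Reduced design matrix ``A'`` for an identifying partition.

    ``A'`` has ``n_items - D`` columns (one per non-dropped item).  Rows of
    non-dropped items are unit vectors; the row of each dropped item has -1
    in the columns of the other items of its set (all zero for a singleton
    set, anchoring that parameter at zero).
    """
    Bm = B.B if isinstance(B, ScoringMatrix) else np.asarray(B, dtype=float)
    n, D = Bm.shape
    if partition.n_sets != D:
        raise IdentificationError(
            f"partition has {partition.n_sets} sets; expected D = {D}"
        )
    C = cmatrix(Bm, partition)
    det = _det(C)
    if abs(det) <= DET_TOL:
        raise IdentificationError(
            "partition does not identify the model (singular C matrix)"
        )
    dropped = set(partition.dropped)
    kept = [i for i in range(n) if i not in dropped]
    col_of = {i: j for j, i in enumerate(kept)}
    A = np.zeros((n, len(kept)))
    for i in kept:
        A[i, col_of[i]] = 1.0
    for s, t in zip(partition.sets, partition.dropped):
        for i in s:
            if i != t:
                A[t, col_of[i]] = -1.0
    return DesignMatrix(A, [f"beta{i + 1}" for i in kept], dropped_items=sorted(dropped))


def _greedy_independent_rows(Bm: np.ndarray, D: int) -> list[int] | None:
    """First D rows (in order) that are linearly independent, or None."""
    chosen: list[int] = []
    for i in range(Bm.shape[0]):
        trial = chosen + [i]
        if np.linalg.matrix_rank(Bm[trial]) == len(trial):
            chosen.append(i)
            if len(chosen) == D:
                return chosen
    return None


def check_identification(
    B: ScoringMatrix | np.ndarray, method: str = "rank"
) -> IdentificationReport:
    """Decide analytical identification of the completely oblique model.

    ``rank``: identified iff ``B`` has full column rank; a witness partition
    of singleton sets is built from D linearly independent rows (greedy).
    ``brute_force``: exhaustive search over all D-subsets of items used as
    singleton-set partitions, accepting the first with ``|det C| > tol``.
    """
    names = B.dimension_names if isinstance(B, ScoringMatrix) else []
    Bm = B.B if isinstance(B, ScoringMatrix) else np.asarray(B, dtype=float)
    n, D = Bm.shape
    rankB = int(np.linalg.matrix_rank(Bm))
    base = dict(rankB=rankB, D=D, n_items=n, method=method, dimension_names=list(names))

    if n < D:
        return IdentificationReport(
            identified=False, reason="too few items: n_items < D", **base
        )

    if method == "rank":
        if rankB < D:
            return IdentificationReport(
                identified=False,
                reason=f"rank(B) = {rankB} < D = {D}: no partition can have nonsingular C",
                **base,
            )
        rows = _greedy_independent_rows(Bm, D)
        partition = ItemPartition.singletons(rows)
    elif method == "brute_force":
        partition = None
        for combo in itertools.combinations(range(n), D):
            p = ItemPartition.singletons(combo)
            if abs(_det(cmatrix(Bm, p))) > DET_TOL:
                partition = p
                break
        if partition is None:
            return IdentificationReport(
                identified=False,
                reason="no singleton-set partition has nonsingular C",
                **base,
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    C = cmatrix(Bm, partition)
    det = _det(C)
    return IdentificationReport(
        identified=True,
        partition=partition,
        C=C,
        detC=det,
        A_reduced=reduced_design_matrix(Bm, partition),
        **base,
    )


def gsm_identification_suite(structure: LoadingStructure) -> list[IdentificationReport]:
    """Identification reports for every subdimension-model reparameterization.

    For a clear structure with S >= 3 specific factors, each choice of
    excluded factor yields a scoring matrix of full column rank; applying
    one common item partition (the first item of each block) to all of them
    gives C matrices whose determinants share the same absolute value,
    reflecting that all reparameterizations span the same latent space.
    """
    if structure.n_specific < 3:
        raise StructureError(
            "the subdimension suite needs at least 3 specific factors"
        )
    diag_first = [int(np.flatnonzero(structure.loads[:, k])[0])
                  for k in range(1, structure.n_specific + 1)]
    # one common partition with D = S sets, reused across reparameterizations
    partition = ItemPartition.singletons(diag_first[: structure.n_specific])
    reports = []
    for excl in range(1, structure.n_specific + 1):
        Bg = gsm_scoring_matrix(structure, excl)
        C = cmatrix(Bg, partition)
        det = _det(C)
        identified = abs(det) > DET_TOL
        reports.append(
            IdentificationReport(
                identified=identified,
                rankB=int(np.linalg.matrix_rank(Bg.B)),
                D=Bg.n_dims,
                n_items=Bg.n_items,
                method="rank",
                partition=partition,
                C=C,
                detC=det,
                A_reduced=reduced_design_matrix(Bg, partition) if identified else None,
                reason=f"excluded specific factor {excl}",
                dimension_names=list(Bg.dimension_names),
            )
        )
    return reports
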