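"""Test dimensionality structures for bifactor Rasch models.

A *loading structure* records which latent dimensions each dichotomous item
measures: column 0 is the general factor (every item loads on it), columns
1..S are the specific factors.  Three named families of structures matter
for oblique bifactor modelling:

* **clear** -- every item loads on the general factor and exactly one
  specific factor ("perfect cluster structure").
* **G-structure** -- at least one *construct item* loads solely on the
  general factor; the remaining items form a clear structure.
* **S-structure** -- no construct items, but at least one *shared item*
  loads on every pair of specific factors.

The scoring matrix ``B`` of the multidimensional random coefficients
multinomial logit representation equals the loading pattern for the
oblique/orthogonal bifactor families; the subdimension family (GSM/SRM)
rewrites one specific factor as the negative sum of the others, which
changes ``B`` (see :func:`gsm_scoring_matrix`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LoadingStructure",
    "ScoringMatrix",
    "DesignMatrix",
    "StructureError",
    "make_clear_structure",
    "make_g_structure",
    "make_s_structure",
    "scoring_matrix",
    "gsm_scoring_matrix",
    "full_design_matrix",
    "validate_structure",
]


class StructureError(ValueError):
    """Invalid structure specification or arguments."""


def _as_sizes(n_specific: int, items_per_specific) -> list[int]:
    if n_specific < 1:
        raise StructureError("n_specific must be positive")
    if np.isscalar(items_per_specific):
        if items_per_specific < 1:
            raise StructureError("items_per_specific must be positive")
        return [int(items_per_specific)] * n_specific
    sizes = [int(m) for m in items_per_specific]
    if len(sizes) != n_specific:
        raise StructureError(
            f"items_per_specific has {len(sizes)} entries for {n_specific} factors"
        )
    if any(m < 1 for m in sizes):
        raise StructureError("every specific factor needs at least one item")
    return sizes


@dataclass
class LoadingStructure:
    """Binary item-by-dimension loading pattern of a bifactor test.

    ``loads`` has shape ``(n_items, n_specific + 1)``; column 0 is the
    general factor and is identically one.  Items load on at most two
    specific factors.
    """

    n_items: int
    n_specific: int
    loads: np.ndarray
    item_labels: list[str] = field(default_factory=list)
    factor_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.loads = np.asarray(self.loads, dtype=int)
        if self.n_items < 1 or self.n_specific < 1:
            raise StructureError("n_items and n_specific must be positive")
        if self.loads.shape != (self.n_items, self.n_specific + 1):
            raise StructureError(
                f"loads shape {self.loads.shape} != ({self.n_items}, {self.n_specific + 1})"
            )
        if not np.isin(self.loads, [0, 1]).all():
            raise StructureError("loads entries must be 0/1")
        if not (self.loads[:, 0] == 1).all():
            raise StructureError("every item must load on the general factor (column 0)")
        nspec = self.loads[:, 1:].sum(axis=1)
        if (nspec > 2).any():
            raise StructureError("items may load on at most two specific factors")
        if (self.loads[:, 1:].sum(axis=0) == 0).any():
            raise StructureError("every specific factor needs at least one item")
        if not self.item_labels:
            self.item_labels = [f"item{i + 1}" for i in range(self.n_items)]
        if not self.factor_labels:
            self.factor_labels = ["general"] + [
                f"specific{k}" for k in range(1, self.n_specific + 1)
            ]

    @property
    def n_dims(self) -> int:
        return self.n_specific + 1

    def construct_items(self) -> np.ndarray:
        """0-based indices of items loading only on the general factor."""
        return np.flatnonzero(self.loads[:, 1:].sum(axis=1) == 0)

    def shared_items(self) -> np.ndarray:
        """0-based indices of items loading on two specific factors."""
        return np.flatnonzero(self.loads[:, 1:].sum(axis=1) == 2)

    def specifics_of_item(self, i: int) -> list[int]:
        """1-based specific-factor indices of item ``i`` (0-based)."""
        return [int(k) for k in np.flatnonzero(self.loads[i, 1:]) + 1]


@dataclass
class ScoringMatrix:
    """Scoring matrix ``B`` mapping item (success) categories to dimensions."""

    B: np.ndarray
    dimension_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        if self.B.ndim != 2:
            raise StructureError("B must be a 2-D matrix")
        if not self.dimension_names:
            self.dimension_names = [f"dim{d}" for d in range(self.B.shape[1])]

    @property
    def n_items(self) -> int:
        return self.B.shape[0]

    @property
    def n_dims(self) -> int:
        return self.B.shape[1]


@dataclass
class DesignMatrix:
    """Design matrix ``A`` mapping item (success) categories to item parameters.

    The unreduced dichotomous case is the identity: one difficulty per item.
    A reduced design matrix (see the identification module) has
    ``n_items - D`` columns, with dropped parameters re-expressed as negative
    sums of their set-mates.
    """

    A: np.ndarray
    parameter_names: list[str] = field(default_factory=list)
    dropped_items: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise StructureError("A must be a 2-D matrix")
        if not self.parameter_names:
            self.parameter_names = [f"beta{j + 1}" for j in range(self.A.shape[1])]

    @property
    def n_items(self) -> int:
        return self.A.shape[0]

    @property
    def n_params(self) -> int:
        return self.A.shape[1]

    @property
    def is_reduced(self) -> bool:
        return self.A.shape[1] < self.A.shape[0]


def _assign_blocks(sizes: list[int], assignment: str) -> list[int]:
    """Per-item specific-factor index (1-based) for non-construct items."""
    S = len(sizes)
    if assignment == "block":
        out = []
        for k, m in enumerate(sizes, start=1):
            out.extend([k] * m)
        return out
    if assignment == "alternating":
        # round-robin over factors, skipping exhausted ones
        remaining = list(sizes)
        out = []
        while any(r > 0 for r in remaining):
            for k in range(S):
                if remaining[k] > 0:
                    out.append(k + 1)
                    remaining[k] -= 1
        return out
    raise StructureError(f"unknown assignment {assignment!r}")


def make_clear_structure(
    n_specific: int, items_per_specific, assignment: str = "block"
) -> LoadingStructure:
    """Clear bifactor structure: each item loads on the general factor and
    exactly one specific factor; no construct or shared items."""
    if n_specific < 2:
        raise StructureError("a clear bifactor structure needs at least 2 specific factors")
    sizes = _as_sizes(n_specific, items_per_specific)
    factors = _assign_blocks(sizes, assignment)
    n = len(factors)
    loads = np.zeros((n, n_specific + 1), dtype=int)
    loads[:, 0] = 1
    for i, k in enumerate(factors):
        loads[i, k] = 1
    return LoadingStructure(n, n_specific, loads)


def make_g_structure(
    n_specific: int,
    items_per_specific,
    n_construct_items: int,
    assignment: str = "block",
) -> LoadingStructure:
    """G-structure: ``n_construct_items`` general-only items followed by a
    clear structure."""
    if n_construct_items < 1:
        raise StructureError(
            "n_construct_items must be >= 1 (use make_clear_structure for 0)"
        )
    clear = make_clear_structure(n_specific, items_per_specific, assignment)
    n = n_construct_items + clear.n_items
    loads = np.zeros((n, n_specific + 1), dtype=int)
    loads[:, 0] = 1
    loads[n_construct_items:] = clear.loads
    return LoadingStructure(n, n_specific, loads)


def _all_pairs_chain(S: int) -> list[tuple[int, int]]:
    # pair k with k-1 (wrapping), one pair per block; covers all pairs iff S <= 3
    if S == 2:
        return [(1, 2)]
    return [tuple(sorted((k, S if k == 1 else k - 1))) for k in range(1, S + 1)]


def make_s_structure(
    n_specific: int,
    items_per_specific,
    shared_pairs="all",
    placement: str = "auto",
    assignment: str = "block",
) -> LoadingStructure:
    """S-structure: no construct items; shared items load on the general
    factor and two specific factors.

    ``shared_pairs`` is ``"all"`` (one shared item per unordered pair of
    specific factors) or an explicit list of 1-based factor pairs.  With
    ``placement="replace"`` each shared item replaces the first item of a
    block belonging to one of its two factors; with ``"append"`` shared
    items are added after the per-factor blocks.  ``"auto"`` replaces when
    a one-pair-per-block matching exists and appends otherwise.
    """
    S = int(n_specific)
    if S < 2:
        raise StructureError("an S-structure needs at least 2 specific factors")
    sizes = _as_sizes(S, items_per_specific)

    if isinstance(shared_pairs, str) and shared_pairs == "all":
        pairs = _all_pairs_chain(S) if S <= 3 else sorted(
            itertools.combinations(range(1, S + 1), 2)
        )
    else:
        pairs = [tuple(sorted(p)) for p in shared_pairs]
    seen = set()
    for a, b in pairs:
        if not (1 <= a <= S and 1 <= b <= S) or a == b:
            raise StructureError(f"invalid factor pair ({a}, {b})")
        if (a, b) in seen:
            raise StructureError(f"repeated factor pair ({a}, {b})")
        seen.add((a, b))

    base = make_clear_structure(S, sizes, assignment)

    # try to match each pair to an unused block whose factor is in the pair
    matching: dict[tuple[int, int], int] = {}
    used: set[int] = set()
    feasible = True
    for p in pairs:
        block = next((k for k in p if k not in used), None)
        if block is None:
            feasible = False
            break
        matching[p] = block
        used.add(block)

    if placement == "auto":
        placement = "replace" if feasible else "append"
    if placement == "replace":
        if not feasible:
            raise StructureError(
                "cannot place every shared pair on a distinct block; use placement='append'"
            )
        loads = base.loads.copy()
        first_of_block = {}
        for k in range(1, S + 1):
            first_of_block[k] = int(np.flatnonzero(base.loads[:, k])[0])
        for p, block in matching.items():
            i = first_of_block[block]
            loads[i, 1:] = 0
            loads[i, [p[0], p[1]]] = 1
        return LoadingStructure(base.n_items, S, loads)
    if placement == "append":
        extra = np.zeros((len(pairs), S + 1), dtype=int)
        extra[:, 0] = 1
        for r, (a, b) in enumerate(pairs):
            extra[r, [a, b]] = 1
        loads = np.vstack([base.loads, extra])
        return LoadingStructure(loads.shape[0], S, loads)
    raise StructureError(f"unknown placement {placement!r}")


def scoring_matrix(structure: LoadingStructure) -> ScoringMatrix:
    """Scoring matrix for the oblique/orthogonal bifactor families:
    ``B`` equals the loading pattern, one column per latent dimension."""
    return ScoringMatrix(structure.loads.astype(float), list(structure.factor_labels))


def gsm_scoring_matrix(structure: LoadingStructure, excluded_factor: int) -> ScoringMatrix:
    """Subdimension-family scoring matrix with one specific factor excluded.

    The excluded specific factor is re-expressed as the negative sum of the
    retained ones (the per-person specific scores sum to zero), so items of
    the excluded factor score ``-1`` on every retained specific column.
    General-only (construct) items keep an all-zero specific row, which is
    how the subdimension model is applied to G-structures.
    ``excluded_factor`` is 1-based.
    """
    S = structure.n_specific
    if S <= 1:
        raise StructureError("subdimension scoring needs at least 2 specific factors")
    if not (1 <= excluded_factor <= S):
        raise StructureError(f"excluded_factor must be in 1..{S}")
    if S == 2:
        warnings.warn(
            "with two specific factors the zero-sum constraint forces their "
            "correlation to -1; the specific covariance structure is degenerate",
            UserWarning,
            stacklevel=2,
        )
    retained = [k for k in range(1, S + 1) if k != excluded_factor]
    n = structure.n_items
    B = np.zeros((n, S), dtype=float)
    B[:, 0] = 1.0
    # substituting th_excluded = -sum(retained) gives, for each retained
    # factor j, the column loads[:, j] - loads[:, excluded]
    for j, k in enumerate(retained, start=1):
        B[:, j] = structure.loads[:, k] - structure.loads[:, excluded_factor]
    names = ["general"] + [structure.factor_labels[k] for k in retained]
    return ScoringMatrix(B, names)


def full_design_matrix(n_items: int) -> DesignMatrix:
    """Unreduced design matrix: one difficulty per item (identity)."""
    return DesignMatrix(np.eye(n_items), [f"beta{j + 1}" for j in range(n_items)])


def validate_structure(structure: LoadingStructure) -> dict:
    """Diagnostics: structure class and item-role counts.

    The class is ``"clear"`` (no construct/shared items), ``"G"`` (construct
    items only), ``"S"`` (shared items only), or ``"mixed"`` (both).
    """
    construct = structure.construct_items()
    shared = structure.shared_items()
    if len(construct) == 0 and len(shared) == 0:
        cls = "clear"
    elif len(shared) == 0:
        cls = "G"
    elif len(construct) == 0:
        cls = "S"
    else:
        cls = "mixed"
    pairs_covered = set()
    for i in shared:
        pairs_covered.add(tuple(structure.specifics_of_item(int(i))))
    all_pairs = set(itertools.combinations(range(1, structure.n_specific + 1), 2))
    return {
        "class": cls,
        "n_items": structure.n_items,
        "n_specific": structure.n_specific,
        "n_construct_items": int(len(construct)),
        "n_shared_items": int(len(shared)),
        "construct_items": [int(i) + 1 for i in construct],
        "shared_items": [int(i) + 1 for i in shared],
        "items_per_specific": structure.loads[:, 1:].sum(axis=0).astype(int).tolist(),
        "uncovered_pairs": sorted(all_pairs - pairs_covered) if cls == "S" else [],
    }
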