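"""Top-t evaluation statistics for trimer interface-pair predictions.

A trimer has three pairwise chain interfaces. For a cutoff ``t`` the
per-trimer statistic NPRPT(t) = (n1, n2, n3) counts, for each interface,
how many true interface pairs appear among the t highest-scoring predicted
pairs. Its L0 norm is the number of interfaces "hit" (>= 1 true pair in
the top t), its L1 norm the total number of true pairs recovered. The
trimer-level accuracy rate at level z is the percentage of trimers whose
L0 is at least z.

``reference_testset_counts`` ships the published 26-trimer benchmark of
per-trimer (L0, L1) values at t = 10, 15, 20, 30, which this module's
reductions reproduce exactly; it doubles as a worked example and a
regression fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "NPRPTVector",
    "nprpt",
    "l0_norm",
    "l1_norm",
    "accuracy_rate",
    "accuracy_table",
    "reference_testset_counts",
]


@dataclass(frozen=True)
class NPRPTVector:
    """Per-trimer true-pair counts in the top-t lists of its 3 interfaces."""

    t: int
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.counts) != 3:
            raise ValueError("a trimer has exactly three interfaces")
        for n in self.counts:
            if not 0 <= n <= self.t:
                raise ValueError(f"count {n} outside 0..t={self.t}")


def nprpt(
    rankings: Sequence[Sequence[Hashable]],
    truth: Sequence[Iterable[Hashable]],
    t: int,
) -> NPRPTVector:
    """Count true pairs among the top-t of each of the three interfaces.

    ``rankings`` holds one score-ordered pair-id list per interface;
    ``truth`` the corresponding sets of true interface pair ids.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    if len(rankings) != 3 or len(truth) != 3:
        raise ValueError("expected rankings and truth for exactly 3 interfaces")
    counts = []
    for ranked, true_pairs in zip(rankings, truth):
        true_set = set(true_pairs)
        counts.append(sum(1 for p in ranked[:t] if p in true_set))
    return NPRPTVector(t=t, counts=tuple(counts))


def l0_norm(v: NPRPTVector) -> int:
    """Number of interfaces with at least one true pair in the top t."""
    return sum(1 for n in v.counts if n > 0)


def l1_norm(v: NPRPTVector) -> int:
    """Total number of true pairs recovered across the three interfaces."""
    return sum(v.counts)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def accuracy_rate(vectors: Sequence[NPRPTVector | int], z: int) -> float:
    """Percentage of trimers with at least z interfaces hit.

    ``vectors`` may hold NPRPT vectors or precomputed L0 values. The rate
    is rounded half-up to two decimals (percentage points).
    """
    if z not in (1, 2, 3):
        raise ValueError(f"z must be 1, 2 or 3, got {z}")
    if len(vectors) == 0:
        raise ValueError("need at least one trimer")
    l0s = [l0_norm(v) if isinstance(v, NPRPTVector) else int(v) for v in vectors]
    sct = sum(1 for l0 in l0s if l0 >= z)
    return _round2(sct / len(l0s) * 100.0)


def accuracy_table(
    l0_by_t: Mapping[int, Sequence[int]], z_values: Sequence[int] = (1, 2, 3)
) -> pd.DataFrame:
    """Accuracy-rate grid (rows: z, columns: t) from per-t L0 value lists."""
    data = {
        t: [accuracy_rate(list(l0s), z) for z in z_values]
        for t, l0s in sorted(l0_by_t.items())
    }
    return pd.DataFrame(data, index=[f"z={z}" for z in z_values])


# Published 26-trimer benchmark: per-trimer (L0, L1) of NPRPT at
# t = 10, 15, 20, 30, from a held-out test set of PDB trimers.
_REFERENCE_ROWS = [
    # pdb,  (l0,l1)@10, @15,    @20,    @30
    ("1osp", 2, 3, 2, 3, 2, 5, 3, 10),
    ("1oy3", 3, 4, 3, 5, 3, 6, 3, 9),
    ("1p32", 1, 3, 1, 3, 1, 3, 1, 4),
    ("1q5x", 3, 5, 3, 5, 3, 6, 3, 10),
    ("1qb3", 3, 4, 3, 4, 3, 4, 3, 9),
    ("1s7o", 3, 7, 3, 9, 3, 11, 3, 14),
    ("1sg2", 2, 3, 3, 5, 3, 7, 3, 9),
    ("1stz", 0, 0, 0, 0, 0, 0, 0, 0),
    ("1sy6", 2, 2, 2, 2, 2, 3, 2, 5),
    ("1w9z", 3, 3, 3, 3, 3, 3, 3, 7),
    ("1wdj", 2, 2, 2, 4, 2, 6, 2, 8),
    ("1ynb", 2, 2, 2, 3, 2, 4, 2, 4),
    ("1za7", 1, 4, 2, 6, 3, 9, 3, 12),
    ("2ig8", 1, 1, 1, 2, 2, 3, 3, 5),
    ("2ium", 1, 2, 3, 4, 3, 6, 3, 9),
    ("2iy0", 3, 10, 3, 14, 3, 16, 3, 19),
    ("2izw", 1, 2, 2, 3, 2, 4, 3, 9),
    ("2ms2", 3, 5, 3, 8, 3, 8, 3, 10),
    ("2r3u", 0, 0, 0, 0, 1, 1, 2, 2),
    ("2wr5", 0, 0, 0, 0, 0, 0, 0, 0),
    ("3dli", 3, 3, 3, 3, 3, 3, 3, 6),
    ("3ffd", 3, 4, 3, 4, 3, 8, 3, 10),
    ("3m6n", 0, 0, 0, 0, 0, 0, 1, 1),
    ("3owt", 1, 3, 2, 4, 2, 5, 2, 8),
    ("3p5j", 0, 0, 2, 2, 2, 3, 3, 4),
    ("3qks", 0, 0, 1, 1, 2, 2, 3, 6),
]

_REFERENCE_T = (10, 15, 20, 30)


def reference_testset_counts() -> pd.DataFrame:
    """The 26-trimer benchmark as a DataFrame indexed by PDB code, with
    columns ``l0_t{t}`` and ``l1_t{t}`` for t in (10, 15, 20, 30)."""
    cols: dict[str, list[int]] = {}
    for i, t in enumerate(_REFERENCE_T):
        cols[f"l0_t{t}"] = [row[1 + 2 * i] for row in _REFERENCE_ROWS]
        cols[f"l1_t{t}"] = [row[2 + 2 * i] for row in _REFERENCE_ROWS]
    return pd.DataFrame(cols, index=[row[0] for row in _REFERENCE_ROWS])
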