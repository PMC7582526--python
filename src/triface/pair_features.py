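"""Residue-pair feature vectors and correlation/F-value feature selection.

Each residue carries a 64-dimensional descriptor (57 sequence-block
features, 2 ionisation constants, 5 structural-geometry features). An
inter-chain residue pair is the concatenation of the two descriptors, 128
columns, oriented lower-chain-id first. Training features are min-max
standardised to [0, 1]; the second feature view is obtained by grouping
columns whose pairwise Pearson |r| exceeds a threshold (connected
components of the correlation graph, i.e. single linkage) and keeping,
per group, the column whose F-value — |mu+ - mu-| / (sigma+ + sigma-),
population standard deviations — is largest. Basic first-order sequence
columns and basic geometric columns are always preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .encoding import N_SEQUENCE_FEATURES, sequence_block_columns

__all__ = [
    "RESIDUE_DESCRIPTOR_WIDTH",
    "PAIR_WIDTH",
    "residue_descriptor_columns",
    "pair_columns",
    "default_preserved_columns",
    "assemble_pair",
    "NormalizationParams",
    "fit_minmax",
    "apply_minmax",
    "pearson_r",
    "f_value",
    "SelectionResult",
    "select_features",
]

ELECTRIC_COLUMNS = ["pk1", "pk2"]
GEOMETRIC_COLUMNS = ["asa_bound", "rasa", "eca", "ica", "eva"]

RESIDUE_DESCRIPTOR_WIDTH = N_SEQUENCE_FEATURES + 2 + 5  # = 64
PAIR_WIDTH = 2 * RESIDUE_DESCRIPTOR_WIDTH  # = 128


def residue_descriptor_columns() -> list[str]:
    """Names of the 64 per-residue descriptor columns (manifest order)."""
    return sequence_block_columns() + ELECTRIC_COLUMNS + GEOMETRIC_COLUMNS


def pair_columns() -> list[str]:
    """Names of the 128 pair-vector columns (``a_``/``b_`` prefixed halves)."""
    res = residue_descriptor_columns()
    return [f"a_{c}" for c in res] + [f"b_{c}" for c in res]


def default_preserved_columns() -> list[int]:
    """Indices of the always-kept columns in the 128-dim pair vector:
    the 7 basic first-order sequence columns and the 5 basic geometric
    columns of both residues (24 columns in total)."""
    basic_seq = list(range(N_SEQUENCE_FEATURES - 7, N_SEQUENCE_FEATURES))
    geometric = list(range(RESIDUE_DESCRIPTOR_WIDTH - 5, RESIDUE_DESCRIPTOR_WIDTH))
    per_residue = basic_seq + geometric
    return sorted(per_residue + [c + RESIDUE_DESCRIPTOR_WIDTH for c in per_residue])


def assemble_pair(desc_a: np.ndarray, desc_b: np.ndarray) -> np.ndarray:
    """Concatenate two 64-dim residue descriptors into one 128-dim pair vector.

    Caller supplies the descriptors already in (lower chain id, higher
    chain id) order; that orientation is the package-wide convention.
    """
    desc_a = np.asarray(desc_a, dtype=float)
    desc_b = np.asarray(desc_b, dtype=float)
    for name, d in (("first", desc_a), ("second", desc_b)):
        if d.shape != (RESIDUE_DESCRIPTOR_WIDTH,):
            raise ValueError(
                f"{name} descriptor has shape {d.shape}, "
                f"expected ({RESIDUE_DESCRIPTOR_WIDTH},)"
            )
    return np.concatenate([desc_a, desc_b])


@dataclass
class NormalizationParams:
    """Per-column training min and max for [0, 1] standardisation."""

    minima: np.ndarray
    maxima: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {"minima": self.minima.tolist(), "maxima": self.maxima.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationParams":
        d = json.loads(text)
        return cls(np.array(d["minima"], float), np.array(d["maxima"], float))


def fit_minmax(matrix: np.ndarray) -> NormalizationParams:
    """Learn per-column min and max on a training matrix (>= 1 row)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValueError("need a 2-D matrix with at least one row")
    return NormalizationParams(matrix.min(axis=0), matrix.max(axis=0))


def apply_minmax(matrix: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Scale columns to [0, 1]; out-of-range values are clipped, constant
    training columns (max == min) map to 0."""
    matrix = np.asarray(matrix, dtype=float)
    span = params.maxima - params.minima
    safe = np.where(span > 0, span, 1.0)
    out = (matrix - params.minima) / safe
    out = np.where(span > 0, out, 0.0)
    return np.clip(out, 0.0, 1.0)


def pearson_r(col_k: np.ndarray, col_l: np.ndarray) -> float:
    """Pearson correlation with population moments; errors on zero variance."""
    x = np.asarray(col_k, dtype=float)
    y = np.asarray(col_l, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length 1-D arrays with >= 2 entries")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a zero-variance column")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov / (sx * sy))


def f_value(pos: np.ndarray, neg: np.ndarray) -> float:
    """Class-separation score |mu+ - mu-| / (sigma+ + sigma-).

    Population standard deviations. If both groups are constant the score
    is +inf for distinct means (a perfect separator) and 0 for equal means.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both class groups must be nonempty")
    num = abs(pos.mean() - neg.mean())
    den = pos.std() + neg.std()
    if den == 0:
        return float("inf") if num > 0 else 0.0
    return float(num / den)


@dataclass
class SelectionResult:
    """Outcome of correlation-grouped F-value filtering."""

    retained: list[int]
    groups: list[list[int]] = field(default_factory=list)
    f_values: np.ndarray | None = None
    preserved: list[int] = field(default_factory=list)
    r_threshold: float = 0.5

    def to_json(self) -> str:
        return json.dumps(
            {
                "retained": self.retained,
                "groups": self.groups,
                "f_values": None
                if self.f_values is None
                else [None if not np.isfinite(v) else float(v) for v in self.f_values],
                "preserved": self.preserved,
                "r_threshold": self.r_threshold,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        d = json.loads(text)
        fv = d.get("f_values")
        return cls(
            retained=list(d["retained"]),
            groups=[list(g) for g in d.get("groups", [])],
            f_values=None
            if fv is None
            else np.array([np.inf if v is None else v for v in fv], float),
            preserved=list(d.get("preserved", [])),
            r_threshold=float(d.get("r_threshold", 0.5)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SelectionResult":
        return cls.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def select_features(
    matrix: np.ndarray,
    labels: np.ndarray,
    r_threshold: float = 0.5,
    preserved: Sequence[int] | None = None,
) -> SelectionResult:
    """Correlation-grouped F-value filtering on a (normalised) training matrix.

    Columns whose pairwise |r| exceeds ``r_threshold`` are grouped by
    single linkage (connected components of the thresholded correlation
    graph, components enumerated in ascending column order). Each group
    contributes its maximal-F column (ties to the lower index); columns in
    ``preserved`` are retained unconditionally. Zero-variance columns have
    no defined correlation and stay as singletons. Requires both labels
    present.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels).astype(bool)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if y.all() or (~y).all():
        raise ValueError("both classes must be present to compute F-values")
    n_cols = X.shape[1]
    preserved = sorted(set(preserved or []))
    if preserved and (preserved[0] < 0 or preserved[-1] >= n_cols):
        raise ValueError("preserved column index out of range")

    stds = X.std(axis=0)
    variable = stds > 0
    # |r| over variable columns only; constant columns stay isolated.
    adj = np.zeros((n_cols, n_cols), dtype=bool)
    if variable.sum() >= 2:
        idx = np.flatnonzero(variable)
        corr = np.corrcoef(X[:, idx], rowvar=False)
        mask = np.abs(corr) > r_threshold
        np.fill_diagonal(mask, False)
        adj[np.ix_(idx, idx)] = mask
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)

    pos, neg = X[y], X[~y]
    fvals = np.array(
        [f_value(pos[:, m], neg[:, m]) for m in range(n_cols)], dtype=float
    )

    groups: list[list[int]] = []
    seen: set[int] = set()
    retained: set[int] = set(preserved)
    for c in range(n_cols):  # ascending column order fixes group enumeration
        comp_id = comp[c]
        if comp_id in seen:
            continue
        seen.add(comp_id)
        members = np.flatnonzero(comp == comp_id).tolist()
        if len(members) > 1:
            groups.append(members)
        best = members[0]
        for m in members[1:]:
            if fvals[m] > fvals[best]:
                best = m
        retained.add(best)

    return SelectionResult(
        retained=sorted(retained),
        groups=groups,
        f_values=fvals,
        preserved=list(preserved),
        r_threshold=r_threshold,
    )
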