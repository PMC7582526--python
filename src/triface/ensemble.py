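"""Two-layer under-sampled SVM ensemble.

The positive class (interface residue pairs) is vastly outnumbered by the
negative class, so each ensemble layer trains ``n_members`` (default 100)
probabilistic SVMs, each on a *balanced subset*: all positives plus an
equally sized random draw of negatives without replacement. A layer's
score for a sample is the mean of its members' interface probabilities —
a monotone rescaling of the members' summed votes, kept in [0, 1] so the
two layers can be fused as

    P(x) = omega * P1(x) + (1 - omega) * P2(x),    omega in [0, 1],

with layer 1 seeing the full 128-column feature view and layer 2 the
correlation/F-value-selected view. Ranking the pairs of an interface by
P(x) and truncating at t gives the top-t prediction list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .pair_features import (
    NormalizationParams,
    SelectionResult,
    apply_minmax,
    default_preserved_columns,
    fit_minmax,
    select_features,
)

__all__ = [
    "EnsembleConfig",
    "make_balanced_subsets",
    "train_member",
    "EnsembleLayer",
    "TwoLayerEnsemble",
    "layer_score",
    "fused_score",
    "rank_pairs",
]


@dataclass
class EnsembleConfig:
    """Hyperparameters of the two-layer ensemble (all overridable)."""

    n_members: int = 100
    omega: float = 0.5
    C: float = 1.0
    gamma: str | float = "scale"
    kernel: str = "rbf"
    r_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"fusion weight omega must be in [0, 1], got {self.omega}")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


def make_balanced_subsets(
    n_negatives: int, n_pos: int, n_subsets: int, seed: int | None = None
) -> list[np.ndarray]:
    """Index sets of ``n_pos`` negatives each, drawn uniformly without
    replacement, independently per subset; reproducible from ``seed``."""
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    if n_negatives < n_pos:
        raise ValueError(
            f"only {n_negatives} negatives for subsets of size {n_pos}; "
            "draw with replacement or lower the subset size"
        )
    rng = np.random.default_rng(seed)
    return [
        rng.choice(n_negatives, size=n_pos, replace=False) for _ in range(n_subsets)
    ]


def train_member(
    X: np.ndarray, y: np.ndarray, config: EnsembleConfig, seed: int | None = None
) -> CalibratedClassifierCV:
    """Train one probabilistic SVM member on a balanced subset.

    The member is an RBF support-vector classifier whose decision values
    are mapped to probabilities by Platt (sigmoid) scaling fitted with
    internal cross-validation."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("balanced subset must contain both classes")
    svc = SVC(
        C=config.C,
        kernel=config.kernel,
        gamma=config.gamma,
        random_state=seed,
    )
    clf = CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


@dataclass
class EnsembleLayer:
    """One feature view: retained columns + its trained members."""

    view_id: int
    columns: list[int]
    members: list[CalibratedClassifierCV] = field(default_factory=list)
    member_seeds: list[int] = field(default_factory=list)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: EnsembleConfig,
        seed: int,
    ) -> "EnsembleLayer":
        """Train ``config.n_members`` members on balanced subsets of the
        already-normalised training matrix ``X`` (this layer's columns are
        selected internally)."""
        y = np.asarray(y).astype(bool)
        Xv = np.asarray(X, dtype=float)[:, self.columns]
        pos_idx = np.flatnonzero(y)
        neg_idx = np.flatnonzero(~y)
        subsets = make_balanced_subsets(
            len(neg_idx), len(pos_idx), config.n_members, seed=seed
        )
        self.members = []
        self.member_seeds = [seed * 1000 + i for i in range(config.n_members)]
        for i, subset in enumerate(subsets):
            rows = np.concatenate([pos_idx, neg_idx[subset]])
            yi = np.concatenate(
                [np.ones(len(pos_idx), int), np.zeros(len(subset), int)]
            )
            self.members.append(
                train_member(Xv[rows], yi, config, seed=self.member_seeds[i])
            )
        return self

    def score(self, X: np.ndarray) -> np.ndarray:
        """Mean member interface-probability per row of the normalised X."""
        if not self.members:
            raise ValueError("layer has no trained members")
        Xv = np.asarray(X, dtype=float)
        if Xv.shape[1] == len(self.columns):
            pass  # already restricted to this layer's view
        else:
            Xv = Xv[:, self.columns]
        probs = np.zeros(len(Xv))
        for clf in self.members:
            pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
            probs += clf.predict_proba(Xv)[:, pos_col]
        return probs / len(self.members)


def layer_score(layer: EnsembleLayer, X: np.ndarray) -> np.ndarray:
    return layer.score(X)


@dataclass
class TwoLayerEnsemble:
    """Full-view layer + selected-view layer + fusion weight + preprocessing."""

    layer1: EnsembleLayer
    layer2: EnsembleLayer
    omega: float
    norm: NormalizationParams
    selection: SelectionResult
    config: EnsembleConfig = field(default_factory=EnsembleConfig)

    @classmethod
    def fit(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        config: EnsembleConfig | None = None,
        seed: int = 0,
        selection: SelectionResult | None = None,
        preserved: Sequence[int] | None = None,
    ) -> "TwoLayerEnsemble":
        """Normalise, select the second view, and train both layers.

        ``selection`` may inject a fixed retained-column list (e.g. a
        published one); otherwise selection is learned from the training
        data. Layer seeds derive from ``seed`` by fixed offsets.
        """
        config = config or EnsembleConfig()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(bool)
        norm = fit_minmax(X)
        Xn = apply_minmax(X, norm)
        if selection is None:
            if preserved is None and X.shape[1] == 128:
                preserved = default_preserved_columns()
            selection = select_features(
                Xn, y, r_threshold=config.r_threshold, preserved=preserved
            )
        layer1 = EnsembleLayer(view_id=1, columns=list(range(X.shape[1])))
        layer2 = EnsembleLayer(view_id=2, columns=list(selection.retained))
        layer1.fit(Xn, y, config, seed=seed * 2 + 1)
        layer2.fit(Xn, y, config, seed=seed * 2 + 2)
        return cls(
            layer1=layer1,
            layer2=layer2,
            omega=config.omega,
            norm=norm,
            selection=selection,
            config=config,
        )

    def layer_scores(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Xn = apply_minmax(np.asarray(X, dtype=float), self.norm)
        return self.layer1.score(Xn), self.layer2.score(Xn)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Fused interface probability P(x) per row (raw, unnormalised X)."""
        p1, p2 = self.layer_scores(X)
        return fused_score(p1, p2, self.omega)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "TwoLayerEnsemble":
        obj = joblib.load(Path(path))
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a {cls.__name__}")
        return obj


def fused_score(
    p1: np.ndarray | float, p2: np.ndarray | float, omega: float = 0.5
) -> np.ndarray | float:
    """Weighted fusion omega*P1 + (1-omega)*P2 of the two layer scores."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"fusion weight omega must be in [0, 1], got {omega}")
    return omega * np.asarray(p1) + (1.0 - omega) * np.asarray(p2)


def rank_pairs(
    scores: np.ndarray,
    pair_ids: Sequence[tuple],
    t: int | None = None,
) -> list[tuple]:
    """Pair ids sorted by score descending, ties by ascending pair id
    (chain-a residue number first), truncated to the top ``t``."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(pair_ids):
        raise ValueError("scores and pair_ids length mismatch")
    if len(scores) == 0:
        return []
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], tuple(pair_ids[i])))
    if t is not None:
        if t < 1:
            raise ValueError("t must be >= 1")
        order = order[:t]
    return [tuple(pair_ids[i]) for i in order]
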