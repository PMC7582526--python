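"""Model/Results front end for the two-layer ensemble.

`InterfacePairModel` holds the training design (128-column pair matrix
and interface labels) plus configuration; `fit()` runs normalisation,
feature selection and ensemble training and returns an
`InterfacePairResults` carrying the trained classifier, the selection
diagnostics and prediction/ranking methods, with a `summary()` in the
spirit of statsmodels results objects.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import EnsembleConfig, TwoLayerEnsemble, rank_pairs
from .pair_features import PAIR_WIDTH, pair_columns

__all__ = ["InterfacePairModel", "InterfacePairResults"]


class InterfacePairModel:
    """Two-layer SVM ensemble model for inter-chain residue pairs.

    Parameters
    ----------
    X : (n, 128) array of pair feature vectors (raw scale).
    y : (n,) boolean/0-1 interface labels.
    config : EnsembleConfig, optional.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: EnsembleConfig | None = None,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).astype(bool)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        self.config = config or EnsembleConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "is_interface",
        config: EnsembleConfig | None = None,
    ) -> "InterfacePairModel":
        """Build from a feature table whose non-label columns are the
        128 pair features (manifest order)."""
        y = df[label_col].to_numpy()
        X = df.drop(columns=[label_col]).to_numpy(dtype=float)
        if X.shape[1] != PAIR_WIDTH:
            raise ValueError(
                f"expected {PAIR_WIDTH} feature columns, got {X.shape[1]}"
            )
        return cls(X, y, config=config)

    def fit(self, seed: int = 0, **fit_kwargs) -> "InterfacePairResults":
        ensemble = TwoLayerEnsemble.fit(
            self.X, self.y, config=self.config, seed=seed, **fit_kwargs
        )
        return InterfacePairResults(self, ensemble, seed=seed)


class InterfacePairResults:
    """Fitted two-layer ensemble with diagnostics."""

    def __init__(
        self, model: InterfacePairModel, ensemble: TwoLayerEnsemble, seed: int
    ) -> None:
        self.model = model
        self.ensemble = ensemble
        self.seed = seed

    # -- estimates -------------------------------------------------------
    @property
    def selection_(self):
        return self.ensemble.selection

    @property
    def n_retained_(self) -> int:
        return len(self.ensemble.selection.retained)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Fused interface probability per pair (raw feature scale)."""
        return self.ensemble.predict_proba(X)

    def layer_scores(self, X: np.ndarray):
        return self.ensemble.layer_scores(X)

    def rank(
        self, X: np.ndarray, pair_ids: Sequence[tuple], t: int | None = None
    ) -> list[tuple]:
        """Top-t pair ids of one interface by fused score."""
        return rank_pairs(self.predict_proba(X), pair_ids, t=t)

    def retained_feature_names(self) -> list[str]:
        names = pair_columns()
        return [names[i] for i in self.ensemble.selection.retained]

    def summary(self) -> str:
        m, e = self.model, self.ensemble
        n_pos = int(m.y.sum())
        n_neg = int(len(m.y) - n_pos)
        sel = e.selection
        lines = [
            "Two-layer SVM ensemble for interface residue pairs",
            "=" * 52,
            f"training pairs:        {len(m.y)}  ({n_pos} interface, {n_neg} non-interface)",
            f"class imbalance:       1:{n_neg / max(n_pos, 1):.1f}",
            f"members per layer:     {m.config.n_members}",
            f"SVM kernel / C:        {m.config.kernel} / {m.config.C}",
            f"fusion weight omega:   {e.omega}",
            f"layer 1 view:          {len(e.layer1.columns)} columns (full)",
            f"layer 2 view:          {len(e.layer2.columns)} columns "
            f"(|r| > {sel.r_threshold} groups, max-F kept, "
            f"{len(sel.preserved)} preserved)",
            f"correlation groups:    {len(sel.groups)}",
            f"random seed:           {self.seed}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<InterfacePairResults members={self.model.config.n_members} "
            f"retained={self.n_retained_}/{self.model.X.shape[1]}>"
        )
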