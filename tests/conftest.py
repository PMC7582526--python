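"""Shared fixtures: study conditions for the synthetic end-to-end runs.

The end-to-end conditions (training pool, per-interface pair counts,
effect size, cutoff) are fixed here once and reused by the synthetic
invariants and the acceptance checks, so the expensive ensemble training
happens once per session per effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from triface.baseline import NullParams, trimer_null_exact
from triface.ensemble import EnsembleConfig, rank_pairs
from triface.evaluation import accuracy_rate, l0_norm, nprpt
from triface.model import InterfacePairModel
from triface.synthetic import (
    SynthConfig,
    generate_pair_dataset,
    generate_trimer_pair_data,
)

# Study conditions for the synthetic end-to-end experiment.
TRAIN_N_POS = 60
TRAIN_NEG_PER_POS = 200
EFFECT_SIZE = 1.5
INFORMATIVE_FRACTION = 0.2
N_EVAL_TRIMERS = 6
EVAL_N_POS = 2  # true pairs per interface
EVAL_N_NEG = 1000  # decoy pairs per interface
TOP_T = 10
TRAIN_SEED = 11
EVAL_SEED = 12
FIT_SEED = 7

EVAL_NULL = NullParams(N=EVAL_N_POS + EVAL_N_NEG, M=EVAL_N_POS, T=TOP_T)


@dataclass
class EndToEndRun:
    """Outcome of train-on-one-draw, evaluate-on-another."""

    effect_size: float
    l0_values: list[int]
    accuracy_z1: float  # percent
    null_z1: float  # percent, exact closed form for the evaluation geometry
    n_retained: int


def _run_end_to_end(effect_size: float) -> EndToEndRun:
    train = generate_pair_dataset(
        SynthConfig(
            n_pos=TRAIN_N_POS,
            neg_per_pos=TRAIN_NEG_PER_POS,
            effect_size=effect_size,
            informative_fraction=INFORMATIVE_FRACTION,
            seed=TRAIN_SEED,
        )
    )
    results = InterfacePairModel(train.X, train.y, config=EnsembleConfig()).fit(
        seed=FIT_SEED
    )
    trimers, _ = generate_trimer_pair_data(
        n_trimers=N_EVAL_TRIMERS,
        n_pos=EVAL_N_POS,
        n_neg=EVAL_N_NEG,
        effect_size=effect_size,
        informative_fraction=INFORMATIVE_FRACTION,
        seed=EVAL_SEED,
    )
    l0s = []
    for trimer in trimers:
        rankings, truths = [], []
        for X, y, pair_ids in trimer.interfaces:
            rankings.append(rank_pairs(results.predict_proba(X), pair_ids, t=TOP_T))
            truths.append({pid for pid, is_pos in zip(pair_ids, y) if is_pos})
        l0s.append(l0_norm(nprpt(rankings, truths, TOP_T)))
    return EndToEndRun(
        effect_size=effect_size,
        l0_values=l0s,
        accuracy_z1=accuracy_rate(l0s, 1),
        null_z1=trimer_null_exact(EVAL_NULL, 1) * 100.0,
        n_retained=results.n_retained_,
    )


@pytest.fixture(scope="session")
def end_to_end_signal() -> EndToEndRun:
    """Full pipeline at the planted effect size d = 1.5."""
    return _run_end_to_end(EFFECT_SIZE)


@pytest.fixture(scope="session")
def end_to_end_null() -> EndToEndRun:
    """Full pipeline with no signal (d = 0)."""
    return _run_end_to_end(0.0)
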