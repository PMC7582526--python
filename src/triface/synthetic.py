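"""Self-contained synthetic fixtures for every pipeline stage.

Two generators are provided. ``generate_pair_dataset`` emulates labelled
inter-chain residue-pair feature vectors: 128 columns of class-conditional
Gaussians in which a seeded subset of "informative" columns is shifted by
an effect size ``d`` (in within-class standard-deviation units) for
interface pairs, the rest being pure noise. It makes no claim about real
interface physics — it exists so that feature selection, the ensemble and
the top-t metrics can be exercised with known ground truth and a
controllable signal. ``generate_toy_trimer`` builds a small three-chain
PDB file on a lattice in which exactly a planted set of cross-chain
residue pairs is in atomic contact, so the geometric labelling can be
verified end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pair_features import PAIR_WIDTH

__all__ = [
    "SynthConfig",
    "SynthDataset",
    "generate_pair_dataset",
    "TrimerPairData",
    "generate_trimer_pair_data",
    "generate_toy_trimer",
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic pair-feature generator."""

    n_pos: int = 60
    neg_per_pos: int = 200
    effect_size: float = 1.5
    informative_fraction: float = 0.2
    noise_sd: float = 1.0
    duplicate_informative: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1:
            raise ValueError("at least one interface pair must be requested")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if not 0 < self.informative_fraction <= 1:
            raise ValueError("informative_fraction must be in (0, 1]")
        if self.duplicate_informative < 0:
            raise ValueError("duplicate_informative must be >= 0")


@dataclass
class SynthDataset:
    """Labelled pair samples with the planted ground truth."""

    X: np.ndarray
    y: np.ndarray
    informative_columns: np.ndarray
    config: SynthConfig = field(repr=False, default=None)


def _informative_columns(rng: np.random.Generator, fraction: float) -> np.ndarray:
    n_info = max(1, int(round(fraction * PAIR_WIDTH)))
    return np.sort(rng.choice(PAIR_WIDTH, size=n_info, replace=False))


def _draw_block(
    rng: np.random.Generator,
    n: int,
    informative: np.ndarray,
    shift: float,
    sd: float,
) -> np.ndarray:
    X = rng.normal(0.0, sd, size=(n, PAIR_WIDTH))
    X[:, informative] += shift
    return X


def generate_pair_dataset(config: SynthConfig) -> SynthDataset:
    """One pooled dataset of ``n_pos`` interface pairs and
    ``n_pos * neg_per_pos`` non-interface pairs; byte-identical for a
    given config.

    With ``duplicate_informative = m > 0`` the first m informative
    columns are copied verbatim over m non-informative columns, planting
    perfectly correlated column groups for feature selection to collapse.
    """
    rng = np.random.default_rng(config.seed)
    informative = _informative_columns(rng, config.informative_fraction)
    shift = config.effect_size * config.noise_sd
    n_neg = config.n_pos * config.neg_per_pos
    X_pos = _draw_block(rng, config.n_pos, informative, shift, config.noise_sd)
    X_neg = _draw_block(rng, n_neg, informative, 0.0, config.noise_sd)
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(config.n_pos, bool), np.zeros(n_neg, bool)])
    if config.duplicate_informative:
        noise_cols = np.setdiff1d(np.arange(PAIR_WIDTH), informative)
        m = config.duplicate_informative
        if m > min(len(informative), len(noise_cols)):
            raise ValueError("not enough columns to plant that many duplicates")
        X[:, noise_cols[:m]] = X[:, informative[:m]]
    return SynthDataset(X=X, y=y, informative_columns=informative, config=config)


@dataclass
class TrimerPairData:
    """Per-trimer evaluation fixture: three interfaces with known truth.

    ``interfaces`` holds, per interface, a tuple ``(X, y, pair_ids)`` with
    one row per candidate inter-chain pair.
    """

    interfaces: list[tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]]


def generate_trimer_pair_data(
    n_trimers: int,
    n_pos: int,
    n_neg: int,
    effect_size: float,
    informative_fraction: float = 0.2,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list[TrimerPairData], np.ndarray]:
    """Evaluation-side fixtures: ``n_trimers`` trimers, three interfaces
    each, every interface holding ``n_pos`` true and ``n_neg`` decoy
    pairs drawn with the same planted informative-column signal.

    Returns the trimers and the informative-column set (shared with any
    training set drawn at the same ``seed`` via
    :func:`generate_pair_dataset` — both derive it from the seed before
    any other draw).
    """
    rng = np.random.default_rng(seed)
    informative = _informative_columns(rng, informative_fraction)
    shift = effect_size * noise_sd
    trimers = []
    for _ in range(n_trimers):
        interfaces = []
        for _ in range(3):
            X_pos = _draw_block(rng, n_pos, informative, shift, noise_sd)
            X_neg = _draw_block(rng, n_neg, informative, 0.0, noise_sd)
            X = np.vstack([X_pos, X_neg])
            y = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
            # shuffle so truth is not encoded in pair order
            perm = rng.permutation(len(y))
            X, y = X[perm], y[perm]
            side = int(np.ceil(np.sqrt(n_pos + n_neg)))
            pair_ids = [(int(i) // side + 1, int(i) % side + 1) for i in perm]
            interfaces.append((X, y, pair_ids))
        trimers.append(TrimerPairData(interfaces=interfaces))
    return trimers, informative


# ---------------------------------------------------------------------------
# toy trimer structures

_CHAIN_ORIGINS = {
    "A": np.array([0.0, 0.0, 0.0]),
    "B": np.array([0.0, 50.0, 0.0]),
    "C": np.array([0.0, 25.0, 50.0]),
}
_SPACING = 6.0  # Å between consecutive CA atoms along x
_BRIDGE_HALF_GAP = 0.4  # Å; two bridge atoms sit 0.8 Å apart at the midpoint
_MIN_SUM_GAP = 3  # planted pairs on one interface need (i+j) sums this far apart


def _pdb_atom(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    xyz: np.ndarray,
    element: str = "C",
) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def generate_toy_trimer(
    chain_lengths: tuple[int, int, int] = (8, 8, 8),
    planted_pairs: dict[tuple[str, str], list[tuple[int, int]]] | None = None,
) -> tuple[str, list[tuple]]:
    """PDB text for a lattice trimer plus the planted interface pairs.

    Chains A, B, C are straight, well-separated poly-alanine CA traces
    (one residue every 6 Å). For each planted pair ``(i, j)`` on interface
    ``(X, Y)`` a pair of bridge pseudo-atoms is placed at the geometric
    midpoint of the two residues, 0.8 Å apart, so exactly the planted
    residue pairs come out in atomic contact. Pairs on one interface must
    have position sums ``i + j`` at least 3 apart (otherwise their bridge
    atoms would touch each other and create unplanted contacts); violating
    this, exceeding the chain length, or asking for chains longer than 30
    residues raises ``ValueError``.

    Returns ``(pdb_text, truth)`` where truth lists
    ``((chain_a, resnum_a), (chain_b, resnum_b))`` planted pairs.
    """
    if len(chain_lengths) != 3:
        raise ValueError("need exactly three chain lengths")
    if any(n < 3 for n in chain_lengths):
        raise ValueError("chain lengths must be >= 3")
    if any(n > 30 for n in chain_lengths):
        raise ValueError("toy chains are limited to 30 residues")
    planted_pairs = planted_pairs or {}
    lengths = dict(zip("ABC", chain_lengths))

    for (ca, cb), pairs in planted_pairs.items():
        if ca not in "ABC" or cb not in "ABC" or ca >= cb:
            raise ValueError(f"interface key must be ordered chain ids, got {(ca, cb)}")
        sums = []
        for i, j in pairs:
            if not (1 <= i <= lengths[ca] and 1 <= j <= lengths[cb]):
                raise ValueError(f"planted pair {(i, j)} outside chains {ca}/{cb}")
            sums.append(i + j)
        sums.sort()
        if any(b - a < _MIN_SUM_GAP for a, b in zip(sums, sums[1:])):
            raise ValueError(
                f"planted pairs on interface {ca}-{cb} too close together: "
                f"position sums {sums} need gaps >= {_MIN_SUM_GAP}"
            )

    ca_pos = {
        c: [
            _CHAIN_ORIGINS[c] + np.array([_SPACING * k, 0.0, 0.0])
            for k in range(lengths[c])
        ]
        for c in "ABC"
    }
    bridge_atoms: dict[tuple[str, int], list[np.ndarray]] = {}
    truth: list[tuple] = []
    for (cid_a, cid_b), pairs in planted_pairs.items():
        for i, j in pairs:
            mid = (ca_pos[cid_a][i - 1] + ca_pos[cid_b][j - 1]) / 2.0
            off = np.array([_BRIDGE_HALF_GAP, 0.0, 0.0])
            bridge_atoms.setdefault((cid_a, i), []).append(mid - off)
            bridge_atoms.setdefault((cid_b, j), []).append(mid + off)
            truth.append(((cid_a, i), (cid_b, j)))

    lines = []
    serial = 1
    for cid in "ABC":
        for resnum in range(1, lengths[cid] + 1):
            lines.append(
                _pdb_atom(serial, "CA", "ALA", cid, resnum, ca_pos[cid][resnum - 1])
            )
            serial += 1
            for b_idx, xyz in enumerate(bridge_atoms.get((cid, resnum), [])):
                lines.append(
                    _pdb_atom(serial, f"CB{b_idx}" if b_idx else "CB", "ALA",
                              cid, resnum, xyz)
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      ALA {cid}{lengths[cid]:4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n", truth
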