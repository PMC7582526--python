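"""Sequence encoding and the amino-acid k-interval product factor (AAIPF).

A protein sequence is mapped, via each property scale, to a numeric
sequence that is treated as *cyclic* (head-to-tail connected). The
k-interval product factor at position ``j`` multiplies the property value
at ``j`` with the value ``k`` positions away (forward variant looks
backwards along the sequence towards ``j-k``, backward variant towards
``j+k``) and divides by ``k``, so that more distant neighbours contribute
less. With interval sizes k = 1..5, both directions, over the first five
property scales, every residue receives 50 AAIPF features; the residue's
own seven scale values (the basic first-order features) complete a
57-dimensional per-residue sequence block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scales import ALPHABET, ScaleTable, default_scales

__all__ = [
    "NumericSequence",
    "encode_sequence",
    "aafipf",
    "aabipf",
    "sequence_feature_block",
    "sequence_block_columns",
    "N_SEQUENCE_FEATURES",
    "N_AAIPF_PROPERTIES",
    "K_MAX",
]

#: AAIPF uses only the first five scales and intervals k = 1..5.
N_AAIPF_PROPERTIES = 5
K_MAX = 5
N_SEQUENCE_FEATURES = N_AAIPF_PROPERTIES * K_MAX * 2 + 7  # = 57


@dataclass(frozen=True)
class NumericSequence:
    """A property-valued protein sequence with cyclic index arithmetic."""

    values: np.ndarray  # shape (L,)
    property_index: int = 0
    cyclic: bool = True

    def __len__(self) -> int:
        return len(self.values)


def encode_sequence(sequence: str, scale: ScaleTable) -> NumericSequence:
    """Map a residue string to its numeric property sequence.

    Raises ``ValueError`` on an empty sequence or on any character outside
    the 20-residue alphabet, naming the offending (1-based) position.
    """
    if len(sequence) == 0:
        raise ValueError("empty sequence cannot be encoded")
    sequence = sequence.upper()
    for pos, ch in enumerate(sequence, start=1):
        if ch not in scale.values:
            raise ValueError(
                f"unknown residue {ch!r} at position {pos} "
                f"(alphabet: {ALPHABET})"
            )
    vals = np.array([scale.values[ch] for ch in sequence], dtype=float)
    return NumericSequence(values=vals)


def _check_jk(seq: NumericSequence, j: int, k: int) -> None:
    if k < 1:
        raise ValueError(f"interval k must be >= 1, got {k}")
    if not 1 <= j <= len(seq):
        raise ValueError(f"position j={j} outside 1..{len(seq)}")


def aafipf(seq: NumericSequence, j: int, k: int) -> float:
    """Forward k-interval product factor at 1-based position ``j``.

    Product of the value at ``j`` and the value ``k`` positions before it
    on the cyclic sequence, divided by ``k``.
    """
    _check_jk(seq, j, k)
    L = len(seq)
    return float(seq.values[j - 1] * seq.values[(j - 1 - k) % L]) / k


def aabipf(seq: NumericSequence, j: int, k: int) -> float:
    """Backward k-interval product factor: partner is ``k`` positions after ``j``."""
    _check_jk(seq, j, k)
    L = len(seq)
    return float(seq.values[j - 1] * seq.values[(j - 1 + k) % L]) / k


def sequence_block_columns(scales: list[ScaleTable] | None = None) -> list[str]:
    """Names of the 57 per-residue sequence-block columns, in fixed order:
    (property 1..5) x (k=1..5) x (forward, backward), then the 7 basic
    first-order features."""
    if scales is None:
        scales = default_scales()
    if len(scales) != 7:
        raise ValueError(f"expected 7 scales, got {len(scales)}")
    cols = []
    for p in range(N_AAIPF_PROPERTIES):
        pname = scales[p].property_name
        for k in range(1, K_MAX + 1):
            cols.append(f"aafipf_{pname}_k{k}")
            cols.append(f"aabipf_{pname}_k{k}")
    cols.extend(f"basic_{s.property_name}" for s in scales)
    return cols


def sequence_feature_block(
    sequence: str, scales: list[ScaleTable] | None = None
) -> np.ndarray:
    """Per-residue 57-column sequence feature matrix, shape ``(L, 57)``.

    Column order is property-major then interval then direction, as given
    by :func:`sequence_block_columns`.
    """
    if scales is None:
        scales = default_scales()
    if len(scales) != 7:
        raise ValueError(f"expected 7 scales, got {len(scales)}")
    numeric = [encode_sequence(sequence, sc) for sc in scales]
    L = len(sequence)
    block = np.empty((L, N_SEQUENCE_FEATURES), dtype=float)
    col = 0
    for p in range(N_AAIPF_PROPERTIES):
        vals = numeric[p].values
        for k in range(1, K_MAX + 1):
            fwd = vals * np.roll(vals, k) / k   # partner at j-k (cyclic)
            bwd = vals * np.roll(vals, -k) / k  # partner at j+k (cyclic)
            block[:, col] = fwd
            block[:, col + 1] = bwd
            col += 2
    for p in range(7):
        block[:, col] = numeric[p].values
        col += 1
    assert col == N_SEQUENCE_FEATURES
    return block
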