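"""Small sequence and numeric helpers shared across modules."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

DNA = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def masked_keys(seq: str):
    """Yield ``seq`` with each position in turn replaced by ``.``.

    Two equal-length sequences at Hamming distance <=1 share at least one
    masked key, which turns one-mismatch neighbour search into dict lookups.
    """
    for i in range(len(seq)):
        yield f"{seq[:i]}.{seq[i + 1:]}"


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with halves away from zero (3.5/28 -> 0.13, not banker's 0.12)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
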