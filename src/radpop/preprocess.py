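"""Read quality filtering, barcode demultiplexing and 41-nt tag trimming.

The cleaning rules mirror a standard single-end RAD protocol: drop reads
with more than 50% of bases at or below quality 5 (strictly greater than
half), drop reads matching an adapter, assign reads whose exact barcode
prefix is followed by the EcoRI remnant AATTC, and trim the remainder to a
uniform 41-nt tag (5-nt site remnant + 36-nt variable sequence).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .simulate import ECORI_SITE, TAG_LENGTH

#: discard reason codes, in the order filters are applied
REASONS = ("low_quality", "adapter", "no_barcode", "no_site", "too_short")


def passes_quality(
    quality: str | Sequence[int],
    max_low_fraction: float = 0.5,
    low_quality: int = 5,
) -> bool:
    """Keep a read unless *more than* ``max_low_fraction`` of its bases are
    at Phred quality <= ``low_quality`` (Phred+33 when given a string)."""
    if isinstance(quality, str):
        scores = [ord(c) - 33 for c in quality]
    else:
        scores = list(quality)
    if not scores:
        return True
    n_low = sum(q <= low_quality for q in scores)
    return n_low <= max_low_fraction * len(scores)


def contains_adapter(sequence: str, adapters: Sequence[str]) -> bool:
    """Exact-substring adapter screen."""
    return any(a in sequence for a in adapters)


def trim_tag(after_barcode: str, tag_length: int = TAG_LENGTH) -> str | None:
    """First ``tag_length`` nt after the barcode, or ``None`` if too short."""
    if len(after_barcode) < tag_length:
        return None
    return after_barcode[:tag_length]


@dataclass
class PreprocessResult:
    """Per-accession tags plus a discard log that preserves read counts."""

    tags_by_accession: dict[str, list[str]]
    discarded: Counter = field(default_factory=Counter)
    n_input: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.tags_by_accession.values())

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded.values())

    @property
    def retention(self) -> float:
        """Fraction of input reads kept (the 'clean data' rate)."""
        return self.n_assigned / self.n_input if self.n_input else float("nan")


def _barcode_lookup(barcode_table: dict[str, str]) -> dict[int, dict[str, str]]:
    seen: dict[str, str] = {}
    for acc, bc in barcode_table.items():
        if bc in seen:
            raise ValueError(
                f"duplicate barcode {bc!r} for {seen[bc]!r} and {acc!r}"
            )
        seen[bc] = acc
    by_length: dict[int, dict[str, str]] = {}
    for bc, acc in seen.items():
        by_length.setdefault(len(bc), {})[bc] = acc
    return dict(sorted(by_length.items(), reverse=True))  # longest match first


def demultiplex(
    reads: Iterable[tuple[str, str, str]],
    barcode_table: dict[str, str],
    site: str = ECORI_SITE,
) -> tuple[dict[str, list[tuple[str, str, str]]], Counter]:
    """Partition reads by exact barcode match followed by the cut-site remnant.

    Reads are ``(name, sequence, quality)`` triples. A read is assigned iff
    its prefix equals a registered barcode (longest match first for
    variable-length sets) and the next ``len(site)`` bases equal ``site``;
    everything else lands in the discard counter under ``no_barcode`` or
    ``no_site``. Assignment is a partition: each read goes to exactly one
    bin. Sequences are returned with the barcode removed.
    """
    by_length = _barcode_lookup(barcode_table)
    assigned: dict[str, list[tuple[str, str, str]]] = {
        acc: [] for acc in barcode_table
    }
    discarded: Counter = Counter()
    w = len(site)
    for name, seq, qual in reads:
        hit = None
        for length, table in by_length.items():
            acc = table.get(seq[:length])
            if acc is not None:
                hit = (length, acc)
                break
        if hit is None:
            discarded["no_barcode"] += 1
            continue
        length, acc = hit
        if seq[length : length + w] != site:
            discarded["no_site"] += 1
            continue
        assigned[acc].append((name, seq[length:], qual[length:]))
    return assigned, discarded


def preprocess_reads(
    reads: Iterable[tuple[str, str, str]],
    barcode_table: dict[str, str],
    adapters: Sequence[str] = (),
    tag_length: int = TAG_LENGTH,
    max_low_fraction: float = 0.5,
    low_quality: int = 5,
) -> PreprocessResult:
    """Full cleaning pass: quality filter -> adapter screen -> demultiplex ->
    41-nt trim. Returns per-accession tag sequences and a reason-coded
    discard log; assigned + discarded always equals the input count."""
    by_length = _barcode_lookup(barcode_table)
    result = PreprocessResult(
        tags_by_accession={acc: [] for acc in barcode_table}
    )
    w = len(ECORI_SITE)
    for name, seq, qual in reads:
        result.n_input += 1
        if not passes_quality(qual, max_low_fraction, low_quality):
            result.discarded["low_quality"] += 1
            continue
        if adapters and contains_adapter(seq, adapters):
            result.discarded["adapter"] += 1
            continue
        hit = None
        for length, table in by_length.items():
            acc = table.get(seq[:length])
            if acc is not None:
                hit = (length, acc)
                break
        if hit is None:
            result.discarded["no_barcode"] += 1
            continue
        length, acc = hit
        if seq[length : length + w] != ECORI_SITE:
            result.discarded["no_site"] += 1
            continue
        tag = trim_tag(seq[length:], tag_length)
        if tag is None:
            result.discarded["too_short"] += 1
            continue
        result.tags_by_accession[acc].append(tag)
    return result
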