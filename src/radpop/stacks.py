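"""Within-accession stack assembly and depth-ratio genotype calling.

Identical 41-nt tags are clustered into stacks; stacks below 10x are
discarded as unreliable and stacks above 300x as repetitive; surviving
stacks within one mismatch of a deeper seed stack merge into a RAD tag
locus (star linkage from the deepest seed, deeper seeds claiming members
first). Per-site genotypes follow the hard depth-ratio rule: with A1/A2
the first and second most frequent bases, a site of total depth >=10 is
homozygous when Depth_A2/Depth_A1 < 0.05, heterozygous when > 0.1, and
discarded as ambiguous in between.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from ._util import DNA, hamming, masked_keys
from .simulate import TAG_LENGTH

MIN_STACK_DEPTH = 10
MAX_STACK_DEPTH = 300
MIN_SITE_DEPTH = 10
HOM_RATIO = 0.05
HET_RATIO = 0.1

_BASE_INDEX = {b: i for i, b in enumerate(DNA)}


@dataclass(frozen=True)
class Stack:
    """A cluster of identical reads within one accession."""

    sequence: str
    depth: int


class CallStatus(str, Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    DISCARDED_AMBIGUOUS = "discarded_ambiguous"
    INSUFFICIENT_DEPTH = "insufficient_depth"


@dataclass(frozen=True)
class SiteCall:
    """Genotype call at one tag position."""

    position: int
    status: CallStatus
    a1: str
    a2: str | None
    depth_a1: int
    depth_a2: int

    @property
    def alleles(self) -> tuple[str, ...] | None:
        """Called allele(s); ``None`` when the site yielded no genotype."""
        if self.status is CallStatus.HOMOZYGOUS:
            return (self.a1,)
        if self.status is CallStatus.HETEROZYGOUS:
            return tuple(sorted((self.a1, self.a2)))
        return None


def call_site_genotype(
    depth_a1: int,
    depth_a2: int,
    min_total: int = MIN_SITE_DEPTH,
    hom_ratio: float = HOM_RATIO,
    het_ratio: float = HET_RATIO,
) -> CallStatus:
    """Depth-ratio genotype rule for the two most frequent alleles.

    Total depth below ``min_total`` is uncallable; a site with no second
    allele, or Depth_A2/Depth_A1 < ``hom_ratio``, is homozygous; a ratio
    above ``het_ratio`` is heterozygous; the closed interval in between is
    discarded as ambiguous.
    """
    if depth_a1 < 0 or depth_a2 < 0:
        raise ValueError("depths must be non-negative")
    if depth_a2 > depth_a1:
        raise ValueError("depth_a1 must be the larger depth")
    if depth_a1 + depth_a2 < min_total:
        return CallStatus.INSUFFICIENT_DEPTH
    if depth_a2 == 0:
        return CallStatus.HOMOZYGOUS
    ratio = depth_a2 / depth_a1
    if ratio < hom_ratio:
        return CallStatus.HOMOZYGOUS
    if ratio > het_ratio:
        return CallStatus.HETEROZYGOUS
    return CallStatus.DISCARDED_AMBIGUOUS


@dataclass
class RadLocus:
    """A merged stack cluster with per-site depth counts and calls."""

    stacks: list[Stack]
    depth_table: np.ndarray  # (4, tag_length) base depths, rows in DNA order

    @property
    def depth(self) -> int:
        return sum(s.depth for s in self.stacks)

    @property
    def seed(self) -> Stack:
        return self.stacks[0]

    @property
    def consensus(self) -> str:
        """Deepest base per site; ties broken alphabetically."""
        idx = np.argmax(self.depth_table, axis=0)  # argmax takes first (A<C<G<T)
        return "".join(DNA[i] for i in idx)

    def site_calls(
        self,
        min_total: int = MIN_SITE_DEPTH,
        hom_ratio: float = HOM_RATIO,
        het_ratio: float = HET_RATIO,
    ) -> list[SiteCall]:
        """Call every tag position with the depth-ratio rule.

        A third allele deeper than ``het_ratio`` of A1 marks the site as
        non-bi-allelic and it is discarded as ambiguous; shallower third
        alleles are treated as sequencing error and ignored.
        """
        calls = []
        for pos in range(self.depth_table.shape[1]):
            col = self.depth_table[:, pos]
            order = np.lexsort((np.arange(4), -col))  # depth desc, base asc
            d1, d2, d3 = int(col[order[0]]), int(col[order[1]]), int(col[order[2]])
            a1 = DNA[order[0]]
            a2 = DNA[order[1]] if d2 > 0 else None
            status = call_site_genotype(d1, d2, min_total, hom_ratio, het_ratio)
            if (
                d3 > 0
                and d1 > 0
                and d3 / d1 > het_ratio
                and status is not CallStatus.INSUFFICIENT_DEPTH
            ):
                status = CallStatus.DISCARDED_AMBIGUOUS
            calls.append(SiteCall(pos, status, a1, a2, d1, d2))
        return calls


def build_stacks(tags: Iterable[str]) -> list[Stack]:
    """Cluster identical tags; returned depth-descending (ties by sequence)."""
    counts = Counter(tags)
    return [
        Stack(seq, depth)
        for seq, depth in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def filter_stacks(
    stacks: Sequence[Stack],
    min_depth: int = MIN_STACK_DEPTH,
    max_depth: int = MAX_STACK_DEPTH,
) -> tuple[list[Stack], list[tuple[Stack, str]]]:
    """Drop shallow (< ``min_depth``) and repetitive (> ``max_depth``) stacks.

    Both bounds are inclusive for retention; the log records each removal
    as ``low`` or ``repetitive``.
    """
    kept, log = [], []
    for s in stacks:
        if s.depth < min_depth:
            log.append((s, "low"))
        elif s.depth > max_depth:
            log.append((s, "repetitive"))
        else:
            kept.append(s)
    return kept, log


def _depth_table(stacks: Sequence[Stack], tag_length: int) -> np.ndarray:
    table = np.zeros((4, tag_length), dtype=np.int64)
    for s in stacks:
        row = [_BASE_INDEX[b] for b in s.sequence]
        table[row, np.arange(tag_length)] += s.depth
    return table


def merge_stacks_to_loci(
    stacks: Sequence[Stack], max_mismatch: int = 1
) -> list[RadLocus]:
    """Star-linkage merge: each stack joins the deepest seed within
    ``max_mismatch``, otherwise founds a new locus.

    Seeds are processed in depth order, so deeper seeds claim members
    first; membership is never chained through intermediate stacks (a stack
    two mismatches from a seed founds its own locus even if it is within
    one mismatch of another member).
    """
    ordered = sorted(stacks, key=lambda s: (-s.depth, s.sequence))
    if not ordered:
        return []
    tag_length = len(ordered[0].sequence)
    seeds: list[list[Stack]] = []
    exact: dict[str, int] = {}
    by_mask: dict[str, int] = {}
    for stack in ordered:
        best = exact.get(stack.sequence)
        if max_mismatch >= 1:
            for key in masked_keys(stack.sequence):
                hit = by_mask.get(key)
                if hit is not None and (best is None or hit < best):
                    best = hit
        if max_mismatch >= 2:  # rare configuration: fall back to scanning
            for idx, members in enumerate(seeds):
                if best is not None and idx >= best:
                    break
                if hamming(members[0].sequence, stack.sequence) <= max_mismatch:
                    best = idx
                    break
        if best is not None:
            seeds[best].append(stack)
        else:
            idx = len(seeds)
            seeds.append([stack])
            exact.setdefault(stack.sequence, idx)
            if max_mismatch >= 1:
                for key in masked_keys(stack.sequence):
                    by_mask.setdefault(key, idx)
    return [
        RadLocus(stacks=members, depth_table=_depth_table(members, tag_length))
        for members in seeds
    ]


def assemble_accession(
    tags: Iterable[str],
    min_depth: int = MIN_STACK_DEPTH,
    max_depth: int = MAX_STACK_DEPTH,
    max_mismatch: int = 1,
) -> tuple[list[RadLocus], list[tuple[Stack, str]]]:
    """tags -> stacks -> depth filter -> loci, for one accession."""
    stacks = build_stacks(tags)
    kept, log = filter_stacks(stacks, min_depth, max_depth)
    return merge_stacks_to_loci(kept, max_mismatch), log
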