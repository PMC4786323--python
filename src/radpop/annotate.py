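"""Tag-to-transcript mapping and synonymous/non-synonymous classification.

SNP-bearing tags are located in a transcript set with a deterministic
ungapped scan of the 36-nt variable region over both strands, allowing at
most one mismatch and honouring minimum-coverage and minimum-identity
thresholds. SNPs falling inside an annotated CDS are classified by
substituting each allele into its codon and translating with the standard
genetic code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from Bio.Seq import Seq

from ._util import revcomp
from .catalog import GenotypeMatrix
from .simulate import VARIABLE_REGION

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class TranscriptAlignment:
    """Best ungapped placement of a tag's variable region in a transcript."""

    transcript_id: str
    offset: int  # transcript position of the region's first aligned base
    strand: str  # '+' as-is, '-' reverse complement
    mismatches: int
    overlap: int  # aligned bases (== region length except at transcript ends)
    region_start: int  # first region position covered by the alignment
    n_ties: int = 0  # equally good placements elsewhere (best kept)


def _scan_one(
    query: str, transcript: str, max_mismatch: int, min_overlap: int
):
    """Yield (offset, mismatches, overlap, query_start) for every ungapped
    placement with enough overlap and few enough mismatches, including
    placements hanging off the transcript ends."""
    L, T = len(query), len(transcript)
    for offset in range(-(L - min_overlap), T - min_overlap + 1):
        q_start = max(0, -offset)
        q_end = min(L, T - offset)
        overlap = q_end - q_start
        if overlap < min_overlap:
            continue
        mism = 0
        for q in range(q_start, q_end):
            if query[q] != transcript[offset + q]:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            yield (max(offset, 0), mism, overlap, q_start)


def map_tag_to_transcripts(
    tag: str,
    transcripts: Mapping[str, str],
    max_mismatch: int = 1,
    min_coverage: float = 0.8,
    min_identity: float = 0.9,
    variable_region: tuple[int, int] = VARIABLE_REGION,
) -> TranscriptAlignment | None:
    """Locate a tag's variable region in a transcript set, or ``None``.

    Both orientations of the region are scanned ungapped against every
    transcript; a placement qualifies when it covers more than
    ``min_coverage`` of the region at identity above ``min_identity`` with
    at most ``max_mismatch`` mismatches. The best alignment (fewest
    mismatches, then longest overlap) wins; exact ties are broken by
    transcript id, offset and strand, and counted in ``n_ties``.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    lo, hi = variable_region
    region = tag[lo:hi] if len(tag) > hi - lo else tag
    L = len(region)
    min_overlap = int(math.floor(min_coverage * L)) + 1  # strict 'above'
    hits = []
    for tx_id in sorted(transcripts):
        seq = transcripts[tx_id]
        for strand, query in (("+", region), ("-", revcomp(region))):
            for offset, mism, overlap, q_start in _scan_one(
                query, seq, max_mismatch, min_overlap
            ):
                if (overlap - mism) / overlap <= min_identity:
                    continue
                if strand == "-":
                    # report region coordinates on the forward query
                    q_start = L - (q_start + overlap)
                hits.append(
                    (mism, -overlap, tx_id, offset, strand, q_start)
                )
    if not hits:
        return None
    hits.sort()
    best = hits[0]
    n_ties = sum(1 for h in hits[1:] if h[:2] == best[:2])
    mism, neg_overlap, tx_id, offset, strand, q_start = best
    return TranscriptAlignment(
        transcript_id=tx_id,
        offset=offset,
        strand=strand,
        mismatches=mism,
        overlap=-neg_overlap,
        region_start=q_start,
        n_ties=n_ties,
    )


@dataclass(frozen=True)
class EffectCall:
    """Coding consequence of one SNP."""

    effect: str  # synonymous | non_synonymous | non_coding | unmapped
    codon_ref: str = ""
    codon_alt: str = ""
    aa_ref: str = ""
    aa_alt: str = ""


UNMAPPED = EffectCall(effect="unmapped")


def classify_coding_effect(
    alignment: TranscriptAlignment,
    snp_region_offset: int,
    ref: str,
    alt: str,
    cds_table: pd.DataFrame,
    transcripts: Mapping[str, str],
) -> EffectCall:
    """Classify a SNP given its transcript alignment and a CDS annotation.

    ``snp_region_offset`` is the SNP position within the 36-nt variable
    region. The SNP is projected into transcript coordinates (respecting
    orientation), and if it falls inside the transcript's CDS interval the
    reference and alternate alleles are substituted into the codon given
    by the annotated frame and translated; identical amino acids mean a
    synonymous substitution. CDS intervals (after the frame offset) must
    span whole codons.
    """
    tx_id = alignment.transcript_id
    tx = transcripts[tx_id]
    region_len = VARIABLE_REGION[1] - VARIABLE_REGION[0]
    rel = snp_region_offset - alignment.region_start
    if alignment.strand == "+":
        t_pos = alignment.offset + rel
        ref_t, alt_t = ref, alt
    else:
        t_pos = alignment.offset + (alignment.overlap - 1 - rel)
        ref_t, alt_t = _COMP[ref], _COMP[alt]
    if not (alignment.region_start <= snp_region_offset
            < alignment.region_start + alignment.overlap):
        return EffectCall(effect="unmapped")  # SNP outside the aligned part
    if tx_id not in cds_table.index:
        return EffectCall(effect="non_coding")
    row = cds_table.loc[tx_id]
    cds_start, cds_end = int(row["cds_start"]), int(row["cds_end"])
    frame = int(row.get("frame", 0))
    start = cds_start + frame
    if (cds_end - start) % 3 != 0:
        raise ValueError(
            f"CDS of {tx_id} is not a whole number of codons "
            f"({start}:{cds_end})"
        )
    if not start <= t_pos < cds_end:
        return EffectCall(effect="non_coding")
    codon_idx = (t_pos - start) // 3
    codon_start = start + 3 * codon_idx
    codon_ref = tx[codon_start : codon_start + 3]
    within = t_pos - codon_start
    # substitute both alleles: the transcript may carry either one
    codon_ref = codon_ref[:within] + ref_t + codon_ref[within + 1 :]
    codon_alt = codon_ref[:within] + alt_t + codon_ref[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    effect = "synonymous" if aa_ref == aa_alt else "non_synonymous"
    return EffectCall(
        effect=effect,
        codon_ref=codon_ref,
        codon_alt=codon_alt,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
    )


def annotate_matrix(
    matrix: GenotypeMatrix,
    transcripts: Mapping[str, str],
    cds_table: pd.DataFrame,
    max_mismatch: int = 1,
    min_coverage: float = 0.8,
    min_identity: float = 0.9,
) -> pd.DataFrame:
    """Map every catalog SNP tag to the transcript set and classify effects.

    Returns one row per locus with the mapping result and effect call.
    """
    lo, _ = VARIABLE_REGION
    rows = []
    for locus in matrix.loci:
        tag = matrix.consensus[locus]
        aln = map_tag_to_transcripts(
            tag, transcripts, max_mismatch, min_coverage, min_identity
        )
        if aln is None:
            rows.append({"locus_id": locus, "transcript_id": None,
                         "strand": None, "effect": "unmapped"})
            continue
        call = classify_coding_effect(
            aln,
            int(matrix.snp_pos[locus]) - lo,
            matrix.ref[locus],
            matrix.alt[locus],
            cds_table,
            transcripts,
        )
        rows.append(
            {
                "locus_id": locus,
                "transcript_id": aln.transcript_id,
                "strand": aln.strand,
                "mismatches": aln.mismatches,
                "effect": call.effect,
                "codon_ref": call.codon_ref,
                "codon_alt": call.codon_alt,
                "aa_ref": call.aa_ref,
                "aa_alt": call.aa_alt,
            }
        )
    return pd.DataFrame(rows).set_index("locus_id")


@dataclass
class DnDsSummary:
    n_non_synonymous: int
    n_synonymous: int
    ratio: float | None  # None when no synonymous calls


def dn_ds_summary(effects: pd.DataFrame | pd.Series) -> DnDsSummary:
    """Count coding effects and form the dN/dS ratio (count ratio)."""
    col = effects["effect"] if isinstance(effects, pd.DataFrame) else effects
    if len(col) == 0:
        raise ValueError("no effect calls")
    n_non = int((col == "non_synonymous").sum())
    n_syn = int((col == "synonymous").sum())
    return DnDsSummary(
        n_non_synonymous=n_non,
        n_synonymous=n_syn,
        ratio=(n_non / n_syn) if n_syn else None,
    )
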