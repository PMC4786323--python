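"""Cross-accession SNP catalog: consensus matching, locus filters, summaries.

Per-accession RAD loci are matched across accessions by consensus sequence
(at most one mismatch to the catalog seed); entries genotyped in at least
14 of 18 accessions and containing exactly one bi-allelic variant inside
the 36-nt variable region become rows of the genotype matrix. Substitution
types (transition A/G, C/T vs transversion) and allele-pair spectra are
summarised from the matrix.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import masked_keys
from .simulate import TAG_LENGTH, VARIABLE_REGION
from .stacks import RadLocus, SiteCall

MIN_ACCESSIONS = 14

#: genotype codes: homozygous reference allele, heterozygous, homozygous
#: alternate, missing
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

TRANSITIONS = ({"A", "G"}, {"C", "T"})


def classify_substitution(a: str, b: str) -> str:
    """'transition' for A/G and C/T pairs, 'transversion' otherwise."""
    if a == b:
        raise ValueError(f"identical alleles {a!r}")
    pair = {a, b}
    if not pair <= set("ACGT"):
        raise ValueError(f"non-nucleotide alleles {a!r}/{b!r}")
    return "transition" if pair in TRANSITIONS else "transversion"


@dataclass
class CatalogEntry:
    """Loci from different accessions matched to one catalog consensus."""

    id: str
    seed_consensus: str
    members: dict[str, RadLocus]  # accession -> locus

    # analysis products (filled by analyze_entry)
    variant_positions: dict[int, tuple[str, ...]] = field(default_factory=dict)
    genotypes: dict[str, int] = field(default_factory=dict)
    snp_pos: int | None = None
    ref: str | None = None
    alt: str | None = None

    @property
    def n_genotyped(self) -> int:
        if self.variant_positions and len(self.variant_positions) == 1:
            return sum(g != MISSING for g in self.genotypes.values())
        return len(self.members)


def match_loci_across_accessions(
    loci_by_accession: Mapping[str, Sequence[RadLocus]],
    max_mismatch: int = 1,
) -> tuple[list[CatalogEntry], list[dict]]:
    """Group per-accession loci whose consensus is within ``max_mismatch``
    of a catalog seed consensus.

    The seed is the consensus of the deepest locus overall; loci are
    processed depth-descending, each joining the deepest matching entry.
    An accession contributes at most one locus per entry: when a second
    locus of the same accession matches, the deeper one (already placed)
    wins and the conflict is logged as a putative paralog.
    """
    flat = [
        (locus, acc)
        for acc, loci in loci_by_accession.items()
        for locus in loci
    ]
    flat.sort(key=lambda t: (-t[0].depth, t[0].consensus, t[1]))
    entries: list[CatalogEntry] = []
    exact: dict[str, int] = {}
    by_mask: dict[str, int] = {}
    conflicts: list[dict] = []
    for locus, acc in flat:
        consensus = locus.consensus
        best = exact.get(consensus)
        if max_mismatch >= 1:
            for key in masked_keys(consensus):
                hit = by_mask.get(key)
                if hit is not None and (best is None or hit < best):
                    best = hit
        if best is not None:
            entry = entries[best]
            if acc in entry.members:
                conflicts.append(
                    {
                        "catalog_id": entry.id,
                        "accession": acc,
                        "kept_depth": entry.members[acc].depth,
                        "dropped_depth": locus.depth,
                    }
                )
            else:
                entry.members[acc] = locus
            continue
        idx = len(entries)
        entries.append(
            CatalogEntry(
                id=f"CAT{idx:05d}", seed_consensus=consensus, members={acc: locus}
            )
        )
        exact.setdefault(consensus, idx)
        for key in masked_keys(consensus):
            by_mask.setdefault(key, idx)
    return entries, conflicts


def analyze_entry(entry: CatalogEntry, min_site_depth: int = 10) -> CatalogEntry:
    """Locate variant positions and per-accession genotypes for one entry.

    A position is variant when the confident calls across member
    accessions expose more than one allele (a heterozygote alone
    suffices). For single-variant entries the reference allele is the seed
    consensus base at the site and genotypes are re-expressed as alt-allele
    dosage; calls showing alleles outside the pair are set to missing.
    """
    calls_by_acc: dict[str, list[SiteCall]] = {
        acc: locus.site_calls(min_total=min_site_depth)
        for acc, locus in entry.members.items()
    }
    tag_length = len(entry.seed_consensus)
    variant_positions: dict[int, tuple[str, ...]] = {}
    for pos in range(tag_length):
        alleles: set[str] = set()
        for calls in calls_by_acc.values():
            got = calls[pos].alleles
            if got:
                alleles.update(got)
        if len(alleles) > 1:
            variant_positions[pos] = tuple(sorted(alleles))
    entry.variant_positions = variant_positions
    entry.genotypes = {}
    entry.snp_pos = entry.ref = entry.alt = None
    if len(variant_positions) == 1:
        (pos, alleles), = variant_positions.items()
        seed_base = entry.seed_consensus[pos]
        if seed_base in alleles:
            ref = seed_base
            others = [a for a in alleles if a != ref]
        else:
            ref, *others = alleles
        alt = others[0] if others else None
        entry.snp_pos, entry.ref, entry.alt = pos, ref, alt
        pair = set(alleles)
        for acc, calls in calls_by_acc.items():
            got = calls[pos].alleles
            if got is None or not set(got) <= pair or len(pair) != 2:
                entry.genotypes[acc] = MISSING
            elif len(got) == 2:
                entry.genotypes[acc] = HET
            else:
                entry.genotypes[acc] = HOM_REF if got[0] == ref else HOM_ALT
    return entry


@dataclass
class GenotypeMatrix:
    """Catalog SNP loci x accessions with dosage-coded calls.

    ``calls`` holds {0: hom-ref, 1: het, 2: hom-alt, -1: missing}; ``ref``/
    ``alt`` give each locus's allele pair, ``snp_pos`` the 0-based offset of
    the SNP in the 41-nt tag, ``consensus`` the catalog consensus sequence.
    """

    calls: pd.DataFrame
    ref: pd.Series
    alt: pd.Series
    snp_pos: pd.Series
    consensus: pd.Series
    group_of: dict[str, str] = field(default_factory=dict)
    class_of_group: dict[str, str] = field(default_factory=dict)

    @property
    def accessions(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.index)

    @property
    def n_loci(self) -> int:
        return len(self.calls)

    def accessions_in_class(self, cls: str) -> list[str]:
        return [
            a
            for a in self.accessions
            if self.class_of_group.get(self.group_of.get(a, ""), "") == cls
        ]

    def members_of_group(self, group: str) -> list[str]:
        return [a for a in self.accessions if self.group_of.get(a) == group]

    def dosage_values(self) -> np.ndarray:
        """Calls as 0 / 0.5 / 1 alt-allele dosage, NaN for missing
        (accessions x loci)."""
        v = self.calls.to_numpy(dtype=float).T / 2.0
        v[v < 0] = np.nan
        return v

    def allele_pairs(self) -> pd.Series:
        return pd.Series(
            ["/".join(sorted((r, a))) for r, a in zip(self.ref, self.alt)],
            index=self.calls.index,
        )

    @classmethod
    def from_calls(
        cls,
        calls: pd.DataFrame | Mapping[str, Sequence[int]],
        ref: Mapping[str, str] | str = "A",
        alt: Mapping[str, str] | str = "T",
        group_of: dict[str, str] | None = None,
        class_of_group: dict[str, str] | None = None,
        snp_pos: int = 5,
    ) -> "GenotypeMatrix":
        """Build a matrix directly from calls (handy for worked examples)."""
        calls = pd.DataFrame(calls).astype("int8")
        idx = calls.index.astype(str)
        calls.index = idx
        ref_s = (
            pd.Series(ref, index=idx)
            if isinstance(ref, str)
            else pd.Series(dict(ref)).reindex(idx)
        )
        alt_s = (
            pd.Series(alt, index=idx)
            if isinstance(alt, str)
            else pd.Series(dict(alt)).reindex(idx)
        )
        pos_s = pd.Series(snp_pos, index=idx)
        cons = pd.Series("", index=idx)
        return cls(
            calls=calls,
            ref=ref_s,
            alt=alt_s,
            snp_pos=pos_s,
            consensus=cons,
            group_of=dict(group_of or {}),
            class_of_group=dict(class_of_group or {}),
        )

    def to_tsv(self, path) -> None:
        out = self.calls.replace(MISSING, pd.NA)
        out.to_csv(path, sep="\t", na_rep="NA")

    def to_vcf(self, path) -> None:
        """Minimal VCF: CHROM = catalog id, POS = SNP offset + 1 (1-based)."""
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.accessions),
        ]
        gt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
        for locus in self.calls.index:
            row = self.calls.loc[locus]
            fields = [
                locus,
                str(int(self.snp_pos[locus]) + 1),
                ".",
                self.ref[locus],
                self.alt[locus],
                ".",
                "PASS",
                ".",
                "GT",
            ] + [gt[int(v)] for v in row]
            lines.append("\t".join(fields))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class SelectionLog:
    """Why catalog entries were excluded from the genotype matrix."""

    reasons: Counter = field(default_factory=Counter)

    @property
    def n_monomorphic(self) -> int:
        return self.reasons["monomorphic"]


def select_biallelic_snp_loci(
    entries: Sequence[CatalogEntry],
    min_accessions: int = MIN_ACCESSIONS,
    variable_region: tuple[int, int] = VARIABLE_REGION,
    group_of: dict[str, str] | None = None,
    class_of_group: dict[str, str] | None = None,
    accessions: Sequence[str] | None = None,
    analyzed: bool = False,
) -> tuple[GenotypeMatrix, SelectionLog]:
    """Keep entries genotyped in >= ``min_accessions`` accessions with
    exactly one bi-allelic variant inside the 36-nt variable region.

    Monomorphic entries carry no SNP and are tallied separately; entries
    whose only variant falls in the 5-nt site remnant are rejected as
    corrupt input (the remnant is invariant by construction).
    """
    log = SelectionLog()
    lo, hi = variable_region
    kept: list[CatalogEntry] = []
    for entry in entries:
        if not analyzed:
            analyze_entry(entry)
        if len(entry.variant_positions) == 0:
            log.reasons["monomorphic"] += 1
        elif len(entry.variant_positions) > 1:
            log.reasons["multi_site"] += 1
        elif len(entry.variant_positions[entry.snp_pos]) != 2:
            log.reasons["multi_allelic"] += 1
        elif not lo <= entry.snp_pos < hi:
            log.reasons["remnant_variant"] += 1
        elif entry.n_genotyped < min_accessions:
            log.reasons["incomplete"] += 1
        else:
            kept.append(entry)

    all_acc = list(accessions) if accessions is not None else sorted(
        {acc for e in entries for acc in e.members}
    )
    calls = pd.DataFrame(
        MISSING,
        index=pd.Index([e.id for e in kept], name="locus_id"),
        columns=all_acc,
        dtype="int8",
    )
    for e in kept:
        for acc, g in e.genotypes.items():
            calls.at[e.id, acc] = g
    matrix = GenotypeMatrix(
        calls=calls,
        ref=pd.Series({e.id: e.ref for e in kept}).reindex(calls.index),
        alt=pd.Series({e.id: e.alt for e in kept}).reindex(calls.index),
        snp_pos=pd.Series({e.id: e.snp_pos for e in kept}).reindex(calls.index),
        consensus=pd.Series({e.id: e.seed_consensus for e in kept}).reindex(
            calls.index
        ),
        group_of=dict(group_of or {}),
        class_of_group=dict(class_of_group or {}),
    )
    return matrix, log


def titv_ratio(n_transitions: int, n_transversions: int) -> float | None:
    """Transition/transversion ratio; ``None`` when undefined."""
    if n_transversions == 0:
        return None
    return n_transitions / n_transversions


@dataclass
class SnpSummary:
    n_loci: int
    n_transitions: int
    n_transversions: int
    titv: float | None
    allele_pair_counts: dict[str, int]
    non_missing_by_accession: dict[str, int]
    het_by_accession: dict[str, int]

    @property
    def transition_fraction(self) -> float:
        return self.n_transitions / self.n_loci


def summarize_snps(matrix: GenotypeMatrix) -> SnpSummary:
    """Substitution-type and completeness summary of a genotype matrix."""
    if matrix.n_loci == 0:
        raise ValueError("empty genotype matrix")
    pairs = matrix.allele_pairs()
    types = [
        classify_substitution(*p.split("/")) for p in pairs
    ]
    ti = sum(t == "transition" for t in types)
    tv = len(types) - ti
    return SnpSummary(
        n_loci=matrix.n_loci,
        n_transitions=ti,
        n_transversions=tv,
        titv=titv_ratio(ti, tv),
        allele_pair_counts=dict(Counter(pairs)),
        non_missing_by_accession={
            a: int((matrix.calls[a] != MISSING).sum()) for a in matrix.accessions
        },
        het_by_accession={
            a: int((matrix.calls[a] == HET).sum()) for a in matrix.accessions
        },
    )
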