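"""Synthetic RAD-seq data generator with recorded ground truth.

Emulates a reduced-representation sequencing experiment on 18 diploid tea
accessions (9 cultivated, 8 wild, 1 admixed landrace) digested with EcoRI:
barcoded 50-nt single-end reads starting at the cut site, per-tag depths of
roughly 40-70x, sequencing errors, low-quality reads, repetitive high-depth
tags, missing accessions, and a subset of loci fixed in the cultivated group
but polymorphic in the wild group. Every stochastic choice is recorded in a
:class:`TruthTable` so downstream SNP discovery can be scored exactly.

Within each group, genotypes follow Hardy-Weinberg proportions at a
group-specific allele frequency drawn from a drifted Beta distribution
around a shared ancestral frequency; the Beta concentration is solved from
the group's requested heterozygosity so that realized per-accession
heterozygosity matches the target. The admixed accession draws one
haplotype from a cultivated-like and one from a wild-like frequency.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import DNA, revcomp

ECORI_SITE = "AATTC"
TAG_LENGTH = 41
VARIABLE_REGION = (5, 41)  # 0-based half-open window where variants may fall

#: transition partner for each base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: the 18 study accessions and their species groups
DEFAULT_GROUPS = {
    **{f"Css-{i}": "Css" for i in range(1, 7)},
    **{f"Csa-{i}": "Csa" for i in range(1, 4)},
    **{f"Ctl-{i}": "Ctl" for i in range(1, 4)},
    **{f"Ccc-{i}": "Ccc" for i in range(1, 5)},
    "Ctg": "Ctg",
    "Ctb": "Ctb",
}

#: cultivated / wild / admixed status of each group
DEFAULT_GROUP_CLASS = {
    "Css": "cultivated",
    "Csa": "cultivated",
    "Ctl": "wild",
    "Ccc": "wild",
    "Ctg": "wild",
    "Ctb": "admixed",
}

# Per-SNP heterozygosity targets per group, back-calculated from the
# printed per-species heterozygosity rates (1.7-5.2 per Kb over 41-nt
# tags => rate * 41 / 1000). The admixed entry is informational only: the
# landrace's heterozygosity emerges from drawing its haplotypes from two
# diverged parental frequencies.
DEFAULT_HET_RATES = {
    "Css": 0.168,
    "Csa": 0.152,
    "Ctl": 0.082,
    "Ccc": 0.098,
    "Ctg": 0.070,
    "Ctb": 0.213,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic RAD-seq experiment.

    Defaults reproduce the study conditions: 18 accessions in 6 groups,
    50-nt reads, 4-8-nt barcodes at pairwise Hamming distance >=2, ~40
    reads per tag per accession, substitution error rate 0.002.
    """

    group_of: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    class_of_group: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_CLASS)
    )
    n_fragments: int = 2000
    fragment_length: int = 300
    read_length: int = 50
    barcode_length_range: tuple[int, int] = (4, 8)
    mean_depth: float = 40.0
    #: negative-binomial size parameter; ``None`` gives the Poisson limit
    depth_dispersion: float | None = None
    error_rate: float = 0.002
    het_rate_by_group: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HET_RATES)
    )
    #: fraction of variant loci with the cultivated group planted as fixed
    fixed_cultivated_fraction: float = 0.042
    #: fraction of tags carrying a second variant (exercises the single-SNP filter)
    two_variant_fraction: float = 0.05
    repeat_fraction: float = 0.02
    repeat_copy_number: int = 10
    missing_rate: float = 0.05
    low_quality_read_fraction: float = 0.02
    low_quality_base_fraction: float = 0.6
    high_quality: int = 38
    low_quality: int = 2
    #: probability a planted substitution is a transition
    transition_fraction: float = 0.6
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    #: groups supplying the admixed accession's two haplotypes
    admixture_parents: tuple[str, str] = ("Csa", "Ctl")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "error_rate",
            "fixed_cultivated_fraction",
            "two_variant_fraction",
            "repeat_fraction",
            "missing_rate",
            "low_quality_read_fraction",
            "low_quality_base_fraction",
            "transition_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fragment_length <= self.read_length:
            raise ValueError("fragment_length must exceed read_length")
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be non-negative")
        for h in self.het_rate_by_group.values():
            if not 0.0 <= h <= 1.0:
                raise ValueError("heterozygosity rates must lie in [0, 1]")
        classes = set(self.class_of_group.values())
        if not {"cultivated", "wild"} <= classes:
            raise ValueError("groups must cover cultivated and wild classes")

    @property
    def accessions(self) -> list[str]:
        return list(self.group_of)

    def accessions_in_class(self, cls: str) -> list[str]:
        return [
            a
            for a, g in self.group_of.items()
            if self.class_of_group[g] == cls
        ]


@dataclass(frozen=True)
class Fragment:
    """One post-digestion reference fragment; repeats reference their source."""

    id: str
    sequence: str
    source: str | None = None  # original fragment id for repeat copies

    @property
    def is_repeat_copy(self) -> bool:
        return self.source is not None


@dataclass
class TruthTable:
    """Ground truth of a simulation: per-locus variants and true genotypes.

    ``loci`` has one row per variant-bearing tag (index = locus id) with the
    reference tag sequence, the primary variant's position and allele pair,
    flags for repeat origin / extra variants, the realized ``selected``
    status (cultivated accessions fixed for one allele while the wild group
    is polymorphic, both judged on non-missing genotypes) and ``clean``
    recoverability. ``genotypes`` holds two-character sorted allele strings
    ("AG" = heterozygote), with "" marking a planted-missing accession.
    """

    loci: pd.DataFrame
    genotypes: pd.DataFrame
    group_of: dict[str, str]
    class_of_group: dict[str, str]

    @property
    def accessions(self) -> list[str]:
        return list(self.genotypes.columns)

    def genotype_codes(self) -> pd.DataFrame:
        """Genotypes as alt-allele dosage codes {0, 1, 2}; -1 for missing."""
        ref = self.loci["ref"]
        alt = self.loci["alt"]
        codes = pd.DataFrame(
            -1, index=self.genotypes.index, columns=self.genotypes.columns, dtype="int8"
        )
        for locus in self.genotypes.index:
            r, a = ref[locus], alt[locus]
            row = self.genotypes.loc[locus]
            codes.loc[locus] = [
                -1 if g == "" else g.count(a) if set(g) <= {r, a} else -1
                for g in row
            ]
        return codes

    def to_tsv(self, loci_path, genotypes_path) -> None:
        self.loci.to_csv(loci_path, sep="\t")
        self.genotypes.to_csv(genotypes_path, sep="\t")


def make_barcode_set(
    n: int,
    length_range: tuple[int, int] = (4, 8),
    min_distance: int = 2,
    seed: int = 0,
    max_tries_per_barcode: int = 2000,
) -> list[str]:
    """Draw ``n`` inline barcodes of mixed lengths.

    Equal-length pairs are kept at Hamming distance >= ``min_distance`` so a
    single sequencing error cannot convert one barcode into another; across
    lengths no barcode is a prefix of another, and barcodes avoid the "AATT"
    motif so the barcode boundary cannot mimic the restriction-site remnant.
    Raises ``ValueError`` when no compliant set can be found.
    """
    if n < 1:
        raise ValueError("need n >= 1 barcodes")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"bad length range {length_range}")
    rng = np.random.default_rng(seed)
    lengths = itertools.cycle(range(lo, hi + 1))
    chosen: list[str] = []
    for _ in range(n):
        length = next(lengths)
        for _ in range(max_tries_per_barcode):
            cand = "".join(rng.choice(list(DNA), size=length))
            if "AATT" in cand:
                continue
            ok = True
            for other in chosen:
                if cand.startswith(other) or other.startswith(cand):
                    ok = False
                    break
                if len(other) == length and sum(
                    x != y for x, y in zip(cand, other)
                ) < min_distance:
                    ok = False
                    break
            if ok:
                chosen.append(cand)
                break
        else:
            raise ValueError(
                f"could not find {n} barcodes with lengths {length_range} "
                f"and pairwise distance >= {min_distance}"
            )
    return chosen


def generate_reference_fragments(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[Fragment]:
    """Random post-digestion fragments, each beginning with the AATTC remnant.

    A ``repeat_fraction`` subset of fragments is emitted in
    ``repeat_copy_number`` near-identical copies (differing only beyond the
    41-nt tag) to emulate repetitive genomic families whose pooled stack
    depth exceeds the repetitive-tag cut-off.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    fragments: list[Fragment] = []
    n_repeat = int(round(config.repeat_fraction * config.n_fragments))
    bases = np.array(list(DNA))
    body_len = config.fragment_length - len(ECORI_SITE)
    for i in range(config.n_fragments):
        body = "".join(rng.choice(bases, size=body_len))
        seq = ECORI_SITE + body
        frag_id = f"F{i:05d}"
        fragments.append(Fragment(frag_id, seq))
        if i < n_repeat:
            for j in range(config.repeat_copy_number - 1):
                # copies differ at two positions beyond the tag
                pos = rng.integers(TAG_LENGTH, len(seq), size=2)
                copy = list(seq)
                for p in pos:
                    copy[p] = rng.choice([b for b in DNA if b != copy[p]])
                fragments.append(
                    Fragment(f"{frag_id}r{j}", "".join(copy), source=frag_id)
                )
    return fragments


def _beta_concentration(het_rate: float, freq_range: tuple[float, float]) -> float:
    """Solve the drift concentration giving the requested HW het rate.

    With ancestral p ~ U(a, b) and group frequency f ~ Beta(p*tau,
    (1-p)*tau), E[2f(1-f)] = E[2p(1-p)] * tau / (tau + 1).
    """
    a, b = freq_range
    mean_p = (a + b) / 2.0
    mean_p2 = (a * a + a * b + b * b) / 3.0
    ceiling = 2.0 * (mean_p - mean_p2)
    if het_rate <= 0:
        return 0.0
    if het_rate >= ceiling:
        raise ValueError(
            f"het rate {het_rate} unattainable; ceiling {ceiling:.3f} "
            f"for ancestral frequencies in {freq_range}"
        )
    return het_rate / (ceiling - het_rate)


def _draw_group_freq(
    rng: np.random.Generator, p: float, tau: float
) -> float:
    if tau == 0.0:  # total drift: groups fix for one allele
        return 1.0 if rng.random() < p else 0.0
    return float(rng.beta(p * tau, (1.0 - p) * tau))


def plant_variants(
    fragments: list[Fragment],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Place bi-allelic variants on non-repeat fragments and draw genotypes.

    Exactly one variant per clean tag, falling inside the 36-nt variable
    window; a ``two_variant_fraction`` subset carries a second variant. A
    ``fixed_cultivated_fraction`` subset is planted with both cultivated
    groups fixed for the same allele while wild groups stay at intermediate
    frequencies. The realized ``selected`` flag is recomputed from the drawn
    genotypes, so drift-fixed loci are flagged on equal terms.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    accessions = config.accessions
    groups = sorted(set(config.group_of.values()))
    tau = {
        g: _beta_concentration(
            config.het_rate_by_group.get(g, 0.1), config.ancestral_freq_range
        )
        for g in groups
    }
    cultivated_groups = [
        g for g in groups if config.class_of_group[g] == "cultivated"
    ]
    parent_c, parent_w = config.admixture_parents

    originals = [f for f in fragments if not f.is_repeat_copy]
    repeat_sources = {f.source for f in fragments if f.is_repeat_copy}

    lo, hi = VARIABLE_REGION
    rows = []
    geno_rows = []
    locus_ids = []
    for frag in originals:
        if frag.id in repeat_sources:
            continue  # repeat families stay invariant
        locus_id = f"L{len(locus_ids):05d}"
        locus_ids.append(locus_id)
        n_var = 2 if rng.random() < config.two_variant_fraction else 1
        if hi - lo < n_var:
            raise ValueError("variable window too small for requested variants")
        positions = sorted(rng.choice(np.arange(lo, hi), size=n_var, replace=False))
        planted_selected = rng.random() < config.fixed_cultivated_fraction and n_var == 1

        # one fixed allele pair per variant
        variant_alleles: list[tuple[str, str]] = []
        for vpos in positions:
            vref = frag.sequence[int(vpos)]
            if rng.random() < config.transition_fraction:
                valt = _TRANSITION[vref]
            else:
                valt = rng.choice(
                    [b for b in DNA if b != vref and b != _TRANSITION[vref]]
                )
            variant_alleles.append((vref, valt))
        pos = int(positions[0])
        ref, alt = variant_alleles[0]

        # per-group alt-allele frequencies for each variant
        freqs_per_variant = []
        for k, vpos in enumerate(positions):
            p = float(rng.uniform(*config.ancestral_freq_range))
            freqs = {}
            for g in groups:
                if planted_selected and k == 0 and g in cultivated_groups:
                    continue  # set below
                freqs[g] = _draw_group_freq(rng, p, tau[g])
            if planted_selected and k == 0:
                fixed_allele_freq = float(rng.integers(0, 2))
                for g in cultivated_groups:
                    freqs[g] = fixed_allele_freq
                # wild groups re-drawn around a mid-range ancestral
                # frequency, still through each group's drift law
                wild_groups = [
                    g for g in groups if config.class_of_group[g] == "wild"
                ]
                p_wild = float(rng.uniform(0.3, 0.7))
                for g in wild_groups:
                    freqs[g] = _draw_group_freq(rng, p_wild, tau[g])
            freqs_per_variant.append(freqs)

        # draw genotypes per accession (two haplotypes; HW within group)
        missing = rng.random(len(accessions)) < config.missing_rate
        geno = {}
        hap_alleles: dict[str, tuple[str, ...]] = {}
        for ai, acc in enumerate(accessions):
            g = config.group_of[acc]
            per_variant = []
            for k, vpos in enumerate(positions):
                freqs = freqs_per_variant[k]
                if config.class_of_group[g] == "admixed":
                    f1, f2 = freqs[parent_c], freqs[parent_w]
                else:
                    f1 = f2 = freqs[g]
                h1 = rng.random() < f1
                h2 = rng.random() < f2
                per_variant.append((h1, h2))
            if missing[ai]:
                geno[acc] = ""
                continue
            h1_primary, h2_primary = per_variant[0]
            pair = "".join(
                sorted((alt if h1_primary else ref, alt if h2_primary else ref))
            )
            geno[acc] = pair
            # haplotype sequences carry every variant
            hap = [list(frag.sequence), list(frag.sequence)]
            for k, vpos in enumerate(positions):
                _, valt = variant_alleles[k]
                h1k, h2k = per_variant[k]
                if h1k:
                    hap[0][int(vpos)] = valt
                if h2k:
                    hap[1][int(vpos)] = valt
            hap_alleles[acc] = ("".join(hap[0]), "".join(hap[1]))

        present = [a for a in accessions if geno[a] != ""]
        cult = [
            a for a in present if config.class_of_group[config.group_of[a]] == "cultivated"
        ]
        wild = [
            a for a in present if config.class_of_group[config.group_of[a]] == "wild"
        ]
        cult_fixed = (
            len(cult) >= 3
            and len({geno[a] for a in cult}) == 1
            and geno[cult[0]][0] == geno[cult[0]][1]
        )
        wild_poly = len(wild) >= 3 and len({geno[a] for a in wild}) > 1
        selected = bool(cult_fixed and wild_poly)
        polymorphic = len({geno[a] for a in present}) > 1
        clean = bool(
            n_var == 1 and len(present) >= 14 and polymorphic
        )
        rows.append(
            {
                "fragment_id": frag.id,
                "tag": frag.sequence[:TAG_LENGTH],
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "n_variants": n_var,
                "all_positions": ",".join(str(int(p)) for p in positions),
                "planted_selected": planted_selected,
                "selected": selected,
                "clean": clean,
                "n_present": len(present),
                "haplotypes": hap_alleles,
            }
        )
        geno_rows.append(geno)

    loci = pd.DataFrame(rows, index=pd.Index(locus_ids, name="locus_id"))
    genotypes = pd.DataFrame(geno_rows, index=loci.index, columns=accessions).fillna("")
    return TruthTable(
        loci=loci,
        genotypes=genotypes,
        group_of=dict(config.group_of),
        class_of_group=dict(config.class_of_group),
    )


@dataclass
class ReadSet:
    """Simulated reads plus the per-(fragment, accession) draw ledger."""

    reads: list[tuple[str, str, str]]  # (name, sequence, quality)
    counts: dict[tuple[str, str], int]

    def __iter__(self):
        return iter(self.reads)

    def __len__(self):
        return len(self.reads)


def _draw_depth(rng: np.random.Generator, config: SimulationConfig) -> int:
    if config.depth_dispersion is None:
        return int(rng.poisson(config.mean_depth))
    size = config.depth_dispersion
    p = size / (size + config.mean_depth)
    return int(rng.negative_binomial(size, p))


def simulate_rad_reads(
    truth: TruthTable,
    fragments: list[Fragment],
    barcodes: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Emit barcoded 50-nt reads for every fragment x accession.

    Per cell the read count follows the configured depth law; heterozygotes
    split reads binomially between their two haplotypes. Substitution
    errors hit each base independently at ``error_rate``; a
    ``low_quality_read_fraction`` tail of reads receives >50% of bases at
    the low quality score to exercise the quality filter (base errors and
    quality are modelled independently). Reads are already oriented: RAD
    reads start at the cut site.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    missing_acc = set(barcodes) - set(config.accessions)
    if missing_acc:
        raise ValueError(f"barcodes for unknown accessions: {sorted(missing_acc)}")
    if set(config.accessions) - set(barcodes):
        raise ValueError("every accession needs a barcode")

    frag_by_id = {f.id: f for f in fragments}
    loci_by_fragment = {
        row.fragment_id: locus_id for locus_id, row in truth.loci.iterrows()
    }
    hq = chr(config.high_quality + 33)
    lq = chr(config.low_quality + 33)
    L = config.read_length
    hq_qual = hq * L
    n_low = int(math.ceil(config.low_quality_base_fraction * L))
    base_arr = np.frombuffer(DNA.encode(), dtype=np.uint8)

    reads: list[tuple[str, str, str]] = []
    counts: dict[tuple[str, str], int] = {}
    counter = 0
    for frag in fragments:
        locus_id = loci_by_fragment.get(frag.id)
        for acc in config.accessions:
            bc = barcodes[acc]
            prefix_len = L - len(bc)
            if locus_id is not None:
                geno = truth.genotypes.at[locus_id, acc]
                if geno == "":
                    continue  # planted missing: no library molecules
                haps = truth.loci.at[locus_id, "haplotypes"][acc]
            else:
                haps = (frag.sequence, frag.sequence)
            n = _draw_depth(rng, config)
            counts[(frag.id, acc)] = n
            if n == 0:
                continue
            n1 = int(rng.binomial(n, 0.5)) if haps[0] != haps[1] else n
            for hap_seq, n_h in ((haps[0], n1), (haps[1], n - n1)):
                if n_h <= 0:
                    continue
                template = bc + hap_seq[:prefix_len]
                n_err = rng.binomial(L, config.error_rate, size=n_h)
                lowq = rng.random(n_h) < config.low_quality_read_fraction
                for i in range(n_h):
                    seq = template
                    if n_err[i]:
                        pos = rng.choice(L, size=n_err[i], replace=False)
                        s = bytearray(seq.encode())
                        for p_ in pos:
                            choices = base_arr[base_arr != s[p_]]
                            s[p_] = rng.choice(choices)
                        seq = s.decode()
                    if lowq[i]:
                        qual = np.full(L, hq, dtype="<U1")
                        qual[rng.choice(L, size=n_low, replace=False)] = lq
                        qual = "".join(qual)
                    else:
                        qual = hq_qual
                    reads.append((f"read{counter:08d}", seq, qual))
                    counter += 1
    return ReadSet(reads=reads, counts=counts)


def generate_toy_transcriptome(
    truth: TruthTable,
    n_embedded: int = 60,
    coding_fraction: float = 0.7,
    reverse_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Embed a subset of variant tags in synthetic transcripts.

    Stand-in for a real transcriptome reference: each chosen locus's 36-nt
    variable region (reference alleles) is embedded in one transcript,
    half of them reverse-complemented, and a CDS interval is placed so that
    ``coding_fraction`` of the variants fall inside a codon. Returns
    ``(transcripts, cds_table, effect_truth)`` where ``effect_truth``
    records each embedded variant's true effect computed by direct codon
    translation; loci not embedded are recorded as ``unmapped``.
    """
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)
    lo, hi = VARIABLE_REGION
    candidates = [
        locus
        for locus, row in truth.loci.iterrows()
        if row["n_variants"] == 1
    ]
    n_embedded = min(n_embedded, len(candidates))
    chosen = list(rng.choice(candidates, size=n_embedded, replace=False))

    transcripts: dict[str, str] = {}
    cds_rows = []
    effect_rows = []
    for t_idx, locus in enumerate(chosen):
        row = truth.loci.loc[locus]
        region = row["tag"][lo:hi]
        snp_in_region = row["pos"] - lo
        strand = "-" if rng.random() < reverse_fraction else "+"
        embedded = revcomp(region) if strand == "-" else region
        utr5 = "".join(rng.choice(list(DNA), size=int(rng.integers(12, 40))))
        utr3 = "".join(rng.choice(list(DNA), size=int(rng.integers(12, 40))))
        tx_seq = utr5 + embedded + utr3
        tx_id = f"TX{t_idx:04d}"
        offset = len(utr5)
        if strand == "+":
            t_pos = offset + snp_in_region
            ref_t, alt_t = row["ref"], row["alt"]
        else:
            t_pos = offset + (len(region) - 1 - snp_in_region)
            ref_t, alt_t = revcomp(row["ref"]), revcomp(row["alt"])

        coding = rng.random() < coding_fraction
        if coding:
            # CDS covering the variant, codon-aligned to cds_start
            max_back = min(t_pos, 9)
            cds_start = t_pos - int(rng.integers(0, max_back + 1))
            n_codons = (len(tx_seq) - cds_start) // 3
            # keep the variant inside and trim to whole codons
            need = (t_pos - cds_start) // 3 + 1
            n_codons = max(need, min(n_codons, need + int(rng.integers(0, 4))))
            cds_end = cds_start + 3 * n_codons
            if cds_end > len(tx_seq):
                tx_seq = tx_seq + "".join(
                    rng.choice(list(DNA), size=cds_end - len(tx_seq))
                )
            codon_idx = (t_pos - cds_start) // 3
            codon_start = cds_start + 3 * codon_idx
            codon_ref = tx_seq[codon_start : codon_start + 3]
            within = t_pos - codon_start
            codon_alt = (
                codon_ref[:within] + alt_t + codon_ref[within + 1 :]
            )
            aa_ref = str(Seq(codon_ref).translate())
            aa_alt = str(Seq(codon_alt).translate())
            effect = "synonymous" if aa_ref == aa_alt else "non_synonymous"
        else:
            # place the CDS wholly after the variant
            cds_start = t_pos + 1 + int(rng.integers(0, 4))
            n_codons = max(1, (len(tx_seq) - cds_start) // 3)
            cds_end = cds_start + 3 * n_codons
            if cds_end > len(tx_seq):
                tx_seq = tx_seq + "".join(
                    rng.choice(list(DNA), size=cds_end - len(tx_seq))
                )
            effect = "non_coding"
        transcripts[tx_id] = tx_seq
        cds_rows.append(
            {"transcript_id": tx_id, "cds_start": cds_start, "cds_end": cds_end, "frame": 0}
        )
        effect_rows.append(
            {
                "locus_id": locus,
                "transcript_id": tx_id,
                "strand": strand,
                "offset": offset,
                "effect": effect,
            }
        )
    for locus in truth.loci.index:
        if locus not in set(chosen):
            effect_rows.append(
                {
                    "locus_id": locus,
                    "transcript_id": None,
                    "strand": None,
                    "offset": None,
                    "effect": "unmapped",
                }
            )
    cds_table = pd.DataFrame(cds_rows).set_index("transcript_id")
    effect_truth = pd.DataFrame(effect_rows).set_index("locus_id")
    return transcripts, cds_table, effect_truth


@dataclass
class SimulatedDataset:
    """Bundle of one simulation: reference, truth, barcodes and reads."""

    config: SimulationConfig
    fragments: list[Fragment]
    truth: TruthTable
    barcodes: dict[str, str]
    reads: ReadSet


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: fragments -> variants -> barcodes -> reads."""
    rng = np.random.default_rng(config.seed)
    fragments = generate_reference_fragments(config, rng)
    truth = plant_variants(fragments, config, rng)
    barcodes = dict(
        zip(
            config.accessions,
            make_barcode_set(
                len(config.accessions),
                config.barcode_length_range,
                seed=config.seed + 3,
            ),
        )
    )
    reads = simulate_rad_reads(truth, fragments, barcodes, config, rng)
    return SimulatedDataset(config, fragments, truth, barcodes, reads)
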